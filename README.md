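# fallowsim

Agent-based simulation of voluntary farmland-conservation enrollment with
quantitative uncertainty analysis (UA) and variance-based sensitivity
analysis (SA).

## The problem

The U.S. Conservation Reserve Program (CRP) pays farmers to retire
environmentally sensitive cropland for at least ten years. How much land
ends up fallow emerges from many interacting, uncertain ingredients:
farmers' willingness to enroll (retirement status, production value, land
tenure, imitation of enrolled neighbors, and their attitude to risk), the
sites and fraction of a parcel they offer, the voluntary bid that
discounts their payment, and the agency's annual ranking and acceptance of
offers. `fallowsim` is for modelers who want to treat such an agent-based
model (ABM) not as a black box but as a quantified object: propagate the
input uncertainty to the output distribution, decompose the output
variance factor by factor, and derive defensible simplified models.

## The method

Nine uncertain factors are sampled from their probability distributions
through inverse CDFs on quasi-random (Sobol') points arranged in a
Saltelli radial design: base matrices A, B and cross matrices
A_B^(i), B_A^(i), totalling N(2k+2) model runs for k free factors. Each
run simulates ten annual signup cycles — willingness via ordered weighted
averaging (OWA) of four criteria against the 0.87 enrollment threshold,
site ranking by distance-to-water, distance-to-forest and slope, offer
pricing from soil rental rates discounted by the bid, and agency selection
of the top *n* offers by a cost- and bid-adjusted environmental-benefits
score — and reports the final fallow area *Y*. From the evaluated blocks
the package estimates, for each factor *i*,

* the first-order index `S_i = V_i / V` (Saltelli cross-block estimator),
* the total-effect index `ST_i = 1 − VC_i / V` (Jansen estimator),
* the interaction share `I = 1 − ΣS`,

with bootstrap standard errors. Two simplification procedures build on
this: the **exploratory** model fixes every negligible factor (S and ST
below threshold) at its median, preserving the output distribution; the
**explanatory** model fixes the single most influential factor at its
support midpoint, shrinking the variance around an unchanged mean.

A seeded synthetic-landscape generator (Voronoi parcel mosaic, smoothed
random fields for slope, soil rent and six correlated benefit-index
layers in the 50–350 point range) makes the whole pipeline runnable and
testable without any external GIS data.

## Worked example

`python examples/06_experiment_pipeline.py` runs the full pipeline at a
reduced base sample (N = 64, 1280 runs) on the default 200×200-cell
synthetic landscape and prints:

```
baseline: 1280 runs, mean fallow area 298 units, variance 967715
 rank     factor       S     ST  negligible
    1        OWA  1.2221 2.0888       False
    ...
    9       LAND -0.0199 0.9193       False

exploratory model keeps ('PRODUCTION', 'OWA', 'LAND'); paired variance ratio 0.998, mean shift -17.6
explanatory model fixes OWA=8; spread reduction 100%, mean shift -298.5
```

Reading: the mean fallow area is ~298 map units (one unit = one 30 m cell
≈ 0.2224 acres). The farmers' decision rule (OWA) dominates the output
variance — on this synthetic system only the most OR-like (risk-taking)
rules push willingness past the 0.87 threshold, so the output switches
between an active and an inactive regime; its S estimate overshoots 1
through Monte-Carlo noise at this small base sample (the bootstrap SE is
reported alongside). Fixing the negligible factors leaves the
distribution essentially unchanged (variance ratio 0.998 on a paired
comparison), while fixing the dominant rule factor at its central
(neutral) rule collapses enrollment entirely — a diagnostic that the
dominant factor here acts as a regime switch rather than a smooth dial.
Other examples in `examples/` demonstrate each capability separately, and
the `abm-uasa` CLI (`synth`, `run`, `sa`, `experiment`, `compare`) wraps
the same functions for shell use.

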