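# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `fallowsim`, and what the synthetic test system does
and does not show about real landscapes.

## 1. The enrollment model

One farmer agent owns each farmland parcel of a raster landscape. Every
simulated year, each not-yet-enrolled agent aggregates four propensity
criteria, each oriented so that larger means more willing to enroll:

| criterion | definition | source of heterogeneity |
|---|---|---|
| retirement | 1 − retirement code (1 if retired) | per-agent draw |
| production | 1 − normalized production value | per-agent draw |
| tenure | ratio of owned to operated acres | per-agent draw |
| enrollment density | enrolled / all neighbors within radius DE | simulation state |

Aggregation uses ordered weighted averaging (OWA): criteria are sorted in
descending order and dotted with a rule-specific weight vector. The 17
rules are generated by the quantifier Q(r) = r^α with
α ∈ {1/9, 1/7, 1/5, 1/4, 1/3, 1/2, 2/3, 4/5, 1, 5/4, 3/2, 2, 3, 4, 5, 7, 9},
indexed 0..16 by strictly descending orness: index 0 is the most OR-like
(risk-taking; orness 0.92), index 8 the neutral arithmetic mean, index 16
the most AND-like (risk-averse). An agent offers land when its OWA
willingness reaches the empirically derived threshold 0.87.

A willing agent ranks the eligible (crop or pasture) cells of its parcel
by the mean of three within-parcel ranks — distance to water ascending,
distance to forest ascending, slope descending (erodible land near water
and forest first; ties broken by cell index) — and offers the first
⌈LAND · m⌉ cells. The offer's annual payment is the soil-rental-rate sum
over the sites times the cell acreage; the discounted annual payment is
DAP = payment · (1 − BID). The agency scores each offer as

    score = EBI_mean + (BID / 0.16) · 150 − (DAP / DAP_max) · 125

(point constants configurable; a maximal bid earns 150 benefit-index
points, the most expensive offer loses 125) and accepts the top *n* per
year, ties resolved by lower DAP then lower agent id. Accepted sites
convert to fallow; enrollment is absorbing over the ten-year horizon.
The scalar output is the final fallow area, in 30 m map units
(1 unit = cell_size²/4046.8564 acres).

### Factor-to-population mapping and determinism

The nine uncertain inputs are exactly the coordinates of the sensitivity
design. Six act run-wide through their inverse CDFs (DE, OWA, LAND, BID,
EBI, n). The three demographic factors act as *population quantile
shifts*: agent *a* draws its attribute at
u_a = frac(u_factor + φ · perm(a)), with φ the golden-ratio fraction and
`perm` a permutation of agent ids derived deterministically from
(master_seed, factor index). Consequences:

* the model is a pure function of (landscape, factor row, master seed) —
  a design row can be replayed bit-for-bit;
* the agent population follows the empirical marginals almost exactly at
  any population size (the quantile set is a low-discrepancy sequence);
* the factor coordinate shifts all agents' quantiles coherently, keeping
  the input space nine-dimensional;
* *fixing* a demographic factor freezes its shift coordinate (at the CDF
  midpoint of the fixed value). The population stays heterogeneous; only
  the factor's run-to-run variability is removed. Collapsing every agent
  to the fixed value instead would, e.g. for the production factor's
  median, zero one criterion for the whole population and extinguish
  enrollment — which is not what fixing a negligible factor means.

Discrete inverse CDFs use right-open cumulative intervals (u ∈ [0, p₁)
maps to the first value), so boundaries are deterministic; the open lower
bound of LAND's (0, 1] support is realized by an ε = 1e-12 offset. The
zero-mass atom of the production distribution is kept in the spec for
fidelity to the source table but can never be drawn.

## 2. Design and estimators

Sampling uses the unscrambled Sobol' sequence (scipy's direction numbers)
with the all-zeros point skipped; determinism and exact reproducibility
across machines were preferred to the variance benefits of scrambling.
The radial design draws N points in 2k dimensions; columns 1..k form A,
columns k+1..2k form B, and for each factor both cross matrices AB_i and
BA_i are built — the 2k+2 scheme, N(2k+2) rows total. Base sample
N = 128 is the default: it is the unique value consistent with all three
reference experiment sizes (2560, 1536, 2304 runs at k = 9, 5, 8).

With centered outputs (centering makes the estimators exactly invariant
under affine rescaling of Y and lowers their variance):

* V_i is estimated by the Saltelli cross-block form
  mean(f_B · (f_AB_i − f_A)), averaged with its mirror
  mean(f_A · (f_BA_i − f_B));
* V − VC_i by the Jansen form mean((f_A − f_AB_i)²)/2, likewise averaged
  over both radial directions;
* V and the mean come from the pooled A∪B outputs (population variance).

Uncertainty summaries (mean, unbiased variance, quantiles, histogram) use
the plain quasi-Monte-Carlo sample A∪B; cross blocks enter only the index
estimators. Monte-Carlo error is quantified by bootstrap over base-sample
indices (default 200–500 resamples; degenerate all-constant resamples,
possible at small N with a mostly-zero output, are skipped with a warning
when they dominate). Negative index estimates are reported as-is —
clipping would mask an insufficient base sample. A factor is *negligible*
when both S and ST fall below a threshold (default 0.01).

### Comparing experiments: paired evaluation

Model-simplification claims ("the simplified model has the same mean and
variance") are tested with common random numbers: the simplified model is
evaluated at the baseline's own A∪B points (restricted to the shared free
coordinates), so integration error cancels and the comparison isolates
the effect of fixing factors. This matters here: with a heavy-tailed,
mostly-zero output, variance estimates from two *independent*
low-discrepancy designs of different dimension carry systematic
integration errors of tens of percent at desk-scale N, which a naive
ratio would misread as a model difference. In the paired comparison the
mean check uses the Monte-Carlo standard error of the experiment mean
(std/√n), the precision at which the experiment itself knows its mean.

## 3. The synthetic landscape

`generate_landscape(config, seed)` is deterministic in both arguments.
Water and forest are contiguous patches from thresholded
Gaussian-smoothed noise fields (defaults 4% and 18% of cells); the
remaining farmland is tessellated into Voronoi parcels around randomly
chosen seed cells (default 300 parcels on a 200×200 grid of 30 m cells;
a full-scale profile with 2687 parcels on ~985 km² is provided). Parcels
are assigned crop or pasture greedily toward a 30%-pasture area share
(class proportions land within ±2 points of the configuration); a 3%
speckle of ineligible cells never touches parcel seed cells, so every
parcel keeps at least one eligible cell. Slope, soil productivity and the
benefit components are further smoothed fields; the soil rental rate is
productivity × a single county cash-rent constant (default $110/acre/yr,
±40% relief) — one constant preserves the mechanism without reproducing
any particular county's derivation.

The six environmental-benefit-index composites are built as
w₁·N1_i + w₂·N2_j + w₃·N3 over 3 × 2 × 1 standardized component variants
and rescaled by a common affine map into [50, 350] points. Sharing
components makes all pairwise correlations positive; with weights
(0.75, 0.5, 1.0) the measured correlations fall in the target
0.35–0.89 band across seeds. The band is a generator *target* exposed in
the configuration, not a hard invariant.

What the synthetic system does not emulate: real parcel size and shape
distributions, spatially structured soil–slope–hydrology dependence,
and any actual geography. Tests passing on it validate the mechanisms
and the estimation machinery, not predictions for a real region.

## 4. Behavior of the synthetic study system

Under the survey-derived factor distributions and the quantifier rule set,
only the most OR-like decision rules (indices 0–3 of 17) ever push
willingness past the 0.87 threshold: the top OWA weight at index 0 is
0.857, so even a maximal single criterion cannot clear the threshold
alone, and offer pools shrink rapidly toward the AND side. Three
consequences, all honest properties of this system rather than artifacts:

* the rule factor dominates the output variance (S ≈ 0.8–1.0 with a wide
  bootstrap band) because the output switches between an active and an
  inactive regime;
* the offer cap *n* is nearly inert at desk scale — willing-farmer pools
  exhaust within the ten-year horizon, so the cap changes the timing but
  not the total of enrollment (it binds, and becomes influential, only
  when pools exceed ~10·n, i.e. at much larger parcel counts);
* the *explanatory* refinement — fix the top-S factor at its support
  midpoint — pins OWA at the neutral rule, where no agent enrolls. The
  refined model's variance collapses (consistent with the procedure's
  variance goal) but its mean drops to zero instead of being preserved.
  Mean preservation under this procedure presumes a dominant factor that
  acts like a smooth dial (as an offer cap does in a competitive,
  oversubscribed regime); a categorical regime-switch factor violates
  that premise. The corresponding acceptance test is kept faithful to the
  stated property and documents this as a red finding; the package's
  diagnostics (paired mean shift alongside the spread reduction) surface
  the situation directly.

The exploratory simplification behaves as intended: factors flagged
negligible at the default threshold are genuinely inert here (the bid
cancels out of the agency score when it is run-wide, the benefit-layer
choice reshuffles ranks without changing totals, and the demographic
shifts act on an equidistributed population), so fixing them leaves the
paired variance ratio within a few percent of 1.

## 5. Problem sizes and tolerances

Defaults used by the test suite and acceptance script, chosen once as
desk-scale study conditions: 200×200 cells, 300 parcels, N = 128 baseline
(2560 runs, seconds on one CPU), estimator validation at N = 2^12–2^13 on
the g-function and Ishigami benchmarks (recovering closed-form indices
within ±0.02), exact-oracle agreement on small discrete models within 3×
bootstrap SE, paired variance-equivalence band ±15%, mean-equivalence
band 2× the Monte-Carlo SE of the mean. Known limitations: no contract
expiry or re-enrollment, no crop-price dynamics, a single scalar output
(no spatial-pattern metrics), run-wide bid and land-fraction factors, and
first-order/total-effect indices only (no pairwise decomposition).
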