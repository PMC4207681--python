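"""Agent-based simulator of voluntary conservation enrollment.

One farmer agent per parcel decides each year whether to offer part of its
parcel for conservation.  Willingness is an ordered-weighted-averaging
(OWA) aggregation of four propensity criteria — retirement status, (low)
production value, tenure, and the local enrollment density — against a
fixed threshold of 0.87.  Willing agents rank their eligible cells by
erodibility-style criteria (near water, near forest, steep first), offer
the first fraction of them, price the offer from the soil rental rate and
discount it by a voluntary bid.  The program agency ranks offers by an
environmental-benefit score adjusted for cost and bid and accepts the top
``n`` each year; accepted land converts to fallow and stays converted for
the whole ten-year horizon.  The scalar model output is the total fallow
area at the end of the run.

Determinism contract: a run is a pure function of (landscape, factor
values, master_seed).  Agent-level draws of the three demographic factors
use a golden-ratio quantile shift: agent ``a`` samples its factor at
``frac(u_factor + phi*perm(a))`` where ``perm`` is a permutation of agent
ids derived (counter-based) from (master_seed, factor index).  The
sensitivity design therefore sees a noiseless model, the agent population
follows the empirical distributions almost exactly (the quantile set is a
low-discrepancy sequence), and the factor coordinate shifts the whole
population coherently.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .factors import FactorSpec, inverse_cdf, inverse_cdf_array, free_factors
from .landscape import (
    Landscape,
    LandUse,
    area_in_acres,
    eligibility_mask,
)

__all__ = [
    "GOLDEN_FRAC",
    "WILLINGNESS_THRESHOLD",
    "OWA_ALPHAS",
    "FarmerAgent",
    "Offer",
    "SimulationResult",
    "FsaScoring",
    "RunFactors",
    "PreparedLandscape",
    "owa_weights",
    "orness",
    "owa_aggregate",
    "enrollment_density",
    "willingness",
    "select_sites",
    "build_offer",
    "fsa_select",
    "step_year",
    "run_simulation",
    "resolve_run_factors",
    "make_model",
    "area_in_acres",
]

#: fractional part of the golden ratio, used for the per-agent quantile shift
GOLDEN_FRAC = (math.sqrt(5.0) - 1.0) / 2.0

#: empirically derived enrollment threshold on OWA willingness
WILLINGNESS_THRESHOLD = 0.87

#: quantifier exponents of the 17 decision rules, ordered by descending
#: orness: index 0 (alpha=1/9) is the most OR-like / risk-taking rule,
#: index 8 (alpha=1) the neutral average, index 16 (alpha=9) the most
#: AND-like / risk-averse.
OWA_ALPHAS = (
    1 / 9, 1 / 7, 1 / 5, 1 / 4, 1 / 3, 1 / 2, 2 / 3, 4 / 5,
    1, 5 / 4, 3 / 2, 2, 3, 4, 5, 7, 9,
)

_N_CRITERIA = 4

#: canonical names of the per-agent demographic factors
DEMOGRAPHIC_FACTORS = ("RETIREMENT", "PRODUCTION", "TENURE")


def owa_weights(rule_index: int) -> np.ndarray:
    """Weight vector of decision rule ``rule_index`` (0..16).

    Weights come from the regular increasing monotone quantifier
    Q(r) = r**alpha: w_i = Q(i/4) - Q((i-1)/4), applied to the criteria
    sorted in descending order.  Small alpha front-loads weight on the
    largest criterion (OR-like), large alpha on the smallest (AND-like).
    """
    if not 0 <= rule_index < len(OWA_ALPHAS):
        raise IndexError(f"rule_index {rule_index} outside 0..{len(OWA_ALPHAS) - 1}")
    a = OWA_ALPHAS[rule_index]
    grid = np.arange(_N_CRITERIA + 1) / _N_CRITERIA
    q = grid**a
    return np.diff(q)


def orness(weights: Sequence[float]) -> float:
    """Position of an OWA operator on the OR(1)..AND(0) spectrum."""
    w = np.asarray(weights, dtype=float)
    m = w.size
    return float(np.sum(w * (m - 1 - np.arange(m))) / (m - 1))


def owa_aggregate(criteria: Sequence[float], weights: Sequence[float]) -> float:
    """OWA aggregation: dot product of descending-sorted criteria with the
    rule's weights.  Criteria must lie in [0, 1]."""
    c = np.asarray(criteria, dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError(f"criteria outside [0, 1]: {c!r}")
    w = np.asarray(weights, dtype=float)
    if c.shape != w.shape:
        raise ValueError("criteria and weights must have equal length")
    return float(np.sort(c)[::-1] @ w)


@dataclass
class FarmerAgent:
    """One farmer, bound to one parcel."""

    agent_id: int
    parcel_id: int
    retirement: int  # 0 retired, 1 working
    production: float  # normalized [0, 1]
    tenure: float  # ratio of owned to operated acres, [0, 1]
    enrolled: bool = False
    centroid: tuple = (0.0, 0.0)  # (row, col) in meters


@dataclass
class Offer:
    """A farmer's enrollment bid for a subset of its parcel."""

    agent_id: int
    sites: np.ndarray  # flat cell indices
    area_units: int
    annual_payment: float  # $/yr
    bid: float  # fraction of payment voluntarily given up
    dap: float  # discounted annual payment, payment*(1-bid)
    ebi_score: float  # mean benefit-index points over the sites

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=np.int64)
        if self.area_units != self.sites.size or self.area_units < 1:
            raise ValueError("area_units must equal the number of sites (>= 1)")
        if not math.isclose(self.dap, self.annual_payment * (1 - self.bid)):
            raise ValueError("dap must equal annual_payment*(1-bid)")


@dataclass(frozen=True)
class FsaScoring:
    """Agency offer-scoring constants, on the benefit-index point scale.

    score = ebi + (bid/bid_max)*bid_points - (dap/dap_max)*cost_points,
    where dap_max is the largest discounted payment among the offers under
    review.  A maximal bid earns ``bid_points`` points; the most expensive
    offer loses ``cost_points``.
    """

    bid_points: float = 150.0
    bid_max: float = 0.16
    cost_points: float = 125.0


@dataclass
class SimulationResult:
    """Outcome of one ten-year run."""

    landuse: np.ndarray
    accepted_per_year: list
    converted_units_per_year: list
    area_units: int
    area_acres: float
    years: int
    master_seed: int
    factor_values: dict


class PreparedLandscape:
    """Static per-parcel structures shared across runs on one landscape.

    For every parcel: its eligible cells pre-ordered by the site-selection
    composite rank, prefix sums of soil rental rate and of each benefit
    layer along that order, the parcel centroid, and a cached neighbor
    graph per neighborhood radius.  All of this depends only on the
    landscape, so a sensitivity experiment prepares it once.
    """

    def __init__(self, landscape: Landscape):
        self.landscape = landscape
        ls = landscape
        self.cell_acres = ls.cell_acres
        elig = eligibility_mask(ls.landuse)
        pid = ls.parcel_id
        self.n_agents = int(pid.max())
        rows, cols = ls.shape

        flat_pid = pid.ravel()
        order = np.argsort(flat_pid, kind="stable")
        flat_sorted = flat_pid[order]
        starts = np.searchsorted(flat_sorted, np.arange(1, self.n_agents + 2))

        dw = ls.dist_water.ravel()
        df = ls.dist_forest.ravel()
        sl = ls.slope.ravel()
        srr = ls.srr.ravel()
        ebi = ls.ebi_layers.reshape(ls.ebi_layers.shape[0], -1)
        el = elig.ravel()

        self.site_order: list[np.ndarray] = []
        self.srr_prefix: list[np.ndarray] = []
        self.ebi_prefix: list[np.ndarray] = []  # each (n_layers, m+1)
        centroids = np.empty((self.n_agents, 2))
        for a in range(self.n_agents):
            cells = order[starts[a] : starts[a + 1]]
            rc = np.column_stack(np.unravel_index(cells, (rows, cols)))
            centroids[a] = rc.mean(axis=0) * ls.cell_size
            ecells = cells[el[cells]]
            ranked = rank_cells(dw[ecells], df[ecells], sl[ecells], ecells)
            self.site_order.append(ranked)
            self.srr_prefix.append(
                np.concatenate([[0.0], np.cumsum(srr[ranked])])
            )
            self.ebi_prefix.append(
                np.concatenate(
                    [np.zeros((ebi.shape[0], 1)), np.cumsum(ebi[:, ranked], axis=1)],
                    axis=1,
                )
            )
        self.centroids = centroids
        self.eligible_count = np.array([s.size for s in self.site_order])
        self._tree = cKDTree(centroids)
        self._neighbor_cache: dict[float, list[np.ndarray]] = {}

    def neighbors(self, radius: float) -> list[np.ndarray]:
        """Agent indices within ``radius`` meters of each agent's parcel
        centroid, excluding the agent itself."""
        radius = float(radius)
        cached = self._neighbor_cache.get(radius)
        if cached is None:
            raw = self._tree.query_ball_point(self.centroids, r=radius)
            cached = [
                np.array([j for j in nb if j != a], dtype=np.int64)
                for a, nb in enumerate(raw)
            ]
            self._neighbor_cache[radius] = cached
        return cached

    def neighbor_arrays(self, radius: float) -> tuple:
        """Flattened neighbor graph: (owner agent per edge, neighbor per
        edge, neighbor count per agent) — lets densities be computed with
        one bincount."""
        key = ("flat", float(radius))
        cached = self._neighbor_cache.get(key)
        if cached is None:
            nbs = self.neighbors(radius)
            counts = np.array([nb.size for nb in nbs], dtype=np.int64)
            owners = np.repeat(np.arange(self.n_agents), counts)
            flat = (
                np.concatenate(nbs) if counts.sum() else np.empty(0, dtype=np.int64)
            )
            cached = (owners, flat, counts)
            self._neighbor_cache[key] = cached
        return cached


def rank_cells(
    dist_water: np.ndarray,
    dist_forest: np.ndarray,
    slope: np.ndarray,
    cell_ids: np.ndarray,
) -> np.ndarray:
    """Order cells for site selection: ascending composite of the three
    within-parcel ranks (distance to water ascending, distance to forest
    ascending, slope descending), ties broken by cell id."""
    cell_ids = np.asarray(cell_ids, dtype=np.int64)
    if cell_ids.size == 0:
        return cell_ids
    composite = (
        rankdata(dist_water) + rankdata(dist_forest) + rankdata(-np.asarray(slope))
    ) / 3.0
    order = np.lexsort((cell_ids, composite))
    return cell_ids[order]


def select_sites(
    parcel_cells: Sequence[int],
    fraction: float,
    dist_water: np.ndarray,
    dist_forest: np.ndarray,
    slope: np.ndarray,
) -> np.ndarray:
    """Pick the first ceil(fraction * m) eligible cells of a parcel in
    composite-rank order.  ``dist_water``/``dist_forest``/``slope`` are
    full flat rasters indexed by the cell ids."""
    cells = np.asarray(parcel_cells, dtype=np.int64)
    if cells.size == 0:
        return cells
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    dw = np.asarray(dist_water).ravel()
    df = np.asarray(dist_forest).ravel()
    sl = np.asarray(slope).ravel()
    ranked = rank_cells(dw[cells], df[cells], sl[cells], cells)
    k = math.ceil(fraction * cells.size)
    return ranked[:k]


def enrollment_density(
    agent_index: int,
    centroids: np.ndarray,
    enrolled: np.ndarray,
    radius: float,
) -> float:
    """Fraction of other agents within ``radius`` of this agent's centroid
    that are enrolled; 0 when the neighborhood is empty."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    centroids = np.asarray(centroids, dtype=float)
    d = np.linalg.norm(centroids - centroids[agent_index], axis=1)
    nb = (d <= radius) & (np.arange(len(centroids)) != agent_index)
    total = int(nb.sum())
    if total == 0:
        return 0.0
    return float(np.count_nonzero(np.asarray(enrolled)[nb])) / total


def willingness(
    retirement: int,
    production: float,
    tenure: float,
    density: float,
    rule_index: int,
) -> float:
    """OWA willingness of one agent.

    Criteria are oriented so larger means more willing: (1 - retirement
    code, 1 - production, tenure, density).  An agent submits an offer iff
    willingness >= 0.87.
    """
    crit = (1.0 - retirement, 1.0 - production, tenure, density)
    return owa_aggregate(crit, owa_weights(rule_index))


def build_offer(
    agent_id: int,
    sites: Sequence[int],
    srr: np.ndarray,
    ebi: np.ndarray,
    bid: float,
    cell_acres: float,
) -> Offer:
    """Price an offer: payment is the soil-rental-rate sum over the sites
    (in $/yr given ``cell_acres`` acres per cell), the discounted annual
    payment applies the voluntary bid, and the benefit score is the mean
    of the active benefit layer over the sites."""
    sites = np.asarray(sites, dtype=np.int64)
    if sites.size == 0:
        raise ValueError("offer needs at least one site")
    if not 0.0 <= bid <= 0.16 + 1e-12:
        raise ValueError(f"bid {bid} outside [0, 0.16]")
    srr = np.asarray(srr).ravel()
    ebi = np.asarray(ebi).ravel()
    payment = float(srr[sites].sum() * cell_acres)
    return Offer(
        agent_id=agent_id,
        sites=sites,
        area_units=int(sites.size),
        annual_payment=payment,
        bid=float(bid),
        dap=payment * (1.0 - bid),
        ebi_score=float(ebi[sites].mean()),
    )


def fsa_select(
    offers: Sequence[Offer], n: int, scoring: FsaScoring | None = None
) -> list[Offer]:
    """Rank offers by benefit score adjusted for bid and cost and accept
    the top ``n``; ties go to the lower discounted payment, then the lower
    agent id."""
    if n < 0:
        raise ValueError("n must be >= 0")
    offers = list(offers)
    if not offers or n == 0:
        return []
    scoring = scoring or FsaScoring()
    dap_max = max(o.dap for o in offers)
    cost_scale = scoring.cost_points / dap_max if dap_max > 0 else 0.0

    def score(o: Offer) -> float:
        return (
            o.ebi_score
            + (o.bid / scoring.bid_max) * scoring.bid_points
            - o.dap * cost_scale
        )

    ranked = sorted(offers, key=lambda o: (-score(o), o.dap, o.agent_id))
    return ranked[: int(n)]


@dataclass
class RunFactors:
    """Resolved factor values for one run.

    Run-wide factors carry their transformed value; the three demographic
    factors carry either a constant (when fixed) or the run's unit-interval
    coordinate plus their spec, from which per-agent values are drawn."""

    de_radius: float
    owa_rule: int
    land_fraction: float
    bid: float
    ebi_layer: int
    n: int
    demographics: dict  # name -> ("constant", value) | ("quantile", u, spec)

    def values_dict(self) -> dict:
        d = {
            "DE": self.de_radius,
            "OWA": self.owa_rule,
            "LAND": self.land_fraction,
            "BID": self.bid,
            "EBI": self.ebi_layer,
            "n": self.n,
        }
        for name, spec in self.demographics.items():
            d[name] = spec[1] if spec[0] == "constant" else ("u", spec[1])
        return d


def _cdf_midpoint(spec: FactorSpec, value: float) -> float:
    """Unit-interval coordinate at the middle of ``value``'s cumulative
    mass interval (used when a demographic factor is fixed)."""
    if spec.kind == "continuous-uniform":
        lo, hi = spec.support
        return (value - lo) / (hi - lo)
    cum = 0.0
    for v, p in zip(spec.support, spec.masses):
        if math.isclose(v, value, rel_tol=0, abs_tol=1e-9):
            return min(cum + p / 2.0, 1.0 - 1e-12)
        cum += p
    raise ValueError(f"{spec.name}: value {value} outside support")


def resolve_run_factors(
    specs: Sequence[FactorSpec], u_row: Sequence[float]
) -> RunFactors:
    """Map one unit-hypercube design row (one coordinate per free factor,
    in spec order) to the run's factor values.

    Demographic factors act on the agent population as a common quantile
    shift, so fixing one freezes its shift coordinate (at the coordinate
    of the fixed value); the population stays heterogeneous and only the
    factor's run-to-run variability is removed.
    """
    free = free_factors(specs)
    u_row = list(u_row)
    if len(u_row) != len(free):
        raise ValueError(f"expected {len(free)} coordinates, got {len(u_row)}")
    it = iter(u_row)
    run: dict = {}
    demo: dict = {}
    for s in specs:
        if s.name in DEMOGRAPHIC_FACTORS:
            if s.is_fixed:
                unfixed = dataclasses.replace(s, fixed_value=None)
                demo[s.name] = (
                    "quantile",
                    _cdf_midpoint(s, s.fixed_value),
                    unfixed,
                )
            else:
                demo[s.name] = ("quantile", float(next(it)), s)
        else:
            run[s.name] = s.fixed_value if s.is_fixed else inverse_cdf(s, next(it))
    missing = ({"DE", "OWA", "LAND", "BID", "EBI", "n"} - run.keys()) | (
        set(DEMOGRAPHIC_FACTORS) - demo.keys()
    )
    if missing:
        raise ValueError(f"incomplete factor vector; missing {sorted(missing)}")
    return RunFactors(
        de_radius=float(run["DE"]),
        owa_rule=int(run["OWA"]),
        land_fraction=float(run["LAND"]),
        bid=float(run["BID"]),
        ebi_layer=int(run["EBI"]),
        n=int(run["n"]),
        demographics=demo,
    )


def _agent_attributes(
    rf: RunFactors, n_agents: int, master_seed: int
) -> dict[str, np.ndarray]:
    """Per-agent demographic draws under the golden-ratio quantile shift."""
    out = {}
    for fidx, name in enumerate(DEMOGRAPHIC_FACTORS):
        kind = rf.demographics[name]
        if kind[0] == "constant":
            out[name] = np.full(n_agents, float(kind[1]))
        else:
            _, u_factor, spec = kind
            # seeded permutation of agent ids: the quantile set stays the
            # low-discrepancy golden-ratio sequence (marginals near-exact),
            # the master seed only decides which agent gets which quantile
            perm = np.random.default_rng(
                np.random.SeedSequence([int(master_seed), fidx])
            ).permutation(n_agents)
            u_agents = (u_factor + GOLDEN_FRAC * perm) % 1.0
            out[name] = inverse_cdf_array(spec, u_agents)
    return out


@dataclass
class SimState:
    """Mutable state threaded through the annual cycles."""

    prepared: PreparedLandscape
    rf: RunFactors
    owa_w: np.ndarray
    retirement: np.ndarray
    production: np.ndarray
    tenure: np.ndarray
    enrolled: np.ndarray
    converted_k: np.ndarray  # accepted site count per agent (0 if not enrolled)
    year: int = 0
    accepted_per_year: list = field(default_factory=list)
    converted_units_per_year: list = field(default_factory=list)
    scoring: FsaScoring = field(default_factory=FsaScoring)

    @property
    def n_agents(self) -> int:
        return self.prepared.n_agents


def step_year(state: SimState) -> SimState:
    """One annual signup cycle, mutating and returning ``state``.

    All willingness evaluations use the enrollment set as of the start of
    the year; agents are processed in fixed agent-id order; enrollment is
    absorbing.
    """
    prep = state.prepared
    rf = state.rf
    enrolled0 = state.enrolled.copy()

    # densities against the start-of-year enrollment set
    owners, flat, counts = prep.neighbor_arrays(rf.de_radius)
    dens = np.zeros(state.n_agents)
    if flat.size:
        enrolled_nb = np.bincount(
            owners, weights=enrolled0[flat].astype(float), minlength=state.n_agents
        )
        nz = counts > 0
        dens[nz] = enrolled_nb[nz] / counts[nz]

    crit = np.column_stack(
        [
            1.0 - state.retirement,
            1.0 - state.production,
            state.tenure,
            dens,
        ]
    )
    will = np.sort(crit, axis=1)[:, ::-1] @ state.owa_w

    offers: list[Offer] = []
    cell_acres = prep.cell_acres
    candidates = np.flatnonzero(
        (~enrolled0)
        & (will >= WILLINGNESS_THRESHOLD)
        & (prep.eligible_count > 0)
    )
    for a in candidates:
        a = int(a)
        m = int(prep.eligible_count[a])
        k = math.ceil(rf.land_fraction * m)
        payment = float(prep.srr_prefix[a][k] * cell_acres)
        ebi_score = float(prep.ebi_prefix[a][rf.ebi_layer, k] / k)
        offers.append(
            Offer(
                agent_id=a,
                sites=prep.site_order[a][:k],
                area_units=k,
                annual_payment=payment,
                bid=rf.bid,
                dap=payment * (1.0 - rf.bid),
                ebi_score=ebi_score,
            )
        )

    accepted = fsa_select(offers, rf.n, state.scoring)
    for o in accepted:
        state.enrolled[o.agent_id] = True
        state.converted_k[o.agent_id] = o.area_units

    state.accepted_per_year.append(len(accepted))
    state.converted_units_per_year.append(int(sum(o.area_units for o in accepted)))
    state.year += 1
    return state


def run_simulation(
    landscape: Landscape | PreparedLandscape,
    run_factors: RunFactors,
    master_seed: int = 0,
    years: int = 10,
    scoring: FsaScoring | None = None,
) -> SimulationResult:
    """Run the full annual loop and report the final fallow area.

    Deterministic: identical (landscape, run_factors, master_seed) give a
    bit-identical result.
    """
    prep = (
        landscape
        if isinstance(landscape, PreparedLandscape)
        else PreparedLandscape(landscape)
    )
    attrs = _agent_attributes(run_factors, prep.n_agents, master_seed)
    state = SimState(
        prepared=prep,
        rf=run_factors,
        owa_w=owa_weights(run_factors.owa_rule),
        retirement=attrs["RETIREMENT"],
        production=attrs["PRODUCTION"],
        tenure=attrs["TENURE"],
        enrolled=np.zeros(prep.n_agents, dtype=bool),
        converted_k=np.zeros(prep.n_agents, dtype=np.int64),
        scoring=scoring or FsaScoring(),
    )
    for _ in range(years):
        step_year(state)

    landuse = prep.landscape.landuse.copy()
    flat = landuse.ravel()
    for a in np.flatnonzero(state.converted_k):
        flat[prep.site_order[a][: state.converted_k[a]]] = int(LandUse.FALLOW)
    area_units = int(state.converted_k.sum())
    return SimulationResult(
        landuse=landuse,
        accepted_per_year=state.accepted_per_year,
        converted_units_per_year=state.converted_units_per_year,
        area_units=area_units,
        area_acres=area_in_acres(area_units, prep.landscape.cell_size),
        years=years,
        master_seed=int(master_seed),
        factor_values=run_factors.values_dict(),
    )


def make_model(
    landscape: Landscape | PreparedLandscape,
    specs: Sequence[FactorSpec],
    master_seed: int = 0,
    years: int = 10,
    scoring: FsaScoring | None = None,
    output: str = "units",
) -> Callable[[np.ndarray], float]:
    """Wrap the simulator as a pure map from a unit-hypercube design row
    (one coordinate per free factor) to the scalar fallow-area output."""
    prep = (
        landscape
        if isinstance(landscape, PreparedLandscape)
        else PreparedLandscape(landscape)
    )
    if output not in {"units", "acres"}:
        raise ValueError("output must be 'units' or 'acres'")

    def model(u_row: np.ndarray) -> float:
        rf = resolve_run_factors(specs, u_row)
        res = run_simulation(prep, rf, master_seed=master_seed, years=years,
                             scoring=scoring)
        return float(res.area_units if output == "units" else res.area_acres)

    model.prepared = prep  # type: ignore[attr-defined]
    return model
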