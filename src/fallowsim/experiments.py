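"""End-to-end experiment orchestration: UA -> SA -> model simplification.

An experiment evaluates the enrollment simulator over a Saltelli design on
a synthetic landscape, summarizes the output distribution (uncertainty
analysis) and decomposes its variance into per-factor shares (sensitivity
analysis).  Two simplification procedures derive follow-up experiments
from a baseline report:

* exploratory simplification fixes every factor flagged negligible (both
  S and ST below a threshold) at its distribution median (or mean),
  keeping the output distribution — and thus the model's capacity to
  explore extreme outcomes — essentially unchanged;
* explanatory refinement fixes the single most influential factor (highest
  S) at its support midpoint, shrinking output variance around an
  unchanged mean so the remaining structure is easier to interpret.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .abm import FsaScoring, make_model
from .design import EvaluatedDesign, evaluate_design, saltelli_design
from .factors import (
    FactorSpec,
    factor_mean,
    factor_median,
    factor_midpoint,
    fix_factor,
    free_factors,
    make_default_factors,
)
from .landscape import Landscape, LandscapeConfig, generate_landscape
from .sensitivity import (
    SensitivityResult,
    rank_factors,
    sobol_indices,
    uncertainty_summary,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "simplify_exploratory",
    "refine_explanatory",
    "compare_reports",
    "paired_comparison",
    "indices_from_log",
]


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    name: str = "baseline"
    landscape_config: LandscapeConfig = field(default_factory=LandscapeConfig)
    landscape_seed: int = 0
    factors: list = field(default_factory=make_default_factors)
    N: int = 128
    master_seed: int = 0
    years: int = 10
    scoring: FsaScoring = field(default_factory=FsaScoring)
    negligibility_threshold: float = 0.01
    output: str = "units"  # model output scale: "units" (cells) or "acres"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")

    @property
    def free_names(self) -> tuple:
        return tuple(s.name for s in free_factors(self.factors))

    @property
    def k(self) -> int:
        return len(self.free_names)

    @property
    def run_count(self) -> int:
        return self.N * (2 * self.k + 2)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "landscape_config": dataclasses.asdict(self.landscape_config),
            "landscape_seed": self.landscape_seed,
            "factors": [s.to_dict() for s in self.factors],
            "N": self.N,
            "master_seed": self.master_seed,
            "years": self.years,
            "scoring": dataclasses.asdict(self.scoring),
            "negligibility_threshold": self.negligibility_threshold,
            "output": self.output,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        lc = d.get("landscape_config", {})
        for key in ("ebi_weights", "ebi_range", "ebi_corr_band"):
            if key in lc:
                lc[key] = tuple(lc[key])
        return cls(
            name=d.get("name", "baseline"),
            landscape_config=LandscapeConfig(**lc),
            landscape_seed=d.get("landscape_seed", 0),
            factors=[FactorSpec.from_dict(x) for x in d["factors"]]
            if "factors" in d
            else make_default_factors(),
            N=d.get("N", 128),
            master_seed=d.get("master_seed", 0),
            years=d.get("years", 10),
            scoring=FsaScoring(**d.get("scoring", {})),
            negligibility_threshold=d.get("negligibility_threshold", 0.01),
            output=d.get("output", "units"),
        )


@dataclass
class ExperimentReport:
    """Results of one experiment: UA summary plus sensitivity indices."""

    config: ExperimentConfig
    run_count: int
    ua: dict
    sens: SensitivityResult | None  # None when the output was constant
    evaluated: EvaluatedDesign | None = field(default=None, repr=False)

    def ranked(self, threshold: float | None = None) -> pd.DataFrame:
        if self.sens is None:
            raise ValueError("constant output: no sensitivity indices")
        thr = (
            self.config.negligibility_threshold if threshold is None else threshold
        )
        return rank_factors(self.sens, threshold=thr)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "run_count": self.run_count,
            "ua": self.ua,
            "sens": self.sens.to_dict() if self.sens is not None else None,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "ExperimentReport":
        d = json.loads(Path(path).read_text())
        sens = d.get("sens")
        return cls(
            config=ExperimentConfig.from_dict(d["config"]),
            run_count=d["run_count"],
            ua=d["ua"],
            sens=SensitivityResult.from_dict(sens) if sens is not None else None,
        )


def run_experiment(
    config: ExperimentConfig,
    landscape: Landscape | None = None,
    checkpoint=None,
    n_boot: int = 200,
) -> ExperimentReport:
    """Build (or reuse) the landscape, evaluate the Saltelli design over
    the free factors, and compute the UA summary and sensitivity indices.

    The UA summary uses the plain quasi-MC outputs (blocks A and B); the
    cross blocks enter only the index estimators.  Fully deterministic for
    a given config.
    """
    if landscape is None:
        landscape = generate_landscape(config.landscape_config, config.landscape_seed)
    design = saltelli_design(config.k, config.N)
    model = make_model(
        landscape,
        config.factors,
        master_seed=config.master_seed,
        years=config.years,
        scoring=config.scoring,
        output=config.output,
    )
    evaluated = evaluate_design(design, model, checkpoint=checkpoint)
    ua = uncertainty_summary(evaluated.mc_sample)
    try:
        sens = sobol_indices(
            evaluated,
            factor_names=config.free_names,
            n_boot=n_boot,
            seed=config.master_seed,
        )
    except ValueError:
        # degenerate (constant) output: UA is still reported, indices are not
        sens = None
    return ExperimentReport(
        config=config,
        run_count=design.n_rows,
        ua=ua,
        sens=sens,
        evaluated=evaluated,
    )


def simplify_exploratory(
    baseline_report: ExperimentReport,
    threshold: float | None = None,
    stat: str = "median",
) -> ExperimentConfig:
    """Derive the exploratory (variance-preserving) simplification.

    Every factor whose S and ST both fall below the threshold is fixed at
    its distribution median (or mean with ``stat='mean'``); influential
    factors stay free.
    """
    if stat not in {"median", "mean"}:
        raise ValueError("stat must be 'median' or 'mean'")
    cfg = baseline_report.config
    ranked = baseline_report.ranked(threshold)
    negligible = list(ranked.loc[ranked["negligible"], "factor"])
    if len(negligible) == len(ranked):
        raise ValueError("all factors flagged negligible; nothing left to vary")
    factors = cfg.factors
    for name in negligible:
        spec = next(s for s in factors if s.name == name)
        if stat == "median":
            value = factor_median(spec)
        else:
            value = factor_mean(spec)
            if spec.kind != "continuous-uniform" and not spec.contains(value):
                # discrete mean may fall between support points: snap to
                # the nearest supported value
                sup = np.asarray(spec.support, dtype=float)
                value = spec.support[int(np.argmin(np.abs(sup - value)))]
        factors = fix_factor(factors, name, value)
    return dataclasses.replace(
        cfg, name=f"{cfg.name}-exploratory", factors=factors
    )


def refine_explanatory(baseline_report: ExperimentReport) -> ExperimentConfig:
    """Derive the explanatory (variance-reducing) refinement: fix the
    factor with the highest first-order index at its support midpoint
    (argmax ties go to the lower factor index)."""
    cfg = baseline_report.config
    sens = baseline_report.sens
    if sens is None:
        raise ValueError("baseline has no sensitivity indices (constant output)")
    top = int(np.argmax(sens.S))
    name = sens.factor_names[top]
    spec = next(s for s in cfg.factors if s.name == name)
    value = factor_midpoint(spec)
    return dataclasses.replace(
        cfg,
        name=f"{cfg.name}-explanatory",
        factors=fix_factor(cfg.factors, name, value),
    )


def compare_reports(report: ExperimentReport, baseline: ExperimentReport) -> dict:
    """Compare an experiment against a baseline: mean shift, variance
    ratio, and spread reduction % = 100*(1 - var/var_baseline)."""
    vb = baseline.ua["variance"]
    if vb == 0:
        raise ValueError("baseline variance is zero")
    v = report.ua["variance"]
    mb, m = baseline.ua["mean"], report.ua["mean"]
    se = float(
        np.sqrt(
            v / report.ua["n"] + vb / baseline.ua["n"]
        )
    )
    table = pd.DataFrame(
        {
            "experiment": [report.config.name, baseline.config.name],
            "n": [report.ua["n"], baseline.ua["n"]],
            "mean": [m, mb],
            "variance": [v, vb],
            "std": [report.ua["std"], baseline.ua["std"]],
        }
    )
    return {
        "mean_difference": m - mb,
        "mean_difference_se": se,
        "mean_ratio": m / mb if mb != 0 else float("nan"),
        "variance_ratio": v / vb,
        "spread_reduction_pct": 100.0 * (1.0 - v / vb),
        "table": table,
    }


def paired_comparison(
    baseline_report: ExperimentReport,
    simplified_config: ExperimentConfig,
    landscape: Landscape | None = None,
) -> dict:
    """Compare a simplified model against its baseline on the *same* base
    sample (common random numbers).

    Evaluating both models at identical free-coordinate points removes
    quasi-Monte-Carlo integration error from the comparison, so mean and
    variance differences reflect only the effect of fixing factors.  The
    simplified config's free factors must be a subset of the baseline's.
    Returns mean difference (with its paired standard error), variance
    ratio and the two output arrays.
    """
    base_ev = baseline_report.evaluated
    if base_ev is None:
        raise ValueError("baseline report carries no evaluated design")
    base_free = list(baseline_report.config.free_names)
    cols = []
    for name in simplified_config.free_names:
        if name not in base_free:
            raise ValueError(f"factor {name} is not free in the baseline")
        cols.append(base_free.index(name))
    if landscape is None:
        landscape = generate_landscape(
            simplified_config.landscape_config, simplified_config.landscape_seed
        )
    model = make_model(
        landscape,
        simplified_config.factors,
        master_seed=simplified_config.master_seed,
        years=simplified_config.years,
        scoring=simplified_config.scoring,
        output=simplified_config.output,
    )
    pts = np.vstack([base_ev.design.A, base_ev.design.B])[:, cols]
    y_base = base_ev.mc_sample
    y_simple = np.array([model(p) for p in pts])
    d = y_simple - y_base
    n = d.size
    return {
        "n": n,
        "mean_difference": float(d.mean()),
        # paired SE of the difference (precision of the comparison itself)
        "mean_difference_se": float(d.std(ddof=1) / np.sqrt(n)),
        # MC standard error of the baseline mean (precision of the mean)
        "baseline_mean_se": float(y_base.std(ddof=1) / np.sqrt(n)),
        "variance_ratio": float(np.var(y_simple, ddof=1) / np.var(y_base, ddof=1)),
        "baseline_outputs": y_base,
        "simplified_outputs": y_simple,
    }


def indices_from_log(log: pd.DataFrame, n_boot: int = 200, seed: int = 0):
    """Recompute sensitivity indices from a tidy run-log written by
    :func:`fallowsim.design.evaluate_design` (columns block, base_index,
    output)."""
    blocks = log.groupby("block")
    fA = blocks.get_group("A").sort_values("base_index")["output"].to_numpy()
    fB = blocks.get_group("B").sort_values("base_index")["output"].to_numpy()
    labels = sorted(
        {b for b in log["block"].unique() if b.startswith("AB")},
        key=lambda s: int(s[2:]),
    )
    k = len(labels)
    N = fA.size
    fAB = np.empty((k, N))
    fBA = np.empty((k, N))
    for i in range(k):
        fAB[i] = blocks.get_group(f"AB{i}").sort_values("base_index")[
            "output"
        ].to_numpy()
        fBA[i] = blocks.get_group(f"BA{i}").sort_values("base_index")[
            "output"
        ].to_numpy()
    ev = EvaluatedDesign(design=None, f_A=fA, f_B=fB, f_AB=fAB, f_BA=fBA)
    return sobol_indices(ev, n_boot=n_boot, seed=seed)
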