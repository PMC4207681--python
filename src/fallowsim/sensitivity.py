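"""Variance-based uncertainty and sensitivity measures.

Given the evaluated blocks of a radial design, this module estimates, for
each factor i,

* the first-order index  S_i  = V_i / V, the share of output variance the
  factor explains on its own, and
* the total-effect index ST_i = 1 - VC_i / V, its share including every
  interaction it takes part in (VC_i is the variance conditional on all
  factors except i),

together with the interaction share I = 1 - sum(S), the fraction of output
variance produced only by factors acting in combination.

Estimators: V_i uses the Saltelli cross-block estimator
mean(f_B * (f_AB_i - f_A)); the complement V - VC_i uses the Jansen
difference estimator mean((f_A - f_AB_i)^2) / 2.  Because the design pays
for both radial directions, each index is averaged over the (A->AB, B->BA)
pair.  Monte-Carlo error is quantified by bootstrap over base-sample
indices.  Negative point estimates are reported as-is (with a warning when
beyond noise level): clipping would mask an insufficient base sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import EvaluatedDesign

__all__ = [
    "SensitivityResult",
    "uncertainty_summary",
    "sobol_indices",
    "first_order_indices",
    "total_effect_indices",
    "interaction_share",
    "rank_factors",
]


def uncertainty_summary(outputs: Sequence[float], bins: int = 20) -> dict:
    """Descriptive summary of a Monte-Carlo output sample.

    Returns the sample mean, unbiased variance, the {2.5, 25, 50, 75, 97.5}
    percent quantiles (linear interpolation) and histogram bin counts/edges.
    """
    y = np.asarray(outputs, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 2:
        raise ValueError("need at least 2 finite outputs")
    qs = (2.5, 25.0, 50.0, 75.0, 97.5)
    counts, edges = np.histogram(y, bins=bins)
    return {
        "n": int(y.size),
        "mean": float(np.mean(y)),
        "variance": float(np.var(y, ddof=1)),
        "std": float(np.std(y, ddof=1)),
        "quantiles": {f"{q:g}": float(v) for q, v in zip(qs, np.percentile(y, qs))},
        "histogram": {"counts": counts.tolist(), "edges": edges.tolist()},
    }


@dataclass
class SensitivityResult:
    """Per-factor (S, ST) estimates with bootstrap errors and UA metadata."""

    factor_names: tuple
    S: np.ndarray
    ST: np.ndarray
    V: float
    mean: float
    N: int
    k: int
    S_se: np.ndarray = None
    ST_se: np.ndarray = None
    S_ci: np.ndarray = None  # shape (k, 2), 95% percentile bootstrap
    ST_ci: np.ndarray = None

    @property
    def I(self) -> float:  # noqa: E743 - the interaction share symbol
        return interaction_share(self.S)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"factor": self.factor_names, "S": self.S, "ST": self.ST})
        if self.S_se is not None:
            df["S_se"] = self.S_se
            df["ST_se"] = self.ST_se
            df["S_lo"], df["S_hi"] = self.S_ci[:, 0], self.S_ci[:, 1]
            df["ST_lo"], df["ST_hi"] = self.ST_ci[:, 0], self.ST_ci[:, 1]
        return df

    def to_dict(self) -> dict:
        d = {
            "factor_names": list(self.factor_names),
            "S": self.S.tolist(),
            "ST": self.ST.tolist(),
            "V": self.V,
            "mean": self.mean,
            "I": self.I,
            "N": self.N,
            "k": self.k,
        }
        if self.S_se is not None:
            d["S_se"] = self.S_se.tolist()
            d["ST_se"] = self.ST_se.tolist()
            d["S_ci"] = self.S_ci.tolist()
            d["ST_ci"] = self.ST_ci.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SensitivityResult":
        kw = dict(
            factor_names=tuple(d["factor_names"]),
            S=np.asarray(d["S"]),
            ST=np.asarray(d["ST"]),
            V=d["V"],
            mean=d["mean"],
            N=d["N"],
            k=d["k"],
        )
        if "S_se" in d:
            kw.update(
                S_se=np.asarray(d["S_se"]),
                ST_se=np.asarray(d["ST_se"]),
                S_ci=np.asarray(d["S_ci"]),
                ST_ci=np.asarray(d["ST_ci"]),
            )
        return cls(**kw)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".csv":
            self.to_frame().to_csv(path, index=False)
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


def _point_estimates(fA, fB, fAB, fBA):
    """(S, ST, V, mean) from block outputs; both radial directions averaged."""
    y = np.concatenate([fA, fB])
    mean = y.mean()
    V = y.var()  # population variance of the combined base sample
    if V <= 0:
        raise ValueError("output variance is zero; indices are undefined")
    # center outputs: makes the estimator exactly invariant under affine
    # rescaling of Y and reduces its variance
    fA = fA - mean
    fB = fB - mean
    fAB = fAB - mean
    fBA = fBA - mean
    Vi = 0.5 * (
        (fB[None, :] * (fAB - fA[None, :])).mean(axis=1)
        + (fA[None, :] * (fBA - fB[None, :])).mean(axis=1)
    )
    Ei = 0.5 * (
        ((fA[None, :] - fAB) ** 2).mean(axis=1) / 2.0
        + ((fB[None, :] - fBA) ** 2).mean(axis=1) / 2.0
    )
    return Vi / V, Ei / V, float(V), float(mean)


def sobol_indices(
    evaluated: EvaluatedDesign,
    factor_names: Sequence[str] | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> SensitivityResult:
    """Estimate (S, ST) for every factor from an evaluated radial design.

    ``n_boot`` bootstrap resamples over base-sample indices give standard
    errors and 95% percentile intervals; set ``n_boot=0`` to skip them.
    """
    fA, fB, fAB, fBA = (
        evaluated.f_A,
        evaluated.f_B,
        evaluated.f_AB,
        evaluated.f_BA,
    )
    N = fA.size
    k = fAB.shape[0]
    if factor_names is None:
        factor_names = tuple(f"x{i}" for i in range(k))
    factor_names = tuple(factor_names)
    if len(factor_names) != k:
        raise ValueError("factor_names length mismatch")

    S, ST, V, mean = _point_estimates(fA, fB, fAB, fBA)
    res = SensitivityResult(
        factor_names=factor_names, S=S, ST=ST, V=V, mean=mean, N=N, k=k
    )

    if n_boot:
        rng = np.random.default_rng(seed)
        Sb = np.full((n_boot, k), np.nan)
        STb = np.full((n_boot, k), np.nan)
        kept = 0
        for b in range(n_boot):
            idx = rng.integers(0, N, size=N)
            try:
                Sb[b], STb[b], _, _ = _point_estimates(
                    fA[idx], fB[idx], fAB[:, idx], fBA[:, idx]
                )
                kept += 1
            except ValueError:
                continue  # degenerate (constant) resample at small N
        if kept < max(2, n_boot // 2):
            warnings.warn(
                "most bootstrap resamples were degenerate; standard errors "
                "are unreliable at this base sample size",
                stacklevel=2,
            )
        res.S_se = np.nanstd(Sb, axis=0, ddof=1)
        res.ST_se = np.nanstd(STb, axis=0, ddof=1)
        res.S_ci = np.nanpercentile(Sb, [2.5, 97.5], axis=0).T
        res.ST_ci = np.nanpercentile(STb, [2.5, 97.5], axis=0).T
        tol = 3.0 * res.S_se
        if np.any(res.S < -tol) or np.any(res.ST < -3.0 * res.ST_se):
            warnings.warn(
                "negative sensitivity estimates beyond 3x bootstrap SE; "
                "the base sample N is likely too small",
                stacklevel=2,
            )
    return res


def first_order_indices(evaluated: EvaluatedDesign, **kw) -> np.ndarray:
    """First-order indices S only (see :func:`sobol_indices`)."""
    return sobol_indices(evaluated, n_boot=0, **kw).S


def total_effect_indices(evaluated: EvaluatedDesign, **kw) -> np.ndarray:
    """Total-effect indices ST only (see :func:`sobol_indices`)."""
    return sobol_indices(evaluated, n_boot=0, **kw).ST


def interaction_share(S: Sequence[float]) -> float:
    """I = 1 - sum(S): variance share attributable to factor interactions.

    Slightly negative values can occur through Monte-Carlo noise and are
    returned as-is.
    """
    return float(1.0 - np.sum(np.asarray(S, dtype=float)))


def rank_factors(result: SensitivityResult, threshold: float = 0.01) -> pd.DataFrame:
    """Rank factors by influence and flag negligible ones.

    Ordering is descending S, ties broken by descending ST then name.  A
    factor is negligible when both S and ST fall below ``threshold``
    (default 0.01, i.e. under one percent of output variance either alone
    or through interactions).
    """
    df = result.to_frame()
    df["negligible"] = (df["S"] < threshold) & (df["ST"] < threshold)
    df = df.sort_values(
        ["S", "ST", "factor"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
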