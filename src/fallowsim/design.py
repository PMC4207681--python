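"""Sobol' low-discrepancy sampling and the Saltelli block design.

The sensitivity engine estimates first-order and total-effect variance
shares from a radial block design: two independent base matrices A and B
drawn as the first and second halves of a 2k-dimensional Sobol' stream,
plus for every factor i the cross matrices AB_i (A with column i replaced
from B) and BA_i.  Evaluating the model on all N*(2k+2) rows yields both
index families for all k factors.

Everything here is deterministic: the Sobol' generator is unscrambled and
the all-zeros leading point is skipped, so two constructions with the same
(k, N) are bit-identical.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = [
    "SaltelliDesign",
    "EvaluatedDesign",
    "sobol_sequence",
    "saltelli_design",
    "evaluate_design",
]

_MAX_DIM = 32


def sobol_sequence(dim: int, count: int, skip: int = 1) -> np.ndarray:
    """Return ``count`` successive points of the unscrambled Sobol' sequence
    in ``[0, 1)^dim``, after skipping the first ``skip`` elements (default 1,
    i.e. the all-zeros point).
    """
    if not 1 <= dim <= _MAX_DIM:
        raise ValueError(f"dim must be in [1, {_MAX_DIM}], got {dim}")
    if count < 1:
        raise ValueError("count must be >= 1")
    eng = qmc.Sobol(d=dim, scramble=False)
    if skip:
        eng.fast_forward(skip)
    with warnings.catch_warnings():
        # balance warnings for non power-of-two counts are expected here
        warnings.simplefilter("ignore", UserWarning)
        pts = eng.random(count)
    return np.asarray(pts, dtype=float)


@dataclass(frozen=True)
class SaltelliDesign:
    """The block-structured input matrix of a radial Sobol'/Saltelli design.

    Row layout: block A (N rows), block B (N rows), then AB_0..AB_{k-1} and
    BA_0..BA_{k-1} (N rows each).  AB_i equals A except that column i is
    taken from B; symmetrically for BA_i.
    """

    k: int
    N: int
    A: np.ndarray
    B: np.ndarray
    AB: np.ndarray  # shape (k, N, k)
    BA: np.ndarray  # shape (k, N, k)

    @property
    def n_rows(self) -> int:
        return self.N * (2 * self.k + 2)

    @property
    def rows(self) -> np.ndarray:
        """All rows stacked in canonical block order, shape (N(2k+2), k)."""
        return np.vstack(
            [self.A, self.B]
            + [self.AB[i] for i in range(self.k)]
            + [self.BA[i] for i in range(self.k)]
        )

    @property
    def block_index(self) -> list[tuple[str, int]]:
        """(block label, base-sample index) per row, aligned with ``rows``."""
        idx: list[tuple[str, int]] = []
        idx += [("A", j) for j in range(self.N)]
        idx += [("B", j) for j in range(self.N)]
        for i in range(self.k):
            idx += [(f"AB{i}", j) for j in range(self.N)]
        for i in range(self.k):
            idx += [(f"BA{i}", j) for j in range(self.N)]
        return idx

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.rows).tobytes())
        return h.hexdigest()[:16]

    def to_frame(self) -> pd.DataFrame:
        bi = self.block_index
        df = pd.DataFrame(self.rows, columns=[f"u{i}" for i in range(self.k)])
        df.insert(0, "base_index", [j for _, j in bi])
        df.insert(0, "block", [b for b, _ in bi])
        df.insert(0, "row", np.arange(len(df)))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def saltelli_design(k: int, N: int) -> SaltelliDesign:
    """Build the N*(2k+2)-row radial design for ``k`` free factors.

    A and B come from one 2k-dimensional Sobol' stream (columns 0..k-1 form
    A, columns k..2k-1 form B) so the pair is a genuine low-discrepancy
    point set in the joint 2k-space.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if N < 2:
        raise ValueError("N must be >= 2")
    base = sobol_sequence(2 * k, N, skip=1)
    A = np.ascontiguousarray(base[:, :k])
    B = np.ascontiguousarray(base[:, k:])
    AB = np.empty((k, N, k), dtype=float)
    BA = np.empty((k, N, k), dtype=float)
    for i in range(k):
        AB[i] = A
        AB[i, :, i] = B[:, i]
        BA[i] = B
        BA[i, :, i] = A[:, i]
    return SaltelliDesign(k=k, N=N, A=A, B=B, AB=AB, BA=BA)


@dataclass
class EvaluatedDesign:
    """Model outputs grouped by design block, base-sample aligned."""

    design: SaltelliDesign
    f_A: np.ndarray
    f_B: np.ndarray
    f_AB: np.ndarray  # shape (k, N)
    f_BA: np.ndarray  # shape (k, N)
    log: pd.DataFrame = field(repr=False, default=None)

    @property
    def all_outputs(self) -> np.ndarray:
        return np.concatenate(
            [self.f_A, self.f_B, self.f_AB.ravel(), self.f_BA.ravel()]
        )

    @property
    def mc_sample(self) -> np.ndarray:
        """Plain quasi-MC outputs (blocks A and B) for uncertainty summaries."""
        return np.concatenate([self.f_A, self.f_B])


def _load_checkpoint(path: Path, design_hash: str) -> dict[int, float]:
    done: dict[int, float] = {}
    if not path.exists():
        return done
    df = pd.read_csv(path, comment="#")
    with open(path) as fh:
        first = fh.readline().strip()
    if first != f"# design={design_hash}":
        raise ValueError(
            f"checkpoint {path} was written for a different design "
            f"({first!r} != hash {design_hash})"
        )
    for r, y in zip(df["row"], df["output"]):
        done[int(r)] = float(y)
    return done


def evaluate_design(
    design: SaltelliDesign,
    model: Callable[[np.ndarray], float],
    checkpoint: str | Path | None = None,
    checkpoint_every: int = 64,
) -> EvaluatedDesign:
    """Run ``model`` (a pure map from a unit-hypercube row to a scalar) over
    every design row.

    With ``checkpoint`` given, finished rows are appended to a CSV keyed by
    the design's content hash, and a restarted evaluation resumes after the
    last flushed row.  Non-finite outputs abort with diagnostics.
    """
    rows = design.rows
    bi = design.block_index
    n_rows = len(rows)
    outputs = np.full(n_rows, np.nan)

    done: dict[int, float] = {}
    ckpt_path = None
    if checkpoint is not None:
        ckpt_path = Path(checkpoint)
        dh = design.content_hash()
        done = _load_checkpoint(ckpt_path, dh)
        if not ckpt_path.exists():
            ckpt_path.parent.mkdir(parents=True, exist_ok=True)
            with open(ckpt_path, "w") as fh:
                fh.write(f"# design={dh}\n")
                fh.write("row,output\n")

    pending: list[tuple[int, float]] = []
    fh = open(ckpt_path, "a") if ckpt_path is not None else None
    try:
        for r in range(n_rows):
            if r in done:
                outputs[r] = done[r]
                continue
            y = float(model(rows[r]))
            if not np.isfinite(y):
                block, j = bi[r]
                raise FloatingPointError(
                    f"model returned non-finite output {y} at row {r} "
                    f"(block {block}, base index {j}, u={rows[r]!r})"
                )
            outputs[r] = y
            if fh is not None:
                pending.append((r, y))
                if len(pending) >= checkpoint_every:
                    fh.writelines(f"{r},{v!r}\n" for r, v in pending)
                    fh.flush()
                    pending.clear()
        if fh is not None and pending:
            fh.writelines(f"{r},{v!r}\n" for r, v in pending)
            fh.flush()
    finally:
        if fh is not None:
            fh.close()

    N, k = design.N, design.k
    f_A = outputs[:N]
    f_B = outputs[N : 2 * N]
    f_AB = outputs[2 * N : (2 + k) * N].reshape(k, N)
    f_BA = outputs[(2 + k) * N :].reshape(k, N)

    log = pd.DataFrame(rows, columns=[f"u{i}" for i in range(k)])
    log.insert(0, "base_index", [j for _, j in bi])
    log.insert(0, "block", [b for b, _ in bi])
    log.insert(0, "row", np.arange(n_rows))
    log["output"] = outputs
    return EvaluatedDesign(
        design=design, f_A=f_A, f_B=f_B, f_AB=f_AB, f_BA=f_BA, log=log
    )
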