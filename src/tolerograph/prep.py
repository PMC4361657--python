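"""RMA-style preprocessing of probe-level microarray intensities.

Three stages take natural-scale probe intensities to one log2 expression
value per probe set per array: a background adjustment (here a per-array
quantile shift; the convolution background model is an extension point),
quantile normalization so every array shares the same intensity
distribution, and robust summarization of each probe set's member probes
by median polish of the additive model

    log2(I_pj) = mu + probe_effect_p + array_effect_j + residual,

with the per-array summary mu + array_effect_j.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataError, ExpressionMatrix
from .datagen import ProbeLevelSet


@dataclass
class PrepConfig:
    background: str = "none"          # "none" | "shift"
    background_q: float = 0.0         # quantile subtracted in "shift" mode
    epsilon: float = 1.0              # positive floor after background shift
    polish_max_iter: int = 20
    polish_tol: float = 1e-9

    def validate(self) -> None:
        if self.background not in ("none", "shift"):
            raise DataError(f"unknown background mode {self.background!r}")
        if not (0.0 <= self.background_q < 1.0):
            raise DataError("background quantile must be in [0, 1)")
        if self.polish_max_iter < 1 or self.polish_tol <= 0:
            raise DataError("polish_max_iter >= 1 and polish_tol > 0 required")
        if self.epsilon <= 0:
            raise DataError("epsilon must be positive")


def background_adjust(data: ProbeLevelSet, cfg: PrepConfig) -> ProbeLevelSet:
    """Subtract a per-array intensity quantile, flooring at ``cfg.epsilon``.

    Mode ``none`` returns the input unchanged.
    """
    cfg.validate()
    if cfg.background == "none":
        return data
    all_rows = np.vstack([m for m in data.intensities.values()])
    bg = np.quantile(all_rows, cfg.background_q, axis=0)
    adjusted = {pid: np.maximum(m - bg[None, :], cfg.epsilon)
                for pid, m in data.intensities.items()}
    return ProbeLevelSet(data.sample_ids, adjusted)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Force every column (array) to the same empirical distribution.

    The target distribution is the row-wise mean of the column-sorted
    input; each value is replaced by the target value at its within-
    column rank, and ties receive the mean of their tied target values.
    Idempotent, and the total sum is preserved up to tie averaging.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise DataError("need a 2-D matrix with >= 2 arrays")
    n, k = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    target = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    for j in range(k):
        col = values[:, j]
        assigned = np.empty(n)
        assigned[order[:, j]] = target
        # average target values over runs of tied input values
        srt = col[order[:, j]]
        ties = np.flatnonzero(np.diff(srt) == 0)
        if ties.size:
            i = 0
            while i < n:
                jj = i
                while jj + 1 < n and srt[jj + 1] == srt[i]:
                    jj += 1
                if jj > i:
                    block = order[i:jj + 1, j]
                    assigned[block] = target[i:jj + 1].mean()
                i = jj + 1
        out[:, j] = assigned
    return out


def median_polish(matrix: np.ndarray, max_iter: int = 20, tol: float = 1e-9):
    """Fit mu + row_effect + col_effect by alternating median sweeps.

    Rows are swept first, then columns, repeating until the largest
    absolute change in the residual matrix falls below ``tol`` or
    ``max_iter`` sweeps have run. Returns (mu, row_effects, col_effects,
    residuals).
    """
    z = np.asarray(matrix, dtype=float).copy()
    n, k = z.shape
    mu = 0.0
    row = np.zeros(n)
    col = np.zeros(k)
    for _ in range(max_iter):
        rmed = np.median(z, axis=1)
        z -= rmed[:, None]
        row += rmed
        cmed_of_row = np.median(row)
        mu += cmed_of_row
        row -= cmed_of_row

        cmed = np.median(z, axis=0)
        z -= cmed[None, :]
        col += cmed
        rmed_of_col = np.median(col)
        mu += rmed_of_col
        col -= rmed_of_col

        if max(np.abs(rmed).max(), np.abs(cmed).max()) < tol:
            break
    return mu, row, col, z


def median_polish_summarize(data: ProbeLevelSet, cfg: PrepConfig | None = None
                            ) -> ExpressionMatrix:
    """Summarize each probe set's log2 member-probe matrix to one value
    per array: mu + array_effect from the median-polish fit."""
    cfg = cfg or PrepConfig()
    cfg.validate()
    probe_ids = sorted(data.intensities)
    summaries = np.empty((len(probe_ids), len(data.sample_ids)))
    for i, pid in enumerate(probe_ids):
        mat = np.log2(data.intensities[pid])
        if mat.shape[1] < 2:
            raise DataError("median polish needs >= 2 arrays")
        mu, _row, colfx, _res = median_polish(
            mat, max_iter=cfg.polish_max_iter, tol=cfg.polish_tol)
        summaries[i] = mu + colfx
    return ExpressionMatrix(probe_ids, list(data.sample_ids), summaries)


def rma(data: ProbeLevelSet, cfg: PrepConfig | None = None) -> ExpressionMatrix:
    """Full preprocessing chain: background adjust, quantile normalize
    across arrays at probe level, median-polish summarize."""
    cfg = cfg or PrepConfig()
    cfg.validate()
    data = background_adjust(data, cfg)
    probe_ids = sorted(data.intensities)
    sizes = [data.intensities[p].shape[0] for p in probe_ids]
    stacked = np.vstack([data.intensities[p] for p in probe_ids])
    normed = quantile_normalize(stacked)
    rebuilt = {}
    start = 0
    for pid, sz in zip(probe_ids, sizes):
        rebuilt[pid] = normed[start:start + sz]
        start += sz
    return median_polish_summarize(ProbeLevelSet(data.sample_ids, rebuilt), cfg)
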