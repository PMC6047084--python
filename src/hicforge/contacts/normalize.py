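"""Outlier removal and sequential-component (SCN) balancing."""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .matrix import ContactMatrix


@dataclass
class OutlierReport:
    threshold: float
    removed: List[Tuple[int, int, float]]  # (i, j, count) with i <= j


def filter_outliers(
    matrix: ContactMatrix, top_permille: float = 5.0, factor: float = 20.0
) -> Tuple[ContactMatrix, OutlierReport]:
    """Zero out pathological pairs.

    The threshold T is the top-``top_permille`` (default 5 per mille, i.e.
    99.5th percentile) count over nonzero fragment pairs; entries exceeding
    ``factor * T`` are removed and logged.
    """
    M = matrix.counts
    iu = np.triu_indices(matrix.n)
    vals = M[iu]
    nz = vals[vals > 0]
    if nz.size == 0:
        return matrix.copy(), OutlierReport(0.0, [])
    T = float(np.percentile(nz, 100.0 - top_permille / 10.0))
    out = matrix.copy()
    removed = []
    cut = factor * T
    ii, jj = iu
    bad = vals > cut
    for i, j, v in zip(ii[bad], jj[bad], vals[bad]):
        removed.append((int(i), int(j), float(v)))
        out.counts[i, j] = 0.0
        out.counts[j, i] = 0.0
    return out, OutlierReport(T, removed)


class ScnConvergenceError(RuntimeError):
    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"SCN did not converge in {max_iter} sweeps (residual {residual:.3g})"
        )
        self.residual = residual


def scn_normalize(
    matrix: ContactMatrix, tol: float = 1e-6, max_iter: int = 2000
) -> Tuple[ContactMatrix, dict]:
    """Sequential component normalization (iterative row/column balancing).

    Rows are divided by their sums, then columns by theirs, and the loop
    stops when every non-empty row and column sum is within ``tol`` of the
    common value.  Each sweep is a pure diagonal scaling ``D1 M D2``, so the
    cross-ratios of all 2x2 minors are preserved exactly and a symmetric
    input converges to a symmetric balanced matrix (it is re-symmetrized
    once at the end to absorb roundoff).  All-zero rows are excluded and
    reported.
    """
    M = matrix.counts.astype(float).copy()
    n = M.shape[0]
    nonempty = M.sum(axis=1) > 0
    info = {"empty_rows": np.flatnonzero(~nonempty).tolist(), "n_iter": 0}
    idx = np.flatnonzero(nonempty)
    if idx.size == 0:
        out = matrix.copy()
        out.normalized = True
        return out, info

    sub = M[np.ix_(idx, idx)]
    residual = np.inf
    for it in range(1, max_iter + 1):
        rs = sub.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        sub = sub / rs
        cs = sub.sum(axis=0, keepdims=True)
        cs[cs == 0] = 1.0
        sub = sub / cs
        rsum, csum = sub.sum(axis=1), sub.sum(axis=0)
        common = rsum.mean()
        residual = float(
            max(np.max(np.abs(rsum - common)), np.max(np.abs(csum - common)))
        )
        if residual < tol:
            info["n_iter"] = it
            break
    else:
        raise ScnConvergenceError(residual, max_iter)

    sub = (sub + sub.T) / 2.0  # absorb roundoff asymmetry
    out = matrix.copy()
    out.counts = np.zeros((n, n))
    out.counts[np.ix_(idx, idx)] = sub
    out.normalized = True
    return out, info
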