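"""Comparison metrics between decompositions.

Two families: (1) content metrics — the average overlap between the
column (spatial-pattern) and row (spectral-pattern) subspaces captured by
two low-rank terms, defined as the mean of the singular values of the
inner product of the orthonormal bases (1 = same span, 0 = orthogonal
spans); (2) physicality metrics — ion counts are non-negative, so the
percentage, sum and mean of negative entries of a low-rank term measure
how far it strays from physical reality.  Per-term energies and global /
per-m/z entry-wise intensity histograms support the noise-reduction
analysis.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg

from .solvers import Decomposition


@dataclasses.dataclass
class OverlapResult:
    """Average column-/row-subspace overlap between two decompositions."""

    column_overlap: float
    row_overlap: float
    rank_a: int
    rank_b: int


@dataclasses.dataclass
class NegativityStats:
    """Percentage, sum and mean of the negative entries of a matrix."""

    pct_negative: float
    sum_negative: float
    mean_negative: float


def subspace_overlap(U1, U2, orthonormalize: bool = False) -> float:
    """Mean of the singular values of ``U1^T U2``.

    Both arguments must carry orthonormal columns spanning subspaces of
    the same ambient space; the singular values of the inner product are
    the cosines of the principal angles, so the mean lies in [0, 1]
    (clipped to absorb rounding).  Set ``orthonormalize=True`` to apply a
    QR orthonormalisation first instead of raising on non-orthonormal
    input.
    """
    U1 = np.asarray(U1, dtype=float)
    U2 = np.asarray(U2, dtype=float)
    if U1.ndim != 2 or U2.ndim != 2 or U1.shape[0] != U2.shape[0]:
        raise ValueError("bases must be 2-D with a common ambient dimension")
    if U1.shape[1] == 0 or U2.shape[1] == 0:
        raise ValueError("overlap undefined for an empty basis")
    if orthonormalize:
        U1 = scipy.linalg.qr(U1, mode="economic")[0]
        U2 = scipy.linalg.qr(U2, mode="economic")[0]
    else:
        for i, U in enumerate((U1, U2), 1):
            G = U.T @ U
            if not np.allclose(G, np.eye(U.shape[1]), atol=1e-8):
                raise ValueError(
                    f"basis {i} is not orthonormal within 1e-8; "
                    "pass orthonormalize=True to fix up"
                )
    s = scipy.linalg.svd(U1.T @ U2, compute_uv=False)
    return float(np.mean(np.clip(s, 0.0, 1.0)))


def decomposition_overlap(
    d1: Decomposition, d2: Decomposition, rank_mode: str = "matched"
) -> OverlapResult:
    """Column- and row-subspace overlap between two low-rank terms.

    ``rank_mode='matched'`` truncates both bases to the common leading
    rank before comparing (terms of similar rank compare like for like);
    ``'native'`` compares the full retrieved bases.
    """
    if d1.shape != d2.shape:
        raise ValueError("decompositions must share the matrix shape")
    if rank_mode not in ("matched", "native"):
        raise ValueError(f"unknown rank_mode {rank_mode!r}")
    r1, r2 = d1.rank_r, d2.rank_r
    if r1 == 0 or r2 == 0:
        raise ValueError("subspace overlap undefined for a rank-0 term")
    k1, k2 = (min(r1, r2),) * 2 if rank_mode == "matched" else (r1, r2)
    return OverlapResult(
        column_overlap=subspace_overlap(d1.U[:, :k1], d2.U[:, :k2]),
        row_overlap=subspace_overlap(d1.V[:, :k1], d2.V[:, :k2]),
        rank_a=r1,
        rank_b=r2,
    )


def negativity_stats(M) -> NegativityStats:
    """Percentage, sum and mean of negative entries (zeros when none)."""
    M = np.asarray(M, dtype=float)
    neg = M[M < 0]
    count = neg.size
    total = M.size
    s = float(neg.sum()) if count else 0.0
    return NegativityStats(
        pct_negative=100.0 * count / total if total else 0.0,
        sum_negative=s,
        mean_negative=s / count if count else 0.0,
    )


def term_energy(d: Decomposition) -> dict:
    """Squared Frobenius norm of each present term and of A (their sum
    per the method's conservation rule)."""
    out = {"B": float(np.sum(d.B**2))}
    A = d.B.copy()
    if d.C is not None:
        out["C"] = float(np.sum(d.C**2))
        A += d.C
    if d.D is not None:
        out["D"] = float(np.sum(d.D**2))
        A += d.D
    out["A"] = float(np.sum(A**2))
    return out


def intensity_histograms(
    d: Decomposition,
    bins: int = 201,
    range_mode: str = "shared",
    column: Optional[int] = None,
) -> pd.DataFrame:
    """Entry-wise intensity histograms of each decomposition term.

    With ``range_mode='shared'`` all terms are binned over one symmetric
    range ``[-a, a]`` with ``a = max |entry|`` across terms, making the
    term histograms directly comparable; ``'per_term'`` bins each term
    over its own range.  ``column`` restricts the analysis to a single
    m/z bin (one matrix column) for per-ion residual inspection.

    Returns a tidy frame with columns ``term, bin_left, bin_right, count``.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if range_mode not in ("shared", "per_term"):
        raise ValueError(f"unknown range_mode {range_mode!r}")
    terms = {"B": d.B}
    if d.C is not None:
        terms["C"] = d.C
    if d.D is not None:
        terms["D"] = d.D
    if column is not None:
        terms = {k: v[:, column] for k, v in terms.items()}

    rows = []
    if range_mode == "shared":
        a = max(np.abs(v).max() for v in terms.values())
        a = a if a > 0 else 1.0
        edges = np.linspace(-a, a, bins + 1)
    for name, M in terms.items():
        if range_mode == "per_term":
            a = np.abs(M).max()
            a = a if a > 0 else 1.0
            edges = np.linspace(-a, a, bins + 1)
        counts, _ = np.histogram(M.ravel(), bins=edges)
        for k in range(bins):
            rows.append(
                {"term": name, "bin_left": edges[k],
                 "bin_right": edges[k + 1], "count": int(counts[k])}
            )
    return pd.DataFrame(rows)
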