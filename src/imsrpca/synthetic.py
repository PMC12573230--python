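"""Synthetic ground-truth generators for low-rank + sparse + dense data.

Two generators: a theory-side one producing ``A = L0 + S0 + N0`` with
exactly known components for solver recovery tests, and an IMS-like one
emulating the structure the decomposition methods assume in tissue
data — a few smooth "anatomical layer" spatial patterns times
non-negative spectral loadings (low-rank), a handful of small
high-intensity structures active in few peaks (sparse), and dense
entry-wise noise.  Both are fully reproducible from a seed.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .datamodel import IMSMatrix


@dataclasses.dataclass
class SyntheticTruth:
    """Ground-truth components and the parameters that generated them.

    ``A = L0 + S0 + N0`` by construction (before any clipping; the
    IMS-like generator records the clipped amount in ``params``).
    """

    L0: np.ndarray
    S0: np.ndarray
    N0: np.ndarray
    support: np.ndarray  # boolean mask of S0's support
    params: dict

    @property
    def A(self) -> np.ndarray:
        return self.L0 + self.S0 + self.N0

    @property
    def column_basis(self) -> np.ndarray:
        """Orthonormal basis of L0's column space (its left singular
        vectors at the true rank)."""
        U, S, _ = np.linalg.svd(self.L0, full_matrices=False)
        r = int(np.count_nonzero(S > 1e-9 * S[0])) if S.size and S[0] > 0 else 0
        return U[:, :r]


def gen_lowrank_sparse(
    m: int,
    n: int,
    rank: int,
    sparsity: float,
    amp: float = 5.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> SyntheticTruth:
    """Exact-rank non-negative low-rank plus sparse plus noise instance.

    ``L0 = |G1| |G2|^T`` with ``G1 (m x rank)``, ``G2 (n x rank)``
    standard normal — taking absolute values of the *factors* keeps the
    rank exactly ``rank`` (with probability 1) while making L0
    non-negative like ion counts.  ``S0`` places entries of value
    ``+/- amp`` (signs uniform) on a uniformly random support of exactly
    ``round(sparsity * m * n)`` cells.  ``N0`` is i.i.d.
    ``Normal(0, noise_sigma)`` (signed; no clipping here so the additive
    model is exact for theory tests).
    """
    if rank > min(m, n):
        raise ValueError("rank cannot exceed min(m, n)")
    if not (0 <= sparsity < 1):
        raise ValueError("sparsity must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if rank == 0:
        L0 = np.zeros((m, n))
    else:
        G1 = np.abs(rng.standard_normal((m, rank)))
        G2 = np.abs(rng.standard_normal((n, rank)))
        L0 = G1 @ G2.T
    k = int(round(sparsity * m * n))
    support = np.zeros(m * n, dtype=bool)
    support[rng.choice(m * n, size=k, replace=False)] = True
    support = support.reshape(m, n)
    S0 = np.zeros((m, n))
    S0[support] = amp * rng.choice([-1.0, 1.0], size=k)
    N0 = (
        rng.normal(0.0, noise_sigma, size=(m, n))
        if noise_sigma > 0
        else np.zeros((m, n))
    )
    return SyntheticTruth(
        L0=L0, S0=S0, N0=N0, support=support,
        params={
            "m": m, "n": n, "rank": rank, "sparsity": sparsity,
            "amp": amp, "noise_sigma": noise_sigma, "seed": seed,
        },
    )


def _smooth_bands(height: int, width: int, n_layers: int, rng) -> np.ndarray:
    """Smooth horizontal band masks, one column per layer, values in [0, 1].

    Each layer is a horizontal band with a soft (logistic) edge profile,
    mimicking stacked anatomical layers viewed in section.
    """
    y = np.arange(height)[:, None]  # (height, 1)
    edges = np.linspace(0, height, n_layers + 1)
    softness = max(height / (6 * n_layers), 0.5)
    masks = np.empty((height * width, n_layers))
    for k in range(n_layers):
        lo, hi = edges[k], edges[k + 1]
        prof = 1.0 / (1.0 + np.exp(-(y - lo) / softness))
        prof *= 1.0 / (1.0 + np.exp((y - hi) / softness))
        masks[:, k] = np.repeat(prof[:, 0], width)
    return masks


def gen_synthetic_ims(
    height: int = 64,
    width: int = 64,
    n_peaks: int = 100,
    n_layers: int = 4,
    n_sparse_structs: int = 10,
    noise_sigma: float = 0.01,
    blob_amp: float = 5.0,
    seed: int = 0,
) -> tuple[IMSMatrix, SyntheticTruth]:
    """IMS-like datacube with layered low-rank plus sparse-blob structure.

    The low-rank part is ``n_layers`` smooth horizontal spatial bands
    times non-negative spectral loadings (half-normal per layer/peak),
    so the noiseless matrix has rank at most ``n_layers``.  The sparse
    part plants ``n_sparse_structs`` small high-intensity blobs (at most
    9 pixels, a 3x3 patch clipped at the grid edge), each active in 1-3
    peaks at amplitude ``blob_amp``.  Gaussian noise of level
    ``noise_sigma`` is added and the measurement is clipped at zero
    (ion counts are non-negative); the clipped amount is recorded in
    ``truth.params['clip_energy']`` and folded into ``N0`` so that
    ``A = L0 + S0 + N0`` remains exact.
    """
    if n_layers > n_peaks:
        raise ValueError("n_layers cannot exceed n_peaks")
    rng = np.random.default_rng(seed)
    m = height * width
    W = _smooth_bands(height, width, n_layers, rng)  # (m, n_layers)
    H = np.abs(rng.standard_normal((n_peaks, n_layers)))  # loadings >= 0
    L0 = W @ H.T

    S0 = np.zeros((m, n_peaks))
    for _ in range(n_sparse_structs):
        cy = rng.integers(0, height)
        cx = rng.integers(0, width)
        ys = np.clip(np.arange(cy - 1, cy + 2), 0, height - 1)
        xs = np.clip(np.arange(cx - 1, cx + 2), 0, width - 1)
        pix = np.unique(
            (ys[:, None] * width + xs[None, :]).ravel()
        )
        peaks = rng.choice(n_peaks, size=rng.integers(1, 4), replace=False)
        for p in peaks:
            S0[pix, p] += blob_amp
    support = S0 != 0

    noise = rng.normal(0.0, noise_sigma, size=(m, n_peaks))
    raw = L0 + S0 + noise
    A = np.maximum(raw, 0.0)
    clip_energy = float(np.sum((A - raw) ** 2))
    N0 = A - L0 - S0  # noise after clipping; keeps the sum exact

    coords = np.stack(
        [np.tile(np.arange(width), height), np.repeat(np.arange(height), width)],
        axis=1,
    )
    mz_axis = np.linspace(400.0, 1400.0, n_peaks)
    x = IMSMatrix(
        values=A, pixel_coords=coords, mz_axis=mz_axis,
        meta={"synthetic": True, "seed": seed},
    )
    truth = SyntheticTruth(
        L0=L0, S0=S0, N0=N0, support=support,
        params={
            "height": height, "width": width, "n_peaks": n_peaks,
            "n_layers": n_layers, "n_sparse_structs": n_sparse_structs,
            "noise_sigma": noise_sigma, "blob_amp": blob_amp,
            "seed": seed, "clip_energy": clip_energy,
        },
    )
    return x, truth
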