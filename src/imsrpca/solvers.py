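"""Low-rank + sparse + dense decompositions of IMS measurement matrices.

The shared model family is ``A = B + C + D`` where ``B = Y Z^T`` is
low-rank (rank r << min(m, n)), ``C`` is sparse and ``D`` is dense
entry-wise noise.  Three convex/spectral methods carve A up differently:

* PCA (truncated SVD): ``min ||A - B|| s.t. rank(B) <= r``; C absent,
  ``D = A - B``.
* PCP (principal component pursuit):
  ``min ||B||_* + lam ||C||_1  s.t.  A = B + C``; D absent.
* SPCP (stable PCP):
  ``min ||B||_* + theta ||C||_1  s.t.  ||A - B - C||_F <= delta``;
  ``D = A - B - C``.

PCP is solved by the inexact augmented-Lagrangian method (alternating
singular-value thresholding and soft thresholding with dual ascent and
geometric penalty growth).  SPCP is solved by the same splitting with an
auxiliary dense-residual variable projected onto the Frobenius ball of
radius delta each sweep; at delta = 0 the scheme reduces exactly to PCP.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from typing import Optional

import h5py
import numpy as np
import scipy.linalg
import scipy.sparse
from sklearn.utils.extmath import randomized_svd


class Method(str, enum.Enum):
    PCA = "pca"
    PCP = "pcp"
    SPCP = "spcp"


@dataclasses.dataclass
class SolverSettings:
    """Hyperparameters shared by the iterative solvers.

    Attributes
    ----------
    tol
        Relative Frobenius feasibility tolerance used for stopping
        (PCP: ||A-B-C||_F/||A||_F; SPCP: constraint satisfaction plus
        relative term change).
    max_iter
        Iteration budget; hitting it sets ``converged=False``.
    mu0
        Initial augmented-Lagrangian penalty; ``None`` selects
        ``1.25 / ||A||_2``.
    rho
        Geometric penalty growth factor (mu <- rho * mu), must be > 1.
    svd_strategy
        'exact' (LAPACK), 'randomized' (seeded, oversampling 10, 2 power
        iterations) or 'adaptive' (exact below a work-size threshold,
        randomized with adaptive rank growth above).
    rank_threshold
        Relative singular-value cutoff for reporting numerical rank.
    seed
        Seed for the randomized SVD.
    """

    tol: float = 1e-7
    max_iter: int = 1000
    mu0: Optional[float] = None
    rho: float = 1.5
    svd_strategy: str = "adaptive"
    rank_threshold: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.rho <= 1:
            raise ValueError("rho must exceed 1")
        if not (0 < self.rank_threshold < 1):
            raise ValueError("rank_threshold must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.svd_strategy not in ("exact", "randomized", "adaptive"):
            raise ValueError(f"unknown svd_strategy {self.svd_strategy!r}")


@dataclasses.dataclass
class Decomposition:
    """Result of one decomposition fit.

    ``B = U diag(S) V^T`` always holds (within round-off); ``C`` is None
    for PCA and ``D`` is None for PCP.  ``params`` records the solver
    parameters used and ``diagnostics`` the iteration count, final
    relative feasibility residual and convergence flag.
    """

    method: Method
    B: np.ndarray
    C: Optional[np.ndarray]
    D: Optional[np.ndarray]
    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    rank_r: int
    params: dict
    diagnostics: dict

    @property
    def shape(self):
        return self.B.shape


# ---------------------------------------------------------------------------
# proximal operators and SVD machinery
# ---------------------------------------------------------------------------

def soft_threshold(x, tau: float):
    """Entry-wise shrinkage sign(x) * max(|x| - tau, 0).

    The proximal map of ``tau * ||.||_1``; applied to the sparse term's
    update in PCP/SPCP.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def _exact_svd(M):
    return scipy.linalg.svd(M, full_matrices=False, lapack_driver="gesdd")


def _svd(M, settings: SolverSettings, rank_guess: Optional[int] = None):
    """SVD dispatcher: exact LAPACK or seeded randomized with rank growth.

    Randomized path grows its target rank until the smallest computed
    singular value is resolved relative to the largest, so downstream
    thresholding sees every value it could retain.
    """
    m, n = M.shape
    work = m * n
    use_exact = settings.svd_strategy == "exact" or (
        settings.svd_strategy == "adaptive" and work <= 5000 * 5000
    )
    if use_exact:
        return _exact_svd(M)
    k = min(max(rank_guess or 10, 1), min(m, n))
    while True:
        U, S, Vt = randomized_svd(
            M,
            n_components=k,
            n_oversamples=10,
            n_iter=2,
            random_state=settings.seed,
        )
        if k == min(m, n) or (S[0] > 0 and S[-1] < 1e-10 * S[0]):
            return U, S, Vt
        k = min(2 * k, min(m, n))


def svt(M, tau: float, settings: Optional[SolverSettings] = None,
        rank_guess: Optional[int] = None):
    """Singular-value thresholding, the proximal map of ``tau * ||.||_*``.

    Returns ``(U diag(max(S - tau, 0)) V^T, retained singular values)``
    where retained values are those strictly above tau (a value exactly
    equal to tau thresholds to zero).
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    settings = settings or SolverSettings()
    U, S, Vt = _svd(M, settings, rank_guess)
    keep = S > tau
    S_kept = S[keep] - tau
    out = (U[:, keep] * S_kept) @ Vt[keep]
    return out, S_kept


def numerical_rank(S, rank_threshold: float) -> int:
    """Count singular values above ``rank_threshold * S[0]`` (0 if S[0]=0)."""
    S = np.asarray(S, dtype=float)
    if S.size == 0 or S[0] == 0:
        return 0
    return int(np.count_nonzero(S > rank_threshold * S[0]))


def _fix_signs(U, V):
    """Make the largest-magnitude entry of each U column positive."""
    if U.shape[1] == 0:
        return U, V
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def _factorize(B, settings: SolverSettings):
    """SVD factors of a term B, sign-fixed, truncated at numerical rank."""
    U, S, Vt = _svd(B, settings)
    r = numerical_rank(S, settings.rank_threshold)
    U, V = _fix_signs(U[:, :r], Vt[:r].T)
    return U, S[:r], V, r


def _values_of(A):
    """Accept a bare matrix or an IMSMatrix-like object with .values."""
    vals = getattr(A, "values", A)
    return np.asarray(vals, dtype=np.float64)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_fit(A, r: int, settings: Optional[SolverSettings] = None) -> Decomposition:
    """Best rank-<=r approximation by truncated SVD; ``D = A - B``.

    Eckart-Young gives ``||A - B||_F^2`` equal to the tail singular-value
    energy, which serves as the module's cross-check oracle.
    """
    settings = settings or SolverSettings()
    A = _values_of(A)
    m, n = A.shape
    if not (0 <= r <= min(m, n)):
        raise ValueError(f"rank r={r} out of range [0, {min(m, n)}]")
    if r == 0:
        U = np.zeros((m, 0))
        S = np.zeros(0)
        V = np.zeros((n, 0))
    else:
        if settings.svd_strategy == "randomized" or (
            settings.svd_strategy == "adaptive" and m * n > 5000 * 5000
        ):
            U, S, Vt = randomized_svd(
                A, n_components=r, n_oversamples=10, n_iter=2,
                random_state=settings.seed,
            )
        else:
            U, S, Vt = _exact_svd(A)
            U, S, Vt = U[:, :r], S[:r], Vt[:r]
        U, V = _fix_signs(U, Vt.T)
    B = (U * S) @ V.T
    D = A - B
    rank_r = numerical_rank(S, settings.rank_threshold)
    return Decomposition(
        method=Method.PCA,
        B=B, C=None, D=D,
        U=U[:, :rank_r], S=S[:rank_r], V=V[:, :rank_r],
        rank_r=rank_r,
        params={"r": r},
        diagnostics={
            "iterations": 0,
            "residual": 0.0,
            "converged": True,
        },
    )


# ---------------------------------------------------------------------------
# PCP — inexact augmented Lagrangian
# ---------------------------------------------------------------------------

def _check_finite(A):
    if not np.all(np.isfinite(A)):
        raise ValueError("input matrix contains non-finite entries")


def pcp_fit(A, lam: float, settings: Optional[SolverSettings] = None) -> Decomposition:
    """Principal component pursuit: min ||B||_* + lam ||C||_1 s.t. A = B + C.

    Inexact ALM iteration: B-step is singular-value thresholding at 1/mu,
    C-step is soft thresholding at lam/mu, followed by dual ascent
    ``Y += mu (A - B - C)`` and penalty growth ``mu <- rho mu``.  Stops
    when the relative feasibility ``||A - B - C||_F / ||A||_F`` drops
    below ``settings.tol`` or the iteration budget is reached (the latter
    sets ``converged=False`` without raising).
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    settings = settings or SolverSettings()
    A = _values_of(A)
    _check_finite(A)
    normA = np.linalg.norm(A)
    m, n = A.shape
    if normA == 0:
        return _zero_decomposition(Method.PCP, m, n, {"lam": lam}, with_D=False)

    norm2 = np.linalg.norm(A, 2)
    mu = settings.mu0 if settings.mu0 is not None else 1.25 / norm2
    mu_bar = mu * 1e7
    # standard dual initialization: Y = A / max(||A||_2, ||A||_inf / lam)
    Y = A / max(norm2, np.abs(A).max() / lam)
    C = np.zeros_like(A)
    B = np.zeros_like(A)
    rank_guess = 10
    converged = False
    residual = np.inf
    S_kept = np.zeros(0)
    for it in range(1, settings.max_iter + 1):
        B, S_kept = svt(A - C + Y / mu, 1.0 / mu, settings, rank_guess)
        rank_guess = max(len(S_kept) + 1, 10)
        C = soft_threshold(A - B + Y / mu, lam / mu)
        R = A - B - C
        Y = Y + mu * R
        mu = min(mu * settings.rho, mu_bar)
        residual = np.linalg.norm(R) / normA
        if residual <= settings.tol:
            converged = True
            break
    U, S, V, rank_r = _factorize(B, settings)
    return Decomposition(
        method=Method.PCP,
        B=B, C=C, D=None,
        U=U, S=S, V=V, rank_r=rank_r,
        params={"lam": lam},
        diagnostics={
            "iterations": it,
            "residual": float(residual),
            "converged": converged,
        },
    )


# ---------------------------------------------------------------------------
# SPCP — alternating directions with Frobenius-ball projection
# ---------------------------------------------------------------------------

def _project_fro_ball(M, radius: float):
    """Project M onto the Frobenius ball of the given radius."""
    if radius <= 0:
        return np.zeros_like(M)
    norm = np.linalg.norm(M)
    if norm <= radius:
        return M.copy()
    return M * (radius / norm)


def spcp_fit(
    A, theta: float, delta: float, settings: Optional[SolverSettings] = None
) -> Decomposition:
    """Stable PCP: min ||B||_* + theta ||C||_1 s.t. ||A - B - C||_F <= delta.

    Splitting scheme over (B, C, D) with the exact constraint
    ``A = B + C + D`` and ``||D||_F <= delta``: B-step is SVT, C-step is
    soft thresholding, D-step projects the residual onto the Frobenius
    ball of radius delta; dual ascent and penalty growth as in PCP.  At
    ``delta = 0`` the D-step returns zero and the iteration coincides
    with :func:`pcp_fit`.  On exit ``D`` is set to ``A - B - C``
    identically.

    When ``delta >= ||A||_F`` the zero decomposition is feasible with
    objective 0, hence optimal; it is returned immediately.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    settings = settings or SolverSettings()
    A = _values_of(A)
    _check_finite(A)
    m, n = A.shape
    normA = np.linalg.norm(A)
    if normA == 0 or delta >= normA:
        d = _zero_decomposition(
            Method.SPCP, m, n, {"theta": theta, "delta": delta}, with_D=True
        )
        d.D = A - d.B - d.C
        return d

    norm2 = np.linalg.norm(A, 2)
    mu = settings.mu0 if settings.mu0 is not None else 1.25 / norm2
    mu_bar = mu * 1e7
    Y = A / max(norm2, np.abs(A).max() / theta)
    B = np.zeros_like(A)
    C = np.zeros_like(A)
    D = np.zeros_like(A)
    rank_guess = 10
    converged = False
    residual = np.inf
    prev_B = B
    prev_C = C
    for it in range(1, settings.max_iter + 1):
        B, S_kept = svt(A - C - D + Y / mu, 1.0 / mu, settings, rank_guess)
        rank_guess = max(len(S_kept) + 1, 10)
        C = soft_threshold(A - B - D + Y / mu, theta / mu)
        D = _project_fro_ball(A - B - C + Y / mu, delta)
        R = A - B - C - D
        Y = Y + mu * R
        mu = min(mu * settings.rho, mu_bar)
        residual = np.linalg.norm(R) / normA
        change = (
            np.linalg.norm(B - prev_B) + np.linalg.norm(C - prev_C)
        ) / normA
        prev_B, prev_C = B, C
        if residual <= settings.tol and change <= max(settings.tol, 1e-6):
            converged = True
            break
    D = A - B - C  # the dense residual is defined as the remainder
    U, S, V, rank_r = _factorize(B, settings)
    return Decomposition(
        method=Method.SPCP,
        B=B, C=C, D=D,
        U=U, S=S, V=V, rank_r=rank_r,
        params={"theta": theta, "delta": delta},
        diagnostics={
            "iterations": it,
            "residual": float(residual),
            "converged": converged,
            "D_norm": float(np.linalg.norm(D)),
        },
    )


def _zero_decomposition(method, m, n, params, with_D):
    Z = np.zeros((m, n))
    return Decomposition(
        method=method,
        B=Z.copy(),
        C=None if method is Method.PCA else Z.copy(),
        D=Z.copy() if with_D else None,
        U=np.zeros((m, 0)),
        S=np.zeros(0),
        V=np.zeros((n, 0)),
        rank_r=0,
        params=params,
        diagnostics={"iterations": 0, "residual": 0.0, "converged": True},
    )


# ---------------------------------------------------------------------------
# persistence (factors for B, triplets for C, dense D)
# ---------------------------------------------------------------------------

def save_decomposition(d: Decomposition, path) -> None:
    """Persist a decomposition: B via its SVD factors, C as sparse
    triplets, D dense (when present)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("B_factors")
        g.create_dataset("U", data=d.U)
        g.create_dataset("S", data=d.S)
        g.create_dataset("V", data=d.V)
        if d.C is not None:
            coo = scipy.sparse.coo_matrix(d.C)
            gc = f.create_group("C")
            gc.create_dataset("row", data=coo.row)
            gc.create_dataset("col", data=coo.col)
            gc.create_dataset("data", data=coo.data)
            gc.attrs["shape"] = d.C.shape
        if d.D is not None:
            f.create_dataset("D", data=d.D)
        f.attrs["method"] = d.method.value
        f.attrs["shape"] = d.B.shape
        f.attrs["rank_r"] = d.rank_r
        f.attrs["params"] = json.dumps(d.params)
        f.attrs["diagnostics"] = json.dumps(d.diagnostics)


def load_decomposition(path) -> Decomposition:
    """Inverse of :func:`save_decomposition`; B is rebuilt from factors."""
    with h5py.File(path, "r") as f:
        U = f["B_factors/U"][()]
        S = f["B_factors/S"][()]
        V = f["B_factors/V"][()]
        B = (U * S) @ V.T
        C = None
        if "C" in f:
            gc = f["C"]
            C = scipy.sparse.coo_matrix(
                (gc["data"][()], (gc["row"][()], gc["col"][()])),
                shape=tuple(gc.attrs["shape"]),
            ).toarray()
        D = f["D"][()] if "D" in f else None
        return Decomposition(
            method=Method(f.attrs["method"]),
            B=B, C=C, D=D, U=U, S=S, V=V,
            rank_r=int(f.attrs["rank_r"]),
            params=json.loads(f.attrs["params"]),
            diagnostics=json.loads(f.attrs["diagnostics"]),
        )
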