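"""Sweep orchestration, denoising, and ion-image quartets.

``run_sweep`` fits every point of a :class:`~imsrpca.parameters.ParameterGrid`,
records per-fit diagnostics, metrics against an optional reference
decomposition, and per-term energies, and (optionally) appends rows
incrementally to a CSV so an interrupted sweep can resume.  ``denoise``
rebuilds a cleaned IMSMatrix from a decomposition's structured terms, and
``image_quartet`` refolds the A/B/C/D columns of one m/z bin into the four
images used to inspect what each term captured spatially.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import IMSMatrix, IonImage, refold_image
from .metrics import decomposition_overlap, negativity_stats, term_energy
from .parameters import (
    ParameterGrid,
    delta_from_multiplier,
    lambda_from_multiplier,
    theta_from_multiplier,
)
from .solvers import (
    Decomposition,
    Method,
    SolverSettings,
    pca_fit,
    pcp_fit,
    spcp_fit,
)

logger = logging.getLogger("imsrpca")

SWEEP_COLUMNS = [
    "grid_index", "method", "r", "lam_mult", "theta_mult", "sigma_mult",
    "rank", "iterations", "residual", "converged",
    "column_overlap", "row_overlap",
    "pct_negative_B", "sum_negative_B", "mean_negative_B",
    "energy_A", "energy_B", "energy_C", "energy_D",
    "runtime_s", "error",
]


@dataclasses.dataclass
class SweepResult:
    """Table of per-grid-point records plus provenance."""

    table: pd.DataFrame
    method: Method
    seed: int
    n_points: int


def fit_grid_point(
    A, method: Method, point: dict, settings: SolverSettings
) -> Decomposition:
    """Fit one grid point, translating multipliers to solver parameters."""
    vals = getattr(A, "values", A)
    m, n = vals.shape
    if method is Method.PCA:
        return pca_fit(vals, point["r"], settings)
    if method is Method.PCP:
        lam = lambda_from_multiplier(point["lam_mult"], m, n)
        return pcp_fit(vals, lam, settings)
    theta = theta_from_multiplier(point["theta_mult"], m, n)
    delta = delta_from_multiplier(
        point["sigma_mult"], m, n, float(np.linalg.norm(vals))
    )
    return spcp_fit(vals, theta, delta, settings)


def run_sweep(
    x,
    grid: ParameterGrid,
    settings: Optional[SolverSettings] = None,
    reference: Optional[Decomposition] = None,
    csv_path=None,
) -> SweepResult:
    """Fit every grid point and collect metrics into one table.

    Grid points are independent; rows are keyed by ``grid_index`` so the
    output order is canonical.  When ``csv_path`` is given, rows are
    appended after each fit and points already present in the file are
    skipped, which makes an interrupted sweep resumable.  A fit that
    raises is recorded in its row's ``error`` column and never aborts
    the sweep.
    """
    settings = settings or SolverSettings()
    done: dict[int, dict] = {}
    csv_path = Path(csv_path) if csv_path is not None else None
    if csv_path is not None and csv_path.exists():
        # round_trip parsing keeps resumed rows bit-identical to the
        # values originally computed and written
        prev = pd.read_csv(csv_path, float_precision="round_trip")
        done = {int(r["grid_index"]): r.to_dict() for _, r in prev.iterrows()}

    rows = []
    for idx, point in grid.points():
        if idx in done:
            rows.append(done[idx])
            continue
        row = dict.fromkeys(SWEEP_COLUMNS)
        row["grid_index"] = idx
        row["method"] = grid.method.value
        row.update({k: point.get(k) for k in ("r", "lam_mult", "theta_mult", "sigma_mult")})
        t0 = time.perf_counter()
        try:
            d = fit_grid_point(x, grid.method, point, settings)
            row["rank"] = d.rank_r
            row["iterations"] = d.diagnostics["iterations"]
            row["residual"] = d.diagnostics["residual"]
            row["converged"] = d.diagnostics["converged"]
            neg = negativity_stats(d.B)
            row["pct_negative_B"] = neg.pct_negative
            row["sum_negative_B"] = neg.sum_negative
            row["mean_negative_B"] = neg.mean_negative
            en = term_energy(d)
            row["energy_A"] = en["A"]
            row["energy_B"] = en["B"]
            row["energy_C"] = en.get("C")
            row["energy_D"] = en.get("D")
            if reference is not None and d.rank_r > 0 and reference.rank_r > 0:
                ov = decomposition_overlap(d, reference)
                row["column_overlap"] = ov.column_overlap
                row["row_overlap"] = ov.row_overlap
            logger.info(
                "grid %d %s: rank=%d iters=%s residual=%.3g",
                idx, grid.method.value, d.rank_r,
                row["iterations"], row["residual"],
            )
        except Exception as exc:  # record, never abort the sweep
            row["error"] = f"{type(exc).__name__}: {exc}"
            logger.warning("grid %d failed: %s", idx, row["error"])
        row["runtime_s"] = time.perf_counter() - t0
        rows.append(row)
        if csv_path is not None:
            pd.DataFrame([row], columns=SWEEP_COLUMNS).to_csv(
                csv_path, mode="a", header=not csv_path.exists(), index=False
            )

    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS).sort_values(
        "grid_index", ignore_index=True
    )
    return SweepResult(
        table=table, method=grid.method, seed=settings.seed,
        n_points=len(grid),
    )


def denoise(
    x: IMSMatrix, d: Decomposition, keep_sparse: bool = False
) -> IMSMatrix:
    """Rebuild a denoised IMSMatrix from a decomposition.

    Returns ``B`` (``keep_sparse=False``) or ``B + C``
    (``keep_sparse=True``) with the original coordinates and m/z axis;
    the dense residual D is always dropped.  Whether to also drop C is
    application-specific: C carries small high-intensity structures, not
    only outliers.
    """
    if keep_sparse:
        if d.C is None:
            raise ValueError("keep_sparse=True requires a method with a "
                             "sparse term (PCP/SPCP); PCA has none")
        vals = d.B + d.C
    else:
        vals = d.B
    return x.with_values(vals, denoised=True, keep_sparse=keep_sparse)


def image_quartet(
    x: IMSMatrix, d: Decomposition, mz_index: int
) -> dict[str, IonImage]:
    """Refold the A, B, C, D columns of one m/z bin into four ion images.

    Absent terms (C for PCA, D for PCP) come back as zero images so the
    quartet always has four panels; check ``term in d`` semantics via
    ``d.C is None`` / ``d.D is None`` upstream if needed.
    """
    if not (0 <= mz_index < x.n):
        raise IndexError(f"mz_index {mz_index} out of range")

    def refold_col(col):
        vals = np.zeros_like(x.values)
        vals[:, mz_index] = col
        return refold_image(x.with_values(vals), mz_index)

    imgs = {"A": refold_image(x, mz_index)}
    for name, M in (("B", d.B), ("C", d.C), ("D", d.D)):
        imgs[name] = refold_col(
            M[:, mz_index] if M is not None else np.zeros(x.m)
        )
    return imgs
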