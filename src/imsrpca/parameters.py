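"""Dimension-free multiplier conventions and parameter sweep grids.

Because useful values of the PCP/SPCP regularisation parameters scale
with the matrix dimensions, sweeps are specified in terms of
dimension-free multipliers:

* ``lam = lam_mult / sqrt(max(m, n))``   (PCP sparsity weight)
* ``theta = theta_mult / sqrt(max(m, n))`` (SPCP sparsity weight)
* ``delta = sqrt(min(m, n) + sqrt(8 min(m, n))) * sigma_mult * ||A||_F``
  (SPCP noise-ball radius; the stable-PCP radius for i.i.d. noise of
  per-entry level ``sigma = sigma_mult * ||A||_F``)

The default sweep grids are: PCA ranks 1..min(m, n) in unit steps;
2000 linearly spaced lam-multipliers on [0.05, 3]; 100 linearly spaced
theta-multipliers on [0.4, 2.0] crossed with 100 log-spaced
sigma-multipliers on [1e-4, 1e-1] (10,000 SPCP pairs).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .solvers import Method

#: default multiplier sweep ranges
PCP_LAM_RANGE = (0.05, 3.0)
PCP_LAM_COUNT = 2000
SPCP_THETA_RANGE = (0.4, 2.0)
SPCP_THETA_COUNT = 100
SPCP_SIGMA_RANGE = (1e-4, 1e-1)
SPCP_SIGMA_COUNT = 100


@dataclasses.dataclass
class ParameterGrid:
    """Multiplier sweep specification for one method."""

    method: Method
    lam_multipliers: Optional[np.ndarray] = None
    theta_multipliers: Optional[np.ndarray] = None
    sigma_multipliers: Optional[np.ndarray] = None
    r_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("lam_multipliers", "theta_multipliers", "sigma_multipliers"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if np.any(v <= 0):
                    raise ValueError(f"{name} must be positive")
                setattr(self, name, v)
        if self.r_values is not None:
            self.r_values = np.asarray(self.r_values, dtype=int)
            if np.any(self.r_values < 1):
                raise ValueError("r_values must be >= 1")

    def points(self):
        """Enumerate grid points as (index, params-dict) pairs."""
        if self.method is Method.PCA:
            return [(i, {"r": int(r)}) for i, r in enumerate(self.r_values)]
        if self.method is Method.PCP:
            return [
                (i, {"lam_mult": float(v)})
                for i, v in enumerate(self.lam_multipliers)
            ]
        return [
            (i * len(self.sigma_multipliers) + j,
             {"theta_mult": float(t), "sigma_mult": float(s)})
            for i, t in enumerate(self.theta_multipliers)
            for j, s in enumerate(self.sigma_multipliers)
        ]

    def __len__(self) -> int:
        return len(self.points())


def lambda_from_multiplier(mult: float, m: int, n: int) -> float:
    """PCP sparsity weight: ``mult / sqrt(max(m, n))``."""
    if mult <= 0:
        raise ValueError("multiplier must be positive")
    return mult / math.sqrt(max(m, n))


def theta_from_multiplier(mult: float, m: int, n: int) -> float:
    """SPCP sparsity weight: ``mult / sqrt(max(m, n))``."""
    if mult <= 0:
        raise ValueError("multiplier must be positive")
    return mult / math.sqrt(max(m, n))


def delta_from_multiplier(
    sigma_mult: float, m: int, n: int, frobA: float
) -> float:
    """SPCP noise-ball radius from a sigma-multiplier.

    ``delta = sqrt(d + sqrt(8 d)) * sigma`` with ``d = min(m, n)`` and
    per-entry noise level ``sigma = sigma_mult * ||A||_F``.  This is the
    stable-PCP radius that contains i.i.d. noise of level sigma with
    high probability; the sigma-multiplier expresses the noise level
    relative to the measurement's total Frobenius energy.
    """
    if sigma_mult <= 0 or frobA <= 0:
        raise ValueError("sigma_mult and frobA must be positive")
    d = min(m, n)
    return math.sqrt(d + math.sqrt(8.0 * d)) * sigma_mult * frobA


def default_grids(method: Method, m: int, n: int) -> ParameterGrid:
    """Build the default sweep grid for one method at given matrix size."""
    method = Method(method)
    if method is Method.PCA:
        return ParameterGrid(
            method=method, r_values=np.arange(1, min(m, n) + 1)
        )
    if method is Method.PCP:
        return ParameterGrid(
            method=method,
            lam_multipliers=np.linspace(*PCP_LAM_RANGE, PCP_LAM_COUNT),
        )
    return ParameterGrid(
        method=method,
        theta_multipliers=np.linspace(*SPCP_THETA_RANGE, SPCP_THETA_COUNT),
        sigma_multipliers=np.logspace(
            math.log10(SPCP_SIGMA_RANGE[0]),
            math.log10(SPCP_SIGMA_RANGE[1]),
            SPCP_SIGMA_COUNT,
        ),
    )
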