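"""Partial nudged elastic band path optimization on analytic potentials.

A band of R replicas (default 60) connects two fixed endpoints. Each
optimization step applies the perpendicular component of the true force plus
a spring force along the local tangent (normalized central difference of the
neighboring replicas), with a spring constant of 10 energy units per Å².
Optimization follows a simulated-annealing protocol — heat, hold, cool —
where temperature enters as additive Gaussian kicks scaled by √T on a
damped-dynamics update; the outer loop stops when the band moves by less
than ΔRMSD = 0.3 Å between annealing iterations.

The "partial" restraint scope of PNEB — springs acting on a subset of atoms
— maps here to an optional coordinate mask; by default all coordinates are
restrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass
class PotentialSurface:
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    dim: int


@dataclass
class Band:
    replicas: np.ndarray          # R × D
    fixed_endpoints: bool = True

    def __post_init__(self):
        self.replicas = np.asarray(self.replicas, dtype=float)
        if self.replicas.ndim != 2 or self.replicas.shape[0] < 3:
            raise ValueError("band needs at least 3 replicas (R × D)")

    @property
    def n_replicas(self) -> int:
        return self.replicas.shape[0]

    @classmethod
    def linear(cls, start, end, n_replicas: int = 60) -> "Band":
        start, end = np.atleast_1d(start), np.atleast_1d(end)
        w = np.linspace(0.0, 1.0, n_replicas)[:, None]
        return cls(replicas=(1 - w) * start[None, :] + w * end[None, :])


@dataclass
class NEBParams:
    k_spring: float = 10.0        # kcal mol⁻¹ Å⁻² analog
    delta_rmsd: float = 0.3       # Å convergence threshold between anneal cycles
    t_max: float = 1.0            # peak annealing temperature (kick scale²)
    n_heat: int = 40
    n_hold: int = 20
    n_cool: int = 100
    step_size: float = 2e-3
    max_outer: int = 60
    restrained: np.ndarray | None = None   # coordinate mask for the springs

    def __post_init__(self):
        if self.k_spring <= 0 or self.delta_rmsd <= 0:
            raise ValueError("k_spring and delta_rmsd must be positive")

    def schedule(self) -> np.ndarray:
        """Temperature per inner step: 0→T_max, hold, T_max→0."""
        return np.concatenate([
            np.linspace(0.0, self.t_max, self.n_heat, endpoint=False),
            np.full(self.n_hold, self.t_max),
            np.linspace(self.t_max, 0.0, self.n_cool),
        ])


def neb_force(band: Band, potential: PotentialSurface,
              params: NEBParams) -> np.ndarray:
    """Perpendicular true force + tangential spring force; endpoints zero."""
    x = band.replicas
    R, D = x.shape
    F = np.zeros_like(x)
    mask = np.ones(D) if params.restrained is None else \
        np.asarray(params.restrained, dtype=float)
    for i in range(1, R - 1):
        t = x[i + 1] - x[i - 1]
        norm = np.linalg.norm(t)
        if norm < 1e-12:
            raise ValueError(f"degenerate band: replicas around {i} coincide")
        t = t / norm
        g = potential.gradient(x[i])
        f_perp = -(g - np.dot(g, t) * t)
        d_fwd = np.linalg.norm(x[i + 1] - x[i])
        d_bwd = np.linalg.norm(x[i] - x[i - 1])
        f_spring = params.k_spring * (d_fwd - d_bwd) * t * mask
        F[i] = f_perp + f_spring
    return F


def band_delta_rmsd(previous: Band, current: Band) -> float:
    """RMSD over movable replica coordinates (shared frame, no fitting)."""
    a, b = previous.replicas, current.replicas
    if a.shape != b.shape:
        raise ValueError("band shapes differ")
    return float(np.sqrt(np.mean((a[1:-1] - b[1:-1]) ** 2)))


def optimize_band(band: Band, potential: PotentialSurface,
                  params: NEBParams | None = None, seed: int = 0
                  ) -> tuple[Band, bool, int]:
    """Simulated-annealing NEB optimization.

    Repeats anneal cycles (damped force updates with √T Gaussian kicks on
    the interior replicas) until the band moves less than the ΔRMSD
    threshold between cycles, or the cycle budget is exhausted. Endpoints
    never move.
    """
    params = params or NEBParams()
    rng = np.random.default_rng(seed)
    x = band.replicas.copy()
    endpoints = (x[0].copy(), x[-1].copy())
    schedule = params.schedule()
    converged = False
    outer = 0
    for outer in range(1, params.max_outer + 1):
        prev = x.copy()
        for T in schedule:
            F = neb_force(Band(x), potential, params)
            if not np.all(np.isfinite(F)):
                raise FloatingPointError("non-finite force during optimization")
            x = x + params.step_size * F
            if T > 0:
                kick = rng.standard_normal(x.shape) * np.sqrt(T) * params.step_size
                kick[0] = kick[-1] = 0.0
                x = x + kick
            x[0], x[-1] = endpoints
        if not np.isfinite(sum(potential.energy(r) for r in x)):
            raise FloatingPointError("non-finite energy during optimization")
        if band_delta_rmsd(Band(prev), Band(x)) < params.delta_rmsd:
            converged = True
            break
    return Band(x), converged, outer


def band_energy_profile(band: Band, potential: PotentialSurface) -> np.ndarray:
    return np.array([potential.energy(r) for r in band.replicas])


# ---------------------------------------------------------------------------
# built-in toy potentials

def double_well_1d() -> PotentialSurface:
    """V(x) = (x² − 1)²: minima at ±1, barrier top at x = 0."""
    return PotentialSurface(
        energy=lambda x: float((x[0] ** 2 - 1) ** 2),
        gradient=lambda x: np.array([4 * x[0] * (x[0] ** 2 - 1)]),
        dim=1)


def quadratic_bowl(dim: int = 2, k: float = 1.0) -> PotentialSurface:
    return PotentialSurface(
        energy=lambda x: float(0.5 * k * np.dot(x, x)),
        gradient=lambda x: k * np.asarray(x, dtype=float),
        dim=dim)


def two_gaussian_wells(depth1: float = 5.0, depth2: float = 4.0,
                       width: float = 0.8) -> PotentialSurface:
    """Two Gaussian wells at (−1, 0) and (1, 0.8) in a confining bowl.

    The saddle between them is off the straight line joining the minima,
    which exercises the perpendicular relaxation of the band.
    """
    c1 = np.array([-1.0, 0.0])
    c2 = np.array([1.0, 0.8])
    w2 = width ** 2

    def energy(x):
        x = np.asarray(x, dtype=float)
        e = -depth1 * np.exp(-np.sum((x - c1) ** 2) / w2)
        e += -depth2 * np.exp(-np.sum((x - c2) ** 2) / w2)
        e += 0.25 * np.sum(x ** 2)
        return float(e)

    def gradient(x):
        x = np.asarray(x, dtype=float)
        g = (2 * depth1 / w2) * (x - c1) * np.exp(-np.sum((x - c1) ** 2) / w2)
        g += (2 * depth2 / w2) * (x - c2) * np.exp(-np.sum((x - c2) ** 2) / w2)
        g += 0.5 * x
        return g

    return PotentialSurface(energy=energy, gradient=gradient, dim=2)


BUILTIN_POTENTIALS = {
    "double_well": double_well_1d,
    "bowl": quadratic_bowl,
    "two_wells": two_gaussian_wells,
}
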