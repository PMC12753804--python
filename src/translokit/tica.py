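"""Distance featurization, time-lagged independent component analysis and
2D free-energy surfaces.

Features are Euclidean distances between Cα atoms (optionally strided) and,
when DNA is included, Cα–P and P–P distances to the ssDNA backbone. TICA
solves the generalized eigenproblem C_τ v = λ C_0 v with a symmetrized
lagged covariance, so eigenvalues are real and bounded by 1; components are
scaled so training-data projections have unit variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .formats_io import Topology, Trajectory

log = logging.getLogger(__name__)


@dataclass
class FeatureSpec:
    pairs: np.ndarray           # n_features × 2 atom indices
    include_dna: bool = True

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.pairs.ndim != 2 or self.pairs.shape[1] != 2:
            raise ValueError("pairs must be n × 2")
        if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise ValueError("self-pairs not allowed")
        keys = {tuple(sorted(p)) for p in self.pairs.tolist()}
        if len(keys) != len(self.pairs):
            raise ValueError("duplicate pairs")

    @property
    def n_features(self) -> int:
        return len(self.pairs)


@dataclass
class FeatureMatrix:
    values: np.ndarray          # frames × features, Å
    spec: FeatureSpec | None = field(default=None, repr=False)


@dataclass
class TICAModel:
    lag: int
    mean: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray      # features × n, scaled to unit output variance
    kept_columns: np.ndarray    # indices of non-constant input features

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass
class FESGrid:
    free_energy: np.ndarray     # bins × bins, kcal/mol; NaN where unoccupied
    x_edges: np.ndarray
    y_edges: np.ndarray
    kT: float

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.free_energy)


def build_feature_spec(topology: Topology, stride: int = 1,
                       include_dna: bool = True) -> FeatureSpec:
    """All unique pairs among the strided Cα set (plus Cα–P and P–P pairs)."""
    ca = topology.ca_indices()[::max(1, stride)]
    if len(ca) == 0:
        raise ValueError("topology has no Cα atoms")
    atoms = list(ca)
    if include_dna:
        atoms += list(topology.dna_p_indices())
    atoms = np.asarray(atoms)
    ii, jj = np.triu_indices(len(atoms), k=1)
    pairs = np.stack([atoms[ii], atoms[jj]], axis=1)
    return FeatureSpec(pairs=pairs, include_dna=include_dna)


def compute_features(traj: Trajectory | np.ndarray,
                     spec: FeatureSpec) -> FeatureMatrix:
    """Per-frame pair distances; entry (t, p) = |r_i(t) − r_j(t)|."""
    coords = traj.coordinates if isinstance(traj, Trajectory) else np.asarray(traj)
    if coords.ndim == 2:
        coords = coords[None]
    if spec.pairs.max() >= coords.shape[1]:
        raise IndexError("feature spec references atoms outside the trajectory")
    diff = coords[:, spec.pairs[:, 0], :] - coords[:, spec.pairs[:, 1], :]
    return FeatureMatrix(values=np.linalg.norm(diff, axis=2), spec=spec)


class CovarianceAccumulator:
    """Streaming accumulation of instantaneous and lagged covariances.

    Feeds per-trajectory feature blocks so no frame pair crosses a
    trajectory boundary; both time directions are accumulated, which
    symmetrizes the lagged covariance.
    """

    def __init__(self, n_features: int, lag: int):
        self.lag = lag
        self.n = 0
        self.sum = np.zeros(n_features)
        self.c00 = np.zeros((n_features, n_features))
        self.c0t = np.zeros((n_features, n_features))

    def add(self, X: np.ndarray) -> None:
        X = np.asarray(X, dtype=float)
        if X.shape[0] <= self.lag:
            return
        X0, Xt = X[:-self.lag], X[self.lag:]
        self.n += X0.shape[0]
        self.sum += 0.5 * (X0.sum(0) + Xt.sum(0))
        self.c00 += 0.5 * (X0.T @ X0 + Xt.T @ Xt)
        self.c0t += 0.5 * (X0.T @ Xt + Xt.T @ X0)

    def finalize(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self.n == 0:
            raise ValueError("no data longer than the lag")
        mean = self.sum / self.n
        C0 = self.c00 / self.n - np.outer(mean, mean)
        Ct = self.c0t / self.n - np.outer(mean, mean)
        return mean, C0, Ct


def _solve_tica(mean, C0, Ct, n) -> TICAModel:
    dim = C0.shape[0]
    eps = 1e-10 * np.trace(C0) / dim
    w, v = scipy.linalg.eigh(Ct, C0 + eps * np.eye(dim))
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    n = min(n, dim)
    lam, V = w[:n], v[:, :n]
    # unit output variance: var(Xv) = vᵀ C0 v
    scale = np.sqrt(np.einsum("ij,jk,ki->i", V.T, C0, V))
    scale[scale == 0] = 1.0
    V = V / scale[None, :]
    return TICAModel(lag=0, mean=mean, eigenvalues=lam, components=V,
                     kept_columns=np.arange(dim))


def fit_tica(X: FeatureMatrix | np.ndarray | list, lag: int,
             n_components: int = 10) -> TICAModel:
    """Fit TICA at the given lag (frames) keeping the top components.

    ``X`` may be one feature matrix or a list of per-trajectory matrices.
    Constant (zero-variance) columns are dropped with a logged notice; the
    near-singular C0 of collinear distance features is ridge-regularized.
    """
    blocks = _as_blocks(X)
    dim = blocks[0].shape[1]
    if any(b.shape[1] != dim for b in blocks):
        raise ValueError("inconsistent feature dimensions")
    variances = np.var(np.concatenate([b[: min(len(b), 10_000)] for b in blocks]),
                       axis=0)
    kept = np.where(variances > 1e-12)[0]
    if len(kept) < dim:
        log.info("dropping %d constant feature columns", dim - len(kept))
    if len(kept) == 0:
        raise ValueError("all feature columns are constant")
    acc = CovarianceAccumulator(len(kept), lag)
    for b in blocks:
        acc.add(b[:, kept])
    mean, C0, Ct = acc.finalize()
    model = _solve_tica(mean, C0, Ct, n_components)
    model.lag = lag
    model.kept_columns = kept
    return model


def _as_blocks(X) -> list[np.ndarray]:
    if isinstance(X, FeatureMatrix):
        return [X.values]
    if isinstance(X, np.ndarray):
        return [X]
    return [b.values if isinstance(b, FeatureMatrix) else np.asarray(b)
            for b in X]


def project(model: TICAModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Project features onto the independent components (frames × n)."""
    V = X.values if isinstance(X, FeatureMatrix) else np.asarray(X)
    if V.ndim == 1:
        V = V[None, :]
    if V.shape[1] == len(model.kept_columns):
        Xk = V
    elif V.shape[1] > max(model.kept_columns, default=-1):
        Xk = V[:, model.kept_columns]
    else:
        raise ValueError("feature dimension mismatch")
    return (Xk - model.mean) @ model.components


def free_energy_surface(Y: np.ndarray, kT: float = 0.5961,
                        bins: int = 60,
                        extent: tuple | None = None) -> FESGrid:
    """Boltzmann inversion of the (IC1, IC2) histogram.

    F = −kT ln(p/p_max) in kcal/mol (default kT for 300 K); the occupied-bin
    minimum is exactly 0 and empty bins are NaN.
    """
    Y = np.asarray(Y)
    if Y.ndim != 2 or Y.shape[0] < 1:
        raise ValueError("need at least one frame of 2D projections")
    H, xe, ye = np.histogram2d(Y[:, 0], Y[:, 1], bins=bins, range=extent)
    with np.errstate(divide="ignore"):
        F = -kT * np.log(H / H.max())
    F[H == 0] = np.nan
    return FESGrid(free_energy=F, x_edges=xe, y_edges=ye, kT=kT)


def write_fes(grid: FESGrid, path) -> None:
    """Plain-text free-energy matrix with bin-edge header lines."""
    with open(path, "w") as fh:
        fh.write("# x_edges " + " ".join(f"{v:.6g}" for v in grid.x_edges) + "\n")
        fh.write("# y_edges " + " ".join(f"{v:.6g}" for v in grid.y_edges) + "\n")
        fh.write(f"# kT {grid.kT}\n")
        np.savetxt(fh, grid.free_energy, fmt="%.6g")
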