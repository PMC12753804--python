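"""Markov state model construction and validation.

Covers the estimation chain used for helicase translocation kinetics:
k-means microstates in IC space, sliding-window transition counts,
maximum-likelihood reversible transition matrices, implied timescales,
the Chapman–Kolmogorov test, PCCA+ macrostates, mean first-passage times
and the on-path/trap decomposition of the coarse chain.

Tie-breaking is lowest-index everywhere and every stochastic step takes an
explicit seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.linalg
import scipy.sparse.csgraph as csgraph
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)


@dataclass
class MicrostateModel:
    k: int
    centers: np.ndarray
    labels: np.ndarray
    seed: int

    def assign(self, Y: np.ndarray) -> np.ndarray:
        """Nearest-center assignment of new projected frames."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        d2 = ((Y[:, None, :] - self.centers[None, :, :]) ** 2).sum(-1)
        return np.argmin(d2, axis=1)


@dataclass
class CountMatrix:
    C: np.ndarray
    lag: int
    mode: str = "sliding"


@dataclass
class TransitionMatrix:
    T: np.ndarray
    pi: np.ndarray
    reversible: bool = True
    #: indices of the original microstates kept after ergodic trimming
    active: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return self.T.shape[0]


@dataclass
class ImpliedTimescales:
    eigenvalues: np.ndarray
    timescales: np.ndarray  # seconds; NaN where undefined, inf for λ→1
    lag: int
    dt_seconds: float


@dataclass
class MacrostateModel:
    m: int
    chi: np.ndarray          # k × m fuzzy memberships, rows sum to 1
    crisp: np.ndarray        # per-microstate argmax assignment
    coarse_T: np.ndarray     # m × m row-stochastic
    weights: np.ndarray      # macrostate stationary weights
    micro: TransitionMatrix = field(repr=False)


@dataclass
class MFPTMatrix:
    mfpt: np.ndarray     # seconds, diagonal 0
    rates: np.ndarray    # 1/MFPT, diagonal 0


@dataclass
class PathwayDecomposition:
    on_path: list[int]
    traps: list[int]


# ---------------------------------------------------------------------------
# microstates and counts

def kmeans_cluster(Y: np.ndarray, k: int, seed: int) -> MicrostateModel:
    """k-means microstate clustering with k-means++ init and a fixed seed."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] < k:
        raise ValueError(f"need at least k={k} frames, got {Y.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed)
    labels = km.fit_predict(Y)
    return MicrostateModel(k=k, centers=km.cluster_centers_, labels=labels, seed=seed)


def count_matrix(labels, lag: int, n_states: int | None = None) -> CountMatrix:
    """Sliding-window transition counts at the given lag.

    ``labels`` is one integer sequence or a list of sequences; sequences are
    counted independently (no pairs across trajectory boundaries).
    """
    if lag <= 0:
        raise ValueError("lag must be positive")
    seqs = [np.asarray(labels, dtype=int)] if np.ndim(labels[0]) == 0 else \
        [np.asarray(s, dtype=int) for s in labels]
    if n_states is None:
        n_states = int(max(s.max() for s in seqs)) + 1
    C = np.zeros((n_states, n_states), dtype=np.int64)
    counted = False
    for s in seqs:
        if len(s) > lag:
            np.add.at(C, (s[:-lag], s[lag:]), 1)
            counted = True
    if not counted:
        raise ValueError(f"no sequence longer than lag={lag}")
    return CountMatrix(C=C, lag=lag)


# ---------------------------------------------------------------------------
# reversible estimation

def _largest_scc(C: np.ndarray) -> np.ndarray:
    n_comp, comp = csgraph.connected_components(C > 0, directed=True,
                                                connection="strong")
    if n_comp == 1:
        return np.arange(C.shape[0])
    sizes = np.bincount(comp, weights=C.sum(1) + C.sum(0))
    keep = np.where(comp == np.argmax(sizes))[0]
    log.warning("ergodic trimming: keeping %d of %d states", len(keep), C.shape[0])
    return keep


def estimate_reversible_T(counts: CountMatrix | np.ndarray,
                          tol: float = 1e-10,
                          max_iter: int = 100_000) -> TransitionMatrix:
    """Maximum-likelihood reversible transition matrix.

    The count matrix is first restricted to its largest strongly connected
    component. The MLE is found by the standard fixed-point iteration on the
    symmetric flux matrix x_ij, stopped when the largest element change of T
    falls below ``tol``.
    """
    C = counts.C if isinstance(counts, CountMatrix) else np.asarray(counts)
    C = np.asarray(C, dtype=float)
    active = _largest_scc(C)
    if len(active) == 0:
        raise ValueError("count matrix has no connected states")
    C = C[np.ix_(active, active)]
    c = C.sum(axis=1)
    Csym = C + C.T
    X = Csym.copy()
    X /= X.sum()
    T_prev = None
    for _ in range(max_iter):
        x = X.sum(axis=1)
        denom = c[:, None] / x[:, None] + c[None, :] / x[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            X = np.where(Csym > 0, Csym / denom, 0.0)
        x = X.sum(axis=1)
        T = X / x[:, None]
        if T_prev is not None and np.max(np.abs(T - T_prev)) < tol:
            break
        T_prev = T
    pi = x / x.sum()
    return TransitionMatrix(T=T, pi=pi, reversible=True, active=active)


def estimate_T(counts: CountMatrix | np.ndarray) -> TransitionMatrix:
    """Plain (non-reversible) maximum-likelihood transition matrix.

    Row-normalized counts on the largest strongly connected component.
    Unbiased under arbitrary start-state distributions, which makes it the
    right estimator for ground-truth label sequences sampled far from
    equilibrium; the reversible estimator remains the default for the MSM
    pipeline.
    """
    C = counts.C if isinstance(counts, CountMatrix) else np.asarray(counts)
    C = np.asarray(C, dtype=float)
    active = _largest_scc(C)
    C = C[np.ix_(active, active)]
    T = C / C.sum(axis=1, keepdims=True)
    return TransitionMatrix(T=T, pi=stationary_distribution(T),
                            reversible=False, active=active)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Left Perron eigenvector of a row-stochastic matrix, normalized."""
    w, v = scipy.linalg.eig(T.T)
    i = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _sorted_spectrum(tm: TransitionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and right eigenvectors of a reversible T.

    Uses the π-symmetrized form so the spectrum is real.
    """
    sqrt_pi = np.sqrt(tm.pi)
    S = sqrt_pi[:, None] * tm.T / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    w, u = scipy.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w, u = w[order], u[:, order]
    psi = u / sqrt_pi[:, None]
    # fix the sign of the stationary eigenvector to be positive
    if psi[0, 0] < 0:
        psi[:, 0] *= -1
    return w, psi


def implied_timescales(tm: TransitionMatrix, lag: int,
                       dt_seconds: float) -> ImpliedTimescales:
    """t_i = -(lag·Δt)/ln λ_i for eigenvalues below the stationary mode.

    Non-positive eigenvalues yield NaN (undefined); eigenvalues at 1 within
    numerical tolerance yield inf.
    """
    w, _ = _sorted_spectrum(tm)
    lam = w[1:]  # exclude the λ=1 stationary mode
    ts = np.full(lam.shape, np.nan)
    near_one = lam >= 1.0 - 1e-12
    ok = (lam > 0) & ~near_one
    ts[near_one] = np.inf
    ts[ok] = -(lag * dt_seconds) / np.log(lam[ok])
    return ImpliedTimescales(eigenvalues=lam, timescales=ts, lag=lag,
                             dt_seconds=dt_seconds)


def select_n_macrostates(its: ImpliedTimescales, max_m: int) -> int:
    """Pick the macrostate count at the largest implied-timescale gap.

    With timescales sorted descending, m = 1 + i where i (1-based) indexes
    the largest ratio t_i/t_{i+1} among the top ``max_m`` timescales; ties
    break toward the smaller m.
    """
    ts = its.timescales[np.isfinite(its.timescales) & (its.timescales > 0)]
    ts = np.sort(ts)[::-1][:max_m]
    if len(ts) < 2:
        raise ValueError("need at least two finite timescales")
    ratios = ts[:-1] / ts[1:]
    return int(np.argmax(ratios)) + 2


# ---------------------------------------------------------------------------
# PCCA+ coarse-graining

def _inner_simplex_vertices(psi: np.ndarray) -> np.ndarray:
    """Indices of m rows of ψ spanning the inner simplex (ISA algorithm)."""
    k, m = psi.shape
    ortho = psi.copy()
    idx = np.zeros(m, dtype=int)
    idx[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho = ortho - ortho[idx[0]]
    for j in range(1, m):
        dist = np.linalg.norm(ortho, axis=1)
        idx[j] = int(np.argmax(dist))
        v = ortho[idx[j]] / dist[idx[j]]
        ortho = ortho - np.outer(ortho @ v, v)
    return idx


def pcca_coarse_grain(tm: TransitionMatrix, m: int) -> MacrostateModel:
    """PCCA+ fuzzy coarse-graining into m macrostates.

    Memberships come from the inner-simplex feasible guess (vertex
    microstates map to the unit vectors); negative entries are clipped and
    rows renormalized. The coarse transition matrix is the π-weighted
    projection (χᵀ diag(π) T χ normalized by the projected weights).
    """
    if m < 2:
        raise ValueError("need m >= 2 macrostates")
    if m > tm.n_states:
        raise ValueError("m exceeds number of microstates")
    w, psi = _sorted_spectrum(tm)
    if np.any(np.abs(np.imag(w[:m])) > 1e-10):
        raise ValueError("complex dominant eigenvalues; chain not reversible")
    psi_m = psi[:, :m]
    idx = _inner_simplex_vertices(psi_m)
    A = np.linalg.inv(psi_m[idx])
    chi = psi_m @ A
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    crisp = np.argmax(chi, axis=1)
    D = tm.pi[:, None] * chi  # diag(π) χ
    coarse = chi.T @ (tm.pi[:, None] * tm.T) @ chi
    norm = chi.T @ D
    coarse = np.linalg.solve(norm, coarse)
    coarse = np.clip(coarse, 0.0, None)
    coarse /= coarse.sum(axis=1, keepdims=True)
    weights = chi.T @ tm.pi
    return MacrostateModel(m=m, chi=chi, crisp=crisp, coarse_T=coarse,
                           weights=weights, micro=tm)


# ---------------------------------------------------------------------------
# kinetics

def markov_mfpt(T: np.ndarray, targets, step_seconds: float) -> np.ndarray:
    """MFPT (seconds) from every state to the target set on a discrete chain.

    Solves m_i = Δ + Σ_{j∉B} T_ij m_j with m_B = 0, where Δ is the physical
    duration of one chain step.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    targets = np.atleast_1d(np.asarray(targets, dtype=int))
    rest = np.setdiff1d(np.arange(n), targets)
    A = np.eye(len(rest)) - T[np.ix_(rest, rest)]
    try:
        m_rest = np.linalg.solve(A, np.full(len(rest), step_seconds))
    except np.linalg.LinAlgError as exc:
        raise ValueError("target set unreachable from some states") from exc
    m = np.zeros(n)
    m[rest] = m_rest
    return m


def mfpt_and_rates(model: MacrostateModel, lag: int,
                   dt_seconds: float) -> MFPTMatrix:
    """Pairwise macrostate MFPTs computed on the microstate chain.

    MFPT(A→B) solves the first-passage linear system on the microstate
    transition matrix with the crisp members of B absorbing, then averages
    over the crisp members of A with π weights. Rates are 1/MFPT.
    """
    tm = model.micro
    step = lag * dt_seconds
    m = model.m
    out = np.zeros((m, m))
    for b in range(m):
        members_b = np.where(model.crisp == b)[0]
        if len(members_b) == 0:
            raise ValueError(f"macrostate {b} has no crisp members")
        mf = markov_mfpt(tm.T, members_b, step)
        for a in range(m):
            if a == b:
                continue
            members_a = np.where(model.crisp == a)[0]
            wa = tm.pi[members_a]
            out[a, b] = np.average(mf[members_a], weights=wa)
    with np.errstate(divide="ignore"):
        rates = np.where(out > 0, 1.0 / np.where(out > 0, out, 1.0), 0.0)
    return MFPTMatrix(mfpt=out, rates=rates)


def decompose_pathway(model_or_T, source: int, sink: int) -> PathwayDecomposition:
    """Maximum-probability source→sink path on the coarse chain; rest = traps.

    The path maximizes the product of step probabilities, i.e. the shortest
    path under edge weight −ln T_ij (edges with T_ij = 0 absent).
    """
    if source == sink:
        raise ValueError("source and sink must differ")
    T = model_or_T.coarse_T if isinstance(model_or_T, MacrostateModel) else \
        np.asarray(model_or_T, dtype=float)
    n = T.shape[0]
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if i != j and T[i, j] > 0:
                G.add_edge(i, j, weight=-np.log(T[i, j]))
    try:
        path = nx.shortest_path(G, source, sink, weight="weight")
    except nx.NetworkXNoPath as exc:
        raise ValueError(f"sink {sink} unreachable from source {source}") from exc
    traps = sorted(set(range(n)) - set(path))
    return PathwayDecomposition(on_path=list(path), traps=traps)


# ---------------------------------------------------------------------------
# validation

def ck_test(tm: TransitionMatrix, labels, lag: int, multiples,
            sets: list[np.ndarray] | None = None) -> dict[int, float]:
    """Chapman–Kolmogorov test: T(kτ) estimated directly vs T(τ)^k.

    Comparison is aggregated over the given state sets (default: each
    microstate its own set). Returns {k: max |ΔP|}.
    """
    results: dict[int, float] = {}
    n = tm.n_states
    active = tm.active if tm.active is not None else np.arange(n)
    if sets is None:
        sets = [np.array([i]) for i in range(n)]
    for k in multiples:
        if k == 1:
            results[1] = 0.0
            continue
        Ck = count_matrix(labels, lag * k, n_states=int(active.max()) + 1)
        tm_k = estimate_reversible_T(Ck)
        # map back into the original index space for comparison
        Tk_direct = np.zeros((n, n))
        pos = {orig: i for i, orig in enumerate(tm_k.active)}
        pos_base = {orig: i for i, orig in enumerate(active)}
        for oi in tm_k.active:
            for oj in tm_k.active:
                if oi in pos_base and oj in pos_base:
                    Tk_direct[pos_base[oi], pos_base[oj]] = tm_k.T[pos[oi], pos[oj]]
        Tk_power = np.linalg.matrix_power(tm.T, k)
        dev = 0.0
        for A in sets:
            wa = tm.pi[A]
            if wa.sum() == 0:
                continue
            wa = wa / wa.sum()
            for B in sets:
                p_direct = float(wa @ Tk_direct[np.ix_(A, B)].sum(axis=1))
                p_power = float(wa @ Tk_power[np.ix_(A, B)].sum(axis=1))
                dev = max(dev, abs(p_direct - p_power))
        results[int(k)] = dev
    return results
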