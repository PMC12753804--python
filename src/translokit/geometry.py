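"""Domain-level geometric descriptors of the helicase–ssDNA complex.

Centers of mass, the Arch↔Fe–S distance d_AF, the Fe–S/RecA1/Arch angle θ,
constriction channel widths, macrostate centroid structures, Cα displacement
fields (porcupine vectors) and the ssDNA translocation register.

The channel width of a constriction is the symmetrized directed mean of
minima: for each wall-A residue take the minimum heavy-atom distance to the
opposite wall, average over residues, and average the two directions. On two
flat parallel walls this reduces to the wall separation and it is robust to
single-atom outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .formats_io import Topology, Trajectory


@dataclass
class DomainGeometry:
    com: dict[str, np.ndarray]
    d_af: float
    theta: float  # degrees


@dataclass
class ConstrictionDefinition:
    name: str
    wall_a: frozenset[int]   # residue numbers lining one side
    wall_b: frozenset[int]
    chain: str = "A"
    enclosed_nucleotides: int = 4

    def __post_init__(self):
        if not self.wall_a or not self.wall_b:
            raise ValueError("constriction walls must be non-empty")
        if set(self.wall_a) & set(self.wall_b):
            raise ValueError("constriction walls must be disjoint")


@dataclass
class WidthSeries:
    widths: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        self.mean = float(np.mean(self.widths))
        self.sd = float(np.std(self.widths, ddof=1)) if len(self.widths) > 1 else 0.0


def center_of_mass(coords: np.ndarray, topology: Topology, domain: str) -> np.ndarray:
    sel = topology.domain_label == domain
    if not np.any(sel):
        raise ValueError(f"domain {domain!r} has no atoms")
    w = topology.mass[sel]
    return np.average(coords[sel], axis=0, weights=w)


def domain_geometry(frame: np.ndarray, topology: Topology) -> DomainGeometry:
    """Mass-weighted domain COMs, d_AF and θ (vertex at the RecA1 COM).

    RecA1, Arch and Fe–S must be populated; other domains contribute a COM
    only when present.
    """
    coms = {}
    for d in ("RecA1", "RecA2", "Arch", "FeS"):
        if d in ("RecA1", "Arch", "FeS") or np.any(topology.domain_label == d):
            coms[d] = center_of_mass(frame, topology, d)
    d_af = float(np.linalg.norm(coms["Arch"] - coms["FeS"]))
    v1 = coms["FeS"] - coms["RecA1"]
    v2 = coms["Arch"] - coms["RecA1"]
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    theta = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return DomainGeometry(com=coms, d_af=d_af, theta=theta)


def _wall_atom_indices(definition: ConstrictionDefinition,
                       topology: Topology) -> tuple[np.ndarray, np.ndarray]:
    prot = topology.chain_id == definition.chain
    a = np.where(prot & np.isin(topology.res_id, list(definition.wall_a)))[0]
    b = np.where(prot & np.isin(topology.res_id, list(definition.wall_b)))[0]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"{definition.name}: wall residues absent from topology")
    return a, b


def constriction_width(frame: np.ndarray, definition: ConstrictionDefinition,
                       topology: Topology) -> float:
    """Channel width (Å) of one constriction in one frame."""
    ia, ib = _wall_atom_indices(definition, topology)
    D = cdist(frame[ia], frame[ib])
    # per-residue minima: group atoms by residue on each side
    res_a = topology.res_id[ia]
    res_b = topology.res_id[ib]
    mins_a = [D[res_a == r].min() for r in np.unique(res_a)]
    mins_b = [D[:, res_b == r].min() for r in np.unique(res_b)]
    return 0.5 * (float(np.mean(mins_a)) + float(np.mean(mins_b)))


def width_series(traj: Trajectory, definition: ConstrictionDefinition,
                 topology: Topology) -> WidthSeries:
    w = np.array([constriction_width(traj.coordinates[t], definition, topology)
                  for t in range(traj.frame_count)])
    return WidthSeries(widths=w)


# ---------------------------------------------------------------------------
# superposition

def kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing |R·mobile + t − ref|."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    H = (mobile - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = rc - R @ mc
    return R, t


def superpose(mobile_frame: np.ndarray, ref_frame: np.ndarray,
              fit_indices: np.ndarray) -> np.ndarray:
    """Superpose a full frame onto a reference using the fit-atom subset."""
    R, t = kabsch(mobile_frame[fit_indices], ref_frame[fit_indices])
    return mobile_frame @ R.T + t


def ca_rmsd(frame_a: np.ndarray, frame_b: np.ndarray,
            topology: Topology) -> float:
    """Cα RMSD after optimal superposition."""
    ca = topology.ca_indices()
    b = superpose(frame_b, frame_a, ca)
    return float(np.sqrt(np.mean(np.sum((frame_a[ca] - b[ca]) ** 2, axis=1))))


def macrostate_centroid(traj: Trajectory, labels: np.ndarray, state,
                        topology: Topology, seed: int = 0,
                        max_members: int = 500) -> int:
    """Index of the member frame minimizing mean Cα RMSD to all other members.

    For states with more than ``max_members`` frames a seeded subsample is
    used. Ties break toward the lowest frame index.
    """
    members = np.where(np.asarray(labels) == state)[0]
    if len(members) == 0:
        raise ValueError(f"macrostate {state!r} has no frames")
    if len(members) > max_members:
        rng = np.random.default_rng(seed)
        members = np.sort(rng.choice(members, size=max_members, replace=False))
    if len(members) == 1:
        return int(members[0])
    ca = topology.ca_indices()
    X = traj.coordinates[members][:, ca, :]
    n = len(members)
    total = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            bj = superpose(X[j], X[i], np.arange(X.shape[1]))
            r = np.sqrt(np.mean(np.sum((X[i] - bj) ** 2, axis=1)))
            total[i] += r
            total[j] += r
    return int(members[np.argmin(total)])


@dataclass
class DisplacementField:
    ca_indices: np.ndarray
    vectors: np.ndarray  # per-Cα displacement B − A after superposition


def displacement_field(centroid_a: np.ndarray, centroid_b: np.ndarray,
                       topology: Topology) -> DisplacementField:
    """Per-Cα displacement vectors between two superposed structures."""
    if centroid_a.shape != centroid_b.shape:
        raise ValueError("centroid structures differ in shape")
    ca = topology.ca_indices()
    b = superpose(centroid_b, centroid_a, ca)
    return DisplacementField(ca_indices=ca, vectors=b[ca] - centroid_a[ca])


# ---------------------------------------------------------------------------
# DNA register

def dna_register_offset(frame_x: np.ndarray, frame_y: np.ndarray,
                        topology: Topology, tie_tol: float = 1e-6) -> int:
    """Integer nucleotide offset of Y relative to X (positive = toward 3′ exit).

    Both frames are put in the protein-fixed frame (superposition on all
    protein atoms); the offset maximizing correspondence of the DNA P-atom
    positions is returned. An exact tie between two offsets is an error.
    """
    prot = np.where(~topology.is_dna() & (topology.atom_name == "CA"))[0]
    p_idx = topology.dna_p_indices()
    if len(p_idx) == 0:
        raise ValueError("topology has no DNA P atoms")
    y = superpose(frame_y, frame_x, prot)
    px = frame_x[p_idx]
    py = y[p_idx]
    L = len(p_idx)
    best: dict[int, float] = {}
    for s in range(-(L - 1), L):
        i = np.arange(L)
        keep = (i + s >= 0) & (i + s < L)
        if keep.sum() < max(2, L // 2):
            continue
        d = np.linalg.norm(py[i[keep]] - px[i[keep] + s], axis=1)
        best[s] = float(np.mean(d))
    scores = sorted(best.items(), key=lambda kv: (kv[1], abs(kv[0]), kv[0]))
    if len(scores) > 1 and scores[1][1] - scores[0][1] < tie_tol:
        cands = [s for s, v in scores if v - scores[0][1] < tie_tol]
        raise ValueError(f"ambiguous DNA register: candidate offsets {sorted(cands)}")
    return int(scores[0][0])
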