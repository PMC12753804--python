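"""Topology/trajectory containers and PDB I/O.

Coordinates are in Å throughout; the PDB dialect is fixed-column with
3-decimal coordinates, so write→read round-trips are exact to 1e-3 Å.
Residue numbering is 1-based and domain ranges are inclusive on both ends.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

log = logging.getLogger(__name__)

DOMAIN_LABELS = ("RecA1", "RecA2", "Arch", "FeS", "DNA", "other")
DNA_RESNAMES = {"DA", "DT", "DG", "DC", "DU", "A", "T", "G", "C", "U"}

#: standard atomic masses for the elements appearing in our models; pseudo-atoms
#: that summarize a side chain carry carbon mass unless stated otherwise.
ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "MG": 24.305, "FE": 55.845, "X": 12.011,
}


def load_residue_classes() -> dict:
    """Load the packaged per-residue chemical-class table."""
    with resources.files("translokit.data").joinpath("residue_classes.json").open() as fh:
        table = json.load(fh)
    table.pop("_comment", None)
    return table


@dataclass
class Topology:
    """Atom table with chemical-class and domain annotations.

    All per-atom fields are parallel numpy arrays. ``ring_id`` is -1 for
    atoms not part of an aromatic ring; positive ids group ring atoms.
    ``charge`` is +1/0/-1 (positive/neutral/negative class).
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    domain_label: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    charge: np.ndarray
    ring_id: np.ndarray
    nonpolar: np.ndarray
    mass: np.ndarray

    def __post_init__(self):
        n = len(self.atom_name)
        for name in ("element", "res_name", "res_id", "chain_id", "domain_label",
                     "donor", "acceptor", "charge", "ring_id", "nonpolar", "mass"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def atom_ids(self) -> np.ndarray:
        """Dense 0-based atom ids."""
        return np.arange(self.n_atoms)

    def mask(self, *, domain: str | None = None, atom_name: str | None = None,
             chain: str | None = None) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)
        if domain is not None:
            m &= self.domain_label == domain
        if atom_name is not None:
            m &= self.atom_name == atom_name
        if chain is not None:
            m &= self.chain_id == chain
        return m

    def ca_indices(self) -> np.ndarray:
        """Indices of protein Cα atoms."""
        return np.where((self.atom_name == "CA") & (self.domain_label != "DNA"))[0]

    def dna_p_indices(self) -> np.ndarray:
        """Indices of DNA backbone phosphorus atoms."""
        return np.where((self.atom_name == "P") & (self.domain_label == "DNA"))[0]

    def is_dna(self) -> np.ndarray:
        return self.domain_label == "DNA"

    def residue_key(self) -> np.ndarray:
        """Per-atom residue key '<chain>:<resid>' used for residue-level grouping."""
        return np.char.add(np.char.add(self.chain_id.astype(str), ":"),
                           self.res_id.astype(str))

    def validate(self) -> None:
        """Check structural invariants (monotone numbering, ring sizes)."""
        for ch in np.unique(self.chain_id):
            rid = self.res_id[self.chain_id == ch]
            if np.any(np.diff(rid) < 0):
                raise ValueError(f"residue numbering not monotone in chain {ch}")
        for ring in np.unique(self.ring_id):
            if ring < 0:
                continue
            if np.sum(self.ring_id == ring) < 5:
                raise ValueError(f"aromatic ring {ring} groups fewer than 5 atoms")


@dataclass
class Trajectory:
    """Conformational ensemble: frames × atoms × 3 coordinates (Å)."""

    coordinates: np.ndarray
    frame_interval_ps: float
    topology: Topology | None = field(default=None, repr=False)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be frames × atoms × 3")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval must be positive")
        if self.topology is not None and self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError("atom count mismatch between coordinates and topology")

    @property
    def frame_count(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


def _residue_runs(chain_id: np.ndarray, res_id: np.ndarray) -> np.ndarray:
    """Per-atom integer run index that changes whenever (chain, resid) changes."""
    change = np.r_[True, (chain_id[1:] != chain_id[:-1]) | (res_id[1:] != res_id[:-1])]
    return np.cumsum(change) - 1


def topology_from_arrays(atom_name, element, res_name, res_id, chain_id,
                         annotation_rules: dict | None = None) -> Topology:
    """Build an annotated :class:`Topology` from parallel per-atom arrays."""
    atom_name = np.asarray(atom_name, dtype=object)
    element = np.asarray(element, dtype=object)
    res_name = np.asarray(res_name, dtype=object)
    res_id = np.asarray(res_id, dtype=int)
    chain_id = np.asarray(chain_id, dtype=object)
    table = load_residue_classes()
    if annotation_rules:
        table = {**table, **annotation_rules}

    # classification is per residue instance; split on residue runs so ring ids
    # are unique per instance
    runs = _residue_runs(chain_id, res_id)
    n = len(atom_name)
    donor = np.zeros(n, bool)
    acceptor = np.zeros(n, bool)
    charge = np.zeros(n, np.int8)
    ring_id = np.full(n, -1, int)
    nonpolar = np.zeros(n, bool)
    ring_counter = 0
    unknown: set[str] = set()
    for r in range(runs[-1] + 1 if n else 0):
        sel = runs == r
        idx = np.where(sel)[0]
        rn = res_name[idx[0]]
        entry = table.get(rn)
        if entry is None:
            unknown.add(str(rn))
            continue
        is_protein = rn not in DNA_RESNAMES
        for i in idx:
            an = atom_name[i]
            if an in entry["donor"] or (is_protein and an == "N"):
                donor[i] = True
            if an in entry["acceptor"] or (is_protein and an == "O"):
                acceptor[i] = True
            if an in entry["positive"]:
                charge[i] = 1
            elif an in entry["negative"]:
                charge[i] = -1
            if an in entry["nonpolar"]:
                nonpolar[i] = True
        if entry["ring"]:
            hit = idx[np.isin(atom_name[idx], entry["ring"])]
            if len(hit) >= 5:
                ring_id[hit] = ring_counter
                ring_counter += 1
    if unknown:
        log.warning("unknown residues %s: defaulting to neutral non-donor atoms",
                    sorted(unknown))

    mass = np.array([ELEMENT_MASS.get(str(e).upper(), 12.011) for e in element])
    domain = np.array(["DNA" if rn in DNA_RESNAMES else "other" for rn in res_name],
                      dtype=object)
    return Topology(atom_name, element, res_name, res_id, chain_id, domain,
                    donor, acceptor, charge, ring_id, nonpolar, mass)


def read_pdb_topology(path, annotation_rules: dict | None = None) -> Topology:
    """Read the first model of a PDB file into an annotated Topology.

    Unknown residues are classified with neutral/non-donor defaults and a
    logged warning rather than failing.
    """
    pdb = PDBFile.read(str(path))
    _scan_models(pdb.lines)  # raises on duplicate serials
    atoms = pdb.get_structure(model=1)
    return topology_from_arrays(atoms.atom_name.astype(object),
                                atoms.element.astype(object),
                                atoms.res_name.astype(object),
                                atoms.res_id,
                                atoms.chain_id.astype(object),
                                annotation_rules)


def _scan_models(lines: Sequence[str]) -> list[int]:
    """Count coordinate records per MODEL block; check serial uniqueness.

    Returns per-model atom counts (a single implicit model if no MODEL
    records are present).
    """
    counts: list[int] = []
    serials: set[str] = set()
    current = 0
    in_model = False
    saw_model = False
    for line in lines:
        rec = line[:6]
        if rec == "MODEL ":
            saw_model = True
            in_model = True
            current = 0
            serials = set()
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM  ", "HETATM"):
            current += 1
            serial = line[6:11]
            if serial in serials:
                raise ValueError(f"duplicate atom serial {serial.strip()} within one model")
            serials.add(serial)
    if not saw_model:
        counts = [current]
    elif in_model:
        counts.append(current)
    return counts


def read_multimodel_trajectory(path, topology: Topology,
                               frame_interval_ps: float) -> Trajectory:
    """Read a multi-model PDB as a trajectory ordered by MODEL index."""
    pdb = PDBFile.read(str(path))
    counts = _scan_models(pdb.lines)
    if len(counts) == 0 or sum(counts) == 0:
        raise ValueError("PDB file contains zero models")
    for k, c in enumerate(counts, start=1):
        if c != topology.n_atoms:
            raise ValueError(
                f"model {k} has {c} atoms, topology has {topology.n_atoms}")
    stack = pdb.get_structure()  # AtomArrayStack, all models
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    return Trajectory(coords, frame_interval_ps, topology)


def write_multimodel_pdb(topology: Topology, trajectory: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (3-decimal coordinates)."""
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.atom_name = topology.atom_name.astype("U6")
    arr.element = topology.element.astype("U2")
    arr.res_name = topology.res_name.astype("U5")
    arr.res_id = topology.res_id
    arr.chain_id = topology.chain_id.astype("U4")
    arr.hetero = np.isin(topology.domain_label, ["other"]) & (topology.atom_name != "CA")
    stack = struc.stack([arr] * trajectory.frame_count)
    stack.coord = np.asarray(trajectory.coordinates, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def annotate_domains(topology: Topology,
                     ranges: Iterable[tuple[str, int, int, str]]) -> Topology:
    """Label atoms by domain from inclusive residue ranges.

    DNA chains are auto-labelled ``DNA``; protein atoms outside every range
    get ``other``. Overlapping ranges (per chain) are an error.
    """
    ranges = list(ranges)
    by_chain: dict[str, list[tuple[int, int, str]]] = {}
    for chain, start, end, label in ranges:
        if label not in DOMAIN_LABELS:
            raise ValueError(f"unknown domain label {label!r}")
        by_chain.setdefault(chain, []).append((start, end, label))
    for chain, rs in by_chain.items():
        rs.sort()
        for (s1, e1, _), (s2, e2, _) in zip(rs, rs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping ranges in chain {chain}: "
                                 f"({s1},{e1}) and ({s2},{e2})")
    label = np.array(["other"] * topology.n_atoms, dtype=object)
    is_dna = np.isin(topology.res_name, list(DNA_RESNAMES))
    label[is_dna] = "DNA"
    for chain, start, end, lab in ranges:
        sel = ((topology.chain_id == chain)
               & (topology.res_id >= start) & (topology.res_id <= end) & ~is_dna)
        label[sel] = lab
    return replace(topology, domain_label=label)
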