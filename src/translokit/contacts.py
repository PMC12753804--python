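"""Typed residue–residue and residue–nucleotide contact analysis.

Four interaction classes with inclusive distance cutoffs: hydrogen bonds
(donor–acceptor heavy-atom distance ≤ 3.2 Å and donor–H–acceptor angle
≥ 135°), salt bridges (≤ 3.2 Å between oppositely charged atoms), π–π
stacking (aromatic ring centroid distance ≤ 3.5 Å) and hydrophobic contacts
(≤ 4.5 Å between non-polar side-chain atoms). A contact is *persistent* in a
macrostate when detected in ≥ 75% of that state's frames.

Contacts are reported at residue resolution: multiple atom-pair hits of one
type within one residue pair in one frame count once. When no explicit
hydrogen is present the donor–H–acceptor angle test uses an idealized H on
the donor→acceptor axis (the event is flagged heavy-atom-only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .formats_io import Topology, Trajectory

#: canonical contact key: ((chain_a, resid_a), (chain_b, resid_b), type)
ContactKey = tuple[tuple[str, int], tuple[str, int], str]

CONTACT_TYPES = ("hbond", "salt_bridge", "pi_stack", "hydrophobic")


@dataclass
class InteractionCriteria:
    hbond_dist: float = 3.2
    hbond_angle: float = 135.0  # degrees, donor–H–acceptor
    salt_bridge_dist: float = 3.2
    pi_stack_dist: float = 3.5
    hydrophobic_dist: float = 4.5
    persistence_threshold: float = 0.75

    def __post_init__(self):
        for name in ("hbond_dist", "salt_bridge_dist", "pi_stack_dist",
                     "hydrophobic_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.persistence_threshold <= 1:
            raise ValueError("persistence_threshold must be in (0, 1]")


@dataclass
class ContactEvent:
    frame: int
    res_a: tuple[str, int]
    res_b: tuple[str, int]
    type: str
    heavy_atom_only: bool = False

    @property
    def key(self) -> ContactKey:
        return (self.res_a, self.res_b, self.type)


@dataclass
class ContactTable:
    """Per-macrostate persistence fractions of typed residue contacts."""

    table: pd.DataFrame  # columns: state, res_a, res_b, type, fraction, persistent
    threshold: float = 0.75
    domains: dict[tuple[str, int], str] = field(default_factory=dict)

    def states(self) -> list:
        return sorted(self.table["state"].unique().tolist())

    def persistent_set(self, state) -> set[ContactKey]:
        sub = self.table[(self.table["state"] == state) & self.table["persistent"]]
        return {(ra, rb, t) for ra, rb, t in
                zip(sub["res_a"], sub["res_b"], sub["type"])}

    def for_state(self, state) -> "ContactTable":
        return ContactTable(self.table[self.table["state"] == state].copy(),
                            self.threshold, self.domains)

    def to_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df["domain_a"] = [self.domains.get(r, "other") for r in df["res_a"]]
        df["domain_b"] = [self.domains.get(r, "other") for r in df["res_b"]]
        df["res_a"] = [f"{c}:{r}" for c, r in df["res_a"]]
        df["res_b"] = [f"{c}:{r}" for c, r in df["res_b"]]
        return df[["state", "res_a", "domain_a", "res_b", "domain_b",
                   "type", "fraction", "persistent"]]


class ContactDetector:
    """Precomputed atom-class indices for fast per-frame detection."""

    def __init__(self, topology: Topology,
                 criteria: InteractionCriteria | None = None):
        self.topology = topology
        self.criteria = criteria or InteractionCriteria()
        t = topology
        self._res = list(zip(t.chain_id.tolist(), t.res_id.tolist()))
        self.donors = np.where(t.donor)[0]
        self.acceptors = np.where(t.acceptor)[0]
        self.pos = np.where(t.charge > 0)[0]
        self.neg = np.where(t.charge < 0)[0]
        backbone = np.isin(t.atom_name, ["CA", "N", "C", "O"])
        self.nonpolar = np.where(t.nonpolar & ~backbone)[0]
        self.hydrogens = np.where(np.char.startswith(
            t.atom_name.astype(str), "H"))[0]
        self.rings: list[tuple[tuple[str, int], np.ndarray]] = []
        for ring in np.unique(t.ring_id):
            if ring < 0:
                continue
            idx = np.where(t.ring_id == ring)[0]
            self.rings.append((self._res[idx[0]], idx))

    def _pairs(self, frame, ia, ib, cutoff) -> set[tuple]:
        """Residue pairs with any atom-pair distance ≤ cutoff (A≠B residues)."""
        out: set[tuple] = set()
        if len(ia) == 0 or len(ib) == 0:
            return out
        D = cdist(frame[ia], frame[ib])
        hits = np.argwhere(D <= cutoff)
        for i, j in hits:
            ra, rb = self._res[ia[i]], self._res[ib[j]]
            if ra == rb:
                continue
            out.add((min(ra, rb), max(ra, rb), int(ia[i]), int(ib[j])))
        return out

    def detect(self, frame: np.ndarray, frame_index: int = 0) -> list[ContactEvent]:
        c = self.criteria
        events: dict[ContactKey, ContactEvent] = {}

        def add(ra, rb, typ, heavy=False):
            key = (ra, rb, typ)
            if key not in events:
                events[key] = ContactEvent(frame_index, ra, rb, typ, heavy)

        # hydrogen bonds (donor→acceptor, with angle test)
        for ra, rb, i, j in self._pairs(frame, self.donors, self.acceptors,
                                        c.hbond_dist):
            heavy = True
            ok = True
            hs = self._donor_hydrogens(i)
            if len(hs):
                heavy = False
                ok = any(self._dha_angle(frame, i, h, j) >= c.hbond_angle
                         for h in hs)
            if ok:
                add(ra, rb, "hbond", heavy)
        # salt bridges
        for ra, rb, i, j in self._pairs(frame, self.pos, self.neg,
                                        c.salt_bridge_dist):
            add(ra, rb, "salt_bridge")
        # pi stacking on ring centroids
        for (resi, idxi), (resj, idxj) in _ring_pairs(self.rings):
            if resi == resj:
                continue
            d = np.linalg.norm(frame[idxi].mean(0) - frame[idxj].mean(0))
            if d <= c.pi_stack_dist:
                ra, rb = min(resi, resj), max(resi, resj)
                add(ra, rb, "pi_stack")
        # hydrophobic (side-chain nonpolar atoms only)
        for ra, rb, i, j in self._pairs(frame, self.nonpolar, self.nonpolar,
                                        c.hydrophobic_dist):
            add(ra, rb, "hydrophobic")
        return list(events.values())

    def _donor_hydrogens(self, donor_idx: int) -> np.ndarray:
        """Explicit hydrogens on the donor's residue (coarse bonding model)."""
        if len(self.hydrogens) == 0:
            return np.empty(0, dtype=int)
        res = self._res[donor_idx]
        return np.array([h for h in self.hydrogens if self._res[h] == res],
                        dtype=int)

    @staticmethod
    def _dha_angle(frame, d, h, a) -> float:
        v1 = frame[d] - frame[h]
        v2 = frame[a] - frame[h]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))


def _ring_pairs(rings):
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            yield rings[i], rings[j]


def detect_contacts_frame(frame: np.ndarray, topology: Topology,
                          criteria: InteractionCriteria | None = None,
                          frame_index: int = 0) -> list[ContactEvent]:
    """All typed contacts in one frame (residue-level, deduplicated)."""
    return ContactDetector(topology, criteria).detect(frame, frame_index)


def persistence_table(events_by_frame: Iterable[list[ContactEvent]],
                      macrostate_labels: np.ndarray,
                      topology: Topology | None = None,
                      criteria: InteractionCriteria | None = None) -> ContactTable:
    """Aggregate per-frame detections into per-macrostate persistence fractions.

    ``events_by_frame`` must align with ``macrostate_labels``; contacts never
    observed within a state are omitted from that state's rows.
    """
    criteria = criteria or InteractionCriteria()
    labels = np.asarray(macrostate_labels)
    events_by_frame = list(events_by_frame)
    if len(events_by_frame) != len(labels):
        raise ValueError("labels must cover all frames")
    states, counts_per_state = np.unique(labels, return_counts=True)
    if np.any(counts_per_state == 0):
        raise ValueError("macrostate with zero frames")
    counts: dict[tuple, int] = {}
    for evs, lab in zip(events_by_frame, labels):
        for ev in evs:
            key = (lab, ev.res_a, ev.res_b, ev.type)
            counts[key] = counts.get(key, 0) + 1
    nframes = dict(zip(states.tolist(), counts_per_state.tolist()))
    rows = []
    for (lab, ra, rb, typ), n in sorted(counts.items(), key=str):
        frac = n / nframes[lab]
        rows.append((lab, ra, rb, typ, frac, frac >= criteria.persistence_threshold))
    df = pd.DataFrame(rows, columns=["state", "res_a", "res_b", "type",
                                     "fraction", "persistent"])
    domains = {}
    if topology is not None:
        for ch, rid, dom in zip(topology.chain_id, topology.res_id,
                                topology.domain_label):
            domains[(ch, int(rid))] = dom
    return ContactTable(df, criteria.persistence_threshold, domains)


def _group_residues(table: ContactTable, group) -> set[tuple[str, int]]:
    """Resolve a group spec (domain label or residue-key iterable) to a set."""
    if isinstance(group, str):
        return {r for r, d in table.domains.items() if d == group}
    out = set()
    for g in group:
        out.add(("A", int(g)) if isinstance(g, (int, np.integer)) else tuple(g))
    return out


def interface_filter(table: ContactTable, group_a, group_b) -> ContactTable:
    """Contacts with one partner in each (disjoint) group."""
    ga, gb = _group_residues(table, group_a), _group_residues(table, group_b)
    if ga & gb:
        raise ValueError("interface groups overlap")
    df = table.table
    keep = (df["res_a"].isin(ga) & df["res_b"].isin(gb)) | \
           (df["res_a"].isin(gb) & df["res_b"].isin(ga))
    return ContactTable(df[keep].copy(), table.threshold, table.domains)


@dataclass
class ContactDiff:
    gained: set[ContactKey]
    lost: set[ContactKey]
    retained: set[ContactKey]


def contact_diff(table_x: ContactTable, table_y: ContactTable) -> ContactDiff:
    """Set differences of persistent contacts between two single-state tables."""
    sx = _single_state_set(table_x)
    sy = _single_state_set(table_y)
    return ContactDiff(gained=sy - sx, lost=sx - sy, retained=sx & sy)


def _single_state_set(table: ContactTable) -> set[ContactKey]:
    states = table.states()
    if len(states) > 1:
        raise ValueError("table must hold exactly one macrostate")
    return table.persistent_set(states[0]) if states else set()


def constriction_contact_counts(table: ContactTable,
                                members_c1: Iterable[int],
                                members_c2: Iterable[int],
                                dna_chain: str = "D") -> pd.DataFrame:
    """Persistent protein–DNA contact counts at the two constrictions.

    Counts, per macrostate, persistent contacts whose DNA partner lies on
    ``dna_chain`` and whose protein partner residue number is in the
    constriction member set.
    """
    m1 = {int(r) for r in members_c1}
    m2 = {int(r) for r in members_c2}
    rows = []
    for state in table.states():
        n1 = n2 = 0
        for ra, rb, typ in table.persistent_set(state):
            dna = [r for r in (ra, rb) if r[0] == dna_chain]
            prot = [r for r in (ra, rb) if r[0] != dna_chain]
            if len(dna) != 1 or len(prot) != 1:
                continue
            if prot[0][1] in m1:
                n1 += 1
            if prot[0][1] in m2:
                n2 += 1
        rows.append((state, n1, n2))
    return pd.DataFrame(rows, columns=["state", "constriction_1", "constriction_2"])
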