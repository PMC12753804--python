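"""Seeded coarse-grained helicase–ssDNA ensembles with known ground truth.

Each fixture is a 4-domain SF2 helicase (RecA1, RecA2, Arch, Fe–S) built
from pseudo-atoms (one Cα per residue plus side-chain/ring pseudo-atoms for
residues with encoded interactions) threaded by a 12-nucleotide ssDNA with
P, C1′ and base-centroid pseudo-atoms. Metastable states are coordinate
templates; dynamics is a continuous-time Markov chain discretized at the
frame interval; frames are templates plus isotropic Gaussian noise.

Embedded ground truth, exact by construction:

* stepwise mean first-passage times — forward rates are calibrated by root
  finding so the discrete kernel reproduces the target MFPTs;
* constriction channel widths — wall pseudo-atoms are placed at the exact
  separation, so the width metric returns the configured value on noise-free
  templates;
* typed contact patterns — interaction pseudo-atoms sit inside/outside the
  detection cutoffs per state (verified against the contact detector at
  build time);
* the ssDNA register — the cycle endpoints share identical protein
  coordinates and differ by exactly one nucleotide rise of the DNA.

The chain topology is a linear on-path sequence with kinetic traps hanging
off the apo endpoint states: a tree, hence exactly reversible, which makes
the reversible maximum-likelihood estimator consistent for the embedded
kinetics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .contacts import ContactDetector, InteractionCriteria
from .formats_io import Topology, Trajectory
from .geometry import ConstrictionDefinition, constriction_width, domain_geometry
from .msm import markov_mfpt, stationary_distribution

RISE = 6.0          # Å per nucleotide along the groove axis
RING_RADIUS = 0.75  # pentagon radius of ring pseudo-atoms

# distances (Å) realizing a present/absent interaction, per contact type;
# "present" sits well inside the cutoff so detection is robust to the
# emission noise used in ensemble generation
_PRESENT = {"hbond": 2.4, "salt_bridge": 2.4, "pi_stack": 2.6, "hydrophobic": 3.6}
_ABSENT = {"hbond": 6.5, "salt_bridge": 6.5, "pi_stack": 7.5, "hydrophobic": 9.0}

_CLASS_ELEMENT = {"pos": "N", "neg": "O", "donor": "O", "acceptor": "O",
                  "nonpolar": "C", "ring": "C", "none": "C"}


@dataclass
class EmissionModel:
    """Isotropic Gaussian positional noise around state templates."""
    sigma: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass
class StateTemplate:
    state_id: str
    coordinates: np.ndarray
    width_c1: float
    width_c2: float
    d_af: float
    theta: float
    contact_pattern: frozenset
    dna_register_offset: int


@dataclass
class KineticFixture:
    name: str
    topology: Topology
    states: list[StateTemplate]
    Q: np.ndarray              # rate matrix, s^-1
    P: np.ndarray              # per-frame kernel expm(Q Δt)
    dt_seconds: float
    on_path: list[str]
    traps: list[str]
    constrictions: dict[str, ConstrictionDefinition]
    constriction_members: dict[str, frozenset[int]]
    domain_ranges: list[tuple[str, int, int, str]]

    @property
    def state_ids(self) -> list[str]:
        return [s.state_id for s in self.states]

    def index(self, state_id: str) -> int:
        return self.state_ids.index(state_id)

    def template_array(self) -> np.ndarray:
        return np.stack([s.coordinates for s in self.states])

    def mfpt(self, source: str, target: str) -> float:
        """Analytic MFPT (seconds) between two states on the discrete kernel."""
        m = markov_mfpt(self.P, [self.index(target)], self.dt_seconds)
        return float(m[self.index(source)])

    def stationary(self) -> np.ndarray:
        return stationary_distribution(self.P)


# ---------------------------------------------------------------------------
# declarative fixture specification

@dataclass(frozen=True)
class _Res:
    resid: int
    resname: str
    domain: str
    klass: str  # pos | neg | donor | acceptor | nonpolar | ring | none


@dataclass(frozen=True)
class _DnaContact:
    res: _Res
    slot: int            # nucleotide slot in the register-0 frame
    target: str          # P | C1p | base
    ctype: str
    states: frozenset
    direction: tuple


@dataclass(frozen=True)
class _PPContact:
    anchor: _Res
    partner: _Res
    site: tuple
    ctype: str
    states: frozenset
    direction: tuple


@dataclass(frozen=True)
class _LigandContact:
    res: _Res
    site_key: str
    ctype: str
    states: frozenset
    direction: tuple


@dataclass
class _FixtureSpec:
    name: str
    chain_states: list[str]           # on-path order
    trap_states: list[str]
    trap_hosts: dict[str, str]
    state_params: dict[str, dict]     # c, a, f, t, w1, w2, register
    trap_perturb: dict[str, tuple[str, tuple]]   # trap -> (domain, offset)
    domain_ranges: list[tuple[str, int, int, str]]
    bulk_resids: dict[str, range]
    domain_base: dict[str, np.ndarray]
    domain_motion: dict[str, dict[str, np.ndarray]]
    wall_resids: dict[str, tuple[tuple[int, ...], tuple[int, ...]]]
    dna_contacts: list[_DnaContact]
    pp_contacts: list[_PPContact]
    ligand_contacts: list[_LigandContact]
    ligand_sites: dict[str, tuple]
    ligand_defs: list[dict]           # resid, resname, atoms, bound states
    site_occupancy: dict[str, dict[str, int]]  # site key -> state -> ligand resid
    extra_ca: dict[int, tuple[str, str, tuple]]  # resid -> (resname, domain, pos)
    mfpt_targets: list[float]
    backward_fraction: float
    traps_kinetics: dict[str, tuple[float, float]]  # trap -> (k_in, k_out)
    dt_seconds: float
    constriction_members: dict[str, frozenset[int]]


def _slot_x(slot: int) -> float:
    return -33.0 + RISE * (slot - 1)


def _slot_pos(slot: int, kind: str) -> np.ndarray:
    x = _slot_x(slot)
    if kind == "P":
        return np.array([x, 0.0, 0.0])
    if kind == "C1p":
        return np.array([x, 1.4, 0.0])
    if kind == "base":
        return np.array([x, 3.0, 0.0])
    raise KeyError(kind)


def _pentagon(center: np.ndarray) -> np.ndarray:
    ang = 2 * np.pi * np.arange(5) / 5
    pts = np.stack([np.cos(ang), np.sin(ang), np.zeros(5)], axis=1) * RING_RADIUS
    return center[None, :] + pts


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class _TopologyBuilder:
    def __init__(self):
        self.rows = []   # dicts
        self._ring_counter = 0

    def add(self, name, resname, resid, chain, domain, klass="none",
            element=None, mass=None, ring_id=-1):
        self.rows.append(dict(
            name=name, resname=resname, resid=resid, chain=chain,
            domain=domain, klass=klass,
            element=element or _CLASS_ELEMENT.get(klass, "C"),
            mass=mass, ring_id=ring_id))
        return len(self.rows) - 1

    def add_ring(self, resname, resid, chain, domain):
        rid = self._ring_counter
        self._ring_counter += 1
        idx = [self.add(f"R{k+1}", resname, resid, chain, domain,
                        klass="ring", ring_id=rid) for k in range(5)]
        return idx

    def build(self) -> Topology:
        order = sorted(range(len(self.rows)),
                       key=lambda i: (self.rows[i]["chain"], self.rows[i]["resid"], i))
        rows = [self.rows[i] for i in order]
        n = len(rows)
        mass_default = {"P": 30.974, "MG": 24.305}
        topo = Topology(
            atom_name=np.array([r["name"] for r in rows], dtype=object),
            element=np.array([r["element"] for r in rows], dtype=object),
            res_name=np.array([r["resname"] for r in rows], dtype=object),
            res_id=np.array([r["resid"] for r in rows], dtype=int),
            chain_id=np.array([r["chain"] for r in rows], dtype=object),
            domain_label=np.array([r["domain"] for r in rows], dtype=object),
            donor=np.array([r["klass"] == "donor" for r in rows]),
            acceptor=np.array([r["klass"] in ("acceptor", "phosphate") for r in rows]),
            charge=np.array([1 if r["klass"] in ("pos",) else
                             -1 if r["klass"] in ("neg", "phosphate") else 0
                             for r in rows], dtype=np.int8),
            ring_id=np.array([r["ring_id"] for r in rows], dtype=int),
            nonpolar=np.array([r["klass"] == "nonpolar" for r in rows]),
            mass=np.array([r["mass"] if r["mass"] is not None else
                           mass_default.get(r["element"], 12.011) for r in rows]),
        )
        self.permutation = np.array(order)
        return topo


def _build_fixture(spec: _FixtureSpec, verify: bool = True
                   ) -> tuple[Topology, KineticFixture]:
    state_ids = spec.chain_states + spec.trap_states
    n_states = len(state_ids)

    # ------------------------------------------------------------------ atoms
    b = _TopologyBuilder()
    placements: list[tuple[int, object]] = []   # (row index, placement rule)

    def place(row, rule):
        placements.append((row, rule))

    # domain bulk pseudo-atoms (rigid clusters around state-dependent centers)
    bulk_offsets = {}
    for d_i, (dom, resids) in enumerate(spec.bulk_resids.items()):
        rng = np.random.default_rng(97 + d_i)   # fixed structural layout
        offs = rng.uniform(-5.0, 5.0, size=(len(resids), 3))
        bulk_offsets[dom] = offs
        for k, resid in enumerate(resids):
            row = b.add("CA", "GLY", resid, "A", dom)
            place(row, ("bulk", dom, k))

    # constriction walls: one CA per wall residue at the exact wall position
    wall_x = {"c1": [_slot_x(s) for s in (1, 2, 3, 4)],
              "c2": [_slot_x(s) for s in (9, 10, 11, 12)]}
    wall_domains = {"c1": ("RecA2", "RecA2"), "c2": ("FeS", "RecA1")}
    for cname, (wa, wb) in spec.wall_resids.items():
        doms = wall_domains[cname]
        for side, resids, dom in (("+", wa, doms[0]), ("-", wb, doms[1])):
            for j, resid in enumerate(resids):
                row = b.add("CA", "GLY", resid, "A", dom)
                place(row, ("wall", cname, side, j))

    # DNA
    dna_seq = ["DA", "DT", "DG", "DC"] * 3
    for nt in range(1, 13):
        rn = dna_seq[nt - 1]
        row = b.add("P", rn, nt, "D", "DNA", klass="phosphate", element="P")
        place(row, ("dna", nt, "P"))
        row = b.add("C1'", rn, nt, "D", "DNA", klass="nonpolar")
        place(row, ("dna", nt, "C1p"))
        for k, ridx in enumerate(b.add_ring(rn, nt, "D", "DNA")):
            place(ridx, ("dna_ring", nt, k))

    # ligands
    for lig in spec.ligand_defs:
        for atom in lig["atoms"]:
            if atom["kind"] == "ring":
                for k, ridx in enumerate(b.add_ring(lig["resname"], lig["resid"],
                                                    "L", "other")):
                    place(ridx, ("lig_ring", lig["resid"], atom["site"], k))
            else:
                row = b.add(atom["name"], lig["resname"], lig["resid"], "L",
                            "other", klass=atom["kind"],
                            element=atom.get("element"))
                place(row, ("lig", lig["resid"], atom["site"]))

    # protein interaction residues
    seen_res: dict[int, dict] = {}

    def protein_atom(res: _Res, pos_rule):
        """Add the side-chain pseudo-atom (or ring) of an interaction residue."""
        info = seen_res.setdefault(res.resid, {"res": res, "has_ca": False})
        if res.klass == "ring":
            idxs = b.add_ring(res.resname, res.resid, "A", res.domain)
            for k, ridx in enumerate(idxs):
                place(ridx, ("ring_at", pos_rule, k))
        else:
            row = b.add("SC", res.resname, res.resid, "A", res.domain,
                        klass=res.klass)
            place(row, ("at", pos_rule))
        if not info["has_ca"]:
            row = b.add("CA", res.resname, res.resid, "A", res.domain)
            place(row, ("ca_of", pos_rule))
            info["has_ca"] = True

    # DNA-facing residues
    for dc in spec.dna_contacts:
        base = _slot_pos(dc.slot, dc.target)
        d = _unit(dc.direction)
        rule = ("span", tuple(base), tuple(d), dc.ctype, dc.states)
        protein_atom(dc.res, rule)

    # protein–protein pairs; an anchor may be an atom already placed by a
    # DNA contact (e.g. a salt bridge onto a DNA-binding arginine), in which
    # case ``site`` is that atom's fixed position and no new atom is added
    anchor_pos: dict[int, np.ndarray] = {}
    for pp in spec.pp_contacts:
        site = np.asarray(pp.site, dtype=float)
        if pp.anchor.resid not in anchor_pos:
            anchor_pos[pp.anchor.resid] = site
            if pp.anchor.resid not in seen_res:
                protein_atom(pp.anchor, ("fixed", tuple(site)))
        apos = anchor_pos[pp.anchor.resid]
        d = _unit(pp.direction)
        rule = ("span", tuple(apos), tuple(d), pp.ctype, pp.states)
        protein_atom(pp.partner, rule)

    # ligand-facing residues
    for lc in spec.ligand_contacts:
        base = np.asarray(spec.ligand_sites[lc.site_key], dtype=float)
        d = _unit(lc.direction)
        rule = ("span", tuple(base), tuple(d), lc.ctype, lc.states)
        protein_atom(lc.res, rule)

    # plain-CA residues (mutation-catalog positions without encoded contacts)
    for resid, (resname, dom, pos) in spec.extra_ca.items():
        row = b.add("CA", resname, resid, "A", dom)
        place(row, ("fixed_pos", tuple(pos)))

    topology = b.build()
    perm = b.permutation
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))

    # -------------------------------------------------------------- templates
    lig_bound = {lig["resid"]: frozenset(lig["bound"]) for lig in spec.ligand_defs}
    lig_bulk = {lig["resid"]: np.asarray(lig["bulk"], float)
                for lig in spec.ligand_defs}
    site_pos = {k: np.asarray(v, float) for k, v in spec.ligand_sites.items()}

    def _rule_center(rule, pid) -> np.ndarray:
        kind = rule[0]
        if kind == "fixed":
            return np.asarray(rule[1], float)
        if kind == "span":
            base, d, ctype, states = (np.asarray(rule[1], float),
                                      np.asarray(rule[2], float), rule[3], rule[4])
            dist = _PRESENT[ctype] if pid in states else _ABSENT[ctype]
            return base + d * dist
        raise KeyError(kind)

    def template_coords(sid: str, pid: str) -> np.ndarray:
        # ``sid`` selects trap perturbations; ``pid`` (the host state for
        # traps) selects contact presence and ligand occupancy
        p = spec.state_params[sid]
        reg = p.get("register", 0)
        shift = np.array([RISE * reg, 0.0, 0.0])
        widths = {"c1": p["w1"], "c2": p["w2"]}
        coords = np.zeros((len(placements), 3))
        for row, rule in placements:
            kind = rule[0]
            if kind == "bulk":
                dom, k = rule[1], rule[2]
                center = spec.domain_base[dom].copy()
                for pname, vec in spec.domain_motion.get(dom, {}).items():
                    center = center + p.get(pname, 0.0) * vec
                pos = center + bulk_offsets[dom][k]
                if sid in spec.trap_perturb and spec.trap_perturb[sid][0] == dom:
                    pos = pos + np.asarray(spec.trap_perturb[sid][1], float)
            elif kind == "wall":
                cname, side, j = rule[1], rule[2], rule[3]
                z = widths[cname] / 2.0 * (1 if side == "+" else -1)
                pos = np.array([wall_x[cname][j], 0.0, z])
            elif kind == "dna":
                pos = _slot_pos(rule[1], rule[2]) + shift
            elif kind == "dna_ring":
                pos = _pentagon(_slot_pos(rule[1], "base") + shift)[rule[2]]
            elif kind == "lig":
                resid, site = rule[1], rule[2]
                pos = site_pos[site] if pid in lig_bound[resid] else lig_bulk[resid]
            elif kind == "lig_ring":
                resid, site, k = rule[1], rule[2], rule[3]
                c = site_pos[site] if pid in lig_bound[resid] else lig_bulk[resid]
                pos = _pentagon(c)[k]
            elif kind == "at":
                pos = _rule_center(rule[1], pid)
            elif kind == "ring_at":
                pos = _pentagon(_rule_center(rule[1], pid))[rule[2]]
            elif kind == "ca_of":
                inner = rule[1]
                if inner[0] == "span":
                    base, d = np.asarray(inner[1], float), np.asarray(inner[2], float)
                    pos = base + d * (_ABSENT[inner[3]] + 4.0)
                else:
                    pos = np.asarray(inner[1], float) + np.array([0.0, 0.0, 4.0])
            elif kind == "fixed_pos":
                pos = np.asarray(rule[1], float)
            else:
                raise KeyError(kind)
            coords[row] = pos
        return coords[perm]

    # trap templates copy their host's parameters plus a bulk perturbation
    for trap, host in spec.trap_hosts.items():
        spec.state_params[trap] = dict(spec.state_params[host])

    # ---------------------------------------------------- declared contact sets
    def declared_pattern(sid: str) -> frozenset:
        reg = spec.state_params[sid].get("register", 0)
        out = set()
        for dc in spec.dna_contacts:
            if sid not in dc.states:
                continue
            nt = dc.slot - reg
            if 1 <= nt <= 12:
                a, bb = ("A", dc.res.resid), ("D", nt)
                out.add((min(a, bb), max(a, bb), dc.ctype))
        for pp in spec.pp_contacts:
            if sid in pp.states:
                a, bb = ("A", pp.anchor.resid), ("A", pp.partner.resid)
                out.add((min(a, bb), max(a, bb), pp.ctype))
        for lc in spec.ligand_contacts:
            if sid not in lc.states:
                continue
            occ = spec.site_occupancy.get(lc.site_key, {}).get(sid)
            if occ is not None:
                a, bb = ("A", lc.res.resid), ("L", occ)
                out.add((min(a, bb), max(a, bb), lc.ctype))
        return frozenset(out)

    # trap presence mirrors the host state
    state_alias = {t: h for t, h in spec.trap_hosts.items()}

    def presence_id(sid: str) -> str:
        return state_alias.get(sid, sid)

    templates = []
    detector = ContactDetector(topology, InteractionCriteria()) if verify else None
    cdefs = _constrictions(spec)
    for sid in state_ids:
        pid = presence_id(sid)
        coords = template_coords(sid, pid)
        p = spec.state_params[pid]
        pattern = declared_pattern(pid)
        geo = domain_geometry(coords, topology)
        w1 = constriction_width(coords, cdefs["c1"], topology)
        w2 = constriction_width(coords, cdefs["c2"], topology)
        if verify:
            assert abs(w1 - p["w1"]) < 1e-9 and abs(w2 - p["w2"]) < 1e-9, \
                f"{sid}: width mismatch {w1}/{w2} vs {p['w1']}/{p['w2']}"
            detected = {ev.key for ev in detector.detect(coords)}
            if detected != set(pattern):
                missing = set(pattern) - detected
                extra = detected - set(pattern)
                raise AssertionError(
                    f"{sid}: contact pattern mismatch; missing={missing} "
                    f"extra={extra}")
        templates.append(StateTemplate(
            state_id=sid, coordinates=coords, width_c1=p["w1"], width_c2=p["w2"],
            d_af=geo.d_af, theta=geo.theta, contact_pattern=pattern,
            dna_register_offset=p.get("register", 0)))

    # ---------------------------------------------------------------- kinetics
    Q = _calibrated_rate_matrix(spec, state_ids)
    P = expm(Q * spec.dt_seconds)

    fixture = KineticFixture(
        name=spec.name, topology=topology, states=templates, Q=Q, P=P,
        dt_seconds=spec.dt_seconds, on_path=list(spec.chain_states),
        traps=list(spec.trap_states), constrictions=_constrictions(spec),
        constriction_members=spec.constriction_members,
        domain_ranges=spec.domain_ranges)
    return topology, fixture


def _constrictions(spec: _FixtureSpec) -> dict[str, ConstrictionDefinition]:
    wa1, wb1 = spec.wall_resids["c1"]
    wa2, wb2 = spec.wall_resids["c2"]
    return {
        "c1": ConstrictionDefinition("Constriction 1", frozenset(wa1),
                                     frozenset(wb1)),
        "c2": ConstrictionDefinition("Constriction 2", frozenset(wa2),
                                     frozenset(wb2)),
    }


def _assemble_Q(spec: _FixtureSpec, state_ids, kf) -> np.ndarray:
    n = len(state_ids)
    L = len(spec.chain_states)
    Q = np.zeros((n, n))
    for i in range(L - 1):
        Q[i, i + 1] = kf[i]
        Q[i + 1, i] = spec.backward_fraction * kf[i]
    for trap, (k_in, k_out) in spec.traps_kinetics.items():
        t = state_ids.index(trap)
        h = state_ids.index(spec.trap_hosts[trap])
        Q[h, t] = k_in
        Q[t, h] = k_out
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _calibrated_rate_matrix(spec: _FixtureSpec, state_ids) -> np.ndarray:
    """Forward rates tuned so discrete stepwise MFPTs hit the targets exactly."""
    targets = spec.mfpt_targets
    kf = [1.0 / t for t in targets]

    for i, target in enumerate(targets):
        def gap(k):
            kf[i] = k
            Q = _assemble_Q(spec, state_ids, kf)
            P = expm(Q * spec.dt_seconds)
            m = markov_mfpt(P, [i + 1], spec.dt_seconds)
            return m[i] - target

        kf[i] = brentq(gap, 0.01 / target, 100.0 / target, xtol=1e-14,
                       rtol=8.9e-16)
    return _assemble_Q(spec, state_ids, kf)


# ---------------------------------------------------------------------------
# simulation and emission

def simulate_state_sequence(fixture: KineticFixture, n_frames: int, seed: int,
                            start: str | None = None) -> np.ndarray:
    """Sample a state-index sequence from the per-frame kernel.

    Starts from the stationary distribution unless ``start`` names a state.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    P = fixture.P
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("kernel is not row-stochastic")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    seq = np.empty(n_frames, dtype=np.int64)
    if start is None:
        pi = fixture.stationary()
        seq[0] = rng.choice(len(pi), p=pi)
    else:
        seq[0] = fixture.index(start)
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        seq[t] = np.searchsorted(cum[seq[t - 1]], u[t - 1], side="right")
    return seq


def simulate_ensemble(fixture: KineticFixture, n_traj: int, n_frames: int,
                      seed: int, starts="spread") -> list[np.ndarray]:
    """Sample many sequences at once (vectorized across trajectories).

    ``starts='spread'`` allocates start states round-robin over all fixture
    states, emulating unbiased runs launched from replicas spanning the
    optimized path; ``'stationary'`` draws starts from π; an explicit list
    of state ids (or indices) is cycled over — useful for variance
    reduction when re-estimating rates out of a rarely-populated state.
    """
    rng = np.random.default_rng(seed)
    n_states = fixture.P.shape[0]
    if isinstance(starts, str) and starts == "spread":
        s0 = np.arange(n_traj) % n_states
    elif isinstance(starts, str) and starts == "stationary":
        s0 = rng.choice(n_states, size=n_traj, p=fixture.stationary())
    elif isinstance(starts, str):
        raise ValueError(starts)
    else:
        idx = np.array([fixture.index(s) if isinstance(s, str) else int(s)
                        for s in starts])
        s0 = idx[np.arange(n_traj) % len(idx)]
    cum = np.cumsum(fixture.P, axis=1)
    seqs = np.empty((n_traj, n_frames), dtype=np.int64)
    seqs[:, 0] = s0
    U = rng.random((n_traj, n_frames - 1))
    cur = s0.copy()
    for t in range(1, n_frames):
        rows = cum[cur]
        cur = (U[:, t - 1][:, None] > rows).sum(axis=1)
        seqs[:, t] = cur
    return [seqs[i] for i in range(n_traj)]


def emit_trajectory(sequence: np.ndarray, fixture: KineticFixture,
                    emission: EmissionModel) -> Trajectory:
    """Frames = per-state templates plus isotropic Gaussian noise."""
    seq = np.asarray(sequence)
    if seq.dtype.kind in "US":
        idx = np.array([fixture.index(s) for s in seq])
    else:
        idx = seq.astype(int)
    if idx.min() < 0 or idx.max() >= len(fixture.states):
        raise ValueError("sequence contains unknown state labels")
    T = fixture.template_array()
    coords = T[idx]
    if emission.sigma > 0:
        rng = np.random.default_rng(emission.seed)
        coords = coords + rng.standard_normal(coords.shape) * emission.sigma
    return Trajectory(coords, fixture.dt_seconds * 1e12, fixture.topology)


def export_fixture(fixture: KineticFixture, directory) -> None:
    """Write templates as a multi-model PDB plus a JSON ground-truth sidecar."""
    from pathlib import Path
    from .formats_io import write_multimodel_pdb
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    traj = Trajectory(fixture.template_array(), fixture.dt_seconds * 1e12,
                      fixture.topology)
    write_multimodel_pdb(fixture.topology, traj, out / f"{fixture.name}_states.pdb")
    sidecar = {
        "name": fixture.name,
        "state_ids": fixture.state_ids,
        "on_path": fixture.on_path,
        "traps": fixture.traps,
        "dt_seconds": fixture.dt_seconds,
        "kernel": fixture.P.tolist(),
        "rate_matrix": fixture.Q.tolist(),
        "observables": {
            s.state_id: {
                "width_c1": s.width_c1, "width_c2": s.width_c2,
                "d_af": s.d_af, "theta": s.theta,
                "dna_register_offset": s.dna_register_offset,
                "contacts": sorted([list(a), list(bb), t]
                                   for a, bb, t in s.contact_pattern),
            } for s in fixture.states
        },
    }
    (out / f"{fixture.name}_ground_truth.json").write_text(
        json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# fixture definitions

def _S(*ids) -> frozenset:
    return frozenset(ids)


def _xpd_spec() -> _FixtureSpec:
    ALL = _S("S1", "S2", "S3", "S4", "S5", "S6", "S7")
    MID = _S("S2", "S3", "S4", "S5", "S6")
    APO = _S("S1", "S2", "S7")
    C2_CLOSED = _S("S1", "S2", "S5", "S6", "S7")
    NUC = _S("S4", "S5")

    def R(resid, resname, domain, klass):
        return _Res(resid, resname, domain, klass)

    dna = [
        _DnaContact(R(627, "TYR", "RecA2", "ring"), 2, "base", "pi_stack", ALL, (0, 0, 1)),
        _DnaContact(R(508, "PHE", "RecA2", "ring"), 3, "base", "pi_stack", MID, (0, 0, 1)),
        _DnaContact(R(511, "ARG", "RecA2", "pos"), 3, "P", "salt_bridge", ALL, (0, -0.7, 0.7)),
        _DnaContact(R(683, "ARG", "RecA2", "pos"), 2, "P", "salt_bridge", ALL, (0, -0.8, -0.6)),
        _DnaContact(R(686, "ARG", "RecA2", "pos"), 4, "P", "salt_bridge", ALL, (0, -1, 0)),
        _DnaContact(R(601, "ARG", "RecA2", "pos"), 1, "P", "salt_bridge", ALL, (0, -1, 0)),
        _DnaContact(R(540, "THR", "RecA2", "donor"), 4, "P", "hbond", MID, (0, -0.4, 0.9)),
        _DnaContact(R(541, "SER", "RecA2", "donor"), 3, "P", "hbond", _S("S3", "S4", "S5"), (0, -0.5, -0.87)),
        _DnaContact(R(542, "TYR", "RecA2", "donor"), 2, "P", "hbond", _S("S3", "S4", "S5"), (0, -0.5, 0.87)),
        _DnaContact(R(543, "GLN", "RecA2", "donor"), 1, "P", "hbond", APO, (0, -0.5, 0.87)),
        _DnaContact(R(625, "TYR", "RecA2", "nonpolar"), 2, "C1p", "hydrophobic", ALL, (0, 0, -1)),
        _DnaContact(R(75, "ARG", "RecA1", "pos"), 6, "P", "salt_bridge", ALL, (0, -1, 0)),
        _DnaContact(R(76, "THR", "RecA1", "donor"), 7, "P", "hbond", _S("S1", "S6", "S7"), (0, -0.6, 0.8)),
        _DnaContact(R(603, "LYS", "RecA2", "pos"), 7, "P", "salt_bridge", _S("S5"), (0, -0.8, -0.6)),
        _DnaContact(R(135, "HIS", "FeS", "ring"), 9, "base", "pi_stack", C2_CLOSED, (0, 0, 1)),
        _DnaContact(R(112, "ARG", "FeS", "pos"), 10, "P", "salt_bridge", C2_CLOSED, (0, -0.7, -0.7)),
        _DnaContact(R(196, "ARG", "FeS", "pos"), 11, "P", "salt_bridge", _S("S1", "S2", "S6", "S7"), (0, -1, 0)),
        _DnaContact(R(210, "HIS", "RecA1", "ring"), 12, "base", "pi_stack", APO, (0, 0, 1)),
        _DnaContact(R(211, "TYR", "RecA1", "donor"), 12, "P", "hbond", APO, (0, -0.6, 0.8)),
        _DnaContact(R(217, "ILE", "RecA1", "nonpolar"), 11, "C1p", "hydrophobic", _S("S1", "S7"), (0, 0, -1)),
        _DnaContact(R(220, "LEU", "RecA1", "nonpolar"), 10, "C1p", "hydrophobic", _S("S1", "S7"), (0, 0, -1)),
        _DnaContact(R(223, "LYS", "RecA1", "pos"), 9, "P", "salt_bridge", _S("S5"), (0, -1, 0)),
        _DnaContact(R(304, "HIS", "Arch", "ring"), 10, "base", "pi_stack", C2_CLOSED, (0, 0, 1)),
        _DnaContact(R(303, "ALA", "Arch", "nonpolar"), 9, "C1p", "hydrophobic", _S("S5"), (0, 0.2, -0.98)),
        _DnaContact(R(305, "LEU", "Arch", "nonpolar"), 11, "C1p", "hydrophobic", _S("S5"), (0, 0.5, -0.87)),
        _DnaContact(R(111, "SER", "FeS", "donor"), 9, "P", "hbond", _S("S5"), (0, -0.5, 0.87)),
        _DnaContact(R(192, "TYR", "FeS", "donor"), 11, "P", "hbond", _S("S5"), (0, -0.5, 0.87)),
        _DnaContact(R(113, "LYS", "FeS", "pos"), 12, "P", "salt_bridge", _S("S5"), (0, -0.8, -0.6)),
    ]
    r683_atom = _slot_pos(2, "P") + _unit((0, -0.8, -0.6)) * _PRESENT["salt_bridge"]
    pp = [
        _PPContact(R(78, "PRO", "RecA1", "nonpolar"), R(608, "ILE", "RecA2", "nonpolar"),
                   (-4, -36, 2), "hydrophobic", _S("S3", "S4"), (-1, 0, 0)),
        _PPContact(R(461, "LEU", "RecA2", "nonpolar"), R(694, "PRO", "RecA1", "nonpolar"),
                   (6, -36, -4), "hydrophobic", NUC, (1, 0, 0)),
        _PPContact(R(461, "LEU", "RecA2", "nonpolar"), R(696, "TRP", "RecA1", "nonpolar"),
                   (6, -36, -4), "hydrophobic", NUC, (0, 0, 1)),
        _PPContact(R(84, "LYS", "RecA1", "pos"), R(668, "ASP", "RecA2", "neg"),
                   (-14, -36, -2), "salt_bridge", _S("S3", "S4"), (-1, 0, 0)),
        _PPContact(R(632, "ILE", "RecA2", "nonpolar"), R(417, "ILE", "Arch", "nonpolar"),
                   (-2, 12, 6), "hydrophobic", ALL, (1, 0, 0)),
        _PPContact(R(635, "ALA", "RecA2", "nonpolar"), R(415, "THR", "Arch", "nonpolar"),
                   (-2, 12, -5), "hydrophobic", ALL, (1, 0, 0)),
        _PPContact(R(240, "ASP", "RecA1", "neg"), R(658, "ARG", "RecA2", "pos"),
                   (8, 12, 0), "salt_bridge", _S("S1", "S2", "S6", "S7"), (1, 0, 0)),
        _PPContact(R(240, "ASP", "RecA1", "neg"), R(636, "ARG", "RecA2", "pos"),
                   (8, 12, 0), "salt_bridge", _S("S3", "S4"), (-0.5, 0, 0.87)),
        _PPContact(R(683, "ARG", "RecA2", "pos"), R(681, "ASP", "RecA2", "neg"),
                   tuple(r683_atom), "salt_bridge", ALL, (0, -1, 0)),
    ]
    lig = [
        _LigandContact(R(44, "SER", "RecA1", "donor"), "phos", "hbond", NUC, (0, -1, 0)),
        _LigandContact(R(49, "THR", "RecA1", "donor"), "phos", "hbond", NUC, (0, -0.6, 0.8)),
        _LigandContact(R(48, "LYS", "RecA1", "pos"), "phos", "salt_bridge", NUC, (0, 0, -1)),
        _LigandContact(R(666, "ARG", "RecA2", "pos"), "phos", "salt_bridge", _S("S4"), (-0.8, -0.6, 0)),
        _LigandContact(R(669, "ARG", "RecA2", "pos"), "phos", "salt_bridge", _S("S4"), (0.8, -0.6, 0)),
        _LigandContact(R(234, "ASP", "RecA1", "neg"), "mg", "salt_bridge", _S("S4"), (0, -1, 0)),
        _LigandContact(R(235, "GLU", "RecA1", "neg"), "mg", "salt_bridge", _S("S4"), (0, -0.6, -0.8)),
        _LigandContact(R(14, "TYR", "RecA1", "ring"), "adenine", "pi_stack", _S("S4"), (0, 0, 1)),
        _LigandContact(R(18, "TYR", "RecA1", "ring"), "adenine", "pi_stack", NUC, (0, 0, -1)),
        _LigandContact(R(12, "PHE", "RecA1", "nonpolar"), "atp_cm", "hydrophobic", _S("S4"), (0, -1, 0)),
        _LigandContact(R(17, "ILE", "RecA1", "nonpolar"), "atp_cm", "hydrophobic", _S("S4"), (0, 0, 1)),
        _LigandContact(R(50, "VAL", "RecA1", "nonpolar"), "atp_cm", "hydrophobic", _S("S4"), (1, 0, 0)),
    ]
    params = {
        "S1": dict(c=0.00, a=0.00, f=0.00, t=0.00, w1=13.2, w2=6.1, register=0),
        "S2": dict(c=0.35, a=0.05, f=0.00, t=0.00, w1=12.6, w2=6.6, register=0),
        "S3": dict(c=0.70, a=0.25, f=0.15, t=0.00, w1=11.9, w2=7.6, register=0),
        "S4": dict(c=1.00, a=1.00, f=1.00, t=0.30, w1=10.7, w2=11.7, register=0),
        "S5": dict(c=0.55, a=0.10, f=0.80, t=0.60, w1=11.6, w2=8.6, register=0),
        "S6": dict(c=0.15, a=0.05, f=0.25, t=1.00, w1=12.4, w2=7.1, register=0),
        "S7": dict(c=0.00, a=0.00, f=0.00, t=0.00, w1=13.2, w2=6.1, register=1),
    }
    return _FixtureSpec(
        name="xpd",
        chain_states=["S1", "S2", "S3", "S4", "S5", "S6", "S7"],
        trap_states=["T1", "T2", "T3"],
        trap_hosts={"T1": "S1", "T2": "S7", "T3": "S7"},
        state_params=params,
        trap_perturb={"T1": ("Arch", (-5, 3, 4)),
                      "T2": ("RecA2", (0, -5, 4)),
                      "T3": ("FeS", (4, 4, -4))},
        domain_ranges=[("A", 1, 87, "RecA1"), ("A", 88, 199, "FeS"),
                       ("A", 200, 245, "RecA1"), ("A", 246, 440, "Arch"),
                       ("A", 441, 689, "RecA2"), ("A", 690, 760, "RecA1")],
        bulk_resids={"RecA1": range(720, 744), "FeS": range(150, 174),
                     "Arch": range(340, 364), "RecA2": range(560, 584)},
        domain_base={"RecA1": np.array([12.0, -16.0, 0.0]),
                     "RecA2": np.array([-20.0, -16.0, 0.0]),
                     "FeS": np.array([26.0, 12.0, 0.0]),
                     "Arch": np.array([16.0, 22.0, 0.0])},
        domain_motion={"RecA2": {"c": np.array([8.0, 4.0, 0.0])},
                       "FeS": {"f": np.array([-6.0, -4.0, 0.0])},
                       "Arch": {"a": np.array([5.0, 7.0, 0.0]),
                                "t": np.array([0.0, 0.0, 3.0])}},
        wall_resids={"c1": ((544, 545, 546, 547), (640, 641, 642, 643)),
                     "c2": ((128, 129, 130, 131), (213, 214, 215, 216))},
        dna_contacts=dna, pp_contacts=pp, ligand_contacts=lig,
        ligand_sites={"phos": (-4.0, -16.0, -8.0), "adenine": (2.0, -16.0, -8.0),
                      "atp_cm": (5.0, -16.0, -6.0), "mg": (-4.0, -19.0, -13.0)},
        ligand_defs=[
            dict(resid=901, resname="ATP", bound=["S4"], bulk=(150, 150, 150),
                 atoms=[dict(name="PG", kind="phosphate", element="P", site="phos"),
                        dict(kind="ring", site="adenine"),
                        dict(name="CM", kind="nonpolar", site="atp_cm")]),
            dict(resid=902, resname="ADP", bound=["S5"], bulk=(150, 150, -150),
                 atoms=[dict(name="PB", kind="phosphate", element="P", site="phos"),
                        dict(kind="ring", site="adenine")]),
            dict(resid=903, resname="MG", bound=["S4"], bulk=(150, -150, 150),
                 atoms=[dict(name="MG", kind="pos", element="MG", site="mg")]),
        ],
        site_occupancy={"phos": {"S4": 901, "S5": 902},
                        "adenine": {"S4": 901, "S5": 902},
                        "atp_cm": {"S4": 901}, "mg": {"S4": 903}},
        extra_ca={47: ("GLY", "RecA1", (-10.0, -12.0, -8.0)),
                  602: ("GLY", "RecA2", (-31.0, -10.5, 2.0))},
        mfpt_targets=[3.6e-3, 1.0e-4, 4.1e-5, 1.0e-4, 1.0e-4, 1.0e-4],
        backward_fraction=0.5,
        traps_kinetics={"T1": (300.0, 700.0), "T2": (150.0, 600.0),
                        "T3": (150.0, 2500.0)},
        dt_seconds=1e-6,
        constriction_members={
            "c1": frozenset({508, 511, 540, 541, 542, 543, 544, 545, 546, 547,
                             599, 601, 602, 625, 626, 627, 628, 640, 641, 642,
                             643, 681, 683, 686}),
            "c2": frozenset({111, 112, 113, 128, 129, 130, 131, 135, 192, 196,
                             210, 211, 213, 214, 215, 216, 217, 220, 223, 303,
                             304, 305}),
        },
    )


def _ding_spec() -> _FixtureSpec:
    ALL = _S("SD1", "SD2", "SD3", "SD4", "SD5")
    APO = _S("SD1", "SD5")
    CLOSED = _S("SD1", "SD2", "SD4", "SD5")
    NUC = _S("SD3", "SD4")

    def R(resid, resname, domain, klass):
        return _Res(resid, resname, domain, klass)

    dna = [
        _DnaContact(R(636, "TYR", "RecA2", "ring"), 2, "base", "pi_stack", ALL, (0, 0, 1)),
        _DnaContact(R(615, "PHE", "RecA2", "ring"), 3, "base", "pi_stack", ALL, (0, 0, 1)),
        _DnaContact(R(545, "ARG", "RecA2", "pos"), 5, "P", "salt_bridge", ALL, (0, -1, 0)),
        _DnaContact(R(612, "LYS", "RecA2", "pos"), 6, "P", "salt_bridge", ALL, (0, -0.7, -0.7)),
        _DnaContact(R(569, "ARG", "RecA2", "pos"), 7, "P", "salt_bridge", ALL, (0, -1, 0)),
        _DnaContact(R(564, "GLN", "RecA2", "donor"), 8, "P", "hbond", ALL, (0, -0.5, 0.87)),
        _DnaContact(R(593, "SER", "RecA2", "donor"), 5, "P", "hbond", ALL, (0, -0.5, 0.87)),
        _DnaContact(R(511, "ILE", "RecA2", "nonpolar"), 6, "C1p", "hydrophobic", ALL, (0, 0, -1)),
        _DnaContact(R(591, "ILE", "RecA2", "nonpolar"), 7, "C1p", "hydrophobic", ALL, (0, 0, -1)),
        _DnaContact(R(617, "PRO", "RecA2", "nonpolar"), 8, "C1p", "hydrophobic", ALL, (0, 0, -1)),
        _DnaContact(R(211, "ARG", "FeS", "pos"), 10, "P", "salt_bridge", CLOSED, (0, -0.7, -0.7)),
        _DnaContact(R(191, "LYS", "FeS", "pos"), 9, "P", "salt_bridge", CLOSED, (0, -1, 0)),
        _DnaContact(R(223, "ASN", "RecA1", "donor"), 11, "P", "hbond", APO, (0, -0.5, 0.87)),
        _DnaContact(R(233, "SER", "RecA1", "donor"), 12, "P", "hbond", APO, (0, -0.6, 0.8)),
        _DnaContact(R(236, "VAL", "RecA1", "nonpolar"), 11, "C1p", "hydrophobic", APO, (0, 0, -1)),
    ]
    pp = [
        _PPContact(R(621, "PRO", "RecA2", "nonpolar"), R(419, "TRP", "Arch", "nonpolar"),
                   (-2, 12, 6), "hydrophobic", ALL, (1, 0, 0)),
        _PPContact(R(628, "GLU", "RecA2", "neg"), R(335, "ARG", "Arch", "pos"),
                   (-2, 12, -5), "salt_bridge", ALL, (1, 0, 0)),
        _PPContact(R(459, "SER", "RecA1", "donor"), R(652, "GLN", "RecA2", "acceptor"),
                   (6, -36, -4), "hbond", _S("SD2", "SD3", "SD4"), (1, 0, 0)),
        _PPContact(R(651, "ILE", "RecA2", "nonpolar"), R(461, "THR", "RecA2", "nonpolar"),
                   (-4, -36, 2), "hydrophobic", _S("SD2", "SD3", "SD4"), (-1, 0, 0)),
        _PPContact(R(571, "ARG", "RecA2", "pos"), R(176, "ASP", "FeS", "neg"),
                   (-14, -36, -2), "salt_bridge", _S("SD2", "SD3"), (-1, 0, 0)),
    ]
    lig = [
        _LigandContact(R(51, "SER", "RecA1", "donor"), "phos", "hbond", NUC, (0, -1, 0)),
        _LigandContact(R(54, "LYS", "RecA1", "pos"), "phos", "salt_bridge", NUC, (0, 0, -1)),
        _LigandContact(R(657, "ARG", "RecA2", "pos"), "phos", "salt_bridge", _S("SD3"), (-0.8, -0.6, 0)),
        _LigandContact(R(24, "TYR", "RecA1", "ring"), "adenine", "pi_stack", NUC, (0, 0, -1)),
        _LigandContact(R(262, "ASP", "RecA1", "neg"), "mg", "salt_bridge", _S("SD3"), (0, -1, 0)),
    ]
    params = {
        "SD1": dict(c=0.00, a=0.00, f=0.00, t=0.00, w1=13.0, w2=9.0, register=0),
        "SD2": dict(c=0.45, a=0.15, f=0.30, t=0.00, w1=12.0, w2=9.8, register=0),
        "SD3": dict(c=1.00, a=1.00, f=1.00, t=0.30, w1=11.0, w2=13.5, register=0),
        "SD4": dict(c=0.50, a=0.20, f=0.60, t=0.80, w1=11.8, w2=11.2, register=0),
        "SD5": dict(c=0.00, a=0.00, f=0.00, t=0.00, w1=13.0, w2=9.0, register=1),
    }
    return _FixtureSpec(
        name="ding",
        chain_states=["SD1", "SD2", "SD3", "SD4", "SD5"],
        trap_states=["TD1", "TD2", "TD3", "TD4"],
        trap_hosts={"TD1": "SD1", "TD2": "SD1", "TD3": "SD5", "TD4": "SD5"},
        state_params=params,
        trap_perturb={"TD1": ("Arch", (-5, 3, 4)), "TD2": ("FeS", (4, 4, -4)),
                      "TD3": ("RecA2", (0, -5, 4)), "TD4": ("Arch", (5, -3, -4))},
        domain_ranges=[("A", 1, 99, "RecA1"), ("A", 100, 218, "FeS"),
                       ("A", 219, 290, "RecA1"), ("A", 291, 450, "Arch"),
                       ("A", 451, 459, "RecA1"), ("A", 460, 699, "RecA2"),
                       ("A", 700, 760, "RecA1")],
        bulk_resids={"RecA1": range(720, 744), "FeS": range(150, 174),
                     "Arch": range(340, 364), "RecA2": range(660, 684)},
        domain_base={"RecA1": np.array([12.0, -16.0, 0.0]),
                     "RecA2": np.array([-20.0, -16.0, 0.0]),
                     "FeS": np.array([26.0, 12.0, 0.0]),
                     "Arch": np.array([16.0, 22.0, 0.0])},
        domain_motion={"RecA2": {"c": np.array([8.0, 4.0, 0.0])},
                       "FeS": {"f": np.array([-6.0, -4.0, 0.0])},
                       "Arch": {"a": np.array([5.0, 7.0, 0.0]),
                                "t": np.array([0.0, 0.0, 3.0])}},
        wall_resids={"c1": ((500, 501, 502, 503), (624, 625, 626, 627)),
                     "c2": ((120, 121, 122, 123), (240, 241, 242, 243))},
        dna_contacts=dna, pp_contacts=pp, ligand_contacts=lig,
        ligand_sites={"phos": (-4.0, -16.0, -8.0), "adenine": (2.0, -16.0, -8.0),
                      "atp_cm": (5.0, -16.0, -6.0), "mg": (-4.0, -19.0, -13.0)},
        ligand_defs=[
            dict(resid=901, resname="ATP", bound=["SD3"], bulk=(150, 150, 150),
                 atoms=[dict(name="PG", kind="phosphate", element="P", site="phos"),
                        dict(kind="ring", site="adenine"),
                        dict(name="CM", kind="nonpolar", site="atp_cm")]),
            dict(resid=902, resname="ADP", bound=["SD4"], bulk=(150, 150, -150),
                 atoms=[dict(name="PB", kind="phosphate", element="P", site="phos"),
                        dict(kind="ring", site="adenine")]),
            dict(resid=903, resname="MG", bound=["SD3"], bulk=(150, -150, 150),
                 atoms=[dict(name="MG", kind="pos", element="MG", site="mg")]),
        ],
        site_occupancy={"phos": {"SD3": 901, "SD4": 902},
                        "adenine": {"SD3": 901, "SD4": 902},
                        "atp_cm": {"SD3": 901}, "mg": {"SD3": 903}},
        extra_ca={},
        mfpt_targets=[8.6e-3, 1.3e-4, 1.3e-4, 1.3e-4],
        backward_fraction=0.5,
        traps_kinetics={"TD1": (300.0, 600.0), "TD2": (120.0, 500.0),
                        "TD3": (150.0, 700.0), "TD4": (120.0, 2800.0)},
        dt_seconds=1e-6,
        constriction_members={
            "c1": frozenset({500, 501, 502, 503, 615, 624, 625, 626, 627, 636}),
            "c2": frozenset({120, 121, 122, 123, 191, 211, 223, 233, 236, 240,
                             241, 242, 243}),
        },
    )


_FIXTURE_CACHE: dict[str, tuple[Topology, KineticFixture]] = {}


def build_xpd_fixture(verify: bool = True) -> tuple[Topology, KineticFixture]:
    """10-state XPD-like system: S1–S7 on the translocation path, 3 traps.

    Embedded stepwise MFPTs: S1→S2 = 3.6e-3 s, S3→S4 = 4.1e-5 s, remaining
    on-path steps 1e-4 s so the full cycle is ≈ 4.0e-3 s, dominated by the
    rate-limiting S1→S2 step. Apo widths (13.2, 6.1) Å and ATP-bound widths
    (10.7, 11.7) Å at Constrictions 1/2. The cached fixture is shared —
    treat it as read-only.
    """
    key = ("xpd", verify)
    if key not in _FIXTURE_CACHE:
        _FIXTURE_CACHE[key] = _build_fixture(_xpd_spec(), verify=verify)
    return _FIXTURE_CACHE[key]


def build_ding_fixture(verify: bool = True) -> tuple[Topology, KineticFixture]:
    """9-state DinG-like system: SD1–SD5 on path, 4 traps.

    SD1→SD2 = 8.6e-3 s; full cycle ≈ 9.0e-3 s. Constriction 2 templates are
    systematically wider than the XPD fixture.
    """
    key = ("ding", verify)
    if key not in _FIXTURE_CACHE:
        _FIXTURE_CACHE[key] = _build_fixture(_ding_spec(), verify=verify)
    return _FIXTURE_CACHE[key]
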