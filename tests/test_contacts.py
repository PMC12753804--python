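"""Typed contact detection, persistence aggregation and interface analysis."""

import numpy as np
import pytest

from translokit.contacts import (ContactEvent, InteractionCriteria,
                                 constriction_contact_counts, contact_diff,
                                 detect_contacts_frame, interface_filter,
                                 persistence_table)
from translokit.formats_io import Topology


def _topo(rows):
    """rows: (name, resname, resid, chain, domain, donor, acceptor, charge,
    ring, nonpolar)"""
    cols = list(zip(*rows))
    return Topology(
        atom_name=np.array(cols[0], dtype=object),
        element=np.array(["C"] * len(rows), dtype=object),
        res_name=np.array(cols[1], dtype=object),
        res_id=np.array(cols[2], dtype=int),
        chain_id=np.array(cols[3], dtype=object),
        domain_label=np.array(cols[4], dtype=object),
        donor=np.array(cols[5], dtype=bool),
        acceptor=np.array(cols[6], dtype=bool),
        charge=np.array(cols[7], dtype=np.int8),
        ring_id=np.array(cols[8], dtype=int),
        nonpolar=np.array(cols[9], dtype=bool),
        mass=np.ones(len(rows)) * 12.0)


def _da_pair():
    # donor (res 1) + acceptor (res 2), no explicit hydrogens
    return _topo([
        ("SC", "SER", 1, "A", "other", True, False, 0, -1, False),
        ("SC", "ASN", 2, "A", "other", False, True, 0, -1, False),
    ])


class TestHydrogenBond:
    def test_inside_both_cutoffs(self):
        topo = _da_pair()
        frame = np.array([[0, 0, 0], [3.0, 0, 0]], dtype=float)
        evs = detect_contacts_frame(frame, topo)
        assert [(e.type, e.heavy_atom_only) for e in evs] == [("hbond", True)]

    def test_boundary_distance_inclusive(self):
        topo = _da_pair()
        frame = np.array([[0, 0, 0], [3.2, 0, 0]], dtype=float)
        assert [e.type for e in detect_contacts_frame(frame, topo)] == ["hbond"]

    def test_just_outside_cutoff(self):
        topo = _da_pair()
        frame = np.array([[0, 0, 0], [3.2001, 0, 0]], dtype=float)
        assert detect_contacts_frame(frame, topo) == []

    def test_explicit_hydrogen_angle_boundary(self):
        # donor-H-acceptor angle exactly 135° passes (inclusive)
        topo = _topo([
            ("OG", "SER", 1, "A", "other", True, False, 0, -1, False),
            ("HG", "SER", 1, "A", "other", False, False, 0, -1, False),
            ("OD1", "ASN", 2, "A", "other", False, True, 0, -1, False),
        ])
        h = np.array([1.0, 0.0, 0.0])
        ang = np.radians(135.0)
        acceptor = h + 1.8 * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0])
        frame = np.vstack([[0, 0, 0], h, acceptor])
        evs = detect_contacts_frame(frame, topo)
        assert [(e.type, e.heavy_atom_only) for e in evs] == [("hbond", False)]

    def test_explicit_hydrogen_angle_too_sharp(self):
        topo = _topo([
            ("OG", "SER", 1, "A", "other", True, False, 0, -1, False),
            ("HG", "SER", 1, "A", "other", False, False, 0, -1, False),
            ("OD1", "ASN", 2, "A", "other", False, True, 0, -1, False),
        ])
        # acceptor at 90° from the donor about the hydrogen
        frame = np.array([[0, 0, 0], [1.0, 0, 0], [1.0, 1.5, 0]])
        assert detect_contacts_frame(frame, topo) == []


class TestOtherTypes:
    def test_salt_bridge_and_cutoff_sides(self):
        topo = _topo([
            ("NH1", "ARG", 1, "A", "other", False, False, 1, -1, False),
            ("OD1", "ASP", 2, "A", "other", False, False, -1, -1, False),
        ])
        near = np.array([[0, 0, 0], [3.1, 0, 0]], dtype=float)
        far = np.array([[0, 0, 0], [3.3, 0, 0]], dtype=float)
        assert [e.type for e in detect_contacts_frame(near, topo)] == \
            ["salt_bridge"]
        assert detect_contacts_frame(far, topo) == []

    @pytest.mark.parametrize("dz,expect", [(3.5, True), (3.6, False)])
    def test_pi_stack_centroid_cutoff(self, dz, expect):
        rows = []
        for resid, ring in ((1, 0), (2, 1)):
            rows += [("R%d" % (k + 1), "PHE", resid, "A", "other",
                      False, False, 0, ring, False) for k in range(5)]
        topo = _topo(rows)
        ang = 2 * np.pi * np.arange(5) / 5
        penta = np.stack([np.cos(ang), np.sin(ang), np.zeros(5)], 1) * 0.7
        frame = np.vstack([penta, penta + [0, 0, dz]])
        types = [e.type for e in detect_contacts_frame(frame, topo)]
        assert ("pi_stack" in types) is expect

    def test_hydrophobic_cutoff_and_backbone_exclusion(self):
        topo = _topo([
            ("CD1", "LEU", 1, "A", "other", False, False, 0, -1, True),
            ("CD1", "ILE", 2, "A", "other", False, False, 0, -1, True),
            ("CA", "LEU", 1, "A", "other", False, False, 0, -1, True),
        ])
        frame = np.array([[0, 0, 0], [4.5, 0, 0], [4.5, 0.1, 0]], dtype=float)
        evs = detect_contacts_frame(frame, topo)
        assert [e.type for e in evs] == ["hydrophobic"]  # CA never counts

    def test_residue_level_dedup_and_order_symmetry(self):
        topo = _topo([
            ("NH1", "ARG", 5, "A", "other", False, False, 1, -1, False),
            ("NH2", "ARG", 5, "A", "other", False, False, 1, -1, False),
            ("OD1", "ASP", 2, "A", "other", False, False, -1, -1, False),
            ("OD2", "ASP", 2, "A", "other", False, False, -1, -1, False),
        ])
        frame = np.array([[0, 0, 0], [0.5, 0, 0], [2.5, 0, 0], [2.0, 1, 0]])
        evs = detect_contacts_frame(frame, topo)
        assert len(evs) == 1
        assert evs[0].res_a == ("A", 2) and evs[0].res_b == ("A", 5)


class TestPersistence:
    def _events(self, present_frames, total=100):
        ev = ContactEvent(0, ("A", 1), ("A", 2), "hbond")
        return [[ev] if t < present_frames else [] for t in range(total)]

    @pytest.mark.parametrize("n,persistent", [(80, True), (75, True),
                                              (74, False)])
    def test_threshold_flips_exactly_at_075(self, n, persistent):
        table = persistence_table(self._events(n), np.zeros(100, dtype=int))
        row = table.table.iloc[0]
        assert row["fraction"] == pytest.approx(n / 100)
        assert bool(row["persistent"]) is persistent

    def test_absent_contact_omitted(self):
        table = persistence_table(self._events(0), np.zeros(100, dtype=int))
        assert len(table.table) == 0

    def test_fractions_invariant_under_frame_permutation(self, rng):
        evs = self._events(40)
        labels = np.zeros(100, dtype=int)
        perm = rng.permutation(100)
        t1 = persistence_table(evs, labels)
        t2 = persistence_table([evs[i] for i in perm], labels[perm])
        assert t1.table.equals(t2.table)

    def test_labels_must_cover_frames(self):
        with pytest.raises(ValueError):
            persistence_table(self._events(5), np.zeros(99, dtype=int))


def _fixture_table(xpd, states=("S1", "S4")):
    """Noise-free per-state tables from template detection."""
    topo, fixture = xpd
    events, labels = [], []
    for s in states:
        st = fixture.states[fixture.index(s)]
        for _ in range(4):
            events.append(detect_contacts_frame(st.coordinates, topo))
            labels.append(s)
    return persistence_table(events, np.array(labels), topo)


class TestInterfaceAndDiff:
    def test_interface_filter_recovers_encoded_reca_interface(self, xpd):
        topo, fixture = xpd
        table = _fixture_table(xpd, states=("S4",))
        sub = interface_filter(table, "RecA1", "RecA2")
        got = {(a, b, t) for a, b, t in sub.persistent_set("S4")}
        s4 = fixture.states[fixture.index("S4")].contact_pattern
        dom = {(c, int(r)): d for c, r, d in
               zip(topo.chain_id, topo.res_id, topo.domain_label)}
        expected = {k for k in s4
                    if {dom.get(k[0]), dom.get(k[1])} == {"RecA1", "RecA2"}}
        assert got == expected and len(expected) > 0

    def test_protein_vs_dna_filter(self, xpd):
        table = _fixture_table(xpd)
        sub = interface_filter(table, [("A", r) for r in range(1, 800)],
                               [("D", n) for n in range(1, 13)])
        for _, row in sub.table.iterrows():
            assert {row["res_a"][0], row["res_b"][0]} == {"A", "D"}

    def test_overlapping_groups_rejected(self, xpd):
        table = _fixture_table(xpd)
        with pytest.raises(ValueError):
            interface_filter(table, [("A", 1)], [("A", 1), ("A", 2)])

    def test_diff_of_identical_states_empty(self, xpd):
        table = _fixture_table(xpd, states=("S1",))
        d = contact_diff(table, table)
        assert d.gained == set() and d.lost == set()

    def test_s1_s4_diff_equals_pattern_xor(self, xpd):
        _, fixture = xpd
        table = _fixture_table(xpd)
        d = contact_diff(table.for_state("S1"), table.for_state("S4"))
        p1 = set(fixture.states[fixture.index("S1")].contact_pattern)
        p4 = set(fixture.states[fixture.index("S4")].contact_pattern)
        assert d.gained == p4 - p1
        assert d.lost == p1 - p4
        assert d.retained == p1 & p4

    def test_diff_antisymmetry(self, xpd):
        table = _fixture_table(xpd)
        d_xy = contact_diff(table.for_state("S1"), table.for_state("S4"))
        d_yx = contact_diff(table.for_state("S4"), table.for_state("S1"))
        assert d_xy.gained == d_yx.lost and d_xy.lost == d_yx.gained


class TestConstrictionCounts:
    def test_apo_maximal_at_constriction_2(self, xpd):
        _, fixture = xpd
        table = _fixture_table(xpd)
        counts = constriction_contact_counts(
            table, fixture.constriction_members["c1"],
            fixture.constriction_members["c2"])
        c = counts.set_index("state")
        assert c.loc["S1", "constriction_2"] > c.loc["S4", "constriction_2"]
        assert c.loc["S4", "constriction_1"] > c.loc["S1", "constriction_1"]

    def test_empty_member_set_gives_zero(self, xpd):
        table = _fixture_table(xpd)
        counts = constriction_contact_counts(table, [], [9999])
        assert (counts["constriction_1"] == 0).all()
        assert (counts["constriction_2"] == 0).all()

    def test_manual_tally_on_toy_table(self):
        import pandas as pd
        from translokit.contacts import ContactTable
        rows = [
            ("X", ("A", 10), ("D", 1), "salt_bridge", 1.0, True),
            ("X", ("A", 11), ("D", 2), "hbond", 1.0, True),
            ("X", ("A", 20), ("D", 3), "hbond", 1.0, True),
            ("X", ("A", 10), ("A", 11), "hbond", 1.0, True),   # not DNA
            ("X", ("A", 30), ("D", 4), "hbond", 0.5, False),   # not persistent
        ]
        df = pd.DataFrame(rows, columns=["state", "res_a", "res_b", "type",
                                         "fraction", "persistent"])
        counts = constriction_contact_counts(ContactTable(df), [10, 11], [20])
        assert counts.iloc[0]["constriction_1"] == 2
        assert counts.iloc[0]["constriction_2"] == 1


class TestCriteriaValidation:
    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            InteractionCriteria(persistence_threshold=0.0)
        with pytest.raises(ValueError):
            InteractionCriteria(hbond_dist=-1.0)
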