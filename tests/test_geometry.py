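"""Domain geometry, constriction widths, superposition and DNA register."""

import numpy as np
import pytest

from translokit.formats_io import Topology
from translokit.geometry import (ConstrictionDefinition, constriction_width,
                                 displacement_field, dna_register_offset,
                                 domain_geometry, kabsch, macrostate_centroid,
                                 superpose)
from translokit.formats_io import Trajectory
from translokit.synthetic import EmissionModel, emit_trajectory


def _topo(domains, resids=None, names=None, chains=None, masses=None):
    n = len(domains)
    return Topology(
        atom_name=np.array(names or ["CA"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        res_name=np.array(["GLY"] * n, dtype=object),
        res_id=np.array(resids or list(range(1, n + 1))),
        chain_id=np.array(chains or ["A"] * n, dtype=object),
        domain_label=np.array(domains, dtype=object),
        donor=np.zeros(n, bool), acceptor=np.zeros(n, bool),
        charge=np.zeros(n, np.int8), ring_id=np.full(n, -1),
        nonpolar=np.zeros(n, bool),
        mass=np.array(masses or [12.0] * n))


class TestDomainGeometry:
    def test_right_angle(self):
        topo = _topo(["FeS", "RecA1", "Arch"])
        frame = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)
        g = domain_geometry(frame, topo)
        assert g.theta == pytest.approx(90.0)

    def test_collinear_is_180(self):
        topo = _topo(["FeS", "RecA1", "Arch"])
        frame = np.array([[-1, 0, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
        assert domain_geometry(frame, topo).theta == pytest.approx(180.0)

    def test_unit_mass_com_is_mean(self, rng):
        topo = _topo(["FeS", "FeS", "RecA1", "Arch"], masses=[1, 1, 1, 1])
        frame = rng.normal(size=(4, 3))
        g = domain_geometry(frame, topo)
        assert np.allclose(g.com["FeS"], frame[:2].mean(axis=0))

    def test_rigid_motion_invariance(self, rng, xpd):
        topo, fixture = xpd
        frame = fixture.states[0].coordinates
        g0 = domain_geometry(frame, topo)
        R, _ = kabsch(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
        moved = frame @ R.T + np.array([5.0, -3.0, 11.0])
        g1 = domain_geometry(moved, topo)
        assert g1.d_af == pytest.approx(g0.d_af, abs=1e-9)
        assert g1.theta == pytest.approx(g0.theta, abs=1e-9)

    def test_empty_domain_errors(self):
        topo = _topo(["FeS", "RecA1"])
        with pytest.raises(ValueError, match="Arch"):
            domain_geometry(np.zeros((2, 3)), topo)


class TestConstrictionWidth:
    def _walls(self, separation, n=4, spacing=8.0):
        topo = _topo(["RecA2"] * (2 * n), resids=list(range(1, n + 1))
                     + list(range(101, 101 + n)))
        a = np.array([[i * spacing, 0, 0] for i in range(n)], dtype=float)
        b = a + [0, 0, separation]
        return topo, np.vstack([a, b])

    def test_parallel_walls_return_separation(self):
        topo, frame = self._walls(6.1)
        d = ConstrictionDefinition("c", frozenset(range(1, 5)),
                                   frozenset(range(101, 105)))
        assert constriction_width(frame, d, topo) == pytest.approx(6.1)

    def test_single_atom_walls(self):
        topo = _topo(["RecA2", "FeS"], resids=[1, 2])
        frame = np.array([[0, 0, 0], [0, 0, 5.0]])
        d = ConstrictionDefinition("c", frozenset([1]), frozenset([2]))
        assert constriction_width(frame, d, topo) == pytest.approx(5.0)

    def test_symmetric_in_wall_exchange(self):
        topo, frame = self._walls(7.3)
        d1 = ConstrictionDefinition("c", frozenset(range(1, 5)),
                                    frozenset(range(101, 105)))
        d2 = ConstrictionDefinition("c", frozenset(range(101, 105)),
                                    frozenset(range(1, 5)))
        assert constriction_width(frame, d1, topo) == \
            constriction_width(frame, d2, topo)

    def test_disjoint_nonempty_walls_enforced(self):
        with pytest.raises(ValueError):
            ConstrictionDefinition("c", frozenset(), frozenset([1]))
        with pytest.raises(ValueError):
            ConstrictionDefinition("c", frozenset([1]), frozenset([1, 2]))

    def test_noisy_frames_recover_template_width(self, xpd):
        topo, fixture = xpd
        seq = np.full(500, fixture.index("S1"))
        traj = emit_trajectory(seq, fixture, EmissionModel(0.2, 21))
        w = np.array([constriction_width(traj.coordinates[t],
                                         fixture.constrictions["c2"], topo)
                      for t in range(500)])
        sem = w.std(ddof=1) / np.sqrt(len(w))
        assert abs(w.mean() - 6.1) < max(3 * sem, 0.05)


class TestCentroidAndDisplacement:
    def test_identical_frames_any_member(self, xpd):
        topo, fixture = xpd
        coords = np.repeat(fixture.states[0].coordinates[None], 5, axis=0)
        traj = Trajectory(coords, 1.0, topo)
        idx = macrostate_centroid(traj, np.zeros(5), 0, topo)
        assert 0 <= idx < 5

    def test_three_frames_middle_wins(self, rng):
        # shape changes of ±v on one atom around an asymmetric scaffold:
        # pairwise RMSDs ≈ (r, r, 2r), the frame on both short edges wins
        topo = _topo(["RecA1"] * 6)
        base = rng.normal(size=(6, 3)) * 4.0
        v = np.array([2.0, 0.5, -1.0])
        frames = np.stack([base, base, base])
        frames[0][0] += v
        frames[2][0] -= v
        traj = Trajectory(frames, 1.0, topo)
        idx = macrostate_centroid(traj, np.zeros(3), 0, topo)
        assert idx == 1

    def test_subsampling_reproducible(self, xpd):
        topo, fixture = xpd
        rng = np.random.default_rng(0)
        coords = (fixture.states[0].coordinates[None]
                  + rng.normal(scale=0.1, size=(30, topo.n_atoms, 3)))
        traj = Trajectory(coords, 1.0, topo)
        a = macrostate_centroid(traj, np.zeros(30), 0, topo, seed=5,
                                max_members=10)
        b = macrostate_centroid(traj, np.zeros(30), 0, topo, seed=5,
                                max_members=10)
        assert a == b

    def test_empty_state_errors(self, xpd):
        topo, fixture = xpd
        traj = Trajectory(fixture.states[0].coordinates[None], 1.0, topo)
        with pytest.raises(ValueError):
            macrostate_centroid(traj, np.zeros(1), 3, topo)

    def test_identical_structures_zero_field(self, xpd):
        topo, fixture = xpd
        c = fixture.states[0].coordinates
        f = displacement_field(c, c, topo)
        assert np.allclose(f.vectors, 0.0, atol=1e-12)

    def test_pure_rotation_removed_by_superposition(self, xpd, rng):
        topo, fixture = xpd
        c = fixture.states[0].coordinates
        R, _ = kabsch(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))
        f = displacement_field(c, c @ R.T + [3.0, 1.0, -2.0], topo)
        assert np.allclose(f.vectors, 0.0, atol=1e-8)

    def test_domain_translation_matches_least_squares_oracle(self, xpd):
        topo, fixture = xpd
        a = fixture.states[0].coordinates
        b = a.copy()
        arch = topo.domain_label == "Arch"
        b[arch] += [2.0, 0.0, 0.0]
        f = displacement_field(a, b, topo)
        ca = topo.ca_indices()
        # independent least-squares superposition oracle
        b_fit = superpose(b, a, ca)
        oracle = b_fit[ca] - a[ca]
        assert np.allclose(f.vectors, oracle, atol=1e-10)
        arch_ca = topo.domain_label[ca] == "Arch"
        mean_vec = f.vectors[arch_ca].mean(axis=0)
        assert mean_vec[0] > 1.0  # translation minus the global-fit residual


class TestDNARegister:
    def test_self_offset_zero(self, xpd):
        topo, fixture = xpd
        c = fixture.states[0].coordinates
        assert dna_register_offset(c, c, topo) == 0

    def test_cycle_endpoints_offset_plus_one(self, xpd):
        topo, fixture = xpd
        s1 = fixture.states[fixture.index("S1")].coordinates
        s7 = fixture.states[fixture.index("S7")].coordinates
        assert dna_register_offset(s1, s7, topo) == 1

    def test_constructed_shift_of_two(self, xpd):
        topo, fixture = xpd
        from translokit.synthetic import RISE
        s1 = fixture.states[0].coordinates
        shifted = s1.copy()
        shifted[topo.is_dna()] += [2 * RISE, 0.0, 0.0]
        assert dna_register_offset(s1, shifted, topo) == 2

    def test_ambiguous_register_errors(self):
        # a perfectly periodic DNA with no protein anchors ties all offsets
        topo = _topo(["RecA1", "RecA1", "DNA", "DNA", "DNA", "DNA"],
                     names=["CA", "CA", "P", "P", "P", "P"],
                     resids=[1, 2, 1, 2, 3, 4],
                     chains=["A", "A", "D", "D", "D", "D"])
        frame = np.array([[0, 5, 0], [10, 5, 0],
                          [0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                         dtype=float)
        other = frame.copy()
        other[2:] += [0.5, 0.0, 0.0]   # half-register shift ties s=0 and s=1
        with pytest.raises(ValueError, match="ambiguous"):
            dna_register_offset(frame, other, topo)
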