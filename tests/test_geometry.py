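"""Superposition, RMSD/Rg, contacts, rim distances and free-energy landscapes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from hostguest import geometry as geo
from hostguest import synth
from hostguest.errors import DegenerateGeometryError, InvalidInputError, TopologyError

R_KCAL = 1.985e-3


def random_rigid_motion(rng):
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.uniform(-10, 10, 3)


class TestKabsch:
    def test_identity(self, rng):
        coords = rng.normal(size=(10, 3))
        rot, trans, rmsd = geo.kabsch_superpose(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_rigid_motion_removable(self, rng):
        ref = rng.normal(size=(12, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot90.T + np.array([5.0, 5.0, 5.0])
        _, _, rmsd = geo.kabsch_superpose(mobile, ref)
        assert rmsd <= 1e-8

    def test_rotation_always_proper(self, rng):
        # reflected configurations must still yield det(+1) rotations
        ref = rng.normal(size=(6, 3))
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = geo.kabsch_superpose(mirrored, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_lifted_square_matches_independent_solver(self):
        """Unit square vs one vertex lifted 1 A: minimized RMSD from an
        independent Wahba-problem solver (scipy align_vectors)."""
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        lifted = square.copy()
        lifted[2, 2] = 1.0
        _, _, rmsd = geo.kabsch_superpose(square, lifted)
        a = square - square.mean(axis=0)
        b = lifted - lifted.mean(axis=0)
        _, rssd = Rotation.align_vectors(b, a)
        assert rmsd == pytest.approx(rssd / math.sqrt(len(square)), rel=1e-9)

    @pytest.mark.parametrize(
        "bad",
        [
            np.zeros((5, 3)),  # coincident
            np.outer(np.arange(5.0), [1.0, 2.0, 3.0]),  # collinear
        ],
    )
    def test_degenerate_selection_rejected(self, bad, rng):
        with pytest.raises(DegenerateGeometryError):
            geo.kabsch_superpose(bad, rng.normal(size=(5, 3)))

    def test_rmsd_symmetric(self, rng):
        a = rng.normal(size=(9, 3))
        b = a + rng.normal(0, 0.3, size=(9, 3))
        _, _, r_ab = geo.kabsch_superpose(a, b)
        _, _, r_ba = geo.kabsch_superpose(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-8)


class TestRmsdSeries:
    def test_identical_frames_zero(self, rng):
        frame = rng.normal(size=(8, 3))
        traj = geo.Trajectory(np.repeat(frame[None], 4, axis=0))
        assert np.all(geo.rmsd_series(traj, frame).values < 1e-10)

    def test_rigid_copies_zero(self, rng):
        frame = rng.normal(size=(8, 3))
        frames = []
        for _ in range(5):
            rot, trans = random_rigid_motion(rng)
            frames.append(frame @ rot.T + trans)
        traj = geo.Trajectory(np.array(frames))
        assert np.all(geo.rmsd_series(traj, frame).values <= 1e-8)

    def test_jittered_ring_matches_framewise_oracle(self, ring_jittered):
        traj, topo = ring_jittered
        ref = traj.coordinates[0]
        series = geo.rmsd_series(traj, ref)
        for i in range(traj.n_frames):
            a = traj.coordinates[i] - traj.coordinates[i].mean(axis=0)
            b = ref - ref.mean(axis=0)
            _, rssd = Rotation.align_vectors(b, a)
            assert series.values[i] == pytest.approx(
                rssd / math.sqrt(traj.n_atoms), rel=1e-6, abs=1e-9
            )

    def test_empty_selection_rejected(self, ring_rigid):
        traj, _ = ring_rigid
        with pytest.raises(InvalidInputError):
            geo.rmsd_series(traj, traj.coordinates[0], selection=[])


class TestRg:
    def test_coincident_atoms(self):
        traj = geo.Trajectory(np.zeros((2, 5, 3)))
        assert np.all(geo.rg_series(traj).values == 0.0)

    def test_symmetric_dumbbell(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 2.0
        assert geo.rg_series(geo.Trajectory(coords)).values[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("k", range(3, 13))
    def test_ring_rg_equals_radius(self, k):
        theta = 2 * np.pi * np.arange(k) / k
        coords = np.stack([6.5 * np.cos(theta), 6.5 * np.sin(theta), np.zeros(k)], axis=1)
        rg = geo.rg_series(geo.Trajectory(coords[None])).values[0]
        assert rg == pytest.approx(6.5, abs=1e-10)

    def test_mass_weighting_moves_rg(self):
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 2.0
        rg = geo.rg_series(geo.Trajectory(coords), masses=np.array([3.0, 1.0])).values[0]
        # com at 0.5; rg = sqrt(0.75*0.25 + 0.25*2.25)
        assert rg == pytest.approx(math.sqrt(0.75 * 0.25 + 0.25 * 2.25), rel=1e-12)


def brute_force_contacts(a, b, cutoff, box=None):
    count = 0
    pairs = set()
    for i in range(len(a)):
        for j in range(len(b)):
            d = a[i] - b[j]
            if box is not None:
                d = d - box * np.round(d / box)
            if np.sqrt((d**2).sum()) <= cutoff:
                count += 1
                pairs.add((i, j))
    return count, pairs


class TestContacts:
    def test_separated_groups_zero(self):
        coords = np.zeros((3, 4, 3))
        coords[:, 2:, 0] = 50.0
        traj = geo.Trajectory(coords)
        total, native, nonnative = geo.contact_series(traj, [0, 1], [2, 3], cutoff=4.5)
        assert np.all(total.values == 0)

    def test_reference_frame_has_no_nonnative(self, rng):
        coords = rng.uniform(0, 8, size=(1, 12, 3))
        traj = geo.Trajectory(np.repeat(coords, 3, axis=0))
        _, _, nonnative = geo.contact_series(traj, range(6), range(6, 12), cutoff=4.0)
        assert np.all(nonnative.values == 0)

    @pytest.mark.parametrize("periodic", [False, True])
    def test_matches_brute_force_oracle(self, rng, periodic):
        box = np.array([12.0, 12.0, 12.0]) if periodic else None
        for _ in range(25):
            na, nb = rng.integers(2, 50), rng.integers(2, 50)
            coords = rng.uniform(0, 12, size=(2, na + nb, 3))
            traj = geo.Trajectory(coords, box=box)
            total, native, nonnative = geo.contact_series(
                traj, range(na), range(na, na + nb), cutoff=3.0, reference_frame=0
            )
            for f in range(2):
                cnt, pairs = brute_force_contacts(
                    coords[f, :na], coords[f, na:], 3.0, box
                )
                assert total.values[f] == cnt
            _, ref_pairs = brute_force_contacts(coords[0, :na], coords[0, na:], 3.0, box)
            _, f1_pairs = brute_force_contacts(coords[1, :na], coords[1, na:], 3.0, box)
            assert native.values[1] == len(ref_pairs & f1_pairs)
            assert nonnative.values[1] == len(f1_pairs - ref_pairs)

    def test_overlapping_groups_rejected(self, ring_rigid):
        traj, _ = ring_rigid
        with pytest.raises(InvalidInputError):
            geo.contact_series(traj, [0, 1, 2], [2, 3], cutoff=4.0)


class TestRimDistances:
    def test_constructed_separation_exact(self, ring_rigid):
        traj, topo = ring_rigid
        rims = geo.rim_distances(traj, topo)
        assert rims.d32 == pytest.approx(3.0, abs=1e-12)

    def test_heptagon_chord_closed_form(self, ring_rigid):
        traj, topo = ring_rigid
        rims = geo.rim_distances(traj, topo)
        assert rims.d44 == pytest.approx(2 * 5.0 * math.sin(math.pi / 7), rel=1e-12)

    def test_cyclic_pairing_includes_ring_closure(self, ring_rigid):
        traj, topo = ring_rigid
        rims = geo.rim_distances(traj, topo)
        assert rims.d32.shape == (traj.n_frames, topo.n_units)
        # pair (n_units -> 1): last column pairs O3(7) with O2(1)
        o3_last = traj.coordinates[0, topo.site_map["O3"][-1]]
        o2_first = traj.coordinates[0, topo.site_map["O2"][0]]
        assert rims.d32[0, -1] == pytest.approx(np.linalg.norm(o3_last - o2_first))

    def test_jittered_matches_direct_arithmetic(self, ring_jittered):
        traj, topo = ring_jittered
        rims = geo.rim_distances(traj, topo)
        n = topo.n_units
        for f in (0, traj.n_frames - 1):
            for u in range(n):
                o3 = traj.coordinates[f, topo.site_map["O3"][u]]
                o2 = traj.coordinates[f, topo.site_map["O2"][(u + 1) % n]]
                o4a = traj.coordinates[f, topo.site_map["O4"][u]]
                o4b = traj.coordinates[f, topo.site_map["O4"][(u + 1) % n]]
                assert rims.d32[f, u] == pytest.approx(
                    math.dist(o3, o2), rel=1e-12
                )
                assert rims.d44[f, u] == pytest.approx(
                    math.dist(o4a, o4b), rel=1e-12
                )

    def test_missing_site_rejected(self, ring_rigid):
        traj, topo = ring_rigid
        broken = geo.Topology(
            names=topo.names, elements=topo.elements, roles=topo.roles,
            unit_index=topo.unit_index, n_units=0, site_map={},
        )
        with pytest.raises(TopologyError):
            geo.rim_distances(traj, broken)


class TestHbondFraction:
    @pytest.mark.parametrize(
        "value, expected", [(3.0, 1.0), (4.0, 0.0)]
    )
    def test_uniform_distances(self, value, expected):
        rims = geo.RimDistances(np.full((4, 7), value), np.full((4, 7), 4.3))
        assert geo.hbond_fraction(rims) == expected

    def test_half_below_half_above(self):
        d32 = np.concatenate([np.full(14, 3.2), np.full(14, 3.8)]).reshape(4, 7)
        rims = geo.RimDistances(d32, np.full((4, 7), 4.3))
        assert geo.hbond_fraction(rims, threshold=3.5) == 0.5


class TestFEL:
    def test_single_occupied_bin(self):
        grid = geo.fel_2d(np.full(50, 1.02), np.full(50, 2.04), 0.1, 0.1)
        occupied = ~np.ma.getmaskarray(grid.f_values)
        assert occupied.sum() == 1
        assert grid.f_values.compressed()[0] == pytest.approx(0.0)

    def test_two_bin_closed_form(self):
        """80/20 split at 303 K: dF = kB*T*ln 4 ~ 0.834 kcal/mol."""
        x = np.concatenate([np.full(80, 0.05), np.full(20, 0.15)])
        grid = geo.fel_2d(x, np.zeros(100), 0.1, 0.1, temperature=303.0)
        df = grid.f_values.max() - grid.f_values.min()
        assert df == pytest.approx(R_KCAL * 303.0 * math.log(4.0), rel=1e-12)

    def test_renormalized_boltzmann_recovers_probabilities(self, rng):
        x = rng.normal(3.2, 0.4, 5000)
        y = rng.normal(4.3, 0.3, 5000)
        grid = geo.fel_2d(x, y, 0.1, 0.1, temperature=303.0)
        occupied = ~np.ma.getmaskarray(grid.f_values)
        w = np.exp(-grid.f_values.data[occupied] / grid.kbt)
        p_back = w / w.sum()
        p_emp = grid.counts[occupied] / grid.n_samples
        assert p_back == pytest.approx(p_emp, abs=1e-12)
        assert grid.counts.sum() == grid.n_samples

    def test_matches_independent_histogram_oracle(self, rng):
        x = rng.normal(3.0, 0.5, 2000)
        y = rng.normal(4.0, 0.5, 2000)
        grid = geo.fel_2d(x, y, 0.1, 0.1, temperature=303.0)
        counts, _, _ = np.histogram2d(x, y, bins=(grid.x_edges, grid.y_edges))
        kbt = R_KCAL * 303.0
        with np.errstate(divide="ignore"):
            f_oracle = -kbt * np.log(counts / len(x))
        f_oracle -= f_oracle[counts > 0].min()
        occupied = counts > 0
        assert grid.f_values.data[occupied] == pytest.approx(f_oracle[occupied], abs=1e-12)
        assert np.array_equal(np.ma.getmaskarray(grid.f_values), ~occupied)

    def test_empty_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            geo.fel_2d(np.array([]), np.array([]), 0.1, 0.1)


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 2**16), scale=st.floats(0.5, 20.0))
def test_rmsd_invariant_under_rigid_motion(seed, scale):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, scale, size=(7, 3))
    b = a + rng.normal(0, 0.2, size=(7, 3))
    _, _, base = geo.kabsch_superpose(a, b)
    rot, trans = random_rigid_motion(rng)
    _, _, moved = geo.kabsch_superpose(a @ rot.T + trans, b)
    assert abs(moved - base) < 1e-8
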