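"""Dihedral geometry, rotamer statistics, superposition and RMSD matrices."""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.spatial.transform import Rotation

from allokin.conformational_analysis import (
    assign_rotamer,
    bootstrap_histogram,
    chi1_series,
    dihedral,
    filter_frames_by_distance,
    kabsch_superpose,
    min_distance,
    pairwise_rmsd_bootstrap,
    pairwise_rmsd_matrix,
    transition_rate,
)
from allokin.trajectory_synth import (
    FrameEnsemble,
    RotamerCTMC,
    StateSeries,
    emit_dihedrals,
    generate_pose_ensemble,
    simulate_ctmc,
    stationary_distribution,
)


def quaternion_rmsd(X, Y):
    """Independent oracle: optimal superposition RMSD via Horn's quaternion
    eigenvalue method (no SVD, no shared code path with the implementation)."""
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    S = Y.T @ X
    sxx, sxy, sxz = S[0]
    syx, syy, syz = S[1]
    szx, szy, szz = S[2]
    K = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(X**2) + np.sum(Y**2) - 2.0 * lam) / X.shape[0]
    return math.sqrt(max(msd, 0.0))


class TestDihedral:
    def test_planar_trans(self):
        assert dihedral([1, 1, 0], [0, 1, 0], [0, 0, 0], [-1, 0, 0]) == pytest.approx(180.0)

    def test_planar_cis(self):
        assert dihedral([1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]) == pytest.approx(0.0)

    def test_plus_ninety_sign_against_handedness_oracle(self):
        p1, p2, p3 = np.array([1.0, 1, 0]), np.array([0.0, 1, 0]), np.array([0.0, 0, 0])
        p4 = np.array([1.0, 0, 0])
        R = Rotation.from_rotvec([0, -math.pi / 2, 0]).as_matrix()  # +90° about p2→p3
        p4r = (R @ (p4 - p3)) + p3
        ang = dihedral(p1, p2, p3, p4r)
        # oracle: sign from the handedness of (n1 × n2) relative to the bond
        b2 = p3 - p2
        n1 = np.cross(p2 - p1, b2)
        n2 = np.cross(b2, p4r - p3)
        assert np.sign(np.dot(np.cross(n1, n2), b2)) == np.sign(ang)
        assert ang == pytest.approx(90.0, abs=1e-9)

    def test_collinear_geometry_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


def _threonine_frames(chi1_deg, n_frames=1):
    """Ideal-geometry Thr fragment (N, CA, CB, OG1 + CG2) built at a set χ1."""
    # place N-CA-CB in a plane, then rotate OG1 about the CA-CB bond
    n = np.array([-1.458, 0.0, 0.0])
    ca = np.zeros(3)
    cb = np.array([0.551, 1.438, 0.0])
    axis = (cb - ca) / np.linalg.norm(cb - ca)
    # reference position at χ1 = 0: OG1 eclipsing N
    d_n = n - ca
    perp = d_n - np.dot(d_n, axis) * axis
    perp /= np.linalg.norm(perp)
    og_ref = cb + 1.42 * (perp * math.sin(math.radians(70.5)) * 1.0
                          + axis * math.cos(math.radians(70.5)))
    rot = Rotation.from_rotvec(axis * math.radians(chi1_deg)).as_matrix()
    og1 = (rot @ (og_ref - cb)) + cb
    coords = np.stack([n, ca, cb, og1])
    frames = np.repeat(coords[None], n_frames, axis=0)
    return FrameEnsemble(
        frames=frames,
        atom_names=("N", "CA", "CB", "OG1"),
        residue_names=("THR",) * 4,
        residue_ids=(497,) * 4,
    )


class TestChi1Series:
    @pytest.mark.parametrize("chi1", [-60.0, 60.0, 180.0, -155.0])
    def test_constructed_geometry_recovers_set_angle(self, chi1):
        ens = _threonine_frames(chi1, n_frames=3)
        series = chi1_series(ens, 497)
        assert series.shape == (3,)
        np.testing.assert_allclose(series, chi1, atol=0.01)

    def test_single_frame_series(self):
        assert chi1_series(_threonine_frames(-60.0), 497).shape == (1,)

    def test_matches_mdtraj_oracle(self, tmp_path):
        md = pytest.importorskip("mdtraj")
        from allokin.io import write_multiframe_pdb

        ens = _threonine_frames(-72.5, n_frames=2)
        path = tmp_path / "thr.pdb"
        write_multiframe_pdb(ens, path)
        traj = md.load(str(path))
        idx = [[0, 1, 2, 3]]
        oracle = np.degrees(md.compute_dihedrals(traj, idx)[:, 0])
        np.testing.assert_allclose(chi1_series(ens, 497), oracle, atol=0.02)

    def test_missing_atom_named_in_error(self):
        ens = _threonine_frames(-60.0)
        broken = FrameEnsemble(
            frames=ens.frames[:, :3, :], atom_names=("N", "CA", "CB"),
            residue_names=("THR",) * 3, residue_ids=(497,) * 3,
        )
        with pytest.raises(ValueError, match="OG1"):
            chi1_series(broken, 497)

    def test_renumbered_copy_identical(self):
        ens = _threonine_frames(60.0, n_frames=2)
        renum = FrameEnsemble(frames=ens.frames, atom_names=ens.atom_names,
                              residue_names=ens.residue_names,
                              residue_ids=(731,) * 4)
        np.testing.assert_array_equal(chi1_series(ens, 497), chi1_series(renum, 731))


class TestAssignRotamer:
    @pytest.mark.parametrize("angle,expect", [
        (60.0, "gauche+"), (-60.0, "gauche-"), (170.0, "trans"), (-170.0, "trans"),
        (0.0, "gauche-"), (120.0, "gauche+"), (-120.0, "trans"), (180.0, "trans"),
        (420.0, "gauche+"),  # wraps to +60
    ])
    def test_bin_definitions(self, angle, expect):
        assert assign_rotamer(angle) == expect


class TestBootstrapHistogram:
    def test_degenerate_pool_single_bin(self):
        h = bootstrap_histogram(np.full(100, 3.7), bin_edges=[0.0, 2.0, 4.0, 6.0],
                                n_boot=20, sample_size=50, seed=0)
        np.testing.assert_allclose(h.mean_freq, [0.0, 1.0, 0.0])
        np.testing.assert_allclose(h.sd_freq, 0.0)

    def test_binomial_sd_closed_form(self):
        pool = np.r_[np.zeros(50000), np.ones(50000)]
        h = bootstrap_histogram(pool, bin_edges=[-0.5, 0.5, 1.5], n_boot=500,
                                sample_size=5000, seed=1)
        expected_sd = math.sqrt(0.5 * 0.5 / 5000)
        for sd in h.sd_freq:
            assert sd == pytest.approx(expected_sd, rel=0.2)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(2)
        h = bootstrap_histogram(rng.normal(size=2000), bin_edges=np.linspace(-5, 5, 21),
                                n_boot=50, sample_size=500, seed=3)
        assert h.mean_freq.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_boot_without_replacement_equals_plain_histogram(self):
        rng = np.random.default_rng(4)
        pool = rng.normal(size=800)
        edges = np.linspace(-4, 4, 17)
        h = bootstrap_histogram(pool, bin_edges=edges, n_boot=1,
                                sample_size=pool.size, seed=5, replace=False)
        plain, _ = np.histogram(pool, bins=edges)
        np.testing.assert_allclose(h.mean_freq, plain / pool.size)

    def test_categorical_pool(self):
        pool = np.array(["gauche+"] * 30 + ["trans"] * 70)
        h = bootstrap_histogram(pool, bin_edges=["gauche+", "gauche-", "trans"],
                                n_boot=200, sample_size=1000, seed=6)
        assert h.mean_freq[0] == pytest.approx(0.3, abs=0.02)
        assert h.mean_freq[1] == 0.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            bootstrap_histogram(np.array([]), bin_edges=[0, 1])


class TestTransitionRate:
    def test_constant_series_zero(self):
        s = StateSeries(states=np.array(["a"] * 100), frame_interval=1.0)
        assert transition_rate(s) == 0.0

    def test_alternating_series_arithmetic(self):
        s = StateSeries(states=np.array(["a", "b"] * 500), frame_interval=1.0)
        # 999 transitions over 0.999 µs
        assert transition_rate(s) == pytest.approx(1000.0)

    def test_state_pair_restriction(self):
        s = StateSeries(states=np.array(["a", "b", "c", "b", "a"]), frame_interval=1000.0)
        # 2 direct a↔b changes over 4 µs
        assert transition_rate(s, state_pair=("a", "b")) == pytest.approx(0.5)
        assert transition_rate(s, state_pair=("a", "c")) == 0.0

    def test_ctmc_estimate_matches_matrix_exponential_oracle(self):
        q = np.array([[-10.0, 8.0, 2.0], [4.0, -5.0, 1.0], [2.0, 3.0, -5.0]])
        dt_ns = 2.0
        model = RotamerCTMC(q_matrix=q, frame_interval=dt_ns)
        pi = stationary_distribution(q)
        P = expm(q * dt_ns / 1000.0)
        expected = float(pi @ (1.0 - np.diag(P))) / (dt_ns / 1000.0)  # per µs
        rates = [transition_rate(simulate_ctmc(model, 50.0, seed=s)) for s in range(12)]
        mean = np.mean(rates)
        sem = np.std(rates, ddof=1) / math.sqrt(len(rates))
        assert abs(mean - expected) < 3 * sem

    def test_discretized_rate_below_true_jump_rate(self):
        q = np.array([[-20.0, 20.0], [20.0, -20.0]])
        model = RotamerCTMC(q_matrix=q, states=("a", "b"), state_angles=(0.0, 1.0),
                            frame_interval=20.0)
        pi = stationary_distribution(q)
        true_rate = float(pi @ -np.diag(q))
        coarse = transition_rate(simulate_ctmc(model, 100.0, seed=1))
        fine_model = RotamerCTMC(q_matrix=q, states=("a", "b"), state_angles=(0.0, 1.0),
                                 frame_interval=1.0)
        fine = transition_rate(simulate_ctmc(fine_model, 100.0, seed=1))
        assert coarse < fine <= true_rate * 1.2
        assert coarse < true_rate


class TestMinDistance:
    def test_member_point_zero(self):
        pts = np.array([[0.0, 0, 0], [1, 1, 1]])
        assert min_distance([1, 1, 1], pts) == 0.0

    def test_unit_offsets(self):
        pts = np.array([[1.0, 0, 0], [2.0, 0, 0]])
        assert min_distance([0, 0, 0], pts) == 1.0

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.standard_normal(3)
            ps = rng.standard_normal((15, 3))
            brute = min(math.dist(p, q) for q in ps)
            assert min_distance(p, ps) == pytest.approx(brute, rel=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            min_distance([0, 0, 0], np.empty((0, 3)))


class TestKabsch:
    def test_identical_frames(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 3))
        R, t, rmsd = kabsch_superpose(X, X)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_superposes_to_zero(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 3))
        R0 = Rotation.random(random_state=2).as_matrix()
        Y = X @ R0.T + np.array([3.0, -1.0, 2.0])
        _, _, rmsd = kabsch_superpose(X, Y)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            X = rng.standard_normal((12, 3))
            Y = rng.standard_normal((12, 3))
            _, _, rmsd = kabsch_superpose(X, Y)
            assert abs(rmsd - quaternion_rmsd(X, Y)) < 1e-9

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_configuration_flagged(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError, match="rank-deficient"):
            kabsch_superpose(line, line)


class TestPairwiseRmsdBootstrap:
    def _two_pose_ensemble(self, n_frames=60, jitter=0.0):
        rng = np.random.default_rng(11)
        anchors = rng.standard_normal((10, 3)) * 4.0
        ligand = rng.standard_normal((6, 3))
        base = np.vstack([anchors, ligand])
        R0 = Rotation.random(random_state=5).as_matrix()
        ens = generate_pose_ensemble(
            base, R0, np.array([0.0, 0.0, 4.0]), p_alt=0.5, jitter_sd=jitter,
            n_frames=n_frames, seed=13, moving_selection=np.arange(10, 16),
        )
        return ens, np.arange(10), np.arange(10, 16)

    def test_identical_frames_all_zero(self):
        rng = np.random.default_rng(9)
        frames = np.repeat(rng.standard_normal((1, 7, 3)), 30, axis=0)
        ens = FrameEnsemble(frames=frames, atom_names=tuple(f"A{i}" for i in range(7)))
        summ = pairwise_rmsd_bootstrap(ens, n_boot=3, sample_size=20, seed=0)
        for m in summ.matrices:
            np.testing.assert_allclose(m, 0.0, atol=1e-12)

    def test_two_pose_values_match_brute_force_oracle(self):
        ens, align, lig = self._two_pose_ensemble()
        summ = pairwise_rmsd_bootstrap(ens, n_boot=2, sample_size=40,
                                       align_selection=align, rmsd_selection=lig, seed=1)
        # brute-force oracle on the two distinct poses
        i = 0
        j = next(k for k in range(ens.n_frames)
                 if not np.allclose(ens.frames[k], ens.frames[0]))
        _, _, d = kabsch_superpose(ens.frames[i], ens.frames[j],
                                   align_selection=align, rmsd_selection=lig)
        for m in summ.matrices:
            vals = np.unique(np.round(m[np.triu_indices(40, k=1)], 9))
            assert vals.size == 2
            assert vals[0] == 0.0
            assert vals[1] == pytest.approx(d, abs=1e-9)

    def test_metric_properties(self):
        ens, align, lig = self._two_pose_ensemble(jitter=0.05)
        summ = pairwise_rmsd_bootstrap(ens, n_boot=2, sample_size=25,
                                       align_selection=align, rmsd_selection=lig, seed=2)
        for m in summ.matrices:
            np.testing.assert_allclose(m, m.T)
            np.testing.assert_allclose(np.diag(m), 0.0, atol=1e-12)
            assert np.all(m >= 0.0)


class TestFilterFrames:
    def test_all_below_threshold_empty(self):
        frames = np.zeros((5, 3, 3))
        assert filter_frames_by_distance(frames, np.full(5, 2.0)).shape[0] == 0

    def test_boundary_excluded_under_strict_greater(self):
        frames = np.zeros((3, 2, 3))
        out = filter_frames_by_distance(frames, np.array([4.5, 4.5001, 10.0]))
        assert out.shape[0] == 2

    def test_subset_size_matches_brute_force(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0.0, 9.0, size=200)
        frames = rng.standard_normal((200, 4, 3))
        out = filter_frames_by_distance(frames, d, threshold=4.5)
        assert out.shape[0] == int(np.sum(d > 4.5))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            filter_frames_by_distance(np.zeros((4, 2, 3)), np.zeros(5))


def test_rotamer_occupancy_pipeline_recovers_stationary_distribution():
    # simulate → emit → assign → bootstrap: occupancies within 3 bootstrap SDs
    q = np.array([[-3.0, 2.0, 1.0], [1.0, -1.5, 0.5], [0.6, 0.9, -1.5]])
    model = RotamerCTMC(q_matrix=q, frame_interval=5.0, angle_sd=15.0)
    pi = stationary_distribution(q)
    series = [simulate_ctmc(model, 40.0, seed=s) for s in range(6)]
    pooled = np.concatenate([
        assign_rotamer(emit_dihedrals(s, model, seed=100 + i))
        for i, s in enumerate(series)
    ])
    cats = list(model.states)
    h = bootstrap_histogram(pooled, bin_edges=cats, n_boot=100, sample_size=5000, seed=7)
    # bootstrap SD understates between-trajectory variation; use a floor
    for i in range(3):
        sd = max(h.sd_freq[i], 0.02)
        assert abs(h.mean_freq[i] - pi[i]) < 3 * sd
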