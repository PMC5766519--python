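import numpy as np
import pytest

from erassay.conformation import (
    ClusterParams,
    assign_helix,
    daura_cluster,
    detect_equilibration,
    kabsch_superpose,
    pairwise_min_rmsd,
    representative_structure,
    rmsd_series,
    rmsf,
)
from erassay.core import CA, Selection
from erassay.synthetic import (
    Conformer,
    HelicityPlant,
    SyntheticSpec,
    generate_trajectory,
)

from conftest import (
    daura_oracle,
    horn_quaternion_rmsd,
    make_ca_topology,
    make_trajectory,
    random_rotation,
)


class TestKabsch:
    def test_identity_on_equal_inputs(self):
        rng = np.random.default_rng(0)
        X = rng.normal(scale=3.0, size=(8, 3))
        R, t, r = kabsch_superpose(X, X)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0.0, atol=1e-10)
        assert r < 1e-12

    def test_recovers_rigid_transform(self):
        rng = np.random.default_rng(1)
        X = rng.normal(scale=3.0, size=(15, 3))
        Rtrue = random_rotation(rng)
        Y = X @ Rtrue.T + np.array([5.0, -2.0, 1.0])
        R, t, r = kabsch_superpose(X, Y)
        assert r < 1e-9
        np.testing.assert_allclose(R, Rtrue, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = rng.integers(4, 20)
            X = rng.normal(scale=2.0, size=(n, 3))
            Y = X + rng.normal(scale=rng.uniform(0.1, 3.0), size=(n, 3))
            _, _, r = kabsch_superpose(X, Y)
            assert r == pytest.approx(horn_quaternion_rmsd(X, Y), abs=1e-9)

    def test_rmsd_of_fit_orthogonal_displacement(self):
        # a unit-norm displacement orthogonal to the 6 rigid-body modes does
        # not move the optimal fit, so RMSD = ||d|| / sqrt(n) = 0.5 for n=4
        rng = np.random.default_rng(3)
        X = rng.normal(scale=2.0, size=(4, 3))
        Xc = X - X.mean(axis=0)
        modes = []
        for ax in range(3):  # translations
            m = np.zeros((4, 3))
            m[:, ax] = 1.0
            modes.append(m.ravel())
        for ax in range(3):  # infinitesimal rotations about the centroid
            e = np.zeros(3)
            e[ax] = 1.0
            modes.append(np.cross(np.broadcast_to(e, (4, 3)), Xc).ravel())
        Q, _ = np.linalg.qr(np.stack(modes, axis=1))
        d = rng.normal(size=12)
        d -= Q @ (Q.T @ d)
        d /= np.linalg.norm(d)
        Y = X + d.reshape(4, 3)
        _, _, r = kabsch_superpose(X, Y)
        assert r == pytest.approx(0.5, abs=0.02)
        assert r == pytest.approx(horn_quaternion_rmsd(X, Y), abs=1e-9)

    def test_symmetry_and_prerotation_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(scale=2.0, size=(10, 3))
        Y = X + rng.normal(scale=1.0, size=(10, 3))
        _, _, r1 = kabsch_superpose(X, Y)
        _, _, r2 = kabsch_superpose(Y, X)
        assert r1 == pytest.approx(r2, abs=1e-10)
        R = random_rotation(rng)
        _, _, r3 = kabsch_superpose(X @ R.T, Y)
        assert r3 == pytest.approx(r1, abs=1e-9)

    def test_collinear_selection_errors(self):
        line = np.stack([[0.0, 0.0, float(i)] for i in range(5)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_superpose(line, line + 1.0)


class TestRmsdSeries:
    def test_static_trajectory_is_zero(self):
        rng = np.random.default_rng(5)
        base = rng.normal(scale=3.0, size=(8, 3))
        traj = make_trajectory(base[None].repeat(5, axis=0))
        series = rmsd_series(traj, base, make_ca_topology(8), CA)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_invariant_to_global_rotation_of_frames(self):
        rng = np.random.default_rng(6)
        base = rng.normal(scale=3.0, size=(8, 3))
        frames = base[None] + rng.normal(scale=0.5, size=(6, 8, 3))
        top = make_ca_topology(8)
        s1 = rmsd_series(make_trajectory(frames), base, top, CA)
        rotated = np.stack([f @ random_rotation(rng).T + 10.0 for f in frames])
        s2 = rmsd_series(make_trajectory(rotated), base, top, CA)
        np.testing.assert_allclose(s1, s2, atol=1e-9)


class TestEquilibration:
    def test_flat_series_starts_immediately(self):
        times = np.arange(50) * 0.1
        assert detect_equilibration(np.ones(50), times) == 0.0

    def test_step_series_detected_at_step(self):
        times = np.arange(100) * 1.0
        series = np.where(np.arange(100) < 40, 0.0, 5.0)
        start = detect_equilibration(series, times, tol=0.5)
        assert start == 40.0

    def test_monotone_drift_never_converges(self):
        times = np.arange(100) * 1.0
        series = np.linspace(0.0, 60.0, 100)
        assert detect_equilibration(series, times, tol=0.5) is None

    def test_too_short_series(self):
        with pytest.raises(ValueError, match="10 frames"):
            detect_equilibration(np.ones(5), np.arange(5.0))


class TestRMSF:
    def test_static_is_zero_and_single_frame_errors(self):
        base = np.random.default_rng(7).normal(size=(6, 3))
        top = make_ca_topology(6)
        traj = make_trajectory(base[None].repeat(3, axis=0))
        np.testing.assert_allclose(rmsf(traj, top, CA).values, 0.0, atol=1e-12)
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(make_trajectory(base[None]), top, CA)

    def test_isotropic_jitter_closed_form(self):
        # sigma per coordinate -> RMSF = sigma * sqrt(3)
        rng = np.random.default_rng(8)
        base = rng.normal(scale=10.0, size=(20, 3))
        coords = base[None] + rng.normal(scale=0.5, size=(5000, 20, 3))
        vals = rmsf(make_trajectory(coords), make_ca_topology(20), CA).values
        assert vals.mean() == pytest.approx(0.5 * np.sqrt(3.0), rel=0.02)

    def test_doubling_sigma_doubles_rmsf(self):
        rng = np.random.default_rng(9)
        base = rng.normal(scale=10.0, size=(10, 3))
        v1 = rmsf(
            make_trajectory(base[None] + rng.normal(scale=0.3, size=(3000, 10, 3))),
            make_ca_topology(10), CA,
        ).values.mean()
        v2 = rmsf(
            make_trajectory(base[None] + rng.normal(scale=0.6, size=(3000, 10, 3))),
            make_ca_topology(10), CA,
        ).values.mean()
        assert v2 / v1 == pytest.approx(2.0, rel=0.05)


class TestDauraClustering:
    def test_identical_frames_single_cluster(self):
        base = np.random.default_rng(10).normal(size=(6, 3))
        traj = make_trajectory(base[None].repeat(7, axis=0))
        result = daura_cluster(traj, make_ca_topology(6))
        assert result.n_clusters == 1
        assert result.populations == (100.0,)
        assert result.centers == (0,)
        assert representative_structure(result, 0) == 0

    def test_matches_exhaustive_oracle_on_random_instances(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(20, 120))
            coords = rng.normal(scale=2.0, size=(n, 6, 3))
            top = make_ca_topology(6)
            cutoff = float(rng.uniform(1.5, 4.0))
            result = daura_cluster(
                make_trajectory(coords), top, ClusterParams(cutoff, CA)
            )
            D = pairwise_min_rmsd(coords)
            a, c, p = daura_oracle(D, cutoff)
            np.testing.assert_array_equal(result.assignment, a)
            assert list(result.centers) == c
            np.testing.assert_allclose(result.populations, p, atol=1e-9)

    def test_planted_mixture_populations(self):
        spec = SyntheticSpec(
            seed=31, n_frames=300, sigma=0.3, ca_only=True,
            conformers=(
                Conformer("major", 0.8),
                Conformer("minor", 0.2,
                          shifts=(("A", 495, 552, (40.0, 0.0, 0.0)),)),
            ),
        )
        top, traj, truth = generate_trajectory(spec)
        sel = Selection.of(chains=["A"], names=["CA"])
        result = daura_cluster(traj, top, ClusterParams(2.75, sel))
        assert result.n_clusters == 2
        assert result.populations[0] == pytest.approx(80.0, abs=3.0)
        assert result.populations[1] == pytest.approx(20.0, abs=3.0)
        # the top-cluster representative belongs to the majority conformer
        center = representative_structure(result, 0)
        assert truth.conformer[center] == "major"

    def test_increasing_cutoff_never_increases_cluster_count(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(scale=2.0, size=(60, 6, 3))
        traj = make_trajectory(coords)
        top = make_ca_topology(6)
        counts = [
            daura_cluster(traj, top, ClusterParams(c, CA)).n_clusters
            for c in (1.0, 2.0, 3.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_rank_out_of_range(self):
        base = np.random.default_rng(12).normal(size=(6, 3))
        result = daura_cluster(
            make_trajectory(base[None].repeat(3, axis=0)), make_ca_topology(6)
        )
        with pytest.raises(IndexError, match="out of range"):
            representative_structure(result, 5)


class TestHelixAssignment:
    def test_ideal_helix_is_fully_helical(self):
        top, traj, _ = generate_trajectory(
            SyntheticSpec(seed=41, n_frames=3, sigma=0.0)
        )
        ha = assign_helix(traj, top)
        assert ha.segment_content("A", 310, 545) == pytest.approx(100.0)
        assert ha.segment_content("B", 310, 545) == pytest.approx(100.0)

    def test_extended_segment_has_zero_content(self):
        spec = SyntheticSpec(
            seed=42, n_frames=3, sigma=0.0,
            helicity_plants=(HelicityPlant("seg", "A", 527, 540, 0.0),),
        )
        top, traj, _ = generate_trajectory(spec)
        ha = assign_helix(traj, top)
        assert ha.segment_content("A", 527, 540) == pytest.approx(0.0)
        # untouched monomer stays helical
        assert ha.segment_content("B", 527, 540) == pytest.approx(100.0)

    def test_planted_fraction_recovered_exactly(self):
        spec = SyntheticSpec(
            seed=43, n_frames=1000, sigma=0.5,
            helicity_plants=(HelicityPlant("seg", "A", 527, 540, 0.6),),
        )
        top, traj, truth = generate_trajectory(spec)
        ha = assign_helix(traj, top)
        content = ha.segment_content("A", 527, 540)
        assert content == pytest.approx(100.0 * truth.helical["seg"].mean(),
                                        abs=1e-9)
        assert abs(content - 60.0) <= 100 * 2.576 * np.sqrt(0.6 * 0.4 / 1000)

    def test_missing_backbone_atoms_error(self):
        top = make_ca_topology(10)
        traj = make_trajectory(np.zeros((2, 10, 3)) + np.arange(10)[None, :, None])
        with pytest.raises(ValueError, match="missing backbone"):
            assign_helix(traj, top)

    def test_per_residue_content_bounds(self):
        spec = SyntheticSpec(
            seed=44, n_frames=50, sigma=0.5,
            helicity_plants=(HelicityPlant("seg", "A", 527, 540, 0.5),),
        )
        top, traj, _ = generate_trajectory(spec)
        content = assign_helix(traj, top).content
        assert (content.values >= 0).all() and (content.values <= 100).all()
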