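import numpy as np
import pytest

from erassay.core import Selection, Topology
from erassay.interactions import (
    HBondParams,
    InteractionSpec,
    MissingHydrogenError,
    contact_persistence,
    detect_hbond_frame,
    persistence,
    pi_stacking,
    signature_panel,
)
from erassay.synthetic import (
    HBondPlant,
    SyntheticSpec,
    generate_trajectory,
)

from conftest import make_trajectory, random_rotation


def triplet_topology():
    """Donor N, its H, and an acceptor O as a free-standing 3-atom system."""
    return Topology(
        atom_name=np.array(["N", "H", "O"], dtype="U6"),
        element=np.array(["N", "H", "O"], dtype="U2"),
        residue_number=np.array([303, 303, 304]),
        residue_name=np.array(["ALA", "ALA", "ALA"], dtype="U5"),
        chain_id=np.array(["A", "A", "A"], dtype="U4"),
    )


def triplet_frame(d: float, angle_dha: float) -> np.ndarray:
    """D at origin, H at 1 Å along x, A at distance d from D such that the
    D-H...A angle (at H) equals angle_dha degrees."""
    D = np.zeros(3)
    H = np.array([1.0, 0.0, 0.0])
    # place A in the xy-plane: direction from H at angle (180 - angle) from H->D
    theta = np.deg2rad(180.0 - angle_dha)
    u = np.array([1.0, 0.0, 0.0])  # H -> away from D
    w = np.array([np.cos(theta), np.sin(theta), 0.0])
    # solve |D - (H + r w)| = d for r > 0
    b = 2.0 * np.dot(H - D, w)
    c = np.dot(H - D, H - D) - d**2
    r = (-b + np.sqrt(b * b - 4 * c)) / 2.0
    A = H + r * w
    assert np.isclose(np.linalg.norm(A - D), d)
    v1, v2 = D - H, A - H
    got = np.degrees(
        np.arccos(np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2))
    )
    assert np.isclose(got, angle_dha, atol=1e-6)
    return np.stack([D, H, A])


HB_SPEC = InteractionSpec(
    kind="hbond",
    label="test",
    donor=Selection.of(names=["N"]),
    hydrogen=Selection.of(names=["H"]),
    acceptor=Selection.of(names=["O"]),
)


class TestHBondRule:
    @pytest.mark.parametrize(
        "d,angle,expected",
        [
            (2.9, 175.0, True),    # comfortably within both cutoffs
            (3.4, 180.0, False),   # distance fails even when perfectly linear
            (3.0, 140.0, False),   # 40 deg deviation exceeds the 35 deg limit
            (3.3, 145.0, True),    # both cutoffs inclusive at the boundary
        ],
    )
    def test_hand_evaluable_geometries(self, d, angle, expected):
        frame = triplet_frame(d, angle)
        assert detect_hbond_frame(frame, triplet_topology(), HB_SPEC) is expected

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(12)
        top = triplet_topology()
        for d, angle in [(2.9, 175.0), (3.0, 150.0), (3.2, 140.0)]:
            frame = triplet_frame(d, angle)
            ref = detect_hbond_frame(frame, top, HB_SPEC)
            for _ in range(5):
                R = random_rotation(rng)
                moved = frame @ R.T + rng.normal(scale=50.0, size=3)
                assert detect_hbond_frame(moved, top, HB_SPEC) is ref

    def test_tightening_cutoffs_never_adds_bonds(self):
        top = triplet_topology()
        frame = triplet_frame(3.1, 150.0)
        loose = HBondParams(d_max=3.3, theta_max=35.0)
        tight_d = HBondParams(d_max=3.0, theta_max=35.0)
        tight_a = HBondParams(d_max=3.3, theta_max=25.0)
        assert detect_hbond_frame(frame, top, HB_SPEC, loose)
        assert not detect_hbond_frame(frame, top, HB_SPEC, tight_d)
        assert not detect_hbond_frame(frame, top, HB_SPEC, tight_a)

    def test_missing_hydrogen_suggests_distance_only(self):
        top = triplet_topology()
        spec = InteractionSpec(
            kind="hbond", label="noH",
            donor=Selection.of(names=["N"]),
            hydrogen=Selection.of(names=["HX"]),
            acceptor=Selection.of(names=["O"]),
        )
        frame = triplet_frame(2.9, 175.0)
        with pytest.raises(MissingHydrogenError, match="distance_only"):
            detect_hbond_frame(frame, top, spec)
        assert detect_hbond_frame(
            frame, top, spec, HBondParams(distance_only=True)
        )


class TestPersistence:
    def test_planted_occupancy_recovered(self):
        plant = HBondPlant(
            "hb", ("A", 377, "NE2"), ("A", 377, "HE2"), ("A", 380, "OE1"), 0.7
        )
        top, traj, truth = generate_trajectory(
            SyntheticSpec(seed=3, n_frames=1000, hbond_plants=(plant,))
        )
        spec = InteractionSpec(
            kind="hbond", label="hb",
            donor=Selection.of(chains=["A"], residues=[377], names=["NE2"]),
            hydrogen=Selection.of(chains=["A"], residues=[377], names=["HE2"]),
            acceptor=Selection.of(chains=["A"], residues=[380], names=["OE1"]),
        )
        series = persistence(traj, top, spec)
        # detection reproduces the generator's latent states exactly...
        np.testing.assert_array_equal(series.present,
                                      truth.hbond_formed["hb"])
        # ...and the estimate sits inside the 99% binomial CI of p=0.7
        assert abs(series.persistence - 70.0) <= 100 * 2.576 * np.sqrt(
            0.7 * 0.3 / 1000
        )

    @pytest.mark.parametrize("occupancy,expected", [(0.0, 0.0), (1.0, 100.0)])
    def test_never_and_always_formed(self, occupancy, expected):
        plant = HBondPlant(
            "hb", ("A", 377, "NE2"), ("A", 377, "HE2"), ("A", 380, "OE1"), occupancy
        )
        top, traj, _ = generate_trajectory(
            SyntheticSpec(seed=5, n_frames=200, hbond_plants=(plant,))
        )
        spec = InteractionSpec(
            kind="hbond", label="hb",
            donor=Selection.of(chains=["A"], residues=[377], names=["NE2"]),
            hydrogen=Selection.of(chains=["A"], residues=[377], names=["HE2"]),
            acceptor=Selection.of(chains=["A"], residues=[380], names=["OE1"]),
        )
        assert persistence(traj, top, spec).persistence == expected

    def test_window_additivity(self):
        plant = HBondPlant(
            "hb", ("A", 377, "NE2"), ("A", 377, "HE2"), ("A", 380, "OE1"), 0.5
        )
        top, traj, _ = generate_trajectory(
            SyntheticSpec(seed=8, n_frames=300, hbond_plants=(plant,))
        )
        spec = InteractionSpec(
            kind="hbond", label="hb",
            donor=Selection.of(chains=["A"], residues=[377], names=["NE2"]),
            hydrogen=Selection.of(chains=["A"], residues=[377], names=["HE2"]),
            acceptor=Selection.of(chains=["A"], residues=[380], names=["OE1"]),
        )
        full = persistence(traj, top, spec)
        w1 = persistence(traj, top, spec, window=slice(0, 120))
        w2 = persistence(traj, top, spec, window=slice(120, 300))
        combined = (120 * w1.persistence + 180 * w2.persistence) / 300
        assert full.persistence == pytest.approx(combined, abs=1e-9)

    def test_empty_window_errors(self):
        top, traj, _ = generate_trajectory(SyntheticSpec(seed=8, n_frames=10))
        spec = InteractionSpec(
            kind="hbond", label="hb",
            donor=Selection.of(names=["N"]),
            hydrogen=Selection.of(names=["H"]),
            acceptor=Selection.of(names=["O"]),
        )
        with pytest.raises(ValueError, match="empty"):
            persistence(traj, top, spec, window=slice(10, 10))


class TestContacts:
    def two_group_topology(self):
        return Topology(
            atom_name=np.array(["CZ2", "CZ3", "CD1", "CD2"], dtype="U6"),
            element=np.array(["C"] * 4, dtype="U2"),
            residue_number=np.array([383, 383, 536, 536]),
            residue_name=np.array(["TRP", "TRP", "LEU", "LEU"], dtype="U5"),
            chain_id=np.array(["A"] * 4, dtype="U4"),
        )

    def test_near_and_far_groups(self):
        top = self.two_group_topology()
        ga = Selection.of(residues=[383])
        gb = Selection.of(residues=[536])
        near = np.array([[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0], [4.5, 0, 0.0]])
        far = near.copy()
        far[2:] += np.array([10.0, 0, 0])
        traj = make_trajectory(np.stack([near, far]))
        series = contact_persistence(traj, top, ga, gb)
        np.testing.assert_array_equal(series.present, [True, False])
        assert series.persistence == 50.0

    def test_planted_approach_fraction(self):
        # reuse the H-bond plant: formed frames put the acceptor <=3.1 A from
        # the donor, unformed frames park it >=4.8 A, so a 4.5 A contact rule
        # recovers the planted 50% exactly
        plant = HBondPlant(
            "approach", ("A", 377, "NE2"), ("A", 377, "HE2"), ("A", 380, "OE1"), 0.5
        )
        top, traj, truth = generate_trajectory(
            SyntheticSpec(seed=17, n_frames=400, hbond_plants=(plant,))
        )
        series = contact_persistence(
            traj, top,
            Selection.of(chains=["A"], residues=[377], names=["NE2"]),
            Selection.of(chains=["A"], residues=[380], names=["OE1"]),
        )
        np.testing.assert_array_equal(series.present, truth.hbond_formed["approach"])
        assert abs(series.persistence / 100 - 0.5) <= 2.576 * np.sqrt(0.25 / 400)


def ring(center, normal, radius=1.4, n=6):
    normal = np.asarray(normal, float)
    normal /= np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal[0]) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    pts = [
        center + radius * (np.cos(t) * u + np.sin(t) * v)
        for t in np.linspace(0, 2 * np.pi, n, endpoint=False)
    ]
    return np.array(pts)


class TestPiStacking:
    def ring_topology(self):
        return Topology(
            atom_name=np.array([f"C{i}" for i in range(6)] * 2, dtype="U6"),
            element=np.array(["C"] * 12, dtype="U2"),
            residue_number=np.array([377] * 6 + [537] * 6),
            residue_name=np.array(["HIS"] * 6 + ["TYR"] * 6, dtype="U5"),
            chain_id=np.array(["A"] * 12, dtype="U4"),
        )

    def series(self, frame, **kw):
        top = self.ring_topology()
        traj = make_trajectory(frame[None])
        return pi_stacking(
            traj, top,
            Selection.of(residues=[537]), Selection.of(residues=[377]), **kw
        )

    def test_parallel_rings_stack(self):
        frame = np.vstack(
            [ring([0, 0, 0], [0, 0, 1]), ring([0, 0, 3.8], [0, 0, 1])]
        )
        assert self.series(frame).present[0]

    def test_perpendicular_rings_do_not(self):
        frame = np.vstack(
            [ring([0, 0, 0], [0, 0, 1]), ring([0, 0, 3.8], [1, 0, 0])]
        )
        assert not self.series(frame).present[0]

    @pytest.mark.parametrize("dz,expected", [(4.9, True), (5.1, False)])
    def test_centroid_distance_boundary_at_25_degrees(self, dz, expected):
        tilt = np.array([np.sin(np.deg2rad(25.0)), 0.0, np.cos(np.deg2rad(25.0))])
        frame = np.vstack([ring([0, 0, 0], [0, 0, 1]), ring([0, 0, dz], tilt)])
        assert bool(self.series(frame).present[0]) is expected

    def test_collinear_ring_is_an_error(self):
        line = np.stack([np.array([0, 0, float(i)]) for i in range(6)])
        frame = np.vstack([line, ring([0, 0, 10], [0, 0, 1])])
        with pytest.raises(ValueError, match="collinear"):
            self.series(frame)


class TestSignaturePanel:
    def test_wild_type_panel_with_planted_e380_h377(self):
        plant = HBondPlant(
            "E380-H377", ("A", 377, "NE2"), ("A", 377, "HE2"),
            ("A", 380, "OE1"), 0.9
        )
        top, traj, _ = generate_trajectory(
            SyntheticSpec(seed=23, n_frames=300, sigma=0.3, hbond_plants=(plant,))
        )
        panel = signature_panel(top, traj, isoform="WT", ligand="END")
        panel = panel.set_index(["chain", "label"])
        row = panel.loc[("A", "E380-H377")]
        assert row["applicable"]
        assert row["persistence_pct"] == pytest.approx(90.0, abs=4.0)
        # serine-537 signature is not applicable in the wild type
        assert not panel.loc[("A", "D351-S537")]["applicable"]
        # ligand salt bridges have no ligand atoms in an apo-style topology
        assert not panel.loc[("A", "LIG-K529")]["applicable"]

    def test_y537s_panel_exposes_serine_signature(self):
        top, traj, _ = generate_trajectory(
            SyntheticSpec(seed=24, n_frames=50, sigma=0.3, variant="Y537S")
        )
        panel = signature_panel(top, traj, isoform="Y537S", ligand="AZD-9496")
        panel = panel.set_index(["chain", "label"])
        assert panel.loc[("A", "D351-S537")]["applicable"]
        assert panel.loc[("B", "D351-S537")]["applicable"]
        # tyrosine ring is gone in Y537S, so stacking is n/a
        assert not panel.loc[("A", "Y537-H377")]["applicable"]

    def test_panel_rows_per_monomer(self):
        top, traj, _ = generate_trajectory(
            SyntheticSpec(seed=25, n_frames=20, sigma=0.3)
        )
        panel = signature_panel(top, traj)
        assert set(panel["chain"]) == {"A", "B"}
        a_rows = panel[panel["chain"] == "A"]
        assert len(a_rows) == len(panel) / 2
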