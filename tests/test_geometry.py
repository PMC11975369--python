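"""Triads, triad angles, CDR3 distance, BOC and hinge angles."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

import tcrchassis as tc
from tcrchassis.geometry import angle_at, assign_triad, reference_triad
from tcrchassis.system import ATOM_COLUMNS, MolecularSystem, SelectionSpec


@pytest.fixture
def core():
    rng = np.random.default_rng(0)
    base = np.array([[x, y, z] for z in (-6.0, -2, 2, 6) for y in (-4.0, 0, 4) for x in (-2.0, 2)])
    return base + rng.normal(0, 0.3, base.shape) + np.array([5.0, -3.0, 12.0])


class TestAssignTriad:
    def test_reference_frame_returns_reference_triad(self, core):
        ref = reference_triad(core)
        out = assign_triad(core, core, ref)
        np.testing.assert_allclose(out.arms, ref.arms, atol=1e-12)
        np.testing.assert_allclose(out.origin, ref.origin, atol=1e-12)

    def test_rotation_about_e2_carries_arms_exactly(self, core):
        ref = reference_triad(core)
        R = Rotation.from_rotvec(np.radians(25.0) * ref.e2).as_matrix()
        cur = (core - ref.origin) @ R.T + ref.origin
        out = assign_triad(cur, core, ref)
        np.testing.assert_allclose(out.arms, ref.arms @ R.T, atol=1e-9)
        ang = tc.triad_angles(ref, out)
        # arccos conditioning near zero bounds the attainable precision
        assert ang.e2 == pytest.approx(0.0, abs=1e-5)
        assert ang.e1 == pytest.approx(25.0, abs=1e-7)
        assert ang.e3 == pytest.approx(25.0, abs=1e-7)

    def test_translation_moves_origin_only(self, core):
        ref = reference_triad(core)
        out = assign_triad(core + np.array([3.0, 4.0, -1.0]), core, ref)
        np.testing.assert_allclose(out.arms, ref.arms, atol=1e-9)
        np.testing.assert_allclose(out.origin, ref.origin + [3.0, 4.0, -1.0], atol=1e-9)

    def test_unfolding_core_warns(self, core):
        rng = np.random.default_rng(1)
        scrambled = core + rng.normal(0, 4.0, core.shape)
        ref = reference_triad(core)
        with pytest.warns(UserWarning, match="unfolding"):
            assign_triad(scrambled, core, ref)

    def test_orthonormality_drift_over_noisy_frames(self, core):
        """Arms stay orthonormal to 1e-8 over thousands of noisy
        reassignments (each frame re-derives the rotation, so errors do
        not accumulate)."""
        rng = np.random.default_rng(2)
        ref = reference_triad(core)
        worst = 0.0
        for _ in range(2000):
            cur = core + rng.normal(0, 0.5, core.shape)
            out = assign_triad(cur, core, ref)
            G = out.arms @ out.arms.T
            worst = max(worst, float(np.abs(G - np.eye(3)).max()))
        assert worst < 1e-8


class TestTriadAngles:
    def test_identical_triads_zero(self, core):
        ref = reference_triad(core)
        ang = tc.triad_angles(ref, ref)
        # zero-angle precision is limited by arccos conditioning at 1
        assert ang.as_array() == pytest.approx([0.0, 0.0, 0.0], abs=1e-5)

    def test_30deg_about_shared_e3(self, core):
        ref = reference_triad(core)
        R = Rotation.from_rotvec(np.radians(30.0) * ref.e3).as_matrix()
        other = ref.rotated(R)
        ang = tc.triad_angles(ref, other)
        assert ang.e1 == pytest.approx(30.0, abs=1e-9)
        assert ang.e2 == pytest.approx(30.0, abs=1e-9)
        assert ang.e3 == pytest.approx(0.0, abs=1e-5)

    def test_random_rotations_match_acos_dot_oracle(self, core):
        ref = reference_triad(core)
        rng = np.random.default_rng(3)
        for _ in range(50):
            R = Rotation.random(random_state=rng).as_matrix()
            other = ref.rotated(R)
            ang = tc.triad_angles(ref, other).as_array()
            oracle = [
                np.degrees(np.arccos(np.clip(np.dot(ref.arms[i], other.arms[i]), -1, 1)))
                for i in range(3)
            ]
            np.testing.assert_allclose(ang, oracle, atol=1e-10)

    def test_symmetric_and_rigid_motion_invariant(self, core):
        ref = reference_triad(core)
        rng = np.random.default_rng(4)
        Rrel = Rotation.random(random_state=rng).as_matrix()
        other = ref.rotated(Rrel)
        a1 = tc.triad_angles(ref, other).as_array()
        a2 = tc.triad_angles(other, ref).as_array()
        np.testing.assert_allclose(a1, a2, atol=1e-12)
        Rg = Rotation.random(random_state=rng).as_matrix()
        np.testing.assert_allclose(
            tc.triad_angles(ref.rotated(Rg), other.rotated(Rg)).as_array(), a1, atol=1e-9
        )

    def test_non_unit_arm_rejected(self, core):
        ref = reference_triad(core)
        bad = tc.Triad(ref.origin, ref.arms.copy())
        bad.arms = bad.arms * 1.1  # bypass constructor check
        with pytest.raises(ValueError, match="unit"):
            tc.triad_angles(ref, bad)


def _ca_system(points):
    """Chain-labelled CA-only system from {(chain, resseq): xyz}."""
    rows, coords = [], []
    for aid, ((chain, resseq), p) in enumerate(sorted(points.items())):
        rows.append((aid, "CA", "C", "GLY", resseq, "", chain))
        coords.append(p)
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    return MolecularSystem(atoms, np.asarray(coords, float)[None], np.array([0.0]))


class TestCdr3Distance:
    def test_coincident_midpoints_zero(self):
        s = _ca_system({
            ("A", 1): [1.0, 0, 0], ("A", 2): [-1.0, 0, 0],
            ("B", 1): [0.0, 1, 0], ("B", 2): [0.0, -1, 0],
        })
        d = tc.cdr3_distance(
            s,
            SelectionSpec("a", "A", (1, 2), "CA"),
            SelectionSpec("b", "B", (1, 2), "CA"),
        )
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_constructed_12A_separation(self):
        s = _ca_system({
            ("A", 1): [0.0, 2, 0], ("A", 2): [0.0, -2, 0],
            ("B", 1): [12.0, 3, 0], ("B", 2): [12.0, -3, 0],
        })
        d = tc.cdr3_distance(
            s,
            SelectionSpec("a", "A", (1, 2), "CA"),
            SelectionSpec("b", "B", (1, 2), "CA"),
        )
        assert d[0] == pytest.approx(12.0, abs=1e-12)

    def test_missing_residue_named_in_error(self, toy, selections):
        bad = SelectionSpec("cdr3_alpha", "A", (25, 999), "CA")
        with pytest.raises(ValueError, match="999"):
            tc.cdr3_distance(toy, bad, selections["cdr3_beta"])


class TestBoc:
    def test_beads_at_hand_computed_centroids(self):
        pts = {}
        for i, (chain, r0) in enumerate((("A", 1), ("A", 10), ("A", 20), ("B", 1), ("B", 10), ("B", 20))):
            for k in range(3):
                pts[(chain, r0 + k)] = np.array([i * 10.0, k * 3.0, 0.0])
        s = _ca_system(pts)
        sel = {
            "Valpha": SelectionSpec("Valpha", "A", ((1, 3),), "CA"),
            "Halpha": SelectionSpec("Halpha", "A", ((10, 12),), "CA"),
            "Calpha": SelectionSpec("Calpha", "A", ((20, 22),), "CA"),
            "Vbeta": SelectionSpec("Vbeta", "B", ((1, 3),), "CA"),
            "Hbeta": SelectionSpec("Hbeta", "B", ((10, 12),), "CA"),
            "Cbeta": SelectionSpec("Cbeta", "B", ((20, 22),), "CA"),
        }
        boc = tc.build_boc(s, sel)
        np.testing.assert_allclose(boc.beads["Valpha"][0], [0.0, 3.0, 0.0])
        np.testing.assert_allclose(boc.beads["Cbeta"][0], [50.0, 3.0, 0.0])
        np.testing.assert_allclose(
            boc.beads["Cmodule"][0], 0.5 * (boc.beads["Calpha"][0] + boc.beads["Cbeta"][0])
        )
        assert set(boc.beads) == {"Valpha", "Halpha", "Calpha", "Vbeta", "Hbeta", "Cbeta", "Cmodule"}

    def test_rigid_rotation_preserves_inter_bead_distances(self, toy, selections):
        R = Rotation.from_euler("xyz", [15, 25, -40], degrees=True).as_matrix()
        moved = toy.frames[0] @ R.T + 5.0
        s = toy.with_frames(np.stack([toy.frames[0], moved]), np.array([0.0, 0.02]))
        boc = tc.build_boc(s, selections)
        for la in boc.beads:
            for lb in boc.beads:
                d0 = np.linalg.norm(boc.beads[la][0] - boc.beads[lb][0])
                d1 = np.linalg.norm(boc.beads[la][1] - boc.beads[lb][1])
                assert d1 == pytest.approx(d0, abs=1e-9)

    def test_missing_hinge_selection_rejected(self, toy, selections):
        partial = {k: v for k, v in selections.items() if k != "Hbeta" and isinstance(v, SelectionSpec)}
        with pytest.raises(ValueError, match="Hbeta"):
            tc.build_boc(toy, partial)


class TestHingeAngles:
    def test_collinear_chain_is_180(self):
        v = np.array([[0.0, 0, 10]])
        h = np.array([[0.0, 0, 0]])
        c = np.array([[0.0, 0, -10]])
        assert angle_at(h, v, c)[0] == pytest.approx(180.0)

    def test_right_angle_construction(self):
        assert angle_at(np.zeros(3), np.array([5.0, 0, 0]), np.array([0.0, 7, 0])) == pytest.approx(90.0)

    def test_zero_length_limb_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            angle_at(np.zeros(3), np.zeros(3), np.array([1.0, 0, 0]))

    def test_two_state_histogram_modes_within_2_degrees(self, selections, sim_two_state_hinge):
        """The 140°/165° two-state bending prescription reappears as a
        bimodal hinge-angle histogram with modes within 2° (1° bins)."""
        system, truth = sim_two_state_hinge
        ha = tc.hinge_angles(tc.build_boc(system, selections))
        for series in (ha.tcr_alpha, ha.tcr_beta):
            counts, edges = np.histogram(series, bins=np.arange(120.0, 181.0, 1.0))
            centers = 0.5 * (edges[:-1] + edges[1:])
            lo_mode = centers[np.argmax(counts * (centers < 152.5))]
            hi_mode = centers[np.argmax(counts * (centers >= 152.5))]
            assert lo_mode == pytest.approx(140.0, abs=2.0)
            assert hi_mode == pytest.approx(165.0, abs=2.0)


class TestCouplingProperties:
    def test_scissoring_reciprocity_opposite_slopes(self, selections, triad_pair, sim_scissor):
        """On the scissoring fixture ∠e2 and ∠e3 regress against CDR3
        distance with opposite-signed slopes."""
        system, truth = sim_scissor
        ta, tb = triad_pair(system)
        ang = tc.triad_angle_series(ta, tb)
        d = tc.cdr3_distance(system, selections["cdr3_alpha"], selections["cdr3_beta"])
        slope_e2 = np.polyfit(d, ang[:, 1], 1)[0]
        slope_e3 = np.polyfit(d, ang[:, 2], 1)[0]
        assert slope_e2 * slope_e3 < 0
        assert abs(slope_e2) > 1.0 and abs(slope_e3) > 1.0

    def test_cdr3_vs_hinge_prescribed_slope_within_10pct(self, spec, selections):
        """With a prescribed linear CDR3–hinge coupling (0.1 Å/deg) on a
        two-state hinge trajectory, regression recovers the slope."""
        hinge = tc.MotionProcess(kind="two_state", state_means=(140.0, 165.0),
                                 dwell_ns=(1.5, 1.5), seed=8)
        system, truth = tc.simulate_trajectory(
            spec, hinge=hinge, cdr3_hinge_coupling=0.1, noise_sigma=0.1,
            n_frames=2000, seed=77,
        )
        ha = tc.hinge_angles(tc.build_boc(system, selections))
        d = tc.cdr3_distance(system, selections["cdr3_alpha"], selections["cdr3_beta"])
        slope = np.polyfit(ha.tcr_alpha, d, 1)[0]
        assert slope == pytest.approx(0.1, rel=0.10)
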