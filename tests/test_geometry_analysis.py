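import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kirgate.geometry_analysis import (
    ctd_rotation, geometry_report, kink_angle, per_residue_rmsd,
    pore_radius_profile,
)
from kirgate.io_structures import Ensemble, Structure
from kirgate.synthetic_data import SyntheticParams, make_channel, make_ensemble


def ca_chain(points, start_res=46):
    n = len(points)
    return Structure(["CA"] * n, ["C"] * n,
                     range(start_res, start_res + n), ["ALA"] * n,
                     ["A"] * n, points)


def bent_trace(angle_deg, n1=11, n2=24, rise=1.5):
    """CA trace straight to residue 56, then bent by the given angle."""
    u1 = np.array([0.0, 0.0, 1.0])
    u2 = Rotation.from_rotvec(
        np.deg2rad(angle_deg) * np.array([1.0, 0.0, 0.0])).apply(u1)
    pts = [rise * k * u1 for k in range(n1)]
    pts += [pts[-1] + rise * k * u2 for k in range(1, n2 + 1)]
    return ca_chain(np.array(pts))


class TestKinkAngle:
    def test_collinear_trace_is_straight(self):
        assert kink_angle(bent_trace(0.0), "A") == pytest.approx(0.0,
                                                                 abs=1e-6)

    def test_right_angle_bend(self):
        assert kink_angle(bent_trace(90.0), "A") == pytest.approx(90.0,
                                                                  abs=1e-6)

    def test_generator_roundtrip_13_degrees(self, spec):
        s = make_channel(SyntheticParams(kink_angle_deg=13.0), spec)
        for c in "ABCD":
            assert kink_angle(s, c) == pytest.approx(13.0, abs=2.0)

    def test_endpoint_method_agrees_on_straight_segments(self):
        t = bent_trace(25.0)
        assert kink_angle(t, "A", method="endpoint") == pytest.approx(
            kink_angle(t, "A", method="principal"), abs=1e-6)

    def test_isometry_invariance(self, rng):
        t = bent_trace(37.0)
        rot = Rotation.random(random_state=7)
        moved = t.with_coords(rot.apply(t.coords) + np.array([3.0, -8.0, 5.0]))
        assert kink_angle(moved, "A") == pytest.approx(
            kink_angle(t, "A"), abs=1e-6)

    def test_missing_residues_rejected(self):
        t = ca_chain(np.random.default_rng(0).uniform(0, 5, (5, 3)),
                     start_res=100)
        with pytest.raises(Exception):
            kink_angle(t, "A")


def two_point_chain(p108, p266):
    return Structure(["CA", "CA"], ["C", "C"], [108, 266],
                     ["LEU", "ILE"], ["A", "A"], [p108, p266])


class TestCtdRotation:
    def test_same_half_plane_is_zero(self):
        s = two_point_chain([5, 0, -10], [7, 0, -40])
        assert ctd_rotation(s, "A") == pytest.approx(0.0, abs=1e-9)

    def test_quarter_turn_right_hand_rule(self):
        s0 = two_point_chain([5, 0, -10], [5, 0, -40])
        base = ctd_rotation(s0, "A")
        rotated = two_point_chain([5, 0, -10], [0, 5, -40])
        assert ctd_rotation(rotated, "A") - base == pytest.approx(90.0,
                                                                  abs=1e-9)

    def test_point_on_axis_rejected(self):
        s = two_point_chain([5, 0, -10], [0, 0, -40])
        with pytest.raises(ValueError, match="axis"):
            ctd_rotation(s, "A")

    def test_generator_roundtrip_33_degrees(self, spec):
        base = make_channel(SyntheticParams(), spec)
        turned = make_channel(SyntheticParams(ctd_rotation_deg=33.0), spec)
        for c in "ABCD":
            diff = ctd_rotation(turned, c) - ctd_rotation(base, c)
            assert diff == pytest.approx(33.0, abs=0.5)

    def test_equivariance_under_ctd_rotation(self, open_channel):
        """Rotating the CTD atoms by θ shifts the dihedral by exactly θ."""
        theta = 21.0
        coords = open_channel.coords.copy()
        ctd = open_channel.res_ids >= 134
        rot = Rotation.from_rotvec([0, 0, np.deg2rad(theta)])
        coords[ctd] = rot.apply(coords[ctd])
        moved = open_channel.with_coords(coords)
        for c in "ABCD":
            diff = ctd_rotation(moved, c) - ctd_rotation(open_channel, c)
            assert diff == pytest.approx(theta, abs=1e-6)

    def test_invariance_under_global_z_rotation(self, open_channel):
        rot = Rotation.from_rotvec([0, 0, np.deg2rad(50.0)])
        moved = open_channel.with_coords(rot.apply(open_channel.coords))
        for c in "AB":
            assert ctd_rotation(moved, c) == pytest.approx(
                ctd_rotation(open_channel, c), abs=1e-6)


class TestPerResidueRmsd:
    def test_copies_of_reference_are_zero(self, open_channel):
        ens = Ensemble(open_channel,
                       np.repeat(open_channel.coords[None], 4, axis=0))
        df = per_residue_rmsd(ens, open_channel)
        assert df["rmsd"].max() == 0.0

    def test_symmetric_oscillation_closed_form(self):
        ref = Structure(["X"], ["C"], [1], ["ALA"], ["A"], [[0, 0, 0]])
        a = 0.7
        coords = np.array([[[a, 0, 0]], [[-a, 0, 0]]])
        df = per_residue_rmsd(Ensemble(ref, coords), ref)
        assert df["rmsd"].iloc[0] == pytest.approx(a, rel=1e-12)

    def test_matches_brute_force_formula(self, spec, rng):
        ens = make_ensemble(SyntheticParams(n_frames=10, seed=31), spec)
        ref = ens.frame(0)
        df = per_residue_rmsd(ens, ref).set_index(["chain", "residue"])
        # independent evaluation with explicit loops on a residue sample
        topo = ens.topology
        for chain, resid in [("A", 124), ("B", 56), ("D", 266)]:
            mask = (topo.chain_ids == chain) & (topo.res_ids == resid)
            idx = np.where(mask)[0]
            per_atom = []
            for i in idx:
                acc = 0.0
                for n in range(ens.n_frames):
                    acc += float(np.sum(
                        (ens.coords[n, i] - ref.coords[i]) ** 2))
                per_atom.append(np.sqrt(acc / ens.n_frames))
            expected = float(np.mean(per_atom))
            assert df.loc[(chain, resid), "rmsd"] == pytest.approx(
                expected, rel=1e-12)

    def test_translation_of_all_frames_and_reference_invariant(self, spec):
        ens = make_ensemble(SyntheticParams(n_frames=5, seed=33), spec)
        ref = ens.frame(0)
        shift = np.array([4.0, -2.0, 9.0])
        moved = Ensemble(ens.topology, ens.coords + shift)
        ref2 = ref.with_coords(ref.coords + shift)
        a = per_residue_rmsd(ens, ref)["rmsd"]
        b = per_residue_rmsd(moved, ref2)["rmsd"]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_topology_mismatch_rejected(self, open_channel, reduced_channel):
        ens = Ensemble(reduced_channel, reduced_channel.coords[None])
        with pytest.raises(ValueError):
            per_residue_rmsd(ens, open_channel)


class TestPoreProfile:
    def test_four_atoms_ring(self):
        coords = [[5, 0, 0], [0, 5, 0], [-5, 0, 0], [0, -5, 0]]
        s = Structure(["X"] * 4, ["C"] * 4, [1, 1, 1, 1], ["ALA"] * 4,
                      ["A"] * 4, coords)
        df = pore_radius_profile(s, z_min=-0.5, z_max=0.5, slab_width=1.0,
                                 atom_radius=1.0)
        assert len(df) == 1
        assert df["radius"].iloc[0] == pytest.approx(4.0)

    def test_minimum_at_closed_gate_z(self, spec, params):
        from kirgate.gating_analysis import GatingState
        s = make_channel(params, spec, state=GatingState.GATE129_CLOSED)
        df = pore_radius_profile(s, slab_width=1.0,
                                 atom_radius=params.pseudo_atom_radius)
        gate_atoms = (s.res_ids == 129) & (s.atom_names == "SC")
        z_gate = s.coords[gate_atoms, 2].mean()
        z_at_min = df.loc[df["radius"].idxmin(), "z"]
        assert abs(z_at_min - z_gate) <= 1.0

    def test_invariant_under_rotation_about_z(self, open_channel):
        rot = Rotation.from_rotvec([0, 0, 1.1])
        moved = open_channel.with_coords(rot.apply(open_channel.coords))
        a = pore_radius_profile(open_channel, z_min=-30, z_max=0,
                                slab_width=2.0)
        b = pore_radius_profile(moved, z_min=-30, z_max=0, slab_width=2.0)
        np.testing.assert_allclose(a["radius"], b["radius"], atol=1e-9)

    def test_empty_slab_reported_missing(self):
        s = Structure(["X"], ["C"], [1], ["ALA"], ["A"], [[3, 0, 0]])
        df = pore_radius_profile(s, z_min=0, z_max=4, slab_width=1.0)
        assert df["radius"].isna().sum() == 3


def test_geometry_report_summary_shape(spec):
    ens = make_ensemble(SyntheticParams(n_frames=3, seed=41), spec)
    report = geometry_report(ens)
    summary = report.summary()
    assert set(summary["metric"]) == {"kink_deg", "rotation_deg"}
    assert set(summary["chain"]) == set("ABCD")
    assert report.rmsd_per_residue["rmsd"].min() >= 0.0
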