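import numpy as np
import pytest

from kirgate.enm_modes import (
    DisconnectedNetworkWarning, ModeSet, SelectionConfig, build_hessian,
    compute_modes, displace_along, load_modes, save_modes,
    select_gating_modes,
)
from kirgate.io_structures import Structure


def two_atom_structure(d=3.0):
    return Structure(["CA", "CA"], ["C", "C"], [1, 2], ["ALA", "ALA"],
                     ["A", "A"], [[0, 0, 0], [d, 0, 0]])


def rmsd(a, b):
    return np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))


class TestHessian:
    def test_two_body_rank_one(self):
        h = build_hessian(two_atom_structure(), cutoff=5.0,
                          spring_k=2.0).toarray()
        assert h.shape == (6, 6)
        assert np.linalg.matrix_rank(h, tol=1e-10) == 1

    def test_exact_symmetry(self, reduced_channel):
        h = build_hessian(reduced_channel, cutoff=12.0)
        assert (h != h.T).nnz == 0

    def test_translational_sum_rule(self, reduced_channel):
        h = build_hessian(reduced_channel, cutoff=12.0)
        for axis in range(3):
            t = np.zeros(h.shape[0])
            t[axis::3] = 1.0
            assert np.abs(h @ t).max() < 1e-10

    def test_disconnected_network_warns(self):
        coords = [[0, 0, 0], [2, 0, 0], [100, 0, 0], [102, 0, 0]]
        s = Structure(["CA"] * 4, ["C"] * 4, range(1, 5), ["ALA"] * 4,
                      ["A"] * 4, coords)
        with pytest.warns(DisconnectedNetworkWarning, match="2 components"):
            build_hessian(s, cutoff=5.0)


class TestComputeModes:
    def test_two_body_eigenvalue_closed_form(self):
        """Mass-weighted two-atom network: nonzero eigenvalue = 2k/m."""
        k, m = 3.0, 2.0
        s = two_atom_structure()
        h = build_hessian(s, cutoff=5.0, spring_k=k,
                          masses=np.array([m, m]))
        modes = compute_modes(h, n_modes=6, mass_weighted=True,
                              masses=np.array([m, m]))
        nonzero = modes.eigenvalues[~modes.rigid]
        assert nonzero.size == 1
        assert nonzero[0] == pytest.approx(2.0 * k / m, rel=1e-10)

    def test_connected_tetramer_has_six_zero_modes(self, reduced_channel):
        h = build_hessian(reduced_channel, cutoff=12.0)
        modes = compute_modes(h, n_modes=30)
        assert modes.rigid.sum() == 6
        assert np.all(np.diff(modes.eigenvalues) >= -1e-12)

    def test_eigen_residuals_small(self, reduced_channel):
        h = build_hessian(reduced_channel, cutoff=12.0)
        modes = compute_modes(h, n_modes=30)
        for i in range(modes.n_modes):
            v = modes.eigenvectors[:, i]
            res = np.linalg.norm(h @ v - modes.eigenvalues[i] * v)
            assert res < 1e-6 * np.linalg.norm(v)

    def test_orthonormal_eigenvectors(self, reduced_channel):
        h = build_hessian(reduced_channel, cutoff=12.0)
        modes = compute_modes(h, n_modes=20)
        gram = modes.eigenvectors.T @ modes.eigenvectors
        np.testing.assert_allclose(gram, np.eye(20), atol=1e-8)

    def test_too_many_modes_rejected(self):
        h = build_hessian(two_atom_structure(), cutoff=5.0)
        with pytest.raises(ValueError):
            compute_modes(h, n_modes=7)

    def test_npz_roundtrip(self, tmp_path, reduced_channel):
        h = build_hessian(reduced_channel, cutoff=12.0)
        modes = compute_modes(h, n_modes=12)
        save_modes(modes, tmp_path / "m.npz")
        back = load_modes(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.eigenvalues, modes.eigenvalues)
        np.testing.assert_array_equal(back.eigenvectors, modes.eigenvectors)


class TestDisplaceAlong:
    def test_zero_target_is_identity(self, reduced_channel, rng):
        v = rng.standard_normal((reduced_channel.n_atoms, 3))
        out = displace_along(reduced_channel, v, 0.0)
        np.testing.assert_array_equal(out.coords, reduced_channel.coords)

    @pytest.mark.parametrize("target", [0.5, 2.0])
    def test_exact_rmsd(self, reduced_channel, rng, target):
        v = rng.standard_normal((reduced_channel.n_atoms, 3))
        out = displace_along(reduced_channel, v, target)
        assert rmsd(out.coords, reduced_channel.coords) == pytest.approx(
            target, abs=1e-6)

    def test_sign_linearity_midpoint(self, reduced_channel, rng):
        v = rng.standard_normal((reduced_channel.n_atoms, 3))
        plus = displace_along(reduced_channel, v, 1.5, +1)
        minus = displace_along(reduced_channel, v, 1.5, -1)
        mid = 0.5 * (plus.coords + minus.coords)
        np.testing.assert_allclose(mid, reduced_channel.coords, atol=1e-9)

    def test_zero_vector_rejected(self, reduced_channel):
        with pytest.raises(ValueError, match="zero"):
            displace_along(reduced_channel,
                           np.zeros((reduced_channel.n_atoms, 3)), 1.0)


def _planted_modeset(structure, extra=None):
    """Candidate modes: planted gating patterns plus random filler.

    Mode 0: spherical breathing (all four 125-CA radially outward);
    mode 1: elliptical (A,C outward, B,D inward); mode 2: rigid rotation
    about z.  Eigenvalues ascending, all non-rigid by construction.
    """
    n = structure.n_atoms
    idx125 = {c: np.where((structure.res_ids == 125)
                          & (structure.chain_ids == c)
                          & (structure.atom_names == "CA"))[0][0]
              for c in "ABCD"}

    def radial(i):
        v = np.zeros((n, 3))
        xy = structure.coords[i, :2]
        v[i, :2] = xy / np.linalg.norm(xy)
        return v

    breathing = sum(radial(idx125[c]) for c in "ABCD")
    # elliptical channel motion riding on a cytoplasmic-domain carrier:
    # keeps the probe-atom amplitude physically small once the whole
    # mode is displaced to a fixed global RMSD
    elliptical = (radial(idx125["A"]) + radial(idx125["C"])
                  - radial(idx125["B"]) - radial(idx125["D"]))
    elliptical /= np.linalg.norm(elliptical)
    carrier = np.zeros((n, 3))
    carrier[structure.res_ids >= 200, 2] = 1.0
    carrier /= np.linalg.norm(carrier)
    elliptical = 0.08 * elliptical + np.sqrt(1 - 0.08 ** 2) * carrier
    rot = np.cross(np.array([0.0, 0.0, 1.0]), structure.coords)

    vecs = [breathing.ravel(), elliptical.ravel(), rot.ravel()]
    if extra is not None:
        vecs.extend(extra)
    rng = np.random.default_rng(0)
    while len(vecs) < 13:
        vecs.append(rng.standard_normal(3 * n))
    basis, _ = np.linalg.qr(np.stack(vecs).T)
    # QR preserves the span order: column i spans vecs[:i+1]
    eigenvalues = 0.001 * np.arange(1, basis.shape[1] + 1)
    return ModeSet(basis, eigenvalues)


class TestGatingModeSelection:
    def test_breathing_mode_scores_highest_and_spherical(
            self, open_channel, spec):
        modes = _planted_modeset(open_channel)
        sel = select_gating_modes(modes, open_channel, spec)
        table = sel.selection
        best = table.loc[table["channel_score"].idxmax()]
        assert best["mode"] == 0
        assert best["shape_class"] == "spherical"
        assert bool(best["selected"])

    def test_elliptical_sign_pattern(self, open_channel, spec):
        modes = _planted_modeset(open_channel)
        sel = select_gating_modes(modes, open_channel, spec)
        row = sel.selection.set_index("mode").loc[1]
        assert row["shape_class"] == "elliptical"
        # opposite-signed diametric distance changes
        assert np.sign(row["delta_pair1"]) != np.sign(row["delta_pair2"])

    def test_rigid_rotation_scores_zero(self, open_channel, spec):
        modes = _planted_modeset(open_channel)
        sel = select_gating_modes(modes, open_channel, spec)
        row = sel.selection.set_index("mode").loc[2]
        assert row["channel_score"] < 1e-6

    def test_selection_invariant_to_mode_sign(self, open_channel, spec):
        modes = _planted_modeset(open_channel)
        flipped = ModeSet(modes.eigenvectors * -1.0, modes.eigenvalues)
        a = select_gating_modes(modes, open_channel, spec)
        b = select_gating_modes(flipped, open_channel, spec)
        assert list(a.selection["channel_score"]) == pytest.approx(
            list(b.selection["channel_score"]), abs=1e-9)

    def test_redundant_channel_pattern_dropped(self, open_channel, spec):
        """Two modes with identical channel sub-vectors but orthogonal
        far-region parts: the higher-frequency twin is discarded."""
        n = open_channel.n_atoms
        lo, hi = spec.channel_range
        in_region = np.repeat((open_channel.res_ids >= lo)
                              & (open_channel.res_ids <= hi), 3)
        rng = np.random.default_rng(1)
        a = np.zeros(3 * n)
        a[in_region] = rng.standard_normal(in_region.sum())
        b = np.zeros(3 * n)
        b[~in_region] = rng.standard_normal((~in_region).sum())
        a /= np.linalg.norm(a)
        b /= np.linalg.norm(b)
        twin1 = (a + b) / np.sqrt(2)
        twin2 = (a - b) / np.sqrt(2)
        modes = _planted_modeset(open_channel, extra=[twin1, twin2])
        cfg = SelectionConfig(n_final=10)
        sel = select_gating_modes(modes, open_channel, spec, cfg)
        chosen = set(sel.selection[sel.selection["selected"]]["mode"])
        assert not {3, 4} <= chosen  # at most one twin survives
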