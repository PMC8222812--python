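"""Elastic-network normal modes and gating-mode selection.

The low-frequency collective motions of the channel are obtained from an
anisotropic elastic network: every atom pair closer than a cutoff is
joined by a uniform harmonic spring, and the resulting Hessian is
diagonalised directly.  A connected network has exactly six zero modes
(rigid translations and rotations), which are flagged and excluded from
selection.

Mode selection follows the gating protocol: displace the structure by a
fixed RMSD along each candidate mode in both directions, score the mode
by how much it changes the diametric inter-chain distances at a probe
residue in the channel, keep the highest-scoring modes, classify the
opening shape (spherical vs. elliptical vs. other) from the sign pattern
of the two diametric distance changes, drop redundant modes by
channel-region cosine similarity, and keep the lowest-frequency
survivors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph
import scipy.sparse.linalg
from scipy.spatial import cKDTree

from .gating_analysis import shortest_distance
from .io_structures import ChannelSpec, Structure


class DisconnectedNetworkWarning(UserWarning):
    pass


#: eigenvalues below this fraction of the largest computed eigenvalue are
#: treated as rigid-body (zero) modes
ZERO_MODE_TOL = 1e-8


@dataclass
class ModeSet:
    """Eigenpairs of the network Hessian, lowest frequency first."""

    eigenvectors: np.ndarray  # (3N, n_modes), orthonormal columns
    eigenvalues: np.ndarray   # ascending
    mass_weighted: bool = False
    masses: np.ndarray | None = None
    selection: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=np.float64)
        if np.any(np.diff(self.eigenvalues) < -1e-10):
            raise ValueError("eigenvalues must be ascending")

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """sqrt of non-negative eigenvalues, arbitrary units."""
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    @property
    def rigid(self) -> np.ndarray:
        """Boolean mask of rigid-body (near-zero) modes."""
        scale = max(self.eigenvalues.max(), 1.0)
        return np.abs(self.eigenvalues) < ZERO_MODE_TOL * scale

    def mode(self, i: int) -> np.ndarray:
        """Cartesian displacement pattern of mode i, shape (N, 3)."""
        v = self.eigenvectors[:, i]
        if self.mass_weighted and self.masses is not None:
            v = v / np.sqrt(np.repeat(self.masses, 3))
            v = v / np.linalg.norm(v)
        return v.reshape(-1, 3)

    def subset(self, indices) -> "ModeSet":
        indices = np.asarray(indices)
        sel = None
        if self.selection is not None:
            sel = self.selection[self.selection["mode"].isin(indices)]
            sel = sel.reset_index(drop=True)
        return ModeSet(self.eigenvectors[:, indices],
                       self.eigenvalues[indices],
                       self.mass_weighted, self.masses, sel)


def build_hessian(structure: Structure, cutoff: float = 12.0,
                  spring_k: float = 1.0,
                  masses: np.ndarray | None = None) -> scipy.sparse.csr_matrix:
    """Anisotropic-network Hessian (3N × 3N, sparse).

    Off-diagonal blocks are ``-k/d² · d_ij d_ijᵀ`` for pairs within the
    cutoff; diagonal blocks enforce the translational sum rule.  When
    ``masses`` is given the Hessian is mass-weighted
    (``M^-1/2 H M^-1/2``).  Warns if the contact network is disconnected.
    """
    coords = structure.coords
    n = coords.shape[0]
    tree = cKDTree(coords)
    pairs = np.array(sorted(tree.query_pairs(cutoff)))
    if pairs.size == 0:
        raise ValueError("no atom pairs within cutoff")

    adj = scipy.sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, _ = scipy.sparse.csgraph.connected_components(adj, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"elastic network is disconnected ({n_comp} components); "
            "expect more than 6 zero modes", DisconnectedNetworkWarning)

    diff = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    d2 = np.einsum("ij,ij->i", diff, diff)
    # per-pair 3x3 super-element: k/d^2 * outer(d, d)
    blocks = spring_k * diff[:, :, None] * diff[:, None, :] / d2[:, None, None]

    rows, cols, vals = [], [], []
    i3 = 3 * pairs[:, 0]
    j3 = 3 * pairs[:, 1]
    for a in range(3):
        for b in range(3):
            v = blocks[:, a, b]
            rows.extend([i3 + a, j3 + a, i3 + a, j3 + a])
            cols.extend([j3 + b, i3 + b, i3 + b, j3 + b])
            vals.extend([-v, -v, v, v])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    hessian = scipy.sparse.coo_matrix((vals, (rows, cols)),
                                      shape=(3 * n, 3 * n)).tocsr()
    # duplicate summation order can differ across the diagonal blocks;
    # enforce bitwise symmetry
    hessian = (hessian + hessian.T) * 0.5
    if masses is not None:
        inv_sqrt_m = 1.0 / np.sqrt(np.repeat(np.asarray(masses, float), 3))
        d = scipy.sparse.diags(inv_sqrt_m)
        hessian = (d @ hessian @ d).tocsr()
    return hessian


def compute_modes(hessian, n_modes: int = 200,
                  mass_weighted: bool = False,
                  masses: np.ndarray | None = None) -> ModeSet:
    """Lowest-frequency eigenpairs of a (sparse or dense) Hessian."""
    hessian = scipy.sparse.csr_matrix(hessian)
    dim = hessian.shape[0]
    if n_modes > dim:
        raise ValueError(f"requested {n_modes} modes from a {dim}-dim Hessian")

    if n_modes >= dim - 1 or dim <= 600:
        dense = hessian.toarray()
        vals, vecs = scipy.linalg.eigh(dense,
                                       subset_by_index=[0, n_modes - 1])
    else:
        # shift-invert about a slightly negative sigma: robust for the
        # singular (rigid-body) end of the spectrum
        scale = abs(hessian).max()
        vals, vecs = scipy.sparse.linalg.eigsh(
            hessian, k=n_modes, sigma=-1e-6 * scale, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    return ModeSet(vecs, vals, mass_weighted=mass_weighted, masses=masses)


def displace_along(structure: Structure, mode_vector: np.ndarray,
                   target_rmsd: float, sign: int = 1) -> Structure:
    """Displace all atoms along a mode to an exact all-atom RMSD (Å)."""
    v = np.asarray(mode_vector, dtype=np.float64).reshape(-1, 3)
    if v.shape[0] != structure.n_atoms:
        raise ValueError("mode vector length does not match structure")
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero mode vector")
    n = structure.n_atoms
    # RMSD of a displacement a*v̂ is a/sqrt(N)
    step = sign * target_rmsd * np.sqrt(n) / norm
    return structure.with_coords(structure.coords + step * v)


@dataclass
class SelectionConfig:
    """Tunables of the gating-mode selection protocol."""

    probe_residue: int = 125
    displace_rmsd: float = 2.0
    n_keep_first: int = 10
    n_final: int = 4
    shape_ratio: float = 0.5     # min/max |δ| for a 'spherical' call
    noise_floor: float = 0.05    # Å; |δ| below this is treated as zero
    redundancy_cos: float = 0.9  # channel sub-vector cosine cut


def _pair_deltas(modes: ModeSet, structure: Structure, spec: ChannelSpec,
                 cfg: SelectionConfig, i: int):
    """Signed probe-distance changes (+displacement vs baseline) and the
    total ± spread, per gate pair, for mode i."""
    v = modes.mode(i)
    plus = displace_along(structure, v, cfg.displace_rmsd, +1)
    minus = displace_along(structure, v, cfg.displace_rmsd, -1)
    deltas, spreads = [], []
    for a, b in spec.gate_pairs:
        d0 = shortest_distance(structure, (cfg.probe_residue, a),
                               (cfg.probe_residue, b))
        dp = shortest_distance(plus, (cfg.probe_residue, a),
                               (cfg.probe_residue, b))
        dm = shortest_distance(minus, (cfg.probe_residue, a),
                               (cfg.probe_residue, b))
        deltas.append(dp - d0)
        spreads.append(abs(dp - dm))
    return np.array(deltas), np.array(spreads)


def _classify_shape(deltas: np.ndarray, cfg: SelectionConfig) -> str:
    mags = np.abs(deltas)
    if mags.max() < cfg.noise_floor:
        return "other"
    d1, d2 = deltas
    if np.sign(d1) == np.sign(d2) and mags.min() >= cfg.noise_floor:
        ratio = mags.min() / mags.max()
        return "spherical" if ratio >= cfg.shape_ratio else "elliptical"
    if mags.min() >= cfg.noise_floor:
        return "elliptical"  # opposite signs, both significant
    return "other"


def select_gating_modes(modes: ModeSet, structure: Structure,
                        spec: ChannelSpec | None = None,
                        config: SelectionConfig | None = None) -> ModeSet:
    """Apply the gating-mode selection protocol.

    Returns the selected modes (lowest frequency first) with a
    ``selection`` table recording every candidate's channel score, shape
    class and fate.
    """
    spec = spec or ChannelSpec()
    cfg = config or SelectionConfig()
    nonrigid = np.where(~modes.rigid)[0]
    if len(nonrigid) < cfg.n_keep_first:
        raise ValueError(
            f"need at least {cfg.n_keep_first} non-rigid modes, "
            f"have {len(nonrigid)}")

    records = []
    for i in nonrigid:
        deltas, spreads = _pair_deltas(modes, structure, spec, cfg, i)
        records.append({
            "mode": int(i),
            "eigenvalue": float(modes.eigenvalues[i]),
            "channel_score": float(spreads.max()),
            "delta_pair1": float(deltas[0]),
            "delta_pair2": float(deltas[1]) if len(deltas) > 1 else np.nan,
            "shape_class": _classify_shape(deltas, cfg),
        })
    table = pd.DataFrame(records)

    # 1. top-scoring modes at the channel probe
    top = table.nlargest(cfg.n_keep_first, "channel_score")
    table["retained_top"] = table["mode"].isin(top["mode"])
    # 2. spherical / elliptical openings only
    shaped = top[top["shape_class"].isin(["spherical", "elliptical"])]
    # 3. redundancy: compare channel-region sub-vectors, keep lower freq
    lo, hi = spec.channel_range
    region_mask = np.repeat(
        (structure.res_ids >= lo) & (structure.res_ids <= hi), 3)
    kept: list[int] = []
    for i in shaped.sort_values("eigenvalue")["mode"]:
        sub_i = modes.eigenvectors[region_mask, i]
        ni = np.linalg.norm(sub_i)
        redundant = False
        for j in kept:
            sub_j = modes.eigenvectors[region_mask, j]
            nj = np.linalg.norm(sub_j)
            if ni > 0 and nj > 0:
                cos = abs(float(sub_i @ sub_j)) / (ni * nj)
                if cos > cfg.redundancy_cos:
                    redundant = True
                    break
        if not redundant:
            kept.append(int(i))
    # 4. lowest-frequency survivors
    kept = sorted(kept, key=lambda i: modes.eigenvalues[i])[: cfg.n_final]
    if len(kept) < cfg.n_final:
        warnings.warn(
            f"only {len(kept)} gating modes survived selection "
            f"(requested {cfg.n_final})")
    kept = sorted(kept)
    table["selected"] = table["mode"].isin(kept)

    out = modes.subset(kept)
    out.selection = table
    return out


def save_modes(modes: ModeSet, path_npz: str, path_csv: str | None = None):
    """Serialize a mode set (NPZ for eigenpairs, CSV for the selection)."""
    np.savez(path_npz, eigenvectors=modes.eigenvectors,
             eigenvalues=modes.eigenvalues,
             mass_weighted=np.array(modes.mass_weighted),
             masses=(modes.masses if modes.masses is not None
                     else np.array([])))
    if path_csv is not None and modes.selection is not None:
        modes.selection.to_csv(path_csv, index=False)


def load_modes(path_npz: str) -> ModeSet:
    data = np.load(path_npz)
    masses = data["masses"]
    return ModeSet(data["eigenvectors"], data["eigenvalues"],
                   bool(data["mass_weighted"]),
                   masses if masses.size else None)
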