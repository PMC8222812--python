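"""Helix kink angles, cytoplasmic-domain rotation, per-residue RMSD,
and a simplified pore-radius profile.

Definitions:

* **TM1 kink** — the angle between the axes of the two sub-segments of
  the outer helix (residues 46–56 and 56–80 by default).  Each axis is
  the principal component of the segment's CA coordinates oriented
  N-terminus → C-terminus; 0° means straight.  An endpoint-vector mode
  (first-to-last CA) is available as a cross-check.

* **CTD rotation** — the pseudo-dihedral of four points: the CA of a
  pore-lining residue (108), its projection on the central z axis, the
  projection of a cytoplasmic-domain residue's CA (266), and that CA
  itself.  A "twist-to-open" order parameter, reported in (−180°, 180°].

* **Per-residue RMSD** — for each atom i over an ensemble of N frames,
  ``RMSD_i = sqrt(1/N Σ_n |r_i(n) − r_i^ref|²)``; the residue value is
  the mean of its atoms.  No superposition unless requested.

* **Pore-radius profile** — at each z slab, the minimum over contained
  atoms of (distance to the z axis − atom radius), floored at zero; a
  geometric stand-in for sphere-probe pore profiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_structures import Ensemble, SelectionError, Structure, select


@dataclass
class GeometryReport:
    """Long-format per-frame, per-chain geometry metrics."""

    angles: pd.DataFrame              # frame, chain, metric, value (deg)
    rmsd_per_residue: pd.DataFrame | None = None
    pore_profile: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        g = self.angles.groupby(["chain", "metric"])["value"]
        return g.agg(["mean", "median", "std"]).reset_index()


def _segment_axis(coords: np.ndarray, method: str) -> np.ndarray:
    """Oriented (N→C) axis of a run of CA coordinates."""
    if len(coords) < 2:
        raise ValueError("segment needs at least two points")
    if method == "endpoint":
        axis = coords[-1] - coords[0]
    elif method == "principal":
        centered = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        if np.dot(axis, coords[-1] - coords[0]) < 0:
            axis = -axis
    else:
        raise ValueError(f"unknown axis method {method!r}")
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("degenerate segment")
    return axis / n


def kink_angle(structure: Structure, chain: str,
               segments: tuple[int, int, int] = (46, 56, 80),
               method: str = "principal") -> float:
    """TM1 kink (degrees) of one chain; 0° = straight."""
    first, mid, last = segments
    ca1 = select(structure, chain=chain, residues=(first, mid),
                 atom_names=["CA"])
    ca2 = select(structure, chain=chain, residues=(mid, last),
                 atom_names=["CA"])
    a1 = _segment_axis(ca1.coords, method)
    a2 = _segment_axis(ca2.coords, method)
    cosang = np.clip(np.dot(a1, a2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _dihedral(p1, p2, p3, p4) -> float:
    """Standard four-point dihedral, degrees in (−180, 180]."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang != -180.0 else 180.0)


def ctd_rotation(structure: Structure, chain: str,
                 res_inner: int = 108, res_outer: int = 266,
                 axis_point: np.ndarray = (0.0, 0.0, 0.0),
                 axis_dir: np.ndarray = (0.0, 0.0, 1.0)) -> float:
    """Cytoplasmic-domain rotation pseudo-dihedral (degrees).

    Points: CA(res_inner), its projection on the central axis, the
    projection of CA(res_outer), CA(res_outer).  Raises if either CA
    lies on the axis (dihedral undefined).
    """
    p0 = np.asarray(axis_point, float)
    u = np.asarray(axis_dir, float)
    u = u / np.linalg.norm(u)

    def _ca(resid):
        sel = select(structure, chain=chain, residues=[resid],
                     atom_names=["CA"])
        return sel.coords[0]

    a = _ca(res_inner)
    b = _ca(res_outer)
    proj_a = p0 + np.dot(a - p0, u) * u
    proj_b = p0 + np.dot(b - p0, u) * u
    if (np.linalg.norm(a - proj_a) < 1e-9
            or np.linalg.norm(b - proj_b) < 1e-9):
        raise ValueError(
            f"residue CA lies on the central axis; dihedral undefined")
    return _dihedral(a, proj_a, proj_b, b)


def per_residue_rmsd(ensemble: Ensemble, reference: Structure,
                     superpose: bool = False) -> pd.DataFrame:
    """Ensemble RMSD per residue (mean of its atoms' RMSD_i), in Å.

    ``superpose`` rigid-fits every frame onto the reference CA atoms
    first (off by default; the flag is recorded in the output attrs).
    """
    if reference.n_atoms != ensemble.n_atoms:
        raise ValueError("reference topology does not match ensemble")
    coords = ensemble.coords
    if superpose:
        from .cluster_relax import _kabsch_align
        fit_idx = np.where(reference.atom_names == "CA")[0]
        coords = np.stack([_kabsch_align(c, reference.coords, fit_idx)
                           for c in coords])
    diff = coords - reference.coords[None]
    rmsd_atom = np.sqrt(np.mean(np.sum(diff ** 2, axis=2), axis=0))

    df = pd.DataFrame({
        "chain": reference.chain_ids,
        "residue": reference.res_ids,
        "rmsd": rmsd_atom,
    }).groupby(["chain", "residue"], as_index=False)["rmsd"].mean()
    df.attrs["superposed"] = superpose
    return df


def pore_radius_profile(structure: Structure,
                        z_min: float | None = None,
                        z_max: float | None = None,
                        slab_width: float = 1.0,
                        atom_radius: float | dict = 0.5,
                        axis_point: np.ndarray = (0.0, 0.0, 0.0)
                        ) -> pd.DataFrame:
    """Pore radius along z: per slab, min(distance to axis − atom radius).

    ``atom_radius`` is a scalar or a mapping from atom name.  Slabs with
    no atoms get NaN.  Radii are floored at zero.
    """
    coords = structure.coords
    p0 = np.asarray(axis_point, float)
    if z_min is None:
        z_min = float(coords[:, 2].min())
    if z_max is None:
        z_max = float(coords[:, 2].max())
    if isinstance(atom_radius, dict):
        radii = np.array([atom_radius.get(str(n), 0.0)
                          for n in structure.atom_names])
    else:
        radii = np.full(structure.n_atoms, float(atom_radius))

    rho = np.sqrt((coords[:, 0] - p0[0]) ** 2 + (coords[:, 1] - p0[1]) ** 2)
    clearance = rho - radii

    edges = np.arange(z_min, z_max + slab_width, slab_width)
    centers, radius = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (coords[:, 2] >= lo) & (coords[:, 2] < hi)
        centers.append(0.5 * (lo + hi))
        radius.append(max(clearance[m].min(), 0.0) if m.any() else np.nan)
    return pd.DataFrame({"z": centers, "radius": radius})


def geometry_report(ensemble: Ensemble, chains=("A", "B", "C", "D"),
                    reference: Structure | None = None,
                    kink_segments: tuple[int, int, int] = (46, 56, 80),
                    rotation_residues: tuple[int, int] = (108, 266),
                    superpose_rmsd: bool = False) -> GeometryReport:
    """Kink and rotation per frame and chain, plus per-residue RMSD.

    The RMSD reference must be stated explicitly: pass a Structure (e.g.
    the starting model) or the string-less default ``None`` to use the
    ensemble coordinate mean.
    """
    rows = []
    for i, frame in enumerate(ensemble):
        for c in chains:
            rows.append({"frame": i, "chain": c, "metric": "kink_deg",
                         "value": kink_angle(frame, c, kink_segments)})
            rows.append({"frame": i, "chain": c, "metric": "rotation_deg",
                         "value": ctd_rotation(frame, c,
                                               *rotation_residues)})
    angles = pd.DataFrame(rows)

    if reference is None:
        reference = ensemble.topology.with_coords(
            ensemble.coords.mean(axis=0))
    rmsd = per_residue_rmsd(ensemble, reference, superpose=superpose_rmsd)
    return GeometryReport(angles, rmsd_per_residue=rmsd)
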