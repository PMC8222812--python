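"""Channel-region clustering, representative selection, and relaxation.

Excited-dynamics structures are grouped by greedy leader clustering on
the RMSD of the channel-lining region (default residues 121–133, 0.9 Å
threshold) after superposing every frame onto the first frame on CA
atoms.  The first frame seeds cluster 1; each subsequent frame joins the
nearest leader within the threshold or seeds a new cluster, so unique
structures become singleton clusters.  Each cluster's representative is
the member closest to the cluster's average channel coordinates.

Representatives are then relaxed by plain (unexcited) Langevin dynamics
to shed the injected kinetic energy, and only the last fraction of each
relaxation trajectory (default three quarters) is kept for analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .io_structures import Ensemble, SelectionError, Structure
from .mdenm_engine import ExcitationConfig, run_free


@dataclass
class Clustering:
    assignments: np.ndarray           # frame -> cluster id (0-based)
    representatives: dict             # cluster id -> frame index
    threshold: float
    region: tuple[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def to_dataframe(self) -> pd.DataFrame:
        reps = set(self.representatives.values())
        return pd.DataFrame({
            "frame": np.arange(len(self.assignments)),
            "cluster": self.assignments,
            "is_representative": [i in reps
                                  for i in range(len(self.assignments))],
        })


def _kabsch_align(mobile: np.ndarray, target: np.ndarray,
                  fit_idx: np.ndarray) -> np.ndarray:
    """Rigid-fit ``mobile`` onto ``target`` using the fit-index atoms."""
    mob_c = mobile[fit_idx].mean(axis=0)
    tgt_c = target[fit_idx].mean(axis=0)
    rot, _ = Rotation.align_vectors(target[fit_idx] - tgt_c,
                                    mobile[fit_idx] - mob_c)
    return rot.apply(mobile - mob_c) + tgt_c


def _region_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def cluster(ensemble: Ensemble, region: tuple[int, int] = (121, 133),
            threshold: float = 0.9, superpose: bool = True) -> Clustering:
    """Greedy leader clustering on channel-region RMSD.

    ``superpose=True`` (default) first rigid-fits every frame onto frame
    0 on CA atoms so the clustering reflects internal channel geometry
    rather than rigid drift; ``False`` uses raw (pore-axis frame)
    coordinates.  Deterministic given the frame order.
    """
    topo = ensemble.topology
    lo, hi = region
    region_mask = (topo.res_ids >= lo) & (topo.res_ids <= hi)
    if not region_mask.any():
        raise SelectionError(f"no atoms in residue range {lo}-{hi}")
    fit_idx = np.where(topo.atom_names == "CA")[0]
    if fit_idx.size == 0:
        fit_idx = np.arange(topo.n_atoms)

    region_coords = np.empty((ensemble.n_frames, region_mask.sum(), 3))
    ref = ensemble.coords[0]
    for i in range(ensemble.n_frames):
        frame = ensemble.coords[i]
        if superpose and i > 0:
            frame = _kabsch_align(frame, ref, fit_idx)
        region_coords[i] = frame[region_mask]

    assignments = np.empty(ensemble.n_frames, dtype=int)
    leaders: list[int] = []
    members: list[list[int]] = []
    for i in range(ensemble.n_frames):
        best, best_d = -1, np.inf
        for c, lead in enumerate(leaders):
            d = _region_rmsd(region_coords[i], region_coords[lead])
            if d <= threshold and d < best_d:
                best, best_d = c, d
        if best < 0:
            best = len(leaders)
            leaders.append(i)
            members.append([])
        assignments[i] = best
        members[best].append(i)

    representatives = {}
    for c, idx in enumerate(members):
        mean = region_coords[idx].mean(axis=0)
        dists = np.array([_region_rmsd(region_coords[i], mean) for i in idx])
        # ties (identical frames up to alignment noise) go to the earliest
        best = int(np.flatnonzero(dists <= dists.min() + 1e-9)[0])
        representatives[c] = idx[best]

    return Clustering(assignments, representatives, threshold, region)


def kept_slice(n_frames: int, keep_fraction: float) -> slice:
    """Frames retained after relaxation: drop the first ceil((1-f)·n)."""
    drop = math.ceil((1.0 - keep_fraction) * n_frames)
    return slice(drop, n_frames)


def relax(representatives: list[Structure], potential_factory,
          duration_ps: float, config: ExcitationConfig,
          masses: np.ndarray, keep_fraction: float = 0.75,
          provenance: list | None = None,
          seed: int | None = None):
    """Relax each representative by free dynamics; keep the tail frames.

    ``potential_factory`` maps a Structure to a potential (each
    representative relaxes on a potential anchored at itself).  Returns
    ``(ensemble, table)`` where the table carries per-frame provenance
    (representative index, cluster id if given, kinetic temperature).
    Representatives whose dynamics go non-finite are skipped and flagged.
    """
    if duration_ps <= 0:
        raise ValueError("duration must be positive")
    base_seed = config.seed if seed is None else seed
    all_coords, rows = [], []
    for r, rep in enumerate(representatives):
        try:
            result = run_free(rep, potential_factory(rep), duration_ps,
                              config, masses, seed=base_seed + r)
        except RuntimeError as exc:
            rows.append({"representative": r, "frame": -1,
                         "cluster": (provenance[r] if provenance else r),
                         "kinetic_temperature": np.nan,
                         "error": str(exc)})
            continue
        traj = result.trajectory
        keep = kept_slice(traj.n_frames, keep_fraction)
        for local, (coords_i, temp) in enumerate(zip(
                traj.coords[keep], result.kinetic_temperatures[keep])):
            all_coords.append(coords_i)
            rows.append({"representative": r,
                         "frame": keep.start + local,
                         "cluster": (provenance[r] if provenance else r),
                         "kinetic_temperature": temp, "error": ""})

    table = pd.DataFrame(rows)
    if not all_coords:
        raise RuntimeError("all relaxation runs failed")
    topo = representatives[0]
    ensemble = Ensemble(topo, np.stack(all_coords), source="relaxed")
    return ensemble, table
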