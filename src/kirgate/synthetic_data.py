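"""Idealized tetrameric channel structures with known gating ground truth.

The generator emulates the geometry the analysis operators measure, not
protein chemistry: each chain is a CA pseudo-atom trace covering residues
35–295 arranged with C4 symmetry about the z (pore) axis, with

* a TM1 outer helix (residues 46–80) built from two exactly straight
  segments meeting at residue 56 with a prescribed kink angle;
* a channel-lining region (residues 121–133) whose constriction residues
  carry an extra side-chain pseudo-atom (``SC``) placed at a prescribed
  radial distance from the pore axis — the gate;
* a cytoplasmic domain (residues ≥ 134, containing the rotation-probe
  residue 266) rigidly rotated about z by a prescribed angle.

Gate pseudo-atom centers sit at radius ``gate_radius - pseudo_atom_radius``,
so the shortest diametric inter-chain distance at an open gate is
``2*gate_radius - 2*pseudo_atom_radius`` — analytically known, which is
what makes classifier and geometry tests exact.

Ensembles draw a gating state per frame i.i.d. from declared state
probabilities, rebuild the gates accordingly and add isotropic Gaussian
coordinate noise; the drawn labels are recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .gating_analysis import GatingState
from .io_structures import ChannelSpec, Ensemble, Structure, assemble_c4

#: Built-in study scenario: an engineered-open channel whose only
#: closed category is the middle (129) gate ...
MUTANT_STATE_PROBS: dict = {
    GatingState.FULLY_OPEN: 0.528,
    GatingState.GATE129_CLOSED: 0.472,
}

#: ... and a wild-type-like channel gated at the two main constrictions.
WT_STATE_PROBS: dict = {
    GatingState.FULLY_OPEN: 0.068,
    GatingState.FULLY_CLOSED: 0.502,
    GatingState.PARTIAL_124_OPEN_132_CLOSED: 0.288,
    GatingState.PARTIAL_132_OPEN_124_CLOSED: 0.142,
    GatingState.GATE129_CLOSED: 0.0,
}

# Which gates are open in each state, keyed by gate role
# (lower main gate / middle gate / upper main gate).
_STATE_GATES: dict = {
    GatingState.FULLY_OPEN: (True, True, True),
    GatingState.FULLY_CLOSED: (False, True, False),
    GatingState.PARTIAL_124_OPEN_132_CLOSED: (True, True, False),
    GatingState.PARTIAL_132_OPEN_124_CLOSED: (False, True, True),
    GatingState.GATE129_CLOSED: (True, False, True),
}


@dataclass
class SyntheticParams:
    """Knobs of the synthetic channel generator.

    ``gate_radius_open``/``gate_radius_closed`` are pore radii (Å) at an
    open/closed gate; ``kink_angle_deg`` is the TM1 kink (scalar or
    per-chain mapping); ``ctd_rotation_deg`` rotates the cytoplasmic
    domain about z.  Defaults mirror the study conditions the analysis
    is meant to resolve: gates well clear of the K+ ionic diameter on
    either side, sub-Å thermal-like noise, and a noticeably kinked TM1.
    """

    n_frames: int = 1000
    state_probs: Mapping = field(
        default_factory=lambda: dict(MUTANT_STATE_PROBS))
    gate_radius_open: float = 4.0
    gate_radius_closed: float = 1.2
    coord_noise_sd: float = 0.15
    kink_angle_deg: float | Mapping = 13.0
    ctd_rotation_deg: float = 0.0
    pseudo_atom_radius: float = 0.5
    seed: int = 0
    ctd_first_residue: int = 134

    def __post_init__(self) -> None:
        total = float(sum(self.state_probs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state_probs sum to {total}, expected 1")
        if min(self.gate_radius_open, self.gate_radius_closed) <= 0:
            raise ValueError("gate radii must be positive")
        if self.gate_radius_closed <= self.pseudo_atom_radius:
            raise ValueError(
                "closed gate radius must exceed the pseudo-atom radius")
        if self.coord_noise_sd < 0:
            raise ValueError("coord_noise_sd must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    def kink_for_chain(self, chain: str) -> float:
        if isinstance(self.kink_angle_deg, Mapping):
            return float(self.kink_angle_deg[chain])
        return float(self.kink_angle_deg)

    def gate_distance(self, open_: bool) -> float:
        """Analytic diametric inter-chain SC-SC distance for a gate."""
        g = self.gate_radius_open if open_ else self.gate_radius_closed
        return 2.0 * (g - self.pseudo_atom_radius)

    def validate_margins(self, spec: ChannelSpec) -> None:
        """Open/closed distances must clear the ionic diameter by >= 3 sd."""
        margin = 3.0 * self.coord_noise_sd
        d_open = self.gate_distance(True)
        d_closed = self.gate_distance(False)
        if d_open - spec.ionic_diameter < margin:
            raise ValueError(
                f"open gate distance {d_open:.3f} Å too close to the ionic "
                f"diameter {spec.ionic_diameter} Å (margin < {margin:.3f})")
        if spec.ionic_diameter - d_closed < margin:
            raise ValueError(
                f"closed gate distance {d_closed:.3f} Å too close to the "
                f"ionic diameter {spec.ionic_diameter} Å")


_RES_NAMES = {46: "TRP", 56: "LEU", 80: "ASP", 108: "LEU", 121: "MET",
              124: "LEU", 129: "ARG", 132: "TYR", 133: "ALA", 266: "ILE",
              35: "HIS", 138: "PRO", 167: "ARG", 250: "PHE", 125: "GLY"}

# Monomer layout constants (Å, degrees); chain A frame, pore axis = z.
_TM1_START = np.array([13.0, 2.0, -8.0])
_TM1_DIR = np.array([0.15, 0.0, 1.0]) / np.linalg.norm([0.15, 0.0, 1.0])
_TM1_RISE = 1.2
_CHANNEL_CA_RADIUS = 8.0
_CTD_RADIUS = 15.0       # radial distance of the CTD block center
_CTD_SPACING = 3.5       # CA-CA lattice spacing inside the CTD block
_CTD_AZIMUTH_DEG = 16.0  # baseline azimuthal offset of the CTD block
_CTD_TOP_Z = -37.0


def _lerp(p0, p1, n):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return np.asarray(p0) + t * (np.asarray(p1) - np.asarray(p0))


def _coil(p0, p1, n, amp, turn=2.0):
    """Points along p0→p1 with a helical offset of the given amplitude.

    Loops and helices other than TM1 are built this way: a straight
    pseudo-atom chain is a floppy central-force network (interior atoms
    hinge freely), so every segment that is not contractually straight
    gets a non-collinear winding.
    """
    base = _lerp(p0, p1, n)
    u = np.asarray(p1, float) - np.asarray(p0, float)
    u = u / np.linalg.norm(u)
    a = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(a) < 1e-6:
        a = np.cross(u, [1.0, 0.0, 0.0])
    a = a / np.linalg.norm(a)
    b = np.cross(u, a)
    phase = turn * np.arange(n)
    return base + amp * (np.cos(phase)[:, None] * a
                         + np.sin(phase)[:, None] * b)


def _monomer(params: SyntheticParams, spec: ChannelSpec, chain: str,
             gate_open: Mapping) -> Structure:
    """One chain (id ``chain``) in the chain-A frame, CA trace + gates."""
    kink = np.deg2rad(params.kink_for_chain(chain))

    positions: dict = {}
    # slide helix 35-45
    for r, p in zip(range(35, 46), _coil([18.0, -4.0, -12.0],
                                         [14.5, 2.0, -11.0], 11, 0.4)):
        positions[r] = p
    # TM1: two exactly straight segments meeting at residue 56
    u1 = _TM1_DIR
    bend = Rotation.from_rotvec(np.array([0.0, 1.0, 0.0]) * kink)
    u2 = bend.apply(u1)
    for k in range(0, 11):  # 46..56
        positions[46 + k] = _TM1_START + _TM1_RISE * k * u1
    p56 = positions[56]
    for k in range(1, 25):  # 57..80
        positions[56 + k] = p56 + _TM1_RISE * k * u2
    # turret / pore helix winding back down alongside TM1
    for r, p in zip(range(81, 96), _coil(positions[80],
                                         [9.5, -2.0, 3.0], 16, 1.6)[1:]):
        positions[r] = p
    # selectivity-filter region
    for r, p in zip(range(96, 108), _coil([8.9, -1.8, 2.0],
                                          [8.2, 0.2, -2.0], 12, 0.8)):
        positions[r] = p
    # TM2 inner helix
    for r, p in zip(range(108, 121), _coil([8.0, 0.0, -3.0],
                                           [8.0, 0.0, -15.0], 13, 1.0)):
        positions[r] = p
    # channel-lining region: one residue per Å of depth
    lo, hi = spec.channel_range
    for i, r in enumerate(range(lo, hi + 1)):
        positions[r] = np.array([_CHANNEL_CA_RADIUS, 0.0, -16.0 - float(i)])
    # linker descending and swinging outward to the CTD block
    n_link = 155 - hi - 1
    n_a = n_link // 2
    for r, p in zip(range(hi + 1, hi + 1 + n_a),
                    _coil([8.5, 0.5, -29.0], [15.0, 4.0, -32.0], n_a, 0.9)):
        positions[r] = p
    for r, p in zip(range(hi + 1 + n_a, 155),
                    _coil([14.5, 3.0, -33.0], [13.0, 1.5, -36.5],
                          n_link - n_a, 0.9)):
        positions[r] = p
    # cytoplasmic domain: a 5x5xM lattice block (one 90-degree sector per
    # chain) at realistic ~3.5 Å CA spacing, rotated to its baseline azimuth
    az0 = np.deg2rad(_CTD_AZIMUTH_DEG)
    rot_az = np.array([[np.cos(az0), -np.sin(az0), 0.0],
                       [np.sin(az0), np.cos(az0), 0.0],
                       [0.0, 0.0, 1.0]])
    for i, r in enumerate(range(155, 296)):
        ix, iy, iz = i % 5, (i // 5) % 5, i // 25
        p = np.array([_CTD_RADIUS + (ix - 2) * _CTD_SPACING,
                      (iy - 2) * _CTD_SPACING,
                      _CTD_TOP_Z - iz * _CTD_SPACING])
        positions[r] = rot_az @ p

    names, elements, res_ids, res_names, coords = [], [], [], [], []
    for r in sorted(positions):
        names.append("CA")
        elements.append("C")
        res_ids.append(r)
        res_names.append(_RES_NAMES.get(r, "ALA"))
        coords.append(positions[r])
        if r in spec.constriction_residues:
            radius = (params.gate_radius_open if gate_open[r]
                      else params.gate_radius_closed)
            rho = radius - params.pseudo_atom_radius
            names.append("SC")
            elements.append("C")
            res_ids.append(r)
            res_names.append(_RES_NAMES.get(r, "ALA"))
            coords.append(np.array([rho, 0.0, positions[r][2]]))

    coords = np.asarray(coords)
    # rigid CTD rotation about the pore axis
    if params.ctd_rotation_deg:
        rot = Rotation.from_rotvec(
            [0.0, 0.0, np.deg2rad(params.ctd_rotation_deg)])
        ctd = np.asarray(res_ids) >= params.ctd_first_residue
        coords[ctd] = rot.apply(coords[ctd])

    return Structure(
        names, elements, res_ids, res_names,
        np.full(len(names), chain, dtype="U2"), coords,
        {"hydrogens": "absent", "generator": "kirgate-synthetic"},
    )


def _gate_openness(state: GatingState, spec: ChannelSpec) -> dict:
    res = sorted(spec.constriction_residues)
    roles = _STATE_GATES[state]
    if len(res) == 3:
        return {res[0]: roles[0], res[1]: roles[1], res[2]: roles[2]}
    if len(res) == 2:
        if state == GatingState.GATE129_CLOSED:
            raise ValueError(
                "GATE129_CLOSED requires a middle constriction residue")
        return {res[0]: roles[0], res[1]: roles[2]}
    raise ValueError("spec must define two or three constriction residues")


def make_channel(params: SyntheticParams, spec: ChannelSpec | None = None,
                 state: GatingState = GatingState.FULLY_OPEN) -> Structure:
    """Noise-free tetramer in the given gating state."""
    spec = spec or ChannelSpec()
    params.validate_margins(spec)
    gate_open = _gate_openness(state, spec)
    uniform_kink = not isinstance(params.kink_angle_deg, Mapping)
    if uniform_kink:
        out = assemble_c4(_monomer(params, spec, "A", gate_open))
    else:
        parts = []
        for k, cid in enumerate(("A", "B", "C", "D")):
            mono = _monomer(params, spec, cid, gate_open)
            rot = Rotation.from_rotvec([0.0, 0.0, np.pi / 2.0 * k])
            mono.coords = rot.apply(mono.coords)
            parts.append(mono)
        out = Structure(
            np.concatenate([p.atom_names for p in parts]),
            np.concatenate([p.elements for p in parts]),
            np.concatenate([p.res_ids for p in parts]),
            np.concatenate([p.res_names for p in parts]),
            np.concatenate([p.chain_ids for p in parts]),
            np.concatenate([p.coords for p in parts]),
            dict(parts[0].metadata),
        )
        out.metadata["symmetric_topology"] = "true"
    out.metadata["gating_state"] = state.value
    return out


def make_ensemble(params: SyntheticParams,
                  spec: ChannelSpec | None = None) -> Ensemble:
    """Labeled ensemble: states drawn i.i.d., Gaussian coordinate noise.

    Fully reproducible from ``params.seed``; labels record the drawn
    ground-truth state of every frame.
    """
    spec = spec or ChannelSpec()
    params.validate_margins(spec)
    rng = np.random.default_rng(params.seed)

    states = [s for s in params.state_probs]
    probs = np.array([params.state_probs[s] for s in states], dtype=float)
    probs = probs / probs.sum()
    draw = rng.choice(len(states), size=params.n_frames, p=probs)
    labels = [states[i] for i in draw]

    bases: dict = {}
    for s in set(labels):
        bases[s] = make_channel(params, spec, state=s)
    topology = next(iter(bases.values()))

    coords = np.empty((params.n_frames, topology.n_atoms, 3))
    for i, s in enumerate(labels):
        noise = rng.normal(0.0, params.coord_noise_sd,
                           size=(topology.n_atoms, 3))
        coords[i] = bases[s].coords + noise

    return Ensemble(topology, coords, labels=labels, source="synthetic")


def write_labels_csv(ensemble: Ensemble, path) -> None:
    """Ground-truth labels as CSV (frame_index, state)."""
    if ensemble.labels is None:
        raise ValueError("ensemble has no labels")
    with open(path, "w") as fh:
        fh.write("frame_index,state\n")
        for i, s in enumerate(ensemble.labels):
            fh.write(f"{i},{s.value}\n")


def read_labels_csv(path) -> list[GatingState]:
    labels = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            _i, s = line.strip().split(",")
            labels.append(GatingState(s))
    return labels
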