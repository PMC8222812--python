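"""Molecular dynamics with excited normal modes (MDeNM) on toy potentials.

The method couples normal modes to dynamics: unit excitation directions
are built as linear combinations of a few selected low-frequency modes,
spread quasi-uniformly over the combination hypersphere, and each
*replica* runs Langevin dynamics during which extra velocities along its
fixed direction are injected periodically.  Each injection carries the
kinetic energy of a prescribed overall temperature rise,
``(3/2)·n_atoms·k_B·ΔT``, and the interval between injections (the
relaxation time) lets the excitation propagate and couple to local
motions.

Potentials are pluggable.  Two toy potentials are provided: a harmonic
elastic network about a reference structure, and the same network with a
radial double well on designated gate atoms, giving the open/close
bistability used to demonstrate that mode-directed excitation crosses
barriers that unbiased thermal dynamics does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._units import KB_KCAL, KE_FACTOR, kinetic_temperature
from .io_structures import Ensemble, Structure
from .enm_modes import ModeSet


@dataclass
class ExcitationConfig:
    """Protocol constants of one MDeNM run.

    Defaults follow the standard protocol: 10 excitations of a 4 K
    overall-temperature rise each, 1 ps of relaxation between
    excitations, a 300 K Langevin bath, 2 fs timestep and 1 ps^-1
    friction.
    """

    n_replicas: int = 62
    n_excitations: int = 10
    delta_T: float = 4.0
    relaxation_time: float = 1.0      # ps
    combination_probe_rmsd: float = 1.0  # Å
    timestep: float = 2.0             # fs
    bath_temperature: float = 300.0   # K
    friction: float = 1.0             # ps^-1
    record_stride: int = 25           # steps between recorded frames
    mass_weight_direction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_replicas", "n_excitations", "relaxation_time",
                     "timestep", "bath_temperature", "friction",
                     "record_stride"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta_T < 0:
            raise ValueError("delta_T must be non-negative")


@dataclass
class ReplicaResult:
    """Output of one replica: its direction, trajectory and bookkeeping."""

    excitation_direction: np.ndarray  # (N, 3), unit Frobenius norm
    trajectory: Ensemble
    injected_energies: list            # kcal/mol per excitation
    kinetic_temperatures: np.ndarray   # per recorded frame, K
    log: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Potentials


class ENMPotential:
    """Harmonic elastic network about a reference structure.

    ``E = 1/2 k Σ_pairs (|r_ij| - |r_ij^0|)²`` over pairs within the
    cutoff in the reference.  Per-pair spring constants may be scaled via
    ``pair_scale`` (callable on the pair index arrays).
    """

    def __init__(self, reference: Structure, cutoff: float = 12.0,
                 spring_k: float = 1.0,
                 pair_k: np.ndarray | None = None):
        self.ref_coords = reference.coords.copy()
        tree = cKDTree(self.ref_coords)
        pairs = np.array(sorted(tree.query_pairs(cutoff)))
        if pairs.size == 0:
            raise ValueError("no pairs within cutoff")
        self.pairs = pairs
        diff = self.ref_coords[pairs[:, 1]] - self.ref_coords[pairs[:, 0]]
        self.d0 = np.linalg.norm(diff, axis=1)
        self.k = (np.full(len(pairs), spring_k) if pair_k is None
                  else np.asarray(pair_k, float))

    def energy_forces(self, coords: np.ndarray):
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        diff = coords[j] - coords[i]
        d = np.linalg.norm(diff, axis=1)
        stretch = d - self.d0
        energy = 0.5 * float(np.dot(self.k, stretch ** 2))
        # force on j along -dE/dr_j = -k*stretch * diff/d
        fpair = (-self.k * stretch / d)[:, None] * diff
        forces = np.zeros_like(coords)
        np.add.at(forces, j, fpair)
        np.add.at(forces, i, -fpair)
        return energy, forces


class DoubleWellGatePotential:
    """Elastic network plus a radial double well on gate atoms.

    Each gate atom feels ``U(ρ) = h·((ρ-c)² - w²)²/w⁴`` in its distance
    ρ from the z axis, with minima at ``c ± w`` (the open and closed gate
    radii) and barrier height ``h`` (kcal/mol).  Elastic-network springs
    touching gate atoms are scaled down so the well, not the network,
    governs the gate coordinate.
    """

    def __init__(self, reference: Structure, gate_indices: np.ndarray,
                 rho_open: float, rho_closed: float,
                 barrier: float = 5.0, cutoff: float = 12.0,
                 spring_k: float = 1.0, gate_spring_scale: float = 0.02):
        self.gate_indices = np.asarray(gate_indices, dtype=int)
        tree = cKDTree(reference.coords)
        pairs = np.array(sorted(tree.query_pairs(cutoff)))
        gate_set = set(self.gate_indices.tolist())
        pair_k = np.full(len(pairs), spring_k)
        touches = np.array([(a in gate_set) or (b in gate_set)
                            for a, b in pairs])
        pair_k[touches] *= gate_spring_scale
        self.enm = ENMPotential(reference, cutoff, spring_k, pair_k)
        self.c = 0.5 * (rho_open + rho_closed)
        self.w = 0.5 * abs(rho_open - rho_closed)
        self.h = barrier

    def energy_forces(self, coords: np.ndarray):
        energy, forces = self.enm.energy_forces(coords)
        g = self.gate_indices
        xy = coords[g, :2]
        rho = np.linalg.norm(xy, axis=1)
        u = (rho - self.c) ** 2 - self.w ** 2
        energy += float(self.h * np.sum(u ** 2) / self.w ** 4)
        # dU/drho = 4h*u*(rho-c)/w^4
        dudrho = 4.0 * self.h * u * (rho - self.c) / self.w ** 4
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(rho[:, None] > 0, xy / rho[:, None], 0.0)
        forces[g, :2] -= dudrho[:, None] * unit
        return energy, forces


# ---------------------------------------------------------------------------
# Mode combination


def _uniform_sphere(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    x = rng.standard_normal((n, dim))
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def expected_uniform_spacing(n_points: int, dim: int,
                             seed: int = 12345) -> float:
    """Mean nearest-neighbour chord distance of uniform points on the
    unit (dim-1)-sphere, estimated by Monte Carlo (deterministic seed)."""
    if dim == 1:
        return 2.0
    rng = np.random.default_rng(seed)
    reps = max(1, 2000 // n_points)
    total = 0.0
    for _ in range(reps):
        pts = _uniform_sphere(rng, n_points, dim)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        total += d.min(axis=1).mean()
    return total / reps


def combine_modes(selected: ModeSet, n_replicas: int,
                  probe_rmsd: float = 1.0, seed: int = 0,
                  min_spacing_factor: float = 0.8,
                  max_tries: int = 500) -> list[np.ndarray]:
    """Unit excitation directions as combinations of the selected modes.

    Coefficient vectors are sampled uniformly on the unit hypersphere and
    accepted only if the structures displaced 1 Å (``probe_rmsd``) along
    them keep a minimum pairwise RMSD — a rejection rule that spreads the
    replicas quasi-uniformly.  With a single mode the hypersphere has two
    points and the directions are ±mode.  Returns (N, 3) arrays of unit
    Frobenius norm.
    """
    k = selected.n_modes
    if k == 0:
        raise ValueError("no selected modes")
    basis = np.stack([selected.mode(i).ravel() for i in range(k)])  # (k, 3N)
    # re-orthonormalise in Cartesian space (mass un-weighting may skew)
    q, _ = np.linalg.qr(basis.T)
    basis = q.T

    if k == 1:
        v = basis[0]
        dirs = [v, -v][:n_replicas]
        if n_replicas > 2:
            warnings.warn("one mode admits only 2 distinct directions")
        return [d.reshape(-1, 3) for d in dirs]

    n_atoms = basis.shape[1] // 3
    spacing = expected_uniform_spacing(n_replicas, k)
    # chord distance on the coefficient sphere maps to displaced-structure
    # RMSD via probe_rmsd (orthonormal basis)
    floor = min_spacing_factor * spacing
    rng = np.random.default_rng(seed)
    coeffs: list[np.ndarray] = []
    tries = 0
    while len(coeffs) < n_replicas and tries < max_tries * n_replicas:
        c = _uniform_sphere(rng, 1, k)[0]
        tries += 1
        if all(np.linalg.norm(c - c0) >= floor for c0 in coeffs):
            coeffs.append(c)
    if len(coeffs) < n_replicas:
        warnings.warn(
            f"placed only {len(coeffs)}/{n_replicas} directions under the "
            f"spacing rule (floor {floor:.3f})")
    return [(c @ basis).reshape(-1, 3) for c in coeffs]


def pairwise_displaced_rmsd(directions, probe_rmsd: float = 1.0) -> np.ndarray:
    """RMSD matrix between structures displaced ``probe_rmsd`` along each
    direction (directions given as (N,3) unit-norm arrays)."""
    flat = np.stack([np.asarray(d).ravel() for d in directions])
    n_atoms = flat.shape[1] // 3
    diff = flat[:, None, :] - flat[None, :, :]
    return probe_rmsd * np.sqrt(n_atoms) * np.linalg.norm(diff, axis=-1) \
        / np.sqrt(n_atoms)


# ---------------------------------------------------------------------------
# Excitation and dynamics


def excite(velocities: np.ndarray, masses: np.ndarray,
           direction: np.ndarray, delta_T: float) -> np.ndarray:
    """Add velocities along ``direction`` carrying the kinetic energy of a
    ``delta_T`` overall-temperature rise: (3/2)·n_atoms·k_B·ΔT.

    The direction is used mass-unweighted; the scaling satisfies the
    energy condition exactly.  ``delta_T = 0`` returns the input.
    """
    d = np.asarray(direction, dtype=np.float64).reshape(-1, 3)
    if np.linalg.norm(d) == 0:
        raise ValueError("zero excitation direction")
    if delta_T == 0:
        return velocities.copy()
    n = d.shape[0]
    e_target = 1.5 * n * KB_KCAL * delta_T
    md2 = float(np.dot(masses, np.einsum("ij,ij->i", d, d)))
    alpha = np.sqrt(2.0 * e_target / (KE_FACTOR * md2))
    return velocities + alpha * d


def injected_energy(masses: np.ndarray, direction: np.ndarray,
                    delta_T: float) -> float:
    """Kinetic energy (kcal/mol) carried by one excitation."""
    n = np.asarray(direction).reshape(-1, 3).shape[0]
    return 1.5 * n * KB_KCAL * delta_T


def _maxwell_velocities(rng, masses, temperature):
    sigma = np.sqrt(KB_KCAL * temperature / (KE_FACTOR * masses))
    return rng.standard_normal((len(masses), 3)) * sigma[:, None]


def run_replica(structure: Structure, potential, direction: np.ndarray,
                config: ExcitationConfig, masses: np.ndarray,
                seed: int | None = None) -> ReplicaResult:
    """One MDeNM replica: Langevin dynamics with periodic excitation.

    The excitation is applied at t=0 and after every relaxation interval,
    ``n_excitations`` times in total; the run ends one relaxation
    interval after the last excitation.  BAOAB Langevin integration;
    reproducible from the seed.  Pass ``delta_T = 0`` (or use
    :func:`run_free`) for plain unexcited dynamics.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    masses = np.asarray(masses, dtype=np.float64)
    d = np.asarray(direction, dtype=np.float64).reshape(-1, 3)
    nd = np.linalg.norm(d)
    if abs(nd - 1.0) > 1e-9:
        raise ValueError("direction must have unit norm")
    if config.mass_weight_direction:
        d = d * np.sqrt(masses)[:, None]
        d = d / np.linalg.norm(d)

    dt = config.timestep * 1e-3  # fs -> ps
    steps_per_interval = max(1, int(round(config.relaxation_time / dt)))
    n_steps = steps_per_interval * config.n_excitations

    coords = structure.coords.copy()
    vel = _maxwell_velocities(rng, masses, config.bath_temperature)

    gamma = config.friction
    c1 = np.exp(-gamma * dt)
    sigma = np.sqrt(KB_KCAL * config.bath_temperature
                    / (KE_FACTOR * masses))[:, None]
    c2 = np.sqrt(1.0 - c1 * c1) * sigma
    inv_m = (1.0 / masses)[:, None] / KE_FACTOR  # force(kcal/mol/Å) -> acc

    energy, forces = potential.energy_forces(coords)
    injected, frames, temps = [], [], []

    for step in range(n_steps):
        if step % steps_per_interval == 0:
            vel = excite(vel, masses, d, config.delta_T)
            injected.append(injected_energy(masses, d, config.delta_T))
        # BAOAB
        vel = vel + 0.5 * dt * forces * inv_m
        coords = coords + 0.5 * dt * vel
        vel = c1 * vel + c2 * rng.standard_normal(vel.shape)
        coords = coords + 0.5 * dt * vel
        energy, forces = potential.energy_forces(coords)
        if not (np.isfinite(energy) and np.isfinite(forces).all()):
            raise RuntimeError(
                f"non-finite energy/forces at step {step} "
                f"(frame {len(frames)})")
        vel = vel + 0.5 * dt * forces * inv_m
        if (step + 1) % config.record_stride == 0:
            frames.append(coords.copy())
            temps.append(kinetic_temperature(masses, vel))

    traj = Ensemble(structure, np.stack(frames) if frames
                    else np.empty((0, structure.n_atoms, 3)),
                    source="mdenm-replica")
    return ReplicaResult(
        excitation_direction=np.asarray(direction).reshape(-1, 3),
        trajectory=traj,
        injected_energies=injected,
        kinetic_temperatures=np.asarray(temps),
        log={"seed": seed, "n_steps": n_steps, "timestep_fs": config.timestep,
             "delta_T": config.delta_T,
             "mass_weight_direction": config.mass_weight_direction,
             "total_injected_kcal_mol": float(np.sum(injected))},
    )


def run_free(structure: Structure, potential, duration_ps: float,
             config: ExcitationConfig, masses: np.ndarray,
             seed: int | None = None) -> ReplicaResult:
    """Plain (unexcited) Langevin run of a given duration."""
    dt = config.timestep * 1e-3
    free_cfg = ExcitationConfig(
        n_replicas=1, n_excitations=1, delta_T=0.0,
        relaxation_time=duration_ps, timestep=config.timestep,
        bath_temperature=config.bath_temperature, friction=config.friction,
        record_stride=config.record_stride,
        seed=config.seed if seed is None else seed)
    dummy = np.zeros((structure.n_atoms, 3))
    dummy[0, 0] = 1.0
    return run_replica(structure, potential, dummy, free_cfg, masses, seed)


@dataclass
class ExplorationFixture:
    """Bistable channel-gate system for excitation-vs-thermal comparisons.

    A reduced channel region (the pore-lining residues plus a margin) on
    a double-well gate potential, with the radial breathing direction of
    the middle-gate side-chain atoms as the excitation mode.  The
    open/closed distance ranges are derived from the construction
    geometry of the underlying synthetic channel.
    """

    structure: Structure
    potential: DoubleWellGatePotential
    direction: np.ndarray          # (N, 3), unit norm, radial breathing
    masses: np.ndarray
    gate_indices: np.ndarray
    gate_chain_order: list
    open_threshold: float          # Å: gate distance above = open range
    closed_threshold: float        # Å: gate distance below = closed range
    #: temperature rise per excitation matched to the toy system's size:
    #: the injected mode energy (3/2·N·kB·ΔT) scales with N, so a
    #: hundred-atom fixture needs a larger ΔT than a 10^5-atom channel
    #: for a comparable energy-to-barrier ratio
    excitation_delta_T: float = 30.0

    def gate_distances(self, coords: np.ndarray):
        """Diametric (A-C, B-D) gate-atom distances for one frame."""
        pos = coords[self.gate_indices]
        idx = {c: i for i, c in enumerate(self.gate_chain_order)}
        return (float(np.linalg.norm(pos[idx["A"]] - pos[idx["C"]])),
                float(np.linalg.norm(pos[idx["B"]] - pos[idx["D"]])))

    def distance_series(self, ensemble: Ensemble) -> np.ndarray:
        return np.array([self.gate_distances(c) for c in ensemble.coords])


def make_exploration_fixture(params=None, spec=None,
                             residue_window: tuple[int, int] = (115, 140),
                             barrier: float = 5.0,
                             gate_residue: int = 129) -> ExplorationFixture:
    """Build the double-well channel fixture.

    The barrier (kcal/mol per gate atom, default 5 ≈ 8 kT at 300 K)
    makes spontaneous thermal crossings negligible on the 10 ps scale,
    while mode-directed excitation carries enough energy to drive the
    concerted open↔closed transition.
    """
    from .io_structures import ChannelSpec, select
    from .synthetic_data import SyntheticParams, make_channel

    params = params or SyntheticParams()
    spec = spec or ChannelSpec()
    full = make_channel(params, spec)  # fully open
    sub = select(full, residues=residue_window)
    gate_idx = np.where((sub.res_ids == gate_residue)
                        & (sub.atom_names == "SC"))[0]
    if gate_idx.size != 4:
        raise ValueError(f"expected 4 gate atoms at residue {gate_residue}")
    rho_open = params.gate_radius_open - params.pseudo_atom_radius
    rho_closed = params.gate_radius_closed - params.pseudo_atom_radius
    potential = DoubleWellGatePotential(sub, gate_idx, rho_open, rho_closed,
                                        barrier=barrier)
    direction = np.zeros((sub.n_atoms, 3))
    for i in gate_idx:
        xy = sub.coords[i, :2]
        direction[i, :2] = xy / np.linalg.norm(xy)
    direction /= np.linalg.norm(direction)
    d_open = 2.0 * rho_open
    d_closed = 2.0 * rho_closed
    return ExplorationFixture(
        structure=sub, potential=potential, direction=direction,
        masses=default_masses(sub), gate_indices=gate_idx,
        gate_chain_order=[str(c) for c in sub.chain_ids[gate_idx]],
        open_threshold=d_open - 0.25 * (d_open - d_closed),
        closed_threshold=d_closed + 0.2 * (d_open - d_closed),
    )


def default_masses(structure: Structure) -> np.ndarray:
    """Per-atom masses (amu): residue-scale for CA pseudo-atoms,
    side-chain-scale for SC pseudo-atoms, else rough element masses."""
    table = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
    out = np.empty(structure.n_atoms)
    for i, (name, elem) in enumerate(zip(structure.atom_names,
                                         structure.elements)):
        if name == "CA" and structure.metadata.get("generator"):
            out[i] = 110.0
        elif name == "SC":
            out[i] = 50.0
        else:
            out[i] = table.get(str(elem), 12.011)
    return out
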