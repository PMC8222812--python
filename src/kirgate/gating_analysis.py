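"""Gate distances, five-state gating classification, and population tables.

The channel's conduction pathway is gated at three constriction residues
(by default 124, 129 and 132).  A gate is *open* when the shortest
diametrically-opposed inter-chain atomic distance at that residue exceeds
the unhydrated K+ ionic diameter (3.5275 Å); the comparison is strict, so
a distance exactly at the threshold counts as closed.  Frames are placed
in a five-state taxonomy:

* ``FULLY_OPEN`` — 124, 132 and 129 all open;
* ``GATE129_CLOSED`` — 124 and 132 open but the 129 side chains occlude
  the pore (the closed category characteristic of an engineered
  arginine at position 129);
* ``PARTIAL_124_OPEN_132_CLOSED`` / ``PARTIAL_132_OPEN_124_CLOSED`` —
  one main gate open, the other closed;
* ``FULLY_CLOSED`` — both main gates closed.

The 124/132 pattern takes precedence over the 129 gate, whose open/closed
status is additionally reported in its own column.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io_structures import ChannelSpec, Ensemble, SelectionError, Structure


class GatingState(enum.Enum):
    FULLY_OPEN = "fully_open"
    FULLY_CLOSED = "fully_closed"
    PARTIAL_124_OPEN_132_CLOSED = "partial_124_open_132_closed"
    PARTIAL_132_OPEN_124_CLOSED = "partial_132_open_124_closed"
    GATE129_CLOSED = "gate129_closed"


#: Row order used in population tables.
STATE_ORDER = (
    GatingState.FULLY_OPEN,
    GatingState.FULLY_CLOSED,
    GatingState.PARTIAL_124_OPEN_132_CLOSED,
    GatingState.PARTIAL_132_OPEN_124_CLOSED,
    GatingState.GATE129_CLOSED,
)


@dataclass
class GateDistances:
    """The six shortest gate distances (Å), keyed (residue, chain pair)."""

    values: dict

    def at(self, residue: int) -> tuple[float, ...]:
        return tuple(v for (r, _pair), v in self.values.items() if r == residue)

    def min_at(self, residue: int) -> float:
        return min(self.at(residue))

    def max_at(self, residue: int) -> float:
        return max(self.at(residue))


@dataclass
class PopulationTable:
    """Per-state percentages over an ensemble."""

    percentages: dict
    n_frames: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if self.n_frames and abs(total - 100.0) > 0.1:
            raise ValueError(f"percentages sum to {total}, expected 100")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(s.value, self.percentages.get(s, 0.0)) for s in STATE_ORDER]
        return pd.DataFrame(rows, columns=["state", "percent"])


def shortest_distance(structure: Structure, res_a: tuple[int, str],
                      res_b: tuple[int, str]) -> float:
    """Minimum atom-atom distance (Å) between two residues.

    ``res_a``/``res_b`` are ``(residue_number, chain_id)``.  All atoms of
    each residue participate, hydrogens included when present.
    """
    coords = []
    for resid, chain in (res_a, res_b):
        m = (structure.res_ids == resid) & (structure.chain_ids == chain)
        if not m.any():
            raise SelectionError(f"residue {resid} chain {chain} not found")
        coords.append(structure.coords[m])
    diff = coords[0][:, None, :] - coords[1][None, :, :]
    # explicit left-to-right sum: reduction order is part of the contract
    # (results are compared exactly against a scalar-loop evaluation)
    d2 = diff[..., 0] ** 2 + diff[..., 1] ** 2 + diff[..., 2] ** 2
    return float(np.sqrt(d2.min()))


def gate_distances(structure: Structure, spec: ChannelSpec) -> GateDistances:
    """The shortest distances at each constriction residue and gate pair."""
    values = {}
    for resid in spec.constriction_residues:
        for pair in spec.gate_pairs:
            values[(resid, pair)] = shortest_distance(
                structure, (resid, pair[0]), (resid, pair[1])
            )
    return GateDistances(values)


def _gate_open(d: GateDistances, residue: int, spec: ChannelSpec,
               open_rule: str) -> bool:
    threshold = spec.ionic_diameter
    if open_rule == "min":
        return d.min_at(residue) > threshold
    if open_rule == "either":
        return d.max_at(residue) > threshold
    raise ValueError(f"unknown open_rule {open_rule!r}")


def classify_state(d: GateDistances, spec: ChannelSpec,
                   open_rule: str = "min") -> GatingState:
    """Assign the gating state from the six gate distances.

    ``open_rule='min'`` (default) requires both diametric pairs of a gate
    to exceed the ionic diameter — an ion cannot pass a gate closed on
    either diagonal; ``'either'`` opens the gate if one pair suffices.
    """
    r124, r129, r132 = _ordered_gates(spec)
    open_124 = _gate_open(d, r124, spec, open_rule)
    open_132 = _gate_open(d, r132, spec, open_rule)
    open_129 = _gate_open(d, r129, spec, open_rule) if r129 is not None else True

    if open_124 and open_132:
        return GatingState.FULLY_OPEN if open_129 else GatingState.GATE129_CLOSED
    if open_124:
        return GatingState.PARTIAL_124_OPEN_132_CLOSED
    if open_132:
        return GatingState.PARTIAL_132_OPEN_124_CLOSED
    return GatingState.FULLY_CLOSED


def _ordered_gates(spec: ChannelSpec):
    """Map constriction residues onto (lower main gate, middle, upper).

    With the default residues this is (124, 129, 132).  When only two
    residues are specified they act as the two main gates and the middle
    (129-style) gate is absent.
    """
    res = sorted(spec.constriction_residues)
    if len(res) == 3:
        return res[0], res[1], res[2]
    if len(res) == 2:
        return res[0], None, res[1]
    raise ValueError("spec must define two or three constriction residues")


def classify_ensemble(ensemble: Ensemble, spec: ChannelSpec,
                      open_rule: str = "min") -> list[GatingState]:
    """Per-frame gating states."""
    return [classify_state(gate_distances(f, spec), spec, open_rule)
            for f in ensemble]


def population_table(ensemble: Ensemble, spec: ChannelSpec,
                     open_rule: str = "min",
                     states: list[GatingState] | None = None) -> PopulationTable:
    """Percentage of frames in each gating state.

    ``states`` may supply precomputed per-frame states (e.g. generator
    labels); otherwise every frame is classified.
    """
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    if states is None:
        states = classify_ensemble(ensemble, spec, open_rule)
    counts = {s: 0 for s in STATE_ORDER}
    for s in states:
        counts[s] += 1
    n = len(states)
    percentages = {s: 100.0 * c / n for s, c in counts.items()}
    return PopulationTable(percentages, n,
                           {"open_rule": open_rule,
                            "hydrogens": ensemble.topology.metadata.get(
                                "hydrogens", "unknown")})


def per_frame_table(ensemble: Ensemble, spec: ChannelSpec,
                    open_rule: str = "min") -> pd.DataFrame:
    """Long table: frame index, the six gate distances, and the state."""
    rows = []
    for i, frame in enumerate(ensemble):
        d = gate_distances(frame, spec)
        state = classify_state(d, spec, open_rule)
        row = {"frame": i, "state": state.value}
        for (resid, pair), v in d.values.items():
            row[f"d{resid}_{pair[0]}{pair[1]}"] = v
        r124, r129, r132 = _ordered_gates(spec)
        if r129 is not None:
            row["gate129_open"] = _gate_open(d, r129, spec, open_rule)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distance series and distributions


def adjacent_chain_pairs(residue: int, chains=("A", "B", "C", "D")):
    """Cyclic (chain n, chain n+1) pairs of one residue."""
    n = len(chains)
    return [((residue, chains[i]), (residue, chains[(i + 1) % n]))
            for i in range(n)]


def same_chain_pairs(res_a: int, res_b: int, chains=("A", "B", "C", "D")):
    """Intra-chain pairs between two residues, one per chain."""
    return [((res_a, c), (res_b, c)) for c in chains]


def distance_series(ensemble: Ensemble, pairs) -> pd.DataFrame:
    """Shortest-distance series over frames for a list of residue pairs.

    ``pairs`` is a list of ``((res, chain), (res, chain))`` tuples, e.g.
    from :func:`adjacent_chain_pairs` or :func:`same_chain_pairs`.
    Returns a long DataFrame (frame, pair, distance).
    """
    rows = []
    for i, frame in enumerate(ensemble):
        for a, b in pairs:
            rows.append({
                "frame": i,
                "pair": f"{a[0]}{a[1]}-{b[0]}{b[1]}",
                "distance": shortest_distance(frame, a, b),
            })
    return pd.DataFrame(rows)


def distance_histogram(series: pd.DataFrame | np.ndarray,
                       bin_width: float = 0.2):
    """Histogram of a distance series with a fixed bin width (Å)."""
    values = (series["distance"].to_numpy()
              if isinstance(series, pd.DataFrame) else np.asarray(series))
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges


def distance_density(series: pd.DataFrame | np.ndarray,
                     grid: np.ndarray | None = None,
                     bandwidth: str | float = "scott"):
    """Gaussian kernel density of a distance series.

    Bandwidth follows the standard plug-in ('scott') rule unless a scalar
    factor is given.  Returns (grid, density).
    """
    values = (series["distance"].to_numpy()
              if isinstance(series, pd.DataFrame) else np.asarray(series))
    kde = gaussian_kde(values, bw_method=bandwidth)
    if grid is None:
        pad = 3.0 * values.std() + 0.5
        grid = np.linspace(values.min() - pad, values.max() + pad, 512)
    return grid, kde(grid)
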