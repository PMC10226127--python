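"""Nonequilibrium condensate aging: LARKS beta-sheet transitions and networks.

Low-complexity aromatic-rich kinked segments (LARKS) in protein low-
complexity domains form interprotein beta-sheets at high local density,
progressively rigidifying a condensate.  The aging algorithm recapitulates
this as a density-triggered, irreversible strengthening of interactions:

* every ``stride`` simulation steps, each fully disordered LARKS is tested;
  when its central C-alpha bead lies within the capture cutoff of the
  central beads of (at least) ``partners`` other disordered LARKS on
  distinct chains, a disorder-to-order transition fires;
* the transition binds the triggering LARKS with its ``partners`` nearest
  neighbors, enhancing the pairwise interaction strength among the four
  LARKS (the strengthened parameters are inputs: the physical magnitudes
  come from atomistic potential-of-mean-force work; a deliberately
  non-physical x4 toy default ships for tests);
* transitions are irreversible, and the strengthened LARKS-LARKS pairs form
  an undirected cross-beta network.

Two analyses characterize the matured network:

* primitive path analysis (PPA): with the beta-sheet-bound beads frozen in
  space, bond rest lengths set to zero and intrachain excluded volume
  removed, minimizing the strand contour length reveals the load-bearing
  network geometry;
* percolation: a cluster spans an axis when, traversed with periodic image
  bookkeeping, it reconnects to itself with a nonzero winding vector.

A chain needs several anchoring points to gelate: chains with a single
LARKS can only form star-like clusters, while three LARKS per chain (as in
the FUS low-complexity domain) allow a system-spanning network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .engine import Simulation, SimulationState

__all__ = [
    "LARKSDefinition",
    "TransitionRule",
    "TransitionEvent",
    "CrossBetaNetwork",
    "detect_transitions",
    "apply_transition",
    "transition_fraction",
    "primitive_path_analysis",
    "percolation_check",
    "AgingSimulation",
    "FUS_LCD_LARKS",
    "HNRNPA1_LCD_LARKS",
    "TDP43_LCD_LARKS",
]

# LARKS segments (residue index ranges, 1-based inclusive) in the three
# low-complexity domains commonly studied for condensate maturation
FUS_LCD_LARKS = {"segments": [(37, 42), (54, 61), (77, 82)],
                 "sequences": ["SYSGYS", "SYSSYGQS", "STGGYG"]}
HNRNPA1_LCD_LARKS = {"segments": [(58, 63)], "sequences": ["GYNGFG"]}
TDP43_LCD_LARKS = {"segments": [(58, 63)], "sequences": ["NFGAFS"]}


@dataclass
class LARKSDefinition:
    """LARKS instances across all chains of a system.

    ``centers[k]`` is the global bead index of the central C-alpha bead of
    LARKS instance k; ``chain_ids[k]`` its chain; ``segments[k]`` the global
    (start, end) bead range (inclusive).  Instances are ordered by
    (chain, segment).
    """

    centers: np.ndarray
    chain_ids: np.ndarray
    segments: list[tuple[int, int]]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.int64)
        self.chain_ids = np.asarray(self.chain_ids, dtype=np.int64)
        prev_end: dict[int, int] = {}
        for k, (a, b) in enumerate(self.segments):
            if not a <= self.centers[k] <= b:
                raise ValueError(f"central bead of LARKS {k} outside segment")
            c = int(self.chain_ids[k])
            if c in prev_end and a <= prev_end[c]:
                raise ValueError(f"overlapping LARKS segments on chain {c}")
            prev_end[c] = b

    @property
    def n(self) -> int:
        return len(self.centers)

    @classmethod
    def from_per_chain(cls, n_chains: int, beads_per_chain: int,
                       per_chain_segments: list[tuple[int, int]],
                       labels: list[str] | None = None) -> "LARKSDefinition":
        """Replicate per-chain segment definitions (0-based, inclusive)."""
        centers, chains, segments = [], [], []
        for c in range(n_chains):
            off = c * beads_per_chain
            for a, b in per_chain_segments:
                if not (0 <= a <= b < beads_per_chain):
                    raise ValueError(f"segment ({a},{b}) outside chain")
                segments.append((off + a, off + b))
                centers.append(off + (a + b) // 2)
                chains.append(c)
        return cls(centers=np.array(centers), chain_ids=np.array(chains),
                   segments=segments,
                   labels=list(labels or []) * n_chains)


@dataclass
class TransitionRule:
    """Trigger rule for disorder-to-order LARKS transitions."""

    cutoff: float = 2.0  # capture distance for central beads (model units)
    partners: int = 3
    stride: int = 100
    strength_factor: float = 4.0  # toy default, non-physical; supply real PMF values
    irreversible: bool = True

    def __post_init__(self) -> None:
        if self.partners < 1:
            raise ValueError("partners must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class TransitionEvent:
    """One disorder-to-order transition binding a LARKS with its partners."""

    center_larks: int
    partner_larks: tuple[int, ...]
    time: float

    @property
    def members(self) -> tuple[int, ...]:
        return (self.center_larks, *self.partner_larks)


class CrossBetaNetwork:
    """Undirected graph of strengthened LARKS-LARKS beta-sheet bonds.

    Nodes are LARKS instances; edges carry their formation time.  Intra-chain
    connectivity (successive LARKS along one chain, linked by the backbone)
    is added for cluster/percolation analysis but marked ``backbone=True``.
    """

    def __init__(self, larks: LARKSDefinition):
        self.larks = larks
        self.graph = nx.Graph()
        for k in range(larks.n):
            self.graph.add_node(k, chain=int(larks.chain_ids[k]),
                                ordered=False)
        # backbone edges between consecutive LARKS of the same chain
        by_chain: dict[int, list[int]] = {}
        for k in range(larks.n):
            by_chain.setdefault(int(larks.chain_ids[k]), []).append(k)
        for nodes in by_chain.values():
            nodes.sort(key=lambda k: larks.segments[k][0])
            for a, b in zip(nodes, nodes[1:]):
                self.graph.add_edge(a, b, backbone=True, time=-1.0)
        self._event_times: list[float] = []

    def is_ordered(self, k: int) -> bool:
        return bool(self.graph.nodes[k]["ordered"])

    @property
    def ordered_count(self) -> int:
        return sum(1 for k in self.graph.nodes
                   if self.graph.nodes[k]["ordered"])

    def add_event(self, event: TransitionEvent) -> None:
        if self._event_times and event.time < self._event_times[-1]:
            raise ValueError("event formation times must be non-decreasing")
        for k in event.members:
            self.graph.nodes[k]["ordered"] = True
        for k in event.members:
            for j in event.members:
                if j > k:
                    self.graph.add_edge(k, j, backbone=False, time=event.time)
        self._event_times.append(event.time)

    def beta_sheet_edges(self) -> list[tuple[int, int, float]]:
        return [(a, b, d["time"]) for a, b, d in self.graph.edges(data=True)
                if not d.get("backbone", False)]


def detect_transitions(state: SimulationState, larks: LARKSDefinition,
                       rule: TransitionRule, network: CrossBetaNetwork,
                       time: float | None = None) -> list[TransitionEvent]:
    """Find and arbitrate disorder-to-order transitions at this evaluation.

    For each fully disordered LARKS (in ascending (chain, segment) order, the
    deterministic arbitration order), the distinct disordered LARKS on other
    chains whose central beads lie within the cutoff are counted; with at
    least ``rule.partners`` of them, an event binds the LARKS with its
    ``partners`` nearest neighbors.  LARKS consumed by an earlier event in
    the same evaluation are skipped (re-evaluated next stride).  Events are
    irreversible and are applied to the network as they fire.
    """
    t = state.time if time is None else time
    centers = state.positions[larks.centers]
    box = state.box
    events: list[TransitionEvent] = []
    consumed: set[int] = set()
    for k in range(larks.n):
        if network.is_ordered(k) or k in consumed:
            continue
        d = centers - centers[k]
        for a in range(3):
            d[:, a] -= np.rint(d[:, a] / box[a]) * box[a]
        dist = np.sqrt((d**2).sum(axis=1))
        cand = [
            (dist[j], j) for j in range(larks.n)
            if j != k
            and larks.chain_ids[j] != larks.chain_ids[k]
            and dist[j] <= rule.cutoff
            and not network.is_ordered(j)
            and j not in consumed
        ]
        if len(cand) < rule.partners:
            continue
        cand.sort()
        chosen = tuple(j for _, j in cand[:rule.partners])
        ev = TransitionEvent(center_larks=k, partner_larks=chosen, time=t)
        network.add_event(ev)
        consumed.update(ev.members)
        events.append(ev)
    return events


def apply_transition(event: TransitionEvent, sim: Simulation,
                     larks: LARKSDefinition,
                     strong_matrix: np.ndarray,
                     factor: float) -> None:
    """Install the strengthened pairwise interactions of one event.

    All LARKS-LARKS pairs among the event's members get their interaction
    strength swapped to the strengthened set (well depth scaled by
    ``factor``); the swap is permanent.  The simulation must have been
    prepared with :func:`install_aging` so its kernels know the per-bead
    LARKS ids.
    """
    if strong_matrix is None:
        raise ValueError("strengthened-parameter table missing")
    for k in event.members:
        for j in event.members:
            if j != k:
                strong_matrix[k, j] = 1
    sim.set_aging_tables(sim.larks_id, strong_matrix, factor)


def install_aging(sim: Simulation, larks: LARKSDefinition,
                  rule: TransitionRule) -> tuple[CrossBetaNetwork, np.ndarray]:
    """Prepare a simulation for aging: per-bead LARKS ids + empty network."""
    larks_id = np.full(sim.state.n, -1, dtype=np.int64)
    for k, (a, b) in enumerate(larks.segments):
        larks_id[a:b + 1] = k
    strong = np.zeros((larks.n, larks.n), dtype=np.uint8)
    sim.set_aging_tables(larks_id, strong, rule.strength_factor)
    return CrossBetaNetwork(larks), strong


class AgingSimulation:
    """Runs MD in stride-sized chunks, firing LARKS transitions in between."""

    def __init__(self, sim: Simulation, larks: LARKSDefinition,
                 rule: TransitionRule):
        self.sim = sim
        self.larks = larks
        self.rule = rule
        self.network, self._strong = install_aging(sim, larks, rule)
        self.events: list[TransitionEvent] = []
        self.fraction_history: list[tuple[float, float]] = []

    def run(self, n_steps: int, stress_stride: int = 0):
        """Advance ``n_steps``, evaluating the trigger every rule.stride."""
        logs = []
        done = 0
        while done < n_steps:
            chunk = min(self.rule.stride, n_steps - done)
            log, _ = self.sim.run(chunk, stress_stride=stress_stride or 0)
            logs.append(log)
            new = detect_transitions(self.sim.state, self.larks, self.rule,
                                     self.network)
            for ev in new:
                apply_transition(ev, self.sim, self.larks, self._strong,
                                 self.rule.strength_factor)
            self.events.extend(new)
            self.fraction_history.append(
                (self.sim.state.time,
                 transition_fraction(self.network, self.larks)))
            done += chunk
        return logs


def transition_fraction(network: CrossBetaNetwork,
                        larks: LARKSDefinition) -> float:
    """Percentage of LARKS that have undergone the beta-sheet transition."""
    if larks.n == 0:
        return 0.0
    return 100.0 * network.ordered_count / larks.n


# ---------------------------------------------------------------------------
# Primitive path analysis
# ---------------------------------------------------------------------------

def primitive_path_analysis(
    positions: np.ndarray, bonds: np.ndarray, frozen: np.ndarray,
    box: np.ndarray | None = None, k_bond: float = 1.0,
    max_iter: int = 2000, f_tol: float = 1e-8, step0: float = 0.05,
) -> dict:
    """Minimize strand contour length with crosslinked beads frozen in space.

    Bonds act as zero-rest-length springs and intrachain excluded volume is
    absent, so each strand between frozen anchors relaxes to the straight
    segment (the primitive path).  Steepest descent with backtracking: a
    step is only accepted if the total contour length does not increase,
    which makes the descent monotonic by construction.

    Returns a dict with the minimized ``positions``, per-iteration
    ``contour_lengths``, ``converged`` flag and the per-bond final lengths.
    Positions are treated as unwrapped; pass ``box`` only to re-wrap the
    *output* for visualization.
    """
    pos = np.array(positions, dtype=np.float64)
    frozen = np.asarray(frozen, dtype=bool)
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    free = ~frozen

    def contour() -> float:
        d = pos[bonds[:, 0]] - pos[bonds[:, 1]]
        return float(np.sqrt((d**2).sum(axis=1)).sum())

    def forces() -> np.ndarray:
        f = np.zeros_like(pos)
        d = pos[bonds[:, 0]] - pos[bonds[:, 1]]
        # harmonic with r0 = 0: F = -2k r
        np.add.at(f, bonds[:, 0], -2.0 * k_bond * d)
        np.add.at(f, bonds[:, 1], 2.0 * k_bond * d)
        f[frozen] = 0.0
        return f

    lengths = [contour()]
    step = step0
    converged = False
    for _ in range(max_iter):
        f = forces()
        fmax = float(np.max(np.abs(f))) if f.size else 0.0
        if fmax < f_tol:
            converged = True
            break
        trial_step = min(step, 0.5 / max(fmax, 1e-12))
        for _ in range(20):  # backtrack until contour does not increase
            new_pos = pos + trial_step * f * free[:, None]
            d = new_pos[bonds[:, 0]] - new_pos[bonds[:, 1]]
            new_len = float(np.sqrt((d**2).sum(axis=1)).sum())
            if new_len <= lengths[-1] + 1e-12:
                break
            trial_step *= 0.5
        else:
            converged = True  # cannot descend further
            break
        pos = new_pos
        lengths.append(new_len)
        step = min(trial_step * 1.5, 0.5)
    if not converged and len(lengths) > 50:
        # practical convergence: contour stopped changing
        converged = lengths[-50] - lengths[-1] < 1e-10 * max(lengths[0], 1e-12)
    d = pos[bonds[:, 0]] - pos[bonds[:, 1]]
    bond_lengths = np.sqrt((d**2).sum(axis=1))
    return {"positions": pos, "contour_lengths": np.array(lengths),
            "converged": converged, "bond_lengths": bond_lengths}


def replicate_for_visualization(positions: np.ndarray, box: np.ndarray,
                                reps: int = 3) -> np.ndarray:
    """Periodic replication (reps^3 images) for network visualization."""
    shifts = np.arange(reps) - reps // 2
    out = []
    for ix in shifts:
        for iy in shifts:
            for iz in shifts:
                out.append(positions + np.array([ix, iy, iz]) * box)
    return np.vstack(out)


# ---------------------------------------------------------------------------
# Percolation
# ---------------------------------------------------------------------------

def percolation_check(network: CrossBetaNetwork, positions: np.ndarray,
                      box: np.ndarray) -> dict:
    """Winding-number percolation test of the cross-beta network.

    A cluster spans an axis when a breadth-first traversal with periodic
    image bookkeeping reaches an already-visited node with a different image
    vector along that axis (the cluster connects to its own periodic image).
    ``positions`` are the coordinates of each LARKS central bead (wrapped or
    not).  Returns per-axis spanning flags and the largest-cluster fraction.
    """
    box = np.asarray(box, dtype=np.float64)
    g = network.graph
    spanning = np.zeros(3, dtype=bool)
    visited: dict[int, np.ndarray] = {}
    largest = 0
    for comp in nx.connected_components(g):
        comp = list(comp)
        largest = max(largest, len(comp))
        root = comp[0]
        visited[root] = np.zeros(3)
        queue = [root]
        while queue:
            a = queue.pop()
            for b in g.neighbors(a):
                # minimum-image displacement between LARKS centers
                raw = positions[b] - positions[a]
                img = np.rint(raw / box)
                disp = raw - img * box
                coord = visited[a] + disp
                if b in visited:
                    wind = coord - visited[b]
                    for ax in range(3):
                        if abs(wind[ax]) > 0.5 * box[ax]:
                            spanning[ax] = True
                else:
                    visited[b] = coord
                    queue.append(b)
    return {"spans": spanning, "spans_any": bool(spanning.any()),
            "largest_cluster_fraction": largest / max(g.number_of_nodes(), 1)}
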