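"""Forward-time simulation of trees with a co-evolving binary character.

The generator is an exact continuous-time (Gillespie) simulation. At any
instant the total event rate is the sum over living lineages of the rates
available to that lineage in its current state (speciation, extinction, and
a state flip); the waiting time to the next event is exponential with that
total rate, and the event type and lineage are drawn with probability
proportional to their rate contributions. The process starts from a single
stem lineage whose state is drawn from the stationary frequency by default,
and stops the first instant the number of living lineages reaches the
requested tip count, with every terminal branch extended to that instant so
tips are contemporaneous. If the whole clade dies first the simulation is
restarted with fresh randomness (bounded by a retry cap).

`prune_extinct` converts the raw simulation record into the reconstructed
extant-only tree the likelihood consumes: extinct lineages are removed,
pass-through nodes are suppressed (lengths summed), and the stem above the
most recent common ancestor of the survivors is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rates import RateSet
from .scenarios import Scenario
from .stationary import stationary_state0_freq
from .trees import PhyloTree, tip_state_summary


class ExtinctionRetryError(RuntimeError):
    """All lineages went extinct more often than the retry cap allows."""


@dataclass
class SimTree:
    """Raw record of one forward simulation (including extinct lineages).

    Node arrays are parallel lists indexed by node id; the root is node 0.
    ``history[i]`` is the piecewise-constant state record of node i as a
    list of (time, state) pairs starting at the node's birth.
    """

    parent: list[int] = field(default_factory=list)
    birth: list[float] = field(default_factory=list)
    end: list[float] = field(default_factory=list)
    children: list[list[int]] = field(default_factory=list)
    extinct: list[bool] = field(default_factory=list)
    history: list[list[tuple[float, int]]] = field(default_factory=list)
    stop_time: float = 0.0
    n_retries: int = 0

    def add_node(self, parent: int, t: float, state: int) -> int:
        i = len(self.parent)
        self.parent.append(parent)
        self.birth.append(t)
        self.end.append(np.nan)
        self.children.append([])
        self.extinct.append(False)
        self.history.append([(t, state)])
        if parent >= 0:
            self.children[parent].append(i)
        return i

    def state_at_end(self, i: int) -> int:
        return self.history[i][-1][1]

    @property
    def extant_tips(self) -> list[int]:
        return [i for i in range(len(self.parent))
                if not self.children[i] and not self.extinct[i]]

    @property
    def extant_count(self) -> int:
        return len(self.extant_tips)


def _root_state(rates: RateSet, mode: str, rng: np.random.Generator) -> int:
    if mode == "fixed0":
        return 0
    if mode == "fixed1":
        return 1
    if mode == "stationary":
        x0 = stationary_state0_freq(rates).x_hat
        return 0 if rng.random() < x0 else 1
    raise ValueError(f"unknown root_state_mode {mode!r}")


def simulate_tree(
    rates: RateSet,
    n_tips: int,
    rng: np.random.Generator,
    root_state_mode: str = "stationary",
    max_retries: int = 1000,
) -> SimTree:
    """Simulate until the living-lineage count first reaches ``n_tips``."""
    if n_tips < 3:
        raise ValueError(f"n_tips must be >= 3, got {n_tips}")
    la = (rates.lambda0, rates.lambda1)
    mu = (rates.mu0, rates.mu1)
    q = (rates.q01, rates.q10)
    per_state_total = (la[0] + mu[0] + q[0], la[1] + mu[1] + q[1])

    for attempt in range(max_retries + 1):
        sim = SimTree()
        sim.n_retries = attempt
        t = 0.0
        root_state = _root_state(rates, root_state_mode, rng)
        root = sim.add_node(-1, 0.0, root_state)
        # living lineages, partitioned by current state
        extant: list[list[int]] = [[], []]
        extant[root_state].append(root)
        n_alive = 1

        alive = True
        while True:
            n0, n1 = len(extant[0]), len(extant[1])
            total = n0 * per_state_total[0] + n1 * per_state_total[1]
            if total <= 0.0:
                # no events possible (e.g. all rates zero in occupied state)
                raise RuntimeError("total event rate is zero; cannot proceed")
            t += rng.exponential(1.0 / total)
            # event category: (state, kind) with kind in {speciate, die, flip}
            u = rng.random() * total
            s = 0
            if u >= n0 * per_state_total[0]:
                u -= n0 * per_state_total[0]
                s = 1
            ns = len(extant[s])
            u /= ns
            lin_idx = int(rng.integers(ns))
            node = extant[s][lin_idx]

            if u < la[s]:  # speciation
                sim.end[node] = t
                # swap-pop removal, then append the two daughters
                extant[s][lin_idx] = extant[s][-1]
                extant[s].pop()
                for _ in range(2):
                    child = sim.add_node(node, t, s)
                    extant[s].append(child)
                n_alive += 1
                if n_alive == n_tips:
                    sim.stop_time = t
                    for st in (0, 1):
                        for i in extant[st]:
                            sim.end[i] = t
                    return sim
            elif u < la[s] + mu[s]:  # extinction
                sim.end[node] = t
                sim.extinct[node] = True
                extant[s][lin_idx] = extant[s][-1]
                extant[s].pop()
                n_alive -= 1
                if n_alive == 0:
                    alive = False
                    break
            else:  # character flip
                extant[s][lin_idx] = extant[s][-1]
                extant[s].pop()
                extant[1 - s].append(node)
                sim.history[node].append((t, 1 - s))
        if not alive:
            continue
    raise ExtinctionRetryError(
        f"clade went extinct {max_retries + 1} times before reaching "
        f"{n_tips} tips")


def prune_extinct(sim: SimTree) -> PhyloTree:
    """Reconstructed extant-only tree.

    Extinct lineages are removed, pass-through (single-surviving-child)
    nodes are suppressed with branch lengths summed, and the stem above the
    most recent common ancestor of the survivors is discarded. Tip states
    are the simulated states at the final instant.
    """
    import sys

    n_nodes = len(sim.parent)
    tips = sim.extant_tips
    if len(tips) < 2:
        raise ValueError(f"need >= 2 extant tips to prune, got {len(tips)}")

    survives = [False] * n_nodes
    for i in tips:
        j = i
        while j >= 0 and not survives[j]:
            survives[j] = True
            j = sim.parent[j]

    def surviving_children(node: int) -> list[int]:
        return [c for c in sim.children[node] if survives[c]]

    def anchor(node: int) -> int:
        # descend through pass-through nodes to a surviving tip or fork
        while True:
            kids = surviving_children(node)
            if len(kids) != 1:
                return node
            node = kids[0]

    crown = anchor(0)

    n_out = len(tips)
    tip_sim: list[int] = []
    internal_sim: list[int] = []
    children_rows: list[list[int]] = []

    def build(node: int) -> int:
        kids = surviving_children(node)
        if not kids:
            tip_sim.append(node)
            return len(tip_sim) - 1
        left = build(anchor(kids[0]))
        right = build(anchor(kids[1]))
        internal_sim.append(node)
        children_rows.append([left, right])
        return n_out + len(children_rows) - 1

    limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(limit, 4 * n_out + 1000))
    try:
        root_id = build(crown)
    finally:
        sys.setrecursionlimit(limit)
    assert root_id == 2 * n_out - 2

    end_time = np.array([sim.end[i] for i in tip_sim + internal_sim])
    children = np.asarray(children_rows, dtype=np.int64)
    lengths = np.zeros(2 * n_out - 1)
    for k in range(n_out - 1):
        p = n_out + k
        for c in children[k]:
            lengths[c] = end_time[c] - end_time[p]
    tip_states = np.array([sim.state_at_end(i) for i in tip_sim], dtype=np.int64)
    tree = PhyloTree(n_tips=n_out, children=children, lengths=lengths,
                     tip_states=tip_states)
    tree.check_ultrametric()
    return tree


def batch_rng(base_seed: int, replicate: int) -> np.random.Generator:
    """The documented per-replicate stream: seeded from the pair
    (base_seed, replicate) via numpy's SeedSequence."""
    return np.random.default_rng([int(base_seed), int(replicate)])


def simulate_batch(
    scenario: Scenario,
    root_state_mode: str = "stationary",
    max_retries: int = 1000,
) -> tuple[list[PhyloTree], dict]:
    """Simulate ``scenario.n_reps`` independent pruned trees.

    Replicate k uses the stream ``batch_rng(scenario.seed, k)``, so batches
    are reproducible and any replicate can be regenerated in isolation.
    Returns the trees plus a summary dict (mean/SD of the state-0 tip
    fraction and per-replicate retry counts).
    """
    trees: list[PhyloTree] = []
    fractions = np.empty(scenario.n_reps)
    retries = np.zeros(scenario.n_reps, dtype=int)
    for k in range(scenario.n_reps):
        rng = batch_rng(scenario.seed, k)
        try:
            sim = simulate_tree(scenario.rates, scenario.n_tips, rng,
                                root_state_mode, max_retries)
        except ExtinctionRetryError as err:
            raise ExtinctionRetryError(
                f"replicate {k} of scenario {scenario.label!r}: {err}") from err
        tree = prune_extinct(sim)
        trees.append(tree)
        retries[k] = sim.n_retries
        fractions[k] = tip_state_summary(tree)[2]
    summary = {
        "label": scenario.label,
        "n_reps": scenario.n_reps,
        "n_tips": scenario.n_tips,
        "mean_frac_state0": float(fractions.mean()),
        "sd_frac_state0": float(fractions.std(ddof=1)) if scenario.n_reps > 1 else 0.0,
        "total_retries": int(retries.sum()),
        "retries": retries.tolist(),
    }
    return trees, summary
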