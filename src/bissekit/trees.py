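"""Array-backed rooted bifurcating trees with binary tip states.

`PhyloTree` is the in-memory container the likelihood and the fitters
consume: an ultrametric, extant-only, strictly bifurcating tree. Nodes are
indexed 0..n_tips-1 for tips and n_tips..2*n_tips-2 for internal nodes, with
internal nodes stored in a valid postorder (children before parents; the
root is last). Branch lengths are indexed by the child node of each branch;
the root carries length 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TreeValidationError(ValueError):
    """A tree violates the PhyloTree invariants."""


@dataclass
class PhyloTree:
    n_tips: int
    #: children[i] = (left, right) node ids of internal node n_tips + i
    children: np.ndarray
    #: branch length above each node (child-indexed); root entry is 0
    lengths: np.ndarray
    #: tip_states[i] in {0, 1} for tip i
    tip_states: np.ndarray
    #: tip labels, defaults to "t1".."tN"
    tip_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.children = np.asarray(self.children, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        self.tip_states = np.asarray(self.tip_states, dtype=np.int64)
        if not self.tip_labels:
            self.tip_labels = [f"t{i+1}" for i in range(self.n_tips)]
        self.validate()

    # ------------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def validate(self) -> None:
        n = self.n_tips
        if n < 2:
            raise TreeValidationError("need at least 2 tips")
        if self.children.shape != (n - 1, 2):
            raise TreeValidationError(
                f"children must have shape ({n-1}, 2), got {self.children.shape}")
        if self.lengths.shape != (self.n_nodes,):
            raise TreeValidationError("lengths must be child-indexed per node")
        if np.any(self.lengths < 0):
            raise TreeValidationError("negative branch length")
        if len(self.tip_labels) != n or len(set(self.tip_labels)) != n:
            raise TreeValidationError("tip labels must be unique, one per tip")
        if self.tip_states.shape != (n,) or not np.isin(self.tip_states, (0, 1)).all():
            raise TreeValidationError("tip states must be 0/1, one per tip")
        # each non-root node has exactly one parent; children precede parents
        seen = np.zeros(self.n_nodes, dtype=bool)
        for i in range(n - 1):
            node = n + i
            for c in self.children[i]:
                if c < 0 or c >= self.n_nodes or c == node:
                    raise TreeValidationError(f"bad child id {c} at node {node}")
                if c >= node:
                    raise TreeValidationError("children must precede parents")
                if seen[c]:
                    raise TreeValidationError(f"node {c} has two parents")
                seen[c] = True
        if seen[self.root]:
            raise TreeValidationError("root cannot be a child")
        if not seen[: self.root].all():
            raise TreeValidationError("orphan node (not reachable from root)")

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths (time from root)."""
        depth = np.zeros(self.n_nodes)
        for i in range(self.n_tips - 2, -1, -1):
            node = self.n_tips + i
            for c in self.children[i]:
                depth[c] = depth[node] + self.lengths[c]
        return depth

    @property
    def height(self) -> float:
        # branch lengths are fixed after construction, so cache this
        cached = getattr(self, "_height", None)
        if cached is None:
            cached = float(self.depths()[: self.n_tips].max())
            self._height = cached
        return cached

    def is_ultrametric(self, rtol: float = 1e-9) -> bool:
        d = self.depths()[: self.n_tips]
        h = d.max()
        return bool(h == 0 or np.all(np.abs(d - h) <= rtol * h))

    def check_ultrametric(self, rtol: float = 1e-9) -> None:
        if not self.is_ultrametric(rtol):
            raise TreeValidationError("tree is not ultrametric")

    # ------------------------------------------------------------------

    def to_newick(self, precision: int = 12) -> str:
        """Serialize as a Newick string (unquoted labels, decimal lengths)."""
        n = self.n_tips

        def fmt(x: float) -> str:
            return f"{x:.{precision}g}"

        def rec(node: int) -> str:
            if node < n:
                return f"{self.tip_labels[node]}:{fmt(self.lengths[node])}"
            l, r = self.children[node - n]
            inner = f"({rec(l)},{rec(r)})"
            if node == self.root:
                return inner
            return f"{inner}:{fmt(self.lengths[node])}"

        return rec(self.root) + ";"

    @property
    def tip_state_map(self) -> dict[str, int]:
        return {lab: int(s) for lab, s in zip(self.tip_labels, self.tip_states)}


def tip_state_summary(tree: PhyloTree) -> tuple[int, int, float]:
    """Counts of tips in each state and the fraction in state 0."""
    count1 = int(tree.tip_states.sum())
    count0 = tree.n_tips - count1
    return count0, count1, count0 / tree.n_tips
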