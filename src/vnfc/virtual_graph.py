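"""Augmenting the functional-connectivity graph with virtual nodes.

Real electrode nodes keep their sparse PLV edges. Each spatial group of
electrodes gains one *local virtual node* connected to every real node of
the group, and a single *global virtual node* connects all local virtual
nodes. With 64 channels in 8 groups the augmented adjacency is 73 x 73.
Node ordering is fixed — real channels first (montage order), then local
virtual nodes by group id, then the global node — so flattened feature
maps are reproducible.

Node features are an all-ones m x N matrix: the classifier sees only the
connection pattern, not per-node signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import SparsePLV
from .montage import GroupScheme, ReductionLayout

__all__ = [
    "AugmentedGraph",
    "build_augmented_graph",
    "make_node_features",
    "subgraph_for_layout",
    "restrict_groups",
]

ROLE_REAL = "real"
ROLE_LOCAL = "local_virtual"
ROLE_GLOBAL = "global_virtual"


@dataclass(frozen=True)
class AugmentedGraph:
    """Weighted adjacency over real + local-virtual + global-virtual nodes."""

    adjacency: np.ndarray  # (m, m), symmetric, zero diagonal
    roles: tuple[str, ...]
    group_of: tuple[int, ...]  # real-channel index -> group id (post-compaction)

    @property
    def m(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_real(self) -> int:
        return sum(1 for r in self.roles if r == ROLE_REAL)

    @property
    def n_groups(self) -> int:
        return sum(1 for r in self.roles if r == ROLE_LOCAL)


def build_augmented_graph(
    sparse: SparsePLV, groups: GroupScheme, w_virtual: float = 1.0
) -> AugmentedGraph:
    """Fuse a sparse PLV matrix with a group scheme via virtual nodes.

    The m = n + g + 1 adjacency has the real-real block equal to the sparse
    PLV off-diagonal block; each real node gets one edge (weight
    ``w_virtual``) to its group's local virtual node; each local virtual
    node gets one edge to the global node. There are no real-global or
    local-local edges, so exactly n + g virtual edges are added.
    """
    n = sparse.n
    if groups.n_channels != n:
        raise ValueError(
            f"group scheme covers {groups.n_channels} channels, PLV has {n}"
        )
    if w_virtual < 0:
        raise ValueError("virtual edge weight must be non-negative")
    g = groups.g
    m = n + g + 1
    A = np.zeros((m, m))
    A[:n, :n] = sparse.values
    np.fill_diagonal(A, 0.0)
    for ch, gid in enumerate(groups.group_of):
        A[ch, n + gid] = A[n + gid, ch] = w_virtual
    A[n : n + g, m - 1] = A[m - 1, n : n + g] = w_virtual
    roles = (ROLE_REAL,) * n + (ROLE_LOCAL,) * g + (ROLE_GLOBAL,)
    return AugmentedGraph(adjacency=A, roles=roles, group_of=tuple(groups.group_of))


def make_node_features(m: int, N: int = 32) -> np.ndarray:
    """All-ones node-feature matrix X of shape (m, N)."""
    if m < 1 or N < 1:
        raise ValueError("m and N must be >= 1")
    return np.ones((m, N))


def restrict_groups(groups: GroupScheme, kept: "tuple[int, ...]") -> GroupScheme:
    """Group scheme over a channel subset; emptied groups are dropped and
    remaining group ids compacted (keeps the augmented graph connected)."""
    sub = [groups.group_of[i] for i in kept]
    present = sorted(set(sub))
    remap = {old: new for new, old in enumerate(present)}
    return GroupScheme(group_of=tuple(remap[g] for g in sub), g=len(present))


def subgraph_for_layout(
    sparse: SparsePLV, groups: GroupScheme, layout: ReductionLayout, w_virtual: float = 1.0
) -> AugmentedGraph:
    """Augmented graph after channel ablation.

    The PLV block is sliced to the kept channels and the group scheme is
    re-derived on them (a group vanishes if all its channels were removed,
    shrinking m by its local virtual node as well).
    """
    if len(layout.kept) == 0:
        raise ValueError("layout keeps no channels")
    kept = tuple(layout.kept)
    if max(kept) >= sparse.n:
        raise ValueError("layout indexes channels outside the PLV matrix")
    idx = np.asarray(kept, dtype=int)
    sliced = SparsePLV(
        values=sparse.values[np.ix_(idx, idx)],
        threshold=sparse.threshold,
        density=sparse.density,
    )
    return build_augmented_graph(sliced, restrict_groups(groups, kept), w_virtual)
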