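"""Common fate graph (CFG): the group-level board representation the energy
function is evaluated over.

Stones joined along rows/columns form one indivisible compound stone; each
CFG node carries the quantities entering the group descriptor
``x_i = c_i (n_i + b_eye^{k_i})``: colour c_i, size n_i, liberty count h_i and
eye count k_i.  Two nodes are CFG-adjacent when they share a liberty or touch
directly; only adjacent pairs can carry interaction weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine as eng
from .board import EMPTY, BoardState, Point


@dataclass(frozen=True)
class CFGNode:
    """One compound stone: a maximal 4-connected monochromatic chain."""

    id: int
    color: int            # +1 white/immune, -1 black/cancer
    members: frozenset    # of Point
    liberties: frozenset  # of Point
    k: int                # eye count

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def h(self) -> int:
        return len(self.liberties)


@dataclass(frozen=True)
class CFGraph:
    nodes: tuple            # of CFGNode, ordered by scan-smallest member
    adjacency: frozenset    # of unordered (i, j) id pairs
    point_index: dict       # Point -> node id
    # flat-array mirrors for the kernels (internal)
    _labels: np.ndarray
    _colors: np.ndarray
    _sizes: np.ndarray
    _nlibs: np.ndarray
    _eyes: np.ndarray
    _roots: np.ndarray
    _shared: np.ndarray     # uint8 (ng, ng): >=1 common liberty
    _eye_entries: tuple     # of (Point, node id)

    def node(self, i: int) -> CFGNode:
        return self.nodes[i]

    def neighbours(self, i: int) -> list:
        return sorted(j for a, b in self.adjacency if i in (a, b)
                      for j in (a, b) if j != i)

    def shares_liberty(self, i: int, j: int) -> bool:
        return bool(self._shared[i, j])

    def edge_dump(self) -> str:
        """Plain-text edge list (node summaries + adjacency) for debugging."""
        lines = [
            f"node {n.id} c={n.color:+d} n={n.n} h={n.h} k={n.k} "
            f"root={min(n.members)}" for n in self.nodes]
        lines += [f"edge {i} {j}" for i, j in sorted(self.adjacency)]
        return "\n".join(lines)


def build_cfg(state: BoardState) -> CFGraph:
    """Partition the stones of `state` into compound groups with liberties,
    eye counts and pairwise adjacency.  Node ids follow the scan order of the
    smallest member point."""
    size = state.size
    neigh = eng.neighbour_table(size)
    (labels, colors, sizes, nlibs, eyes, roots, ng,
     eye_pts, eye_grps, ne) = eng.k_groups(state._board, neigh)
    shared, adj = eng.k_pair_matrices(state._board, neigh, labels, ng)

    members: list = [[] for _ in range(ng)]
    for idx in np.flatnonzero(labels >= 0):
        members[labels[idx]].append(Point(int(idx) // size, int(idx) % size))
    libs: list = [set() for _ in range(ng)]
    board = state._board
    for idx in np.flatnonzero(board == EMPTY):
        for k in range(4):
            r = int(neigh[idx, k])
            if r >= 0 and board[r] != EMPTY:
                libs[labels[r]].add(Point(int(idx) // size, int(idx) % size))

    nodes = tuple(
        CFGNode(id=g, color=int(colors[g]), members=frozenset(members[g]),
                liberties=frozenset(libs[g]), k=int(eyes[g]))
        for g in range(ng))
    adjacency = frozenset(
        (i, j) for i in range(ng) for j in range(i + 1, ng) if adj[i, j])
    point_index = {p: g for g in range(ng) for p in members[g]}
    eye_entries = tuple(
        (Point(int(eye_pts[t]) // size, int(eye_pts[t]) % size),
         int(eye_grps[t])) for t in range(ne))
    return CFGraph(nodes=nodes, adjacency=adjacency, point_index=point_index,
                   _labels=labels, _colors=colors, _sizes=sizes,
                   _nlibs=nlibs, _eyes=eyes, _roots=roots, _shared=shared,
                   _eye_entries=eye_entries)


def liberties_of(node: CFGNode, state: BoardState) -> set:
    """Empty orthogonal neighbours of the node's members (h_i = their count)."""
    size = state.size
    out = set()
    for (r, c) in node.members:
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < size and 0 <= cc < size and \
                    state._board[rr * size + cc] == EMPTY:
                out.add(Point(rr, cc))
    return out


def count_eyes(node: CFGNode, state: BoardState) -> int:
    """k_i: empty points whose every on-board orthogonal neighbour is the
    node's colour, at least one of them belonging to this node.  An eye
    bordered by several same-colour groups counts for each of them."""
    size = state.size
    k = 0
    for (r, c) in liberties_of(node, state):
        ok = True
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < size and 0 <= cc < size and \
                    state._board[rr * size + cc] != node.color:
                ok = False
                break
        if ok:
            k += 1
    return k
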