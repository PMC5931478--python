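"""Detectors for the tactic patterns that parameterize the interaction term:
eye, net, ladder, connection, invasion, reduction — plus atari.

The tumour–immune reading: an eye is an initial micro-tumour (or a tumour
suppressor barrier for white); a net is a pre-metastatic niche / cytotoxic
enclosure; a ladder a chased escape line; a connection the knitting of allied
groups; an invasion a deep isolated placement among adversaries; a reduction
a boundary incursion supported by nearby allies.  Atari (one liberty left)
is detected for the agents but carries no interaction weight.

Each detector is an operational definition with deterministic scan-order
tie-breaking; parameters (`ladder_depth_cap`, `net_depth`,
`invasion_radius`) live in :class:`goising.energy.TacticConfig`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _engine as eng
from .board import BoardState
from .cfg_graph import CFGraph


class TacticKind(enum.Enum):
    EYE = "eye"
    NET = "net"
    LADDER = "ladder"
    CONNECTION = "connection"
    INVASION = "invasion"
    REDUCTION = "reduction"
    ATARI = "atari"


@dataclass(frozen=True)
class TacticInstance:
    """One detected pattern.

    `owner_color` is the side executing the tactic (+1 immune, -1 cancer);
    for ladder/net/atari that is the attacker, i.e. the adversary of the
    group in `groups`.  `between` is the node pair whose interaction the
    instance mediates, when pair-specific (connections); `mediator` the
    group whose descriptor x_s scales the weight; `anchor` the eye point for
    eyes."""

    kind: TacticKind
    owner_color: int
    groups: frozenset
    between: Optional[tuple] = None
    mediator: Optional[int] = None
    anchor: Optional[object] = None


def detect_atari(cfg: CFGraph, state: BoardState) -> list:
    """One ATARI per node with a single liberty; owner = the adversary."""
    return [
        TacticInstance(TacticKind.ATARI, owner_color=-node.color,
                       groups=frozenset([node.id]))
        for node in cfg.nodes if node.h == 1]


def detect_eyes(cfg: CFGraph, state: BoardState) -> list:
    """One EYE per (group, eye point) pair; owner = the group's colour."""
    out = []
    for point, g in cfg._eye_entries:
        node = cfg.nodes[g]
        out.append(TacticInstance(TacticKind.EYE, owner_color=node.color,
                                  groups=frozenset([g]), mediator=g,
                                  anchor=point))
    return out


def _attacker_mediator(cfg: CFGraph, g: int, owner: int) -> Optional[int]:
    """Scan-smallest owner-colour node CFG-adjacent to g."""
    best = None
    for i, j in cfg.adjacency:
        if g in (i, j):
            other = j if i == g else i
            if cfg.nodes[other].color == owner and (best is None or other < best):
                best = other
    return best


def detect_ladder(cfg: CFGraph, state: BoardState,
                  depth_cap: int = 50) -> list:
    """Bounded ladder read-out for every node in atari: the defender extends
    at its single liberty, the attacker answers with the scan-smallest legal
    non-self-atari liberty that restores atari.  A node captured within
    `depth_cap` plies is LADDER-captured (owner = attacker)."""
    if depth_cap < 1:
        raise ValueError("ladder depth_cap must be >= 1")
    neigh = eng.neighbour_table(state.size)
    out = []
    for node in cfg.nodes:
        if node.h != 1:
            continue
        root = int(cfg._roots[node.id])
        if eng.k_ladder_captured(state._board, neigh, root, depth_cap):
            owner = -node.color
            out.append(TacticInstance(
                TacticKind.LADDER, owner_color=owner,
                groups=frozenset([node.id]),
                mediator=_attacker_mediator(cfg, node.id, owner)))
    return out


def detect_net(cfg: CFGraph, state: BoardState, depth: int = 4) -> list:
    """A node with <= 2 liberties is NETTED (owner = adversary) when a
    `depth`-ply escape search — defender first, maximizing liberties;
    attacker filling liberties — cannot raise its liberties above 2."""
    neigh = eng.neighbour_table(state.size)
    out = []
    for node in cfg.nodes:
        if node.h > 2 or node.k >= 2:
            # two eyes = alive: the liberties can never be filled
            continue
        root = int(cfg._roots[node.id])
        if eng.k_net_check(state._board, neigh, root, depth):
            owner = -node.color
            out.append(TacticInstance(
                TacticKind.NET, owner_color=owner,
                groups=frozenset([node.id]),
                mediator=_attacker_mediator(cfg, node.id, owner)))
    return out


def detect_connection(cfg: CFGraph, state: BoardState) -> list:
    """One CONNECTION per unordered same-colour node pair sharing >= 1
    liberty; the scan-smaller node mediates."""
    out = []
    for i, j in sorted(cfg.adjacency):
        if cfg._shared[i, j] and cfg.nodes[i].color == cfg.nodes[j].color:
            out.append(TacticInstance(
                TacticKind.CONNECTION, owner_color=cfg.nodes[i].color,
                groups=frozenset([i, j]), between=(i, j), mediator=min(i, j)))
    return out


def detect_invasion_reduction(cfg: CFGraph, state: BoardState,
                              radius: int = 2) -> list:
    """Classify groups by the stone balance of the Chebyshev-`radius`
    neighbourhood of their members (members excluded).

    INVASION: the node touches no allied group (no connection incident) and
    adversary stones strictly outnumber allied ones — a deep placement.
    REDUCTION: any other node with at least one adversary stone in its
    neighbourhood — a supported boundary incursion.  A node is at most one
    of the two."""
    if radius < 1:
        raise ValueError("invasion radius must be >= 1")
    ng = len(cfg.nodes)
    has_conn = np.zeros(ng, np.uint8)
    for i, j in cfg.adjacency:
        if cfg._shared[i, j] and cfg.nodes[i].color == cfg.nodes[j].color:
            has_conn[i] = 1
            has_conn[j] = 1
    kinds = eng.k_incursions(state._board, cfg._labels, cfg._colors,
                             cfg._sizes, cfg._roots, ng, state.size,
                             radius, has_conn)
    out = []
    for g in range(ng):
        if kinds[g] == 0:
            continue
        kind = TacticKind.INVASION if kinds[g] == 1 else TacticKind.REDUCTION
        out.append(TacticInstance(kind, owner_color=cfg.nodes[g].color,
                                  groups=frozenset([g]), mediator=g))
    return out


def detect_all(cfg: CFGraph, state: BoardState, ladder_depth_cap: int = 50,
               net_depth: int = 4, invasion_radius: int = 2) -> list:
    """All tactic instances of a position, in a fixed kind-then-scan order."""
    return (detect_eyes(cfg, state)
            + detect_connection(cfg, state)
            + detect_atari(cfg, state)
            + detect_ladder(cfg, state, ladder_depth_cap)
            + detect_net(cfg, state, net_depth)
            + detect_invasion_reduction(cfg, state, invasion_radius))


def instance_listing(instances) -> str:
    """Plain-text listing of detected instances (debug aid)."""
    lines = []
    for t in instances:
        side = "cancer" if t.owner_color == eng.BLACK else "immune"
        extra = ""
        if t.between is not None:
            extra += f" between={t.between}"
        if t.anchor is not None:
            extra += f" at={tuple(t.anchor)}"
        lines.append(f"{t.kind.value:<10} owner={side} "
                     f"groups={sorted(t.groups)}{extra}")
    return "\n".join(lines)
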