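"""Ising Hamiltonian over the common fate graph.

Every group of stones (cells) i carries a signed descriptor

    x_i = c_i * (n_i + b_eye**k_i)        (eye term 0 when k_i = 0)

with colour c_i (+1 immune, -1 cancer), size n_i and eye count k_i; eyes make
a group exponentially harder to remove (two eyes = uncapturable).  Pairs of
CFG-adjacent groups interact with weight

    w_ij = sum over tactic instances attached to (i, j) of r_t(owner) * |x_s|

where s is the instance's mediating group (always owner-coloured; its
descriptor enters with the owner's own-side sign, mirroring the field-term
convention — otherwise one colour's tactics would systematically lower the
energy while the other's raised it) and r_t the side-specific tactic
weight (cancer: eye 0.7, net 0.6, ladder 0.5, connection 0.1, invasion 0.4;
immune: eye 0.4, net 0.7, ladder 0.5, connection 0.1, reduction 0.5); a pair
sharing a liberty but carrying no instance couples with r_sl = 1.  The total
energy is

    H = sum_{i<j} w_ij x_i x_j  -  mu * sum_i h_i x_i

with h_i the liberty count acting as the local field multiplier; this raw
signed sum is reported as `H_literal`.  The per-side energies use own-sign
descriptors throughout, so the convention is symmetric between the colours:
a side's own-pair synergy and its liberty field are stabilizing (negative),

    H_side(c) = - sum_{i<j, both c} w_ij |x_i||x_j|
                + 1/2 sum_{mixed i<j} w_ij |x_i||x_j|
                - mu * sum_{i: c_i=c} h_i |x_i|,

while the tension of mixed cancer–immune contact raises both sides' energies
half each.  H_total = H_cancer + H_immune.  The simulation winner is the
side with the more negative final energy: more, larger, better-connected and
eye-protected groups with more liberties.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _engine as eng
from .board import BLACK, BoardState
from .cfg_graph import CFGNode, CFGraph, build_cfg
from .tactics import TacticInstance, TacticKind

#: Side-specific tactic weights: cancer (black) per the tumour-progression
#: assignment, immune (white) per the immune-reaction assignment.
DEFAULT_CANCER = {"eye": 0.7, "net": 0.6, "ladder": 0.5, "connection": 0.1,
                  "invasion": 0.4}
DEFAULT_IMMUNE = {"eye": 0.4, "net": 0.7, "ladder": 0.5, "connection": 0.1,
                  "reduction": 0.5}


@dataclass(frozen=True)
class TacticConfig:
    """Search parameters of the tactic detectors."""

    ladder_depth_cap: int = 50
    net_depth: int = 4
    invasion_radius: int = 2

    def validate(self) -> "TacticConfig":
        if self.ladder_depth_cap < 1:
            raise ValueError("ladder_depth_cap must be >= 1")
        if self.net_depth < 0:
            raise ValueError("net_depth must be >= 0")
        if self.invasion_radius < 1:
            raise ValueError("invasion_radius must be >= 1")
        return self


@dataclass(frozen=True)
class WeightConfig:
    """Tactic weights, the single-liberty coupling r_sl, the eye base b_eye
    of the group descriptor (> 1), and the field strength mu."""

    cancer: dict = field(default_factory=lambda: dict(DEFAULT_CANCER))
    immune: dict = field(default_factory=lambda: dict(DEFAULT_IMMUNE))
    r_sl: float = 1.0
    b_eye: float = 2.0
    mu: float = 1.0
    tactics: TacticConfig = field(default_factory=TacticConfig)

    def validate(self) -> "WeightConfig":
        for side, table, incursion in (("cancer", self.cancer, "invasion"),
                                       ("immune", self.immune, "reduction")):
            for key in ("eye", "net", "ladder", "connection", incursion):
                if key not in table:
                    raise ValueError(f"{side}.{key} missing")
                if table[key] < 0:
                    raise ValueError(f"{side}.{key} must be >= 0")
            unknown = set(table) - {"eye", "net", "ladder", "connection",
                                    incursion}
            if unknown:
                raise ValueError(f"unknown {side} weight keys: {sorted(unknown)}")
        if self.r_sl < 0:
            raise ValueError("r_sl must be >= 0")
        if self.b_eye <= 1:
            raise ValueError("b_eye must be > 1")
        self.tactics.validate()
        return self

    def side_weight(self, color: int, kind: TacticKind) -> float:
        """Tactic weight r_t for the side executing the tactic; invasion and
        reduction both map to the side's incursion weight; atari carries 0."""
        table = self.cancer if color == BLACK else self.immune
        if kind in (TacticKind.INVASION, TacticKind.REDUCTION):
            return table["invasion" if color == BLACK else "reduction"]
        if kind is TacticKind.ATARI:
            return 0.0
        return table[kind.value]

    def to_array(self) -> np.ndarray:
        """Kernel packing: [cancer eye,net,ladder,conn,incursion;
        immune likewise; r_sl; b_eye; mu]."""
        c, m = self.cancer, self.immune
        return np.array([
            c["eye"], c["net"], c["ladder"], c["connection"], c["invasion"],
            m["eye"], m["net"], m["ladder"], m["connection"], m["reduction"],
            self.r_sl, self.b_eye, self.mu], np.float64)

    @classmethod
    def from_mapping(cls, data: Optional[dict]) -> "WeightConfig":
        """Build from a (possibly partial) mapping such as a parsed YAML/JSON
        weights file; missing keys take the defaults."""
        data = dict(data or {})
        cancer = dict(DEFAULT_CANCER)
        cancer.update(data.pop("cancer", {}) or {})
        immune = dict(DEFAULT_IMMUNE)
        immune.update(data.pop("immune", {}) or {})
        tac = TacticConfig(
            ladder_depth_cap=int(data.pop("ladder_depth_cap", 50)),
            net_depth=int(data.pop("net_depth", 4)),
            invasion_radius=int(data.pop("invasion_radius", 2)))
        kwargs = {}
        for key in ("r_sl", "b_eye", "mu"):
            if key in data:
                kwargs[key] = float(data.pop(key))
        if data:
            raise ValueError(f"unknown weight keys: {sorted(data)}")
        return cls(cancer=cancer, immune=immune, tactics=tac,
                   **kwargs).validate()

    def swapped_sides(self) -> "WeightConfig":
        """Exchange the two sides' tables (the incursion weight follows its
        side); used by the colour-swap symmetry checks."""
        cancer = dict(self.immune)
        cancer["invasion"] = cancer.pop("reduction")
        immune = dict(self.cancer)
        immune["reduction"] = immune.pop("invasion")
        return replace(self, cancer=cancer, immune=immune)


@dataclass(frozen=True)
class GroupDescriptor:
    """The Eq-style per-group quantity x_i and its components."""

    node_id: int
    x: float
    c: int
    n: int
    k: int
    eye_term: float


def group_x(node: CFGNode, w: WeightConfig) -> GroupDescriptor:
    """x_i = c_i (n_i + b_eye^{k_i}); the eye term vanishes when k_i = 0."""
    eye_term = w.b_eye ** node.k if node.k >= 1 else 0.0
    return GroupDescriptor(node_id=node.id, x=node.color * (node.n + eye_term),
                           c=node.color, n=node.n, k=node.k,
                           eye_term=eye_term)


def interaction_w(i: int, j: int, cfg: CFGraph, instances, w: WeightConfig
                  ) -> float:
    """Pairwise interaction weight w_ij = w_ji.

    Sums r_t(owner) * |x_s| over the tactic instances attached to the pair:
    a connection attaches to its own pair; an eye to every (owner group,
    adjacent adversary) pair; ladder/net to every (target, adjacent
    attacker-colour) pair; invasion/reduction to every (node, adjacent
    adversary) pair.  An instance-free pair sharing a liberty couples with
    r_sl * 1.  This is the readable reference; `hamiltonian` computes the
    same quantity through the compiled kernel.
    """
    if i == j:
        raise ValueError("w_ij needs two distinct nodes")
    a, b = (i, j) if i < j else (j, i)
    if (a, b) not in cfg.adjacency:
        return 0.0
    ci, cj = cfg.nodes[a].color, cfg.nodes[b].color
    total = 0.0
    attached = False
    for t in instances:
        r = w.side_weight(t.owner_color, t.kind)
        if t.kind is TacticKind.ATARI:
            continue
        if t.kind is TacticKind.CONNECTION:
            if t.between == (a, b):
                total += r * abs(group_x(cfg.nodes[t.mediator], w).x)
                attached = True
            continue
        (g,) = t.groups
        if t.kind in (TacticKind.EYE, TacticKind.INVASION,
                      TacticKind.REDUCTION):
            # owner group g against each adjacent adversary
            if g in (a, b) and ci != cj:
                total += r * abs(group_x(cfg.nodes[g], w).x)
                attached = True
        else:  # LADDER / NET: target g, attacker-colour partner
            other = b if g == a else a if g == b else None
            if other is not None and cfg.nodes[other].color == t.owner_color:
                med = (cfg.nodes[t.mediator] if t.mediator is not None
                       else None)
                xs = abs(group_x(med, w).x) if med is not None else 1.0
                total += r * xs
                attached = True
    if not attached and cfg.shares_liberty(a, b):
        return w.r_sl
    return total


@dataclass
class EnergyReport:
    """Hamiltonian evaluation of one position.

    `H_total = H_cancer + H_immune` by the side-split contract; `H_margin`
    is H_cancer - H_immune accumulated from the side-specific terms only
    (the mixed-pair halves cancel exactly), which keeps the winner signal
    above float resolution when eye terms grow large; `H_literal` is the raw
    signed-field sum (its field term flips sign between colours).  `pair_w`
    maps (i, j), i < j, to w_ij for CFG-adjacent pairs.
    """

    H_total: float
    H_cancer: float
    H_immune: float
    H_margin: float
    H_literal: float
    x: dict
    h: dict
    pair_w: dict
    instances: tuple
    cfg: CFGraph
    event: Optional[int] = None

    def side(self, color: int) -> float:
        return self.H_cancer if color == BLACK else self.H_immune


_KIND_BY_CODE = {
    eng.K_EYE: TacticKind.EYE, eng.K_NET: TacticKind.NET,
    eng.K_LADDER: TacticKind.LADDER, eng.K_CONNECTION: TacticKind.CONNECTION,
    eng.K_INVASION: TacticKind.INVASION, eng.K_REDUCTION: TacticKind.REDUCTION,
    eng.K_ATARI: TacticKind.ATARI}


def hamiltonian(state: BoardState, w: Optional[WeightConfig] = None,
                event: Optional[int] = None) -> EnergyReport:
    """Evaluate the position's Ising energy with the stone descriptors,
    tactic-weighted interactions and liberty field described above."""
    w = (w or WeightConfig()).validate()
    neigh = eng.neighbour_table(state.size)
    tac = w.tactics
    (H_c, H_i, H_diff, H_lit, labels, colors, sizes, nlibs, eyes, roots,
     ng, x, pair_i, pair_j, pair_w, pair_shared, npairs,
     inst_kind, inst_owner, inst_grp, inst_med, inst_pt, ninst) = \
        eng.k_evaluate(state._board, neigh, state.size, w.to_array(),
                       tac.ladder_depth_cap, tac.net_depth,
                       tac.invasion_radius)
    cfg = build_cfg(state)
    size = state.size
    instances = []
    for t in range(ninst):
        kind = _KIND_BY_CODE[int(inst_kind[t])]
        g = int(inst_grp[t])
        med = int(inst_med[t]) if inst_med[t] >= 0 else None
        anchor = None
        between = None
        groups = frozenset([g])
        if kind is TacticKind.EYE:
            p = int(inst_pt[t])
            from .board import Point
            anchor = Point(p // size, p % size)
        elif kind is TacticKind.CONNECTION:
            partner = int(inst_pt[t])
            between = (g, partner)
            groups = frozenset([g, partner])
        instances.append(TacticInstance(
            kind=kind, owner_color=int(inst_owner[t]), groups=groups,
            between=between, mediator=med, anchor=anchor))
    report = EnergyReport(
        H_total=float(H_c + H_i), H_cancer=float(H_c), H_immune=float(H_i),
        H_margin=float(H_diff), H_literal=float(H_lit),
        x={g: float(x[g]) for g in range(ng)},
        h={g: int(nlibs[g]) for g in range(ng)},
        pair_w={(int(pair_i[t]), int(pair_j[t])): float(pair_w[t])
                for t in range(npairs)},
        instances=tuple(instances), cfg=cfg, event=event)
    return report


def side_energies(board: np.ndarray, size: int, w_arr: np.ndarray,
                  tac: TacticConfig) -> tuple:
    """Fast path for agents and trajectories: (H_cancer, H_immune,
    H_margin) from a flat board array."""
    neigh = eng.neighbour_table(size)
    H_c, H_i, H_d, _, _ = eng.k_eval_sides(board, neigh, size, w_arr,
                                           tac.ladder_depth_cap,
                                           tac.net_depth, tac.invasion_radius)
    return float(H_c), float(H_i), float(H_d)
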