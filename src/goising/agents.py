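"""Move-selection policies of graded strength.

Four seedable agents stand in for the simulator line-up: a uniform RANDOM
control, a deliberately weak Monte-Carlo player (PASSIVE_MC), a 1-ply
energy-greedy player (GOOD) and a tactical-cascade + 2-ply minimax player
(AGGRESSIVE).  The agents are defined by their policies and their empirical
strength ordering, not by any external engine.  All agents refuse to fill
their own single-point eyes (so self-play terminates) and pass when no other
legal move exists; all are deterministic given the same state and seed.

Agents score positions with their energy margin H_own - H_adversary (the
winner is the side with the more negative final energy, so the margin is the
quantity a player should drive down); their
internal candidate evaluations use a shallower tactic search than the
reporting configuration (an agent design choice — the game trajectory is
always scored with the full configuration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine as eng
from .board import BLACK, PASS, BoardState, Move, Point
from .energy import WeightConfig

AGENT_KINDS = ("random", "passive_mc", "good", "aggressive")


@dataclass(frozen=True)
class AgentSpec:
    """Agent kind plus policy parameters.

    passive_mc: `candidates` sampled moves, `rollouts` uniform playouts each,
    `rollout_depth` plies per playout (intentionally weak defaults).
    aggressive: `pool_size` heuristic candidates, `top_m` kept for the 2-ply
    minimax, `reply_m` opponent replies examined per candidate.
    `eval_ladder_cap` / `eval_net_depth` set the tactic-search depth of the
    agent's internal evaluations.
    """

    kind: str
    candidates: int = 10
    rollouts: int = 5
    rollout_depth: int = 30
    pool_size: int = 20
    top_m: int = 6
    reply_m: int = 5
    eval_ladder_cap: int = 50
    eval_net_depth: int = 2
    sweep_ladder_cap: int = 50
    sweep_net_depth: int = 0
    epsilon: float = None  # per-kind default; see eff_epsilon

    def validate(self) -> "AgentSpec":
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}; "
                             f"expected one of {AGENT_KINDS}")
        for name in ("candidates", "rollouts", "rollout_depth", "pool_size",
                     "top_m", "reply_m", "eval_ladder_cap", "sweep_ladder_cap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.eval_net_depth < 0:
            raise ValueError("eval_net_depth must be >= 0")
        if self.epsilon is not None and not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must be in [0, 1)")
        return self

    @property
    def eff_epsilon(self) -> float:
        """Exploration rate: the aggressive agent plays the most
        disciplined game (2%), the other deterministic agents 5%."""
        if self.epsilon is not None:
            return self.epsilon
        return 0.02 if self.kind == "aggressive" else 0.05


def _playable(board: np.ndarray, neigh, color: int, ko: int) -> np.ndarray:
    out = np.empty(board.shape[0], np.int32)
    cnt = eng.k_playable_points(board, neigh, color, ko, True, out)
    return out[:cnt].copy()


def _side(H_c: float, H_i: float, color: int) -> float:
    return H_c if color == BLACK else H_i


def _margin_of(H_d: float, color: int) -> float:
    """Own side energy minus the adversary's (negative = we are ahead),
    from the kernel's exactly-accumulated H_cancer - H_immune."""
    return H_d if color == BLACK else -H_d


class _Evaluator:
    """Caches the packed weight array + tactic depths for one decision."""

    def __init__(self, size: int, weights: WeightConfig, spec: AgentSpec):
        self.size = size
        self.neigh = eng.neighbour_table(size)
        self.W = weights.to_array()
        self.ladder_cap = spec.eval_ladder_cap
        self.net_depth = spec.eval_net_depth
        self.radius = weights.tactics.invasion_radius

    def sides(self, board: np.ndarray):
        return eng.k_eval_sides(board, self.neigh, self.size, self.W,
                                self.ladder_cap, self.net_depth, self.radius)

    def after_move(self, board: np.ndarray, p: int, color: int):
        """(ok, new_board, ncap, ko) after playing p."""
        work = board.copy()
        ok, ncap, cap_pt, own = eng.k_play(work, self.neigh, p, color)
        ko = int(cap_pt) if (ncap == 1 and own == 1) else -1
        return ok, work, int(ncap), ko


def _to_point(p: int, size: int) -> Point:
    return Point(p // size, p % size)


# --------------------------------------------------------------------------
# policies

def random_move(state: BoardState, color: int, rng: np.random.Generator
                ) -> Move:
    """Uniform over legal moves excluding own single-point eyes; PASS when
    none remain."""
    neigh = eng.neighbour_table(state.size)
    pts = _playable(state._board, neigh, color, state._ko_idx)
    if len(pts) == 0:
        return PASS
    return _to_point(int(pts[rng.integers(len(pts))]), state.size)


def passive_mc_move(state: BoardState, color: int, spec: AgentSpec,
                    rng: np.random.Generator, weights: WeightConfig) -> Move:
    """Weak Monte-Carlo policy: sample a few candidate moves, score each with
    a handful of short uniform rollouts evaluated by the mover's side energy
    at the horizon, play the candidate with the lowest mean."""
    ev = _Evaluator(state.size, weights, spec)
    pts = _playable(state._board, neigh=ev.neigh, color=color,
                    ko=state._ko_idx)
    if len(pts) == 0:
        return PASS
    m = min(spec.candidates, len(pts))
    order = rng.permutation(len(pts))[:m]
    best_p = -1
    best_mean = np.inf
    for t in order:
        p = int(pts[t])
        ok, work, _, ko = ev.after_move(state._board, p, color)
        if not ok:
            continue
        total = 0.0
        for _ in range(spec.rollouts):
            roll = work.copy()
            seed = int(rng.integers(0, 2**31 - 1))
            eng.k_random_playout(roll, ev.neigh, -color, ko,
                                 spec.rollout_depth, seed)
            _, _, H_d, _, _ = ev.sides(roll)
            total += _margin_of(H_d, color)
        mean = total / spec.rollouts
        if mean < best_mean:
            best_mean = mean
            best_p = p
    if best_p < 0:
        return PASS
    return _to_point(best_p, state.size)


def _explore(state: BoardState, spec: AgentSpec, color: int,
             rng: np.random.Generator):
    """Seeded exploration: with probability `epsilon` the deterministic
    agents play a uniform playable point instead of their policy move, so
    that seeded batteries vary the way batteries of real engines do."""
    eps = spec.eff_epsilon
    if eps > 0.0 and rng.random() < eps:
        return random_move(state, color, rng)
    return None


def good_move(state: BoardState, color: int, spec: AgentSpec,
              rng: np.random.Generator, weights: WeightConfig) -> Move:
    """1-ply greedy on the energy margin over every legal (non-own-eye)
    move; ties broken by more captures, then more own liberties, then scan
    order; passes when no move improves the margin."""
    exploration = _explore(state, spec, color, rng)
    if exploration is not None:
        return exploration
    ev = _Evaluator(state.size, weights, spec)
    pts = _playable(state._board, neigh=ev.neigh, color=color,
                    ko=state._ko_idx)
    if len(pts) == 0:
        return PASS
    best = None
    best_key = None
    for p in pts:  # scan order
        p = int(p)
        ok, work, ncap, _ = ev.after_move(state._board, p, color)
        if not ok:
            continue
        _, _, H_d, lib_c, lib_i = ev.sides(work)
        H = _margin_of(H_d, color)
        own_libs = lib_c if color == BLACK else lib_i
        key = (H, -ncap, -own_libs, p)
        if best_key is None or key < best_key:
            best_key = key
            best = p
    if best is None:
        return PASS
    # pass when no move improves the margin: the position is settled
    _, _, H_d0, _, _ = ev.sides(state._board)
    if best_key[0] >= _margin_of(H_d0, color):
        return PASS
    return _to_point(best, state.size)


def _heuristic_scores(board: np.ndarray, size: int, color: int,
                      labels, nlibs, pts: np.ndarray) -> np.ndarray:
    """Cheap tactical urgency of each candidate point: adjacency to
    low-liberty chains (both colours), plain stone contact, centrality."""
    neigh = eng.neighbour_table(size)
    scores = np.zeros(len(pts), np.float64)
    center = (size - 1) / 2.0
    for t, p in enumerate(pts):
        p = int(p)
        s = 0.0
        for k in range(4):
            r = int(neigh[p, k])
            if r < 0:
                continue
            v = board[r]
            if v == 0:
                continue
            libs = int(nlibs[labels[r]])
            if v == -color:
                s += 1.0 + (6.0 if libs == 1 else 3.0 if libs == 2 else 0.0)
            else:
                s += 0.5 + (4.0 if libs == 1 else 1.5 if libs == 2 else 0.0)
        r, c = divmod(p, size)
        s += 0.1 * (1.0 - (abs(r - center) + abs(c - center)) / size)
        scores[t] = s
    return scores


def _top_pool(board, size, color, labels, nlibs, pts, pool):
    scores = _heuristic_scores(board, size, color, labels, nlibs, pts)
    # descending score, ascending scan order
    order = np.lexsort((pts, -scores))
    return pts[order[:pool]]


def aggressive_move(state: BoardState, color: int, spec: AgentSpec,
                    rng: np.random.Generator, weights: WeightConfig) -> Move:
    """Tactical cascade, then 2-ply energy minimax.

    1. capture the largest adversary group in atari;
    2. rescue the largest own group in atari whose ladder fails for the
       attacker (extend at its liberty, if that yields >= 2 liberties);
    3. create a new eye for an own group of >= 3 stones;
    4. otherwise: rank a heuristic candidate pool at 1 ply by own side
       energy, keep the best `top_m`, and play the candidate minimizing the
       worst-case (over `reply_m` heuristic opponent replies, plus pass)
       H_own - H_adversary after 2 plies.
    """
    exploration = _explore(state, spec, color, rng)
    if exploration is not None:
        return exploration
    ev = _Evaluator(state.size, weights, spec)
    board = state._board
    size = state.size
    neigh = ev.neigh
    ko = state._ko_idx
    (labels, colors, sizes, nlibs, eyes, roots, ng, _, _, _) = \
        eng.k_groups(board, neigh)
    buf = np.empty(4, np.int32)

    # 1: capture an adversary group in atari (largest; tie scan order) —
    # unless it is already held by a working ladder or net, in which case
    # capturing is unnecessary and forfeits the standing pressure
    target = -1
    target_size = 0
    for g in range(ng):
        if colors[g] == -color and nlibs[g] == 1:
            if sizes[g] > target_size:
                root = int(roots[g])
                if eng.k_ladder_captured(board, neigh, root,
                                         spec.eval_ladder_cap) or \
                        eng.k_net_check(board, neigh, root,
                                        spec.eval_net_depth):
                    continue
                eng.k_chain_libs_capped(board, neigh, root, 1, buf)
                p = int(buf[0])
                if eng.k_is_legal(board, neigh, p, color, ko):
                    target = p
                    target_size = int(sizes[g])
    if target >= 0:
        return _to_point(target, size)

    # 2: escape from a failing ladder
    full_cap = weights.tactics.ladder_depth_cap
    own_atari = sorted(
        (int(-sizes[g]), int(roots[g])) for g in range(ng)
        if colors[g] == color and nlibs[g] == 1)
    for _, root in own_atari:
        if eng.k_ladder_captured(board, neigh, root, full_cap):
            continue  # the ladder works: escaping only feeds the attacker
        eng.k_chain_libs_capped(board, neigh, root, 1, buf)
        p = int(buf[0])
        if not eng.k_is_legal(board, neigh, p, color, ko):
            continue
        ok, work, _, _ = ev.after_move(board, p, color)
        if ok and eng.k_chain_libs_capped(work, neigh, p, 2, buf) >= 2:
            return _to_point(p, size)

    # 3: make an eye for a >= 3 stone own group
    own_eye_total = int(np.sum(eyes[colors == color])) if ng else 0
    eye_cands: set = set()
    libbuf = np.empty(board.shape[0], np.int32)
    for g in range(ng):
        if colors[g] == color and sizes[g] >= 3:
            nl = eng.k_chain_liberty_points(board, neigh, int(roots[g]),
                                            libbuf)
            eye_cands.update(int(libbuf[t]) for t in range(nl))
    for p in sorted(eye_cands):
        if not eng.k_is_legal(board, neigh, p, color, ko):
            continue
        if eng.k_is_own_eye(board, neigh, p, color):
            continue
        ok, work, _, _ = ev.after_move(board, p, color)
        if not ok:
            continue
        g2 = eng.k_groups(work, neigh)
        eyes2 = int(np.sum(g2[4][g2[1] == color])) if g2[6] else 0
        if eyes2 > own_eye_total:
            return _to_point(p, size)

    # 4: rank every playable move at 1 ply with a cheap evaluation (shallow
    # tactic search), then 2-ply minimax over the best `top_m`
    pts = _playable(board, neigh, color, ko)
    if len(pts) == 0:
        return PASS
    sweep = _Evaluator(state.size, weights, spec)
    sweep.ladder_cap = spec.sweep_ladder_cap
    sweep.net_depth = spec.sweep_net_depth
    scored = []
    for p in pts:  # scan order
        p = int(p)
        ok, work, _, ko2 = sweep.after_move(board, p, color)
        if not ok:
            continue
        _, _, H_d, _, _ = sweep.sides(work)
        scored.append((_margin_of(H_d, color), p, work, ko2))
    if not scored:
        return PASS
    scored.sort(key=lambda t: (t[0], t[1]))
    # settled position: the best candidate no longer lowers our energy
    _, _, H_d0s, _, _ = sweep.sides(board)
    if scored[0][0] >= _margin_of(H_d0s, color):
        return PASS
    best_p = -1
    best_val = np.inf
    libbuf2 = np.empty(board.shape[0], np.int32)
    for H1, p, work, ko2 in scored[:spec.top_m]:
        _, _, H_d1, _, _ = ev.sides(work)
        worst = _margin_of(H_d1, color)  # pass reply
        # sharp replies only (capture-quiescent minimax): the opponent's
        # punishments are the liberties of our low-liberty chains
        g2 = eng.k_groups(work, neigh)
        replies = set()
        for g in range(g2[6]):
            if g2[1][g] == color and g2[3][g] <= 2:
                nl = eng.k_chain_liberty_points(work, neigh, int(g2[5][g]),
                                                libbuf2)
                replies.update(int(libbuf2[t]) for t in range(nl))
        for q in sorted(replies)[:spec.reply_m]:
            if q == ko2:
                continue
            ok, work2, _, _ = ev.after_move(work, q, -color)
            if not ok:
                continue
            _, _, H_d2, _, _ = ev.sides(work2)
            diff = _margin_of(H_d2, color)
            if diff > worst:
                worst = diff
        if worst < best_val:
            best_val = worst
            best_p = p
    if best_p < 0:
        return PASS
    return _to_point(best_p, size)


def select_move(state: BoardState, color: int, spec: AgentSpec,
                rng: np.random.Generator, weights: WeightConfig) -> Move:
    """Dispatch to the policy named by `spec.kind`."""
    spec.validate()
    if spec.kind == "random":
        return random_move(state, color, rng)
    if spec.kind == "passive_mc":
        return passive_mc_move(state, color, spec, rng, weights)
    if spec.kind == "good":
        return good_move(state, color, spec, rng, weights)
    return aggressive_move(state, color, spec, rng, weights)
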