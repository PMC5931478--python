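"""Numba kernels shared by the board, cfg_graph, tactics, energy and agent layers.

Board encoding: a flat ``int8`` array of length ``size*size`` in row-major scan
order; ``0`` = empty, ``+1`` = white (immune system), ``-1`` = black (cancer).
Group/tactic/energy kernels are pure functions of that array plus a
precomputed neighbour table, so every higher-level module evaluates positions
through exactly one implementation.

Weight vectors are packed as ``float64[13]``::

    [0..4]  cancer  (black): eye, net, ladder, connection, incursion(invasion)
    [5..9]  immune  (white): eye, net, ladder, connection, incursion(reduction)
    [10]    r_sl   single-liberty coupling
    [11]    b_eye  eye base of the group descriptor x_i
    [12]    mu     external-field strength

Tactic kinds are encoded as small ints (shared with :mod:`goising.tactics`):
EYE=0, NET=1, LADDER=2, CONNECTION=3, INVASION=4, REDUCTION=5, ATARI=6.
"""

from __future__ import annotations

import numpy as np
from numba import njit

EMPTY = 0
WHITE = 1
BLACK = -1

K_EYE = 0
K_NET = 1
K_LADDER = 2
K_CONNECTION = 3
K_INVASION = 4
K_REDUCTION = 5
K_ATARI = 6

_NEIGH_CACHE: dict[int, np.ndarray] = {}


def neighbour_table(size: int) -> np.ndarray:
    """(size*size, 4) int32 table of orthogonal neighbour indices, -1 off-board."""
    tab = _NEIGH_CACHE.get(size)
    if tab is None:
        n = size * size
        tab = np.full((n, 4), -1, dtype=np.int32)
        for p in range(n):
            r, c = divmod(p, size)
            if r > 0:
                tab[p, 0] = p - size
            if c > 0:
                tab[p, 1] = p - 1
            if c < size - 1:
                tab[p, 2] = p + 1
            if r < size - 1:
                tab[p, 3] = p + size
        tab.setflags(write=False)
        _NEIGH_CACHE[size] = tab
    return tab


# --------------------------------------------------------------------------
# chains and liberties

@njit(cache=True)
def k_chain_points(board, neigh, start, out):
    """Collect the chain containing `start` into `out`; returns its size."""
    c = board[start]
    n = board.shape[0]
    seen = np.zeros(n, np.uint8)
    out[0] = start
    seen[start] = 1
    head = 0
    cnt = 1
    while head < cnt:
        q = out[head]
        head += 1
        for k in range(4):
            r = neigh[q, k]
            if r >= 0 and board[r] == c and seen[r] == 0:
                seen[r] = 1
                out[cnt] = r
                cnt += 1
    return cnt


@njit(cache=True)
def k_chain_liberty_points(board, neigh, start, libs):
    """Distinct liberty points of the chain containing `start` (a stone).

    Fills `libs` (ascending scan order NOT guaranteed) and returns the count.
    """
    n = board.shape[0]
    c = board[start]
    seen = np.zeros(n, np.uint8)
    mark = np.zeros(n, np.uint8)
    stack = np.empty(n, np.int32)
    stack[0] = start
    seen[start] = 1
    sp = 1
    nl = 0
    while sp > 0:
        sp -= 1
        q = stack[sp]
        for k in range(4):
            r = neigh[q, k]
            if r < 0:
                continue
            if board[r] == c:
                if seen[r] == 0:
                    seen[r] = 1
                    stack[sp] = r
                    sp += 1
            elif board[r] == EMPTY:
                if mark[r] == 0:
                    mark[r] = 1
                    libs[nl] = r
                    nl += 1
    return nl


@njit(cache=True)
def k_chain_lib_count(board, neigh, start):
    libs = np.empty(board.shape[0], np.int32)
    return k_chain_liberty_points(board, neigh, start, libs)


@njit(cache=True)
def k_chain_libs_capped(board, neigh, start, cap, libbuf):
    """Like k_chain_liberty_points but stops as soon as `cap` distinct
    liberties are found; returns min(#libs, cap). `libbuf` needs room for
    `cap` points."""
    n = board.shape[0]
    c = board[start]
    seen = np.zeros(n, np.uint8)
    mark = np.zeros(n, np.uint8)
    stack = np.empty(n, np.int32)
    stack[0] = start
    seen[start] = 1
    sp = 1
    nl = 0
    while sp > 0:
        sp -= 1
        q = stack[sp]
        for k in range(4):
            r = neigh[q, k]
            if r < 0:
                continue
            if board[r] == c:
                if seen[r] == 0:
                    seen[r] = 1
                    stack[sp] = r
                    sp += 1
            elif board[r] == EMPTY:
                if mark[r] == 0:
                    mark[r] = 1
                    libbuf[nl] = r
                    nl += 1
                    if nl >= cap:
                        return nl
    return nl


@njit(cache=True)
def k_remove_chain(board, neigh, start):
    """Remove the chain containing `start`; returns number of stones removed."""
    c = board[start]
    n = board.shape[0]
    stack = np.empty(n, np.int32)
    stack[0] = start
    board[start] = EMPTY
    sp = 1
    cnt = 1
    while sp > 0:
        sp -= 1
        q = stack[sp]
        for k in range(4):
            r = neigh[q, k]
            if r >= 0 and board[r] == c:
                board[r] = EMPTY
                stack[sp] = r
                sp += 1
                cnt += 1
    return cnt


@njit(cache=True)
def k_play(board, neigh, p, c):
    """Place a stone of colour `c` at empty point `p`, resolving captures.

    Mutates `board` only if the move is not suicide. Returns
    ``(ok, ncaptured, captured_point, own_libs_after)`` where
    `captured_point` is the point of the captured stone when exactly one
    stone was captured (else -1).
    """
    board[p] = c
    ncap = 0
    cap_pt = -1
    buf = np.empty(2, np.int32)
    for k in range(4):
        r = neigh[p, k]
        if r >= 0 and board[r] == -c:
            if k_chain_libs_capped(board, neigh, r, 1, buf) == 0:
                removed = k_remove_chain(board, neigh, r)
                if ncap == 0 and removed == 1:
                    cap_pt = r
                ncap += removed
    if ncap > 1:
        cap_pt = -1
    own = k_chain_libs_capped(board, neigh, p, 2, buf)
    if own == 0:
        board[p] = EMPTY
        return False, 0, -1, 0
    return True, ncap, cap_pt, own


@njit(cache=True)
def k_is_own_eye(board, neigh, p, c):
    """True if empty `p` has every on-board orthogonal neighbour of colour `c`."""
    any_nb = False
    for k in range(4):
        r = neigh[p, k]
        if r >= 0:
            any_nb = True
            if board[r] != c:
                return False
    return any_nb


@njit(cache=True)
def k_is_legal(board, neigh, p, c, ko_point):
    if board[p] != EMPTY or p == ko_point:
        return False
    # fast path: an empty orthogonal neighbour rules out suicide
    for k in range(4):
        r = neigh[p, k]
        if r >= 0 and board[r] == EMPTY:
            return True
    work = board.copy()
    ok, _, _, _ = k_play(work, neigh, p, c)
    return ok


@njit(cache=True)
def k_playable_points(board, neigh, c, ko_point, exclude_own_eyes, out):
    """Legal points for colour `c` (optionally excluding own single-point eyes),
    in scan order. Fills `out`, returns the count."""
    cnt = 0
    for p in range(board.shape[0]):
        if board[p] != EMPTY or p == ko_point:
            continue
        if exclude_own_eyes and k_is_own_eye(board, neigh, p, c):
            continue
        if k_is_legal(board, neigh, p, c, ko_point):
            out[cnt] = p
            cnt += 1
    return cnt


# --------------------------------------------------------------------------
# group decomposition (common fate graph node statistics)

@njit(cache=True)
def k_groups(board, neigh):
    """Label maximal 4-connected monochromatic chains in scan order.

    Returns ``(labels, colors, sizes, nlibs, eyes, roots, ng,
    eye_pts, eye_grps, n_eye_entries)``.  `roots[g]` is the scan-smallest
    member of group g; labels are assigned in ascending root order.
    Eye entries enumerate (eye point, bordering group) pairs: an empty point
    whose on-board orthogonal neighbours are all one colour is an eye of every
    distinct bordering group of that colour.
    """
    n = board.shape[0]
    labels = np.full(n, -1, np.int32)
    colors = np.empty(n, np.int8)
    sizes = np.zeros(n, np.int32)
    roots = np.empty(n, np.int32)
    stack = np.empty(n, np.int32)
    ng = 0
    for p in range(n):
        if board[p] != EMPTY and labels[p] == -1:
            c = board[p]
            labels[p] = ng
            roots[ng] = p
            colors[ng] = c
            stack[0] = p
            sp = 1
            cnt = 0
            while sp > 0:
                sp -= 1
                q = stack[sp]
                cnt += 1
                for k in range(4):
                    r = neigh[q, k]
                    if r >= 0 and board[r] == c and labels[r] == -1:
                        labels[r] = ng
                        stack[sp] = r
                        sp += 1
            sizes[ng] = cnt
            ng += 1
    nlibs = np.zeros(max(ng, 1), np.int32)
    eyes = np.zeros(max(ng, 1), np.int32)
    eye_pts = np.empty(4 * n, np.int32)
    eye_grps = np.empty(4 * n, np.int32)
    ne = 0
    for p in range(n):
        if board[p] != EMPTY:
            continue
        # distinct adjacent groups (at most 4)
        g0 = -1
        g1 = -1
        g2 = -1
        g3 = -1
        eye_col = 0  # 0 unknown, +-1 candidate eye colour, 2 not an eye
        for k in range(4):
            r = neigh[p, k]
            if r < 0:
                continue
            if board[r] == EMPTY:
                eye_col = 2
                continue
            if eye_col == 0:
                eye_col = board[r]
            elif eye_col != board[r]:
                eye_col = 2
            lg = labels[r]
            if lg != g0 and lg != g1 and lg != g2 and lg != g3:
                if g0 == -1:
                    g0 = lg
                elif g1 == -1:
                    g1 = lg
                elif g2 == -1:
                    g2 = lg
                else:
                    g3 = lg
        if g0 >= 0:
            nlibs[g0] += 1
        if g1 >= 0:
            nlibs[g1] += 1
        if g2 >= 0:
            nlibs[g2] += 1
        if g3 >= 0:
            nlibs[g3] += 1
        if eye_col == 1 or eye_col == -1:
            # p is an eye; credit every distinct bordering group (shared eyes
            # count once per bordering group)
            if g0 >= 0:
                eyes[g0] += 1
                eye_pts[ne] = p
                eye_grps[ne] = g0
                ne += 1
            if g1 >= 0:
                eyes[g1] += 1
                eye_pts[ne] = p
                eye_grps[ne] = g1
                ne += 1
            if g2 >= 0:
                eyes[g2] += 1
                eye_pts[ne] = p
                eye_grps[ne] = g2
                ne += 1
            if g3 >= 0:
                eyes[g3] += 1
                eye_pts[ne] = p
                eye_grps[ne] = g3
                ne += 1
    return (labels, colors[:ng], sizes[:ng], nlibs[:ng], eyes[:ng],
            roots[:ng], ng, eye_pts[:ne], eye_grps[:ne], ne)


@njit(cache=True)
def k_pair_matrices(board, neigh, labels, ng):
    """Boolean (ng, ng) matrices: `shared` (>=1 common liberty) and `adj`
    (shared liberty OR directly adjacent stones)."""
    n = board.shape[0]
    shared = np.zeros((ng, ng), np.uint8)
    adj = np.zeros((ng, ng), np.uint8)
    for p in range(n):
        if board[p] == EMPTY:
            g0 = -1
            g1 = -1
            g2 = -1
            g3 = -1
            for k in range(4):
                r = neigh[p, k]
                if r >= 0 and board[r] != EMPTY:
                    lg = labels[r]
                    if lg != g0 and lg != g1 and lg != g2 and lg != g3:
                        if g0 == -1:
                            g0 = lg
                        elif g1 == -1:
                            g1 = lg
                        elif g2 == -1:
                            g2 = lg
                        else:
                            g3 = lg
            if g1 >= 0:
                shared[g0, g1] = 1
                shared[g1, g0] = 1
            if g2 >= 0:
                shared[g0, g2] = 1
                shared[g2, g0] = 1
                shared[g1, g2] = 1
                shared[g2, g1] = 1
            if g3 >= 0:
                shared[g0, g3] = 1
                shared[g3, g0] = 1
                shared[g1, g3] = 1
                shared[g3, g1] = 1
                shared[g2, g3] = 1
                shared[g3, g2] = 1
        else:
            a = labels[p]
            for k in range(4):
                r = neigh[p, k]
                if r >= 0 and board[r] != EMPTY:
                    b = labels[r]
                    if b != a:
                        adj[a, b] = 1
                        adj[b, a] = 1
    for i in range(ng):
        for j in range(ng):
            if shared[i, j]:
                adj[i, j] = 1
    return shared, adj


# --------------------------------------------------------------------------
# tactic searches

@njit(cache=True)
def k_quick_escape(board, neigh, libs, nl, chain_color):
    """Sound escape certificate for a chain with liberties ``libs[:nl]``.

    True if extending at some liberty yields >= 3 liberties even ignoring
    merges and captures (which can only add liberties); such a chain can
    neither be ladder-captured nor held in a net.
    """
    for t in range(nl):
        p = libs[t]
        cnt = nl - 1
        for k in range(4):
            r = neigh[p, k]
            if r >= 0 and board[r] == EMPTY:
                already = False
                for u in range(nl):
                    if libs[u] == r:
                        already = True
                        break
                if not already:
                    cnt += 1
        if cnt >= 3:
            return True
    return False


@njit(cache=True)
def k_ladder_captured(board, neigh, start, depth_cap):
    """Bounded forced read-out for a chain in atari (exactly one liberty).

    Defender extends at its single liberty; with two liberties the attacker
    plays the scan-smallest legal, non-self-atari liberty that returns the
    chain to atari.  True iff the chain is captured within `depth_cap` plies.
    """
    n = board.shape[0]
    work = board.copy()
    dcolor = work[start]
    tstart = start
    libs = np.empty(4, np.int32)
    buf = np.empty(2, np.int32)
    plies = 0
    while plies < depth_cap:
        nl = k_chain_libs_capped(work, neigh, tstart, 3, libs)
        if nl == 0:
            return True
        if nl >= 3:
            return False
        if nl == 1:
            if k_quick_escape(work, neigh, libs, nl, dcolor):
                return False
            p = libs[0]
            ok, _, _, _ = k_play(work, neigh, p, dcolor)
            if not ok:
                return True  # the extension is suicide: unavoidable capture
            plies += 1
            tstart = p
            continue
        # nl == 2: attacker's turn.  A liberty qualifies when filling it is
        # legal, not self-atari, and returns the chain to atari; among
        # qualifying liberties the attacker drives the ladder by choosing the
        # one leaving the defender's forced extension the fewest liberties
        # (tie: scan order), the standard chase rule.
        a = libs[0]
        b = libs[1]
        if a > b:
            a, b = b, a
        best_score = 99
        plybuf = np.empty(4, np.int32)
        best_trial = work
        for t in range(2):
            p = a if t == 0 else b
            trial = work.copy()
            ok, _, _, own = k_play(trial, neigh, p, -dcolor)
            if not ok or own < 2:
                continue
            if trial[tstart] == EMPTY:
                continue
            if k_chain_libs_capped(trial, neigh, tstart, 2, buf) != 1:
                continue
            # defender's forced reply: extend at the remaining liberty
            look = trial.copy()
            ok2, _, _, _ = k_play(look, neigh, buf[0], dcolor)
            score = 0 if not ok2 else k_chain_libs_capped(look, neigh, buf[0],
                                                          4, plybuf)
            if score < best_score:
                best_score = score
                best_trial = trial
        if best_score == 99:
            return False
        work = best_trial
        plies += 1
    return False


@njit(cache=True)
def k_net_check(board0, neigh, tstart, depth):
    """Depth-limited escape search for a chain with <= 2 liberties.

    The defender (the chain's colour) moves first, trying to raise the
    chain's liberties above 2 by extending at a liberty or capturing an
    adjacent adversary chain in atari; the attacker replies by filling a
    chain liberty (scan order).  Returns True iff the defender cannot exceed
    2 liberties within `depth` plies — the chain is held in the net.

    Iterative AND-OR search (defender nodes require every child trapped,
    attacker nodes require one child trapped) with an explicit stack.
    """
    n = board0.shape[0]
    dcolor = board0[tstart]
    libs = np.empty(4, np.int32)
    ebuf = np.empty(2, np.int32)
    nl0 = k_chain_libs_capped(board0, neigh, tstart, 3, libs)
    if nl0 >= 3:
        return False
    if k_quick_escape(board0, neigh, libs, nl0, dcolor):
        return False
    if depth == 0 or nl0 == 0:
        return True
    boards = np.empty((depth + 1, n), np.int8)
    moves = np.empty((depth + 1, n), np.int32)
    nmov = np.zeros(depth + 1, np.int64)
    imov = np.zeros(depth + 1, np.int64)
    boards[0, :] = board0
    lev = 0
    state = 0  # 0: enter node, 1: propagate result, 2: advance to next child
    result = False
    while True:
        if state == 0:
            b = boards[lev]
            defender = lev % 2 == 0
            if b[tstart] == EMPTY:
                result = True  # captured during the search
                state = 1
                continue
            nl = k_chain_libs_capped(b, neigh, tstart, 3, libs)
            if nl >= 3:
                result = False
                state = 1
                continue
            if lev == depth:
                result = True
                state = 1
                continue
            if defender and k_quick_escape(b, neigh, libs, nl, dcolor):
                result = False
                state = 1
                continue
            nm = 0
            if defender:
                mask = np.zeros(n, np.uint8)
                for t in range(nl):
                    mask[libs[t]] = 1
                chain = np.empty(n, np.int32)
                csz = k_chain_points(b, neigh, tstart, chain)
                for t in range(csz):
                    q = chain[t]
                    for k in range(4):
                        r = neigh[q, k]
                        if r >= 0 and b[r] == -dcolor:
                            if k_chain_libs_capped(b, neigh, r, 2, ebuf) == 1:
                                mask[ebuf[0]] = 1
                for p in range(n):
                    if mask[p]:
                        moves[lev, nm] = p
                        nm += 1
            else:
                order = np.sort(libs[:nl])
                for t in range(nl):
                    moves[lev, nm] = order[t]
                    nm += 1
            nmov[lev] = nm
            imov[lev] = 0
            state = 2
            continue
        if state == 2:
            defender = lev % 2 == 0
            c = dcolor if defender else -dcolor
            pushed = False
            while imov[lev] < nmov[lev]:
                p = moves[lev, imov[lev]]
                imov[lev] += 1
                boards[lev + 1, :] = boards[lev]
                ok, _, _, _ = k_play(boards[lev + 1], neigh, p, c)
                if ok:
                    lev += 1
                    state = 0
                    pushed = True
                    break
            if not pushed:
                # children exhausted without a short-circuit
                result = defender  # defender: all tries stay trapped; attacker: no hold found
                state = 1
            continue
        # state == 1: propagate `result` of node `lev` to its parent
        if lev == 0:
            return result
        lev -= 1
        defender = lev % 2 == 0
        if defender:
            if not result:
                state = 1  # an escaping line refutes the net
            else:
                state = 2
        else:
            if result:
                state = 1  # attacker found a holding reply
            else:
                state = 2


@njit(cache=True)
def k_incursions(board, labels, colors, sizes, roots, ng, size, radius, has_conn):
    """Classify each group as INVASION (1), REDUCTION (2) or neither (0).

    A group's neighbourhood is the Chebyshev-`radius` window around its
    members, excluding the members themselves.  INVASION: the group has no
    same-colour shared-liberty partner (isolated) and adversary stones
    strictly outnumber allied ones in the neighbourhood.  REDUCTION: any
    other group with at least one adversary stone in the neighbourhood.
    """
    n = board.shape[0]
    kind = np.zeros(ng, np.int8)
    # bucket members by label
    offs = np.zeros(ng + 1, np.int32)
    for p in range(n):
        if board[p] != EMPTY:
            offs[labels[p] + 1] += 1
    for g in range(ng):
        offs[g + 1] += offs[g]
    members = np.empty(offs[ng], np.int32)
    cur = offs.copy()
    for p in range(n):
        if board[p] != EMPTY:
            members[cur[labels[p]]] = p
            cur[labels[p]] += 1
    stamp = np.full(n, -1, np.int32)
    for g in range(ng):
        c = colors[g]
        adv = 0
        ally = 0
        for t in range(offs[g], offs[g + 1]):
            p = members[t]
            pr = p // size
            pc = p % size
            r0 = pr - radius if pr - radius > 0 else 0
            r1 = pr + radius if pr + radius < size - 1 else size - 1
            c0 = pc - radius if pc - radius > 0 else 0
            c1 = pc + radius if pc + radius < size - 1 else size - 1
            for rr in range(r0, r1 + 1):
                base = rr * size
                for cc in range(c0, c1 + 1):
                    q = base + cc
                    if stamp[q] == g:
                        continue
                    stamp[q] = g
                    if board[q] == EMPTY or labels[q] == g:
                        continue
                    if board[q] == c:
                        ally += 1
                    else:
                        adv += 1
        if adv > ally and has_conn[g] == 0:
            kind[g] = 1
        elif adv >= 1:
            kind[g] = 2
    return kind


# --------------------------------------------------------------------------
# full position evaluation

@njit(cache=True)
def k_evaluate(board, neigh, size, W, ladder_cap, net_depth, inv_radius):
    """Evaluate the Ising Hamiltonian of a position, both sides.

    Returns ``(H_c, H_i, H_literal, labels, colors, sizes, nlibs, eyes,
    roots, ng, x, pair_i, pair_j, pair_w, pair_shared, npairs,
    inst_kind, inst_owner, inst_grp, inst_med, inst_pt, ninst)`` —
    everything needed to build the rich report; callers on the hot path use
    only the leading scalars.
    """
    (labels, colors, sizes, nlibs, eyes, roots, ng,
     eye_pts, eye_grps, ne) = k_groups(board, neigh)
    b_eye = W[11]
    mu = W[12]
    r_sl = W[10]
    x = np.empty(ng, np.float64)
    for g in range(ng):
        e = b_eye ** eyes[g] if eyes[g] >= 1 else 0.0
        x[g] = colors[g] * (sizes[g] + e)
    shared, adj = k_pair_matrices(board, neigh, labels, ng)

    # CFG-adjacent pair list + per-group neighbour index
    npairs = 0
    for i in range(ng):
        for j in range(i + 1, ng):
            if adj[i, j]:
                npairs += 1
    pair_i = np.empty(npairs, np.int32)
    pair_j = np.empty(npairs, np.int32)
    pair_shared = np.empty(npairs, np.uint8)
    pair_w = np.zeros(npairs, np.float64)
    pair_has_inst = np.zeros(npairs, np.uint8)
    # mixed-pair pressure decomposition: instance terms press the owner's
    # adversary (press_b: terms raising the cancer side, press_w: immune)
    press_b = np.zeros(npairs, np.float64)
    press_w = np.zeros(npairs, np.float64)
    pair_id = np.full((ng, ng), -1, np.int64)
    deg = np.zeros(ng + 1, np.int64)
    t = 0
    for i in range(ng):
        for j in range(i + 1, ng):
            if adj[i, j]:
                pair_i[t] = i
                pair_j[t] = j
                pair_shared[t] = shared[i, j]
                pair_id[i, j] = t
                pair_id[j, i] = t
                deg[i + 1] += 1
                deg[j + 1] += 1
                t += 1
    for g in range(ng):
        deg[g + 1] += deg[g]
    nbr = np.empty(2 * npairs, np.int32)
    cur = deg.copy()
    for t in range(npairs):
        i = pair_i[t]
        j = pair_j[t]
        nbr[cur[i]] = j
        cur[i] += 1
        nbr[cur[j]] = i
        cur[j] += 1

    has_conn = np.zeros(ng, np.uint8)
    for t in range(npairs):
        if pair_shared[t] and colors[pair_i[t]] == colors[pair_j[t]]:
            has_conn[pair_i[t]] = 1
            has_conn[pair_j[t]] = 1

    inc = k_incursions(board, labels, colors, sizes, roots, ng, size,
                       inv_radius, has_conn)

    # Mediating descriptors enter the pair weights with the owner's
    # own-side sign (|x_s|), mirroring the side-relative field convention;
    # otherwise one side's tactics would systematically lower the energy
    # while the other side's raised it.
    # instance log: kind, owner colour, principal group, mediating group,
    # anchor (eye point; partner group id for CONNECTION; else -1)
    cap = ne + npairs + 4 * ng + 8
    inst_kind = np.empty(cap, np.int8)
    inst_owner = np.empty(cap, np.int8)
    inst_grp = np.empty(cap, np.int32)
    inst_med = np.empty(cap, np.int32)
    inst_pt = np.empty(cap, np.int32)
    ninst = 0

    # eyes: one instance per (group, eye point); weight r_eye(owner side),
    # mediated by the owning group, attached to every adjacent adversary pair
    for e_t in range(ne):
        g = eye_grps[e_t]
        c = colors[g]
        base = 0 if c == BLACK else 5
        r = W[base + 0]
        inst_kind[ninst] = K_EYE
        inst_owner[ninst] = c
        inst_grp[ninst] = g
        inst_med[ninst] = g
        inst_pt[ninst] = eye_pts[e_t]
        ninst += 1
        for u in range(deg[g], deg[g + 1]):
            j = nbr[u]
            if colors[j] != c:
                pid = pair_id[g, j]
                val = r * abs(x[g])
                pair_w[pid] += val
                pair_has_inst[pid] = 1
                if c == BLACK:
                    press_w[pid] += val
                else:
                    press_b[pid] += val

    # connections: same-colour pairs sharing >= 1 liberty; mediator = smaller id
    for t in range(npairs):
        i = pair_i[t]
        j = pair_j[t]
        if pair_shared[t] and colors[i] == colors[j]:
            c = colors[i]
            base = 0 if c == BLACK else 5
            pair_w[t] += W[base + 3] * abs(x[i])
            pair_has_inst[t] = 1
            inst_kind[ninst] = K_CONNECTION
            inst_owner[ninst] = c
            inst_grp[ninst] = i
            inst_med[ninst] = i
            inst_pt[ninst] = j
            ninst += 1

    # atari, ladder, net per group; invasion/reduction attachment
    for g in range(ng):
        c = colors[g]
        owner = -c
        base_adv = 0 if owner == BLACK else 5
        caught_ladder = False
        caught_net = False
        if nlibs[g] == 1:
            inst_kind[ninst] = K_ATARI
            inst_owner[ninst] = owner
            inst_grp[ninst] = g
            inst_med[ninst] = -1
            inst_pt[ninst] = -1
            ninst += 1
            if k_ladder_captured(board, neigh, roots[g], ladder_cap):
                caught_ladder = True
        if nlibs[g] <= 2 and eyes[g] < 2:
            # two-eyed groups are alive (their liberties can never be
            # filled), hence never nettable
            if k_net_check(board, neigh, roots[g], net_depth):
                caught_net = True
        if caught_ladder or caught_net:
            med = -1
            for u in range(deg[g], deg[g + 1]):
                j = nbr[u]
                if colors[j] == owner and (med == -1 or j < med):
                    med = j
            xm = abs(x[med]) if med >= 0 else 1.0
            for two in range(2):
                if two == 0 and not caught_ladder:
                    continue
                if two == 1 and not caught_net:
                    continue
                r = W[base_adv + 2] if two == 0 else W[base_adv + 1]
                inst_kind[ninst] = K_LADDER if two == 0 else K_NET
                inst_owner[ninst] = owner
                inst_grp[ninst] = g
                inst_med[ninst] = med
                inst_pt[ninst] = -1
                ninst += 1
                for u in range(deg[g], deg[g + 1]):
                    j = nbr[u]
                    if colors[j] == owner:
                        pid = pair_id[g, j]
                        val = r * xm
                        pair_w[pid] += val
                        pair_has_inst[pid] = 1
                        if owner == BLACK:
                            press_w[pid] += val
                        else:
                            press_b[pid] += val
        if inc[g] != 0:
            base = 0 if c == BLACK else 5
            r = W[base + 4]
            inst_kind[ninst] = K_INVASION if inc[g] == 1 else K_REDUCTION
            inst_owner[ninst] = c
            inst_grp[ninst] = g
            inst_med[ninst] = g
            inst_pt[ninst] = -1
            ninst += 1
            for u in range(deg[g], deg[g + 1]):
                j = nbr[u]
                if colors[j] != c:
                    pid = pair_id[g, j]
                    val = r * abs(x[g])
                    pair_w[pid] += val
                    pair_has_inst[pid] = 1
                    if c == BLACK:
                        press_w[pid] += val
                    else:
                        press_b[pid] += val

    # single-liberty coupling for instance-free shared-liberty pairs,
    # then Hamiltonian assembly over the pair list.  Side split: own-side
    # synergy is stabilizing (same-colour pairs enter a side's energy with a
    # minus sign, mirroring the side-relative field convention); the tension
    # of mixed pairs raises both sides' energies half each.  H_literal keeps
    # the raw signed Eq-style sum.
    # H_diff accumulates H_cancer - H_immune from the side-specific terms
    # only: the mixed-pair halves cancel exactly in the difference, and
    # summing them first would drown the margin below float64 resolution
    # once eye terms grow large.
    H_c = 0.0
    H_i = 0.0
    H_lit = 0.0
    H_diff = 0.0
    for t in range(npairs):
        if pair_shared[t] and not pair_has_inst[t]:
            pair_w[t] = r_sl
        w = pair_w[t]
        if w != 0.0:
            i = pair_i[t]
            j = pair_j[t]
            H_lit += w * x[i] * x[j]
            axi = x[i] if x[i] >= 0 else -x[i]
            axj = x[j] if x[j] >= 0 else -x[j]
            mag = w * axi * axj
            if colors[i] == colors[j]:
                if colors[i] == BLACK:
                    H_c -= mag
                    H_diff -= mag
                else:
                    H_i -= mag
                    H_diff += mag
            else:
                # adversary tactic pressure raises the pressured side's
                # energy; the ownerless r_sl coupling splits evenly
                xx = axi * axj
                pb = press_b[t] * xx
                pw = press_w[t] * xx
                rest = mag - pb - pw
                H_c += pb + 0.5 * rest
                H_i += pw + 0.5 * rest
                H_diff += pb - pw
    for g in range(ng):
        ax = x[g] if x[g] >= 0 else -x[g]
        fld = mu * nlibs[g] * ax
        if colors[g] == BLACK:
            H_c -= fld
            H_diff -= fld
        else:
            H_i -= fld
            H_diff += fld
        H_lit -= mu * nlibs[g] * x[g]
    return (H_c, H_i, H_diff, H_lit, labels, colors, sizes, nlibs, eyes,
            roots, ng, x, pair_i, pair_j, pair_w, pair_shared, npairs,
            inst_kind[:ninst], inst_owner[:ninst], inst_grp[:ninst],
            inst_med[:ninst], inst_pt[:ninst], ninst)


@njit(cache=True)
def k_eval_sides(board, neigh, size, W, ladder_cap, net_depth, inv_radius):
    """Fast path: (H_cancer, H_immune, H_diff, lib_sum_cancer, lib_sum_immune)
    with H_diff = H_cancer - H_immune accumulated without the (exactly
    cancelling) mixed-pair terms."""
    out = k_evaluate(board, neigh, size, W, ladder_cap, net_depth, inv_radius)
    colors = out[5]
    nlibs = out[7]
    lib_c = 0
    lib_i = 0
    for g in range(colors.shape[0]):
        if colors[g] == BLACK:
            lib_c += nlibs[g]
        else:
            lib_i += nlibs[g]
    return out[0], out[1], out[2], lib_c, lib_i


# --------------------------------------------------------------------------
# random playout (used by the Monte-Carlo agent)

@njit(cache=True)
def k_random_playout(board, neigh, to_move, ko_point, depth, seed):
    """Uniform-random playout in place for `depth` plies (or until both sides
    pass), excluding own single-point eyes. Deterministic for a given seed."""
    np.random.seed(seed)
    n = board.shape[0]
    cand = np.empty(n, np.int32)
    passes = 0
    c = to_move
    ko = ko_point
    for _ in range(depth):
        ncand = 0
        for p in range(n):
            if board[p] == EMPTY and p != ko and not k_is_own_eye(board, neigh, p, c):
                cand[ncand] = p
                ncand += 1
        played = False
        while ncand > 0:
            t = np.random.randint(0, ncand)
            p = cand[t]
            ok, ncap, cap_pt, own = k_play(board, neigh, p, c)
            if ok:
                ko = cap_pt if (ncap == 1 and own == 1) else -1
                played = True
                break
            cand[t] = cand[ncand - 1]
            ncand -= 1
        if played:
            passes = 0
        else:
            passes += 1
            ko = -1
            if passes >= 2:
                break
        c = -c
    return 0
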