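"""Independent brute-force oracles used by the test suite.

Everything here is implemented from the documented rules with plain Python
dictionaries/sets and recursion — no shared code with the package's compiled
kernels — so agreement between the two is a meaningful check.
"""

from __future__ import annotations

import itertools

BLACK = -1
WHITE = 1
EMPTY = 0


def neighbours(p, size):
    r, c = p
    out = []
    if r > 0:
        out.append((r - 1, c))
    if c > 0:
        out.append((r, c - 1))
    if c < size - 1:
        out.append((r, c + 1))
    if r < size - 1:
        out.append((r + 1, c))
    return out


def chain_of(grid, size, p):
    """Set of points of the monochromatic chain containing stone p."""
    color = grid[p]
    seen = {p}
    frontier = [p]
    while frontier:
        q = frontier.pop()
        for r in neighbours(q, size):
            if grid.get(r, EMPTY) == color and r not in seen:
                seen.add(r)
                frontier.append(r)
    return seen


def chain_liberties(grid, size, chain):
    libs = set()
    for q in chain:
        for r in neighbours(q, size):
            if grid.get(r, EMPTY) == EMPTY:
                libs.add(r)
    return libs


def play(grid, size, p, color):
    """Play-and-check move application.

    Returns (new_grid, captured_count) or None if the move is suicide.
    `grid` maps point -> colour for stones only.
    """
    if grid.get(p, EMPTY) != EMPTY:
        raise ValueError("occupied")
    new = dict(grid)
    new[p] = color
    captured = 0
    for r in neighbours(p, size):
        if new.get(r, EMPTY) == -color:
            ch = chain_of(new, size, r)
            if not chain_liberties(new, size, ch):
                for q in ch:
                    del new[q]
                captured += len(ch)
    own = chain_of(new, size, p)
    if not chain_liberties(new, size, own):
        return None
    return new, captured


def legal_points(grid, size, color, ko_point=None):
    """All empty points where `color` may play: not suicide, not the ko
    point."""
    out = set()
    for p in itertools.product(range(size), range(size)):
        if grid.get(p, EMPTY) != EMPTY or p == ko_point:
            continue
        if play(grid, size, p, color) is not None:
            out.add(p)
    return out


def area_scores(grid, size, captures_black=0, captures_white=0, komi=0.0):
    """Flood-fill area scoring oracle."""
    black = sum(1 for v in grid.values() if v == BLACK) + captures_black
    white = sum(1 for v in grid.values() if v == WHITE) + captures_white
    seen = set()
    for p in itertools.product(range(size), range(size)):
        if grid.get(p, EMPTY) != EMPTY or p in seen:
            continue
        region = {p}
        frontier = [p]
        borders = set()
        while frontier:
            q = frontier.pop()
            for r in neighbours(q, size):
                v = grid.get(r, EMPTY)
                if v == EMPTY:
                    if r not in region:
                        region.add(r)
                        frontier.append(r)
                else:
                    borders.add(v)
        seen |= region
        if borders == {BLACK}:
            black += len(region)
        elif borders == {WHITE}:
            white += len(region)
    return float(black), float(white) + komi


# --------------------------------------------------------------------------
# group decomposition via union-find (independent of the flood-fill kernels)

class _UF:
    def __init__(self):
        self.parent = {}

    def find(self, a):
        while self.parent.setdefault(a, a) != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def groups_of(grid, size):
    """Partition stones into chains with union-find; returns a list of
    (color, frozenset(points)) sorted by smallest member in scan order."""
    uf = _UF()
    for p, v in grid.items():
        uf.find(p)
        for r in neighbours(p, size):
            if grid.get(r, EMPTY) == v:
                uf.union(p, r)
    buckets = {}
    for p in grid:
        buckets.setdefault(uf.find(p), set()).add(p)
    out = [(grid[next(iter(m))], frozenset(m)) for m in buckets.values()]
    return sorted(out, key=lambda t: min(t[1]))


def eyes_of_group(grid, size, chain, color):
    """Eye points of a chain: empty points whose every on-board neighbour is
    `color`, at least one of them in `chain`."""
    out = set()
    for p in chain_liberties(grid, size, chain):
        nbrs = neighbours(p, size)
        if all(grid.get(r, EMPTY) == color for r in nbrs) and \
                any(r in chain for r in nbrs):
            out.add(p)
    return out


# --------------------------------------------------------------------------
# tactic searches (independent recursive formulations)

def ladder_captured(grid, size, chain_pt, depth_cap=50):
    """Forced ladder read-out on a chain in atari.

    Defender extends at its single liberty; attacker fills the qualifying
    liberty (legal, not self-atari, re-ataris the chain) that leaves the
    defender's forced extension the fewest liberties, ties by scan order.
    """
    grid = dict(grid)
    color = grid[chain_pt]
    target = chain_pt
    for _ in range(depth_cap):
        chain = chain_of(grid, size, target)
        libs = sorted(chain_liberties(grid, size, chain))
        if len(libs) == 0:
            return True
        if len(libs) >= 3:
            return False
        if len(libs) == 1:
            res = play(grid, size, libs[0], color)
            if res is None:
                return True
            grid = res[0]
            target = libs[0]
            continue
        best = None
        for p in libs:
            res = play(grid, size, p, -color)
            if res is None:
                continue
            g2 = res[0]
            att = chain_of(g2, size, p)
            if len(chain_liberties(g2, size, att)) < 2:
                continue
            if target not in g2:
                continue
            tch = chain_of(g2, size, target)
            tlibs = chain_liberties(g2, size, tch)
            if len(tlibs) != 1:
                continue
            (ext,) = tlibs
            res2 = play(g2, size, ext, color)
            score = 0 if res2 is None else len(
                chain_liberties(res2[0], size, chain_of(res2[0], size, ext)))
            if best is None or score < best[0]:
                best = (score, p, g2)
        if best is None:
            return False
        grid = best[2]
    return False


def net_trapped(grid, size, chain_pt, depth=4, defender_turn=True):
    """Escape search: True iff the chain cannot exceed 2 liberties within
    `depth` plies (defender extends or captures adjacent ataris; attacker
    fills chain liberties)."""
    if grid.get(chain_pt, EMPTY) == EMPTY:
        return True
    color = grid[chain_pt]
    chain = chain_of(grid, size, chain_pt)
    libs = chain_liberties(grid, size, chain)
    if len(libs) >= 3:
        return False
    if len(libs) == 0:
        return True
    if depth == 0:
        return True
    if defender_turn:
        moves = set(libs)
        for q in chain:
            for r in neighbours(q, size):
                if grid.get(r, EMPTY) == -color:
                    ech = chain_of(grid, size, r)
                    elibs = chain_liberties(grid, size, ech)
                    if len(elibs) == 1:
                        moves |= elibs
        for p in sorted(moves):
            res = play(grid, size, p, color)
            if res is None:
                continue
            if not net_trapped(res[0], size, chain_pt, depth - 1, False):
                return False
        return True
    for p in sorted(libs):
        res = play(grid, size, p, -color)
        if res is None:
            continue
        if net_trapped(res[0], size, chain_pt, depth - 1, True):
            return True
    return False


def incursion_kind(grid, size, chain, color, all_groups, radius=2):
    """'invasion' | 'reduction' | None under the neighbourhood-count rule."""
    window = set()
    for (r, c) in chain:
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                q = (r + dr, c + dc)
                if 0 <= q[0] < size and 0 <= q[1] < size:
                    window.add(q)
    ally = sum(1 for q in window
               if grid.get(q, EMPTY) == color and q not in chain)
    adv = sum(1 for q in window if grid.get(q, EMPTY) == -color)
    libs = chain_liberties(grid, size, chain)
    isolated = True
    for other_color, other in all_groups:
        if other is chain or other_color != color:
            continue
        if libs & chain_liberties(grid, size, other):
            isolated = False
            break
    if isolated and adv > ally:
        return "invasion"
    if adv >= 1:
        return "reduction"
    return None


# --------------------------------------------------------------------------
# full energy evaluation

def evaluate(grid, size, *, cancer=None, immune=None, r_sl=1.0, b_eye=2.0,
             mu=1.0, ladder_cap=50, net_depth=4, radius=2):
    """Brute-force Hamiltonian: returns (H_cancer, H_immune, H_margin).

    Follows the documented model: x_i = c_i (n_i + b_eye^k_i); pair weights
    sum r_t(owner)·|x_s| over attached tactic instances (connection: its own
    pair, mediated by the smaller id; eye/invasion/reduction: every adjacent
    adversary pair, mediated by the owner group; ladder/net: every adjacent
    attacker-colour pair, mediated by the scan-smallest attacker neighbour);
    instance-free shared-liberty pairs couple with r_sl.  Side energies:
    own-side pairs -w|x_i||x_j|; a mixed pair's instance terms raise the
    energy of the owner's adversary (the pressured side) while its r_sl part
    splits evenly; field -mu·h_i·|x_i|.  Two-eyed chains are never netted.
    """
    cancer = cancer or {"eye": 0.7, "net": 0.6, "ladder": 0.5,
                        "connection": 0.1, "invasion": 0.4}
    immune = immune or {"eye": 0.4, "net": 0.7, "ladder": 0.5,
                        "connection": 0.1, "reduction": 0.5}

    def r_of(color, tactic):
        table = cancer if color == BLACK else immune
        if tactic == "incursion":
            return table["invasion"] if color == BLACK else table["reduction"]
        return table[tactic]

    gs = groups_of(grid, size)
    n = len(gs)
    libs = [chain_liberties(grid, size, m) for _, m in gs]
    eyes = [eyes_of_group(grid, size, m, c) for c, m in gs]
    x = [c * (len(m) + (b_eye ** len(eyes[i]) if eyes[i] else 0.0))
         for i, (c, m) in enumerate(gs)]

    def adjacent(i, j):
        if libs[i] & libs[j]:
            return True
        ci, mi = gs[i]
        cj, mj = gs[j]
        return any(r in mj for q in mi for r in neighbours(q, size))

    adj = {(i, j) for i in range(n) for j in range(i + 1, n)
           if adjacent(i, j)}
    shared = {(i, j) for (i, j) in adj if libs[i] & libs[j]}

    w = {}
    press = {}  # key -> [raises_cancer, raises_immune] (mixed pairs)
    has_inst = set()

    def attach(i, j, val, owner):
        key = (min(i, j), max(i, j))
        w[key] = w.get(key, 0.0) + val
        has_inst.add(key)
        if gs[i][0] != gs[j][0]:
            pb, pw = press.get(key, (0.0, 0.0))
            if owner == BLACK:
                pw += val  # black-owned tactic presses the immune side
            else:
                pb += val
            press[key] = (pb, pw)

    for i, (c, m) in enumerate(gs):
        # eyes: one instance per eye point
        for _ in eyes[i]:
            for j in range(n):
                if i != j and gs[j][0] != c and \
                        (min(i, j), max(i, j)) in adj:
                    attach(i, j, r_of(c, "eye") * abs(x[i]), c)
        # incursions
        kind = incursion_kind(grid, size, m, c, gs, radius)
        if kind is not None:
            for j in range(n):
                if i != j and gs[j][0] != c and \
                        (min(i, j), max(i, j)) in adj:
                    attach(i, j, r_of(c, "incursion") * abs(x[i]), c)
        # ladder / net against this chain
        caught = []
        if len(libs[i]) == 1 and ladder_captured(grid, size, min(m),
                                                 ladder_cap):
            caught.append("ladder")
        if len(libs[i]) <= 2 and len(eyes[i]) < 2 and \
                net_trapped(grid, size, min(m), net_depth):
            caught.append("net")
        if caught:
            owner = -c
            partners = [j for j in range(n)
                        if j != i and gs[j][0] == owner
                        and (min(i, j), max(i, j)) in adj]
            med = min(partners) if partners else None
            xs = abs(x[med]) if med is not None else 1.0
            for tactic in caught:
                for j in partners:
                    attach(i, j, r_of(owner, tactic) * xs, owner)
    for (i, j) in shared:
        if gs[i][0] == gs[j][0]:
            attach(i, j, r_of(gs[i][0], "connection") * abs(x[min(i, j)]),
                   gs[i][0])
    for (i, j) in shared - has_inst:
        w[(i, j)] = r_sl

    H_c = H_i = H_d = 0.0
    for (i, j), wij in w.items():
        xx = abs(x[i]) * abs(x[j])
        mag = wij * xx
        if gs[i][0] == gs[j][0]:
            if gs[i][0] == BLACK:
                H_c -= mag
                H_d -= mag
            else:
                H_i -= mag
                H_d += mag
        else:
            pb, pw = press.get((i, j), (0.0, 0.0))
            pb *= xx
            pw *= xx
            rest = mag - pb - pw
            H_c += pb + 0.5 * rest
            H_i += pw + 0.5 * rest
            H_d += pb - pw
    for i, (c, m) in enumerate(gs):
        fld = mu * len(libs[i]) * abs(x[i])
        if c == BLACK:
            H_c -= fld
            H_d -= fld
        else:
            H_i -= fld
            H_d += fld
    return H_c, H_i, H_d
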