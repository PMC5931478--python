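"""Go rules engine: board state, legal moves, captures, ko, scoring, SGF I/O.

The playing surface doubles as the tissue in the tumour–immune analogy:
black stones are cancer cells (spin −1), white stones immune/healthy elements
(spin +1).  The engine implements the standard rules subset the simulations
need: positional capture, suicide prohibition, simple ko, game end on two
consecutive passes, and area scoring (stones + territory + captures, with
optional komi).  No superko, handicap or time controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Union

import numpy as np

from . import _engine as eng

BLACK = eng.BLACK  #: cancer side, spin -1
WHITE = eng.WHITE  #: immune side, spin +1
EMPTY = eng.EMPTY

CANCER = BLACK
IMMUNE = WHITE


class _PassType:
    """Singleton sentinel for a pass move."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "PASS"


PASS = _PassType()

Move = Union["Point", _PassType]


class Point(NamedTuple):
    """0-based (row, col), row-major, (0, 0) = top-left."""

    row: int
    col: int


class IllegalMoveError(ValueError):
    """A move violating the rules; `.reason` is 'occupied', 'suicide' or 'ko'."""

    def __init__(self, message: str, reason: str):
        super().__init__(message)
        self.reason = reason


def opponent(color: int) -> int:
    if color not in (BLACK, WHITE):
        raise ValueError(f"invalid color {color!r}")
    return -color


@dataclass(frozen=True)
class BoardState:
    """An immutable Go position; `apply_move` returns a new state.

    `captures[c]` counts adversary stones captured *by* colour c.  `ko_point`
    is the point temporarily barred by the simple-ko rule, if any.
    """

    size: int
    _board: np.ndarray  # flat int8, length size*size; treat as read-only
    to_move: int
    ko_point: Optional[Point]
    captures: dict
    history: tuple

    @classmethod
    def empty(cls, size: int = 19) -> "BoardState":
        if size < 1:
            raise ValueError("board size must be >= 1")
        return cls(size=size, _board=np.zeros(size * size, np.int8),
                   to_move=BLACK, ko_point=None,
                   captures={BLACK: 0, WHITE: 0}, history=())

    # -- views ------------------------------------------------------------

    @property
    def grid(self) -> np.ndarray:
        """(size, size) int8 copy: -1 black, +1 white, 0 empty."""
        return self._board.reshape(self.size, self.size).copy()

    @property
    def ply(self) -> int:
        return len(self.history)

    def stone_at(self, point: Point) -> int:
        return int(self._board[self._idx(point)])

    def stones(self, color: Optional[int] = None) -> set:
        """Occupied points, optionally restricted to one colour."""
        if color is None:
            idx = np.flatnonzero(self._board != EMPTY)
        else:
            idx = np.flatnonzero(self._board == color)
        return {Point(int(i) // self.size, int(i) % self.size) for i in idx}

    def _idx(self, point: Point) -> int:
        r, c = point
        if not (0 <= r < self.size and 0 <= c < self.size):
            raise ValueError(f"point {point} off a {self.size}x{self.size} board")
        return r * self.size + c

    def _point(self, idx: int) -> Point:
        return Point(idx // self.size, idx % self.size)

    @property
    def _ko_idx(self) -> int:
        return -1 if self.ko_point is None else self._idx(self.ko_point)

    # -- rules ------------------------------------------------------------

    def legal_moves(self, color: Optional[int] = None) -> set:
        """Every empty point where `color` may legally play (no suicide, no
        immediate ko recapture). Pass is always available and not listed."""
        c = self.to_move if color is None else color
        if c not in (BLACK, WHITE):
            raise ValueError(f"invalid color {c!r}")
        neigh = eng.neighbour_table(self.size)
        out = np.empty(self.size * self.size, np.int32)
        cnt = eng.k_playable_points(self._board, neigh, c, self._ko_idx,
                                    False, out)
        return {self._point(int(out[i])) for i in range(cnt)}

    def is_legal(self, color: int, move: Move) -> bool:
        if move is PASS:
            return True
        if color not in (BLACK, WHITE):
            raise ValueError(f"invalid color {color!r}")
        neigh = eng.neighbour_table(self.size)
        return bool(eng.k_is_legal(self._board, neigh, self._idx(move), color,
                                   self._ko_idx))

    def apply_move(self, color: int, move: Move) -> "BoardState":
        """Play `move` (a Point or PASS) for `color`; returns the new state.

        Captured adversary groups are removed and credited to
        ``captures[color]``; the simple-ko point is set when a single stone
        was captured and the played stone's group ends with one liberty.
        """
        if color not in (BLACK, WHITE):
            raise ValueError(f"invalid color {color!r}")
        if move is PASS:
            return BoardState(
                size=self.size, _board=self._board, to_move=-color,
                ko_point=None, captures=dict(self.captures),
                history=self.history + ((color, PASS),))
        p = self._idx(move)
        if self._board[p] != EMPTY:
            raise IllegalMoveError(f"{move} is occupied", "occupied")
        if p == self._ko_idx:
            raise IllegalMoveError(f"{move} is barred by ko", "ko")
        neigh = eng.neighbour_table(self.size)
        board = self._board.copy()
        ok, ncap, cap_pt, own_libs = eng.k_play(board, neigh, p, color)
        if not ok:
            raise IllegalMoveError(f"{move} would be suicide", "suicide")
        ko = None
        if ncap == 1 and own_libs == 1 and cap_pt >= 0:
            ko = self._point(int(cap_pt))
        captures = dict(self.captures)
        captures[color] += int(ncap)
        return BoardState(size=self.size, _board=board, to_move=-color,
                          ko_point=ko, captures=captures,
                          history=self.history + ((color, move),))


def is_game_over(state: BoardState, max_events: int = 500) -> bool:
    """Game ends on two consecutive passes, at the event cap, or when the
    side to move has no legal stone placement."""
    h = state.history
    if len(h) >= 2 and h[-1][1] is PASS and h[-2][1] is PASS:
        return True
    if state.ply >= max_events:
        return True
    neigh = eng.neighbour_table(state.size)
    out = np.empty(state.size * state.size, np.int32)
    cnt = eng.k_playable_points(state._board, neigh, state.to_move,
                                state._ko_idx, False, out)
    return cnt == 0


def area_score(state: BoardState, komi: float = 0.0) -> tuple:
    """Area scoring: (black, white) = own stones + exclusively-bordered
    territory + own capture count; white additionally receives `komi`.

    Auxiliary to the simulations, whose winner is decided by the Ising
    energy, not the score.
    """
    size = state.size
    grid = state._board
    n = size * size
    neigh = eng.neighbour_table(state.size)
    black = int(np.sum(grid == BLACK)) + state.captures[BLACK]
    white = int(np.sum(grid == WHITE)) + state.captures[WHITE]
    seen = np.zeros(n, bool)
    for p0 in range(n):
        if grid[p0] != EMPTY or seen[p0]:
            continue
        # flood the empty region, note bordering colours
        stack = [p0]
        seen[p0] = True
        region = 0
        bordering = set()
        while stack:
            q = stack.pop()
            region += 1
            for k in range(4):
                r = int(neigh[q, k])
                if r < 0:
                    continue
                if grid[r] == EMPTY:
                    if not seen[r]:
                        seen[r] = True
                        stack.append(r)
                else:
                    bordering.add(int(grid[r]))
        if bordering == {BLACK}:
            black += region
        elif bordering == {WHITE}:
            white += region
    return float(black), float(white) + float(komi)


@dataclass
class GameRecord:
    """A finished game: the move list, the replayed final state, the winner
    under the most-negative-energy rule, and run metadata."""

    moves: list
    final_state: BoardState
    winner: str  # 'cancer' | 'immune' | 'draw'
    metadata: dict = field(default_factory=dict)


def replay(moves: Iterable, size: int = 19) -> BoardState:
    """Apply a (color, Point-or-PASS) list from the empty board."""
    state = BoardState.empty(size)
    for i, (color, mv) in enumerate(moves):
        try:
            state = state.apply_move(color, mv)
        except IllegalMoveError as exc:
            raise IllegalMoveError(
                f"move {i} ({'B' if color == BLACK else 'W'} {mv}): {exc}",
                exc.reason) from exc
    return state


# --------------------------------------------------------------------------
# SGF (FF[4] subset: SZ, B, W, RE, GN, KM, C)

_RESULT_TO_SGF = {"cancer": "B+E", "immune": "W+E", "draw": "0"}
_SGF_TO_RESULT = {"B": "cancer", "W": "immune", "0": "draw", "D": "draw"}


def _sgf_coord(point: Point) -> str:
    return chr(ord("a") + point.col) + chr(ord("a") + point.row)


def _parse_coord(text: str, size: int) -> Move:
    if text == "" or (text == "tt" and size <= 19):
        return PASS
    if len(text) != 2:
        raise ValueError(f"bad SGF coordinate {text!r}")
    col = ord(text[0]) - ord("a")
    row = ord(text[1]) - ord("a")
    if not (0 <= row < size and 0 <= col < size):
        raise ValueError(f"SGF coordinate {text!r} off a {size}x{size} board")
    return Point(row, col)


def write_sgf(record: GameRecord, path) -> None:
    size = record.final_state.size
    meta = record.metadata
    props = [f"GM[1]FF[4]SZ[{size}]KM[{meta.get('komi', 0)}]"]
    props.append(f"RE[{_RESULT_TO_SGF[record.winner]}]")
    if "name" in meta:
        props.append(f"GN[{meta['name']}]")
    if "cancer_agent" in meta:
        props.append(f"PB[{meta['cancer_agent']}]")
    if "immune_agent" in meta:
        props.append(f"PW[{meta['immune_agent']}]")
    if "seed" in meta:
        props.append(f"C[seed={meta['seed']}]")
    nodes = []
    for color, mv in record.moves:
        tag = "B" if color == BLACK else "W"
        nodes.append(f";{tag}[{'' if mv is PASS else _sgf_coord(mv)}]")
    with open(path, "w") as fh:
        fh.write("(;" + "".join(props) + "".join(nodes) + ")\n")


def _tokenize_sgf(text: str):
    """Yield (property, value) pairs of the main line; raises on malformed
    input with the character position."""
    i = 0
    n = len(text)
    depth = 0
    while i < n:
        ch = text[i]
        if ch == "(":
            depth += 1
            if depth > 1:
                raise ValueError(f"SGF variations not supported (position {i})")
            i += 1
        elif ch == ")":
            depth -= 1
            i += 1
        elif ch in ";\n\r\t ":
            i += 1
        elif ch.isalpha():
            j = i
            while j < n and text[j].isalpha():
                j += 1
            ident = text[i:j]
            i = j
            while i < n and text[i] == "[":
                j = text.find("]", i)
                while j > 0 and text[j - 1] == "\\":
                    j = text.find("]", j + 1)
                if j < 0:
                    raise ValueError(f"unterminated SGF value at position {i}")
                yield ident, text[i + 1:j]
                i = j + 1
        else:
            raise ValueError(f"unexpected character {ch!r} at position {i}")
    if depth != 0:
        raise ValueError("unbalanced parentheses in SGF")


def read_sgf(path) -> GameRecord:
    """Parse an SGF file (FF[3]/FF[4], single game tree) and replay it.

    Moves illegal under the engine's rules raise IllegalMoveError naming the
    offending move index.
    """
    with open(path) as fh:
        text = fh.read()
    size = 19
    winner = "draw"
    meta = {}
    moves = []
    for prop, value in _tokenize_sgf(text):
        if prop == "SZ":
            size = int(value)
        elif prop == "RE":
            winner = _SGF_TO_RESULT.get(value.split("+")[0].strip() or "0",
                                        "draw")
        elif prop == "GN":
            meta["name"] = value
        elif prop == "PB":
            meta["cancer_agent"] = value
        elif prop == "PW":
            meta["immune_agent"] = value
        elif prop == "KM":
            meta["komi"] = float(value)
        elif prop == "C":
            meta["comment"] = value
        elif prop in ("B", "W"):
            moves.append((BLACK if prop == "B" else WHITE,
                          _parse_coord(value, size)))
    final = replay(moves, size)
    meta["size"] = size
    return GameRecord(moves=moves, final_state=final, winner=winner,
                      metadata=meta)
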