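"""Hand-specified board positions used across the test suites and demos.

Each fixture is stored as a legal move sequence and replayed through the
rules engine from the empty board, so every fixture position is reachable
and internally consistent (captures, ko point, counters).
"""

from __future__ import annotations

from .board import BLACK, WHITE, BoardState, Point, replay

_B = BLACK
_W = WHITE


def _mv(color, *points):
    return [(color, Point(r, c)) for (r, c) in points]

#: name -> (board size, move list). See `describe` for the intent of each.
FIXTURES = {
    # black stone in atari at (1,1); white ladder drives it to capture
    "ladder_corner": (7, _mv(_B, (1, 1)) + _mv(_W, (0, 1), (1, 0), (2, 1),
                                               (0, 2))),
    # same, plus a black breaker on the escape path: the read-out frees it
    "ladder_breaker": (7, _mv(_B, (1, 1), (2, 3)) + _mv(_W, (0, 1), (1, 0),
                                                        (2, 1), (0, 2))),
    # white stone loosely enclosed by black: held by the net search
    "geta_net": (7, _mv(_W, (2, 2)) + _mv(_B, (1, 2), (2, 1), (3, 1), (1, 3),
                                          (3, 3))),
    # one black chain with two one-point holes: k = 2, uncapturable
    "two_eyes": (5, _mv(_B, (1, 0), (1, 1), (1, 2), (1, 3), (1, 4), (0, 0),
                        (0, 2), (0, 4))),
    # two distinct black chains bordering the same eye at (1, 1)
    "shared_eye": (5, _mv(_B, (0, 0), (0, 1), (1, 0), (2, 1), (2, 2),
                          (1, 2))),
    # lone black stone outnumbered 6:0 by white in its radius-2 window
    "invasion_5x5": (5, _mv(_W, (0, 0), (0, 2), (0, 4), (4, 0), (4, 2),
                            (4, 4)) + _mv(_B, (2, 2))),
    # black stone pressing a white group with black support within radius 2
    "reduction_5x5": (5, _mv(_B, (2, 2), (0, 1), (0, 2)) + _mv(_W, (2, 3),
                                                               (3, 3))),
    # black just captured one white stone at (2,2); white's recapture is
    # barred by simple ko
    "ko_shape": (5, _mv(_B, (1, 2), (2, 1), (3, 2)) + _mv(_W, (1, 3), (3, 3),
                                                          (2, 4), (2, 2))
                 + _mv(_B, (2, 3))),
}


def make_fixture(name: str) -> BoardState:
    """Replay the named fixture from the empty board."""
    try:
        size, moves = FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return replay(moves, size)


def fixture_moves(name: str):
    """The (color, Point) list of a fixture (for SGF round-trip tests)."""
    if name not in FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    size, moves = FIXTURES[name]
    return size, list(moves)
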