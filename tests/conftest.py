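"""Shared helpers: ASCII boards and random reachable positions.

Random positions are generated with the independent oracle rules (not the
package's engine), so engine-vs-oracle comparisons are not self-fulfilling.
"""

from __future__ import annotations

import random

import numpy as np
import pytest

from goising.board import BLACK, WHITE, BoardState, Point

import oracles


def board_from_grid(grid: dict, size: int) -> BoardState:
    """Build a BoardState carrying exactly the stones of `grid`
    (point -> colour).  History/captures are synthetic: the state is used
    for position-level checks only."""
    flat = np.zeros(size * size, np.int8)
    for (r, c), v in grid.items():
        flat[r * size + c] = v
    return BoardState(size=size, _board=flat, to_move=BLACK, ko_point=None,
                      captures={BLACK: 0, WHITE: 0}, history=())


def board_from_ascii(text: str) -> BoardState:
    """'.' empty, 'X' black/cancer, 'O' white/immune; rows on lines."""
    rows = [line.strip() for line in text.strip().splitlines()]
    size = len(rows)
    grid = {}
    for r, line in enumerate(rows):
        assert len(line) == size, "ascii board must be square"
        for c, ch in enumerate(line):
            if ch == "X":
                grid[(r, c)] = BLACK
            elif ch == "O":
                grid[(r, c)] = WHITE
    return board_from_grid(grid, size)


def random_position(rng: random.Random, size: int, n_moves: int):
    """A reachable random position as an oracle grid (point -> colour),
    built by playing random legal oracle moves from the empty board."""
    grid = {}
    color = oracles.BLACK
    for _ in range(n_moves):
        legal = sorted(oracles.legal_points(grid, size, color))
        if not legal:
            break
        p = rng.choice(legal)
        res = oracles.play(grid, size, p, color)
        grid = res[0]
        color = -color
    return grid


@pytest.fixture(scope="session")
def rng():
    return random.Random(20240)
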