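"""Rules engine: legal moves, captures, ko, scoring, SGF round-trips."""

import random

import numpy as np
import pytest

import oracles
from conftest import board_from_ascii, board_from_grid, random_position

from goising.board import (BLACK, PASS, WHITE, BoardState, GameRecord,
                           IllegalMoveError, Point, area_score, is_game_over,
                           read_sgf, replay, write_sgf)
from goising.fixtures import make_fixture


class TestLegalMoves:
    def test_empty_board_all_points_legal(self):
        state = BoardState.empty(19)
        assert len(state.legal_moves(BLACK)) == 361

    def test_suicide_point_excluded(self):
        # the single empty point is surrounded by white groups with >= 2 libs
        state = board_from_ascii("""
            .O.
            O.O
            .O.
        """)
        assert Point(1, 1) not in state.legal_moves(BLACK)
        assert Point(1, 1) in state.legal_moves(WHITE)

    def test_invalid_color_raises(self):
        with pytest.raises(ValueError):
            BoardState.empty(5).legal_moves(7)

    def test_matches_play_and_check_oracle_on_random_positions(self, rng):
        for _ in range(60):
            grid = random_position(rng, 5, rng.randrange(3, 18))
            state = board_from_grid(grid, 5)
            for color in (BLACK, WHITE):
                got = {(p.row, p.col) for p in state.legal_moves(color)}
                assert got == oracles.legal_points(grid, 5, color)


class TestApplyMove:
    def test_capture_single_stone(self):
        state = board_from_ascii("""
            .O.
            OXO
            ...
        """)
        after = state.apply_move(WHITE, Point(2, 1))
        assert after.stone_at(Point(1, 1)) == 0
        assert after.captures[WHITE] == 1
        assert after.captures[BLACK] == 0

    def test_pass_leaves_grid_and_increments_ply(self):
        state = BoardState.empty(9).apply_move(BLACK, Point(4, 4))
        after = state.apply_move(WHITE, PASS)
        assert np.array_equal(after.grid, state.grid)
        assert after.ply == state.ply + 1
        assert after.to_move == BLACK

    def test_occupied_point_rejected_with_reason(self):
        state = BoardState.empty(5).apply_move(BLACK, Point(2, 2))
        with pytest.raises(IllegalMoveError) as err:
            state.apply_move(WHITE, Point(2, 2))
        assert err.value.reason == "occupied"

    def test_simple_ko_recapture_barred(self):
        state = make_fixture("ko_shape")
        assert state.ko_point == Point(2, 2)
        with pytest.raises(IllegalMoveError) as err:
            state.apply_move(WHITE, Point(2, 2))
        assert err.value.reason == "ko"
        # after white plays elsewhere the ko lifts
        relaxed = state.apply_move(WHITE, Point(0, 0))
        assert relaxed.ko_point is None

    def test_multi_stone_capture_does_not_set_ko(self):
        state = board_from_ascii("""
            .OO..
            OXXO.
            .O...
            .....
            .....
        """)
        after = state.apply_move(WHITE, Point(2, 2))
        assert after.captures[WHITE] == 2
        assert after.stone_at(Point(1, 1)) == 0
        assert after.ko_point is None

    def test_stone_conservation_along_random_games(self, rng):
        state = BoardState.empty(7)
        colors = [BLACK, WHITE]
        for ply in range(60):
            color = colors[ply % 2]
            moves = sorted(state.legal_moves(color))
            if not moves:
                break
            state = state.apply_move(color, moves[rng.randrange(len(moves))])
            stones = int(np.count_nonzero(state.grid))
            nonpass = sum(1 for _, m in state.history if m is not PASS)
            captured = state.captures[BLACK] + state.captures[WHITE]
            assert stones + captured == nonpass


class TestGameOver:
    def test_two_passes_end_the_game(self):
        state = BoardState.empty(5)
        state = state.apply_move(BLACK, PASS).apply_move(WHITE, PASS)
        assert is_game_over(state, max_events=500)

    def test_event_cap(self):
        state = BoardState.empty(5).apply_move(BLACK, Point(0, 0))
        assert is_game_over(state, max_events=1)
        assert not is_game_over(state, max_events=10)

    def test_fresh_board_not_over(self):
        assert not is_game_over(BoardState.empty(5), max_events=500)


class TestAreaScore:
    def test_empty_board(self):
        assert area_score(BoardState.empty(5), komi=0) == (0.0, 0.0)

    def test_nearly_full_black_board(self):
        grid = {(r, c): BLACK for r in range(5) for c in range(5)
                if (r, c) != (2, 2)}
        state = board_from_grid(grid, 5)
        black, white = area_score(state)
        assert (black, white) == (25.0, 0.0)  # 24 stones + 1 territory

    def test_komi_added_to_white(self):
        _, white = area_score(BoardState.empty(9), komi=6.5)
        assert white == 6.5

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(40):
            grid = random_position(rng, 5, rng.randrange(5, 22))
            state = board_from_grid(grid, 5)
            assert area_score(state) == oracles.area_scores(grid, 5)


class TestSGF:
    def test_coordinate_convention(self, tmp_path):
        rec = GameRecord(
            moves=[(BLACK, Point(3, 3)), (WHITE, Point(15, 15))],
            final_state=replay([(BLACK, Point(3, 3)),
                                (WHITE, Point(15, 15))], 19),
            winner="cancer")
        path = tmp_path / "g.sgf"
        write_sgf(rec, path)
        text = path.read_text()
        assert "B[dd]" in text and "W[pp]" in text

    def test_round_trip_identity(self, tmp_path, rng):
        moves = []
        state = BoardState.empty(9)
        colors = [BLACK, WHITE]
        for ply in range(40):
            color = colors[ply % 2]
            legal = sorted(state.legal_moves(color))
            mv = PASS if not legal else legal[rng.randrange(len(legal))]
            moves.append((color, mv))
            state = state.apply_move(color, mv)
        rec = GameRecord(moves=moves, final_state=state, winner="immune",
                         metadata={"name": "round-trip", "size": 9})
        path = tmp_path / "g.sgf"
        write_sgf(rec, path)
        back = read_sgf(path)
        assert back.moves == moves
        assert back.winner == "immune"
        assert np.array_equal(back.final_state.grid, state.grid)

    def test_replay_reproduces_final_grid_exactly(self):
        state = make_fixture("ko_shape")
        again = replay(list(state.history), state.size)
        assert np.array_equal(again.grid, state.grid)
        assert again.captures == state.captures
        assert again.ko_point == state.ko_point

    def test_malformed_sgf_raises_with_position(self, tmp_path):
        path = tmp_path / "bad.sgf"
        path.write_text("(;GM[1]SZ[9];B[aa;W[bb])")
        with pytest.raises(ValueError):
            read_sgf(path)

    def test_illegal_move_in_sgf_names_index(self, tmp_path):
        path = tmp_path / "bad.sgf"
        path.write_text("(;GM[1]FF[4]SZ[9];B[aa];W[aa])")
        with pytest.raises(IllegalMoveError, match="move 1"):
            read_sgf(path)
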