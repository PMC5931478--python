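"""Hamiltonian: group descriptors, interaction weights, side energies."""

import dataclasses

import numpy as np
import pytest

import oracles
from conftest import board_from_ascii, board_from_grid, random_position

from goising.board import BLACK, WHITE, BoardState, Point
from goising.cfg_graph import CFGNode, build_cfg
from goising.energy import (GroupDescriptor, WeightConfig, group_x,
                            hamiltonian, interaction_w)
from goising.fixtures import FIXTURES, make_fixture
from goising.tactics import TacticInstance, TacticKind, detect_all


def _node(color, n, k):
    members = frozenset(Point(0, i) for i in range(n))
    return CFGNode(id=0, color=color, members=members,
                   liberties=frozenset([Point(1, 0)]), k=k)


class TestGroupDescriptor:
    @pytest.mark.parametrize("color, n, k, expected", [
        (BLACK, 5, 0, -5.0),   # no eye: descriptor is signed size
        (WHITE, 3, 2, 7.0),    # 3 + 2^2
        (BLACK, 1, 1, -3.0),   # 1 + 2^1
    ])
    def test_worked_values(self, color, n, k, expected):
        assert group_x(_node(color, n, k), WeightConfig()).x == expected

    def test_eye_monotonicity(self):
        w = WeightConfig()
        for k in range(4):
            lo = abs(group_x(_node(BLACK, 4, k), w).x)
            hi = abs(group_x(_node(BLACK, 4, k + 1), w).x)
            assert hi > lo


class TestInteractionW:
    def test_no_adjacency_no_instances_gives_zero(self):
        state = board_from_ascii("""
            X....
            .....
            .....
            .....
            ....O
        """)
        cfg = build_cfg(state)
        assert interaction_w(0, 1, cfg, [], WeightConfig()) == 0.0

    def test_shared_liberty_without_instances_gives_r_sl(self):
        state = board_from_ascii("""
            .....
            .X.X.
            .....
            .....
            .....
        """)
        cfg = build_cfg(state)
        assert interaction_w(0, 1, cfg, [], WeightConfig()) == 1.0

    def test_immune_ladder_weight_times_mediator(self):
        # white chain of two stones (x_s = +2) adjacent to a black stone;
        # an immune-owned ladder instance contributes 0.5 * 2 = 1.0
        state = board_from_ascii("""
            .....
            .....
            ..XOO
            .....
            .....
        """)
        cfg = build_cfg(state)
        black = next(n.id for n in cfg.nodes if n.color == BLACK)
        white = next(n.id for n in cfg.nodes if n.color == WHITE)
        inst = TacticInstance(TacticKind.LADDER, owner_color=WHITE,
                              groups=frozenset([black]), mediator=white)
        assert interaction_w(black, white, cfg, [inst],
                             WeightConfig()) == pytest.approx(1.0)

    def test_agrees_with_kernel_pair_weights(self, rng):
        w = WeightConfig()
        for _ in range(15):
            grid = random_position(rng, 5, rng.randrange(5, 18))
            state = board_from_grid(grid, 5)
            cfg = build_cfg(state)
            instances = detect_all(cfg, state)
            report = hamiltonian(state, w)
            for (i, j), wij in report.pair_w.items():
                assert interaction_w(i, j, cfg, instances, w) == \
                    pytest.approx(wij)


class TestHamiltonian:
    def test_empty_board_is_zero(self):
        rep = hamiltonian(BoardState.empty(5))
        assert rep.H_total == rep.H_cancer == rep.H_immune == 0.0

    def test_single_black_stone_field_term(self):
        state = BoardState.empty(5).apply_move(BLACK, Point(2, 2))
        rep = hamiltonian(state)
        assert rep.H_cancer == -4.0
        assert rep.H_immune == 0.0

    def test_total_is_sum_of_sides(self, rng):
        for _ in range(10):
            grid = random_position(rng, 5, rng.randrange(4, 20))
            rep = hamiltonian(board_from_grid(grid, 5))
            assert rep.H_total == pytest.approx(rep.H_cancer + rep.H_immune)

    def test_matches_brute_force_oracle_on_random_boards(self, rng):
        for _ in range(25):
            grid = random_position(rng, 5, rng.randrange(4, 22))
            rep = hamiltonian(board_from_grid(grid, 5))
            H_c, H_i, H_d = oracles.evaluate(grid, 5)
            assert rep.H_cancer == pytest.approx(H_c)
            assert rep.H_immune == pytest.approx(H_i)
            assert rep.H_margin == pytest.approx(H_d)

    @pytest.mark.parametrize("name", sorted(FIXTURES))
    def test_matches_brute_force_oracle_on_fixtures(self, name):
        state = make_fixture(name)
        grid = {(int(p.row), int(p.col)): int(state.stone_at(p))
                for p in state.stones()}
        rep = hamiltonian(state)
        H_c, H_i, H_d = oracles.evaluate(grid, state.size)
        assert rep.H_cancer == pytest.approx(H_c)
        assert rep.H_immune == pytest.approx(H_i)
        assert rep.H_margin == pytest.approx(H_d)

    def test_color_and_weight_swap_exchanges_sides(self, rng):
        w = WeightConfig()
        for name in sorted(FIXTURES):
            state = make_fixture(name)
            grid = {(int(p.row), int(p.col)): int(state.stone_at(p))
                    for p in state.stones()}
            swapped = board_from_grid({p: -v for p, v in grid.items()},
                                      state.size)
            rep = hamiltonian(state, w)
            rep_sw = hamiltonian(swapped, w.swapped_sides())
            assert rep_sw.H_cancer == pytest.approx(rep.H_immune)
            assert rep_sw.H_immune == pytest.approx(rep.H_cancer)
        for _ in range(10):
            grid = random_position(rng, 5, rng.randrange(4, 20))
            rep = hamiltonian(board_from_grid(grid, 5), w)
            rep_sw = hamiltonian(
                board_from_grid({p: -v for p, v in grid.items()}, 5),
                w.swapped_sides())
            assert rep_sw.H_cancer == pytest.approx(rep.H_immune)
            assert rep_sw.H_immune == pytest.approx(rep.H_cancer)

    def test_margin_equals_side_difference(self, rng):
        for _ in range(10):
            grid = random_position(rng, 5, rng.randrange(4, 20))
            rep = hamiltonian(board_from_grid(grid, 5))
            assert rep.H_margin == pytest.approx(rep.H_cancer - rep.H_immune)


class TestWeightConfig:
    def test_defaults_mirror_side_tables(self):
        w = WeightConfig()
        assert w.cancer == {"eye": 0.7, "net": 0.6, "ladder": 0.5,
                            "connection": 0.1, "invasion": 0.4}
        assert w.immune == {"eye": 0.4, "net": 0.7, "ladder": 0.5,
                            "connection": 0.1, "reduction": 0.5}
        assert (w.r_sl, w.b_eye, w.mu) == (1.0, 2.0, 1.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="cancer.eye"):
            WeightConfig(cancer={**WeightConfig().cancer, "eye": -1}).validate()

    def test_b_eye_must_exceed_one(self):
        with pytest.raises(ValueError, match="b_eye"):
            WeightConfig(b_eye=1.0).validate()

    def test_partial_mapping_keeps_defaults(self):
        w = WeightConfig.from_mapping({"mu": 0.5})
        assert w.mu == 0.5
        assert w.cancer["eye"] == 0.7

    def test_swapped_sides_moves_incursion_weight(self):
        sw = WeightConfig().swapped_sides()
        assert sw.cancer["invasion"] == 0.5   # was immune reduction
        assert sw.immune["reduction"] == 0.4  # was cancer invasion
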