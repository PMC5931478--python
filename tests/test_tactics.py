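"""Tactic detectors: atari, eyes, ladder, net, connection, invasion/reduction."""

import itertools

import pytest

import oracles
from conftest import board_from_ascii, board_from_grid, random_position

from goising.board import BLACK, WHITE, Point
from goising.cfg_graph import build_cfg
from goising.fixtures import make_fixture
from goising.tactics import (TacticKind, detect_all, detect_atari,
                             detect_connection, detect_eyes,
                             detect_invasion_reduction, detect_ladder,
                             detect_net)


def _kinds(instances):
    return sorted(t.kind.value for t in instances)


class TestAtari:
    def test_surrounded_stone_in_atari(self):
        state = board_from_ascii("""
            .O...
            OXO..
            .....
            .....
            .....
        """)
        cfg = build_cfg(state)
        found = detect_atari(cfg, state)
        assert len(found) == 1
        (inst,) = found
        assert inst.owner_color == WHITE
        assert cfg.nodes[next(iter(inst.groups))].color == BLACK

    def test_empty_board_no_atari(self):
        from goising.board import BoardState
        state = BoardState.empty(5)
        assert detect_atari(build_cfg(state), state) == []

    def test_matches_liberty_recount_on_random_positions(self, rng):
        for _ in range(30):
            grid = random_position(rng, 5, rng.randrange(4, 20))
            state = board_from_grid(grid, 5)
            cfg = build_cfg(state)
            got = {frozenset(t.groups) for t in detect_atari(cfg, state)}
            want = {frozenset([n.id]) for n in cfg.nodes if n.h == 1}
            assert got == want


class TestLadder:
    def test_corner_ladder_is_captured(self):
        state = make_fixture("ladder_corner")
        cfg = build_cfg(state)
        found = detect_ladder(cfg, state)
        assert len(found) == 1
        (inst,) = found
        assert inst.owner_color == WHITE
        assert cfg.nodes[next(iter(inst.groups))].color == BLACK

    def test_breaker_on_the_path_frees_the_chain(self):
        state = make_fixture("ladder_breaker")
        cfg = build_cfg(state)
        assert detect_ladder(cfg, state) == []

    def test_empty_board(self):
        from goising.board import BoardState
        state = BoardState.empty(7)
        assert detect_ladder(build_cfg(state), state) == []

    def test_depth_cap_validation(self):
        state = make_fixture("ladder_corner")
        with pytest.raises(ValueError):
            detect_ladder(build_cfg(state), state, depth_cap=0)

    def test_matches_oracle_readout_on_random_positions(self, rng):
        for _ in range(25):
            grid = random_position(rng, 5, rng.randrange(6, 20))
            state = board_from_grid(grid, 5)
            cfg = build_cfg(state)
            got = {next(iter(t.groups)) for t in detect_ladder(cfg, state)}
            want = set()
            for node in cfg.nodes:
                if node.h == 1 and oracles.ladder_captured(
                        grid, 5, tuple(min(node.members)), 50):
                    want.add(node.id)
            assert got == want


class TestNet:
    def test_loose_enclosure_is_netted(self):
        state = make_fixture("geta_net")
        cfg = build_cfg(state)
        found = detect_net(cfg, state)
        assert len(found) == 1
        (inst,) = found
        assert inst.owner_color == BLACK
        assert cfg.nodes[next(iter(inst.groups))].color == WHITE

    def test_open_board_stone_not_netted(self):
        from goising.board import BoardState
        state = BoardState.empty(7).apply_move(WHITE, Point(3, 3))
        assert detect_net(build_cfg(state), state) == []

    def test_two_eyed_group_never_netted(self):
        state = make_fixture("two_eyes")
        assert detect_net(build_cfg(state), state) == []

    def test_ladder_captured_chain_also_netted(self):
        state = make_fixture("ladder_corner")
        cfg = build_cfg(state)
        lad = {next(iter(t.groups)) for t in detect_ladder(cfg, state)}
        net = {next(iter(t.groups)) for t in detect_net(cfg, state, depth=4)}
        assert lad <= net

    def test_matches_oracle_search_on_random_positions(self, rng):
        for _ in range(20):
            grid = random_position(rng, 5, rng.randrange(6, 20))
            state = board_from_grid(grid, 5)
            cfg = build_cfg(state)
            got = {next(iter(t.groups)) for t in detect_net(cfg, state)}
            want = set()
            for node in cfg.nodes:
                if node.h <= 2 and node.k < 2 and oracles.net_trapped(
                        grid, 5, tuple(min(node.members)), 4):
                    want.add(node.id)
            assert got == want


class TestConnection:
    def test_one_point_jump_is_a_connection(self):
        state = board_from_ascii("""
            .....
            .X.X.
            .....
            .....
            .....
        """)
        cfg = build_cfg(state)
        found = detect_connection(cfg, state)
        assert len(found) == 1
        assert found[0].between == (0, 1)
        assert found[0].mediator == 0

    def test_three_point_gap_is_not(self):
        state = board_from_ascii("""
            .....
            X...X
            .....
            .....
            .....
        """)
        cfg = build_cfg(state)
        assert detect_connection(cfg, state) == []

    def test_matches_shared_liberty_oracle(self, rng):
        for _ in range(25):
            grid = random_position(rng, 7, rng.randrange(6, 30))
            state = board_from_grid(grid, 7)
            cfg = build_cfg(state)
            got = {t.between for t in detect_connection(cfg, state)}
            gs = oracles.groups_of(grid, 7)
            want = set()
            for i, j in itertools.combinations(range(len(gs)), 2):
                if gs[i][0] == gs[j][0] and (
                        oracles.chain_liberties(grid, 7, gs[i][1])
                        & oracles.chain_liberties(grid, 7, gs[j][1])):
                    want.add((i, j))
            assert got == want


class TestInvasionReduction:
    def test_outnumbered_isolated_stone_is_invasion(self):
        state = make_fixture("invasion_5x5")
        cfg = build_cfg(state)
        found = detect_invasion_reduction(cfg, state)
        black = [t for t in found
                 if cfg.nodes[next(iter(t.groups))].color == BLACK]
        assert len(black) == 1
        assert black[0].kind is TacticKind.INVASION

    def test_supported_incursion_is_reduction(self):
        state = make_fixture("reduction_5x5")
        cfg = build_cfg(state)
        found = detect_invasion_reduction(cfg, state)
        centre = [t for t in found
                  if Point(2, 2) in cfg.nodes[next(iter(t.groups))].members]
        assert len(centre) == 1
        assert centre[0].kind is TacticKind.REDUCTION

    def test_empty_board(self):
        from goising.board import BoardState
        state = BoardState.empty(5)
        assert detect_invasion_reduction(build_cfg(state), state) == []

    def test_radius_validation(self):
        state = make_fixture("invasion_5x5")
        with pytest.raises(ValueError):
            detect_invasion_reduction(build_cfg(state), state, radius=0)

    def test_matches_neighbourhood_count_oracle(self, rng):
        for _ in range(20):
            grid = random_position(rng, 5, rng.randrange(4, 20))
            state = board_from_grid(grid, 5)
            cfg = build_cfg(state)
            got = {next(iter(t.groups)): t.kind.value
                   for t in detect_invasion_reduction(cfg, state)}
            gs = oracles.groups_of(grid, 5)
            want = {}
            for i, (c, m) in enumerate(gs):
                kind = oracles.incursion_kind(grid, 5, m, c, gs)
                if kind:
                    want[i] = kind
            assert got == want


class TestInvariants:
    def test_color_swap_maps_instances_with_owner_negated(self, rng):
        for _ in range(10):
            grid = random_position(rng, 5, rng.randrange(6, 20))
            state = board_from_grid(grid, 5)
            swapped = board_from_grid({p: -v for p, v in grid.items()}, 5)
            a = detect_all(build_cfg(state), state)
            b = detect_all(build_cfg(swapped), swapped)
            a_neg = sorted((t.kind.value, -t.owner_color,
                            tuple(sorted(t.groups))) for t in a)
            b_key = sorted((t.kind.value, t.owner_color,
                            tuple(sorted(t.groups))) for t in b)
            assert a_neg == b_key

    def test_detection_is_deterministic(self, rng):
        grid = random_position(rng, 7, 25)
        state = board_from_grid(grid, 7)
        one = detect_all(build_cfg(state), state)
        two = detect_all(build_cfg(state), state)
        assert one == two
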