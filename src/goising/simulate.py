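"""Scenario batteries: tumour–immune games, energy trajectories, winners,
phase transitions and duration summaries.

A scenario pits a cancer agent (black, moves first — the seeding tumour)
against an immune agent (white).  After every event (one stone placement or
pass) the position's Ising energy is evaluated for both sides; the winner of
a game is the side with the more negative final side energy.  Trajectories
are normalized per game by the maximum absolute energy across both sides, and
phase transitions are flagged where the normalized energy jumps by more than
a threshold between consecutive events.  Batteries aggregate wins, duration
histograms (nine 50-event bins up to the 500-event horizon) and transition
statistics, and write one SGF plus one energy CSV per game.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _engine as eng
from .agents import AgentSpec, select_move
from .board import (BLACK, WHITE, BoardState, GameRecord, is_game_over,
                    write_sgf)
from .energy import WeightConfig

CANCER_WIN = "cancer"
IMMUNE_WIN = "immune"
DRAW = "draw"

#: Upper edges of the duration histogram bins (events).
END_EVENT_BINS = (100, 150, 200, 250, 300, 350, 400, 450, 500)

#: The four scenario line-ups; cancer agent first.
SCENARIOS = {
    "random": ("random", "random"),
    "aggressive-vs-passive": ("aggressive", "passive_mc"),
    "aggressive-vs-good": ("aggressive", "good"),
    "aggressive-vs-aggressive": ("aggressive", "aggressive"),
}


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    cancer_agent: AgentSpec
    immune_agent: AgentSpec
    n_games: int = 100
    board_size: int = 19
    max_events: int = 500
    weights: WeightConfig = field(default_factory=WeightConfig)
    base_seed: int = 0
    transition_tau: float = 0.1

    def validate(self) -> "ScenarioConfig":
        if self.n_games < 1:
            raise ValueError("n_games must be >= 1")
        if self.max_events < 2:
            raise ValueError("max_events must be >= 2")
        self.cancer_agent.validate()
        self.immune_agent.validate()
        self.weights.validate()
        if self.transition_tau <= 0:
            raise ValueError("transition_tau must be > 0")
        return self

    def game_seed(self, game_index: int) -> int:
        return self.base_seed + game_index


def scenario_config(name: str, n_games: int = 100, board_size: int = 19,
                    base_seed: int = 0,
                    weights: Optional[WeightConfig] = None,
                    max_events: int = 500) -> ScenarioConfig:
    """Build one of the four named scenario configurations."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"expected one of {sorted(SCENARIOS)}")
    ck, ik = SCENARIOS[name]
    return ScenarioConfig(
        name=name, cancer_agent=AgentSpec(kind=ck), immune_agent=AgentSpec(kind=ik),
        n_games=n_games, board_size=board_size, max_events=max_events,
        weights=weights or WeightConfig(), base_seed=base_seed).validate()


@dataclass
class Trajectory:
    """Per-event side energies of one game (one entry per event)."""

    h_cancer: np.ndarray
    h_immune: np.ndarray
    h_margin: Optional[np.ndarray] = None  # H_cancer - H_immune, exact
    h_cancer_norm: Optional[np.ndarray] = None
    h_immune_norm: Optional[np.ndarray] = None
    winner: Optional[str] = None

    @property
    def end_event(self) -> int:
        return len(self.h_cancer)


def decide_winner(trajectory: Trajectory) -> str:
    """Most-negative final side energy wins; exact equality is a draw.

    Uses the exactly-accumulated margin H_cancer - H_immune when the
    trajectory carries it (the subtraction of the reported side energies
    loses the signal once both are dominated by their shared mixed-pair
    terms); otherwise compares the stored side energies."""
    if trajectory.end_event == 0:
        raise ValueError("cannot decide a winner from an empty trajectory")
    if trajectory.h_margin is not None:
        m = float(trajectory.h_margin[-1])
    else:
        m = float(trajectory.h_cancer[-1]) - float(trajectory.h_immune[-1])
    if m < 0:
        return CANCER_WIN
    if m > 0:
        return IMMUNE_WIN
    return DRAW


def normalize_trajectory(trajectory: Trajectory) -> Trajectory:
    """Divide both series by the game's maximum absolute energy (across both
    sides); an all-zero game maps to all-zero."""
    scale = max(np.max(np.abs(trajectory.h_cancer), initial=0.0),
                np.max(np.abs(trajectory.h_immune), initial=0.0))
    if scale == 0.0:
        trajectory.h_cancer_norm = trajectory.h_cancer.copy()
        trajectory.h_immune_norm = trajectory.h_immune.copy()
    else:
        trajectory.h_cancer_norm = trajectory.h_cancer / scale
        trajectory.h_immune_norm = trajectory.h_immune / scale
    return trajectory


def detect_transitions(trajectory: Trajectory, tau: float = 0.1) -> list:
    """Events where either side's normalized energy jumps by more than `tau`
    from the previous event; runs of consecutive flagged events are merged
    and reported by their first event index."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if trajectory.h_cancer_norm is None:
        normalize_trajectory(trajectory)
    flags = ((np.abs(np.diff(trajectory.h_cancer_norm)) > tau)
             | (np.abs(np.diff(trajectory.h_immune_norm)) > tau))
    out = []
    prev = False
    for e, f in enumerate(flags, start=1):
        if f and not prev:
            out.append(e)
        prev = f
    return out


def simulate_game(config: ScenarioConfig, game_index: int
                  ) -> tuple:
    """Play one seeded game; returns (GameRecord, Trajectory).

    Cancer (black) moves first; after every event the Hamiltonian is
    evaluated with the full reporting configuration.
    """
    config.validate()
    seed = config.game_seed(game_index)
    rng = np.random.default_rng(seed)
    state = BoardState.empty(config.board_size)
    neigh = eng.neighbour_table(config.board_size)
    W = config.weights.to_array()
    tac = config.weights.tactics
    h_c = []
    h_i = []
    h_d = []
    agents = {BLACK: config.cancer_agent, WHITE: config.immune_agent}
    while not is_game_over(state, config.max_events):
        color = state.to_move
        move = select_move(state, color, agents[color], rng, config.weights)
        try:
            state = state.apply_move(color, move)
        except ValueError as exc:
            side = "cancer" if color == BLACK else "immune"
            raise RuntimeError(
                f"agent {agents[color].kind!r} ({side}) returned an illegal "
                f"move {move} at ply {state.ply}: {exc}") from exc
        Hc, Hi, Hd, _, _ = eng.k_eval_sides(state._board, neigh, state.size,
                                            W, tac.ladder_depth_cap,
                                            tac.net_depth,
                                            tac.invasion_radius)
        h_c.append(float(Hc))
        h_i.append(float(Hi))
        h_d.append(float(Hd))
    traj = Trajectory(h_cancer=np.asarray(h_c), h_immune=np.asarray(h_i),
                      h_margin=np.asarray(h_d))
    normalize_trajectory(traj)
    traj.winner = decide_winner(traj)
    record = GameRecord(
        moves=list(state.history), final_state=state, winner=traj.winner,
        metadata={"name": config.name, "seed": seed, "size": config.board_size,
                  "cancer_agent": config.cancer_agent.kind,
                  "immune_agent": config.immune_agent.kind, "komi": 0})
    return record, traj


def summarize_end_events(end_events) -> list:
    """Percentage of games whose end event falls in each 50-event bin
    (bin b covers the events in (b-50, b]); returns
    [(bin_upper_edge, percentage), ...] over END_EVENT_BINS."""
    end_events = list(end_events)
    if not end_events:
        raise ValueError("no end events to summarize")
    n = len(end_events)
    rows = []
    for i, edge in enumerate(END_EVENT_BINS):
        lo = 0 if i == 0 else END_EVENT_BINS[i - 1]
        cnt = sum(1 for e in end_events if lo < e <= edge)
        rows.append((edge, 100.0 * cnt / n))
    return rows


@dataclass
class ScenarioSummary:
    """Battery-level aggregate: win counts, duration histogram, transitions."""

    name: str
    n_games: int
    wins: dict                 # {'cancer': int, 'immune': int, 'draw': int}
    end_events: list
    end_event_histogram: list  # [(bin_upper_edge, percentage), ...]
    transition_counts: list    # per game
    transition_events: list    # flattened event indices

    @property
    def cancer_win_rate(self) -> float:
        return self.wins[CANCER_WIN] / self.n_games

    def to_dict(self) -> dict:
        return {
            "scenario": self.name,
            "n_games": self.n_games,
            "wins": dict(self.wins),
            "end_events": list(map(int, self.end_events)),
            "end_event_histogram": [
                {"bin": int(b), "pct": round(p, 6)}
                for b, p in self.end_event_histogram],
            "transitions": {
                "per_game_counts": list(map(int, self.transition_counts)),
                "mean_per_game": (float(np.mean(self.transition_counts))
                                  if self.transition_counts else 0.0),
            },
        }


def _write_trajectory_csv(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("event,H_cancer,H_immune,H_cancer_norm,H_immune_norm\n")
        for e in range(traj.end_event):
            fh.write(f"{e + 1},{traj.h_cancer[e]:.6g},{traj.h_immune[e]:.6g},"
                     f"{traj.h_cancer_norm[e]:.6g},"
                     f"{traj.h_immune_norm[e]:.6g}\n")


def run_scenario(config: ScenarioConfig, out_dir=None,
                 progress=None) -> ScenarioSummary:
    """Simulate the battery with per-game seeds base_seed + index.

    When `out_dir` is given, writes game_<i>.sgf, game_<i>_energy.csv and
    summary.json there (the directory is created; an unwritable destination
    raises before any simulation starts).
    """
    config.validate()
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        probe = os.path.join(out_dir, ".write_probe")
        with open(probe, "w") as fh:
            fh.write("")
        os.remove(probe)
    wins = {CANCER_WIN: 0, IMMUNE_WIN: 0, DRAW: 0}
    end_events = []
    tcounts = []
    tevents = []
    for i in range(config.n_games):
        record, traj = simulate_game(config, i)
        wins[traj.winner] += 1
        end_events.append(traj.end_event)
        trans = detect_transitions(traj, config.transition_tau)
        tcounts.append(len(trans))
        tevents.extend(trans)
        if out_dir is not None:
            write_sgf(record, os.path.join(out_dir, f"game_{i}.sgf"))
            _write_trajectory_csv(
                traj, os.path.join(out_dir, f"game_{i}_energy.csv"))
        if progress is not None:
            progress(i, traj)
    summary = ScenarioSummary(
        name=config.name, n_games=config.n_games, wins=wins,
        end_events=end_events,
        end_event_histogram=summarize_end_events(end_events),
        transition_counts=tcounts, transition_events=tevents)
    if out_dir is not None:
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
    return summary
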