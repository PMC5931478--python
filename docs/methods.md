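# Methods

`goising` simulates the competition between a growing tumour and the immune
system as a game of Go scored by an Ising-type energy. Black stones are
cancer cells (circulating tumour cells, tumour-initiating cells, solid
tumours); white stones are tumour-suppressor elements (cytotoxic T cells, NK
cells, therapy). The board is a tissue; one *event* is one stone placement
or pass. This note records the model, the operational definitions behind
every detector, the agents, the numerical choices, and the limitations.

## Board representation and rules

The rules engine implements positional capture, the suicide prohibition,
simple ko (the point recreating the position after a single-stone capture is
barred for one turn; multi-stone captures never set a ko point), game end on
two consecutive passes or at the event cap, and area scoring
(stones + exclusively-bordered territory + captures, optional komi).
Superko, handicap and time controls are deliberately out of scope; the
event cap (default 500) breaks any cycle simple ko cannot. Komi defaults to
0 in simulations because the winner is decided by energy, not score.

Positions are partitioned into **common fate graph** (CFG) nodes: maximal
4-connected monochromatic chains, the units that live or die together. Each
node i carries its colour c_i (+1 immune, −1 cancer), size n_i, liberty
count h_i, and eye count k_i. An **eye** is an empty point whose every
on-board orthogonal neighbour has the node's colour (edge and corner points
therefore need only 3 or 2 matching neighbours), with at least one neighbour
in the node; an eye bordered by several same-colour chains counts once for
each of them. Two nodes are CFG-adjacent when they share a liberty or touch
directly; only adjacent pairs can interact.

## The energy model

Each node carries the descriptor

    x_i = c_i · (n_i + b_eye^{k_i}),        eye term 0 when k_i = 0,

with eye base `b_eye = 2` (any value > 1 preserves the qualitative
behaviour: each additional eye multiplies the group's weight, reflecting
that two eyes make a group uncapturable). Adjacent pairs (i, j) interact
with weight

    w_ij = Σ_t  r_t(owner) · |x_s|

summed over the tactic instances attached to the pair, where s is the
instance's mediating group and r_t the owner side's tactic weight:

| tactic      | cancer (black) | immune (white) | biological reading |
|-------------|---------------|----------------|--------------------|
| eye         | 0.7           | 0.4            | initial micro-tumour / suppressor barrier |
| net         | 0.6           | 0.7            | pre-metastatic niche / cytotoxic enclosure |
| ladder      | 0.5           | 0.5            | secreted-factor chase / protected tissue |
| connection  | 0.1           | 0.1            | microenvironment knitting / antigen signalling |
| invasion or reduction | 0.4 (invasion) | 0.5 (reduction) | primary seeding / therapy arrival |

A pair sharing a liberty but carrying no instance couples with the
single-liberty constant `r_sl = 1`. The mediating descriptor always enters
as a magnitude (|x_s|; the mediator is owner-coloured, so this is the
owner's own-sign value): with the raw signed descriptor every black-owned
tactic would lower the energy while every white-owned tactic raised it,
and one colour would win every symmetric battery.

The raw lattice sum

    H_literal = Σ_{i<j} w_ij x_i x_j − μ Σ_i h_i x_i        (μ = 1)

is reported for reference, but the *per-side* energies — the quantities the
winner rule and the trajectory plots use — apply own-sign conventions
symmetrically:

    H_side(c) = − Σ_{i<j, both colour c} w_ij |x_i||x_j|      (synergy)
                + Σ_{mixed pairs}  [pressure terms against c]  (tension)
                + ½ Σ_{mixed pairs} r_sl-part                  (contact)
                − μ Σ_{i: c_i = c} h_i |x_i|                   (field)

Own-side synergy and the liberty field are stabilizing. A mixed pair's
instance terms raise the energy of the *owner's adversary* — the side under
the pressure of the tactic (a netted chain's side carries the net's weight);
the ownerless r_sl contact term splits evenly. `H_total = H_cancer +
H_immune` by construction, and flipping every stone's colour while
exchanging the two weight tables exchanges the two side energies exactly.

**Numerical note.** Eye terms grow as 2^k, so late positions reach |H| ≳
10^20 and the two sides' energies share enormous mixed-contact terms. The
winner margin `H_cancer − H_immune` is therefore accumulated separately
from the side-specific terms only (the shared terms cancel exactly); naively
subtracting the two reported sums loses the signal below float64 resolution
and produced spurious draws.

## Tactic detectors (operational definitions)

The tactic vocabulary comes from Go; none of the patterns has a canonical
algorithmic definition, so each detector below is an explicit, deterministic
operationalization (scan-order = row-major from the top-left).

* **Atari** — any chain with exactly one liberty; owner is the adversary.
  Detected for the agents; carries no interaction weight.
* **Ladder** (`ladder_depth_cap = 50` plies) — forced read-out for a chain
  in atari: the defender extends at its single liberty; when the chain has
  two liberties the attacker fills the qualifying liberty (legal, not
  self-atari, returns the chain to atari) that leaves the defender's forced
  extension the fewest liberties (tie: scan order) — the standard chase
  rule; a plain scan-order choice lets canonical corner ladders escape by
  driving from the wrong side. Captured within the cap ⇒ LADDER.
* **Net** (`net_depth = 4` plies) — for chains with ≤ 2 liberties and fewer
  than two eyes: an AND–OR escape search (defender extends at a liberty or
  captures an adjacent adversary chain in atari; attacker fills a chain
  liberty). If the defender cannot exceed 2 liberties within the budget the
  chain is NETTED. Two-eyed chains are alive — their liberties can never be
  filled — and are never netted. A sound shortcut prunes most open-board
  chains: if some extension reaches ≥ 3 liberties even ignoring merges and
  captures, the chain escapes.
* **Connection** — each unordered same-colour pair of chains sharing ≥ 1
  liberty; the scan-smaller chain mediates.
* **Invasion / reduction** (`invasion_radius = 2`) — classify each chain by
  the stone balance of the Chebyshev-radius window around its members
  (members excluded): INVASION if the chain touches no allied chain (no
  connection incident) *and* adversary stones strictly outnumber allied
  ones — a deep, unsupported placement, the seeding of a metastasis;
  REDUCTION for any other chain with at least one adversary stone in its
  window — a supported boundary incursion. A chain is at most one of the
  two. Both map to the owner side's single incursion weight.

Instance attachment: a connection attaches to its own pair; an eye instance
(one per eye point and bordering group) to every (owner, adjacent adversary)
pair; ladder and net to every (target, adjacent attacker-colour) pair,
mediated by the scan-smallest attacker neighbour; invasion/reduction to
every (node, adjacent adversary) pair.

## Agents

Four seedable policies of graded strength stand in for the original
simulator line-up; they are defined by their policies and their empirical
ordering, not by any external engine. All agents refuse to fill their own
single-point eyes (so self-play terminates), pass when no other legal move
exists, and — the energy-guided ones — pass when no move improves their
**margin** (own side energy minus the adversary's, computed exactly as
above): the margin is what the winner rule compares, so it is the quantity
a rational player drives down. Energy-guided agents evaluate candidates
with a slightly shallower net search (depth 2; full ladder read-outs) than
the reporting configuration — an internal speed/strength trade-off; game
trajectories are always scored with the full configuration.

* **random** — uniform over playable points. The control: pure seeding with
  no strategy.
* **passive_mc** (weak by design) — samples 10 candidate moves, scores each
  with 5 uniform random rollouts of 30 plies evaluated by the margin at the
  horizon, plays the lowest mean. The shallow, noisy read models a sluggish
  immune response.
* **good** — 1-ply greedy: evaluates the margin after every playable move;
  ties broken by captures, then own liberties, then scan order.
* **aggressive** — a tactical cascade, then search: (1) capture the largest
  adversary chain in atari *unless it is already held by a working ladder
  or net* (capturing a dead chain forfeits the standing pressure); (2)
  rescue the largest own chain in atari whose ladder fails; (3) create a
  new eye for an own chain of ≥ 3 stones; (4) otherwise rank every playable
  move at 1 ply (with net search off in this sweep) and refine the best 6 by
  a 2-ply minimax in which the opponent's replies are restricted to the
  *sharp* responses — the liberties of the mover's low-liberty chains, plus
  pass. An unrestricted shallow minimax is dominated by horizon noise
  (capture swings just beyond the search edge) and measurably weakened the
  agent.

Deterministic agents play a seeded uniform exploration move with probability
ε (5%; 2% for the aggressive agent, which plays the most disciplined game),
so that seeded batteries vary the way batteries of real engines do while
preserving the strength ordering.

## Scenarios, trajectories, transitions

A scenario battery plays `n_games` seeded games (game i uses seed
`base_seed + i`), cancer (black) moving first. After every event both side
energies and the exact margin are recorded; the winner is the side with the
more negative final energy (exact tie ⇒ draw). Trajectories are normalized
per game by the maximum absolute energy across both sides (all-zero games
stay zero); **phase transitions** are events where either normalized series
jumps by more than τ = 0.1 (runs of consecutive flagged events merge and
report their first index) — read biologically as abrupt shifts of dominance
(a large capture: a tumour cleared, a tissue region overrun). Durations are
summarized as percentages over nine 50-event bins up to the 500-event
horizon. Every run writes one SGF and one energy CSV per game, a
`summary.json`, and a `manifest.json` sufficient to reproduce it.

The four named scenarios: `random` (control), `aggressive-vs-passive`
(metastatic cancer vs a weak immune system), `aggressive-vs-good`
(remission/relapse boundary), `aggressive-vs-aggressive` (strong cancer vs
strong immune system).

## Problem sizes

Full batteries are 100 games on 19×19 with a 500-event cap; the acceptance
script runs exactly that. The test suite exercises the same machinery at
reduced sizes chosen once — 50-game random and 12–24-game agent batteries
on 19×19, oracle comparisons on 5×5/7×7 — so the whole suite completes in a
few minutes on one CPU.

## What the batteries show — and the one known gap

With the default weights the batteries reproduce the qualitative structure
the model targets: the random control is near-balanced with a first-mover
edge for cancer (~55%), every random game runs past event 300; the
aggressive agent wins ≥ 90% against the passive one and ≥ 80% against the
greedy one; aggressive self-play is balanced with a cancer lean. One
duration statistic falls short: in aggressive self-play roughly a third of
games end in the (250, 300] bin rather than the large majority — our
margin-improvement pass rule lets the endgame grind on for a few dozen more
events than an engine with a territorial stopping criterion. The gap is
reported as measured.

## Limitations

* The tactic detectors are bounded searches with deterministic move
  selection, not full life-and-death analysis; deep seki, snapback chains
  and loose ladders beyond the depth caps are invisible to the energy.
* The agents are stand-ins: their absolute strength is far below real Go
  engines, and conclusions transfer only at the level of *relative*
  strength between scenarios.
* Energies are reported in model units; magnitudes are dominated by the
  exponential eye term and are not comparable across board sizes.
* The model is two-dimensional and binary (cancer/immune); multi-clone
  competition or 3-D growth would need a multi-state (Potts-type) extension
  and is out of scope.
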