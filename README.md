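# goising

Tumour–immune competition simulated as the game of Go, scored by an Ising
Hamiltonian over common-fate-graph groups.

The package is for computational-biology researchers who want a minimal,
fully reproducible playground for the cancer-as-Go metaphor: black stones
are cancer cells (seeding, micro-tumours, pre-metastatic niches), white
stones the immune system and therapies (suppressor barriers, cytotoxicity,
chemo/radiotherapy arrival). Each board position is a tissue state; every
stone placement or pass is one *event*; the per-side Ising energy quantifies
which side dominates, and seeded agent batteries of different strength
pairings reproduce win-rate and game-duration statistics for scenarios from
"random seeding" to "aggressive metastasis vs a strong immune system".

## The model

Stones connected along rows/columns form indivisible groups (common fate
graph nodes). A group i has colour c_i (+1 immune, −1 cancer), size n_i,
liberties h_i and eyes k_i, and carries the descriptor

    x_i = c_i (n_i + b_eye^{k_i}),      b_eye = 2, eye term 0 if k_i = 0.

Adjacent groups interact with weight w_ij = Σ_t r_t(owner)·|x_s| over the
tactic patterns attached to the pair — eye, net, ladder, connection, and
invasion/reduction, with side-specific weights (cancer: 0.7/0.6/0.5/0.1/0.4;
immune: 0.4/0.7/0.5/0.1/0.5) — or with the single-liberty constant
r_sl = 1 when they merely share a liberty. The energy of a position is

    H = Σ_{i<j} w_ij x_i x_j − μ Σ_i h_i x_i,       μ = 1,

split per side so that own-group synergy and the liberty field are
stabilizing while the pressure of adversary tactics raises the pressured
side's energy. The **winner of a simulation is the side with the more
negative final energy**. Abrupt jumps of the normalized energy trajectory
are flagged as phase transitions — qualitative shifts of dominance.
`docs/methods.md` has the full model, every detector's operational
definition, and the design rationale.

## Worked example

```python
import goising as G

state = G.make_fixture("geta_net")   # a white stone caught in a loose net
rep = G.hamiltonian(state)
print(f"H_cancer = {rep.H_cancer:.6g}")
print(f"H_immune = {rep.H_immune:.6g}")
print(f"H_total  = {rep.H_total:.6g}")
```

prints

```
H_cancer = -23.1
H_immune = 7.6
H_total  = -15.5
```

Cancer (black) has netted the lone white stone: black's three chains and
their mutual connections pull `H_cancer` down to −23.1, while the net's
pressure on the trapped stone pushes `H_immune` up to +7.6 — under the
most-negative-energy rule, black dominates this tissue region. The detected
patterns behind those numbers:

```python
from goising.tactics import detect_all, instance_listing
print(instance_listing(detect_all(G.build_cfg(state), state)))
```

```
connection owner=cancer groups=[0, 1] between=(0, 1)
connection owner=cancer groups=[0, 3] between=(0, 3)
connection owner=cancer groups=[1, 3] between=(1, 3)
net        owner=cancer groups=[2]
reduction  owner=cancer groups=[0]
reduction  owner=cancer groups=[1]
invasion   owner=immune groups=[2]
reduction  owner=cancer groups=[3]
```

Batteries run from the shell. Each game is written as SGF plus a per-event
energy CSV, with a manifest that reproduces the run exactly:

```
goising simulate --scenario aggressive-vs-passive --n 100 --seed 1 \
    --out out/metastasis
goising report out/metastasis
goising evaluate out/metastasis/game_0.sgf     # re-score a saved game
```

Scenarios: `random` (control), `aggressive-vs-passive` (metastasis vs a
weak immune system), `aggressive-vs-good` (remission boundary),
`aggressive-vs-aggressive` (strong vs strong). Agents are seeded stand-ins
of graded strength (uniform random, weak Monte-Carlo, 1-ply energy-greedy,
tactical cascade + 2-ply search); tactic weights and model constants can be
overridden with `--weights` (see `examples/weights.yaml`).

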