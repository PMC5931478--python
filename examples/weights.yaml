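# Tactic weights and model constants (defaults shown; any subset may be
# overridden — omitted keys keep these values).
cancer:            # black: tumour progression
  eye: 0.7         # initial micro-tumours
  net: 0.6         # pre-metastatic niche / solid tumour
  ladder: 0.5      # tumour-secreted factors and extracellular vesicles
  connection: 0.1  # metastatic microenvironment setup
  invasion: 0.4    # primary invasion (seeding)
immune:            # white: immune reaction
  eye: 0.4         # tumour suppressor barriers
  net: 0.7         # cytotoxicity
  ladder: 0.5      # protected tissue
  connection: 0.1  # antigen presentation and cell signalling
  reduction: 0.5   # arrival of immune cells / chemo- or radio-therapy
r_sl: 1.0          # single-liberty coupling
b_eye: 2.0         # eye base of the group descriptor (> 1)
mu: 1.0            # external-field strength
ladder_depth_cap: 50
net_depth: 4
invasion_radius: 2
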