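# Default ARE scoring weights shipped with translatome.
# The engine is fully parameter-driven; edit or replace this file to use
# a different weighting scheme.
motif: AUUUA
base_score: 1.0
pair_bonuses:
  - [2, 1.5]     # overlapping or nearly adjacent pentamers (gap <= 2 nt)
  - [10, 0.75]   # clustered pentamers (gap 3-10 nt)
au_context_bonus: 0.5
au_context_window: 20
au_context_fraction: 0.75
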