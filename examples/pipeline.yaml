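# Full-pipeline configuration: simulate -> rank -> model -> stats -> rlq -> sdm.
# Remove a stage block to skip that stage (and the stages that need it).
seed: 1

simulate:
  n_species: 62
  n_sites: 120        # scaled survey; the full design uses 611 sites
  plots_per_site: 3
  quadrats_per_plot: 5

rank:
  unit: quadrat       # sampling unit for relative frequency

model:
  algorithm: forest   # or: boosting
  design: observation # or: species (no identity leakage, honest but small-n)
  n_repeats: 50       # permutation-importance repeats

stats:
  traits: [sla, hundred_grain_weight]
  alpha: 0.05

rlq:
  n_axes: 2

sdm:
  select: [sla]       # traits combined into the presence weight
  background_ratio: 10
  penalty: 0.01
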