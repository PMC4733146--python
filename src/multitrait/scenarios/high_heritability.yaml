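# Factorial-mating simulation scenario with high heritabilities
name: high_heritability
g0:
  - [1.0, 0.4, 0.6]
  - [0.4, 1.5, 0.9]
  - [0.6, 0.9, 2.5]
r0:
  - [1.0, 0.5, 0.5]
  - [0.5, 1.0, 0.5]
  - [0.5, 0.5, 1.0]
n_seed: 25
n_pollen: 25
n_replicates: 50
base_seed: 2015
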