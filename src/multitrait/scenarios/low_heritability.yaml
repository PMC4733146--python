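# Factorial-mating simulation scenario with low heritabilities and
# negative covariances
name: low_heritability
g0:
  - [5.0, -2.0, 3.0]
  - [-2.0, 7.0, 4.0]
  - [3.0, 4.0, 10.0]
r0:
  - [20.0, -5.0, 1.0]
  - [-5.0, 28.0, 3.0]
  - [1.0, 3.0, 35.0]
n_seed: 25
n_pollen: 25
n_replicates: 50
base_seed: 2015
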