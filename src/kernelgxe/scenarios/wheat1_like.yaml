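# Four mega-environments, one negatively correlated with the rest;
# n/p on the order of the ~600-line, ~1300-marker DArT panels.
name: wheat1_like
n: 599
m: 4
p: 1279
UE_corr:
  - [1.0, -0.3, -0.3, -0.2]
  - [-0.3, 1.0, 0.6, 0.4]
  - [-0.3, 0.6, 1.0, 0.5]
  - [-0.2, 0.4, 0.5, 1.0]
UE_var: [0.5, 0.5, 0.5, 0.5]
FE_corr:
  - [1.0, -0.2, -0.2, -0.1]
  - [-0.2, 1.0, 0.3, 0.2]
  - [-0.2, 0.3, 1.0, 0.2]
  - [-0.1, 0.2, 0.2, 1.0]
FE_var: [0.15, 0.15, 0.15, 0.15]
Sigma_true: [0.35, 0.35, 0.35, 0.35]
maf_range: [0.05, 0.5]
architecture: additive
seed: 11
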