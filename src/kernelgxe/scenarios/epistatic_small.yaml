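# Small epistatic-architecture scenario for kernel-comparison experiments:
# half of the genetic variance comes from pairwise marker products, which a
# linear kernel cannot represent.
name: epistatic_small
n: 200
m: 3
p: 600
UE_corr:
  - [1.0, 0.8, 0.8]
  - [0.8, 1.0, 0.8]
  - [0.8, 0.8, 1.0]
UE_var: [0.7, 0.7, 0.7]
Sigma_true: [0.3, 0.3, 0.3]
maf_range: [0.1, 0.5]
architecture: epistatic
additive_share: 0.3
seed: 33
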