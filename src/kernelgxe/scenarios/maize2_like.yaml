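# Three positively correlated environments with negligible non-marker
# genetic covariance (FE omitted), GBS-scale marker count reduced for speed.
name: maize2_like
n: 504
m: 3
p: 2000
UE_corr:
  - [1.0, 0.7, 0.6]
  - [0.7, 1.0, 0.7]
  - [0.6, 0.7, 1.0]
UE_var: [0.6, 0.6, 0.6]
Sigma_true: [0.4, 0.4, 0.4]
maf_range: [0.05, 0.5]
architecture: additive
seed: 22
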