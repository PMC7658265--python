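# Three mass-coupled cells in a cyclic array operated as a logic gate by the
# central knockout perturbation system (knockout word 0 1 1).
# Reproduces the full input-word sequence: a pattern-selecting input installs
# its own discrete Turing pattern; any other input word sends the array back
# to uniform oscillations, which the receptor-gated knockout pulses convert
# to the 0 1 1 reference pattern before the output is read.
analysis: gate
topology:
  kind: cyclic
  N: 3
params:
  sigma_M: 100.0
  sigma_inh: 35.0
  k_ADP: 0.1
  q: 1.0
schedule: []
solver: {}
seed: 0
options:
  knockout: "011"
  infer: true
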