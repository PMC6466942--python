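# Shipped detector defaults: three-branch search boundaries (published
# grid-search optima) and sliding-window configuration.
onset:
  kind: onset
  breakpoints: [0.76, 1.13]
  ald: 0.4
  alu: 0.2
  ard: 0.4
  aru: 0.4
  amd: 0.3
  amu: 0.0
  lower_intercepts: [0.02, 0.04, 0.04]
  upper_intercepts: [0.16, 0.24, 0.4]
offset:
  kind: offset
  breakpoints: [0.72, 1.1]
  ald: 0.2
  alu: 0.1
  ard: 0.2
  aru: 0.0
  amd: 0.0
  amu: 0.1
  lower_intercepts: [0.18, 0.18, 0.18]
  upper_intercepts: [0.3, 0.4, 0.48]
swa:
  w_on: 0.12
  w_off: 0.128
  p: 0.016
  use_abs_area: true
  min_span: 0.08
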