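condition: compressed
n_ambient_top: 1.0
p: 0.05
weights:
- 0.0
- 0.0
- 0.0
- 0.6666666666666666
- 6.0
- 0.3333333333333333
signature_layers:
- 0
- 1
- 2
- 3
- 4
- 4
layers:
- name: EPI
  n: 1.33
  d: 0.08
  Cb: 0.0
  Cw: 0.05
  Cf: 0.0
  vd: 0.0
  ra: 0.5
  rv: 0.5
  SpO2: 0.97
  SvO2: 0.67
  gamma: 0.5
  pulsatile: false
  scatter_class: EPI
  is_epidermis: true
- name: CL
  n: 1.37
  d: 0.008
  Cb: 0.0012
  Cw: 0.15
  Cf: 0.0
  vd: 10.0
  ra: 1.0
  rv: 0.0
  SpO2: 0.97
  SvO2: 0.67
  gamma: 0.5
  pulsatile: true
  scatter_class: dermal
  is_epidermis: false
- name: UP
  n: 1.4
  d: 0.004
  Cb: 0.0024
  Cw: 0.15
  Cf: 0.0
  vd: 20.0
  ra: 1.0
  rv: 0.0
  SpO2: 0.97
  SvO2: 0.67
  gamma: 0.5
  pulsatile: true
  scatter_class: dermal
  is_epidermis: false
- name: RD&DP
  n: 1.4
  d: 0.1
  Cb: 0.024
  Cw: 0.15
  Cf: 0.0
  vd: 20.0
  ra: 1.0
  rv: 0.0
  SpO2: 0.97
  SvO2: 0.67
  gamma: 0.5
  pulsatile: true
  scatter_class: dermal
  is_epidermis: false
- name: SC
  n: 1.44
  d: 0.2
  Cb: 0.036
  Cw: 0.35
  Cf: 0.4
  vd: 40.0
  ra: 0.75
  rv: 0.25
  SpO2: 0.97
  SvO2: 0.67
  gamma: 0.25
  pulsatile: true
  scatter_class: SC
  is_epidermis: false
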