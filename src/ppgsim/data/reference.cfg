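condition: reference
n_ambient_top: 1.0
p: 0.05
weights:
- 0.0
- 0.0
- 0.3333333333333333
- 0.6666666666666666
- 1.0
- 0.3333333333333333
signature_layers:
- 0
- 1
- 2
- 3
- 4
- 5
layers:
- name: EPI
  n: 1.33
  d: 0.08
  Cb: 0.0
  Cw: 0.2
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
  d: 0.015
  Cb: 0.004
  Cw: 0.65
  Cf: 0.0
  vd: 10.0
  ra: 0.5
  rv: 0.5
  SpO2: 0.97
  SvO2: 0.67
  gamma: 0.5
  pulsatile: true
  scatter_class: dermal
  is_epidermis: false
- name: UP
  n: 1.4
  d: 0.008
  Cb: 0.02
  Cw: 0.65
  Cf: 0.0
  vd: 20.0
  ra: 0.5
  rv: 0.5
  SpO2: 0.97
  SvO2: 0.67
  gamma: 0.5
  pulsatile: true
  scatter_class: dermal
  is_epidermis: false
- name: RD
  n: 1.4
  d: 0.12
  Cb: 0.004
  Cw: 0.65
  Cf: 0.0
  vd: 20.0
  ra: 0.5
  rv: 0.5
  SpO2: 0.97
  SvO2: 0.67
  gamma: 0.5
  pulsatile: true
  scatter_class: dermal
  is_epidermis: false
- name: DP
  n: 1.4
  d: 0.05
  Cb: 0.04
  Cw: 0.65
  Cf: 0.0
  vd: 40.0
  ra: 0.5
  rv: 0.5
  SpO2: 0.97
  SvO2: 0.67
  gamma: 0.5
  pulsatile: true
  scatter_class: dermal
  is_epidermis: false
- name: SC
  n: 1.44
  d: 0.5
  Cb: 0.03
  Cw: 0.05
  Cf: 0.4
  vd: 50.0
  ra: 0.5
  rv: 0.5
  SpO2: 0.97
  SvO2: 0.67
  gamma: 0.25
  pulsatile: true
  scatter_class: SC
  is_epidermis: false
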