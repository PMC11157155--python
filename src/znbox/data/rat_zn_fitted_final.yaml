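name: rat_zn_fitted_final
description: 'Balanced network with calibrated unknowns: bone exchange 3212/300.2
  ug/day each way (bone residence 300.2 d from the diet-switch calibration), plasma->integument
  4 ug/day, renal fractionation amplitude 0.44 per mil (alpha=1.00044), intestinal
  absorption split amplitude -0.025/+0.025 per mil and integument amplitude -0.30
  per mil from this package''s sweep-fit representative against the observed compositions.'
compartments:
- name: diet
  mass: infinite
  role: source
  delta0: 0.42
- name: intestine
  mass: 1000
  role: internal
- name: plasma
  mass: 32
  role: internal
  delta0: 0.36
- name: liver
  mass: 378
  role: internal
  delta0: -0.48
- name: rbc
  mass: 320
  role: internal
  delta0: 0.47
- name: muscle
  mass: 1960
  role: internal
  delta0: -0.21
- name: bone
  mass: 3212
  role: internal
  delta0: 0.37
- name: kidney
  mass: 63
  role: internal
  delta0: -0.12
- name: integument
  mass: 2787
  role: internal
  delta0: 0.08
- name: feces
  mass: 813
  role: accumulator
  delta0: 0.44
- name: urine
  mass: 7
  role: accumulator
- name: waste
  mass: infinite
  role: sink
fluxes:
- from: diet
  to: intestine
  rate: 1000
  alpha: 1.0
- from: intestine
  to: feces
  rate: 989
  alpha: 1.0
- from: intestine
  to: plasma
  rate: 305
  alpha: 0.999975000312
- from: plasma
  to: intestine
  rate: 294
  alpha: 1.000025000313
- from: plasma
  to: liver
  rate: 900
  alpha: 0.999580088188
- from: plasma
  to: rbc
  rate: 35
  alpha: 1.00005000125
- from: plasma
  to: muscle
  rate: 227
  alpha: 0.999720039196
- from: plasma
  to: bone
  rate: 10.699533644237176
  alpha: 1.00001000005
- from: plasma
  to: integument
  rate: 4
  alpha: 0.999700044996
- from: plasma
  to: kidney
  rate: 118
  alpha: 1.0
- from: liver
  to: plasma
  rate: 900
  alpha: 1.000420088212
- from: rbc
  to: plasma
  rate: 35
  alpha: 0.99995000125
- from: muscle
  to: plasma
  rate: 227
  alpha: 1.000280039204
- from: bone
  to: plasma
  rate: 10.699533644237176
  alpha: 0.99999000005
- from: kidney
  to: plasma
  rate: 111
  alpha: 1.0
- from: kidney
  to: urine
  rate: 7
  alpha: 1.000440096814
- from: urine
  to: waste
  rate: 7
  alpha: 1.0
- from: integument
  to: waste
  rate: 4
  alpha: 1.0
- from: feces
  to: waste
  rate: 989
  alpha: 1.0
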