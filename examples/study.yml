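# Study operating point: sigma2 = 3.33e4, S0 = 1, D3 = 2 D2 = 6,
# layer heights 2 / 2 / 10 / 2 (unit-cell radius 1, hole mouth a3 = 0.1).
schema_version: 1
profile: fast
geometry:
  shape: concave_paraboloid_up
  alpha: 0.93
  gamma: 0.5
params:
  sigma2: 3.33e4
  S0: 1.0
  D2: 3.0
  D3: 6.0
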