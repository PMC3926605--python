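# GA-optimized indicator parameters reported for the original 9-driver
# simulator study (shipped as a named preset).
STD_lp: {}
STD_sw: {}
STD_he: {}
MSE_lp:
  p: 1.865
MSE_he:
  p: -1.2
Lanex:
  x_L: 2.27
  x_R: 1.42
TLC_5s:
  a: 6.4
  x_L: 2.27
  x_R: 1.42
TLC_avg:
  x_L: 2.27
  x_R: 1.42
RSWM:
  d: 13.0
PERCLOS:
  closure_threshold: 0.8
  blink_max: 0.5
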