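# Literature default indicator parameters (before optimization).
# Units: p in m (MSE_lp) or deg (MSE_he); x_L/x_R in m; a, tlc_max, blink_max in s;
# d in deg/s; closure_threshold is a fraction.
STD_lp: {}
STD_sw: {}
STD_he: {}
MSE_lp:
  p: 1.875
MSE_he:
  p: 0.0
Lanex:
  x_L: 2.625
  x_R: 1.125
TLC_5s:
  a: 5.0
  x_L: 2.625
  x_R: 1.125
  tlc_max: 30.0
TLC_avg:
  x_L: 2.625
  x_R: 1.125
  tlc_max: 30.0
RSWM:
  d: 125.0
PERCLOS:
  closure_threshold: 0.8
  blink_max: 0.5
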