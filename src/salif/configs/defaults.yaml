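# Default LIF/WTA/noise parameters (SI units; map units for noise).
# Conventions follow the classic saliency-toolbox implementation: 0.1 ms
# integration step, leak reversal at 0 V, 1 mV firing threshold, and a
# saliency map of order 1e-9 converted to current through Ginput.  The
# noise defaults (1e-17 random, 1e-14 constant) are the model's stock
# values; they are tiny relative to the map scale on purpose.
lif:
  dt: 1.0e-4        # s
  Eleak: 0.0        # V
  Eexc: 0.1         # V
  Einh: -0.02       # V
  Gleak: 1.0e-8     # S
  Gexc: 2.0e-7      # S, excitatory pulse to the WTA layer per spike
  Ginh: 0.0         # S
  GinhDecay: 1.0    # s (inert before the first spike)
  Ginput: 5.0e-2    # S, saliency -> input current scale
  Vthresh: 1.0e-3   # V
  C: 1.0e-9         # F
wta:
  C: 1.0e-8         # F
  Gleak: 1.0e-8     # S
  Ginh: 0.0         # S (global inhibition; post-spike only)
noise:
  noise_ampl: 1.0e-17   # map units, uniform noise drawn once per run
  noise_const: 1.0e-14  # map units, constant offset
  map_range: 1.0e-9     # map units, nominal saliency output range
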