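# Endogenous-to-exogenous transition under growth (qualitative reproduction).
# A shoot growing from 2 cm through the reduced-model critical length
# (~6.6 cm) with a weak endogenous oscillator: early tip orbits have the
# endogenous period (20 min); once the flutter instability engages, large
# orbits near the ~88 min exogenous period take over, with trochoid-like
# patterns in between. The growth zone is set to 7 cm (upper end of the
# plausible range) so the shoot is still unlignified when it crosses the
# threshold.
kind: simulate
preset: baseline
growth:
  ell0: 2 cm
  ell_g: 7 cm
  tau_g: 20 h
stimulus:
  alpha: 0.2
t_end: 36 h
out_every: 1 min
n_nodes: 80
initial_tilt: 1.0e-3
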