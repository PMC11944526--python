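# Promolecular per-element radial parameters: rho_atom(r) = amplitude * exp(-r/decay_bohr).
# Amplitudes are normalized so each atomic density integrates to Z electrons
# (a = Z / (8 pi lambda^3)); H is the exact ground-state hydrogen density.
# Conventional single-exponential constants for an analytic test-bed density.
element,amplitude,decay_bohr
H,0.3183098861837907,0.5
C,6.073997929926801,0.34
N,10.315598163363589,0.3
O,16.171817618441835,0.27
S,19.428093639147377,0.32
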