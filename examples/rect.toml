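# Rectangle-well run configuration (µm; probabilities per time step).
[domain]
kind = "box"
lx = 40.0
ly = 15.0
lz = 15.0

[params]
t_steps = 1000
p_cross = 0.005
k_nuc = 0.5
r_replicates = 1
seed = 1
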