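# Shape x severing grid at smoke-test scale (see mtconfine sweep).
[params]
t_steps = 300
r_replicates = 3
seed = 100

[[domains]]
kind = "box"
lx = 40.0
ly = 15.0
lz = 15.0
label = "rect"

[[domains]]
kind = "box"
lx = 20.0
ly = 20.0
lz = 15.0
label = "square"

[experiment]
name = "shape_severing_demo"
p_cross_values = [0.005, 0.0]
out_dir = "scratch/demo_results"
snapshot_every = 0
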