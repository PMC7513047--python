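# Scaled-down two-temperature melt: 16 chains of 40 monomers, Th = 3.
[system]
M = 16
N = 40
density = 0.85
box_aspect = [1.0, 1.0, 2.0]

[thermostats]
Tc = 1.0
Th = 3.0
zeta = 1.5

[run]
dt = 0.005
duration = 100.0
sample_interval = 25.0
seed = 7
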