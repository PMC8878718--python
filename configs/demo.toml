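# Demo run: 100 ps dimer with role switches at 15 and 64 ps, plus the
# 200-molecule ring-associated liquid in the 39.182 Å reference cell.
seed = 11
outdir = "results/demo"

[dimer]
n_steps = 200000
dt = 0.5
temperature = 300.0
switch_times = [15.0, 64.0]
ou_mu = 3.0
ou_sd = 0.15
ou_theta = 0.005

[liquid]
n_molecules = 200
cell = 39.182
first_shell = [2.7, 2.9]
ring_size = 10

[analysis]
d_HA_min = 1.6
d_HA_max = 2.0
gap_tolerance = 20.0
hold = 1.0
snapshot_interval = 1.45
envelope_width = 20.0
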