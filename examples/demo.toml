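# Desk-scale demonstration run: simulate a 600 kb two-population contrast
# with one planted hard sweep, then run all scan stages.
seed = 42
object_group = "fat"
reference_group = "thin"

[simulate]
n_diploids_per_pop = 20
sequence_length = 600_000
n_sites = 600
split_generations = 50
recombination_rate = 7e-7
sweep_positions = [299_999]
sweep_s = [0.15]

[fstpi]
window = 100_000
step = 25_000
mode = "quantile"
q = 0.12

[xpclr]
grid_spacing = 20_000
window_genetic_span = 0.07
max_snps_per_window = 60
morgans_per_bp = 7e-7
quadrature_points = 48
top_fraction = 0.05

[roh]
preset = "test"
island_threshold = 20.0
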