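"""Sweep drive efficiencies and map where suppression works.

Grid-evaluates the cutting probability against the carrier fitness cost
for the paper wasp (10 replicates per cell, 50 generations), printing a
suppression-rate table.  Other drive parameters sit at their optima so
each axis is probed in isolation.  Pair with
``waspdrive.plotting.plot_sweep_heatmap`` for a figure.
"""

from waspdrive import PAPER_WASP, SimConfig, sweep_drive_parameters

base = SimConfig(species=PAPER_WASP, replicates=10, seed=2)
table = sweep_drive_parameters(
    base,
    ("p_cut", [0.85, 0.95, 1.0]),
    ("p_het_mort", [0.0, 0.2, 0.4]),
    generations=50,
)

print(table.pivot(index="p_het_mort", columns="p_cut", values="suppression_rate"))
print("\nrows: carrier pre-mating mortality; columns: cutting probability;")
print("cells: fraction of 10 replicates suppressed within 50 generations")
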