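"""Follow allele frequencies through one replicate, year by year.

Runs a single paper-wasp replicate with the default female-infertility
drive and prints the queen count and the four allele frequencies (wildtype,
drive, functional resistance, non-functional repair) among queens each
generation.  The drive climbs toward its ceiling of 0.5 — homozygous
carriers are infertile and never appear among reproducing queens — and
either crashes the population or is overtaken by a resistance allele.
"""

from waspdrive import PAPER_WASP, SimConfig, run_replicate

config = SimConfig(species=PAPER_WASP, generations=25, seed=4)
result = run_replicate(config, replicate_index=0)

print("gen  queens    WT    GD    RE    NF")
for gen, n, (wt, gd, re, nf) in zip(
    result.generation, result.n_queens, result.allele_freqs
):
    if n:
        print(f"{gen:3d}  {n:6d}  {wt:.3f} {gd:.3f} {re:.3f} {nf:.3f}")
    else:
        print(f"{gen:3d}  {n:6d}  population suppressed")

print("suppressed:", result.suppressed)
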