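"""How queen mating number shapes drive success.

Compares the paper wasp (nearly monandrous) against a doubled-polyandry
variant, and the hornet against a no-polyandry variant, at a reduced
replicate count.  Polyandrous queens occupy more of the limited male
mating slots, so fewer gynes mate at all; the unmated foundresses still
compete for nest sites, thinning the reproductive core of the population
and leaving it more vulnerable to stochastic loss of the wildtype allele.
"""

from waspdrive import HORNET, PAPER_WASP, SimConfig, polyandry_variant, run_scenario

REPLICATES = 10

for label, species in [
    ("hornet (polyandrous)", HORNET),
    ("hornet, no polyandry", polyandry_variant(HORNET, "no_polyandry")),
    ("paper wasp (monandrous)", PAPER_WASP),
    ("paper wasp, doubled polyandry", polyandry_variant(PAPER_WASP, "doubled")),
]:
    summary = run_scenario(
        SimConfig(species=species, replicates=REPLICATES, generations=25, seed=8)
    )
    print(f"{label:32s} suppressed {summary.n_suppressed}/{REPLICATES}")
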