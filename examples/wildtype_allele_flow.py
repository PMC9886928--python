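"""Why the drive cannot shrink a population it fails to eradicate.

At the drive's frequency ceiling (just under 0.5) a hornet population of
1000 queens still contains a few dozen wildtype homozygotes and many
heterozygotes whose uncut wildtype alleles leak through the germline.
This deterministic diagnostic counts the wildtype alleles those queens
pass to the next generation's overwintered queens — more than enough to
refill the carrying capacity, which is why population size is unaffected
until complete suppression.
"""

from waspdrive import expected_wt_transmission

ww = expected_wt_transmission(
    n_queens=40, genotype_class="wt_wt", offspring_mean=300, winter_mortality=0.97
)
het = expected_wt_transmission(
    n_queens=960, genotype_class="wt_gd", offspring_mean=300,
    winter_mortality=0.97, p_cut=0.95,
)

print(f"wildtype alleles from 40 WT/WT queens:   {ww:.0f}")
print(f"wildtype alleles from 960 WT/GD queens:  {het:.0f}")
print(f"total wildtype alleles reaching next-generation queens: {ww + het:.0f}")
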