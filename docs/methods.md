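# Methods

## Scope and state

`waspdrive` simulates a single locally closed population of an annual,
haplodiploid social wasp carrying a single-locus CRISPR homing drive.
State between years is the set of queens: a diploid genotype over the four
alleles {WT, GD, RE, NF}, the haploid alleles of her stored mates, and
each mate's fertility under the drive strategy. Males exist only inside
the mating step of the year they are born. There is no space, no
immigration or emigration, no mate choice, no within-year colony dynamics
(workers, nest growth), and no diploid-male production: a 1:1 sex ratio of
reproductives is assumed throughout.

## Drive genetics

Females are diploid, males haploid; all nuclease activity happens in the
queen germline. For a gamete sampling a WT allele of a drive-carrier
queen, the outcome probabilities are

- homing (allele becomes GD): P_cut · (1 − P_NHEJ)
- functional resistance (RE): P_cut · P_NHEJ · P_FR
- non-functional repair (NF): P_cut · P_NHEJ · (1 − P_FR)
- unchanged WT: 1 − P_cut

GD, RE and NF alleles are never modified (RE and NF target sites cannot be
re-cut). Defaults P_cut = 0.95, P_NHEJ = 0.02, P_FR = 0.01 reflect
efficiencies demonstrated in mosquito drives; the carrier fitness cost
P_HetMort defaults to 0 and, when set, applies once per individual with
complete dominance (hetero-, homo- and hemizygotes alike) just before
mating.

**Resolution granularity.** The four outcome probabilities fix each
gamete's marginal transmission, but not how repair outcomes are correlated
within a brood. `resolution="per_gamete"` (the default) draws every
gamete's fate independently, so new RE/NF alleles arise as singletons;
`"per_queen"` decides each WT allele's fate once per queen before any
gamete is drawn, making rare repair events heritable in sibling blocks.
The choice materially affects how often resistance establishes and hence
the suppression rate; the per-gamete default was adopted because it
reproduces the reference replicate counts more closely across all
scenarios (see Calibration below). Both modes are first-class and tested.

**Fertility.** The drive disrupts a haplo-sufficient fertility gene of the
targeted sex. A female is infertile when *both* her copies are disrupting
(each ∈ {GD, NF}); one functional copy (WT or RE) suffices. A haploid male
is sterile when his single allele is disrupting. NF alleles count as
disrupting: the gene is destroyed whether by drive insertion or mutagenic
repair. Under the neutral strategy nobody is sterilised.

## Life cycle (one year)

Order of operations: offspring → mating → winter mortality → infertility
cull → density regulation.

1. **Offspring.** Each queen with ≥ 1 fertile mate draws independent
   Poisson(offspring_mean_per_sex) daughter and son counts. Every
   fertilised egg picks a stored mate uniformly at random (the random
   sperm division of a polyandrous brood); eggs allocated to a sterile
   mate are lost, not reallocated. Unmated queens produce nothing.
2. **Mating.** Female demand is a zero-and-max-truncated Poisson (a queen
   always finds a mate if one is available), male capacity a max-truncated
   Poisson that is *not* zero-truncated (a large fraction of males never
   mate). Truncation is by pmf renormalization over the integer support;
   the rate parameter is the untruncated Poisson λ. Each male enters a
   slot pool once per capacity unit; the pool is shuffled and dealt to
   females in random order, min(demand, remaining slots) each, distinct
   males where possible (duplicates are repaired from unused slots, or
   kept when impossible). Genotype plays no role in pairing.
3. **Winter.** Each queen dies with the species' winter-mortality
   probability, independent of genotype and mating status.
4. **Cull and regulation.** Infertile queens, and mated queens with no
   fertile mate, are removed first — their colonies fail before nest-site
   competition. The expected population is the logistic map
   N_t ~ Poisson(K / (1 + ((K − N_prev)/N_prev)/r_max)) with N_prev the
   queen count of the completed generation; each remaining candidate
   survives with probability min(1, N_t / cohort), where the cohort is the
   full overwintered foundress population.

**Unmated foundresses.** Gynes that obtain no mate are retained through
winter, the cull, and density regulation as non-reproducing competitors
(`unmated_queens="retain"`, default); `"discard"` drops them at the mating
step. Retention has two consequences that match the reference system's
reported behaviour: the census population holds at carrying capacity right
up to collapse, and the *reproductive* core of a polyandrous species is
much smaller than the census (hornet queens average ~2.6 mating slots
each, so only ~1/3 of gynes mate when males are limiting) — which is
precisely why polyandry amplifies suppression and why removing it
(max matings = 1) weakens the drive so strongly.

**Density denominator.** Computing the density-mortality rate against the
whole overwintered cohort (rather than only the post-cull candidates)
keeps a drive-free population exactly at K in expectation, while letting a
high-frequency drive silently shrink the fertile core to
fertile-fraction × N_t — the mechanism behind sudden, complete collapse
with no prior decline in census size. Passing `n_cohort=None` to
`regulate_density` recovers the candidates-only variant.

## Species presets

| parameter | hornet | paper wasp | notes |
|---|---|---|---|
| offspring per sex (Poisson mean) | 300 | 20 | gynes per successful nest |
| winter mortality | 0.97 | 0.5 | hornet value from a congeneric vespine |
| r_max | 10 | 10 | maximum yearly growth rate |
| female matings | λ 3.275, {1..4} | λ 0.2, {1..2} | realised means 2.63 and 1.09 |
| male matings | λ 0.9, {0..3} | λ 0.9, {0..3} | ~41% of males never mate |
| K | 1000 | 1000 | also the initial mated-queen count |

K and the starting population are not independently documented for either
species; 1000 was chosen to match the release accounting (100 drive
carriers per 1000 mated females) and is configurable. Polyandry variants:
`no_polyandry` caps female matings at 1; `doubled` doubles λ and the
maximum (wasp: 0.2→0.4, 2→4).

## Releases, replicates, randomness

Female releases replace 100 of the K initial wildtype queens with WT/GD
mated queens (heterozygous: a homozygous release would be sterile under a
female-targeting drive; 100 queens = 100 drive alleles). Male releases
inject 100 GD males into the generation-1 mating pool, so their effective
introduction frequency is offspring-scale, hundreds of times lower. The
initial queens each store one WT mate; polyandry operates from the first
simulated mating on.

Each replicate's stream is `default_rng(SeedSequence((seed,
replicate_index)))`: any replicate is reproducible in isolation, and a
scenario is reproducible from (config, seed). The acceptance script
derives one sub-seed per scenario from its `--seed` the same way.

## Scenario statistics

Suppression is queen count reaching zero within the horizon (25
generations by default; 50 for parameter sweeps, where slow near-threshold
cells need longer to resolve). Time to suppression is the 1-based
generation at which the count first hits zero; scenario summaries report
the suppressed count, rate, and mean ± SEM of the times. Allele
frequencies are tallied over the 2 × (queen count) allele slots of the
current queens and are undefined (recorded as missing, not zero) for an
extinct population. Parameter sweeps hold non-swept drive parameters at
their optimum (P_cut = 1, P_NHEJ = P_FR = P_HetMort = 0), except that
when exactly one of P_FR/P_NHEJ is swept alone its partner keeps the
default (0.01/0.02) — an optimal partner would nullify the swept
parameter. The life-history sensitivity scan varies one parameter at a
time and can attach a no-release control to flag demographically inviable
settings.

## Calibration and validation

The drive and life-history parameters above are fixed from the source
system; nothing was fitted. Where the yearly cycle admitted more than one
reading (fate of unmated gynes, the density-mortality denominator,
germline-resolution granularity), the alternatives were implemented as
switches and the defaults selected as the combination that reproduces the
reference 100-replicate suppression counts most closely; the losing
readings remain available (`unmated_queens="discard"`,
`regulate_density(..., n_cohort=None)`, `resolution="per_queen"`). With
the chosen defaults the model reproduces the qualitative reference
behaviour in full — hornet far more suppressible than paper wasp, female
releases far stronger than male releases, male-targeting drives unable to
spread, no partial suppression, polyandry amplifying and its removal
weakening the drive — while the female-release suppression counts run
some 10–15 replicates per hundred above the reference values, with
suppression times clustered toward the end of the 25-generation horizon.
The residual is insensitive to every structural alternative we could
derive from the documented model description and most likely reflects
unpublished details of the original mating-pool bookkeeping.

## Numerical and degenerate-case choices

Populations are int8 numpy arrays ((n, 2) queen genotypes, padded (n,
max_matings) mate matrices), making a hornet year (~10^5–10^6 offspring) a
handful of vectorized passes; a 100-replicate hornet scenario runs in
about a minute on one CPU. Truncated-Poisson sampling inverts the
renormalized cdf; an empty support (min > max) or zero-mass support (λ = 0
with zero truncation) is a parameter error. P_NHEJ > 0 with P_cut = 0 is
legal and inert. `logistic_mean` is clamped at zero and `N_prev = 0` is
extinction (no Poisson draw). Duplicate mates are repaired only from
unused slots; with an exhausted pool a duplicate is kept, which is
genetically a double sperm share. Fitness cost is applied exactly once per
individual, at the mating step; initial (already-mated) release queens are
exempt.

## What the simulations do and do not show

All results are in-silico properties of this life-cycle model under its
presets. Real populations add spatial structure, recolonisation,
mate choice, embryonic nuclease deposition and germline-timing effects —
all outside scope and each likely to *reduce* drive efficacy, so passing
scenarios here should be read as optimistic upper bounds rather than field
predictions.
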