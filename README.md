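# waspdrive

Individual-based, discrete-generation simulation of CRISPR homing gene
drives in invasive haplodiploid social wasps — the Asian hornet
(*Vespa velutina nigrithorax*) and the European paper wasp
(*Polistes dominula*).

Gene drives are being considered as a control tool for invasive social
insects, where nest destruction and trapping have proven expensive and
ineffective. Whether a drive can actually crash a wasp population depends
on an interplay of drive biochemistry (cutting, end-joining repair,
resistance-allele formation) and social-insect life history (huge colony
fecundity, brutal overwintering mortality, polyandrous queens, haploid
males). `waspdrive` models that interplay for researchers who want to
estimate suppression probabilities, allele-frequency trajectories, and the
sensitivity of both to drive and life-history parameters.

## The model

One simulated year, for a population of mated queens at carrying capacity
*K* (default 1000):

1. **Offspring.** Each successfully mated queen produces
   Poisson(*n*) daughters and Poisson(*n*) sons (*n* = 300 for the hornet,
   20 for the paper wasp). Drive dynamics act in the queen germline: in a
   drive carrier each wildtype (WT) allele sampled by a gamete is cut with
   probability P<sub>cut</sub>; a cut homes (converting to the drive, GD)
   unless non-homologous end-joining intervenes (P<sub>NHEJ</sub>), which
   yields a functional, uncuttable resistance allele (RE) with probability
   P<sub>FR</sub> and a non-functional allele (NF) otherwise. Daughters are
   diploid (egg + sperm from one of the queen's mates, brood divided
   randomly over mates); sons are haploid and drive-inactive.
2. **Mating.** Drive carriers of both sexes first pay an optional
   pre-mating fitness cost P<sub>HetMort</sub> (fully dominant). Queens
   demand a zero-and-max-truncated Poisson number of matings (hornet:
   λ = 3.275, max 4; wasp: λ = 0.2, max 2), males offer a max-truncated
   Poisson number of mating slots (λ = 0.9, max 3, zero allowed); the
   shuffled slot pool is dealt to females in random order. Gynes that find
   no mate remain in the population as non-reproducing foundresses.
3. **Winter.** Uniform queen mortality, blind to genotype (0.97 hornet,
   0.5 paper wasp).
4. **Spring cull and density regulation.** Queens that are infertile under
   the drive strategy (both target-gene copies disrupted — the gene is
   haplo-sufficient), or whose every mate is sterile, fail before founding
   a nest. The survivors then pass a logistic density filter: the target
   population is N<sub>t</sub> ~ Poisson(K / (1 + ((K − N<sub>t−1</sub>) /
   N<sub>t−1</sub>) / r<sub>max</sub>)) and each candidate survives with
   probability min(1, N<sub>t</sub> / cohort), the cohort being all
   overwintered foundresses competing for nest sites.

Four drive strategies are built in (neutral, female-, male-, and
both-sex-infertility) and two release routes: 100 heterozygous mated
queens at initialization, or 100 hemizygous males injected into the first
mating swarm. Suppression means the queen population hits zero within the
horizon (default 25 generations).

## A worked example

```python
from waspdrive import HORNET, SimConfig, run_scenario

config = SimConfig(species=HORNET, replicates=10, generations=25, seed=1)
summary = run_scenario(config)
```

prints, via `examples/run_suppression_scenario.py`:

```
replicates:        10
suppressed:        8
suppression rate:  0.80
times (years):     [15, 16, 16, 17, 17, 18, 22, 22]
mean time:         17.9 +/- 1.0 (SEM)
```

Eight of ten replicate hornet populations were extinct within 25 years of
a female-infertility drive release; in the other two a functional
resistance allele formed by rare end-joining repair and swept through the
population, rescuing it. The deterministic counterpart
(`examples/wildtype_allele_flow.py`) shows why failure is all-or-nothing:
even at the drive's frequency ceiling, surviving wildtype alleles
(40 × 2 × 300 × 0.03 = 720 from wildtype homozygotes plus
960 × 0.05 × 300 × 0.03 = 432 leaking through heterozygote germlines)
refill the carrying capacity every year, so population size is untouched
until the moment of collapse.

Other entry points: `examples/allele_trajectories.py` (per-generation
allele frequencies), `examples/polyandry_comparison.py` (mating-system
effects), `examples/drive_parameter_sweep.py` (efficiency heatmaps), and a
CLI:

```bash
waspdrive run --species hornet --strategy female_infertility \
    --release female --replicates 10 --seed 1 --out results/
waspdrive diagnose --n 40 --genotype wt_wt --offspring 300 --winter-mortality 0.97
```

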