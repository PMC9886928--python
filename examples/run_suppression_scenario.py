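"""Run a small Asian-hornet suppression scenario and summarise it.

Releases 100 heterozygous drive queens into an established population of
1000 mated hornet queens and runs 10 replicate 25-year simulations of a
female-infertility homing drive at current-technology efficiencies
(cutting 0.95, end-joining 0.02, functional repair 0.01).
"""

from waspdrive import HORNET, SimConfig, run_scenario

config = SimConfig(species=HORNET, replicates=10, generations=25, seed=1)
summary = run_scenario(config)

print(f"replicates:        {summary.n_replicates}")
print(f"suppressed:        {summary.n_suppressed}")
print(f"suppression rate:  {summary.suppression_rate:.2f}")
print(f"times (years):     {sorted(summary.times_to_suppression)}")
if summary.mean_time_to_suppression is not None:
    print(f"mean time:         {summary.mean_time_to_suppression:.1f} "
          f"+/- {summary.sem_time_to_suppression:.1f} (SEM)")

# The suppression rate is the fraction of replicate populations driven to
# zero queens within the horizon; in the remaining replicates a functional
# resistance allele usually forms and rescues the population.
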