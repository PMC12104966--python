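"""Traveling-window effective-inbreeding trajectory under three scenarios.

Generates a synthetic founder-bottleneck population reinforced with outbred
immigrants, then slides a 40-individual window through the genotype series
under each reinforcement scenario and projects fitness via the
lethal-equivalents transform (2B = 12).
"""

from lynxmon import popgen, synthdata

config = synthdata.SimConfig(seed=7)
table, truth = synthdata.simulate_drift_population(config.drift, config.rng("drift"))
print(f"{len(table)} genotyped individuals, {table.n_loci} microsatellite loci\n")

for scenario in ("remnant_only", "dinaric_reinforcement", "fully_connected"):
    series = popgen.scenario_series(table, scenario, h_reference=0.592)
    final = series.frame.iloc[-1]
    print(
        f"{scenario:>22}: final-window Fe = {final['fe']:+.3f}, "
        f"delta = {final['delta']:.2f}, relative fitness = {final['fitness']:.2f}"
    )

print(
    "\nFe is heterozygosity loss relative to the source population (0.592);"
    "\ndelta is the expected inbreeding depression at 12 diploid lethal"
    "\nequivalents, and fitness = 1 - delta. The more connected the scenario,"
    "\nthe lower the final-window Fe."
)
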