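"""Differential region calling between two conditions.

Generates a two-condition methylome whose AD-like condition carries
planted hyper-5mC and hypo-5hmC regions, simulates two replicates per
condition for each assay, tests every CpG site (two-proportion test,
coverage >= 5 in both groups) and segments regions under the stated
criteria: >= 10 CpGs, |mean difference| >= 0.1, inter-CpG gaps < 300 bp,
Mann-Whitney U p < 0.001.
"""

import numpy as np

from duomod import differential as dd
from duomod import simulate as sim

scenario = sim.SimulationScenario(seed=3, genome_length=250_000, n_genes=50,
                                  h_body_multiplier=1.0, n_hyper_m=4,
                                  n_hypo_h=4)
truth = sim.generate_scenario(scenario)
rng = np.random.default_rng(30)

for assay, proto in (("5mC", "CD"), ("5hmC", "ACE")):
    piles = {}
    for cond in ("WT", "AD"):
        piles[cond] = [
            sim.simulate_pileups(
                truth.genome,
                sim.jitter_methylome(truth.methylomes[cond], truth.genes,
                                     scenario.rep_jitter_sd,
                                     np.random.default_rng(int(rng.integers(2**31)))),
                proto, depth=30, seed=int(rng.integers(2**31)))
            for _ in range(2)]
    diffs = dd.test_dmc(piles)
    regions = dd.call_regions(diffs)
    counts = dd.classify_direction(regions).set_index("direction")["n"]
    print(f"\n{assay} ({proto}-seq): {int(diffs['significant'].sum())} "
          f"differential CpGs, {len(regions)} regions "
          f"({counts['hyper']} hyper, {counts['hypo']} hypo)")
    print(regions.to_string(index=False))

print("\nPlanted truth:")
print(truth.planted.to_string(index=False))
print("\nHyper regions (gained in AD) should match the planted hyper-5mC "
      "windows and\nhypo regions the planted hypo-5hmC windows, each "
      "within a few CpGs of the\ntrue boundaries.")
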