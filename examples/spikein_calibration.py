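"""Spike-in calibration of assay false-positive and conversion rates.

Simulates a CD-seq and a TAB-seq library at 200x over a small genome
carrying the two spike-in controls (fully methylated lambda-like contig,
fully hydroxymethylated 480-bp construct), then estimates each assay's
rates exactly as the caller would on real data.
"""

from duomod import calling
from duomod import simulate as sim

scenario = sim.SimulationScenario(seed=1, genome_length=40_000, n_genes=8,
                                  n_hyper_m=2, n_hypo_h=2)
truth = sim.generate_scenario(scenario)

for proto in ("CD", "TAB", "ACE"):
    pil = sim.simulate_pileups(truth.genome, truth.methylomes["WT"], proto,
                               depth=200, seed=10 + len(proto))
    cal = calling.calibrate(pil, proto)
    print(f"{proto}-seq: false-positive rate {cal.false_positive_rate:.4f} "
          f"(pooled over {cal.n_fp} spike-in bases), "
          f"conversion {cal.conversion_rate * 100:.1f}%, "
          f"target-mark retention {cal.retention * 100:.1f}%")

print("\nThe false-positive rate is the binomial null used for site "
      "calling; conversion\nis its complement; retention is the fraction "
      "of the assay's target mark still\nread as C (CD-seq: 5mC; "
      "TAB/ACE-seq: 5hmC).")
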