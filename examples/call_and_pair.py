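"""Subtraction-free paired calling of 5mC and 5hmC.

Simulates a CD-seq (5mC) and an ACE-seq (5hmC) library from the same
synthetic methylome, calibrates each on its spike-ins, calls modified
sites with the binomial test + BH correction (q <= 0.05, coverage >= 5),
and joins the two call sets into one per-site table carrying both marks.
"""

from duomod import calling, pairing
from duomod import simulate as sim

scenario = sim.SimulationScenario(seed=5, genome_length=120_000, n_genes=24,
                                  n_hyper_m=3, n_hypo_h=3)
truth = sim.generate_scenario(scenario)

calls = {}
for assay, proto in (("5mC", "CD"), ("5hmC", "ACE")):
    pil = sim.simulate_pileups(truth.genome, truth.methylomes["WT"], proto,
                               depth=30, seed=50 + len(proto))
    cal = calling.calibrate(pil, proto)
    calls[assay] = calling.call_sites(pil, cal)
    n = int(calls[assay]["called"].sum())
    print(f"{proto}-seq: p-hat {cal.false_positive_rate:.4f}; "
          f"{n} of {len(calls[assay])} tested sites called {assay}")

paired = pairing.pair_sites(calls["5mC"], calls["5hmC"])
cpg = paired.paired[paired.paired["context"] == "CpG"]
print(f"\n{len(paired.paired)} paired sites "
      f"({len(paired.only_m)} 5mC-only, {len(paired.only_h)} 5hmC-only)")
print(f"mean CpG levels: 5mC {cpg['level_5mC'].mean():.3f}, "
      f"5hmC {cpg['level_5hmC'].mean():.3f}")
print("Each paired row carries independent per-mark levels from two "
      "libraries — no\nBS-minus-5hmC subtraction is ever computed.")
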