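# duomod — subtraction-free dual analysis of 5mC and 5hmC

`duomod` is a Python toolkit for base-resolution DNA-modification
analysis built around *paired direct-readout chemistries*: a 5mC-direct
assay (CD-seq or CT-seq, in which the enzyme CMD1 glycerylates 5mC to
deaminase/bisulfite-resistant 5gmC) run alongside a 5hmC-direct assay
(ACE-seq or TAB-seq, in which βGT-glucosylation protects 5hmC).  Because
each mark is read out independently, the classical estimate

m̂ = (BS-seq level) − (5hmC level)

is never needed — a difference of two noisy binomial fractions that, at
finite depth, is badly behaved at low-5mC/high-5hmC sites and routinely
goes *negative*.  `duomod` models the conversion chemistries, simulates
realistic two-condition methylomes with spike-in controls, calls
modified cytosines with a spike-in-calibrated binomial test, and runs
the downstream differential and association analyses.

## What is in the box

| layer | module | what it does |
|---|---|---|
| chemistry | `duomod.chemistry` | each assay as ordered enzymatic steps with per-substrate efficiencies; closed-form P(read C \| state) |
| simulation | `duomod.simulate` | seeded genome/gene models, bimodal CpG methylome, gene-body 5hmC, spike-ins (incl. the 480-bp fully-hydroxymethylated construct), Poisson–binomial pileups, coupled NB expression |
| calling | `duomod.calling` | spike-in calibration (pooled rates); one-sided binomial test vs. p̂; BH FDR; coverage ≥ 5 filter |
| pairing | `duomod.pairing` | 5mC/5hmC site join, CpG/CHG/CHH context, promoter/gene-body annotation (TSS ± 1 kb), subtraction comparison |
| differential | `duomod.differential` | DMC/DhMC site tests; DMR/DhMR segmentation (≥ 10 CpGs, \|Δ\| ≥ 0.1, gaps < 300 bp, MWU p < 0.001); hyper/hypo classes; gene mapping |
| expression | `duomod.expression` | differential expression (p < 0.05, \|log2FC\| > 0.58); per-gene modification–expression correlation; DMG/DhMG/DEG overlap |
| pipeline | `duomod.pipeline`, `duomod.cli` | end-to-end orchestration with a SHA-256 run manifest; thin `duomod` CLI |

## The statistical core

At a site with coverage *n* and converted-read C-count *k*, the caller
tests

p-value = P[X ≥ k],  X ~ Binomial(n, p̂)

where p̂ is the assay's **false-positive rate measured from its
spike-in**: the pooled C-fraction of the control whose modification
should read T (the fully hydroxymethylated 480-bp construct for CD/CT;
the fully methylated lambda-like control for ACE/TAB).  Sites with
coverage < 5 are excluded before testing; Benjamini–Hochberg adjustment
is applied jointly and a site is called modified at q ≤ 0.05.

## Worked example

```bash
python examples/spikein_calibration.py
```

prints (seeded, so exactly reproducible):

```
CD-seq: false-positive rate 0.0311 (pooled over 35081 spike-in bases), conversion 96.9%, target-mark retention 93.0%
TAB-seq: false-positive rate 0.0208 (pooled over 451675 spike-in bases), conversion 97.9%, target-mark retention 95.0%
ACE-seq: false-positive rate 0.0059 (pooled over 451675 spike-in bases), conversion 99.4%, target-mark retention 97.9%
```

CD-seq deaminates ~97% of the hydroxymethylated spike-in (so 5hmC reads
T) while retaining ~93% of the methylated spike-in as C — the two rates
that make direct 5mC readout work.  The other example scripts each
demonstrate one capability:

* `examples/chemistry_truth_tables.py` — ideal vs. calibrated readout of all five chemistries
* `examples/call_and_pair.py` — calibrate → call → pair on one synthetic methylome
* `examples/subtraction_artifact.py` — 38% negative "5mC" estimates at depth 10 under subtraction; 0% under direct readout
* `examples/differential_regions.py` — DMR/DhMR recovery against planted truth
* `examples/expression_correlation.py` — positive 5hmC / negative 5mC correlation-sign recovery and the DEG overlap report
* `examples/full_pipeline.py` — one-call end-to-end run with manifest

The same stages are scriptable from a shell via the thin CLI
(`duomod simulate|chem|calibrate|call|pair|diff|associate|run`).

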