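# Methods

## Conversion-chemistry model

Each assay is modelled as an ordered list of enzymatic steps applied
independently to each sequenced molecule, followed by a C/T readout.  A
step is a map `substrate state -> (product state, efficiency)`; states
not listed pass through unchanged.  The state set is closed:
{C, 5mC, 5hmC, 5gmC, 5fC, 5caC, 5ghmC} plus one terminal
"deaminated/converted, reads T" state.  5fC and 5caC are collapsed into a
single oxidised state because no supported chemistry reads them out
separately — they exist only as way-stations to a T readout.  The
probability that a state is sequenced as C is computed in closed form by
propagating a distribution over states through the steps (no sampling);
a Monte-Carlo trajectory sampler exists only as a test oracle.

The five built-in protocols:

| protocol | steps | reads C |
|---|---|---|
| BS  | bisulfite | 5mC and 5hmC (confounded) |
| TAB | βGT → TET → bisulfite | 5hmC |
| ACE | βGT → deaminase | 5hmC |
| CD  | CMD1 → deaminase | 5mC |
| CT  | CMD1 → TET → bisulfite | 5mC |

Model assumptions: steps are conditionally independent per molecule;
there is no within-molecule correlation between neighbouring cytosines
(consistent with the per-site binomial caller downstream); chemistry is
strand-symmetric.  Sequencing error is a separate symmetric C↔T flip
(default 0.001) applied by the read simulator after chemistry, since
achieved assay rates never separate sequencer noise from chemistry.

### Default efficiencies

Defaults live in `duomod/data/default_chemistry.yaml` and are calibrated
to the rates the assays achieve on spike-in controls rather than to
per-enzyme mechanistic constants: deaminase converts 97% of 5hmC in the
CD/ACE context; CMD1 protects 93% of 5mC (so CD-seq retention lands
above 92%); TET leaves 2% of 5mC unoxidised (TAB-seq's false-positive
source).  The split between CMD1 conversion efficiency and 5gmC
deamination resistance is not identifiable from pooled retention alone;
the defaults attribute the entire 5mC loss to CMD1 and give 5gmC full
resistance, with both knobs independently overridable.

## Synthetic study design

The generator emulates the two-condition (WT-like vs. AD-like) brain
methylome study the analysis layers target, at desk scale.  Defaults:
1 Mb genome, 200 non-overlapping genes, 30× depth, two replicates per
condition, 0.5% of each spike-in.

* **Genome.** Random sequence (42% GC) with CpG-enriched islands at
  promoters (TSS ± 1 kb, strand-aware).  Two extra contigs carry the
  spike-ins: the 480-bp fully hydroxymethylated PCR construct
  (sequence fixed, every cytosine h = 1) and a 5-kb lambda-like control
  methylated at every cytosine (m = 1 in all contexts — real M.SssI is
  CpG-specific, but only the pooled readout of this contig is ever
  used, so the simplification is inconsequential and noted here).
* **Methylome.** Per cytosine, 5mC level m and 5hmC level h with
  m + h ≤ 1 enforced.  CpG methylation is bimodal: Beta(0.6, 6) in
  promoters (mean ≈ 0.09), Beta(6, 1.5) elsewhere (mean ≈ 0.8).  5hmC
  is small and gene-body enriched: Beta(3, 22) in bodies (mean ≈ 0.12),
  Beta(1, 30) elsewhere.  Non-CpG modification is near zero
  (means ≈ 0.5–1%).  No public per-site distribution exists for
  hippocampal 5hmC, so these are field-plausible placeholders, not
  measured values.
* **Condition effect.** The AD-like condition multiplies gene-body h by
  0.5 (a genome-wide hydroxymethylation loss) and carries planted
  differential regions on a non-overlapping grid: hyper-5mC windows
  (both-condition baseline m = 0.30, AD + 0.30) and hypo-5hmC windows
  (baseline h = 0.40, AD − 0.30), 2 kb each, CpG sites only.  Planted
  effects are set as explicit levels, not increments, so the planted
  truth provably satisfies the region criteria.
* **Replicates.** Biological replicates receive gene-coherent jitter:
  one δm and one δh ~ N(0, 0.02) per gene per sample, applied to all
  sites of that gene's promoter/body and clipped back into the simplex.
  Spike-in and intergenic sites are never jittered, so calibration is
  unaffected.
* **Pileups.** Coverage ~ Poisson(depth) per site; C-count ~
  Binomial(coverage, p) with p the chemistry's expected read-C
  probability for the site's (m, h) mixture plus the sequencing-error
  flip.  Spike-in contigs use the same per-base depth times a
  configurable factor (default 1): deriving spike depth from the 0.5%
  mass fraction would be arbitrary at desk-scale genome sizes, so the
  mass fraction is recorded but not used for coverage.
* **Expression.** Per-gene counts are Gamma–Poisson (NB) with
  log2 mean = baseline(gene) + 12·(gene-body h) − 12·(gene-level m),
  evaluated on the per-sample (jittered) levels, so the coupling signs
  are recoverable from across-sample per-gene correlation.  The
  association cohort uses six samples per condition with gene-level
  jitter sd 0.04: per-gene correlation at two replicates is ill-posed,
  so the cohort is deliberately larger than the sequencing design, and
  the jitter is the biological variability that makes the correlation
  identifiable.

What the generator does **not** emulate: read-level artefacts (fragment
length, PCR duplicates, mapping bias), strand-asymmetric chemistry,
SNP/C-to-T confusion, overdispersed per-site methylation between
replicates beyond the gene-level jitter, and linked methylation of
neighbouring CpGs.  Passing tests therefore demonstrate correctness of
the statistical machinery under the stated forward model, not robustness
to alignment- or library-level artefacts of real data.

## Calibration and calling

The false-positive rate p̂ of an assay is the pooled C-fraction over the
spike-in whose modification should read T (CD/CT: the hydroxymethylated
construct; ACE/TAB: the methylated control); pooling across positions is
used rather than per-position averaging because positions are exchangeable
under the uniform spike-in state.  The conversion rate is 1 − p̂ and the
retention of the target mark is the pooled C-fraction of the other
spike-in.  A zero false-positive count is floored at 1/(pooled
coverage + 1) to keep the test proper, and flagged.

Calling is a one-sided upper-tail binomial test — modification can only
inflate the C-count above p̂, so the upper tail is the only direction
consistent with the estimand.  Sites under the coverage floor (default
5) are excluded *before* testing (not reported as negatives), BH is
applied jointly across all tested sites of one library (no per-chromosome
or per-context stratification), and `called` requires q ≤ α (default
0.05).  No correction of 5mC levels for residual 5hmC leakage is
applied: the leakage is part of p̂ by construction.

## Differential analysis

Site test: replicates are pooled per group (coverage ≥ 5 required in
both) and compared with a two-proportion z-test with continuity
correction.  This is a deliberate surrogate for a dispersion-shrinkage
count model, kept behind a single function so it can be swapped;
pooling discards between-replicate variance, which the gene-coherent
jitter keeps small at the default settings.  Significance is
conjunctive: p < 0.05 *and* |Δ| ≥ 0.1.

Region segmentation is a greedy seed-and-extend surrogate for recursive
binary segmentation.  Within runs of CpGs separated by < 300 bp, each
significant site seeds a region that extends while (a) at least 80% of
members share the seed's sign and (b) no two consecutive non-matching
sites are crossed; the region is then trimmed to its outermost
significant same-sign members and emitted only if it satisfies all four
criteria — ≥ 10 member CpGs, |mean Δ| ≥ 0.1, all gaps < 300 bp, and a
two-sided Mann–Whitney U p < 0.001 comparing member-site levels between
groups.  The "≥ 10 CpGs" criterion is interpreted as ten member CpGs
(not ten individually significant ones); region p-values are not
multiplicity-adjusted because the criterion is a raw threshold.  A
post-hoc validator recomputes all four criteria from member sites and
is run over every emitted region in the test suite.  Both strands'
CpGs enter segmentation merged by position; a symmetric strand merge
before testing is available but not the default, since the
strand-collapsing convention is a free choice.

## Expression association

Differential expression uses a per-gene Welch t-test on log2(CPM + 1)
(library-size normalised), flagged at p < 0.05 and |log2FC| > 0.58 —
threshold logic, not an NB shrinkage model, and swappable.  Per-gene
modification–expression correlation is Pearson across samples, per
feature (promoter / gene body) and per mark, requiring ≥ 5 informative
CpGs and nonzero variance; an across-gene mode is available by flag.

One compositional caveat established during design: a *genome-wide*
gene-body 5hmC reduction shifts every gene's expression through the
coupling, and library-size normalisation absorbs exactly that common
shift — so genes with below-average 5hmC can have their apparent
correlation sign flipped.  The sign-recovery experiments therefore run
with the global multiplier disabled (planted regions and per-sample
jitter only), which isolates the per-gene coupling that correlation can
actually identify; with the global shift enabled the majority signs
still recover, just with a smaller margin.

## Numerical and I/O conventions

Coordinates are 0-based half-open everywhere (BED convention).  Contexts
are strand-aware trinucleotides (CpG/CHG/CHH), NA within two bases of a
contig end.  Overlapping promoter and gene-body annotations resolve to
promoter.  All randomness flows through `numpy.random.default_rng` from
a single integer seed; pipeline stages draw deterministic child seeds,
and identical configs reproduce byte-identical outputs (verified by
SHA-256 in the run manifest).  MWU p-values on constant inputs return 1.
Degenerate inputs (p̂ ∈ {0, 1}, zero spike-in coverage, zero library
size, unsorted site tables, m + h > 1) raise informative errors rather
than propagating NaNs.

## Problem sizes

The shipped configurations are desk-scale by design: 1 Mb genome / 200
genes / 30× / 2 + 2 replicates for the end-to-end demo; 250 kb genomes
for region-recovery experiments; 600 kb (≈ 50k CpG cytosines per strand
pair) for the null false-discovery checks; spike-in calibration at
150–250×.  These sizes give the statistical checks comfortable power
while keeping any single experiment under a few minutes on one core.

## Known limitations

* The two-proportion site test ignores between-replicate overdispersion;
  with strongly variable replicates it would be anti-conservative.
* Greedy segmentation is not guaranteed to find the optimal partition a
  recursive segmentation would; the acceptance surface is the stated
  output criteria, not any particular segmentation algorithm.
* Per-gene correlations at small cohort sizes are noisy; the default
  six-per-condition cohort is a deliberate deviation from two-replicate
  sequencing designs.
* Calibration assumes spike-ins experience the same chemistry as the
  genome; real libraries can violate this (fragment-size effects,
  denaturation differences), which only real controls can reveal.
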