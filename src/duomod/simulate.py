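"""Seeded synthetic genome / methylome / pileup / expression generator.

The generator emulates the study design the analysis layers expect:

* a random genome with CpG-island promoters and non-overlapping gene
  models (promoter = TSS +/- 1 kb, strand aware);
* a per-site methylome per condition with bimodal CpG methylation
  (hypomethylated promoters, hypermethylated elsewhere), small gene-body
  enriched 5hmC, and near-zero non-CpG modification, under the hard
  constraint m + h <= 1 per site;
* an "AD-like" condition carrying a genome-wide gene-body 5hmC reduction
  plus sparse planted differential regions (hyper-5mC and hypo-5hmC);
* the two spike-in controls carried through every library: a fully
  methylated lambda-like contig and the 480-bp fully hydroxymethylated
  PCR construct (sequence reproduced verbatim);
* assay-converted per-site pileups: coverage ~ Poisson(depth), C-count ~
  Binomial(coverage, expected read-C probability under the chemistry,
  plus a symmetric sequencing-error flip);
* per-gene negative-binomial expression counts whose log2 mean is coupled
  positively to gene-body 5hmC and negatively to gene-level 5mC, with
  gene-coherent per-sample biological jitter so that across-sample
  modification-expression correlation is identifiable.

Everything is driven by one integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from duomod import chemistry
from duomod.chemistry import ChemistryConfig, CytosineState

__all__ = [
    "SPIKE_5HMC_NAME",
    "SPIKE_5MC_NAME",
    "SPIKE_5HMC_SEQ",
    "SimulationScenario",
    "SimulatedTruth",
    "generate_scenario",
    "enumerate_cytosines",
    "simulate_pileups",
    "jitter_methylome",
    "gene_level_table",
    "simulate_expression",
    "ExpressionSim",
]

#: Contig names used for the two spike-in controls.
SPIKE_5HMC_NAME = "spike_5hmC_480bp"
SPIKE_5MC_NAME = "spike_lambda_5mC"

#: The 480-bp fully hydroxymethylated spike-in construct (every cytosine
#: carries 5hmC after PCR with 5hm-dCTP).
SPIKE_5HMC_SEQ = (
    "GAATTCTTGCAGCACTAGTGCATCTATAAGTTATCTCAAATCAAGAAATCAGTCTAATGAGAATTTCA"
    "ATAACTTCAGCAATTTAAGCTGCATGCATCAGTGTCATCGTTATTTTTTTTTTGAGACGTAGTCATGC"
    "TCTGTTGCTGAGTCTGCAGTACAGTGACGAGATATCGACTCAGCACAACATCTGCATCACATGTTCAA"
    "GCGATTCTCATGCTTCAGCTTGCAGAGTAGCTGTCACTACAGACACTGAGCAGCATGCGTGACTAATT"
    "TTTGTATTTTTAGTAGAGAGTGCATTTCGTCATGTTGTACAGTCTAGTTTCAAACTCATGACTTCAGT"
    "TGATCTAACTGACACGATCTCAGAATTTACTGTCATTACAGTACTGTCACACAGTGACAGTCATTTTT"
    "CTTAATTTTTAAAAATATTAAAGTTTTATCTCATTCGTGTTGAAGCATATTCGTGATTTAAAAGTTGC"
    "AAAG"
)
assert len(SPIKE_5HMC_SEQ) == 480


@dataclass
class SimulationScenario:
    """All knobs of one synthetic study; defaults are the desk-scale study
    conditions (two replicates per condition, 30x depth, 0.5% spike-ins)."""

    seed: int = 0
    genome_length: int = 1_000_000
    n_genes: int = 200
    depth: float = 30.0
    n_replicates: int = 2
    # spike-ins
    spike_fraction: float = 0.005          # mass fraction, recorded for provenance
    spike_depth_factor: float = 1.0        # per-base depth multiplier on spike contigs
    lambda_length: int = 5_000
    # promoter definition
    promoter_halfwidth: int = 1_000
    # methylome distributions (Beta parameters)
    m_promoter_beta: tuple[float, float] = (0.6, 6.0)     # hypomethylated
    m_background_beta: tuple[float, float] = (6.0, 1.5)   # hypermethylated
    m_noncpg_beta: tuple[float, float] = (0.2, 40.0)      # near zero
    h_body_beta: tuple[float, float] = (3.0, 22.0)        # gene-body enriched
    h_background_beta: tuple[float, float] = (1.0, 30.0)
    h_noncpg_beta: tuple[float, float] = (0.2, 80.0)
    # AD-like condition effects
    h_body_multiplier: float = 0.5
    n_hyper_m: int = 8
    n_hypo_h: int = 8
    planted_size: int = 2_000
    hyper_m_base: float = 0.30
    hyper_m_effect: float = 0.30
    hypo_h_base: float = 0.40
    hypo_h_effect: float = 0.30
    # per-replicate gene-coherent biological jitter (levels, sd)
    rep_jitter_sd: float = 0.02
    # expression model; the association cohort carries larger gene-level
    # biological variability so across-sample correlation is identifiable
    n_expr_reps: int = 6
    assoc_jitter_sd: float = 0.04
    coupling_h: float = 12.0       # log2 units per unit gene-body 5hmC
    coupling_m: float = -12.0      # log2 units per unit gene-level 5mC
    expr_base_log2: float = 6.0
    expr_base_sd: float = 1.0
    expr_dispersion: float = 0.02  # NB dispersion alpha; size = 1/alpha

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("spike_fraction", "h_body_multiplier"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.genome_length < 20 * self.n_genes:
            raise ValueError("genome too short for the requested gene count")


@dataclass
class SimulatedTruth:
    """Ground truth of one generated scenario."""

    scenario: SimulationScenario
    genome: dict[str, str]
    genes: pd.DataFrame           # gene_id, contig, start, end, strand, tss
    methylomes: dict[str, pd.DataFrame]   # condition -> site table with m, h
    planted: pd.DataFrame         # contig, start, end, kind, wt_level, ad_level
    main_contig: str = "chr1"


# ---------------------------------------------------------------------------
# genome and gene models

def _synthesize_main_contig(rng: np.random.Generator, length: int,
                            islands: list[tuple[int, int]]) -> str:
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=[0.29, 0.21, 0.21, 0.29])
    for start, end in islands:
        start, end = max(start, 0), min(end, length)
        seq[start:end] = rng.choice(bases, size=end - start,
                                    p=[0.16, 0.34, 0.34, 0.16])
    return "".join(seq)


def _place_genes(rng: np.random.Generator, scenario: SimulationScenario
                 ) -> pd.DataFrame:
    slot = scenario.genome_length // scenario.n_genes
    rows = []
    for i in range(scenario.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        max_len = max(int(slot * 0.7), 1200)
        length = int(rng.integers(min(1200, max_len), max_len + 1))
        lo = i * slot + 200
        hi = min((i + 1) * slot, scenario.genome_length) - length - 200
        start = int(rng.integers(lo, max(hi, lo + 1)))
        end = start + length
        tss = start if strand == "+" else end
        rows.append((f"g{i:04d}", "chr1", start, end, strand, tss))
    return pd.DataFrame(rows, columns=["gene_id", "contig", "start", "end",
                                       "strand", "tss"])


def feature_arrays(genes: pd.DataFrame, length: int, promoter_halfwidth: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-base feature code (0 intergenic, 1 gene body, 2 promoter; promoter
    wins overlaps) and gene index (-1 where intergenic)."""
    code = np.zeros(length, dtype=np.int8)
    gidx = np.full(length, -1, dtype=np.int32)
    for i, row in enumerate(genes.itertuples(index=False)):
        code[row.start:row.end] = 1
        gidx[row.start:row.end] = i
    for i, row in enumerate(genes.itertuples(index=False)):
        p0 = max(row.tss - promoter_halfwidth, 0)
        p1 = min(row.tss + promoter_halfwidth, length)
        code[p0:p1] = 2
        gidx[p0:p1] = i
    return code, gidx


# ---------------------------------------------------------------------------
# cytosine enumeration

_FEATURE_LABELS = np.array(["intergenic", "gene_body", "promoter"])


def enumerate_cytosines(seq: str, contig: str) -> pd.DataFrame:
    """All cytosines of both strands with trinucleotide context.

    Context is strand-aware: CpG if the next base (5'->3' on the site's
    strand) is G, else CHG if the base after that is G, else CHH; sites
    too close to the contig end for the lookahead are labelled NA.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n = len(arr)
    frames = []
    for strand, base in (("+", b"C"), ("-", b"G")):
        pos = np.flatnonzero(arr == base)
        ctx = np.full(pos.shape, "CHH", dtype=object)
        if strand == "+":
            nxt1 = np.where(pos + 1 < n, pos + 1, pos)
            nxt2 = np.where(pos + 2 < n, pos + 2, pos)
            is_cpg = (pos + 1 < n) & (arr[nxt1] == b"G")
            is_chg = (pos + 2 < n) & (arr[nxt2] == b"G") & ~is_cpg
            na = pos + 1 >= n
            na |= (pos + 2 >= n) & ~is_cpg
        else:
            prv1 = np.where(pos - 1 >= 0, pos - 1, pos)
            prv2 = np.where(pos - 2 >= 0, pos - 2, pos)
            is_cpg = (pos - 1 >= 0) & (arr[prv1] == b"C")
            is_chg = (pos - 2 >= 0) & (arr[prv2] == b"C") & ~is_cpg
            na = pos - 1 < 0
            na |= (pos - 2 < 0) & ~is_cpg
        ctx[is_chg] = "CHG"
        ctx[is_cpg] = "CpG"
        ctx[na] = "NA"
        frames.append(pd.DataFrame({"contig": contig, "pos": pos.astype(np.int64),
                                    "strand": strand, "context": ctx}))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="mergesort",
                           ignore_index=True)


# ---------------------------------------------------------------------------
# methylome

def _beta(rng, params, size):
    a, b = params
    return rng.beta(a, b, size=size)


def generate_scenario(scenario: SimulationScenario) -> SimulatedTruth:
    """Generate genome, gene models and the two condition methylomes."""
    rng = np.random.default_rng(scenario.seed)
    genes = _place_genes(rng, scenario)
    hw = scenario.promoter_halfwidth
    islands = [(t - hw, t + hw) for t in genes["tss"]]
    seq = _synthesize_main_contig(rng, scenario.genome_length, islands)

    bases = np.array(list("ACGT"))
    lam = "".join(rng.choice(bases, size=scenario.lambda_length,
                             p=[0.27, 0.23, 0.23, 0.27]))
    genome = {"chr1": seq, SPIKE_5MC_NAME: lam, SPIKE_5HMC_NAME: SPIKE_5HMC_SEQ}

    sites = enumerate_cytosines(seq, "chr1")
    if not (sites["context"] == "CpG").any():
        raise ValueError("degenerate genome: no CpG sites")
    code, gidx = feature_arrays(genes, scenario.genome_length, hw)
    sites["feature"] = _FEATURE_LABELS[code[sites["pos"].to_numpy()]]
    gi = gidx[sites["pos"].to_numpy()]
    gene_ids = genes["gene_id"].to_numpy()
    sites["gene_id"] = np.where(gi >= 0, gene_ids[np.maximum(gi, 0)], "")

    n = len(sites)
    cpg = (sites["context"] == "CpG").to_numpy()
    prom = (sites["feature"] == "promoter").to_numpy()
    body = (sites["feature"] == "gene_body").to_numpy()

    m = np.empty(n)
    m[cpg & prom] = _beta(rng, scenario.m_promoter_beta, (cpg & prom).sum())
    m[cpg & ~prom] = _beta(rng, scenario.m_background_beta, (cpg & ~prom).sum())
    m[~cpg] = _beta(rng, scenario.m_noncpg_beta, (~cpg).sum())

    h = np.empty(n)
    h[cpg & body] = _beta(rng, scenario.h_body_beta, (cpg & body).sum())
    h[cpg & ~body] = _beta(rng, scenario.h_background_beta, (cpg & ~body).sum())
    h[~cpg] = _beta(rng, scenario.h_noncpg_beta, (~cpg).sum())
    h = np.minimum(h, 1.0 - m)

    wt = sites.copy()
    wt["m"], wt["h"] = m, h

    ad = sites.copy()
    m_ad, h_ad = m.copy(), h.copy()
    h_ad[body] = h_ad[body] * scenario.h_body_multiplier

    # planted differential regions on a coarse grid (non-overlapping)
    size = scenario.planted_size
    n_plants = scenario.n_hyper_m + scenario.n_hypo_h
    planted_rows = []
    if n_plants > 0:
        grid = np.arange(2 * hw, scenario.genome_length - size - 2 * hw,
                         3 * size)
        if len(grid) < n_plants:
            raise ValueError("genome too short for the requested planted regions")
        starts = np.sort(rng.choice(grid, size=n_plants, replace=False))
        kinds = np.array(["hyper_m"] * scenario.n_hyper_m
                         + ["hypo_h"] * scenario.n_hypo_h)
        rng.shuffle(kinds)
        pos = sites["pos"].to_numpy()
        for start, kind in zip(starts, kinds):
            inside = cpg & (pos >= start) & (pos < start + size)
            if kind == "hyper_m":
                w_lvl = scenario.hyper_m_base
                a_lvl = scenario.hyper_m_base + scenario.hyper_m_effect
                m[inside] = w_lvl
                m_ad[inside] = a_lvl
                h[inside] = np.minimum(h[inside], 1.0 - w_lvl)
                h_ad[inside] = np.minimum(h_ad[inside], 1.0 - a_lvl)
            else:
                w_lvl = scenario.hypo_h_base
                a_lvl = max(scenario.hypo_h_base - scenario.hypo_h_effect, 0.0)
                m[inside] = np.minimum(m[inside], 0.5)
                m_ad[inside] = np.minimum(m_ad[inside], 0.5)
                h[inside] = w_lvl
                h_ad[inside] = a_lvl
            planted_rows.append(("chr1", int(start), int(start + size), kind,
                                 w_lvl, a_lvl))
    planted = pd.DataFrame(planted_rows, columns=["contig", "start", "end",
                                                  "kind", "wt_level", "ad_level"])

    wt["m"], wt["h"] = m, np.minimum(h, 1.0 - m)
    ad["m"], ad["h"] = m_ad, np.minimum(h_ad, 1.0 - m_ad)

    # spike-in sites with fixed uniform states
    spike_frames = []
    for name, (sm, sh) in ((SPIKE_5MC_NAME, (1.0, 0.0)),
                           (SPIKE_5HMC_NAME, (0.0, 1.0))):
        sdf = enumerate_cytosines(genome[name], name)
        sdf["feature"] = "spikein"
        sdf["gene_id"] = ""
        sdf["m"], sdf["h"] = sm, sh
        spike_frames.append(sdf)

    methylomes = {}
    for cond, df in (("WT", wt), ("AD", ad)):
        methylomes[cond] = pd.concat([df] + [f.copy() for f in spike_frames],
                                     ignore_index=True)

    return SimulatedTruth(scenario=scenario, genome=genome, genes=genes,
                          methylomes=methylomes, planted=planted)


# ---------------------------------------------------------------------------
# pileups

def simulate_pileups(genome: Mapping[str, str], methylome: pd.DataFrame,
                     protocol, config: ChemistryConfig | None = None,
                     depth: float = 30.0, seed: int = 0,
                     spike_depth_factor: float = 1.0) -> pd.DataFrame:
    """Assay-converted per-site read counts for one library.

    Coverage is Poisson(depth) per site (spike-in contigs scaled by
    ``spike_depth_factor``); the C-count is Binomial(coverage, p) where p
    is the chemistry's expected read-C probability for the site's (m, h)
    mixture, perturbed by the symmetric sequencing-error flip.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if config is None:
        config = chemistry.default_config()
    proto = chemistry.get_protocol(protocol, config) \
        if isinstance(protocol, str) else protocol
    m = methylome["m"].to_numpy(dtype=float)
    h = methylome["h"].to_numpy(dtype=float)
    if np.any(m + h > 1.0 + 1e-9):
        raise ValueError("methylome violates m + h <= 1")
    p_m = chemistry.prob_read_C(CytosineState.MC, proto)
    p_h = chemistry.prob_read_C(CytosineState.HMC, proto)
    p_c = chemistry.prob_read_C(CytosineState.C, proto)
    p = m * p_m + h * p_h + (1.0 - m - h) * p_c
    eps = config.seq_error
    p = p * (1.0 - eps) + (1.0 - p) * eps

    rng = np.random.default_rng(seed)
    contig = methylome["contig"].to_numpy()
    is_spike = np.isin(contig, [SPIKE_5MC_NAME, SPIKE_5HMC_NAME])
    lam = np.where(is_spike, depth * spike_depth_factor, depth)
    cov = rng.poisson(lam)
    count_c = rng.binomial(cov, p)
    out = methylome[["contig", "pos", "strand", "context"]].copy()
    out["count_C"] = count_c
    out["count_T"] = cov - count_c
    return out


# ---------------------------------------------------------------------------
# per-sample biological jitter and expression

def jitter_methylome(methylome: pd.DataFrame, genes: pd.DataFrame,
                     sd: float, rng: np.random.Generator) -> pd.DataFrame:
    """Gene-coherent biological perturbation of one sample's methylome.

    Each gene receives one delta-m and one delta-h ~ N(0, sd) applied to
    every site in its promoter/body, then levels are clipped back into
    the simplex m, h >= 0, m + h <= 1.  Intergenic and spike-in sites are
    untouched, so calibration is never perturbed.
    """
    if sd <= 0:
        return methylome.copy()
    out = methylome.copy()
    n_genes = len(genes)
    dm = rng.normal(0.0, sd, size=n_genes)
    dh = rng.normal(0.0, sd, size=n_genes)
    gene_pos = {g: i for i, g in enumerate(genes["gene_id"])}
    gi = out["gene_id"].map(gene_pos).fillna(-1).astype(int).to_numpy()
    has_gene = gi >= 0
    m = out["m"].to_numpy(dtype=float)
    h = out["h"].to_numpy(dtype=float)
    m[has_gene] = np.clip(m[has_gene] + dm[gi[has_gene]], 0.0, 1.0)
    h[has_gene] = np.clip(h[has_gene] + dh[gi[has_gene]], 0.0, 1.0)
    h = np.minimum(h, 1.0 - m)
    out["m"], out["h"] = m, h
    return out


def gene_level_table(methylome: pd.DataFrame, genes: pd.DataFrame
                     ) -> pd.DataFrame:
    """Per-gene mean CpG modification levels by feature.

    Returns one row per gene with columns ``m_promoter, m_body, m_gene,
    h_promoter, h_body, h_gene`` (gene = promoter plus body pooled) and
    CpG counts.  Only CpG-context sites contribute.
    """
    cpg = methylome[(methylome["context"] == "CpG")
                    & (methylome["gene_id"] != "")]
    grouped = cpg.groupby(["gene_id", "feature"], observed=True)[["m", "h"]].mean()
    counts = cpg.groupby("gene_id", observed=True).size()
    pooled = cpg.groupby("gene_id", observed=True)[["m", "h"]].mean()
    out = pd.DataFrame(index=genes["gene_id"])
    for feat, suffix in (("promoter", "promoter"), ("gene_body", "body")):
        sub = grouped.xs(feat, level="feature") if feat in \
            grouped.index.get_level_values("feature") else pd.DataFrame()
        out[f"m_{suffix}"] = sub["m"] if len(sub) else np.nan
        out[f"h_{suffix}"] = sub["h"] if len(sub) else np.nan
    out["m_gene"] = pooled["m"]
    out["h_gene"] = pooled["h"]
    out["n_cpg"] = counts
    out["n_cpg"] = out["n_cpg"].fillna(0).astype(int)
    return out.reset_index()


@dataclass
class ExpressionSim:
    """Simulated expression cohort: counts plus the per-sample gene-level
    modification truth the counts were coupled to."""

    counts: pd.DataFrame          # genes x samples
    samples: pd.DataFrame         # sample, condition, replicate
    gene_levels: pd.DataFrame     # long: gene_id, sample, m_gene, h_body, ...


def simulate_expression(genes: pd.DataFrame,
                        methylomes: Mapping[str, pd.DataFrame],
                        scenario: SimulationScenario,
                        seed: int = 0,
                        n_reps: int | None = None,
                        coupling_h: float | None = None,
                        coupling_m: float | None = None,
                        planted_log2fc: Mapping[str, float] | None = None,
                        gene_levels_by_sample: pd.DataFrame | None = None
                        ) -> ExpressionSim:
    """Negative-binomial counts coupled to per-sample modification levels.

    log2 mean = gene baseline + coupling_h * (gene-body 5hmC)
    + coupling_m * (gene-level 5mC) [+ planted AD log2FC].  Per-sample
    levels are the condition truth plus gene-coherent jitter (or are
    supplied via ``gene_levels_by_sample``, long-form with columns
    gene_id, sample, condition, m_gene, h_body, m_promoter, h_promoter),
    so the configured coupling sign is recoverable from across-sample
    per-gene correlation.
    """
    rng = np.random.default_rng(seed)
    n_reps = scenario.n_expr_reps if n_reps is None else n_reps
    ch = scenario.coupling_h if coupling_h is None else coupling_h
    cm = scenario.coupling_m if coupling_m is None else coupling_m
    gene_ids = genes["gene_id"].to_numpy()
    base = rng.normal(scenario.expr_base_log2, scenario.expr_base_sd,
                      size=len(gene_ids))

    # assemble per-sample gene-level modification tables
    level_rows = []
    if gene_levels_by_sample is not None:
        for name, sub in gene_levels_by_sample.groupby("sample", sort=False):
            sub = sub.set_index("gene_id").reindex(gene_ids).reset_index()
            sub["sample"] = name
            level_rows.append(sub)
    else:
        cond_levels = {c: gene_level_table(mm, genes).set_index("gene_id")
                       for c, mm in methylomes.items()}
        for cond in methylomes:
            for rep in range(1, n_reps + 1):
                lv = cond_levels[cond]
                dm = rng.normal(0.0, scenario.assoc_jitter_sd, size=len(gene_ids))
                dh = rng.normal(0.0, scenario.assoc_jitter_sd, size=len(gene_ids))
                level_rows.append(pd.DataFrame({
                    "gene_id": gene_ids, "sample": f"{cond}_{rep}",
                    "condition": cond,
                    "m_gene": np.clip(lv["m_gene"].to_numpy() + dm, 0, 1),
                    "h_body": np.clip(lv["h_body"].to_numpy() + dh, 0, 1),
                    "m_promoter": np.clip(lv["m_promoter"].to_numpy() + dm, 0, 1),
                    "h_promoter": np.clip(lv["h_promoter"].to_numpy() + dh, 0, 1),
                }))

    sample_rows, count_cols = [], {}
    for lv in level_rows:
        name = lv["sample"].iloc[0]
        cond = lv["condition"].iloc[0]
        rep = len([s for s, c, _ in sample_rows if c == cond]) + 1
        sample_rows.append((name, cond, rep))
        m_gene = lv["m_gene"].to_numpy(dtype=float)
        h_body = lv["h_body"].to_numpy(dtype=float)
        log2mu = base + ch * np.nan_to_num(h_body) + cm * np.nan_to_num(m_gene)
        if planted_log2fc and cond == "AD":
            extra = pd.Series(planted_log2fc).reindex(gene_ids).fillna(0.0)
            log2mu = log2mu + extra.to_numpy()
        mu = np.exp2(np.clip(log2mu, 0.0, 25.0))
        size = 1.0 / scenario.expr_dispersion
        lam = rng.gamma(size, mu / size)
        count_cols[name] = rng.poisson(lam)

    counts = pd.DataFrame(count_cols, index=gene_ids)
    counts.index.name = "gene_id"
    samples = pd.DataFrame(sample_rows, columns=["sample", "condition",
                                                 "replicate"])
    return ExpressionSim(counts=counts, samples=samples,
                         gene_levels=pd.concat(level_rows, ignore_index=True))
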