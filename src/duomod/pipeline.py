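"""End-to-end orchestration: simulate -> calibrate -> call -> pair ->
differential -> association, with a reproducibility manifest.

A run is fully specified by one config mapping (YAML-able) whose
``seed`` drives every stage through deterministically derived child
seeds; rerunning the same config into a fresh directory reproduces
byte-identical outputs.  Any stage's inputs can be supplied externally
(real-data mode: pileup TSVs and a gene BED), in which case simulation
is skipped and the downstream schema is unchanged.

The manifest records the config snapshot, package version, SHA-256
digest and row count of every written file, and per-stage row
accounting, so filter losses (coverage floor, unjoined sites) are
auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import duomod
from duomod import calling, chemistry, differential, expression, io, pairing
from duomod import simulate as sim

__all__ = ["default_run_config", "run_pipeline", "measured_gene_levels"]

logger = logging.getLogger(__name__)


def default_run_config() -> dict:
    """The desk-scale demo: 1 Mb genome, 200 genes, 30x, 2+2 replicates."""
    return {
        "seed": 42,
        "scenario": {},            # overrides for SimulationScenario fields
        "protocols": {"m": "CD", "h": "ACE"},
        "chemistry": None,         # path to a chemistry YAML, or None
        "calling": {"alpha": 0.05, "min_coverage": 5},
        "association": {"min_cpg": 5},
        "inputs": None,            # real-data mode, see run_pipeline
    }


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def measured_gene_levels(pileup_m: pd.DataFrame, pileup_h: pd.DataFrame,
                         genes: pd.DataFrame, min_coverage: int = 5,
                         ) -> pd.DataFrame:
    """Per-gene mean CpG raw levels by feature, measured from two pileups.

    Returns one row per gene: m_promoter, m_gene (promoter+body pooled),
    h_promoter, h_body and the informative CpG count (minimum over the
    two assays).
    """
    out = pd.DataFrame(index=genes["gene_id"])
    for tag, pil in (("m", pileup_m), ("h", pileup_h)):
        df = pil[pil["context"] == "CpG"].copy()
        cov = df["count_C"] + df["count_T"]
        df = df[cov >= min_coverage]
        df["level"] = df["count_C"] / (df["count_C"] + df["count_T"])
        df = pairing.annotate_features(df, genes)
        df = df[df["gene_id"] != ""]
        per_feat = df.groupby(["gene_id", "feature"], observed=True)["level"].mean()
        pooled = df.groupby("gene_id", observed=True)["level"].mean()
        counts = df.groupby("gene_id", observed=True).size()
        if ("promoter" in per_feat.index.get_level_values("feature")):
            out[f"{tag}_promoter"] = per_feat.xs("promoter", level="feature")
        else:
            out[f"{tag}_promoter"] = np.nan
        if ("gene_body" in per_feat.index.get_level_values("feature")):
            out[f"{tag}_body"] = per_feat.xs("gene_body", level="feature")
        else:
            out[f"{tag}_body"] = np.nan
        out[f"{tag}_gene"] = pooled
        out[f"n_cpg_{tag}"] = counts
    out["n_cpg"] = out[["n_cpg_m", "n_cpg_h"]].min(axis=1).fillna(0).astype(int)
    return out.reset_index()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.files: dict[str, dict] = {}
        self.counts: dict[str, int] = {}

    def write(self, name: str, writer, df=None) -> Path:
        path = self.outdir / name
        writer(path)
        entry = {"sha256": _sha256(path)}
        if df is not None:
            entry["rows"] = int(len(df))
        self.files[name] = entry
        return path


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Execute all stages; returns the path to the run manifest.

    ``config`` may be a mapping or a YAML path; unknown scenario keys
    raise.  In real-data mode (``inputs`` set) the simulate stage is
    skipped: ``inputs`` must provide ``genes`` (BED6) and ``pileups``,
    a mapping {condition: {assay: [pileup TSV paths]}} whose spike-in
    contigs drive calibration.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = default_run_config()
    for key, value in config.items():
        if key not in cfg:
            raise ValueError(f"unknown config key {key!r}")
        cfg[key] = value

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = _Run(outdir)
    seed = int(cfg["seed"])
    chem = chemistry.ChemistryConfig.from_yaml(cfg["chemistry"]) \
        if cfg["chemistry"] else chemistry.default_config()
    call_cfg = calling.CallingConfig(**cfg["calling"])
    proto_m, proto_h = cfg["protocols"]["m"], cfg["protocols"]["h"]

    stage = "simulate"
    try:
        if cfg["inputs"] is None:
            scenario = sim.SimulationScenario(seed=seed, **cfg["scenario"])
            truth = sim.generate_scenario(scenario)
            genes = truth.genes
            run.write("genome.fa", lambda p: io.write_fasta(truth.genome, p))
            run.write("genes.bed", lambda p: io.write_genes_bed(genes, p), genes)
            run.write("planted_regions.tsv",
                      lambda p: io.write_table(truth.planted, p), truth.planted)
            seeds = iter(_child_seeds(seed, 4 * scenario.n_replicates
                                      + 4 * scenario.n_expr_reps + 16))
            pileups: dict[tuple[str, str, int], pd.DataFrame] = {}
            for cond in ("WT", "AD"):
                for rep in range(1, scenario.n_replicates + 1):
                    jm = sim.jitter_methylome(
                        truth.methylomes[cond], genes, scenario.rep_jitter_sd,
                        np.random.default_rng(next(seeds)))
                    for assay, proto in (("m", proto_m), ("h", proto_h)):
                        pil = sim.simulate_pileups(
                            truth.genome, jm, proto, chem,
                            depth=scenario.depth, seed=next(seeds),
                            spike_depth_factor=scenario.spike_depth_factor)
                        pileups[(assay, cond, rep)] = pil
                        run.write(f"pileup_{assay}_{cond}_{rep}.tsv",
                                  lambda p, d=pil: io.write_pileup(d, p), pil)
        else:
            scenario = sim.SimulationScenario(seed=seed, **cfg["scenario"])
            truth = None
            genes = io.read_genes_bed(cfg["inputs"]["genes"])
            pileups = {}
            for cond, by_assay in cfg["inputs"]["pileups"].items():
                for assay, paths in by_assay.items():
                    for rep, path in enumerate(paths, start=1):
                        pileups[(assay, cond, rep)] = io.read_pileup(path)
            seeds = iter(_child_seeds(seed, 64))

        stage = "calibrate"
        conditions = sorted({c for (_, c, _) in pileups})
        reps = sorted({r for (_, _, r) in pileups})
        cal_rows = []
        calibrations = {}
        for assay, proto in (("m", proto_m), ("h", proto_h)):
            pooled = pd.concat([pileups[(assay, c, r)]
                                for c in conditions for r in reps],
                               ignore_index=True)
            cal = calling.calibrate(pooled, proto)
            calibrations[assay] = cal
            cal_rows.append({"assay": assay, "protocol": proto,
                             "false_positive_rate": cal.false_positive_rate,
                             "conversion_rate": cal.conversion_rate,
                             "retention": cal.retention,
                             "n_fp": cal.n_fp, "n_target": cal.n_target})
        cal_df = pd.DataFrame(cal_rows)
        run.write("calibration.tsv", lambda p: io.write_table(cal_df, p), cal_df)

        stage = "call"
        calls = {}
        for assay in ("m", "h"):
            for cond in conditions:
                pooled = pd.concat([pileups[(assay, cond, r)] for r in reps],
                                   ignore_index=True)
                pooled = (pooled.groupby(["contig", "pos", "strand", "context"],
                                         observed=True, sort=False)
                          [["count_C", "count_T"]].sum().reset_index())
                res = calling.call_sites(pooled, calibrations[assay], call_cfg)
                calls[(assay, cond)] = res
                run.write(f"calls_{assay}_{cond}.tsv",
                          lambda p, d=res: io.write_table(d, p), res)
                run.write(f"levels_{assay}_{cond}.bedgraph",
                          lambda p, d=res: io.write_bedgraph(d, "raw_level", p),
                          res)
                run.counts[f"called_{assay}_{cond}"] = int(res["called"].sum())

        stage = "pair"
        summaries = []
        for cond in conditions:
            pr = pairing.pair_sites(calls[("m", cond)], calls[("h", cond)])
            run.write(f"paired_{cond}.tsv",
                      lambda p, d=pr.paired: io.write_table(d, p), pr.paired)
            run.counts[f"paired_{cond}"] = len(pr.paired)
            by_feat, _ = pairing.summarize_by_feature(pr.paired, genes)
            by_feat.insert(0, "condition", cond)
            summaries.append(by_feat)
        feat_df = pd.concat(summaries, ignore_index=True)
        run.write("feature_summary.tsv",
                  lambda p: io.write_table(feat_df, p), feat_df)

        stage = "differential"
        gene_sets = {}
        for assay, label in (("m", "dmr"), ("h", "dhmr")):
            by_group = {c: [pileups[(assay, c, r)] for r in reps]
                        for c in conditions}
            diffs = differential.test_dmc(
                by_group, min_coverage=call_cfg.min_coverage,
                groups=tuple(conditions[::-1]) if conditions[0] == "AD"
                else tuple(conditions))
            regions = differential.call_regions(diffs)
            run.write(f"sites_{label}.tsv",
                      lambda p, d=diffs: io.write_table(d, p), diffs)
            run.write(f"regions_{label}.tsv",
                      lambda p, d=regions: io.write_table(d, p), regions)
            run.counts[f"n_{label}"] = len(regions)
            gmap = differential.map_to_genes(regions, genes)
            gene_sets[label] = set(gmap.loc[gmap["flagged"], "gene_id"])
            if assay == "m":
                dmc_table = diffs
            else:
                dhmc_table = diffs
        classes = differential.intersect_classes(dmc_table, dhmc_table)
        class_counts = pd.DataFrame(
            [(k, len(v)) for k, v in classes.items()], columns=["class", "n"])
        run.write("site_classes.tsv",
                  lambda p: io.write_table(class_counts, p), class_counts)

        stage = "associate"
        if truth is not None:
            assoc_seeds = _child_seeds(seed + 1, 3 * 2 * scenario.n_expr_reps)
            it = iter(assoc_seeds)
            level_frames, measured_frames = [], []
            for cond in ("WT", "AD"):
                for rep in range(1, scenario.n_expr_reps + 1):
                    name = f"{cond}_{rep}"
                    jm = sim.jitter_methylome(
                        truth.methylomes[cond], genes, scenario.assoc_jitter_sd,
                        np.random.default_rng(next(it)))
                    lv = sim.gene_level_table(jm, genes)
                    lv["sample"], lv["condition"] = name, cond
                    level_frames.append(lv)
                    pm = sim.simulate_pileups(truth.genome, jm, proto_m, chem,
                                              depth=scenario.depth,
                                              seed=next(it))
                    ph = sim.simulate_pileups(truth.genome, jm, proto_h, chem,
                                              depth=scenario.depth,
                                              seed=next(it))
                    meas = measured_gene_levels(pm, ph, genes,
                                                call_cfg.min_coverage)
                    meas["sample"], meas["condition"] = name, cond
                    measured_frames.append(meas)
            gene_levels_truth = pd.concat(level_frames, ignore_index=True)
            expr = sim.simulate_expression(
                genes, truth.methylomes, scenario, seed=_child_seeds(seed, 1)[0],
                gene_levels_by_sample=gene_levels_truth)
            measured = pd.concat(measured_frames, ignore_index=True)
            counts_out = expr.counts.reset_index()
            run.write("expression_counts.tsv",
                      lambda p: io.write_table(counts_out, p), counts_out)
            de = expression.differential_expression(expr.counts, expr.samples)
            run.write("differential_expression.tsv",
                      lambda p: io.write_table(de, p), de)
            corr = expression.correlate(measured, expr.counts,
                                        min_cpg=cfg["association"]["min_cpg"])
            run.write("gene_correlations.tsv",
                      lambda p: io.write_table(corr, p), corr)
            signs = expression.sign_summary(corr)
            run.write("correlation_signs.tsv",
                      lambda p: io.write_table(signs, p), signs)
            deg = set(de.loc[de["deg"], "gene_id"])
            overlap = expression.overlap_report(gene_sets["dmr"],
                                                gene_sets["dhmr"], deg)
            run.write("gene_overlap.tsv",
                      lambda p: io.write_table(overlap, p), overlap)
        else:
            logger.info("associate: skipped (no expression inputs)")

    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "tool": "duomod",
        "version": duomod.__version__,
        "seed": seed,
        "config": {k: v for k, v in cfg.items()},
        "files": run.files,
        "stage_counts": run.counts,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest_path
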