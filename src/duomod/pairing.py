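"""Subtraction-free pairing of 5mC and 5hmC calls, and genomic annotation.

The point of running a 5mC-direct assay (CD/CT) alongside a 5hmC-direct
assay (ACE/TAB) is that per-site levels of the two marks come from
independent libraries and never need the classical "BS-seq level minus
5hmC level" subtraction, which at finite depth produces negative 5mC
estimates wherever 5hmC is high.  :func:`subtraction_estimate` implements
that legacy estimator purely for comparison reports.

Paired levels live in [0, 1] independently; nothing forces
level_5mC + level_5hmC <= 1 at finite coverage because the two numbers
are estimated from different read pools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from duomod.simulate import feature_arrays, _FEATURE_LABELS

__all__ = [
    "PairedResult",
    "pair_sites",
    "subtraction_estimate",
    "annotate_context",
    "annotate_features",
    "summarize_by_feature",
]

logger = logging.getLogger(__name__)

_SITE_KEY = ["contig", "pos", "strand"]


@dataclass
class PairedResult:
    """Inner join of a 5mC and a 5hmC call table plus the unmatched rows."""

    paired: pd.DataFrame
    only_m: pd.DataFrame
    only_h: pd.DataFrame


def pair_sites(calls_m: pd.DataFrame, calls_h: pd.DataFrame) -> PairedResult:
    """Join per-site 5mC and 5hmC calls on (contig, position, strand).

    Raises if the two tables share no contig names (a genome-build or
    naming mismatch); unmatched sites are returned in side tables and
    their counts logged.
    """
    contigs_m = set(calls_m["contig"].unique())
    contigs_h = set(calls_h["contig"].unique())
    if contigs_m and contigs_h and not (contigs_m & contigs_h):
        raise ValueError(
            "no shared contigs between the 5mC and 5hmC tables; "
            f"5mC has {sorted(contigs_m)}, 5hmC has {sorted(contigs_h)}")

    keep = _SITE_KEY + [c for c in ("context", "coverage", "raw_level",
                                    "p_value", "q_value", "called")
                        if c in calls_m.columns]
    m = calls_m[keep].rename(columns={
        "coverage": "coverage_m", "raw_level": "level_5mC",
        "p_value": "p_value_m", "q_value": "q_value_m", "called": "called_m"})
    keep_h = _SITE_KEY + [c for c in ("coverage", "raw_level", "p_value",
                                      "q_value", "called")
                          if c in calls_h.columns]
    h = calls_h[keep_h].rename(columns={
        "coverage": "coverage_h", "raw_level": "level_5hmC",
        "p_value": "p_value_h", "q_value": "q_value_h", "called": "called_h"})

    paired = m.merge(h, on=_SITE_KEY, how="inner")
    m_idx = pd.MultiIndex.from_frame(calls_m[_SITE_KEY])
    h_idx = pd.MultiIndex.from_frame(calls_h[_SITE_KEY])
    shared = m_idx.intersection(h_idx)
    only_m = calls_m.loc[~m_idx.isin(shared)].copy()
    only_h = calls_h.loc[~h_idx.isin(shared)].copy()
    logger.info("pair_sites: %d paired, %d 5mC-only, %d 5hmC-only",
                len(paired), len(only_m), len(only_h))
    paired = paired.sort_values(_SITE_KEY, kind="mergesort", ignore_index=True)
    return PairedResult(paired=paired, only_m=only_m, only_h=only_h)


def subtraction_estimate(bs_level, h_level):
    """Legacy 5mC estimate: BS-seq level minus 5hmC level.

    Explicitly signed — at finite depth the difference of two noisy
    fractions goes negative wherever true 5mC is low and 5hmC high,
    which is the artifact the paired direct assays remove.
    """
    return np.asarray(bs_level, dtype=float) - np.asarray(h_level, dtype=float)


def annotate_context(sites: pd.DataFrame, genome) -> pd.Series:
    """Strand-aware trinucleotide context (CpG / CHG / CHH / NA) of each site.

    Plus-strand C at i: CpG if base i+1 is G, else CHG if base i+2 is G,
    else CHH; minus-strand mirrored upstream.  Sites whose lookahead runs
    off the contig are labelled NA.
    """
    out = np.full(len(sites), "NA", dtype=object)
    for contig, idx in sites.groupby("contig").groups.items():
        seq = genome[contig]
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        n = len(arr)
        sub = sites.loc[idx]
        pos = sub["pos"].to_numpy()
        plus = (sub["strand"] == "+").to_numpy()
        ctx = np.full(len(sub), "NA", dtype=object)

        p = pos[plus]
        c = np.full(p.shape, "NA", dtype=object)
        ok1 = p + 1 < n
        is_cpg = np.zeros(p.shape, bool)
        is_cpg[ok1] = arr[p[ok1] + 1] == b"G"
        ok2 = p + 2 < n
        is_chg = np.zeros(p.shape, bool)
        is_chg[ok2] = (arr[p[ok2] + 2] == b"G")
        c[ok2 & ~is_cpg & ~is_chg] = "CHH"
        c[is_chg & ~is_cpg] = "CHG"
        c[is_cpg] = "CpG"
        ctx[plus] = c

        q = pos[~plus]
        c = np.full(q.shape, "NA", dtype=object)
        ok1 = q - 1 >= 0
        is_cpg = np.zeros(q.shape, bool)
        is_cpg[ok1] = arr[q[ok1] - 1] == b"C"
        ok2 = q - 2 >= 0
        is_chg = np.zeros(q.shape, bool)
        is_chg[ok2] = arr[q[ok2] - 2] == b"C"
        c[ok2 & ~is_cpg & ~is_chg] = "CHH"
        c[is_chg & ~is_cpg] = "CHG"
        c[is_cpg] = "CpG"
        ctx[~plus] = c

        out[sites.index.get_indexer(idx)] = ctx
    return pd.Series(out, index=sites.index, name="context")


def annotate_features(sites: pd.DataFrame, genes: pd.DataFrame,
                      contig_lengths: dict[str, int] | None = None,
                      promoter_halfwidth: int = 1000) -> pd.DataFrame:
    """Label each site promoter / gene_body / intergenic with its gene.

    Promoter = TSS +/- 1 kb strand-aware; a site inside both a promoter
    and a gene body is labelled promoter.
    """
    feature = np.full(len(sites), "intergenic", dtype=object)
    gene_id = np.full(len(sites), "", dtype=object)
    for contig, idx in sites.groupby("contig").groups.items():
        g = genes[genes["contig"] == contig]
        if g.empty:
            continue
        length = int(contig_lengths[contig]) if contig_lengths else \
            int(max(g["end"].max(), sites.loc[idx, "pos"].max() + 1)
                + promoter_halfwidth)
        code, gidx = feature_arrays(g.reset_index(drop=True), length,
                                    promoter_halfwidth)
        pos = sites.loc[idx, "pos"].to_numpy()
        loc = sites.index.get_indexer(idx)
        feature[loc] = _FEATURE_LABELS[code[pos]]
        ids = g["gene_id"].to_numpy()
        gi = gidx[pos]
        gene_id[loc] = np.where(gi >= 0, ids[np.maximum(gi, 0)], "")
    out = sites.copy()
    out["feature"] = feature
    out["gene_id"] = gene_id
    return out


def summarize_by_feature(paired: pd.DataFrame, genes: pd.DataFrame,
                         contig_lengths: dict[str, int] | None = None,
                         cpg_only: bool = True
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean paired levels per genomic feature and per gene.

    Returns ``(by_feature, by_gene)``: by_feature has one row per feature
    with mean level_5mC / level_5hmC over detected CpG sites (empty
    feature classes appear with NaN means and a warning); by_gene has
    per-gene per-feature means for the correlation layer.
    """
    df = annotate_features(paired, genes, contig_lengths)
    if cpg_only and "context" in df.columns:
        df = df[df["context"] == "CpG"]
    levels = [c for c in ("level_5mC", "level_5hmC") if c in df.columns]
    by_feature = (df.groupby("feature", observed=False)[levels]
                  .agg(["mean", "count"]))
    by_feature.columns = ["_".join(c) for c in by_feature.columns]
    by_feature = by_feature.reindex(["promoter", "gene_body", "intergenic"])
    empty = by_feature.filter(like="_count").fillna(0).sum(axis=1) == 0
    for feat in by_feature.index[empty]:
        logger.warning("summarize_by_feature: no sites in feature %r", feat)
    by_gene = (df[df["gene_id"] != ""]
               .groupby(["gene_id", "feature"], observed=True)[levels]
               .agg(["mean", "count"]))
    by_gene.columns = ["_".join(c) for c in by_gene.columns]
    return by_feature.reset_index(), by_gene.reset_index()
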