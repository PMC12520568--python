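"""Differential 5mC/5hmC analysis: sites (DMC/DhMC), regions (DMR/DhMR),
direction classification, class intersection and gene mapping.

Site test
    Replicates are pooled per group and compared with a two-proportion
    z-test with continuity correction (a deliberate, swappable surrogate
    for a dispersion-shrinkage count model).  A site is significant when
    p < 0.05 and the absolute mean-level difference is >= 0.1; both
    conditions are required.  Only sites with pooled coverage >= 5 in
    *both* groups are tested.

Region segmentation
    Greedy seed-and-extend over position-sorted CpG sites: each
    significant site seeds a candidate region that grows in both
    directions while consecutive member CpGs stay < 300 bp apart and at
    least 80% of members share the seed's sign of difference; the region
    is then trimmed to its outermost significant same-sign sites.  An
    emitted region must satisfy all four stated criteria: >= 10 member
    CpGs, |mean difference| >= 0.1, all gaps < 300 bp, and a
    Mann-Whitney U p-value < 0.001 comparing member-site levels between
    groups.  Region p-values are not multiplicity-adjusted (the
    criterion is a raw threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "RegionCriteria",
    "test_dmc",
    "two_proportion_test",
    "call_regions",
    "validate_regions",
    "classify_direction",
    "intersect_classes",
    "map_to_genes",
]

logger = logging.getLogger(__name__)

_SITE_KEY = ["contig", "pos", "strand"]


def two_proportion_test(x1, n1, x2, n2) -> np.ndarray:
    """Two-sided pooled two-proportion z-test with continuity correction.

    Vectorised; degenerate sites (pooled proportion 0 or 1) get p = 1.
    """
    x1, n1, x2, n2 = (np.asarray(a, dtype=float) for a in (x1, n1, x2, n2))
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pool * (1.0 - pool) * (1.0 / n1 + 1.0 / n2))
    cc = 0.5 * (1.0 / n1 + 1.0 / n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(p1 - p2) - cc) / se
    z = np.where(np.isfinite(z), np.maximum(z, 0.0), 0.0)
    return 2.0 * stats.norm.sf(z)


def _pool_group(pileups: list[pd.DataFrame]) -> pd.DataFrame:
    frames = [df[_SITE_KEY + ["context", "count_C", "count_T"]]
              for df in pileups]
    cat = pd.concat(frames, ignore_index=True)
    pooled = (cat.groupby(_SITE_KEY + ["context"], observed=True, sort=False)
              [["count_C", "count_T"]].sum().reset_index())
    return pooled


def test_dmc(pileups_by_group: dict[str, list[pd.DataFrame]],
             min_coverage: int = 5, alpha: float = 0.05,
             min_diff: float = 0.1,
             groups: tuple[str, str] = ("WT", "AD")) -> pd.DataFrame:
    """Per-site two-group test on pooled replicate counts.

    ``diff`` is mean(second group) - mean(first group), i.e. AD - WT with
    the default ordering.  Sites absent from a group, or below the
    coverage floor in either group, are excluded (counts logged).
    """
    ref, alt = groups
    a = _pool_group(pileups_by_group[ref])
    b = _pool_group(pileups_by_group[alt])
    merged = a.merge(b, on=_SITE_KEY + ["context"], how="inner",
                     suffixes=("_1", "_2"))
    n_unjoined = len(a) + len(b) - 2 * len(merged)
    if n_unjoined:
        logger.info("test_dmc: %d sites present in only one group", n_unjoined)
    n1 = merged["count_C_1"] + merged["count_T_1"]
    n2 = merged["count_C_2"] + merged["count_T_2"]
    keep = (n1 >= min_coverage) & (n2 >= min_coverage)
    logger.info("test_dmc: %d of %d joined sites pass coverage >= %d in both "
                "groups", int(keep.sum()), len(merged), min_coverage)
    merged = merged.loc[keep].copy()
    n1, n2 = n1[keep].to_numpy(float), n2[keep].to_numpy(float)
    x1 = merged["count_C_1"].to_numpy(float)
    x2 = merged["count_C_2"].to_numpy(float)
    merged[f"level_{ref}"] = x1 / n1
    merged[f"level_{alt}"] = x2 / n2
    merged["coverage_1"], merged["coverage_2"] = n1.astype(int), n2.astype(int)
    merged["diff"] = merged[f"level_{alt}"] - merged[f"level_{ref}"]
    merged["p_value"] = two_proportion_test(x1, n1, x2, n2)
    merged["significant"] = (merged["p_value"] < alpha) & \
        (merged["diff"].abs() >= min_diff)
    merged = merged.drop(columns=["count_C_1", "count_T_1",
                                  "count_C_2", "count_T_2"])
    merged = merged.rename(columns={f"level_{ref}": "level_ref",
                                    f"level_{alt}": "level_alt"})
    merged.attrs["groups"] = groups
    return merged.sort_values(["contig", "pos", "strand"], kind="mergesort",
                              ignore_index=True)


@dataclass(frozen=True)
class RegionCriteria:
    """The four region criteria plus the segmentation consistency rule."""

    min_cpg: int = 10
    min_mean_diff: float = 0.1
    max_gap: int = 300
    max_mwu_p: float = 1e-3
    min_consistency: float = 0.8


def _mwu(ref_levels: np.ndarray, alt_levels: np.ndarray) -> float:
    if len(ref_levels) < 2:
        return 1.0
    try:
        return float(stats.mannwhitneyu(ref_levels, alt_levels,
                                        alternative="two-sided").pvalue)
    except ValueError:   # all identical values
        return 1.0


def call_regions(site_diffs: pd.DataFrame,
                 criteria: RegionCriteria | None = None,
                 cpg_only: bool = True) -> pd.DataFrame:
    """Segment differential regions from a position-sorted site table.

    Input must come from :func:`test_dmc` (needs level_ref, level_alt,
    diff, p_value, significant) and be position-sorted per contig; an
    unsorted table raises.  Returns BED-like rows: contig, start, end
    (half-open, covering the member CpGs), n_cpg, mean_diff, mwu_p,
    direction.
    """
    criteria = criteria or RegionCriteria()
    df = site_diffs
    if cpg_only and "context" in df.columns:
        df = df[df["context"] == "CpG"]
    regions = []
    for contig, sub in df.groupby("contig", sort=True):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"site table not position-sorted on {contig}")
        diff = sub["diff"].to_numpy()
        sig = sub["significant"].to_numpy()
        lref = sub["level_ref"].to_numpy()
        lalt = sub["level_alt"].to_numpy()
        # split into blocks at inter-CpG gaps >= max_gap
        breaks = np.flatnonzero(np.diff(pos) >= criteria.max_gap) + 1
        for block in np.split(np.arange(len(pos)), breaks):
            regions.extend(
                _segment_block(contig, pos[block], diff[block], sig[block],
                               lref[block], lalt[block], criteria))
    out = pd.DataFrame(regions, columns=["contig", "start", "end", "n_cpg",
                                         "mean_diff", "mwu_p", "direction"])
    return out.sort_values(["contig", "start"], ignore_index=True)


def _segment_block(contig, pos, diff, sig, lref, lalt,
                   criteria: RegionCriteria) -> list[tuple]:
    """Greedy seed-and-extend within one gap-free block of CpGs."""
    n = len(pos)
    out = []
    consumed = 0  # first index not yet claimed by an emitted region
    i = 0
    while i < n:
        if not sig[i] or diff[i] == 0:
            i += 1
            continue
        s = np.sign(diff[i])
        match = (np.sign(diff) == s)
        # extend right: stop at two consecutive non-matching sites or when
        # overall consistency would fall below the floor
        lo = hi = i
        n_match = 1
        j = i + 1
        while j < n:
            if not match[j] and not match[j - 1] and j - 1 > i:
                break
            n_match2 = n_match + int(match[j])
            if n_match2 / (j - lo + 1) < criteria.min_consistency:
                break
            hi, n_match = j, n_match2
            j += 1
        # extend left symmetrically, not crossing an emitted region
        j = lo - 1
        while j >= consumed:
            if not match[j] and j + 1 <= hi and not match[j + 1] and j + 1 < i:
                break
            n_match2 = n_match + int(match[j])
            if n_match2 / (hi - j + 1) < criteria.min_consistency:
                break
            lo, n_match = j, n_match2
            j -= 1
        # trim to the outermost significant same-sign members
        core = np.flatnonzero(sig[lo:hi + 1] & match[lo:hi + 1]) + lo
        lo, hi = int(core.min()), int(core.max())
        members = np.arange(lo, hi + 1)
        mean_diff = float(diff[members].mean())
        ok = (len(members) >= criteria.min_cpg
              and abs(mean_diff) >= criteria.min_mean_diff
              and np.sign(mean_diff) == s)
        if ok:
            p = _mwu(lref[members], lalt[members])
            if p < criteria.max_mwu_p:
                out.append((contig, int(pos[lo]), int(pos[hi]) + 1,
                            len(members), mean_diff, p,
                            "hyper" if mean_diff > 0 else "hypo"))
                consumed = hi + 1
        i = hi + 1
    return out


def validate_regions(regions: pd.DataFrame, site_diffs: pd.DataFrame,
                     criteria: RegionCriteria | None = None,
                     cpg_only: bool = True) -> pd.DataFrame:
    """Recompute the four region criteria from member sites.

    Independent post-hoc check: for each region, members are the CpG
    sites inside [start, end); returns per-region booleans for each
    criterion plus direction consistency.
    """
    criteria = criteria or RegionCriteria()
    df = site_diffs
    if cpg_only and "context" in df.columns:
        df = df[df["context"] == "CpG"]
    rows = []
    for reg in regions.itertuples(index=False):
        sub = df[(df["contig"] == reg.contig) & (df["pos"] >= reg.start)
                 & (df["pos"] < reg.end)].sort_values("pos")
        gaps = np.diff(sub["pos"].to_numpy()) if len(sub) > 1 else np.array([0])
        mean_diff = float(sub["diff"].mean()) if len(sub) else np.nan
        mwu = _mwu(sub["level_ref"].to_numpy(), sub["level_alt"].to_numpy())
        rows.append({
            "contig": reg.contig, "start": reg.start, "end": reg.end,
            "ok_n_cpg": len(sub) >= criteria.min_cpg,
            "ok_mean_diff": abs(mean_diff) >= criteria.min_mean_diff,
            "ok_gap": bool(np.all(gaps < criteria.max_gap)),
            "ok_mwu": mwu < criteria.max_mwu_p,
            "ok_direction": (np.sign(mean_diff) > 0) == (reg.direction == "hyper"),
            "recomputed_mean_diff": mean_diff,
            "recomputed_mwu_p": mwu,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["ok_all"] = out[["ok_n_cpg", "ok_mean_diff", "ok_gap",
                             "ok_mwu", "ok_direction"]].all(axis=1)
    return out


def classify_direction(regions: pd.DataFrame) -> pd.DataFrame:
    """Hyper/hypo counts (hyper = level increased in the second group)."""
    counts = regions["direction"].value_counts()
    return pd.DataFrame({"direction": ["hyper", "hypo"],
                         "n": [int(counts.get("hyper", 0)),
                               int(counts.get("hypo", 0))]})


def intersect_classes(dmc: pd.DataFrame, dhmc: pd.DataFrame
                      ) -> dict[str, pd.DataFrame]:
    """Three-way classification of significant sites.

    Returns DMC-only, DhMC-only and the overlap class D(M/hM) as exact
    coordinate-set intersections of the *significant* sites.
    """
    a = dmc[dmc["significant"]][_SITE_KEY]
    b = dhmc[dhmc["significant"]][_SITE_KEY]
    both = a.merge(b, on=_SITE_KEY)
    a_idx = pd.MultiIndex.from_frame(a)
    b_idx = pd.MultiIndex.from_frame(b)
    shared = a_idx.intersection(b_idx)
    return {"dmc_only": a.loc[~a_idx.isin(shared)].reset_index(drop=True),
            "dhmc_only": b.loc[~b_idx.isin(shared)].reset_index(drop=True),
            "both": both.reset_index(drop=True)}


def map_to_genes(regions: pd.DataFrame, genes: pd.DataFrame,
                 promoter_halfwidth: int = 1000) -> pd.DataFrame:
    """Genes containing at least one region in promoter (+/- 1 kb) or body.

    Interval overlap between each region span and each gene's
    promoter-union-body extent; returns one row per gene with a boolean
    flag and the overlapping region count.
    """
    trees: dict[str, IntervalTree] = {}
    for reg in regions.itertuples(index=False):
        trees.setdefault(reg.contig, IntervalTree()).addi(
            reg.start, max(reg.end, reg.start + 1), None)
    rows = []
    for g in genes.itertuples(index=False):
        lo = min(g.start, g.tss - promoter_halfwidth)
        hi = max(g.end, g.tss + promoter_halfwidth)
        tree = trees.get(g.contig)
        n = len(tree.overlap(lo, hi)) if tree is not None else 0
        rows.append((g.gene_id, n > 0, n))
    return pd.DataFrame(rows, columns=["gene_id", "flagged", "n_regions"])
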