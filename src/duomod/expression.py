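"""Differential expression and modification-expression association.

Differential expression uses a per-gene Welch t-test on log2(CPM + 1)
with library-size normalisation — a deliberately simple, swappable
surrogate for a negative-binomial shrinkage model.  A gene is flagged
differentially expressed (DEG) when p < 0.05 and |log2FC| > 0.58
(i.e. fold change > 1.5); both gates are required.

Per-gene modification-expression correlation is computed across samples
(Pearson, on log2(CPM + 1)); genes need a minimum number of informative
CpGs and nonzero variance on both axes.  An across-gene mode (one
correlation over genes within each sample set) is available as a flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "differential_expression",
    "log2_cpm",
    "correlate",
    "sign_summary",
    "overlap_report",
]

logger = logging.getLogger(__name__)


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(counts-per-million + 1), columns = samples."""
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    return np.log2(counts.div(lib, axis=1) * 1e6 + 1.0)


def differential_expression(counts: pd.DataFrame, samples: pd.DataFrame,
                            groups: tuple[str, str] = ("WT", "AD"),
                            alpha: float = 0.05,
                            min_abs_lfc: float = 0.58) -> pd.DataFrame:
    """Per-gene two-sample test of the second group against the first.

    ``log2_fc`` is the difference of group means of log2(CPM + 1)
    (second minus first).  All-zero genes are excluded with a logged
    count.  Requires >= 2 replicates per group.
    """
    ref, alt = groups
    cols_ref = samples.loc[samples["condition"] == ref, "sample"].tolist()
    cols_alt = samples.loc[samples["condition"] == alt, "sample"].tolist()
    if len(cols_ref) < 2 or len(cols_alt) < 2:
        raise ValueError("need >= 2 replicates per group for the test")
    nonzero = counts[cols_ref + cols_alt].sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("differential_expression: dropped %d all-zero genes",
                    n_dropped)
    counts = counts.loc[nonzero]
    logcpm = log2_cpm(counts[cols_ref + cols_alt])
    a = logcpm[cols_ref].to_numpy()
    b = logcpm[cols_alt].to_numpy()
    lfc = b.mean(axis=1) - a.mean(axis=1)
    t = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isfinite(t.pvalue), t.pvalue, 1.0)
    out = pd.DataFrame({
        "gene_id": counts.index,
        "mean_ref": counts[cols_ref].mean(axis=1).to_numpy(),
        "mean_alt": counts[cols_alt].mean(axis=1).to_numpy(),
        "log2_fc": lfc,
        "p_value": p,
    })
    out["deg"] = (out["p_value"] < alpha) & (out["log2_fc"].abs() > min_abs_lfc)
    return out.reset_index(drop=True)


def correlate(gene_levels: pd.DataFrame, counts: pd.DataFrame,
              level_columns: dict[tuple[str, str], str] | None = None,
              min_cpg: int = 5, mode: str = "per_gene") -> pd.DataFrame:
    """Per-gene Pearson correlation between modification level and expression.

    ``gene_levels`` is long-form with columns gene_id, sample and one
    numeric column per (feature, assay) pair as declared in
    ``level_columns`` (default: promoter/body x m/h as produced by the
    simulator).  Expression is log2(CPM + 1).  Genes with fewer than
    ``min_cpg`` informative CpGs (column ``n_cpg`` when present) or zero
    variance on either axis are excluded (correlation NA).

    ``mode='per_gene'`` correlates across samples within each gene;
    ``mode='across_genes'`` returns one correlation per (feature, assay)
    computed over gene means.
    """
    if level_columns is None:
        level_columns = {("promoter", "m"): "m_promoter",
                         ("gene_body", "m"): "m_gene",
                         ("promoter", "h"): "h_promoter",
                         ("gene_body", "h"): "h_body"}
    logcpm = log2_cpm(counts)
    expr = logcpm.stack()
    expr.index.names = ["gene_id", "sample"]
    df = gene_levels.set_index(["gene_id", "sample"])
    df = df.join(expr.rename("expr"), how="inner")
    if "n_cpg" in df.columns:
        df = df[df["n_cpg"] >= min_cpg]

    rows = []
    if mode == "per_gene":
        for gene, sub in df.groupby(level="gene_id"):
            e = sub["expr"].to_numpy()
            for (feature, assay), col in level_columns.items():
                x = sub[col].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(e)
                if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(e[ok]) == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(x[ok], e[ok])[0, 1])
                rows.append((gene, feature, assay, r, int(ok.sum())))
        return pd.DataFrame(rows, columns=["gene_id", "feature", "assay",
                                           "correlation", "n_samples"])
    elif mode == "across_genes":
        gmeans = df.groupby(level="gene_id").mean(numeric_only=True)
        for (feature, assay), col in level_columns.items():
            x = gmeans[col].to_numpy(dtype=float)
            e = gmeans["expr"].to_numpy()
            ok = np.isfinite(x) & np.isfinite(e)
            r = float(np.corrcoef(x[ok], e[ok])[0, 1]) if ok.sum() >= 3 else np.nan
            rows.append((feature, assay, r, int(ok.sum())))
        return pd.DataFrame(rows, columns=["feature", "assay", "correlation",
                                           "n_genes"])
    raise ValueError(f"unknown mode {mode!r}")


def sign_summary(correlations: pd.DataFrame) -> pd.DataFrame:
    """Proportion of positive vs negative per-gene correlations per
    (feature, assay); NA correlations are excluded."""
    df = correlations.dropna(subset=["correlation"])
    out = []
    for (feature, assay), sub in df.groupby(["feature", "assay"]):
        n = len(sub)
        pos = int((sub["correlation"] > 0).sum())
        out.append((feature, assay, n, pos / n if n else np.nan,
                    (n - pos) / n if n else np.nan))
    return pd.DataFrame(out, columns=["feature", "assay", "n_genes",
                                      "frac_positive", "frac_negative"])


def overlap_report(dmg: set, dhmg: set, deg: set) -> pd.DataFrame:
    """All seven disjoint cells of the DMG / DhMG / DEG Venn diagram."""
    dmg, dhmg, deg = set(dmg), set(dhmg), set(deg)
    cells = {
        "dmg_only": dmg - dhmg - deg,
        "dhmg_only": dhmg - dmg - deg,
        "deg_only": deg - dmg - dhmg,
        "dmg_dhmg": (dmg & dhmg) - deg,
        "dmg_deg": (dmg & deg) - dhmg,
        "dhmg_deg": (dhmg & deg) - dmg,
        "all_three": dmg & dhmg & deg,
    }
    rows = [(k, len(v)) for k, v in cells.items()]
    rows.append(("union", len(dmg | dhmg | deg)))
    return pd.DataFrame(rows, columns=["cell", "n_genes"])
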