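"""Spike-in calibration and binomial calling of modified cytosines.

Calibration pools converted-read counts over the spike-in contigs: the
spike-in whose modification should read T under the assay yields the
false-positive rate p-hat (the binomial null), and the spike-in whose
modification should read C yields the retention of the target mark.  For
the 5mC assays (CD, CT) the false-positive source is the fully
hydroxymethylated construct; for the 5hmC assays (ACE, TAB) it is the
fully methylated lambda-like control.

Each genomic site with coverage n and C-count k is then tested one-sided
against Binomial(n, p-hat): p = P[X >= k].  Sites below the minimum
coverage are excluded before testing; Benjamini-Hochberg adjustment is
applied jointly across all tested sites, and a site is called modified
when q <= alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from duomod.simulate import SPIKE_5HMC_NAME, SPIKE_5MC_NAME

__all__ = [
    "CalibrationResult",
    "CallingConfig",
    "CalibrationError",
    "calibrate",
    "raw_level",
    "adjust_bh",
    "call_sites",
]

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    pass


#: Which spike-in contig reads T (false-positive source) and which reads C
#: (retention source) under each assay.
_SPIKE_ROLES = {
    "CD": (SPIKE_5HMC_NAME, SPIKE_5MC_NAME),
    "CT": (SPIKE_5HMC_NAME, SPIKE_5MC_NAME),
    "ACE": (SPIKE_5MC_NAME, SPIKE_5HMC_NAME),
    "TAB": (SPIKE_5MC_NAME, SPIKE_5HMC_NAME),
    "BS": (SPIKE_5HMC_NAME, SPIKE_5MC_NAME),  # 5hmC reads C under BS; roles
                                              # kept for API symmetry
}


@dataclass(frozen=True)
class CalibrationResult:
    """Pooled spike-in rates for one assay/library.

    ``false_positive_rate`` is the pooled C-fraction of the spike-in that
    should read T (the binomial null p-hat); ``conversion_rate`` is its
    complement (fraction of the should-convert mark actually read as T);
    ``retention`` is the pooled C-fraction of the spike-in carrying the
    assay's target mark.
    """

    protocol: str
    false_positive_rate: float
    conversion_rate: float
    retention: float
    n_fp: int          # pooled coverage on the false-positive spike-in
    n_target: int      # pooled coverage on the retention spike-in
    floored: bool = False


def _pooled_fraction(pileups: pd.DataFrame, contig: str,
                     protocol: str) -> tuple[float, int]:
    sub = pileups[pileups["contig"] == contig]
    total = int(sub["count_C"].sum() + sub["count_T"].sum())
    if total == 0:
        raise CalibrationError(
            f"spike-in contig {contig!r} has zero pooled coverage for "
            f"{protocol}; raise the simulated depth or check the input")
    return float(sub["count_C"].sum()) / total, total


def calibrate(pileups: pd.DataFrame, protocol: str,
              fp_contig: str | None = None,
              target_contig: str | None = None) -> CalibrationResult:
    """Estimate assay false-positive and conversion rates from spike-ins.

    Rates are exact pooled ratios over all spike-in positions (not
    per-position averages).  A zero false-positive count is floored at
    1 / (pooled coverage + 1) so the downstream binomial test stays
    proper; the flooring is logged and flagged on the result.
    """
    if protocol not in _SPIKE_ROLES:
        raise CalibrationError(f"unknown protocol {protocol!r}")
    default_fp, default_target = _SPIKE_ROLES[protocol]
    fp_contig = fp_contig or default_fp
    target_contig = target_contig or default_target

    p_hat, n_fp = _pooled_fraction(pileups, fp_contig, protocol)
    retention, n_target = _pooled_fraction(pileups, target_contig, protocol)
    floored = False
    if p_hat == 0.0:
        p_hat = 1.0 / (n_fp + 1)
        floored = True
        logger.warning("%s calibration: zero false-positive reads over %d "
                       "spike-in bases; flooring p-hat at %.3g",
                       protocol, n_fp, p_hat)
    return CalibrationResult(protocol=protocol, false_positive_rate=p_hat,
                             conversion_rate=1.0 - p_hat, retention=retention,
                             n_fp=n_fp, n_target=n_target, floored=floored)


def raw_level(count_C, count_T):
    """Raw modification signal: C / (C + T).  Zero-coverage rows are the
    caller's responsibility to exclude (they are undefined here)."""
    count_C = np.asarray(count_C, dtype=float)
    count_T = np.asarray(count_T, dtype=float)
    cov = count_C + count_T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = count_C / cov
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CallingConfig:
    """Thresholds for the binomial caller (one-sided upper tail)."""

    alpha: float = 0.05
    min_coverage: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha={self.alpha} outside (0, 1)")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, stable
    under input permutation)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_sites(pileups: pd.DataFrame, calibration: CalibrationResult | float,
               config: CallingConfig | None = None,
               exclude_spikes: bool = True) -> pd.DataFrame:
    """Binomial test of every sufficiently covered site against p-hat.

    Returns the tested sites (coverage >= min_coverage) sorted by
    coordinate, with ``raw_level``, one-sided ``p_value`` = P[X >= k]
    under Binomial(n, p-hat), joint BH ``q_value`` and the ``called``
    flag (q <= alpha).  Low-coverage sites are excluded before BH (their
    count is logged), not reported as negatives.
    """
    config = config or CallingConfig()
    p_hat = calibration.false_positive_rate \
        if isinstance(calibration, CalibrationResult) else float(calibration)
    if p_hat >= 1.0:
        raise CalibrationError("false-positive rate of 1 is uninformative; "
                               "check the spike-in assignment")
    if p_hat <= 0.0:
        raise CalibrationError("p-hat must be positive; calibrate() floors "
                               "zero rates")
    df = pileups
    if exclude_spikes:
        df = df[~df["contig"].isin([SPIKE_5HMC_NAME, SPIKE_5MC_NAME])]
    cov = df["count_C"].to_numpy() + df["count_T"].to_numpy()
    keep = cov >= config.min_coverage
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("call_sites: excluded %d sites below coverage %d",
                    n_dropped, config.min_coverage)
    out = df.loc[keep].copy()
    out = out.sort_values(["contig", "pos", "strand"], kind="mergesort",
                          ignore_index=True)
    n = out["count_C"].to_numpy() + out["count_T"].to_numpy()
    k = out["count_C"].to_numpy()
    out["coverage"] = n
    out["raw_level"] = k / n
    # P[X >= k] = sf(k - 1)
    out["p_value"] = stats.binom.sf(k - 1, n, p_hat)
    out["q_value"] = adjust_bh(out["p_value"].to_numpy())
    out["called"] = out["q_value"] <= config.alpha
    return out
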