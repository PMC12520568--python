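"""Spike-in calibration and the binomial caller: rate recovery, an exact
tail-sum oracle, BH behaviour, FDR control and order invariance."""

import math

import numpy as np
import pandas as pd
import pytest

from duomod import calling
from duomod import chemistry as ch
from duomod import simulate as sim


@pytest.fixture(scope="module")
def spike_pileups():
    sc = sim.SimulationScenario(seed=21, genome_length=40_000, n_genes=8,
                                n_hyper_m=2, n_hypo_h=2)
    truth = sim.generate_scenario(sc)
    cfg = ch.default_config()
    return {proto: sim.simulate_pileups(truth.genome, truth.methylomes["WT"],
                                        proto, cfg, depth=120, seed=22 + i)
            for i, proto in enumerate(("CD", "TAB"))}, cfg


def test_calibration_recovers_configured_rates(spike_pileups):
    piles, cfg = spike_pileups
    eps = cfg.seq_error
    # CD-seq: false positives come from the 5hmC construct (3% reads C)
    cal = calling.calibrate(piles["CD"], "CD")
    p = 0.03 * (1 - eps) + 0.97 * eps
    assert abs(cal.false_positive_rate - p) <= 3 * np.sqrt(p * (1 - p) / cal.n_fp)
    assert cal.conversion_rate == pytest.approx(1 - cal.false_positive_rate)
    r = 0.93035 * (1 - eps) + (1 - 0.93035) * eps
    assert abs(cal.retention - r) <= 3 * np.sqrt(r * (1 - r) / cal.n_target)
    # TAB-seq: false positives come from the methylated control (~2%)
    cal = calling.calibrate(piles["TAB"], "TAB")
    p = 0.02 * (1 - eps) + 0.98 * eps
    assert abs(cal.false_positive_rate - p) <= 3 * np.sqrt(p * (1 - p) / cal.n_fp)


def test_ideal_calibration_floors_zero_rate():
    sc = sim.SimulationScenario(seed=23, genome_length=40_000, n_genes=8,
                                n_hyper_m=2, n_hypo_h=2)
    truth = sim.generate_scenario(sc)
    pil = sim.simulate_pileups(truth.genome, truth.methylomes["WT"], "CD",
                               ch.ideal_config(), depth=60, seed=1)
    cal = calling.calibrate(pil, "CD")
    assert cal.floored
    assert cal.false_positive_rate == pytest.approx(1 / (cal.n_fp + 1))
    assert cal.retention == 1.0


def test_zero_coverage_spikein_raises():
    empty = pd.DataFrame({"contig": ["chr1"], "pos": [0], "strand": "+",
                          "context": "CpG", "count_C": [3], "count_T": [4]})
    with pytest.raises(calling.CalibrationError, match="zero pooled coverage"):
        calling.calibrate(empty, "CD")


@pytest.mark.parametrize("c,t,expected", [(5, 5, 0.5), (0, 12, 0.0),
                                          (7, 3, 0.7)])
def test_raw_level(c, t, expected):
    assert calling.raw_level(c, t) == pytest.approx(expected)


def test_binomial_pvalues_match_exact_tail_sum():
    """Oracle: direct pmf summation with exact integer binomial
    coefficients, compared at 1e-12 absolute tolerance."""
    rng = np.random.default_rng(77)
    n = rng.integers(5, 60, size=1000)
    k = np.array([rng.integers(0, nn + 1) for nn in n])
    p_hat = rng.uniform(0.001, 0.2, size=1000)
    rows = pd.DataFrame({"contig": "c", "pos": np.arange(1000), "strand": "+",
                         "context": "CpG", "count_C": k, "count_T": n - k})
    res = calling.call_sites(rows, float(0.05), calling.CallingConfig(
        min_coverage=1))
    # recompute per-row with the row's own p-hat via the public API
    for nn, kk, pp in zip(n[:200], k[:200], p_hat[:200]):
        one = pd.DataFrame({"contig": "c", "pos": [0], "strand": "+",
                            "context": "CpG", "count_C": [kk],
                            "count_T": [nn - kk]})
        got = calling.call_sites(one, float(pp),
                                 calling.CallingConfig(min_coverage=1))
        exact = sum(math.comb(int(nn), j) * pp**j * (1 - pp)**(int(nn) - j)
                    for j in range(int(kk), int(nn) + 1))
        assert got["p_value"].iloc[0] == pytest.approx(exact, abs=1e-12)
    # k = 0 gives p = 1 at any coverage
    assert res.loc[res["count_C"] == 0, "p_value"].eq(1.0).all()


def test_bh_step_up_hand_examples():
    assert calling.adjust_bh([0.04]) == pytest.approx([0.04])
    got = calling.adjust_bh([0.01, 0.02, 0.03, 1.0])
    assert got == pytest.approx([0.04, 0.04, 0.04, 1.0])
    assert calling.adjust_bh([0.2] * 7) == pytest.approx([0.2] * 7)
    # permutation stability
    p = np.random.default_rng(3).uniform(size=50)
    order = np.random.default_rng(4).permutation(50)
    assert calling.adjust_bh(p)[order] == pytest.approx(
        calling.adjust_bh(p[order]))


def test_coverage_filter_and_call_invariant():
    rng = np.random.default_rng(8)
    n = rng.integers(0, 30, size=500)
    k = rng.binomial(n, 0.5)
    df = pd.DataFrame({"contig": "c", "pos": np.arange(500), "strand": "+",
                       "context": "CpG", "count_C": k, "count_T": n - k})
    res = calling.call_sites(df, 0.03, calling.CallingConfig(min_coverage=5))
    assert (res["coverage"] >= 5).all()
    assert len(res) == int((n >= 5).sum())
    called = res[res["called"]]
    assert (called["q_value"] <= 0.05).all()


def test_call_sites_invariant_to_row_order():
    rng = np.random.default_rng(12)
    n = rng.integers(5, 40, size=300)
    df = pd.DataFrame({"contig": "c", "pos": np.arange(300),
                       "strand": "+", "context": "CpG",
                       "count_C": rng.binomial(n, 0.1), "count_T": 0})
    df["count_T"] = n - df["count_C"]
    a = calling.call_sites(df, 0.05)
    b = calling.call_sites(df.sample(frac=1, random_state=1), 0.05)
    pd.testing.assert_frame_equal(a, b)


def test_fdr_control_on_null_sites():
    """All-null sites at the calibrated rate: called fraction <= alpha."""
    for seed in (1, 2, 3):
        rng = np.random.default_rng(seed)
        n = rng.poisson(30, size=20_000)
        p_hat = 0.03
        k = rng.binomial(n, p_hat)
        df = pd.DataFrame({"contig": "c", "pos": np.arange(20_000),
                           "strand": "+", "context": "CpG",
                           "count_C": k, "count_T": n - k})
        res = calling.call_sites(df, p_hat)
        frac = res["called"].mean()
        mc_err = np.sqrt(0.05 * 0.95 / len(res))
        assert frac <= 0.05 + 2 * mc_err


def test_power_nondecreasing_in_coverage():
    cfg = calling.CallingConfig(min_coverage=1)
    fracs = []
    for depth in (10, 30, 80):
        rng = np.random.default_rng(100 + depth)
        n = np.full(3000, depth)
        k = rng.binomial(n, 0.2)   # modest true modification vs p-hat 0.03
        df = pd.DataFrame({"contig": "c", "pos": np.arange(3000),
                           "strand": "+", "context": "CpG",
                           "count_C": k, "count_T": n - k})
        fracs.append(calling.call_sites(df, 0.03, cfg)["called"].mean())
    assert fracs[0] <= fracs[1] <= fracs[2]


def test_degenerate_calibrations_rejected():
    df = pd.DataFrame({"contig": "c", "pos": [0], "strand": "+",
                       "context": "CpG", "count_C": [5], "count_T": [5]})
    with pytest.raises(calling.CalibrationError):
        calling.call_sites(df, 1.0)
    with pytest.raises(calling.CalibrationError):
        calling.call_sites(df, 0.0)
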