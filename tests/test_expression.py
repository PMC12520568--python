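"""Expression layer: DEG threshold logic, fold-change recovery,
modification-expression correlation signs, and overlap set arithmetic."""

import numpy as np
import pandas as pd
import pytest

from duomod import expression as ex
from duomod import simulate as sim


def _samples(n_per_group=4):
    rows = [(f"{c}_{r}", c, r) for c in ("WT", "AD")
            for r in range(1, n_per_group + 1)]
    return pd.DataFrame(rows, columns=["sample", "condition", "replicate"])


@pytest.fixture(scope="module")
def coupled_sim():
    sc = sim.SimulationScenario(seed=41, genome_length=200_000, n_genes=60,
                                h_body_multiplier=1.0)
    truth = sim.generate_scenario(sc)
    esim = sim.simulate_expression(truth.genes, truth.methylomes, sc, seed=42)
    return sc, truth, esim


def test_deg_flag_is_conjunctive_and_pure():
    rng = np.random.default_rng(9)
    samples = _samples()
    base = rng.poisson(2000, size=(50, 8)).astype(float)
    counts = pd.DataFrame(base, columns=samples["sample"],
                          index=[f"g{i}" for i in range(50)])
    counts.index.name = "gene_id"
    # g0: strong true fold change; g1: reproducible but tiny fold change
    counts.iloc[0, 4:] *= 4.0
    counts.iloc[1, 4:] *= 2 ** 0.4
    res = ex.differential_expression(counts, samples)
    r = res.set_index("gene_id")
    assert r.loc["g0", "deg"]
    assert r.loc["g0", "log2_fc"] > 1.5
    assert r.loc["g1", "p_value"] < 0.05 and abs(r.loc["g1", "log2_fc"]) < 0.58
    assert not r.loc["g1", "deg"]
    # flag is a pure function of (p, log2_fc)
    re_derived = (res["p_value"] < 0.05) & (res["log2_fc"].abs() > 0.58)
    assert (res["deg"] == re_derived).all()


def test_identical_groups_deg_rate_near_type_one():
    rng = np.random.default_rng(10)
    samples = _samples()
    counts = pd.DataFrame(rng.poisson(500, size=(300, 8)),
                          columns=samples["sample"],
                          index=[f"g{i}" for i in range(300)])
    res = ex.differential_expression(counts, samples)
    assert res["deg"].mean() < 0.1


def test_planted_fold_change_recovered(coupled_sim):
    sc, truth, _ = coupled_sim
    # keep the planted set small so library-size normalisation does not
    # absorb an appreciable part of the fold change
    planted = {g: 1.0 for g in truth.genes["gene_id"][:5]}
    esim = sim.simulate_expression(truth.genes, truth.methylomes, sc,
                                   seed=43, coupling_h=0.0, coupling_m=0.0,
                                   planted_log2fc=planted)
    res = ex.differential_expression(esim.counts, esim.samples)
    hit = res[res["gene_id"].isin(planted)]
    assert hit["deg"].all()
    assert hit["log2_fc"].mean() == pytest.approx(1.0, abs=0.2)


def test_correlation_sign_recovery(coupled_sim):
    """Positive 5hmC coupling and negative 5mC coupling are recovered in
    the across-sample per-gene correlations for both features."""
    _, _, esim = coupled_sim
    corr = ex.correlate(esim.gene_levels, esim.counts, min_cpg=0)
    s = ex.sign_summary(corr).set_index(["feature", "assay"])
    for feature in ("promoter", "gene_body"):
        assert s.loc[(feature, "h"), "frac_positive"] >= 0.8
        assert s.loc[(feature, "m"), "frac_negative"] >= 0.8


def test_zero_coupling_signs_near_even(coupled_sim):
    sc, truth, _ = coupled_sim
    esim = sim.simulate_expression(truth.genes, truth.methylomes, sc,
                                   seed=44, coupling_h=0.0, coupling_m=0.0)
    corr = ex.correlate(esim.gene_levels, esim.counts, min_cpg=0)
    s = ex.sign_summary(corr)
    assert ((s["frac_positive"] > 0.3) & (s["frac_positive"] < 0.7)).all()


def test_zero_variance_gene_excluded():
    samples = _samples(3)
    counts = pd.DataFrame(np.full((2, 6), 100), columns=samples["sample"],
                          index=["g0", "g1"])
    levels = pd.DataFrame({
        "gene_id": ["g0"] * 6 + ["g1"] * 6,
        "sample": list(samples["sample"]) * 2,
        "m_gene": [0.5] * 6 + list(np.linspace(0.1, 0.6, 6)),
        "h_body": 0.1, "m_promoter": 0.1, "h_promoter": 0.1,
    })
    corr = ex.correlate(levels, counts, min_cpg=0)
    g0 = corr[(corr["gene_id"] == "g0") & (corr["assay"] == "m")
              & (corr["feature"] == "gene_body")]
    assert g0["correlation"].isna().all()


def test_overlap_report_matches_brute_force(rng):
    universe = [f"g{i}" for i in range(200)]
    dmg = set(rng.choice(universe, 50, replace=False))
    dhmg = set(rng.choice(universe, 60, replace=False))
    deg = set(rng.choice(universe, 40, replace=False))
    rep = ex.overlap_report(dmg, dhmg, deg).set_index("cell")["n_genes"]
    # brute force enumeration over the union
    cells = dict.fromkeys(["dmg_only", "dhmg_only", "deg_only", "dmg_dhmg",
                           "dmg_deg", "dhmg_deg", "all_three"], 0)
    for g in dmg | dhmg | deg:
        key = (g in dmg, g in dhmg, g in deg)
        name = {(1, 0, 0): "dmg_only", (0, 1, 0): "dhmg_only",
                (0, 0, 1): "deg_only", (1, 1, 0): "dmg_dhmg",
                (1, 0, 1): "dmg_deg", (0, 1, 1): "dhmg_deg",
                (1, 1, 1): "all_three"}[tuple(map(int, key))]
        cells[name] += 1
    for name, n in cells.items():
        assert rep[name] == n
    assert sum(cells.values()) == rep["union"]
    # disjoint DEG zeroes every DEG-containing cell
    rep2 = ex.overlap_report({"a", "b"}, {"b", "c"}, {"x"}) \
        .set_index("cell")["n_genes"]
    assert rep2["deg_only"] == 1
    assert rep2["dmg_deg"] == rep2["dhmg_deg"] == rep2["all_three"] == 0


def test_uncoupled_overlap_near_hypergeometric(coupled_sim):
    """With coupling off, DhMG/DEG overlap matches the chance expectation."""
    sc, truth, _ = coupled_sim
    rng = np.random.default_rng(45)
    universe = list(truth.genes["gene_id"])
    dhmg = set(rng.choice(universe, 20, replace=False))
    esim = sim.simulate_expression(truth.genes, truth.methylomes, sc,
                                   seed=46, coupling_h=0.0, coupling_m=0.0,
                                   planted_log2fc={g: 1.5 for g in
                                                   rng.choice(universe, 20,
                                                              replace=False)})
    res = ex.differential_expression(esim.counts, esim.samples)
    deg = set(res.loc[res["deg"], "gene_id"])
    rep = ex.overlap_report(set(), dhmg, deg).set_index("cell")["n_genes"]
    expected = len(dhmg) * len(deg) / len(universe)
    sd = np.sqrt(expected)
    assert abs(rep["dhmg_deg"] + rep["all_three"] - expected) <= 3 * sd + 2


def test_all_zero_genes_dropped_and_zero_library_rejected():
    samples = _samples(2)
    counts = pd.DataFrame(np.ones((3, 4)) * 50, columns=samples["sample"],
                          index=["g0", "g1", "g2"])
    counts.loc["g1"] = 0
    res = ex.differential_expression(counts, samples)
    assert "g1" not in set(res["gene_id"])
    with pytest.raises(ValueError, match="zero library"):
        ex.log2_cpm(counts * 0)
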