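"""Differential layer: site tests, region segmentation against planted
truth, the four region criteria, and gene mapping vs a naive oracle."""

import numpy as np
import pandas as pd
import pytest

from duomod import differential as dd
from duomod import simulate as sim


def _two_group_pileups(truth, proto, seed, n_reps=2, depth=30, jitter=0.02):
    rng = np.random.default_rng(seed)
    piles = {}
    for cond in ("WT", "AD"):
        piles[cond] = []
        for _ in range(n_reps):
            jm = sim.jitter_methylome(truth.methylomes[cond], truth.genes,
                                      jitter,
                                      np.random.default_rng(int(rng.integers(2**31))))
            piles[cond].append(sim.simulate_pileups(
                truth.genome, jm, proto, depth=depth,
                seed=int(rng.integers(2**31))))
    return piles


def _jaccard(a0, a1, b0, b1):
    inter = max(0, min(a1, b1) - max(a0, b0))
    return inter / (max(a1, b1) - min(a0, b0))


@pytest.fixture(scope="module")
def planted_run():
    """One seeded scenario with planted regions on an otherwise unchanged
    background, plus its site tests and regions for both assays."""
    sc = sim.SimulationScenario(seed=31, genome_length=250_000, n_genes=50,
                                h_body_multiplier=1.0, n_hyper_m=5,
                                n_hypo_h=5)
    truth = sim.generate_scenario(sc)
    out = {}
    for seed, (assay, proto) in enumerate((("m", "CD"), ("h", "ACE")),
                                          start=32):
        diffs = dd.test_dmc(_two_group_pileups(truth, proto, seed=seed))
        out[assay] = (diffs, dd.call_regions(diffs))
    return truth, out


def test_identical_groups_yield_no_regions(small_truth):
    piles = {
        "WT": [sim.simulate_pileups(small_truth.genome,
                                    small_truth.methylomes["WT"], "CD",
                                    depth=30, seed=s) for s in (1, 2)],
        "AD": [sim.simulate_pileups(small_truth.genome,
                                    small_truth.methylomes["WT"], "CD",
                                    depth=30, seed=s) for s in (3, 4)],
    }
    diffs = dd.test_dmc(piles)
    # significant-site fraction stays near the test's type-I rate
    assert diffs["significant"].mean() < 0.02
    assert len(dd.call_regions(diffs)) == 0


def test_significance_is_conjunctive():
    """A tiny p-value cannot rescue a difference below 0.1."""
    n = 100_000
    piles = {"WT": [pd.DataFrame({"contig": "c", "pos": [0], "strand": "+",
                                  "context": "CpG", "count_C": [0],
                                  "count_T": [n]})],
             "AD": [pd.DataFrame({"contig": "c", "pos": [0], "strand": "+",
                                  "context": "CpG",
                                  "count_C": [int(0.09 * n)],
                                  "count_T": [n - int(0.09 * n)]})]}
    diffs = dd.test_dmc(piles)
    assert diffs["p_value"].iloc[0] < 1e-6
    assert abs(diffs["diff"].iloc[0]) < 0.1
    assert not diffs["significant"].iloc[0]


def test_planted_site_recall(planted_run):
    truth, out = planted_run
    diffs, _ = out["m"]
    for plant in truth.planted.query("kind == 'hyper_m'").itertuples():
        member = diffs[(diffs["pos"] >= plant.start)
                       & (diffs["pos"] < plant.end)
                       & (diffs["context"] == "CpG")]
        assert member["significant"].mean() >= 0.6


def test_planted_regions_recovered(planted_run):
    truth, out = planted_run
    for assay, kind in (("m", "hyper_m"), ("h", "hypo_h")):
        _, regions = out[assay]
        for plant in truth.planted.query(f"kind == '{kind}'").itertuples():
            best = max((_jaccard(plant.start, plant.end, r.start, r.end)
                        for r in regions.itertuples()), default=0.0)
            assert best >= 0.7
        direction = "hyper" if kind == "hyper_m" else "hypo"
        assert (regions["direction"] == direction).all()


def test_emitted_regions_satisfy_all_criteria(planted_run):
    _, out = planted_run
    for assay in ("m", "h"):
        diffs, regions = out[assay]
        val = dd.validate_regions(regions, diffs)
        assert val["ok_all"].all()
        # and the validator does flag a deliberately corrupted region
        broken = regions.copy()
        broken.loc[0, "end"] = broken.loc[0, "end"] + 50_000
        val2 = dd.validate_regions(broken, diffs)
        assert not val2["ok_all"].iloc[0]


def test_cpg_desert_splits_region():
    """A > 300 bp gap inside an otherwise uniform differential stretch
    must split the emitted region in two."""
    pos = np.concatenate([np.arange(0, 2000, 50),
                          np.arange(2500, 4500, 50)])
    rng = np.random.default_rng(5)
    n = 60
    lref = rng.binomial(n, 0.2, size=len(pos)) / n
    lalt = rng.binomial(n, 0.5, size=len(pos)) / n
    diffs = pd.DataFrame({
        "contig": "c", "pos": pos, "strand": "+", "context": "CpG",
        "level_ref": lref, "level_alt": lalt, "diff": lalt - lref,
        "p_value": 1e-6, "significant": True,
        "coverage_1": n, "coverage_2": n,
    })
    regions = dd.call_regions(diffs)
    assert len(regions) == 2
    assert regions["end"].iloc[0] <= 2000
    assert regions["start"].iloc[1] >= 2500


def test_unsorted_input_raises():
    diffs = pd.DataFrame({"contig": "c", "pos": [100, 50], "strand": "+",
                          "context": "CpG", "level_ref": 0.1,
                          "level_alt": 0.5, "diff": 0.4, "p_value": 0.001,
                          "significant": True})
    with pytest.raises(ValueError, match="sorted"):
        dd.call_regions(diffs)


def test_direction_classification(planted_run):
    _, out = planted_run
    regions = pd.concat([out["m"][1], out["h"][1]], ignore_index=True)
    counts = dd.classify_direction(regions)
    assert counts.set_index("direction")["n"].sum() == len(regions)
    assert (regions.loc[regions["mean_diff"] > 0, "direction"] == "hyper").all()
    assert (regions.loc[regions["mean_diff"] < 0, "direction"] == "hypo").all()


def test_intersection_algebra(planted_run):
    _, out = planted_run
    dmc, dhmc = out["m"][0], out["h"][0]
    classes = dd.intersect_classes(dmc, dhmc)
    n_dmc = int(dmc["significant"].sum())
    n_dhmc = int(dhmc["significant"].sum())
    n_both = len(classes["both"])
    assert n_both <= min(n_dmc, n_dhmc)
    assert len(classes["dmc_only"]) == n_dmc - n_both
    assert len(classes["dhmc_only"]) == n_dhmc - n_both
    # planted m- and h-perturbations are at disjoint loci: overlap ~ chance
    assert n_both < 0.05 * min(n_dmc, n_dhmc)


def test_map_to_genes_matches_naive_overlap(rng):
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(40)],
        "contig": "chr1",
        "start": np.sort(rng.integers(0, 450_000, size=40)),
    })
    genes["end"] = genes["start"] + rng.integers(2000, 8000, size=40)
    genes["strand"] = np.where(rng.random(40) < 0.5, "+", "-")
    genes["tss"] = genes["start"].where(genes["strand"] == "+", genes["end"])
    starts = rng.integers(0, 480_000, size=300)
    regions = pd.DataFrame({"contig": "chr1", "start": starts,
                            "end": starts + rng.integers(200, 5000, size=300),
                            "direction": "hyper"})
    got = dd.map_to_genes(regions, genes)
    for g in genes.itertuples():
        lo = min(g.start, g.tss - 1000)
        hi = max(g.end, g.tss + 1000)
        naive = int(((regions["start"] < hi) & (regions["end"] > lo)).sum())
        row = got[got["gene_id"] == g.gene_id].iloc[0]
        assert row["n_regions"] == naive
        assert row["flagged"] == (naive > 0)
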