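"""The four stability algorithms, their identities and aggregation."""

import math

import numpy as np
import pytest

import refrank as rr
from conftest import make_ct
from oracles import (brute_bestkeeper, brute_delta_ct, brute_genorm_m,
                     brute_normfinder_v, normfinder_sigma_sq_by_system)


# ---------------------------------------------------------------------------
# delta-CT
# ---------------------------------------------------------------------------


def test_identical_profiles_score_zero():
    row = [20.0, 21.0, 22.0, 23.0]
    scores = rr.delta_ct_stability(make_ct([row, row, row]))
    assert all(s.value == 0.0 for s in scores)


def test_constant_shift_between_genes_scores_zero_pairwise():
    a = [20.0, 21.0, 22.0, 23.0]
    b = [x + 3.0 for x in a]
    scores = rr.delta_ct_stability(make_ct([a, b]))
    assert all(s.value == pytest.approx(0.0, abs=1e-12) for s in scores)


def test_three_gene_worked_example():
    ds = make_ct([[20, 21, 22, 23], [20, 21, 22, 23], [20, 23, 20, 23]],
                 genes=["A", "B", "C"])
    by_id = {s.gene_id: s for s in rr.delta_ct_stability(ds)}
    expected_ac = math.sqrt(8.0 / 3.0)           # SD of [0, -2, 2, 0]
    assert by_id["A"].value == pytest.approx(expected_ac / 2)   # ~0.816
    assert by_id["B"].value == pytest.approx(expected_ac / 2)
    assert by_id["C"].value == pytest.approx(expected_ac)       # ~1.633
    assert by_id["C"].rank == 3


def test_delta_ct_needs_two_samples():
    with pytest.raises(rr.ValidationError, match="SD undefined"):
        rr.delta_ct_stability(make_ct([[20.0], [21.0]]))


def test_delta_ct_matches_brute_force(random_ct):
    for seed in range(5):
        ds = random_ct(seed)
        values = [s.value for s in rr.delta_ct_stability(ds)]
        assert values == pytest.approx(brute_delta_ct(ds.ct_matrix()),
                                       abs=1e-12)


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------


def test_full_set_m_equals_delta_ct_statistic(random_ct):
    """With base 2 the geNorm M value is the delta-CT statistic, exactly."""
    ds = random_ct(0)
    m = rr.genorm_m_values(ds, 2.0)
    dct = {s.gene_id: s.value for s in rr.delta_ct_stability(ds)}
    for gid in ds.gene_ids:
        assert abs(m[gid] - dct[gid]) < 1e-12


def test_genorm_m_matches_brute_force(random_ct):
    for seed in range(5):
        ds = random_ct(seed)
        m = rr.genorm_m_values(ds, 2.0)
        brute = brute_genorm_m(ds.ct_matrix(), 2.0)
        assert [m[g] for g in ds.gene_ids] == pytest.approx(brute, abs=1e-10)


def test_proportional_quantities_give_zero_m_and_v():
    base = np.array([20.0, 21.5, 19.0, 22.0, 20.5])
    ds = make_ct([base, base + 1.0, base + 2.5, base - 0.5])
    res = rr.genorm(ds)
    assert all(v == pytest.approx(0.0, abs=1e-12) for v in res.m_final.values())
    assert all(v == pytest.approx(0.0, abs=1e-12)
               for v in res.pairwise_variation.values())


def test_noisiest_gene_excluded_first():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        ct = 20.0 + rng.normal(0.0, 0.1, size=(4, 9))
        ct[3] += rng.normal(0.0, 1.0, size=9)
        res = rr.genorm(make_ct(ct))
        hits += res.exclusion_order[0] == "g4"
    assert hits >= 95


def test_genorm_tie_excludes_lexicographically_last():
    # two mirrored noisy genes tie exactly in M; two constant partners
    noisy = np.array([0.0, 1.0, -1.0, 0.5, -0.5])
    ct = np.vstack([np.full(5, 20.0), np.full(5, 21.0),
                    22.0 + noisy, 23.0 - noisy])
    res = rr.genorm(make_ct(ct, genes=["a", "b", "c", "d"]))
    assert res.exclusion_order[0] == "d"


def test_genorm_ranks_share_rank_one_for_final_pair(random_ct):
    res = rr.genorm(random_ct(1))
    ranks = sorted(s.rank for s in res.scores)
    assert ranks[:3] == [1, 1, 3]
    pair_ranks = {s.gene_id: s.rank for s in res.scores}
    assert all(pair_ranks[g] == 1 for g in res.most_stable_pair)


def test_genorm_v_series_lengths(random_ct):
    ds = random_ct(2)
    res = rr.genorm(ds)
    assert list(res.pairwise_variation) == [f"V{n}/{n + 1}"
                                            for n in range(2, ds.n_genes)]


def test_genorm_requires_three_genes():
    with pytest.raises(rr.ValidationError, match="3 genes"):
        rr.genorm(make_ct([[20, 21], [22, 23]]))


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------


def test_constant_gene_sd_zero_r_undefined():
    res = rr.bestkeeper(make_ct([[20.0, 20.0, 20.0], [21.0, 22.0, 23.0]],
                                genes=["flat", "mov"]))
    row = res.per_gene.loc["flat"]
    assert row["sd_ct"] == 0.0 and row["cv_pct"] == 0.0
    assert math.isnan(row["pearson_r"])
    assert {s.gene_id: s.rank for s in res.scores}["flat"] == 1


def test_two_gene_worked_example():
    res = rr.bestkeeper(make_ct([[20.0, 21.0, 22.0], [22.0, 23.0, 24.0]],
                                genes=["A", "B"]))
    expected_index = [math.sqrt(20 * 22), math.sqrt(21 * 23),
                      math.sqrt(22 * 24)]
    assert res.index.to_numpy() == pytest.approx(expected_index, abs=1e-9)
    assert res.per_gene.loc["A", "pearson_r"] == pytest.approx(1.0)
    assert res.per_gene.loc["B", "pearson_r"] == pytest.approx(1.0)


def test_bestkeeper_matches_brute_force(random_ct):
    for seed in range(5):
        ds = random_ct(seed)
        res = rr.bestkeeper(ds)
        brute = brute_bestkeeper(ds.ct_matrix())
        assert res.index.to_numpy() == pytest.approx(brute["index"], abs=1e-12)
        for gid, exp in zip(ds.gene_ids, brute["per_gene"]):
            row = res.per_gene.loc[gid]
            assert row["mean_ct"] == pytest.approx(exp["mean"], abs=1e-12)
            assert row["geo_mean_ct"] == pytest.approx(exp["geo_mean"], abs=1e-12)
            assert row["sd_ct"] == pytest.approx(exp["sd"], abs=1e-12)
            assert row["cv_pct"] == pytest.approx(exp["cv"], abs=1e-12)
            assert row["pearson_r"] == pytest.approx(exp["r"], abs=1e-12)


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------


def test_exactly_additive_data_scores_zero():
    alpha = np.array([20.0, 22.0, 25.0])[:, None]
    beta = np.array([0.0, 1.0, -1.0, 0.5])[None, :]
    res = rr.normfinder_single_group(make_ct(alpha + beta))
    assert res.stability == pytest.approx(np.zeros(3), abs=1e-12)


def test_sigma_sq_matches_expectation_system_solve():
    rng = np.random.default_rng(9)
    ct = rng.uniform(18, 30, size=(4, 5))
    res = rr.normfinder_single_group(make_ct(ct))
    expected = normfinder_sigma_sq_by_system(ct)
    assert res.sigma_sq == pytest.approx(expected, abs=1e-10)
    assert res.residual_variance == pytest.approx(brute_normfinder_v(ct),
                                                  abs=1e-10)


def test_normfinder_requires_three_genes():
    with pytest.raises(rr.ValidationError, match="g < 3"):
        rr.normfinder_single_group(make_ct([[20, 21], [22, 23]]))


def test_normfinder_estimates_improve_with_sample_size():
    """Estimator consistency: error shrinks from n=50 to n=500."""
    sigma = np.linspace(0.1, 0.8, 8)
    errs = {}
    for n in (50, 500):
        per_seed = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            ct = (rng.uniform(18, 28, size=(8, 1))
                  + rng.normal(0, 1, size=(1, n))
                  + rng.normal(0, 1, size=(8, n)) * sigma[:, None])
            res = rr.normfinder_single_group(make_ct(ct))
            per_seed.append(np.mean(np.abs(res.stability - sigma)))
        errs[n] = np.mean(per_seed)
    assert errs[500] < errs[50]


# ---------------------------------------------------------------------------
# Aggregation and summaries
# ---------------------------------------------------------------------------


def test_dominant_gene_gets_aggregate_rank_one():
    rng = np.random.default_rng(4)
    ct = 22.0 + rng.normal(0, 1.0, size=(5, 9))
    ct[0] = 22.0 + rng.normal(0, 0.01, size=9)
    ranking = rr.rank_all(make_ct(ct))
    assert ranking.aggregate[0].gene_id == "g1"
    assert ranking.aggregate[0].rank == 1


def test_duplicated_gene_pair_shares_rank_one():
    rng = np.random.default_rng(6)
    base = 20.0 + rng.normal(0, 0.05, size=9)
    ct = np.vstack([base, base + 1.0,
                    25.0 + rng.normal(0, 1.0, size=9),
                    27.0 + rng.normal(0, 1.5, size=9)])
    res = rr.genorm(make_ct(ct))
    ranks = {s.gene_id: s.rank for s in res.scores}
    assert ranks["g1"] == ranks["g2"] == 1
    assert sorted(ranks.values()) == [1, 1, 3, 4]


def test_method_skipped_when_preconditions_fail(random_ct):
    ds = random_ct(3, g=2, n=9)          # too few genes for geNorm/NormFinder
    ranking = rr.rank_all(ds)
    assert set(ranking.method_scores) == {"deltaCT", "BestKeeper"}
    assert len(ranking.aggregate) == 2


def test_rank_groups_runs_each_group_separately(random_ct):
    rankings = rr.rank_groups({"OP": random_ct(1, group="OP"),
                               "RP": random_ct(2, group="RP")})
    assert rankings["OP"].group == "OP" and rankings["RP"].group == "RP"


def test_ct_summary_mean_and_sd():
    ds = make_ct([[19.0, 20.0, 21.0]], genes=["a"])
    summary = rr.ct_summary([ds])
    row = summary.per_gene.iloc[0]
    assert row["mean_ct"] == 20.0 and row["sd_ct"] == pytest.approx(1.0)


def test_identical_groups_have_zero_difference(random_ct):
    op = random_ct(5, group="OP")
    rp = rr.CtDataset(op.gene_ids, op.sample_labels, op.values.copy(),
                      group="RP")
    summary = rr.ct_summary([op, rp])
    assert summary.group_difference.to_numpy() == pytest.approx(
        np.zeros(op.n_genes), abs=1e-12)


# ---------------------------------------------------------------------------
# Invariance properties
# ---------------------------------------------------------------------------


def test_shift_invariance_of_stability_statistics(random_ct):
    ds = random_ct(12)
    shifted_values = ds.values.copy()
    shifted_values[2] += 5.0                     # one gene shifted everywhere
    shifted = rr.CtDataset(ds.gene_ids, ds.sample_labels, shifted_values)

    for fn in (lambda d: [s.value for s in rr.delta_ct_stability(d)],
               lambda d: [rr.genorm_m_values(d)[g] for g in d.gene_ids],
               lambda d: list(rr.normfinder_single_group(d).stability)):
        assert fn(shifted) == pytest.approx(fn(ds), abs=1e-9)

    bk_base = rr.bestkeeper(ds).per_gene
    bk_shift = rr.bestkeeper(shifted).per_gene
    assert bk_shift["sd_ct"].to_numpy() == pytest.approx(
        bk_base["sd_ct"].to_numpy(), abs=1e-9)
    # CV is SD over mean, so the shifted gene's CV must change
    assert bk_shift["cv_pct"].iloc[2] < bk_base["cv_pct"].iloc[2]


def test_monotone_degradation_with_added_noise():
    """Mean statistic over seeds weakly increases with injected noise."""
    levels = (0.0, 0.5, 1.0)
    sums = {m: np.zeros(len(levels)) for m in
            ("deltaCT", "geNorm", "BestKeeper", "NormFinder")}
    for seed in range(30):
        rng = np.random.default_rng(seed)
        base = 21.0 + rng.normal(0, 0.2, size=(5, 9))
        z = rng.normal(0, 1.0, size=9)
        for li, sigma in enumerate(levels):
            ct = base.copy()
            ct[0] += sigma * z
            ds = make_ct(ct)
            sums["deltaCT"][li] += rr.delta_ct_stability(ds)[0].value
            sums["geNorm"][li] += rr.genorm_m_values(ds)["g1"]
            sums["BestKeeper"][li] += rr.bestkeeper(ds).per_gene[
                "sd_ct"].iloc[0]
            sums["NormFinder"][li] += rr.normfinder_single_group(
                ds).stability[0]
    for method, totals in sums.items():
        assert totals[0] < totals[1] < totals[2], method
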