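"""Spot filtering, gene statistics, DE filter, TAD Fisher, bootstrap, ΔΔCq."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps
from scipy.stats import hypergeom

from woundrepair import exprstats, simkit
from woundrepair.exprstats import (bootstrap_median, de_filter,
                                   delta_delta_cq, filter_spots,
                                   gene_statistics, tad_enrichment)
from woundrepair.simkit import ExprSimParams


def spot_row(fg1=1000.0, bg1=100.0, sd1=10.0, fg2=1000.0, bg2=100.0,
             sd2=10.0, flag=False, spot_id="s0"):
    return {"spot_id": spot_id, "fg_ch1": fg1, "bg_ch1": bg1,
            "bg_sd_ch1": sd1, "fg_ch2": fg2, "bg_ch2": bg2,
            "bg_sd_ch2": sd2, "qc_flag": flag}


class TestFilterSpots:
    def test_good_spot_kept(self):
        kept, log = filter_spots(pd.DataFrame([spot_row()]))
        assert len(kept) == 1 and len(log) == 0

    def test_low_signal_both_channels_removed(self):
        kept, log = filter_spots(pd.DataFrame(
            [spot_row(fg1=199.0, fg2=199.0)]))
        assert len(kept) == 0
        assert log["rule"].iloc[0] == "low_signal"

    def test_low_signal_one_channel_kept(self):
        kept, _ = filter_spots(pd.DataFrame([spot_row(fg1=199.0)]))
        assert len(kept) == 1

    def test_within_3sd_removed(self):
        kept, log = filter_spots(pd.DataFrame(
            [spot_row(fg1=100.0 + 2 * 10.0)]))
        assert len(kept) == 0
        assert log["rule"].iloc[0] == "bg3sd"

    def test_flagged_removed(self):
        kept, log = filter_spots(pd.DataFrame([spot_row(flag=True)]))
        assert len(kept) == 0
        assert log["rule"].iloc[0] == "flagged"

    def test_row_conservation_on_synthetic_table(self):
        spots, _ = simkit.simulate_expression_study(
            ExprSimParams(n_genes=500, n_up=5, n_down=5, rng_seed=0))
        kept, log = filter_spots(spots)
        assert len(kept) + len(log) == len(spots)
        # constructed violators are exactly the removed spots
        truth_bad = spots["fails_bg3sd"] | spots["fails_low_signal"] \
            | spots["fails_flag"]
        assert set(log["spot_id"]) == set(spots.loc[truth_bad, "spot_id"])


class TestGeneStatistics:
    def test_zero_variance_conventions(self):
        tab = pd.DataFrame({"rep_1": [1.0, 0.0], "rep_2": [1.0, 0.0],
                            "rep_3": [1.0, 0.0], "rep_4": [1.0, 0.0]})
        out = gene_statistics(tab)
        assert out["logFC"].iloc[0] == 1.0
        assert out["p_value"].iloc[0] == 0.0   # identical nonzero replicates
        assert out["p_value"].iloc[1] == 1.0   # identical zero replicates

    def test_symmetric_replicates_mean_zero(self):
        tab = pd.DataFrame({"rep_1": [0.4], "rep_2": [-0.4],
                            "rep_3": [0.2], "rep_4": [-0.2]})
        assert gene_statistics(tab)["logFC"].iloc[0] == 0.0

    def test_matches_closed_form_t(self):
        """p equals the textbook one-sample t computed from the t CDF."""
        rng = np.random.default_rng(0)
        x = rng.normal(0.3, 1.0, (50, 4))
        tab = pd.DataFrame(x, columns=[f"rep_{i}" for i in range(1, 5)])
        out = gene_statistics(tab)
        m = x.mean(axis=1)
        se = x.std(axis=1, ddof=1) / 2.0
        t = m / se
        p_oracle = 2 * sps.t.sf(np.abs(t), df=3)
        np.testing.assert_allclose(out["p_value"], p_oracle, rtol=1e-10)

    def test_single_replicate_raises(self):
        with pytest.raises(ValueError):
            gene_statistics(pd.DataFrame({"rep_1": [1.0]}))


def brute_force_bh(p, q):
    """Max-k BH oracle: reject the k smallest p with p(k) <= k q / m."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_max]] = True
    return rejected


class TestDeFilter:
    def test_all_p_one_no_calls(self):
        tab = pd.DataFrame({"logFC": [2.0] * 5, "p_value": [1.0] * 5})
        de = de_filter(tab)
        assert de.n_total_called == 0

    def test_bh_oracle_equivalence(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205,
             0.212, 0.216]
        lfc = [1.0, -1.0, 1.0, 1.0, -1.0, 1.0, 1.0, -1.0, 1.0, 1.0]
        tab = pd.DataFrame({"logFC": lfc, "p_value": p})
        de = de_filter(tab, fdr=0.05)
        expected = brute_force_bh(p, 0.05)
        np.testing.assert_array_equal(
            (de.table["call"] != "unaffected").to_numpy(), expected)

    def test_planted_genes_all_called_with_direction(self):
        p = ExprSimParams(n_genes=2000, n_up=30, n_down=40, noise_sigma=0.1,
                          effect_low=1.0, effect_high=1.4, rng_seed=1)
        _, expr = simkit.simulate_expression_study(p)
        de = de_filter(gene_statistics(expr))
        merged = de.table
        up_truth = merged["truth"] == "up"
        down_truth = merged["truth"] == "down"
        assert (merged.loc[up_truth, "call"] == "up").all()
        assert (merged.loc[down_truth, "call"] == "down").all()

    def test_fold_change_criterion_blocks_small_effects(self):
        tab = pd.DataFrame({"logFC": [0.5, 0.585, -0.5, -0.6],
                            "p_value": [1e-9] * 4})
        de = de_filter(tab)
        np.testing.assert_array_equal(
            de.table["call"], ["unaffected", "up", "unaffected", "down"])

    def test_monotone_in_fdr(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame({"logFC": rng.normal(0, 1, 200),
                            "p_value": rng.uniform(0, 1, 200)})
        counts = [de_filter(tab, fdr=q).n_total_called
                  for q in (0.01, 0.05, 0.1, 0.2)]
        assert counts == sorted(counts)

    def test_monotone_in_lfc_threshold(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame({"logFC": rng.normal(0, 1, 200),
                            "p_value": rng.uniform(0, 1, 200) ** 3})
        counts = [de_filter(tab, lfc_threshold=th).n_total_called
                  for th in (0.0, 0.3, 0.585, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_fdr(self):
        tab = pd.DataFrame({"logFC": [1.0], "p_value": [0.01]})
        with pytest.raises(ValueError):
            de_filter(tab, fdr=1.5)


def fisher_2x2_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration."""
    (a, b), (c, d) = table
    n1, n2 = a + b, c + d
    k = a + c
    n = n1 + n2
    rv = hypergeom(n, k, n1)
    p_obs = rv.pmf(a)
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    probs = rv.pmf(support)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestTadEnrichment:
    def test_2x2_matches_hypergeometric_enumeration(self):
        # two TADs, regulated/unaffected counts [[1, 9], [11, 3]]
        calls = np.array(["up"] * 1 + ["unaffected"] * 9
                         + ["up"] * 11 + ["unaffected"] * 3, dtype=object)
        tads = np.array([0] * 10 + [1] * 14)
        res = tad_enrichment(calls, tads)
        assert res.method == "exact-2x2"
        assert res.p_value == pytest.approx(
            fisher_2x2_oracle([[1, 9], [11, 3]]), rel=1e-9)

    def test_all_unaffected_p_one(self):
        calls = np.array(["unaffected"] * 30, dtype=object)
        tads = np.arange(30) % 3
        assert tad_enrichment(calls, tads).p_value == 1.0

    def test_unmapped_genes_excluded_and_counted(self):
        calls = np.array(["up", "unaffected", "unaffected", "up"], dtype=object)
        tads = pd.Series([0, 0, 1, None])
        res = tad_enrichment(calls, tads)
        assert res.n_unmapped == 1
        assert res.table.sum() == 3

    def test_mc_reproducible_and_consistent_across_seeds(self):
        rng = np.random.default_rng(0)
        calls = np.array(rng.choice(["up", "unaffected"], 300, p=[0.2, 0.8]),
                         dtype=object)
        tads = rng.integers(0, 6, 300)
        r1 = tad_enrichment(calls, tads, n_mc=5000, seed=1)
        r1b = tad_enrichment(calls, tads, n_mc=5000, seed=1)
        r2 = tad_enrichment(calls, tads, n_mc=5000, seed=99)
        assert r1.method == "monte-carlo"
        assert r1.p_value == r1b.p_value  # seed-deterministic
        se = np.hypot(r1.mc_se, r2.mc_se)
        assert abs(r1.p_value - r2.p_value) < 3 * se

    def test_clustering_lowers_p(self):
        """Planted genes packed into one TAD yield smaller Fisher p than the
        same study with scattered planted genes, in >=95% of seeded runs."""
        wins = 0
        n_runs = 100
        for seed in range(n_runs):
            kw = dict(n_genes=400, n_up=10, n_down=10, n_tads=8,
                      tad_cluster_size=50, rng_seed=seed)
            _, clustered = simkit.simulate_expression_study(
                ExprSimParams(tad_clustering=True, **kw))
            _, scattered = simkit.simulate_expression_study(
                ExprSimParams(tad_clustering=False, **kw))
            calls_c = np.where(clustered["truth"] == "unaffected",
                               "unaffected", "up")
            calls_s = np.where(scattered["truth"] == "unaffected",
                               "unaffected", "up")
            p_on = tad_enrichment(calls_c.astype(object),
                                  clustered["tad_id"], n_mc=2000,
                                  seed=seed).p_value
            p_off = tad_enrichment(calls_s.astype(object),
                                   scattered["tad_id"], n_mc=2000,
                                   seed=seed).p_value
            wins += p_on < p_off
        assert wins >= 0.95 * n_runs

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            tad_enrichment(np.array([], dtype=object), np.array([]))


class TestBootstrapMedian:
    def test_constant_values(self):
        assert bootstrap_median([2.5] * 20) == (2.5, 2.5, 2.5)

    def test_seed_determinism(self):
        x = np.random.default_rng(0).lognormal(1.0, 0.5, 100)
        assert bootstrap_median(x, seed=5) == bootstrap_median(x, seed=5)
        assert bootstrap_median(x, seed=5) != bootstrap_median(x, seed=6)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            bootstrap_median([1.0])

    def test_ci_brackets_median(self):
        x = np.random.default_rng(1).lognormal(np.log(2.5), 0.6, 200)
        med, lo, hi = bootstrap_median(x, seed=0)
        assert lo <= med <= hi


class TestDeltaDeltaCq:
    def _table(self, cq_t_kd, cq_r_kd=15.0, cq_t_c=20.0, cq_r_c=15.0):
        return pd.DataFrame({
            "condition": ["knockdown", "knockdown", "control", "control"],
            "role": ["target", "reference"] * 2,
            "cq": [cq_t_kd, cq_r_kd, cq_t_c, cq_r_c],
        })

    def test_identical_conditions_zero(self):
        res = delta_delta_cq(self._table(20.0))
        assert res.delta_delta_cq == 0.0
        assert res.efficiency_pct == 0.0

    def test_one_cycle_is_half(self):
        assert delta_delta_cq(self._table(21.0)).efficiency_pct == \
            pytest.approx(50.0)

    def test_three_cycles(self):
        assert delta_delta_cq(self._table(23.0)).efficiency_pct == \
            pytest.approx(100 * (1 - 2 ** -3))

    def test_technical_replicates_averaged_first(self):
        tab = pd.DataFrame({
            "condition": ["knockdown"] * 4 + ["control"] * 2,
            "role": ["target", "target", "reference", "reference",
                     "target", "reference"],
            "cq": [22.5, 23.5, 15.0, 15.0, 20.0, 15.0],
        })
        assert delta_delta_cq(tab).delta_delta_cq == pytest.approx(3.0)

    def test_missing_cq_raises(self):
        tab = self._table(23.0).iloc[:3]
        with pytest.raises(ValueError, match="missing Cq"):
            delta_delta_cq(tab)

    @given(st.floats(min_value=-5.0, max_value=5.0))
    def test_shift_invariance(self, shift):
        """Adding a constant to every Cq leaves the efficiency unchanged."""
        tab = self._table(22.0)
        shifted = tab.assign(cq=tab["cq"] + shift)
        assert delta_delta_cq(shifted).efficiency_pct == pytest.approx(
            delta_delta_cq(tab).efficiency_pct)

    def test_strictly_increasing_in_ddcq(self):
        effs = [delta_delta_cq(self._table(20.0 + d)).efficiency_pct
                for d in (0.0, 0.5, 1.0, 2.0, 3.0)]
        assert all(b > a for a, b in zip(effs, effs[1:]))
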