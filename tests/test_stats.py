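"""Inference layer: PERMANOVA, one-way models, Tukey HSD letters, logistic
regression and group summaries, each checked against an independent route."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from escapekin.stats import (
    compact_letter_display,
    logistic_jump,
    oneway_lm,
    permanova,
    scramble_vs_jump,
    summarize,
    tukey_hsd,
)


class TestPermanova:
    def test_identical_rows_give_zero_f(self):
        x = np.ones((8, 3))
        labels = np.repeat(["a", "b"], 4)
        res = permanova(x, labels, n_perm=99, seed=0)
        assert res.pseudo_f == 0.0

    def test_separated_clusters_hit_minimum_p(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(50, 0.1, (10, 2))])
        labels = np.repeat(["a", "b"], 10)
        res = permanova(x, labels, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_p_value_lower_bound(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 3))
        res = permanova(x, np.repeat(["a", "b", "c"], 4), n_perm=49, seed=0)
        assert res.p_value >= 1 / 50
        assert res.pseudo_f >= 0

    def test_univariate_pseudo_f_equals_anova_f(self):
        """On Euclidean distances of 1-D data the pseudo-F is the classical
        one-way ANOVA F (algebraic identity)."""
        rng = np.random.default_rng(3)
        values = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        res = permanova(values.reshape(-1, 1), labels, n_perm=9, seed=0)
        f_classic, _ = sps.f_oneway(values[:10], values[10:20], values[20:])
        assert res.pseudo_f == pytest.approx(f_classic, rel=1e-9)

    def test_agrees_with_scikit_bio(self):
        """Independent implementation cross-check on the same distances."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(4)
        x = rng.normal(size=(15, 3))
        x[10:] += 1.5
        labels = np.repeat(["a", "b", "c"], 5)
        dm = skbio_stats.DistanceMatrix(squareform(pdist(x)))
        oracle = skbio_stats.permanova(dm, labels.tolist(), permutations=99)
        res = permanova(x, labels, n_perm=99, seed=0)
        assert res.pseudo_f == pytest.approx(oracle["test statistic"], rel=1e-9)

    def test_deterministic_and_row_order_invariant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(16, 2))
        labels = np.repeat(["a", "b"], 8)
        r1 = permanova(x, labels, n_perm=199, seed=9)
        r2 = permanova(x, labels, n_perm=199, seed=9)
        assert r1 == r2
        perm = rng.permutation(16)
        r3 = permanova(x[perm], labels[perm], n_perm=199, seed=9)
        assert r3.pseudo_f == pytest.approx(r1.pseudo_f, rel=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="2 members"):
            permanova(np.eye(3), ["a", "a", "b"], n_perm=9, seed=0)
        with pytest.raises(ValueError, match="2 groups"):
            permanova(np.eye(4), ["a"] * 4, n_perm=9, seed=0)


class TestOneway:
    def test_equal_groups_give_zero_f(self):
        res = oneway_lm([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.f == pytest.approx(0.0, abs=1e-12)

    def test_balanced_three_groups_match_hand_sums_of_squares(self):
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 10.0, 11.0, 12.0])
        res = oneway_lm(values, groups)
        # hand computation via sums of squares
        grand = values.mean()
        ss_b = 3 * sum((values[i : i + 3].mean() - grand) ** 2 for i in (0, 3, 6))
        ss_w = sum(((values[i : i + 3] - values[i : i + 3].mean()) ** 2).sum() for i in (0, 3, 6))
        f_hand = (ss_b / 2) / (ss_w / 6)
        assert res.f == pytest.approx(f_hand, rel=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_lm([1, 2, 3], ["a", "a", "a"])

    def test_all_constant_groups_rejected(self):
        with pytest.raises(ValueError, match="zero within-group variance"):
            oneway_lm([1, 1, 2, 2], ["a", "a", "b", "b"])


class TestTukey:
    def test_pairwise_p_matches_scipy_oracle(self):
        a, b, c = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [10.0, 11.0, 12.0]
        res = tukey_hsd(a + b + c, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        oracle = sps.tukey_hsd(np.array(a), np.array(b), np.array(c))
        got = {
            frozenset((r["group1"], r["group2"])): r["p_adj"]
            for r in res.table.to_dict("records")
        }
        names = ["a", "b", "c"]
        for i, j in itertools.combinations(range(3), 2):
            assert got[frozenset((names[i], names[j]))] == pytest.approx(
                oracle.pvalue[i, j], abs=1e-9
            )

    def test_unequal_n_matches_scipy_tukey_kramer(self):
        rng = np.random.default_rng(6)
        samples = [rng.normal(m, 1.0, n) for m, n in [(0, 5), (1.0, 8), (2.5, 4)]]
        values = np.concatenate(samples)
        groups = ["a"] * 5 + ["b"] * 8 + ["c"] * 4
        res = tukey_hsd(values, groups)
        oracle = sps.tukey_hsd(*samples)
        got = {
            frozenset((r["group1"], r["group2"])): r["p_adj"]
            for r in res.table.to_dict("records")
        }
        names = ["a", "b", "c"]
        for i, j in itertools.combinations(range(3), 2):
            assert got[frozenset((names[i], names[j]))] == pytest.approx(
                oracle.pvalue[i, j], abs=1e-9
            )

    def test_letter_display_separates_only_significant_pairs(self):
        values = [1.0, 2.0, 3.0, 2.0, 3.0, 4.0, 10.0, 11.0, 12.0]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = tukey_hsd(values, groups)
        assert set(res.letters["a"]) & set(res.letters["b"])
        assert not set(res.letters["a"]) & set(res.letters["c"])
        assert not set(res.letters["b"]) & set(res.letters["c"])

    def test_null_configuration_shares_one_letter(self):
        """Three groups with identical values (equal means, shared spread)
        can have no significant pair; all share a single letter."""
        values = np.tile(np.arange(8.0), 3)
        groups = np.repeat(["a", "b", "c"], 8)
        res = tukey_hsd(values, groups)
        assert not res.table["reject"].any()
        common = set.intersection(*(set(v) for v in res.letters.values()))
        assert common

    def test_two_groups_match_single_pairwise_test(self):
        rng = np.random.default_rng(8)
        values = np.concatenate([rng.normal(0, 1, 6), rng.normal(3, 1, 6)])
        groups = ["a"] * 6 + ["b"] * 6
        res = tukey_hsd(values, groups)
        sig = res.table["reject"].iloc[0]
        share = set(res.letters["a"]) & set(res.letters["b"])
        assert sig == (not share)

    def test_pairwise_p_monotone_in_mean_difference(self):
        rng = np.random.default_rng(9)
        noise = rng.normal(0, 1, 8)
        ps = []
        for delta in (0.5, 1.5, 3.0, 6.0):
            values = np.concatenate([noise, noise + delta])
            res = tukey_hsd(values, ["a"] * 8 + ["b"] * 8)
            ps.append(res.table["p_adj"].iloc[0])
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_zero_mse_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd([1, 1, 2, 2], ["a", "a", "b", "b"])

    def test_insert_and_absorb_chain(self):
        """Chain a < b < c with only (a, c) significant: b bridges both."""
        letters = compact_letter_display(
            ["a", "b", "c"], {"a": 1.0, "b": 2.0, "c": 3.0}, [("a", "c")]
        )
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


class TestLogistic:
    def test_symmetric_predictor_gives_unit_odds_ratio(self):
        x = [-1.0, -1.0, 1.0, 1.0, -2.0, -2.0, 2.0, 2.0]
        y = [0, 1, 0, 1, 0, 1, 0, 1]
        res = logistic_jump(x, y)
        assert res.slope == pytest.approx(0.0, abs=1e-6)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_mle_matches_grid_search_oracle(self):
        x = np.array([10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0])
        y = np.array([1, 1, 1, 0, 1, 0, 0, 0])
        res = logistic_jump(x, y)

        def negll(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(np.log1p(np.exp(eta))) - np.sum(y * eta))

        # iteratively refined grid search, independent of the fitting library
        b0, b1, half0, half1 = 0.0, 0.0, 10.0, 1.0
        for _ in range(30):
            g0 = np.linspace(b0 - half0, b0 + half0, 21)
            g1 = np.linspace(b1 - half1, b1 + half1, 21)
            vals = [(negll(a, b), a, b) for a in g0 for b in g1]
            _, b0, b1 = min(vals)
            half0 *= 0.55
            half1 *= 0.55
        assert res.slope == pytest.approx(b1, abs=1e-4)
        assert res.intercept == pytest.approx(b0, abs=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            logistic_jump([1.0, 2.0, 3.0], [1, 1, 1])

    def test_complete_separation_flagged(self):
        x = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        y = [0, 0, 0, 1, 1, 1]
        with pytest.raises(ValueError):
            logistic_jump(x, y)


class TestScrambleVsJump:
    def test_f_equals_squared_t(self):
        rng = np.random.default_rng(10)
        takeoff = np.concatenate([rng.normal(88, 15, 12), rng.normal(126, 15, 9)])
        mode = ["jump"] * 12 + ["scramble"] * 9
        res = scramble_vs_jump(takeoff, mode)
        t, _ = sps.ttest_ind(takeoff[:12], takeoff[12:], equal_var=True)
        assert res.f == pytest.approx(t**2, rel=1e-9)
        assert res.mean_jump == pytest.approx(takeoff[:12].mean())
        assert res.mean_scramble == pytest.approx(takeoff[12:].mean())

    def test_identical_samples_give_zero_f(self):
        vals = [100.0, 110.0, 120.0, 100.0, 110.0, 120.0]
        res = scramble_vs_jump(vals, ["jump"] * 3 + ["scramble"] * 3)
        assert res.f == pytest.approx(0.0, abs=1e-12)

    def test_missing_mode_rejected(self):
        with pytest.raises(ValueError):
            scramble_vs_jump([1.0, 2.0], ["jump", "jump"])


class TestSummarize:
    def test_mean_se_n(self):
        df = pd.DataFrame(
            {
                "species": ["DIME"] * 3 + ["DIDE"],
                "reaction_ms": [1.0, 2.0, 3.0, 5.0],
            }
        )
        out = summarize(df, metrics=["reaction_ms"])
        dime = out[out["species"] == "DIME"].iloc[0]
        assert dime["mean"] == pytest.approx(2.0)
        assert dime["se"] == pytest.approx(1.0 / np.sqrt(3))
        assert dime["n"] == 3
        dide = out[out["species"] == "DIDE"].iloc[0]
        assert pd.isna(dide["se"])  # single value: SE undefined
        assert dide["n"] == 1

    def test_empty_cells_yield_null(self):
        df = pd.DataFrame({"species": ["NEAL"], "takeoff_speed_ms1": [np.nan]})
        out = summarize(df, metrics=["takeoff_speed_ms1"])
        assert pd.isna(out.iloc[0]["mean"])
        assert out.iloc[0]["n"] == 0

    def test_fixture_regeneration_recovers_configured_means(self):
        """Monte-Carlo at n=500: the generator's reaction-time sample mean is
        within 3 SE of the truncated-normal generative mean."""
        from escapekin.synthetic_data import SpeciesProfile, generate_trials

        prof = SpeciesProfile(
            species_code="DIDE",
            mass_mean_g=89.0,
            mass_se_g=5.0,
            jump_propensity=1.0,
            reaction_mean_ms=18.8,
            reaction_se_ms=1.5,
            takeoff_mean_ms=77.8,
            takeoff_se_ms=6.0,
            takeoff_speed_mean_ms1=2.6,
            takeoff_speed_se_ms1=0.1,
            angle_mean_deg=35.3,
            angle_se_deg=3.8,
            fps=250,
            n_reference={"mass": 27, "reaction": 24, "takeoff": 24, "speed": 25, "angle": 25},
        )
        trials = generate_trials([prof], 500, seed=21, measurement_noise=False)
        out = summarize(trials, metrics=["reaction_ms"]).iloc[0]
        sd = prof.sd("reaction", prof.reaction_se_ms)
        a = (4.0 - 18.8) / sd
        true_mean = sps.truncnorm.mean(a, np.inf, loc=18.8, scale=sd)
        assert abs(out["mean"] - true_mean) <= 3 * out["se"]


class TestPermanovaTypeIError:
    def test_null_rejection_rate_near_alpha(self):
        """On label-free multivariate normal data the PERMANOVA rejects at
        about its nominal 5% level (1,000 replicates)."""
        rng = np.random.default_rng(123)
        labels = np.repeat(["a", "b", "c", "d"], 5)
        rejections = 0
        n_rep = 1000
        for i in range(n_rep):
            x = rng.normal(size=(20, 3))
            res = permanova(x, labels, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07
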