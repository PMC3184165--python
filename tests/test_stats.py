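"""Per-bin linear models, BH correction, correlations, ANOVA variants —
each against hand computations, algebraic identities, or an independent
library implementation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pdynims.stats import (
    adjust_bh,
    anova_tukey,
    build_design,
    correlate_with_behavior,
    fit_all_bins,
    fit_linear_model,
    repeated_measures_anova,
)


def _design(values_by_group, runs=(1,), bin_mz=712.4, region="SN_lateral"):
    rows = []
    i = 0
    for group, values in values_by_group.items():
        for v in values:
            for run in runs:
                rows.append(
                    {
                        "animal_id": f"{group}{i}",
                        "group": group,
                        "run_id": run,
                        "region": region,
                        "bin_mz": bin_mz,
                        "log2_ratio": v,
                    }
                )
            i += 1
    return pd.DataFrame(rows)


class TestLinearModel:
    def test_all_equal_gives_null_result(self):
        design = _design({"LC": [0.3] * 4, "HD": [0.3] * 5})
        res = fit_linear_model(design, 712.4)
        assert res.effect == 0.0
        assert res.p == 1.0

    def test_two_group_reduces_to_pooled_t_test(self, rng):
        a, b = rng.normal(0, 1, 5), rng.normal(0.8, 1, 6)
        design = _design({"LC": a, "HD": b})
        res = fit_linear_model(design, 712.4)
        t, p = sps.ttest_ind(b, a)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.effect == pytest.approx(b.mean() - a.mean(), abs=1e-12)

    def test_balanced_batch_offset_leaves_effect_unchanged(self, rng):
        a, b = rng.normal(0, 0.3, 4), rng.normal(0.8, 0.3, 5)
        clean = _design({"LC": a, "HD": b}, runs=(1, 2))
        offset = clean.copy()
        offset.loc[offset.run_id == 2, "log2_ratio"] += 1.7  # same shift in every group
        res_clean = fit_linear_model(clean, 712.4)
        res_offset = fit_linear_model(offset, 712.4)
        assert res_offset.effect == pytest.approx(res_clean.effect, abs=1e-10)

    def test_effect_recovery_under_cv_noise(self):
        """Planted 1.75-fold HD effect, 30% CV on 6-spot region means,
        n=5/group x 2 runs: the log2 estimate lands within +-0.25 of
        log2(1.75) in >=95% of seeds."""
        target = np.log2(1.75)
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            rows = []
            for g, fold, n in (("LC", 1.0, 5), ("LD", 1.0, 5), ("HD", 1.75, 5)):
                for i in range(n):
                    for run in (1, 2):
                        les = fold * r.lognormal(0, 0.3, 6).mean()
                        intact = r.lognormal(0, 0.3, 6).mean()
                        rows.append(
                            {
                                "animal_id": f"{g}{i}",
                                "group": g,
                                "run_id": run,
                                "region": "SN_lateral",
                                "bin_mz": 712.4,
                                "log2_ratio": np.log2(les / intact),
                            }
                        )
            res = fit_linear_model(pd.DataFrame(rows), 712.4)
            if abs(res.effect - target) <= 0.25:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_rank_deficient_design_names_columns(self):
        design = _design({"LC": [0.1, 0.2], "HD": [0.5, 0.6]})
        design["run_id"] = np.where(design["group"] == "HD", 2, 1)  # run == group
        with pytest.raises(ValueError, match="confounded.*run"):
            fit_linear_model(design, 712.4)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 treatment groups"):
            fit_linear_model(_design({"HD": [0.1, 0.2, 0.3]}), 712.4)


class TestBuildDesign:
    def test_log2_side_ratio(self):
        summaries = pd.DataFrame(
            [
                {"section_id": "a1_run1", "hemisphere": h, "region": "SN_lateral",
                 "bin_mz": 712.4, "mean_area": v, "n_spots": 6,
                 "animal_id": "a1", "run_id": 1}
                for h, v in (("intact", 2.0), ("lesioned", 8.0))
            ]
        )
        animals = pd.DataFrame([{"animal_id": "a1", "group": "HD"}])
        design = build_design(summaries, animals)
        assert design["log2_ratio"].iloc[0] == pytest.approx(2.0)

    def test_run_averaging(self):
        rows = []
        for run, ratio in ((1, 2.0), (2, 8.0)):
            for h, v in (("intact", 1.0), ("lesioned", ratio)):
                rows.append(
                    {"section_id": f"a1_run{run}", "hemisphere": h, "region": "SN_lateral",
                     "bin_mz": 712.4, "mean_area": v, "n_spots": 6,
                     "animal_id": "a1", "run_id": run}
                )
        animals = pd.DataFrame([{"animal_id": "a1", "group": "HD"}])
        design = build_design(pd.DataFrame(rows), animals, average_runs=True)
        assert len(design) == 1
        assert design["log2_ratio"].iloc[0] == pytest.approx(2.0)  # mean of log2(2), log2(8)


class TestAdjustBH:
    def test_hand_computed_example(self):
        out = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_bh([0.123])[0] == pytest.approx(0.123)

    def test_matches_step_up_oracle(self, rng):
        """Independent oracle: p*(m/rank) with running-min enforcement from
        the largest p downward."""
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 50))
            order = np.argsort(p)
            m = p.size
            adj_sorted = p[order] * m / np.arange(1, m + 1)
            adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(adj_sorted, 1.0)
            assert np.allclose(adjust_bh(p), expected, atol=1e-12)

    def test_permutation_equivariance_monotonicity_idempotence(self, rng):
        p = rng.uniform(0, 1, 30)
        adj = adjust_bh(p)
        assert np.all(adj >= p)
        perm = rng.permutation(30)
        assert np.allclose(adjust_bh(p[perm]), adj[perm])
        assert np.allclose(adjust_bh(adj), adjust_bh(adjust_bh(adj)))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            adjust_bh([0.5, 1.2])

    def test_null_rejection_rate(self):
        """Under a uniform null with m=1000 bins, the fraction of seeds
        with any BH rejection at alpha=0.05 stays near alpha."""
        n_seeds = 500
        any_rej = 0
        for seed in range(n_seeds):
            p = np.random.default_rng(seed).uniform(0, 1, 1000)
            if (adjust_bh(p) < 0.05).any():
                any_rej += 1
        rate = any_rej / n_seeds
        mc_sd = np.sqrt(0.05 * 0.95 / n_seeds)
        assert rate <= 0.05 + 3 * mc_sd


class TestCorrelation:
    def test_perfect_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = correlate_with_behavior(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_hand_computed_r(self):
        res = correlate_with_behavior([1, 2, 3], [2, 1, 3])
        assert res.r == pytest.approx(0.5)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            correlate_with_behavior([1, 1, 1], [1, 2, 3])

    def test_affine_invariance(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        base = correlate_with_behavior(x, y)
        trans = correlate_with_behavior(3 * x + 7, 0.5 * y - 2)
        assert trans.r == pytest.approx(base.r, abs=1e-12)
        assert trans.p == pytest.approx(base.p, abs=1e-12)

    def test_planted_rho_recovered_in_expectation(self):
        rho, n = 0.8, 10
        rs = []
        for seed in range(500):
            r = np.random.default_rng(seed)
            z = r.standard_normal(n)
            x = z
            y = rho * z + np.sqrt(1 - rho**2) * r.standard_normal(n)
            rs.append(correlate_with_behavior(x, y).r)
        assert np.mean(rs) == pytest.approx(rho, abs=0.1)


class TestAnovaTukey:
    def test_identical_groups(self):
        F, p, pairs = anova_tukey({"a": [1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
        assert F == 0.0 and p == 1.0
        assert (pairs["p_adj"] == 1.0).all()

    def test_two_groups_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
        F, p, _ = anova_tukey({"a": a, "b": b})
        t, tp = sps.ttest_ind(a, b)
        assert F == pytest.approx(t**2, abs=1e-10)
        assert p == pytest.approx(tp, abs=1e-10)

    def test_f_matches_sum_of_squares_oracle(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0], "c": [5.0, 5.0, 8.0]}
        F, _p, _ = anova_tukey(groups)
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_b = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_w = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        F_oracle = (ss_b / 2) / (ss_w / (allv.size - 3))
        assert F == pytest.approx(F_oracle, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_tukey({"a": [1.0], "b": [1.0, 2.0]})


class TestRepeatedMeasures:
    def test_identical_trajectories_null_group_effect(self):
        traj = np.array([1.0, 2.0, 3.0, 4.0])
        Y = np.tile(traj, (6, 1))
        res = repeated_measures_anova(Y, ["LD"] * 3 + ["HD"] * 3)
        assert res["p_group"] == 1.0

    def test_constant_offset_detected_without_interaction(self):
        traj = np.array([1.0, 2.0, 3.0, 4.0])
        Y = np.vstack([np.tile(traj, (3, 1)), np.tile(traj + 5.0, (3, 1))])
        res = repeated_measures_anova(Y, ["LD"] * 3 + ["HD"] * 3)
        assert res["p_group"] < 1e-6
        assert res["F_interaction"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_pingouin_mixed_anova(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(0, 1, (10, 4)) + np.arange(4) * 0.5
        Y[5:] += 2.0
        labels = ["LD"] * 5 + ["HD"] * 5
        res = repeated_measures_anova(Y, labels)
        df = pd.DataFrame(
            [
                {"subject": i, "session": s, "group": labels[i], "score": Y[i, s]}
                for i in range(10)
                for s in range(4)
            ]
        )
        ref = pg.mixed_anova(
            data=df, dv="score", within="session", subject="subject", between="group"
        ).set_index("Source")
        assert res["F_group"] == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert res["F_time"] == pytest.approx(ref.loc["session", "F"], rel=1e-6)
        assert res["F_interaction"] == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)
        assert res["p_group"] == pytest.approx(ref.loc["group", "p_unc"], rel=1e-6)

    def test_missing_cells_rejected(self):
        Y = np.ones((4, 3))
        Y[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            repeated_measures_anova(Y, ["a", "a", "b", "b"])

    def test_bonferroni_posthoc_factor(self):
        Y = np.vstack([np.zeros((3, 4)), np.ones((3, 4)) * np.arange(1, 5)])
        res = repeated_measures_anova(Y, ["LD"] * 3 + ["HD"] * 3)
        post = res["posthoc"]
        assert len(post) == 4
        assert np.allclose(post["p_adj"], np.minimum(post["p"] * 4, 1.0))


class TestFitAllBins:
    def test_bh_applied_across_bins(self, rng):
        frames = []
        for b, shift in ((700.0, 0.0), (800.0, 2.0)):
            d = _design(
                {"LC": rng.normal(0, 0.1, 5), "HD": rng.normal(shift, 0.1, 5)}, bin_mz=b
            )
            frames.append(d)
        out = fit_all_bins(pd.concat(frames, ignore_index=True))
        assert list(out["bin_mz"]) == [700.0, 800.0]
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert out.loc[1, "p_adj"] < 0.05
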