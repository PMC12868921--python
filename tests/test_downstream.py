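"""Drug response models, survival statistics and pan-cancer summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from brafsig import ClinicalTable, GroupAssignment, SimulationConfig
from brafsig.core import DrugResponseTable
from brafsig.downstream import (
    active_quiet_split,
    bh_adjust,
    category_enrichment,
    cox_fit,
    cox_models,
    drug_differential,
    logrank_test,
    merge_screens,
    pancancer_correlate,
    rcs_basis,
    tertile_split,
)
from brafsig.simulate import simulate_drug_response, simulate_survival

from test_derive import mutation_table
from test_simulate import _groups


class TestBhAdjust:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_and_singleton(self):
        assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels_and_is_monotone(self, pvals):
        from statsmodels.stats.multitest import multipletests

        mine = bh_adjust(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(mine, ref, atol=1e-12)
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(mine[order]) >= -1e-12)
        assert np.all(mine <= 1.0)


def _drug_table(values, samples, categories=None):
    drugs = [f"d{i}" for i in range(values.shape[0])]
    categories = categories or ["cat"] * len(drugs)
    ic50 = pd.DataFrame(values, index=drugs, columns=samples)
    ann = pd.DataFrame(
        {"target": categories, "target_category": categories}, index=drugs
    )
    return DrugResponseTable(ic50, ann)


class TestDrugDifferential:
    def test_noiseless_shift_recovered_exactly(self):
        groups = _groups(8, prefix="c")
        samples = groups.sample_ids
        vals = np.zeros((1, 8))
        vals[0, :4] = -2.0  # high-activity lines
        drugs = _drug_table(vals, samples)
        out = drug_differential(drugs, groups)
        assert out.loc["d0", "delta_log2_ic50"] == pytest.approx(-2.0, abs=1e-12)
        assert out.loc["d0", "direction"] == "sensitive"

    def test_coefficients_match_normal_equations_on_toy_design(self):
        groups = _groups(6, prefix="c")
        samples = groups.sample_ids
        y = np.array([[1.3, 0.7, 2.1, 3.0, 4.2, 2.8]])
        drugs = _drug_table(y, samples)
        mutants, wt = samples[:2] + samples[4:5], samples[2:4] + samples[5:]
        mt = mutation_table(mutants, wt)
        out = drug_differential(drugs, groups, mt)

        X = np.column_stack([
            np.ones(6),
            [1, 1, 1, 0, 0, 0],
            [1 if s in set(mutants) else 0 for s in samples],
        ])
        beta = np.linalg.solve(X.T @ X, X.T @ y[0])
        resid = y[0] - X @ beta
        sigma2 = resid @ resid / 3
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        p = 2 * stats.t.sf(abs(t), 3)
        assert out.loc["d0", "delta_log2_ic50"] == pytest.approx(beta[1], abs=1e-10)
        assert out.loc["d0", "p_value"] == pytest.approx(p, abs=1e-10)

    def test_collinear_design_flagged(self):
        groups = _groups(8, prefix="c")
        samples = groups.sample_ids
        drugs = _drug_table(np.ones((1, 8)), samples)
        mt = mutation_table(samples[:4], samples[4:])  # mutation == group
        out = drug_differential(drugs, groups, mt)
        assert out.loc["d0", "fit"] == "unestimable"

    def test_sparse_drug_skipped(self):
        groups = _groups(8, prefix="c")
        samples = groups.sample_ids
        vals = np.full((1, 8), np.nan)
        vals[0, :3] = 1.0
        drugs = _drug_table(vals, samples)
        out = drug_differential(drugs, groups)
        assert out.loc["d0", "fit"] == "skipped"

    def test_planted_category_flagged_on_simulated_screen(self):
        cfg = SimulationConfig(seed=13, n_genes=50, n_samples=60)
        groups = _groups(60)
        drugs = simulate_drug_response(cfg, groups)
        out = drug_differential(drugs, groups)
        planted = out[out["target_category"] == cfg.drugs.sensitive_category]
        others = out[out["target_category"] != cfg.drugs.sensitive_category]
        assert planted["hit"].all() and (planted["direction"] == "sensitive").all()
        assert not others["hit"].any()


class TestMergeScreens:
    def test_smaller_raw_p_wins(self):
        a = pd.DataFrame({"p_value": [0.01], "delta_log2_ic50": [1.0], "fit": ["ok"]},
                         index=["d0"])
        b = pd.DataFrame({"p_value": [0.2], "delta_log2_ic50": [9.9], "fit": ["ok"]},
                         index=["d0"])
        merged = merge_screens([b, a])
        assert merged.loc["d0", "delta_log2_ic50"] == 1.0


class TestCategoryEnrichment:
    def test_hand_example(self):
        tested = [f"d{i}" for i in range(20)]
        ann = pd.Series(["hit_cat"] * 5 + ["other"] * 15, index=tested)
        hits = ["d0", "d1", "d2", "d5"]  # 3 of 4 hits in the 5-drug category
        out = category_enrichment(hits, tested, ann)
        assert out.loc["hit_cat", "p_value"] == pytest.approx(155 / 4845, abs=1e-12)

    def test_empty_hits_and_full_category(self):
        tested = [f"d{i}" for i in range(6)]
        ann = pd.Series(["cat"] * 6, index=tested)
        out = category_enrichment([], tested, ann)
        assert (out["p_value"] == 1.0).all()
        out2 = category_enrichment(tested[:3], tested, ann)
        assert out2.loc["cat", "p_value"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        tested = [f"d{i}" for i in range(10)]
        ann = pd.Series(["A"] * 4 + ["B"] * 6, index=tested)
        hits = ["d0", "d1", "d4", "d5"]
        out = category_enrichment(hits, tested, ann)
        n = len(hits)
        for cat, K_members in (("A", tested[:4]), ("B", tested[4:])):
            k_obs = len(set(hits) & set(K_members))
            count = sum(
                1
                for draw in itertools.combinations(tested, n)
                if len(set(draw) & set(K_members)) >= k_obs
            )
            expected = count / len(list(itertools.combinations(tested, n)))
            assert out.loc[cat, "p_value"] == pytest.approx(expected, abs=1e-12)

    def test_stray_hit_rejected(self):
        with pytest.raises(ValueError, match="not among"):
            category_enrichment(["x"], ["d0"], pd.Series({"d0": "cat"}))


class TestTertileSplit:
    def test_one_to_nine(self):
        s = pd.Series(np.arange(1.0, 10.0), index=[f"s{i}" for i in range(9)])
        out = tertile_split(s)
        assert out.samples_with("low") == ["s0", "s1", "s2"]
        assert out.samples_with("mid") == ["s3", "s4", "s5"]
        assert out.samples_with("high") == ["s6", "s7", "s8"]

    def test_permutation_invariance(self, rng):
        s = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        base = tertile_split(s)
        perm = s.sample(frac=1.0, random_state=1)
        shuffled = tertile_split(perm)
        assert (base.labels.loc[s.index] == shuffled.labels.loc[s.index]).all()

    def test_balanced_sizes_without_ties(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 40))
            s = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
            sizes = tertile_split(s).labels.value_counts()
            assert sizes.max() - sizes.min() <= 1

    def test_constant_rejected(self):
        s = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        with pytest.raises(ValueError, match="identical"):
            tertile_split(s)


def _clinical(times, events, ids=None, **extra):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return ClinicalTable(pd.DataFrame({
        "sample_id": ids, "os_time": times, "os_event": events, **extra
    }))


class TestLogrank:
    def test_four_subject_hand_table(self):
        clin = _clinical([1, 2, 3, 4], [1, 1, 1, 1])
        groups = pd.Series(["A", "B", "A", "B"], index=clin.sample_ids)
        stat, p = logrank_test(groups, clin)
        assert stat == pytest.approx(0.6153846154, abs=1e-8)

    def test_balanced_duplicated_groups_score_zero(self):
        clin = _clinical([1, 1, 2, 2, 3, 3], [1, 1, 1, 1, 1, 1])
        groups = pd.Series(["A", "B"] * 3, index=clin.sample_ids)
        stat, _ = logrank_test(groups, clin)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_time_rescaling(self, rng):
        times = rng.exponential(100, size=40)
        events = rng.integers(0, 2, size=40)
        events[0] = 1
        groups = pd.Series(
            ["A", "B"] * 20, index=[f"s{i}" for i in range(40)]
        )
        s1, _ = logrank_test(groups, _clinical(times, events))
        s2, _ = logrank_test(groups, _clinical(times * 365.0, events))
        assert s1 == pytest.approx(s2, rel=1e-10)

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        for k in (2, 3):
            n = 60
            times = rng.exponential(50, size=n).round(1) + 1
            events = rng.integers(0, 2, size=n)
            events[:5] = 1
            lab = rng.integers(0, k, size=n)
            groups = pd.Series(
                [f"g{v}" for v in lab], index=[f"s{i}" for i in range(n)]
            )
            stat, p = logrank_test(groups, _clinical(times, events))
            ref = multivariate_logrank_test(times, lab, events)
            assert stat == pytest.approx(ref.test_statistic, rel=1e-8)
            assert p == pytest.approx(ref.p_value, rel=1e-6)

    def test_zero_events_rejected(self):
        clin = _clinical([1, 2], [0, 0])
        groups = pd.Series(["A", "B"], index=clin.sample_ids)
        with pytest.raises(ValueError, match="events"):
            logrank_test(groups, clin)


class TestRcsBasis:
    def test_three_knots_give_two_columns(self, rng):
        x = rng.normal(size=100)
        basis = rcs_basis(x, n_knots=3)
        assert list(basis.columns) == ["x", "spline_1"]
        assert len(basis.attrs["knots"]) == 3

    def test_linear_beyond_boundary_knots(self, rng):
        x = np.linspace(0, 10, 200)
        basis = rcs_basis(x, knots=[2.0, 5.0, 8.0])
        s = basis["spline_1"].to_numpy()
        # second differences vanish where x < first knot and x > last knot
        left = s[x < 2.0]
        right = s[x > 8.0]
        assert np.allclose(np.diff(left, 2), 0.0, atol=1e-10)
        assert np.allclose(np.diff(right, 2), 0.0, atol=1e-8)

    def test_columns_linearly_independent(self, rng):
        x = rng.normal(size=80)
        basis = rcs_basis(x, n_knots=3)
        assert np.linalg.matrix_rank(
            np.column_stack([np.ones(80), basis.to_numpy()])
        ) == 3

    def test_linear_response_leaves_nonlinear_term_null(self, rng):
        x = rng.uniform(0, 10, size=300)
        y = 2.0 + 0.5 * x + rng.normal(scale=0.05, size=300)
        basis = rcs_basis(x, n_knots=3)
        A = np.column_stack([np.ones(300), basis.to_numpy()])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert abs(coef[2]) < 0.05

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            rcs_basis([1.0, 1.0, 2.0], n_knots=3)


class TestCox:
    def test_recovers_planted_hazard_ratio(self):
        cfg = SimulationConfig(seed=21, n_genes=50, n_samples=300)
        cfg.survival.hazard_ratios = {"high": 2.0, "low": 1.0}
        groups = _groups(300)
        clin = simulate_survival(cfg, groups)
        df = clin.table.copy()
        df["high"] = (df["group"] == "high").astype(float)
        res = cox_fit(df.set_index("sample_id"), "os_time", "os_event", ["high"])
        est = res.terms.loc["high"]
        assert abs(est["coef"] - np.log(2.0)) < 2 * est["se"]
        assert est["ci_low"] < est["hr"] < est["ci_high"]

    def test_additive_data_give_null_interaction(self):
        cfg = SimulationConfig(seed=22, n_genes=50, n_samples=400)
        cfg.survival.hazard_ratios = {"high": 2.0, "low": 1.0}
        groups = _groups(400)
        clin = simulate_survival(cfg, groups)
        rng = np.random.default_rng(0)
        samples = clin.sample_ids
        mutants = [s for s in samples if rng.random() < 0.4]
        wt = [s for s in samples if s not in set(mutants)]
        mt = mutation_table(mutants, wt)
        vocab_groups = GroupAssignment(
            pd.Series([("high" if s in set(_groups(400).samples_with("high")) else "low")
                       for s in samples], index=samples),
            ("low", "high"),
        )
        res = cox_models(clin, vocab_groups, mt, interaction=True)
        inter = res.terms.loc["group_high_x_mutant"]
        assert abs(inter["coef"]) < 2 * inter["se"]

    def test_spline_age_block_fits(self):
        cfg = SimulationConfig(seed=23, n_genes=50, n_samples=200)
        clin = simulate_survival(cfg, _groups(200))
        res = cox_models(clin, covariates=["age"], spline_age=True)
        assert {"age", "age_spline_1"} <= set(res.terms.index)

    def test_univariate_mode_fits_blocks_separately(self):
        cfg = SimulationConfig(seed=24, n_genes=50, n_samples=200)
        cfg.survival.hazard_ratios = {"high": 2.0, "low": 1.0}
        groups = _groups(200)
        clin = simulate_survival(cfg, groups)
        mt = mutation_table(clin.sample_ids[:50], clin.sample_ids[50:])
        multi = cox_models(clin, groups, mt, mode="multivariate")
        uni = cox_models(clin, groups, mt, mode="univariate")
        assert set(multi.terms.index) == set(uni.terms.index)
        assert uni.logrank_p is not None and uni.logrank_p < 0.05


class TestPanCancer:
    def test_monotone_and_antimonotone(self):
        df = pd.DataFrame({
            "mean_index": [1.0, 2.0, 3.0, 4.0],
            "mutation_ratio": [0.1, 0.2, 0.3, 0.4],
        }, index=list("abcd"))
        rho, _ = pancancer_correlate(df)
        assert rho == pytest.approx(1.0)
        df["mutation_ratio"] = df["mutation_ratio"].iloc[::-1].to_numpy()
        rho, _ = pancancer_correlate(df)
        assert rho == pytest.approx(-1.0)

    def test_noisy_monotone_recovery_across_seeds(self):
        rhos = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ratio = rng.uniform(0, 0.6, size=30)
            index = ratio + rng.normal(scale=0.12, size=30)
            df = pd.DataFrame({
                "mean_index": index, "mutation_ratio": ratio,
            }, index=[f"c{i}" for i in range(30)])
            true_rho = stats.spearmanr(ratio, ratio + 0 * index).statistic
            rhos.append(pancancer_correlate(df)[0])
        # planted monotone relation, noise attenuates toward ~0.8
        assert 0.6 < np.mean(rhos) < 1.0

    def test_too_few_or_constant_rejected(self):
        df = pd.DataFrame({"mean_index": [1, 2, 3], "mutation_ratio": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="4 cohorts"):
            pancancer_correlate(df)
        df2 = pd.DataFrame({
            "mean_index": [1.0] * 5, "mutation_ratio": [0.1, 0.2, 0.3, 0.4, 0.5],
        })
        with pytest.raises(ValueError, match="constant"):
            pancancer_correlate(df2)


class TestActiveQuietSplit:
    def test_bimodal_mixture_recovered(self):
        hits = 0
        total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            lo = rng.normal(-1.0, 0.3, size=15)
            hi = rng.normal(1.0, 0.3, size=15)
            s = pd.Series(
                np.concatenate([lo, hi]), index=[f"c{i}" for i in range(30)]
            )
            labels, cut = active_quiet_split(s)
            assert -0.5 < cut < 0.5
            truth = np.array(["quiet"] * 15 + ["active"] * 15)
            hits += (labels.to_numpy() == truth).sum()
            total += 30
        assert hits / total >= 0.95

    def test_unimodal_falls_back_to_median(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.normal(size=40), index=[f"c{i}" for i in range(40)])
        with pytest.warns(UserWarning, match="unimodal"):
            labels, cut = active_quiet_split(s)
        assert cut == pytest.approx(float(np.median(s)), abs=1e-12)
        assert set(labels) == {"active", "quiet"}

    def test_higher_mean_group_named_active(self):
        rng = np.random.default_rng(2)
        s = pd.Series(
            np.concatenate([rng.normal(-2, 0.2, 10), rng.normal(2, 0.2, 10)]),
            index=[f"c{i}" for i in range(20)],
        )
        labels, _ = active_quiet_split(s)
        assert s[labels == "active"].mean() > s[labels == "quiet"].mean()
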