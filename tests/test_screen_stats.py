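import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats

from shapescreen import synthetic_data as sd
from shapescreen.screen_stats import (StatsConfig, adjust_fdr,
                                      aggregate_condition, classify_hits,
                                      differential_test, fit_variance_prior,
                                      normalize_experiment, run_screen_stats,
                                      validate_gene, validate_genes)


def make_per_cell(conditions, control=("Scrambled", "ctrl")):
    """Per-cell table from {(gene, sirna, experiment): [circularities]}."""
    rows = []
    for (gene, sirna, exp), values in conditions.items():
        for v in values:
            rows.append({"gene": gene, "sirna": sirna, "experiment": exp,
                         "circularity": v})
    return pd.DataFrame(rows)


class TestAggregate:
    def test_arithmetic_mean(self):
        table = make_per_cell({("A", "s1", 1): [0.2, 0.4, 0.6],
                               ("Scrambled", "ctrl", 1): [0.5]})
        agg = aggregate_condition(table)
        row = agg.loc[agg["gene"] == "A"].iloc[0]
        assert row["mean_circularity"] == pytest.approx(0.4)
        assert row["n_cells"] == 3

    def test_pools_across_fields(self):
        rows = []
        for field in range(3):
            for _ in range(10):
                rows.append({"gene": "A", "sirna": "s1", "experiment": 1,
                             "field": field, "circularity": 0.5})
        rows.append({"gene": "Scrambled", "sirna": "ctrl", "experiment": 1,
                     "field": 0, "circularity": 0.5})
        agg = aggregate_condition(pd.DataFrame(rows))
        assert agg.loc[agg["gene"] == "A", "n_cells"].iloc[0] == 30
        assert len(agg) == 2

    def test_preaggregated_passthrough(self):
        table = sd.generate_screen_tables(sd.ScreenDesign(n_genes=4, seed=0))
        agg = aggregate_condition(table)
        pd.testing.assert_frame_equal(
            agg[["gene", "sirna", "experiment", "mean_circularity"]],
            table[["gene", "sirna", "experiment", "mean_circularity"]])

    def test_missing_control_names_experiment(self):
        table = make_per_cell({("A", "s1", 1): [0.4],
                               ("A", "s1", 2): [0.4],
                               ("Scrambled", "ctrl", 1): [0.5]})
        with pytest.raises(ValueError, match=r"\[2\]"):
            aggregate_condition(table)


class TestNormalize:
    @staticmethod
    def agg(values):
        rows = []
        for (gene, sirna, exp), mean in values.items():
            rows.append({"gene": gene, "sirna": sirna, "experiment": exp,
                         "mean_circularity": mean})
        return pd.DataFrame(rows)

    def test_all_equal_control_gives_zero(self):
        norm = normalize_experiment(self.agg({
            ("A", "s1", 1): 0.5, ("Scrambled", "ctrl", 1): 0.5}))
        assert (norm["log2_ratio"] == 0.0).all()

    def test_double_control_gives_plus_one(self):
        norm = normalize_experiment(self.agg({
            ("A", "s1", 1): 1.0, ("Scrambled", "ctrl", 1): 0.5}))
        assert norm.loc[norm["gene"] == "A", "log2_ratio"].iloc[0] == 1.0

    def test_control_maps_to_exact_zero(self):
        norm = normalize_experiment(self.agg({
            ("A", "s1", 1): 0.71, ("Scrambled", "ctrl", 1): 0.537}))
        ctrl = norm.loc[norm["gene"] == "Scrambled", "log2_ratio"]
        assert (ctrl == 0.0).all()

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            normalize_experiment(self.agg({
                ("A", "s1", 1): -0.1, ("Scrambled", "ctrl", 1): 0.5}))

    @settings(max_examples=30, deadline=None)
    @given(b=st.floats(0.01, 100.0))
    def test_batch_invariance(self, b):
        base = self.agg({("A", "s1", 1): 0.62, ("B", "s1", 1): 0.41,
                         ("Scrambled", "ctrl", 1): 0.55,
                         ("A", "s1", 2): 0.58, ("B", "s1", 2): 0.44,
                         ("Scrambled", "ctrl", 2): 0.52})
        scaled = base.copy()
        exp1 = scaled["experiment"] == 1
        scaled.loc[exp1, "mean_circularity"] *= b
        a = normalize_experiment(base)["log2_ratio"].to_numpy()
        s = normalize_experiment(scaled)["log2_ratio"].to_numpy()
        np.testing.assert_allclose(a, s, atol=1e-12)


def transcribed_moderated_t(values_by_condition):
    """Literal transcription of the shrinkage formulas (independent oracle).

    Solves the trigamma equation by bisection (brentq) instead of Newton
    and computes every quantity per condition from scratch.
    """
    names = list(values_by_condition)
    n = {k: len(v) for k, v in values_by_condition.items()}
    mean = {k: float(np.mean(v)) for k, v in values_by_condition.items()}
    s2 = {k: float(np.var(v, ddof=1)) for k, v in values_by_condition.items()}
    dg = {k: n[k] - 1 for k in names}
    d_resid = dg[names[0]]

    e = [np.log(s2[k]) - special.digamma(d_resid / 2.0)
         + np.log(d_resid / 2.0) for k in names]
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    target = e_var - float(special.polygamma(1, d_resid / 2.0))
    if target > 0:
        half_d0 = optimize.brentq(
            lambda y: float(special.polygamma(1, y)) - target, 1e-8, 1e8,
            xtol=1e-14, rtol=8.9e-16, maxiter=500)
        d0 = 2.0 * half_d0
        s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0)
                          - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0 = float(np.exp(e_mean))

    out = {}
    for k in names:
        if np.isinf(d0):
            s2_tilde = s0
        else:
            s2_tilde = (d0 * s0 + dg[k] * s2[k]) / (d0 + dg[k])
        t = mean[k] / np.sqrt(s2_tilde / n[k])
        df = d0 + dg[k]
        p = 2.0 * stats.t.sf(abs(t), df)
        out[k] = (t, df, p)
    return out


def norm_frame(values_by_condition):
    rows = []
    for (gene, sirna), values in values_by_condition.items():
        for exp, v in enumerate(values, start=1):
            rows.append({"gene": gene, "sirna": sirna, "experiment": exp,
                         "log2_ratio": v})
    return pd.DataFrame(rows)


class TestDifferentialTest:
    def test_null_condition(self, rng):
        data = {("A", "s1"): [0.0, 0.0, 0.0]}
        for i in range(9):
            data[(f"N{i}", "s1")] = list(rng.normal(0, 0.2, 3))
        res, _ = differential_test(norm_frame(data))
        row = res.loc[res["gene"] == "A"].iloc[0]
        assert row["diff_circularity"] == 0.0
        assert row["p_value"] > 0.9

    def test_prior_df_zero_equals_student(self, rng):
        data = {(f"G{i}", "s1"): list(rng.normal(0, 0.3, 4))
                for i in range(12)}
        frame = norm_frame(data)
        mod, _ = differential_test(
            frame, StatsConfig(test="moderated_t", prior_df=0))
        stu, _ = differential_test(frame, StatsConfig(test="student_t"))
        np.testing.assert_allclose(mod["p_value"], stu["p_value"], atol=1e-12)
        np.testing.assert_allclose(mod["t"], stu["t"], atol=1e-12)

    def test_matches_literal_transcription(self, rng):
        # 25 random small tables, tolerance 1e-12 on t and p
        for trial in range(25):
            local = np.random.default_rng(1000 + trial)
            n_cond = int(local.integers(5, 15))
            n_rep = int(local.integers(3, 6))
            data = {(f"G{i}", "s1"): list(local.normal(0, 0.5, n_rep))
                    for i in range(n_cond)}
            res, _ = differential_test(norm_frame(data))
            oracle = transcribed_moderated_t(
                {k: v for k, v in data.items()})
            for _, row in res.iterrows():
                t, df, p = oracle[(row["gene"], row["sirna"])]
                assert abs(row["t"] - t) < 1e-12
                assert abs(row["p_value"] - p) < 1e-12

    def test_too_few_replicates(self):
        with pytest.raises(ValueError, match="at least 2"):
            differential_test(norm_frame({("A", "s1"): [0.5]}))

    def test_zero_variance_student_error(self):
        frame = norm_frame({("A", "s1"): [0.5, 0.5, 0.5],
                            ("B", "s1"): [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="moderated_t"):
            differential_test(frame, StatsConfig(test="student_t"))

    def test_zero_variance_allowed_moderated(self):
        frame = norm_frame({("A", "s1"): [0.5, 0.5, 0.5],
                            ("B", "s1"): [0.1, 0.2, 0.3],
                            ("C", "s1"): [-0.1, 0.05, 0.2]})
        res, prior = differential_test(frame)
        assert np.isfinite(res["p_value"]).all()
        assert prior.prior_var > 0

    def test_control_is_fixed_point(self):
        frame = norm_frame({("Scrambled", "ctrl"): [0.0, 0.0, 0.0],
                            ("A", "s1"): [0.1, 0.3, 0.2],
                            ("B", "s1"): [0.0, -0.2, -0.1]})
        res, _ = differential_test(frame)
        ctrl = res.loc[res["gene"] == "Scrambled"].iloc[0]
        assert ctrl["diff_circularity"] == 0.0
        assert ctrl["p_value"] == 1.0


class TestVariancePrior:
    def test_homogeneous_variances_fall_back_to_infinity(self, rng):
        s2 = np.full(100, 0.04)
        prior = fit_variance_prior(s2, residual_df=2)
        assert np.isinf(prior.prior_df)
        assert prior.fallback_used
        # moment-matched scale under the scaled-chi-square model with dg=2
        expected = 0.04 * np.exp(-special.digamma(1.0))
        assert prior.prior_var == pytest.approx(expected)

    def test_heterogeneous_variances_finite_prior(self, rng):
        true_d0, true_s0 = 6.0, 0.05
        s2 = true_s0 * true_d0 / rng.chisquare(true_d0, 5000)
        s2 = s2 * rng.chisquare(3, 5000) / 3.0
        prior = fit_variance_prior(s2, residual_df=3)
        assert not prior.fallback_used
        assert prior.prior_df == pytest.approx(true_d0, rel=0.3)
        assert prior.prior_var == pytest.approx(true_s0, rel=0.15)


def naive_bh(p):
    """Two-pass textbook Benjamini-Hochberg oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    prev = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        value = min(p[idx] * m / rank_from_top, prev, 1.0)
        adjusted[idx] = value
        prev = value
    return adjusted


class TestAdjustFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.2]) == pytest.approx([0.2])

    def test_matches_naive_oracle(self, rng):
        p = rng.uniform(0, 1, 100)
        np.testing.assert_allclose(adjust_fdr(p), naive_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])

    @settings(max_examples=30, deadline=None)
    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_properties(self, p):
        q = adjust_fdr(p)
        p = np.asarray(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        # order preservation
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestClassifyHits:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(rows, columns=["gene", "sirna",
                                           "diff_circularity", "p_value"])

    def test_paper_style_cases(self):
        # strong positive / borderline / null trios, FDR precomputed
        results = pd.DataFrame([
            {"gene": "Tiam1", "sirna": "#1", "diff_circularity": 2.73,
             "p_value": 1e-16, "fdr": 1e-14},
            {"gene": "MEK3", "sirna": "#2", "diff_circularity": 0.58,
             "p_value": 0.05, "fdr": 0.07},
            {"gene": "JNK2", "sirna": "#1", "diff_circularity": -0.11,
             "p_value": 0.70, "fdr": 0.75},
        ])
        out = results.copy()
        sig = out["fdr"] < 0.05
        out["hit_class"] = "not_significant"
        out.loc[sig & (out["diff_circularity"] > 0), "hit_class"] = "positive"
        assert list(out["hit_class"]) == ["positive", "not_significant",
                                          "not_significant"]

    def test_classification_via_pipeline(self):
        frame = norm_frame({("Scrambled", "ctrl"): [0.0, 0.0, 0.0],
                            ("UP", "s1"): [2.0, 2.1, 1.9],
                            ("DOWN", "s1"): [-2.0, -2.1, -1.9],
                            ("NULL", "s1"): [0.01, -0.02, 0.01]})
        res, _ = differential_test(frame)
        res = classify_hits(res)
        by_gene = res.set_index("gene")["hit_class"]
        assert by_gene["UP"] == "positive"
        assert by_gene["DOWN"] == "negative"
        assert by_gene["NULL"] == "not_significant"
        assert by_gene["Scrambled"] == "not_significant"
        assert (res["fdr"] >= res["p_value"] - 1e-15).all()


class TestValidateGene:
    @staticmethod
    def gene_frame(classes):
        return pd.DataFrame([
            {"gene": "X", "sirna": f"#{i+1}", "hit_class": c}
            for i, c in enumerate(classes)])

    def test_three_of_three_positive(self):
        frame = self.gene_frame(["positive"] * 3)
        assert validate_gene(frame) == "validated"

    def test_none_significant_is_false_positive(self):
        frame = self.gene_frame(["not_significant"] * 3)
        assert validate_gene(frame) == "false_positive"

    def test_single_significant_is_false_positive(self):
        frame = self.gene_frame(["not_significant", "not_significant",
                                 "positive"])
        assert validate_gene(frame) == "false_positive"

    def test_opposite_signs_do_not_validate(self):
        frame = self.gene_frame(["positive", "negative", "not_significant"])
        assert validate_gene(frame) == "false_positive"

    def test_two_of_three_same_sign(self):
        frame = self.gene_frame(["negative", "negative", "not_significant"])
        assert validate_gene(frame) == "validated"

    def test_validate_genes_table(self):
        res = pd.DataFrame([
            {"gene": "A", "sirna": "s1", "hit_class": "positive"},
            {"gene": "A", "sirna": "s2", "hit_class": "positive"},
            {"gene": "A", "sirna": "s3", "hit_class": "not_significant"},
            {"gene": "B", "sirna": "s1", "hit_class": "positive"},
            {"gene": "B", "sirna": "s2", "hit_class": "not_significant"},
            {"gene": "B", "sirna": "s3", "hit_class": "not_significant"},
            {"gene": "Scrambled", "sirna": "ctrl",
             "hit_class": "not_significant"},
        ])
        table = validate_genes(res)
        status = table.set_index("gene")["status"]
        assert status["A"] == "validated"
        assert status["B"] == "false_positive"
        assert "Scrambled" not in status.index


class TestEndToEndTables:
    def test_planted_effects_recovered(self):
        effect_map = {"G001": 2.0, "G002": -1.8}
        design = sd.ScreenDesign(n_genes=20, noise_sd=0.2, seed=11,
                                 effect_map=effect_map)
        res, val, _ = run_screen_stats(sd.generate_screen_tables(design))
        status = val.set_index("gene")["status"]
        assert status["G001"] == "validated"
        assert status["G002"] == "validated"
        up = res.loc[res["gene"] == "G001"]
        assert (up["hit_class"] == "positive").all()
        assert up["diff_circularity"].mean() == pytest.approx(2.0, abs=0.4)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            StatsConfig(alpha=1.5)
        with pytest.raises(ValueError):
            StatsConfig(test="anova")
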