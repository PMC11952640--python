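"""Association engines and strategy runners."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multigwas.assoc import (
    LinearGWAS,
    LogisticGWAS,
    maf_inclusion,
    run_gwas_linear,
    run_gwas_logistic,
    run_strategy_pergroup,
    run_strategy_pooled,
)
from multigwas.popsim import GenotypePanel, LDBlockSpec, VariantTable, simulate_frequencies, simulate_panel
from multigwas.structure import PCSet, compute_pcs


def _toy_table(freqs_by_group: dict) -> VariantTable:
    m = len(next(iter(freqs_by_group.values())))
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(m)],
            "chrom": "1",
            "pos_bp": 1_000 * (np.arange(m) + 1),
            "allele_ref": "A",
            "allele_alt": "G",
            "ancestral_freq": 0.5,
            "genetic_pos_cM": np.arange(m, dtype=float),
        }
    )
    return VariantTable(variants, pd.DataFrame(freqs_by_group))


class TestMafInclusion:
    def test_any_group_includes_one_common(self):
        vt = _toy_table({"A": [0.005], "B": [0.20]})
        assert maf_inclusion(vt, "any_group") == ["v0"]

    def test_all_groups_excludes_rare_anywhere(self):
        vt = _toy_table({"A": [0.005], "B": [0.20]})
        assert maf_inclusion(vt, "all_groups") == []

    def test_minor_allele_folding(self):
        vt = _toy_table({"A": [0.995]})
        assert maf_inclusion(vt, "this_group", group="A") == []

    def test_threshold_boundary_strict(self):
        vt = _toy_table({"A": [0.01, 0.011]})
        assert maf_inclusion(vt, "this_group", group="A") == ["v1"]


def _ols_oracle(y, X):
    """Naive matrix-inversion OLS with normal-based Wald p for the last column."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(sigma2 * XtX_inv[-1, -1])
    return beta[-1], se


class TestLinearEngine:
    def test_exact_fit_recovers_coefficient(self, independent_panel):
        y = 0.5 * independent_panel.dosage[:, 3].astype(float)
        res = run_gwas_linear(independent_panel, y, variant_ids=[independent_panel.variants.variant_id[3]])
        row = res.frame.iloc[0]
        assert abs(row["beta"] - 0.5) < 1e-12
        assert row["p"] < 1e-300 or row["p"] == 0.0

    def test_matches_matrix_inversion_oracle(self):
        rng = np.random.default_rng(70)
        vt = simulate_frequencies(100, ["EUR"], {"EUR": 0.0}, seed=71)
        panel = simulate_panel(vt, {"EUR": 120}, LDBlockSpec(rho=0.0), seed=72)
        cov = rng.normal(size=(120, 3))
        y = rng.normal(size=120)
        res = LinearGWAS(y, panel, cov).fit()
        for col in rng.choice(panel.n_variants, size=25, replace=False):
            g = panel.dosage[:, col].astype(float)
            if g.var() < 1e-12:
                continue
            X = np.column_stack([np.ones(120), cov, g])
            b, se = _ols_oracle(y, X)
            row = res.frame.iloc[col]
            assert abs(row["beta"] - b) < 1e-8
            assert abs(row["se"] - se) < 1e-8

    def test_wald_identity(self, independent_panel):
        y = np.random.default_rng(73).normal(size=independent_panel.n_samples)
        res = run_gwas_linear(independent_panel, y)
        f = res.frame[res.frame["converged"]]
        p_check = 2 * stats.norm.sf(np.abs(f["beta"] / f["se"]))
        np.testing.assert_allclose(f["p"], p_check, atol=1e-10)

    def test_permutation_null_type1(self, independent_panel):
        rng = np.random.default_rng(74)
        y = rng.permutation(independent_panel.dosage[:, 0].astype(float))
        res = run_gwas_linear(independent_panel, y)
        p = res.frame["p"].dropna()
        rate = (p <= 0.05).mean()
        band = 3 * np.sqrt(0.05 * 0.95 / len(p))
        assert abs(rate - 0.05) < band + 0.005

    def test_null_pvalues_uniform(self, independent_panel):
        y = np.random.default_rng(75).normal(size=independent_panel.n_samples)
        res = run_gwas_linear(independent_panel, y)
        ks = stats.kstest(res.frame["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_zero_variance_dosage_flagged(self):
        vt = _toy_table({"A": [0.5, 0.5]})
        dosage = np.zeros((50, 2), dtype=np.int8)
        dosage[:, 1] = np.random.default_rng(76).integers(0, 3, 50)
        panel = GenotypePanel(
            dosage=dosage,
            sample_id=np.array([f"S{i}" for i in range(50)]),
            group_label=np.array(["A"] * 50),
            variants=vt,
            age=np.zeros(50),
            sex=np.zeros(50, dtype=np.int8),
        )
        y = np.random.default_rng(77).normal(size=50)
        res = run_gwas_linear(panel, y)
        assert not res.frame.iloc[0]["converged"]
        assert np.isnan(res.frame.iloc[0]["p"])
        assert res.frame.iloc[1]["converged"]

    def test_rank_deficient_covariates_rejected(self, independent_panel):
        cov = np.ones((independent_panel.n_samples, 2))  # collinear with intercept
        y = np.zeros(independent_panel.n_samples)
        with pytest.raises(ValueError):
            LinearGWAS(y, independent_panel, cov)


class TestLogisticEngine:
    def test_matches_contingency_table_log_or(self):
        rng = np.random.default_rng(80)
        g = rng.integers(0, 2, size=2_000)  # binary dosage {0,1}
        p = np.where(g == 1, 0.3, 0.15)
        y = (rng.random(2_000) < p).astype(int)
        vt = _toy_table({"A": [0.3]})
        panel = GenotypePanel(
            dosage=g[:, None].astype(np.int8),
            sample_id=np.array([f"S{i}" for i in range(2_000)]),
            group_label=np.array(["A"] * 2_000),
            variants=vt,
            age=np.zeros(2_000),
            sex=np.zeros(2_000, dtype=np.int8),
        )
        res = run_gwas_logistic(panel, y)
        a = ((y == 1) & (g == 1)).sum()
        b = ((y == 0) & (g == 1)).sum()
        c = ((y == 1) & (g == 0)).sum()
        d = ((y == 0) & (g == 0)).sum()
        log_or = np.log(a * d / (b * c))
        assert abs(res.frame.iloc[0]["beta"] - log_or) < 1e-6

    def test_null_type1_in_band(self):
        vt = simulate_frequencies(2_000, ["EUR"], {"EUR": 0.0}, seed=81)
        panel = simulate_panel(vt, {"EUR": 800}, LDBlockSpec(rho=0.0), seed=82)
        y = np.random.default_rng(83).integers(0, 2, size=800)
        res = run_gwas_logistic(panel, y)
        p = res.frame["p"].dropna()
        rate = (p <= 0.05).mean()
        band = 3 * np.sqrt(0.05 * 0.95 / len(p))
        assert abs(rate - 0.05) < band + 0.005

    def test_single_class_rejected(self, independent_panel):
        y = np.ones(independent_panel.n_samples)
        with pytest.raises(ValueError):
            LogisticGWAS(y, independent_panel)

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(84)
        vt = simulate_frequencies(5, ["EUR"], {"EUR": 0.0}, seed=85)
        panel = simulate_panel(vt, {"EUR": 500}, LDBlockSpec(rho=0.0), seed=86)
        cov = rng.normal(size=(500, 2))
        eta = 0.3 * panel.dosage[:, 0] - 0.2 * cov[:, 0]
        y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(int)
        res = LogisticGWAS(y, panel, cov).fit()
        for col in range(5):
            X = sm.add_constant(np.column_stack([cov, panel.dosage[:, col]]))
            ref = sm.Logit(y, X).fit(disp=0)
            row = res.frame.iloc[col]
            if row["converged"]:
                assert abs(row["beta"] - ref.params[-1]) < 1e-6
                assert abs(row["se"] - ref.bse[-1]) < 1e-5


class TestStrategies:
    def test_single_group_pooled_equals_pergroup(self):
        vt = simulate_frequencies(300, ["EUR"], {"EUR": 0.05}, seed=90)
        panel = simulate_panel(vt, {"EUR": 400}, LDBlockSpec(rho=0.0), seed=91)
        pcs = compute_pcs(panel, 10, "cross_group")
        pcs_as_group = PCSet(
            scope="per_group:EUR",
            sample_id=pcs.sample_id,
            scores=pcs.scores,
            eigenvalues=pcs.eigenvalues,
        )
        y = np.random.default_rng(92).normal(size=400)
        pooled = run_strategy_pooled(panel, y, pcs)
        studies = run_strategy_pergroup(panel, y, {"EUR": pcs_as_group}, min_group_n=10)
        a = pooled.frame.set_index("variant_id")
        b = studies[0].results.frame.set_index("variant_id")
        common = a.index.intersection(b.index)
        np.testing.assert_allclose(a.loc[common, "beta"], b.loc[common, "beta"], atol=1e-10)
        np.testing.assert_allclose(a.loc[common, "se"], b.loc[common, "se"], atol=1e-10)

    def test_group_specific_maf_inclusion_asymmetry(self):
        vt = _toy_table({"A": [0.02, 0.3], "B": [0.001, 0.3]})
        rng = np.random.default_rng(93)
        dosage = rng.integers(0, 3, size=(200, 2)).astype(np.int8)
        panel = GenotypePanel(
            dosage=dosage,
            sample_id=np.array([f"S{i}" for i in range(200)]),
            group_label=np.array(["A"] * 100 + ["B"] * 100),
            variants=vt,
            age=rng.normal(50, 5, 200),
            sex=rng.integers(0, 2, 200).astype(np.int8),
        )
        y = rng.normal(size=200)
        pcs = {
            g: PCSet(f"per_group:{g}", panel.sample_id[panel.group_mask(g)],
                     rng.normal(size=(100, 10)), np.arange(10, 0, -1.0))
            for g in ("A", "B")
        }
        cross = PCSet("cross_group", panel.sample_id, rng.normal(size=(200, 10)), np.arange(10, 0, -1.0))
        pooled = run_strategy_pooled(panel, y, cross)
        studies = run_strategy_pergroup(panel, y, pcs, min_group_n=10)
        by_group = {s.group: set(s.results.frame["variant_id"]) for s in studies}
        assert "v0" in set(pooled.frame["variant_id"])  # MAF 2% in A: pooled keeps it
        assert "v0" in by_group["A"]
        assert "v0" not in by_group["B"]

    def test_small_group_skipped(self, independent_panel):
        pcs = {
            g: compute_pcs(independent_panel, 10, f"per_group:{g}")
            for g in independent_panel.groups
        }
        y = np.random.default_rng(94).normal(size=independent_panel.n_samples)
        studies = run_strategy_pergroup(independent_panel, y, pcs, min_group_n=600)
        assert studies == []

    def test_empty_phenotype_rejected(self, independent_panel):
        with pytest.raises(ValueError):
            LinearGWAS(np.array([]), independent_panel)

    def test_sumstats_round_trip(self, independent_panel, tmp_path):
        from multigwas.io import read_sumstats

        y = np.random.default_rng(95).normal(size=independent_panel.n_samples)
        res = run_gwas_linear(independent_panel, y)
        path = tmp_path / "sumstats.tsv"
        res.write_tsv(path)
        back = read_sumstats(path)
        np.testing.assert_allclose(back.frame["beta"], res.frame["beta"], rtol=1e-6)
        assert list(back.frame["variant_id"]) == list(res.frame["variant_id"])
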