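"""Phenotype generators: stratification spec, null/continuous/binary models,
intercept calibration, case-control sampling."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

from multigwas.phenosim import (
    calibrate_intercept,
    make_stratification,
    sample_case_control,
    simulate_binary,
    simulate_continuous,
    simulate_null_phenotype,
)
from multigwas.structure import PCSet, compute_pcs


def _fake_pcs(n=2_000, k=10, seed=0, eigenvalues=None):
    rng = np.random.default_rng(seed)
    scores, _ = np.linalg.qr(rng.normal(size=(n, k)))
    lam = np.sort(np.asarray(eigenvalues, float))[::-1] if eigenvalues is not None else np.arange(k, 0, -1.0)
    scores = scores * np.sqrt(lam * (n - 1))
    return PCSet(
        scope="cross_group",
        sample_id=np.array([f"S{i}" for i in range(n)]),
        scores=scores,
        eigenvalues=lam,
    )


class TestMakeStratification:
    def test_alpha_zero_gives_zero_deltas(self):
        spec = make_stratification(_fake_pcs(), 0.0)
        assert np.allclose(spec.delta, 0.0)

    def test_construction_identity(self):
        spec = make_stratification(_fake_pcs(seed=1), 0.05)
        total = np.sum(np.asarray(spec.delta) ** 2 * np.asarray(spec.pc_variances))
        assert abs(total - 0.05) < 1e-10

    def test_equal_eigenvalues_equal_contributions(self):
        pcs = _fake_pcs(seed=2, eigenvalues=np.ones(10) * 3.0)
        spec = make_stratification(pcs, 0.04)
        contrib = np.asarray(spec.delta) ** 2 * np.asarray(spec.pc_variances)
        np.testing.assert_allclose(contrib, contrib[0], rtol=1e-6)

    def test_alpha_one_rejected(self):
        with pytest.raises(ValueError):
            make_stratification(_fake_pcs(), 1.0)


class TestNullPhenotype:
    def test_pure_noise_is_standard_normal(self):
        pcs = _fake_pcs(n=10_000, seed=3)
        spec = make_stratification(pcs, 0.0)
        pheno = simulate_null_phenotype(pcs, spec, seed=4)
        ks = stats.kstest(pheno.values, "norm")
        assert ks.pvalue > 0.01

    def test_unit_variance_and_pc_r2_at_alpha(self):
        n = 20_000
        pcs = _fake_pcs(n=n, seed=5)
        spec = make_stratification(pcs, 0.05)
        pheno = simulate_null_phenotype(pcs, spec, seed=6)
        var = pheno.values.var(ddof=1)
        assert abs(var - 1.0) < 4 * np.sqrt(2 / (n - 1))
        X = np.column_stack([np.ones(n), pcs.scores])
        coef, *_ = np.linalg.lstsq(X, pheno.values, rcond=None)
        resid = pheno.values - X @ coef
        r2 = 1 - resid.var() / pheno.values.var()
        assert abs(r2 - 0.05) < 10 / n + 4 * np.sqrt(4 * 0.05 / n)

    def test_alpha_grid_accepted(self):
        pcs = _fake_pcs(n=500, seed=7)
        for alpha in (0.0, 0.002, 0.005, 0.01, 0.02, 0.05):
            spec = make_stratification(pcs, alpha)
            pheno = simulate_null_phenotype(pcs, spec, seed=8)
            assert pheno.n == 500

    def test_group_specific_scope(self, three_group_panel):
        pcs = {
            g: compute_pcs(three_group_panel, 10, f"per_group:{g}")
            for g in three_group_panel.groups
        }
        spec = make_stratification(pcs, 0.02, "group_specific")
        pheno = simulate_null_phenotype(pcs, spec, seed=9)
        assert set(pheno.group_label) == set(three_group_panel.groups)
        assert abs(pheno.values.var() - 1.0) < 0.2


class TestContinuous:
    def test_no_genetic_effect_null_pvalues(self, independent_panel):
        pheno = simulate_continuous(independent_panel, None, None, 0.0, None, seed=10, n_causal=20)
        # regressing y on a causal dosage within one group: null t-test
        mask = independent_panel.group_mask("AFR")
        idx = list(independent_panel.variants.variant_id).index(pheno.causal_ids[0])
        g = independent_panel.dosage[mask, idx].astype(float)
        r = stats.linregress(g, pheno.values[mask])
        assert r.pvalue > 1e-3

    def test_genetic_variance_matches_h2(self, independent_panel):
        h2 = 0.4
        vals = []
        for s in range(10):
            pheno = simulate_continuous(independent_panel, None, None, h2, None, seed=100 + s, n_causal=100)
            vals.append(pheno.genetic_component.var(ddof=1))
        mean = np.mean(vals)
        # Var over effect draws: sum u^2 ~ h2 * chi2_L / L
        se = h2 * np.sqrt(2 / 100) / np.sqrt(len(vals))
        assert abs(mean - h2) < 4 * se + 0.01

    def test_variance_budget_sums_to_one(self, independent_panel):
        pheno = simulate_continuous(independent_panel, None, None, 0.3, None, seed=11, n_causal=50)
        total_model = pheno.genetic_component.var() + pheno.pc_component.var() + pheno.noise_sigma2
        assert abs(total_model - 1.0) < 0.12

    def test_single_causal_per_allele_effect(self):
        # per-allele slope recovered by within-group OLS equals u / sqrt(2f(1-f))
        from multigwas.popsim import LDBlockSpec, simulate_frequencies, simulate_panel

        vt = simulate_frequencies(50, ["EUR"], {"EUR": 0.0}, ancestral_freq_range=(0.3, 0.7), seed=12)
        panel = simulate_panel(vt, {"EUR": 20_000}, LDBlockSpec(rho=0.0), seed=13)
        u = np.array([0.25])
        pheno = simulate_continuous(
            panel, None, None, u[0] ** 2, None, seed=14, causal_effects=u
        )
        idx = list(panel.variants.variant_id).index(pheno.causal_ids[0])
        f = vt.freq["EUR"].iloc[idx]
        per_allele = u[0] / np.sqrt(2 * f * (1 - f))
        g = panel.dosage[:, idx].astype(float)
        r = stats.linregress(g, pheno.values)
        assert abs(r.slope - per_allele) < 2 * r.stderr

    def test_residual_variance_guard(self, independent_panel):
        with pytest.raises(ValueError):
            simulate_continuous(independent_panel, None, None, 1.2, None, seed=15, n_causal=10)


class TestCalibrateIntercept:
    def test_zero_liability_closed_form(self):
        a = calibrate_intercept(np.zeros(100), 0.1)
        assert abs(a - logit(0.1)) < 1e-6

    def test_monotone_in_target(self):
        liab = np.random.default_rng(16).normal(size=1_000)
        alphas = [calibrate_intercept(liab, t) for t in (0.05, 0.1, 0.2, 0.4)]
        assert all(a < b for a, b in zip(alphas, alphas[1:]))

    def test_normal_liability_convergence(self):
        liab = np.random.default_rng(17).normal(size=50_000)
        a = calibrate_intercept(liab, 0.2)
        assert abs(expit(a + liab).mean() - 0.2) < 1e-4

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            calibrate_intercept(np.array([np.nan, 0.0]), 0.1)


class TestBinary:
    def test_intercept_only_prevalence(self, independent_panel):
        pheno = simulate_binary(
            independent_panel, None, None, 0.0, 0.1, None, seed=18, n_causal=5
        )
        prev = pheno.values.mean()
        se = np.sqrt(0.1 * 0.9 / pheno.n)
        assert abs(prev - 0.1) < 4 * se

    def test_genetic_variance_matches_h2_logit(self, independent_panel):
        h2 = 0.57
        vals = []
        for s in range(10):
            pheno = simulate_binary(independent_panel, None, None, h2, 0.1, None, seed=200 + s, n_causal=100)
            vals.append(pheno.genetic_component.var(ddof=1))
        se = h2 * np.sqrt(2 / 100) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - h2) < 4 * se + 0.02

    def test_per_group_prevalence_targets(self, independent_panel):
        targets = {"AFR": 0.05, "EUR": 0.2}
        pheno = simulate_binary(
            independent_panel, None, None, 0.3, targets, None, seed=19, n_causal=50
        )
        for g, t in targets.items():
            mask = independent_panel.group_mask(g)
            prev = pheno.values[mask].mean()
            se = np.sqrt(t * (1 - t) / mask.sum())
            assert abs(prev - t) < 3 * se + 0.01

    def test_effects_shared_across_groups(self, independent_panel):
        pheno = simulate_binary(independent_panel, None, None, 0.3, 0.1, None, seed=20, n_causal=30)
        assert len(pheno.causal_effects) == 30  # one shared standardized vector


class TestCaseControlSampling:
    def test_one_to_one(self):
        y = np.array([1] * 100 + [0] * 1_000)
        idx = sample_case_control(y, 1.0, seed=21)
        assert len(idx) == 200
        assert y[idx].sum() == 100

    def test_one_to_two(self):
        y = np.array([1] * 100 + [0] * 1_000)
        idx = sample_case_control(y, 2.0, seed=22)
        assert len(idx) == 300

    def test_deterministic(self):
        y = np.array([1] * 50 + [0] * 500)
        a = sample_case_control(y, 1.0, seed=23)
        b = sample_case_control(y, 1.0, seed=23)
        np.testing.assert_array_equal(a, b)

    def test_insufficient_controls_names_deficit(self):
        y = np.array([1] * 100 + [0] * 30)
        with pytest.raises(ValueError, match="deficit 70"):
            sample_case_control(y, 1.0, seed=24)
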