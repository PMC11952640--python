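"""Phenotype simulation under the unit-variance generative models.

Three generators share one variance-budget convention: the total phenotype
variance within each ancestry group is 1, split between a genetic component
(heritability ``h2`` on the standardized-genotype scale), a
population-stratification component carried by principal components
(variance ``alpha``, allocated across PCs proportionally to their
eigenvalues), and residual noise making up the remainder.

* Null phenotypes: ``y = sum_k delta_k PC_k + eps``, ``eps ~ N(0, 1-alpha)``
  with ``delta_k = sqrt(w_k alpha / Var(PC_k))`` and ``w_k`` the eigenvalue
  share of PC k.  No genetic effect.
* Continuous traits: ``y = gamma_j + sum_l X_l u_l + sum_k delta_k PC_k +
  eps`` with standardized genotypes ``X = (G - 2 f_j)/sqrt(2 f_j (1-f_j))``
  (the sample's own group frequency), shared standardized effects
  ``u_l ~ N(0, h2/L)`` and ``eps ~ N(0, 1 - h2 - alpha)``.
* Binary traits: the same linear predictor on the logit scale, with the
  group intercept calibrated by bisection to hit a target prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from multigwas.popsim import GenotypePanel, VariantTable
from multigwas.structure import PCSet

logger = logging.getLogger(__name__)


@dataclass
class StratificationSpec:
    """PC-structured stratification: how much phenotype variance (``alpha``)
    the top PCs carry and how it is split across them.

    For cross-group scope, ``weights``/``delta``/``pc_variances`` are plain
    arrays; for group-specific scope they are dicts keyed by group code.
    """

    scope: str  # "cross_group" or "group_specific"
    alpha: float
    weights: object
    delta: object
    pc_variances: object

    def _check_one(self, w, d, v) -> None:
        if abs(np.sum(w) - 1.0) > 1e-12:
            raise ValueError("PC weights must sum to 1")
        if abs(np.sum(np.asarray(d) ** 2 * np.asarray(v)) - self.alpha) > 1e-10:
            raise ValueError("delta does not reproduce alpha")

    def validate(self) -> None:
        if self.scope == "cross_group":
            self._check_one(self.weights, self.delta, self.pc_variances)
        else:
            for g in self.weights:
                self._check_one(self.weights[g], self.delta[g], self.pc_variances[g])


@dataclass
class PhenotypeSet:
    """Simulated outcomes with their full generative metadata.

    Components (``genetic_component``, ``pc_component``) are stored so the
    realized variance budget can be audited after the fact.
    """

    values: np.ndarray
    trait_type: str  # "null" | "continuous" | "binary"
    sample_id: np.ndarray
    group_label: np.ndarray
    causal_ids: list[str] = field(default_factory=list)
    causal_effects: np.ndarray | None = None  # standardized-scale u_l
    h2: float = 0.0
    group_intercepts: dict[str, float] = field(default_factory=dict)
    stratification: StratificationSpec | None = None
    noise_sigma2: float = 1.0
    seed: object = None
    genetic_component: np.ndarray | None = None
    pc_component: np.ndarray | None = None
    liability: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.values)

    def to_frame(self, age=None, sex=None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "trait": self.values,
                "group": self.group_label,
            }
        )
        if age is not None:
            out["age"] = age
        if sex is not None:
            out["sex"] = sex
        return out


def make_stratification(pcs, alpha: float, scope: str = "cross_group", k: int = 10) -> StratificationSpec:
    """Eigenvalue-proportional allocation of stratification variance.

    ``w_k = lambda_k / sum(lambda)`` over the top ``k`` PCs and
    ``delta_k = sqrt(w_k alpha / Var(PC_k))``, so that
    ``sum_k delta_k^2 Var(PC_k) = alpha`` exactly.  ``pcs`` is a single
    :class:`PCSet` for cross-group scope or a dict of per-group PCSets for
    group-specific scope.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")

    def one(p: PCSet):
        lam = p.eigenvalues[:k]
        if len(lam) < k:
            raise ValueError(f"need at least {k} PCs, have {len(lam)}")
        w = lam / lam.sum()
        v = p.score_variances()[:k]
        d = np.sqrt(w * alpha / v)
        return w, d, v

    if scope == "cross_group":
        if not isinstance(pcs, PCSet):
            raise TypeError("cross_group scope expects a single PCSet")
        w, d, v = one(pcs)
        spec = StratificationSpec(scope, alpha, w, d, v)
    elif scope == "group_specific":
        ws, ds, vs = {}, {}, {}
        for g, p in pcs.items():
            ws[g], ds[g], vs[g] = one(p)
        spec = StratificationSpec(scope, alpha, ws, ds, vs)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    spec.validate()
    return spec


def _pc_component(panel: GenotypePanel, pcs, spec: StratificationSpec | None, k: int = 10) -> np.ndarray:
    """Per-sample PC stratification component, aligned to panel order."""
    n = panel.n_samples
    comp = np.zeros(n)
    if spec is None or spec.alpha == 0.0:
        return comp
    order = {s: i for i, s in enumerate(panel.sample_id)}
    if spec.scope == "cross_group":
        rows = [order[s] for s in pcs.sample_id]
        comp[rows] = pcs.scores[:, : len(spec.delta)] @ spec.delta
    else:
        for g, p in pcs.items():
            d = spec.delta[g]
            rows = [order[s] for s in p.sample_id]
            comp[rows] = p.scores[:, : len(d)] @ d
    return comp


def simulate_null_phenotype(pcs, strat_spec: StratificationSpec, seed=None) -> PhenotypeSet:
    """Null phenotype with PC-structured stratification and no genetic
    effect; within-group mean 0 and variance 1 by construction."""
    rng = np.random.default_rng(seed)
    alpha = strat_spec.alpha
    if strat_spec.scope == "cross_group":
        items = [(None, pcs)]
        deltas = {None: np.asarray(strat_spec.delta)}
    else:
        items = list(pcs.items())
        deltas = {g: np.asarray(strat_spec.delta[g]) for g, _ in items}

    sample_id, group_label, values, pc_comp = [], [], [], []
    for g, p in items:
        d = deltas[g]
        comp = p.scores[:, : len(d)] @ d
        eps = rng.normal(0.0, np.sqrt(1.0 - alpha), size=len(comp))
        sample_id.append(p.sample_id)
        group_label.append(np.array([g if g is not None else "ALL"] * len(comp)))
        values.append(comp + eps)
        pc_comp.append(comp)

    return PhenotypeSet(
        values=np.concatenate(values),
        trait_type="null",
        sample_id=np.concatenate(sample_id),
        group_label=np.concatenate(group_label),
        stratification=strat_spec,
        noise_sigma2=1.0 - alpha,
        seed=seed,
        pc_component=np.concatenate(pc_comp),
    )


def _standardized_causal(
    panel: GenotypePanel, variant_table: VariantTable, causal_idx: np.ndarray
) -> np.ndarray:
    """Standardized genotypes X at causal variants, using each sample's own
    group allele frequency f_jl."""
    G = panel.dosage[:, causal_idx].astype(np.float64)
    X = np.empty_like(G)
    for g in panel.groups:
        mask = panel.group_mask(g)
        if g in variant_table.freq.columns:
            f = variant_table.freq[g].to_numpy()[causal_idx]
        else:  # admixed or unlabeled group: fall back to its sample frequency
            f = panel.dosage[mask][:, causal_idx].mean(axis=0) / 2.0
            f = np.clip(f, 1e-6, 1.0 - 1e-6)
        X[mask] = (G[mask] - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    return X


def _draw_causal(
    rng: np.random.Generator, n_variants: int, causal_fraction: float | None, n_causal: int | None
) -> np.ndarray:
    if n_causal is None:
        if causal_fraction is None or not 0.0 < causal_fraction <= 1.0:
            raise ValueError("causal_fraction must be in (0, 1]")
        n_causal = max(1, int(round(causal_fraction * n_variants)))
    return np.sort(rng.choice(n_variants, size=n_causal, replace=False))


def simulate_continuous(
    panel: GenotypePanel,
    variant_table: VariantTable | None = None,
    causal_fraction: float | None = 0.05,
    h2: float = 0.4,
    pc_effects: tuple | None = None,
    seed=None,
    *,
    n_causal: int | None = None,
    causal_effects: np.ndarray | None = None,
) -> PhenotypeSet:
    """Continuous trait with shared standardized effects across groups.

    ``pc_effects`` is an optional ``(pcs, StratificationSpec)`` pair adding
    a PC-structured component.  ``causal_effects`` fixes the standardized
    effect vector instead of drawing ``u_l ~ N(0, h2/L)``.
    """
    if variant_table is None:
        variant_table = panel.variants
    rng = np.random.default_rng(seed)
    causal_idx = _draw_causal(
        rng, panel.n_variants, causal_fraction, n_causal if causal_effects is None else len(causal_effects)
    )
    L = len(causal_idx)
    u = rng.normal(0.0, np.sqrt(h2 / L), size=L) if causal_effects is None else np.asarray(causal_effects, float)

    X = _standardized_causal(panel, variant_table, causal_idx)
    genetic = X @ u

    spec = pc_effects[1] if pc_effects is not None else None
    pc_comp = _pc_component(panel, pc_effects[0] if pc_effects else None, spec)
    alpha = spec.alpha if spec is not None else 0.0

    sigma2 = 1.0 - h2 - alpha
    if sigma2 <= 0.0:
        raise ValueError(f"residual variance 1 - h2 - alpha = {sigma2:.4g} is not positive")

    intercepts = {g: rng.normal(0.0, 1.0) for g in panel.groups}
    gamma = np.array([intercepts[g] for g in panel.group_label])
    eps = rng.normal(0.0, np.sqrt(sigma2), size=panel.n_samples)
    y = gamma + genetic + pc_comp + eps

    return PhenotypeSet(
        values=y,
        trait_type="continuous",
        sample_id=panel.sample_id,
        group_label=panel.group_label,
        causal_ids=[variant_table.variant_id[i] for i in causal_idx],
        causal_effects=u,
        h2=h2,
        group_intercepts=intercepts,
        stratification=spec,
        noise_sigma2=sigma2,
        seed=seed,
        genetic_component=genetic,
        pc_component=pc_comp,
    )


def calibrate_intercept(liability: np.ndarray, target_prevalence: float, tol: float = 1e-4) -> float:
    """Intercept a such that mean(expit(a + liability)) hits the target.

    Monotone in the target; solved by root bracketing on a.  With zero
    liabilities this reduces to logit(target).
    """
    liability = np.asarray(liability, dtype=float)
    if liability.size == 0:
        raise ValueError("empty liability sample")
    if not np.isfinite(liability).all():
        raise ValueError("non-finite liabilities")
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")

    def gap(a: float) -> float:
        return float(expit(a + liability).mean() - target_prevalence)

    lo, hi = -40.0, 40.0
    return float(brentq(gap, lo, hi, xtol=tol / 10.0))


def simulate_binary(
    panel: GenotypePanel,
    variant_table: VariantTable | None = None,
    causal_fraction: float | None = 0.01,
    h2_logit: float = 0.57,
    target_prevalence_per_group: dict[str, float] | float = 0.1,
    pc_effects: tuple | None = None,
    seed=None,
    *,
    n_causal: int | None = None,
    causal_effects: np.ndarray | None = None,
) -> PhenotypeSet:
    """Binary trait from a logistic liability model.

    The logit-scale linear predictor is the genetic component plus any PC
    component plus a group intercept calibrated so the expected prevalence
    within each group matches its target.
    """
    if variant_table is None:
        variant_table = panel.variants
    rng = np.random.default_rng(seed)
    causal_idx = _draw_causal(
        rng, panel.n_variants, causal_fraction, n_causal if causal_effects is None else len(causal_effects)
    )
    L = len(causal_idx)
    u = (
        rng.normal(0.0, np.sqrt(h2_logit / L), size=L)
        if causal_effects is None
        else np.asarray(causal_effects, float)
    )

    X = _standardized_causal(panel, variant_table, causal_idx)
    genetic = X @ u
    spec = pc_effects[1] if pc_effects is not None else None
    pc_comp = _pc_component(panel, pc_effects[0] if pc_effects else None, spec)
    liability = genetic + pc_comp

    if not isinstance(target_prevalence_per_group, dict):
        target_prevalence_per_group = {g: float(target_prevalence_per_group) for g in panel.groups}

    intercepts = {}
    prob = np.empty(panel.n_samples)
    for g in panel.groups:
        mask = panel.group_mask(g)
        a = calibrate_intercept(liability[mask], target_prevalence_per_group[g])
        intercepts[g] = a
        prob[mask] = expit(a + liability[mask])
    y = (rng.random(panel.n_samples) < prob).astype(np.int8)

    return PhenotypeSet(
        values=y,
        trait_type="binary",
        sample_id=panel.sample_id,
        group_label=panel.group_label,
        causal_ids=[variant_table.variant_id[i] for i in causal_idx],
        causal_effects=u,
        h2=h2_logit,
        group_intercepts=intercepts,
        stratification=spec,
        noise_sigma2=float("nan"),
        seed=seed,
        genetic_component=genetic,
        pc_component=pc_comp,
        liability=liability,
    )


def sample_case_control(
    phenotypes: PhenotypeSet | np.ndarray,
    ratio: float = 1.0,
    seed=None,
) -> np.ndarray:
    """Indices of all cases plus ``ratio`` controls per case, drawn without
    replacement; raises naming the deficit when controls run short."""
    y = phenotypes.values if isinstance(phenotypes, PhenotypeSet) else np.asarray(phenotypes)
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("need at least one case and one control")
    n_controls = int(round(ratio * len(cases)))
    if n_controls > len(controls):
        raise ValueError(
            f"insufficient controls: need {n_controls}, have {len(controls)} "
            f"(deficit {n_controls - len(controls)})"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(controls, size=n_controls, replace=False)
    return np.sort(np.concatenate([cases, picked]))
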