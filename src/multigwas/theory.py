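"""Estimator algebra for pooled versus meta-analysis and their asymptotic
relative efficiency (ARE).

In a J-group cohort with constant allelic effect beta and genotype
``g_ij ~ Bin(2, f_j)``, the within-group slope uses the within-group
genotype sum of squares, the pooled slope uses the total sum of squares,
and the inverse-variance fixed-effect meta estimate reduces to the ratio of
summed within-group cross-products to summed within-group sums of squares.
The ANOVA identity

    SS_total = SS_within + SS_between,
    SS_between = sum_j n_j (gbar_j - gbar)^2,

gives ARE = Var(beta_M)/Var(beta_P) = SS_total / SS_within >= 1, with
equality only when all group dosage means coincide: pooled analysis is
never less efficient, and its advantage grows with the sample-size-weighted
variance of allele frequencies across groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from multigwas.popsim import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class EffectEstimates:
    """Within-group, pooled and meta effect estimates for one variant."""

    beta_j: dict[str, float]
    var_j: dict[str, float]
    beta_pooled: float
    var_pooled: float
    beta_meta: float
    var_meta: float
    sigma2: float
    groups_used: list[str]


@dataclass
class AREReport:
    """ANOVA decomposition of genotype variation and the implied ARE."""

    ss_within: float
    ss_between: float
    ss_total: float
    are: float
    asymptotic_are: float

    def to_dict(self) -> dict:
        return {
            "ss_within": self.ss_within,
            "ss_between": self.ss_between,
            "ss_total": self.ss_total,
            "are": self.are,
            "asymptotic_are": self.asymptotic_are,
        }


def estimate_effects(genotypes, phenotype, group_labels) -> EffectEstimates:
    """Within-group, pooled and IVW-meta slopes for one variant.

    Implements the intercept-only simple-regression forms: each slope is a
    ratio of centered cross-products to centered genotype sums of squares;
    the meta estimate pools the within-group numerators and denominators.
    The residual variance ``sigma2`` is estimated from the pooled
    regression and treated as shared across groups for variance reporting.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    labels = np.asarray(group_labels)
    if len(np.unique(g)) < 2:
        raise ValueError("need at least two distinct dosage values")

    gbar, ybar = g.mean(), y.mean()
    ss_tot = float(((g - gbar) ** 2).sum())
    sxy_tot = float(((g - gbar) * (y - ybar)).sum())
    beta_p = sxy_tot / ss_tot
    resid = (y - ybar) - beta_p * (g - gbar)
    dof = max(len(y) - 2, 1)
    sigma2 = float((resid**2).sum()) / dof

    beta_j, var_j, used = {}, {}, []
    num_meta = den_meta = 0.0
    for grp in dict.fromkeys(labels.tolist()):
        mask = labels == grp
        gj, yj = g[mask], y[mask]
        ssj = float(((gj - gj.mean()) ** 2).sum())
        if ssj <= 0.0:
            logger.info("group %s has zero dosage variance; excluded from meta", grp)
            continue
        sxyj = float(((gj - gj.mean()) * (yj - yj.mean())).sum())
        beta_j[grp] = sxyj / ssj
        var_j[grp] = sigma2 / ssj
        num_meta += sxyj
        den_meta += ssj
        used.append(grp)

    return EffectEstimates(
        beta_j=beta_j,
        var_j=var_j,
        beta_pooled=beta_p,
        var_pooled=sigma2 / ss_tot,
        beta_meta=num_meta / den_meta,
        var_meta=sigma2 / den_meta,
        sigma2=sigma2,
        groups_used=used,
    )


def _anova(g: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    gbar = g.mean()
    ss_total = float(((g - gbar) ** 2).sum())
    ss_within = 0.0
    ss_between = 0.0
    for grp in np.unique(labels):
        gj = g[labels == grp]
        ss_within += float(((gj - gj.mean()) ** 2).sum())
        ss_between += len(gj) * float((gj.mean() - gbar) ** 2)
    return ss_within, ss_between, ss_total


def are_empirical(genotype_panel: GenotypePanel, variant_id: str) -> AREReport:
    """Realized ANOVA decomposition and ARE for one variant of a panel.

    ``asymptotic_are`` plugs the model expectations -- within-group dosage
    variance ``2 f_j (1-f_j)`` and group dosage mean ``2 f_j`` from the
    panel's variant table -- into the same expression.
    """
    idx = list(genotype_panel.variants.variant_id).index(variant_id)
    g = genotype_panel.dosage[:, idx].astype(float)
    labels = genotype_panel.group_label
    ss_within, ss_between, ss_total = _anova(g, labels)
    if ss_within == 0.0:
        raise ValueError("zero within-group dosage variance: ARE undefined")

    sizes = genotype_panel.group_sizes
    freqs = {g_: genotype_panel.variants.freq[g_].iloc[idx] for g_ in sizes if g_ in genotype_panel.variants.freq.columns}
    if len(freqs) == len(sizes):
        asym = are_asymptotic([sizes[g_] for g_ in sizes], [freqs[g_] for g_ in sizes])
    else:
        asym = float("nan")

    return AREReport(
        ss_within=ss_within,
        ss_between=ss_between,
        ss_total=ss_total,
        are=ss_total / ss_within,
        asymptotic_are=asym,
    )


def are_asymptotic(n_per_group, f_per_group) -> float:
    """Closed-form ARE from group sizes and allele frequencies.

    ``E[SS_within] = sum_j n_j 2 f_j (1-f_j)`` and the between term is
    ``sum_j n_j (2 f_j - 2 fbar_w)^2`` with ``fbar_w`` the size-weighted
    mean frequency; ARE is their total over the within part.  Equals 1
    exactly when all frequencies coincide and always is >= 1.
    """
    n = np.asarray(n_per_group, dtype=float)
    f = np.asarray(f_per_group, dtype=float)
    if (n <= 0).any():
        raise ValueError("group sizes must be positive")
    if ((f <= 0) | (f >= 1)).any():
        raise ValueError("frequencies must be in (0, 1)")
    within = float((n * 2.0 * f * (1.0 - f)).sum())
    fbar = float((n * f).sum() / n.sum())
    between = float((n * (2.0 * f - 2.0 * fbar) ** 2).sum())
    return (within + between) / within
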