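"""Population-structure estimation: LD pruning, principal components, and
phenotypic variance explained by PC sets.

PCs are computed either on the pooled panel ("cross_group" scope) or within
a single ancestry group ("per_group" scope).  Genotypes are standardized to
``(g - 2f)/sqrt(2f(1-f))`` with the allele frequency estimated from the
samples the PCA runs on, so each scope is standardized against its own
dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.utils.extmath import randomized_svd

from multigwas.popsim import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class PCSet:
    """Principal-component scores for one scope.

    ``scores`` is samples x K with mutually orthogonal columns;
    ``eigenvalues`` are the corresponding eigenvalues of the sample
    covariance of standardized dosages, sorted nonincreasing.
    """

    scope: str  # "cross_group" or "per_group:<code>"
    sample_id: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    pruned_variant_ids: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def score_variances(self) -> np.ndarray:
        return self.scores.var(axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.scores[:, i] for i in range(self.k)}
        return pd.DataFrame({"sample_id": self.sample_id, **cols})


@dataclass
class VarianceExplainedReport:
    """Delta-R2 of a trait on ancestry-group-specific versus cross-group PC
    sets, after residualizing on age and sex within group."""

    trait_id: str
    r2_group_specific: float
    r2_cross_group: float
    ci_group_specific: tuple[float, float] | None
    ci_cross_group: tuple[float, float] | None
    n_bootstrap: int
    collinear: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scope, r2, ci in (
            ("group_specific", self.r2_group_specific, self.ci_group_specific),
            ("cross_group", self.r2_cross_group, self.ci_cross_group),
        ):
            rows.append(
                {
                    "trait_id": self.trait_id,
                    "pc_scope": scope,
                    "delta_r2": r2,
                    "ci_low": None if ci is None else ci[0],
                    "ci_high": None if ci is None else ci[1],
                    "n_bootstrap": self.n_bootstrap,
                    "collinear": self.collinear,
                }
            )
        return pd.DataFrame(rows)


def ld_prune(
    panel: GenotypePanel,
    r2_threshold: float = 0.1,
    window_bp: int = 500_000,
    seed=None,
) -> list[str]:
    """Greedy left-to-right LD pruning.

    Scanning variants in position order, a variant is removed if its
    genotype r^2 with any already-retained variant within ``window_bp``
    upstream (same chromosome) exceeds the threshold.  Deterministic; the
    ``seed`` argument is accepted for interface symmetry but unused.
    """
    if panel.n_variants == 0:
        raise ValueError("empty panel")
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")

    pos = panel.variants.variants["pos_bp"].to_numpy()
    chrom = panel.variants.variants["chrom"].to_numpy()
    ids = panel.variants.variant_id
    dosage = panel.dosage

    # Only centered columns of retained variants inside the active window
    # are buffered, keeping memory flat in the number of variants.
    retained: list[int] = []
    buf_idx: list[int] = []
    buf_cols: list[np.ndarray] = []
    buf_norms: list[float] = []
    for l in range(panel.n_variants):
        while buf_idx and (
            chrom[buf_idx[0]] != chrom[l] or pos[l] - pos[buf_idx[0]] > window_bp
        ):
            buf_idx.pop(0)
            buf_cols.pop(0)
            buf_norms.pop(0)
        col = dosage[:, l].astype(np.float32)
        col -= col.mean()
        norm = float(np.sqrt(col @ col))
        keep = True
        if norm > 0 and window_bp > 0 and buf_idx:
            # nearest retained variants first: pruned variants exit early
            for c, cn in zip(reversed(buf_cols), reversed(buf_norms)):
                r = (c @ col) / (cn * norm)
                if r * r > r2_threshold:
                    keep = False
                    break
        if keep:
            retained.append(l)
            if norm > 0:
                buf_idx.append(l)
                buf_cols.append(col)
                buf_norms.append(norm)
    return [ids[i] for i in retained]


def _standardize(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize dosage columns by the sample allele frequency; returns
    (standardized matrix, mask of retained polymorphic columns)."""
    f = G.mean(axis=0) / 2.0
    keep = (f > 0.0) & (f < 1.0)
    Z = (G[:, keep] - 2.0 * f[keep]) / np.sqrt(2.0 * f[keep] * (1.0 - f[keep]))
    return Z, keep


def compute_pcs(
    panel: GenotypePanel,
    k: int = 10,
    scope: str = "cross_group",
    variant_ids: list[str] | None = None,
) -> PCSet:
    """Top-k principal components of standardized dosages.

    ``scope`` is ``"cross_group"`` (all samples) or ``"per_group:<code>"``.
    ``variant_ids`` restricts the computation, typically to an LD-pruned
    set.  Scores are the projections onto the top-k eigenvectors of the
    sample covariance; eigenvalues are returned nonincreasing; each
    component's sign is fixed so its largest-magnitude loading is positive.
    """
    if scope == "cross_group":
        sub = panel
    elif scope.startswith("per_group:"):
        sub = panel.subset_samples(np.flatnonzero(panel.group_mask(scope.split(":", 1)[1])))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if variant_ids is not None:
        sub = sub.subset_variants(variant_ids)

    Z, keep = _standardize(sub.dosage.astype(np.float64))
    n, m = Z.shape
    if k >= min(n, m):
        raise ValueError(f"k={k} too large for {n} samples x {m} polymorphic variants")

    if n * m > 4_000_000 and k < min(n, m) // 4:
        # Randomized range-finder with power iterations and a fixed seed:
        # deterministic, and accurate for the leading well-separated
        # (ancestry) components, which is what the top-k are used for.
        U, s, Vt = randomized_svd(
            Z, n_components=k, n_oversamples=10, n_iter=10, random_state=0
        )
    else:
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        U, s, Vt = U[:, :k], s[:k], Vt[:k]

    signs = np.sign(Vt[np.arange(k), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    scores = U * s * signs
    eigenvalues = s**2 / (n - 1)
    return PCSet(
        scope=scope,
        sample_id=sub.sample_id,
        scores=scores,
        eigenvalues=eigenvalues,
        pruned_variant_ids=list(variant_ids) if variant_ids is not None else list(sub.variants.variant_id),
    )


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """Projection-based R^2 of y on [1, X] (rank-deficiency tolerant)."""
    X1 = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
    fitted = X1 @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return 0.0
    return 1.0 - ((y - fitted) ** 2).sum() / ss_tot


def variance_explained_by_pcs(
    trait: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    group_labels: np.ndarray,
    pcs_cross: PCSet,
    pcs_group: dict[str, PCSet],
    n_bootstrap: int = 1_000,
    seed=None,
    trait_id: str = "trait",
) -> VarianceExplainedReport:
    """Two-step estimate of trait variance explained by each PC set.

    Step 1 residualizes the trait on age and sex within each ancestry
    group.  Step 2 computes, on the pooled residuals, the difference in R^2
    between the full model (cross-group PCs + stacked group-specific PCs)
    and the reduced model with only the other PC set.  Bootstrap over
    samples gives percentile CIs; ``n_bootstrap = 0`` skips them.
    """
    trait = np.asarray(trait, dtype=float)
    n = len(trait)
    order = {s: i for i, s in enumerate(pcs_cross.sample_id)}

    # Stack each sample's own group's PC scores into one matrix.
    k = pcs_cross.k
    stacked = np.zeros((n, k))
    for g, pcs in pcs_group.items():
        rows = [order[s] for s in pcs.sample_id]
        stacked[rows, : pcs.k] = pcs.scores[:, :k]

    resid = np.empty(n)
    for g in np.unique(group_labels):
        mask = group_labels == g
        C = np.column_stack([np.ones(mask.sum()), age[mask], sex[mask]])
        coef, *_ = np.linalg.lstsq(C, trait[mask], rcond=None)
        resid[mask] = trait[mask] - C @ coef

    cross = pcs_cross.scores
    full = np.column_stack([cross, stacked])
    collinear = np.linalg.matrix_rank(full) < full.shape[1]
    if collinear:
        logger.warning("cross-group and group-specific PC sets are collinear")

    def deltas(idx: np.ndarray) -> tuple[float, float]:
        r2_full = _r2(resid[idx], full[idx])
        d_group = r2_full - _r2(resid[idx], cross[idx])
        d_cross = r2_full - _r2(resid[idx], stacked[idx])
        return d_group, d_cross

    all_idx = np.arange(n)
    d_group, d_cross = deltas(all_idx)

    ci_g = ci_c = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = np.array(
            [deltas(rng.integers(0, n, size=n)) for _ in range(n_bootstrap)]
        )
        ci_g = tuple(np.percentile(boots[:, 0], [2.5, 97.5]))
        ci_c = tuple(np.percentile(boots[:, 1], [2.5, 97.5]))

    return VarianceExplainedReport(
        trait_id=trait_id,
        r2_group_specific=d_group,
        r2_cross_group=d_cross,
        ci_group_specific=ci_g,
        ci_cross_group=ci_c,
        n_bootstrap=n_bootstrap,
        collinear=collinear,
    )
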