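"""Combining per-group summary statistics.

Two combiners operate on :class:`~multigwas.assoc.StudyStats` collections:

* Inverse-variance-weighted (IVW) fixed-effect meta-analysis:
  ``beta_M = sum(w_j beta_j) / sum(w_j)`` with ``w_j = 1/se_j^2`` and
  ``se_M = (sum w_j)^{-1/2}``; a variant contributes whichever groups carry
  it, so the output mirrors the pooled "MAF > 1% in at least one group"
  inclusion rule.

* MR-MEGA-style meta-regression: per-group effects are regressed (weighted
  by ``1/se_j^2``) on T axes of genetic variation obtained by classical
  multidimensional scaling of the mean squared allele-frequency difference
  between groups.  The association test is the weighted-RSS drop from the
  empty (no-parameter) model to the full model (chi-square, df T+1); the
  ancestry-correlated heterogeneity test is the drop from intercept-only to
  full (df T); residual heterogeneity is the full-model weighted RSS (df
  J-T-2).  Output is restricted to variants informative in all groups,
  reproducing MR-MEGA's "MAF > 1% in all groups" restriction.

The number of axes follows the rule T = J - 3 for J >= 4 ancestry groups;
with fewer than four groups the meta-regression is not applicable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from multigwas.assoc import GWASResults, StudyStats

logger = logging.getLogger(__name__)


@dataclass
class AxesOfVariation:
    """Per-group coordinates on T axes of genetic variation."""

    coords: pd.DataFrame  # groups x T, column-centered
    distance_matrix: pd.DataFrame  # J x J mean squared frequency differences
    eigenvalues: np.ndarray

    @property
    def T(self) -> int:
        return self.coords.shape[1]

    @property
    def groups(self) -> list[str]:
        return list(self.coords.index)


def select_num_axes(n_groups: int) -> int | None:
    """Axis-count rule: T = J - 3 for J >= 4 groups, else not applicable
    (returns None)."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups < 4:
        return None
    return n_groups - 3


def compute_axes(per_group_frequency_matrix: pd.DataFrame, T: int) -> AxesOfVariation:
    """Axes of genetic variation from allele-frequency divergence.

    The pairwise dissimilarity between groups j and k is the mean squared
    allele-frequency difference across the shared variant set.  Classical
    (Torgerson) MDS of the J x J matrix yields the coordinates; the top T
    positive-eigenvalue axes are returned, column-centered, each axis
    signed so its largest-magnitude coordinate is positive.
    """
    F = per_group_frequency_matrix
    groups = list(F.columns)
    J = len(groups)
    if T > J - 1:
        raise ValueError(f"T={T} exceeds J-1={J - 1}")
    A = F.to_numpy(dtype=float).T  # J x m
    diff = A[:, None, :] - A[None, :, :]
    D = (diff**2).mean(axis=2)  # squared-distance-like dissimilarity

    # Torgerson double-centering: B = -1/2 J D J
    Jc = np.eye(J) - np.ones((J, J)) / J
    B = -0.5 * Jc @ D @ Jc
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(-evals)
    evals, evecs = evals[order], evecs[:, order]
    lam = np.clip(evals[:T], 0.0, None)
    coords = evecs[:, :T] * np.sqrt(lam)
    for t in range(T):
        i = np.argmax(np.abs(coords[:, t]))
        if coords[i, t] < 0:
            coords[:, t] = -coords[:, t]
    coords -= coords.mean(axis=0)

    return AxesOfVariation(
        coords=pd.DataFrame(coords, index=groups, columns=[f"axis{t + 1}" for t in range(T)]),
        distance_matrix=pd.DataFrame(D, index=groups, columns=groups),
        eigenvalues=evals,
    )


def _collect(studies: list[StudyStats]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Long-to-wide alignment of per-group beta/se (converged rows only),
    plus a variant metadata frame."""
    betas, ses, meta = {}, {}, []
    for st in studies:
        f = st.results.frame
        ok = f["converged"] & f["se"].notna()
        sub = f[ok]
        betas[st.group] = pd.Series(sub["beta"].to_numpy(), index=sub["variant_id"])
        ses[st.group] = pd.Series(sub["se"].to_numpy(), index=sub["variant_id"])
        meta.append(f[["variant_id", "chrom", "pos_bp", "allele_ref", "allele_alt"]])
    B = pd.DataFrame(betas)
    S = pd.DataFrame(ses)
    M = pd.concat(meta).drop_duplicates("variant_id").set_index("variant_id")
    return B, S, M


def ivw_meta(studies: list[StudyStats]) -> pd.DataFrame:
    """Fixed-effect inverse-variance-weighted meta-analysis.

    Returns one row per variant with ``beta_meta``, ``se_meta``, a z-test
    ``p``, and ``n_groups_used``.  Variants with no usable contributing
    group are dropped with a log entry.
    """
    if not studies:
        raise ValueError("no studies supplied")
    B, S, M = _collect(studies)
    W = 1.0 / S**2
    wsum = W.sum(axis=1, skipna=True)
    n_used = W.notna().sum(axis=1)
    dropped = int((n_used == 0).sum())
    if dropped:
        logger.info("dropping %d variants with no contributing study", dropped)
    keep = n_used > 0
    beta = (B * W).sum(axis=1, skipna=True)[keep] / wsum[keep]
    se = 1.0 / np.sqrt(wsum[keep])
    z = beta / se
    variant_ids = beta.index
    out = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "method": "IVW",
            "beta_meta": beta.to_numpy(),
            "se_meta": se.to_numpy(),
            "p": 2.0 * stats.norm.sf(np.abs(z.to_numpy())),
            "n_groups_used": n_used[keep].to_numpy(),
        }
    )
    loc = M.reindex(variant_ids)
    out.insert(1, "chrom", loc["chrom"].to_numpy())
    out.insert(2, "pos_bp", loc["pos_bp"].to_numpy())
    return out.sort_values(["chrom", "pos_bp"]).reset_index(drop=True)


def mrmega_test(
    studies: list[StudyStats],
    axes: AxesOfVariation,
    variant_ids=None,
) -> pd.DataFrame:
    """Meta-regression of per-group effects on axes of genetic variation.

    Per variant with usable statistics in all J groups (optionally further
    restricted by ``variant_ids``), fits weighted least squares of beta_j
    on an intercept plus T axis coordinates with weights 1/se_j^2 and
    partitions the weighted sum of squares into association (df T+1),
    ancestry-correlated heterogeneity (df T) and residual heterogeneity
    (df J-T-2) chi-square statistics.
    """
    J = len(studies)
    T = axes.T
    if J < T + 2:
        raise ValueError(f"need at least T+2={T + 2} groups, have {J}")
    B, S, M = _collect(studies)
    B, S = B[[s.group for s in studies]], S[[s.group for s in studies]]
    full = B.notna().all(axis=1) & S.notna().all(axis=1)
    n_dropped = int((~full).sum())
    if n_dropped:
        logger.info("MR-MEGA: %d variants lack statistics in all groups (dropped)", n_dropped)
    B, S = B[full], S[full]
    if variant_ids is not None:
        keep = B.index.isin(list(variant_ids))
        B, S = B[keep], S[keep]

    X = np.column_stack([np.ones(J), axes.coords.loc[[s.group for s in studies]].to_numpy()])
    df_assoc, df_anc, df_res = T + 1, T, J - T - 2

    b = B.to_numpy(dtype=float)  # n_variants x J
    w = 1.0 / S.to_numpy(dtype=float) ** 2
    # Batched WLS normal equations: one (T+1)x(T+1) solve per variant.
    XtWX = np.einsum("jp,vj,jq->vpq", X, w, X)
    XtWb = np.einsum("jp,vj,vj->vp", X, w, b)
    try:
        coef = np.linalg.solve(XtWX, XtWb[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # degenerate axes (e.g. identical group frequencies): minimum-norm LS
        coef = np.einsum("vpq,vq->vp", np.linalg.pinv(XtWX), XtWb)
    rss_empty = np.einsum("vj,vj->v", w, b**2)
    rss_full = np.maximum(rss_empty - np.einsum("vp,vp->v", coef, XtWb), 0.0)
    beta_w = (w * b).sum(axis=1) / w.sum(axis=1)
    rss_int = np.einsum("vj,vj->v", w, (b - beta_w[:, None]) ** 2)

    chi_assoc = np.maximum(rss_empty - rss_full, 0.0)
    chi_anc = np.maximum(rss_int - rss_full, 0.0)
    chi_res = rss_full
    out = pd.DataFrame(
        {
            "variant_id": B.index.to_numpy(),
            "method": "MRMEGA",
            "chi2_assoc": chi_assoc,
            "df_assoc": df_assoc,
            "p_assoc": stats.chi2.sf(chi_assoc, df_assoc),
            "chi2_het_ancestry": chi_anc,
            "df_het_ancestry": df_anc,
            "p_het_ancestry": stats.chi2.sf(chi_anc, df_anc) if df_anc > 0 else np.nan,
            "chi2_het_residual": chi_res,
            "df_het_residual": df_res,
            "p_het_residual": stats.chi2.sf(chi_res, df_res) if df_res > 0 else np.nan,
            "n_groups_used": J,
        }
    )
    if len(out):
        loc = M.reindex(out["variant_id"])
        out.insert(1, "chrom", loc["chrom"].to_numpy())
        out.insert(2, "pos_bp", loc["pos_bp"].to_numpy())
        out = out.sort_values(["chrom", "pos_bp"]).reset_index(drop=True)
    return out


class IVWMeta:
    """Model-style wrapper: ``IVWMeta(studies).fit()`` returns a
    :class:`MetaResults` over the IVW combination."""

    def __init__(self, studies: list[StudyStats]):
        self.studies = studies

    def fit(self) -> "MetaResults":
        return MetaResults(ivw_meta(self.studies), method="IVW")


class MRMEGA:
    """Model-style wrapper for the meta-regression combiner.

    Axes are computed from the per-group frequency matrix of the supplied
    studies unless given explicitly; ``T`` defaults to the J-3 rule.
    Raises when fewer than four groups are supplied and no explicit T
    override is given.
    """

    def __init__(self, studies: list[StudyStats], axes: AxesOfVariation | None = None, T: int | None = None):
        self.studies = studies
        if axes is None:
            J = len(studies)
            if T is None:
                T = select_num_axes(J)
                if T is None:
                    raise ValueError(
                        f"MR-MEGA requires at least four ancestry groups (have {J}); "
                        "pass an explicit T to override"
                    )
            F = pd.DataFrame({s.group: s.freq for s in studies}).dropna()
            axes = compute_axes(F, T)
        self.axes = axes

    def fit(self, variant_ids=None) -> "MetaResults":
        return MetaResults(mrmega_test(self.studies, self.axes, variant_ids), method="MRMEGA")


class MetaResults:
    """Combined per-variant statistics from a meta combiner."""

    def __init__(self, frame: pd.DataFrame, method: str):
        self.frame = frame
        self.method = method

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def pvalues(self) -> np.ndarray:
        col = "p" if self.method == "IVW" else "p_assoc"
        return self.frame[col].to_numpy()

    def significant(self, threshold: float = 5e-8) -> pd.DataFrame:
        col = "p" if self.method == "IVW" else "p_assoc"
        p = self.frame[col]
        return self.frame[p.notna() & (p <= threshold)]

    def summary(self, threshold: float = 5e-8) -> str:
        return (
            f"{self.method} combination: {len(self.frame)} variants, "
            f"{len(self.significant(threshold))} significant at p <= {threshold:g}"
        )

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA")
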