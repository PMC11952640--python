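"""Per-variant fixed-effect association engines.

`LinearGWAS` and `LogisticGWAS` follow the model/fit/results idiom: build
the model from a phenotype, a genotype panel (or raw dosage matrix) and a
covariate matrix, call :meth:`fit`, and receive a :class:`GWASResults`
holding one row per variant (effect, standard error, two-sided Wald p,
sample size, effect-allele frequency).  The linear engine residualizes the
phenotype and every dosage column on the covariates once
(Frisch-Waugh-Lovell), which reproduces the full per-variant OLS exactly;
the logistic engine runs per-variant iteratively reweighted least squares.

Strategy runners wire the engines to the variant-inclusion rules: pooled
analysis adjusts for cross-group PCs and keeps variants with MAF > 1% in at
least one ancestry group; per-group analyses adjust for that group's own
PCs and keep variants with MAF > 1% within the group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from multigwas.popsim import GenotypePanel, VariantTable
from multigwas.phenosim import PhenotypeSet
from multigwas.structure import PCSet

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = [
    "CHR", "POS", "ID", "REF", "ALT", "A1FREQ", "N", "BETA", "SE", "P", "CONVERGED", "SCOPE",
]


def maf_inclusion(
    variant_table: VariantTable,
    mode: str = "any_group",
    threshold: float = 0.01,
    group: str | None = None,
) -> list[str]:
    """Variant ids passing the minor-allele-frequency rule.

    MAF is ``min(f, 1-f)`` per group.  ``any_group`` keeps variants common
    in at least one ancestry group (pooled and meta-analysis rule);
    ``all_groups`` requires MAF > threshold in every group (the
    MR-MEGA output restriction); ``this_group`` applies the rule within a
    single named group.
    """
    maf = variant_table.freq.apply(lambda f: np.minimum(f, 1.0 - f))
    if mode == "any_group":
        keep = (maf > threshold).any(axis=1)
    elif mode == "all_groups":
        keep = (maf > threshold).all(axis=1)
    elif mode == "this_group":
        if group is None:
            raise ValueError("this_group mode requires a group code")
        keep = maf[group] > threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [v for v, k in zip(variant_table.variant_id, keep.to_numpy()) if k]


class GWASResults:
    """Per-variant association results for one analysis scope."""

    def __init__(self, frame: pd.DataFrame, scope: str, trait_type: str = "continuous"):
        self.frame = frame.reset_index(drop=True)
        self.scope = scope
        self.trait_type = trait_type

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def pvalues(self) -> np.ndarray:
        return self.frame["p"].to_numpy()

    def significant(self, threshold: float = 5e-8) -> pd.DataFrame:
        p = self.frame["p"]
        return self.frame[p.notna() & (p <= threshold)]

    def summary(self, threshold: float = 5e-8) -> str:
        f = self.frame
        ok = f["converged"].sum()
        n_sig = len(self.significant(threshold))
        lines = [
            f"GWAS results [{self.scope}] ({self.trait_type} trait)",
            f"  variants tested : {len(f)}  (converged {ok})",
            f"  significant (p <= {threshold:g}) : {n_sig}",
        ]
        top = f.nsmallest(min(5, len(f)), "p")
        if len(top):
            lines.append("  top hits:")
            for _, r in top.iterrows():
                lines.append(
                    f"    {r['variant_id']:>16}  beta={r['beta']:+.4f}  "
                    f"se={r['se']:.4f}  p={r['p']:.3e}"
                )
        return "\n".join(lines)

    def to_sumstats(self) -> pd.DataFrame:
        """Summary statistics in the tabular dialect common to GWAS tools."""
        f = self.frame
        return pd.DataFrame(
            {
                "CHR": f["chrom"],
                "POS": f["pos_bp"],
                "ID": f["variant_id"],
                "REF": f["allele_ref"],
                "ALT": f["allele_alt"],
                "A1FREQ": f["freq"],
                "N": f["n"],
                "BETA": f["beta"],
                "SE": f["se"],
                "P": f["p"],
                "CONVERGED": f["converged"],
                "SCOPE": self.scope,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_sumstats().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_sumstats(cls, frame: pd.DataFrame, scope: str | None = None) -> "GWASResults":
        scope = scope or (frame["SCOPE"].iloc[0] if "SCOPE" in frame else "unknown")
        out = pd.DataFrame(
            {
                "variant_id": frame["ID"],
                "chrom": frame["CHR"].astype(str),
                "pos_bp": frame["POS"],
                "allele_ref": frame.get("REF", "A"),
                "allele_alt": frame.get("ALT", "G"),
                "freq": frame["A1FREQ"],
                "n": frame["N"],
                "beta": frame["BETA"],
                "se": frame["SE"],
                "p": frame["P"],
                "converged": frame.get("CONVERGED", True),
            }
        )
        return cls(out, scope=scope)


@dataclass
class StudyStats:
    """One ancestry group's contribution to a meta-analysis."""

    group: str
    results: GWASResults
    freq: pd.Series  # per-variant ALT frequency within the group
    n: int


def _variant_meta(panel: GenotypePanel, cols: np.ndarray) -> pd.DataFrame:
    v = panel.variants.variants.iloc[cols]
    return v[["variant_id", "chrom", "pos_bp", "allele_ref", "allele_alt"]].reset_index(drop=True)


class LinearGWAS:
    """Per-variant ordinary least squares with covariate adjustment.

    Parameters
    ----------
    endog : array or PhenotypeSet
        Continuous outcome.
    panel : GenotypePanel
        Genotypes; the ALT allele is the effect allele.
    covariates : array, optional
        n x p covariate matrix (no intercept column; one is added).
    variant_ids : list, optional
        Restrict testing to these variants.
    """

    def __init__(self, endog, panel: GenotypePanel, covariates=None, variant_ids=None, scope="pooled"):
        y = endog.values if isinstance(endog, PhenotypeSet) else np.asarray(endog, dtype=float)
        if len(y) == 0:
            raise ValueError("empty phenotype")
        if len(y) != panel.n_samples:
            raise ValueError("phenotype and panel sample counts differ")
        self.endog = y
        self.panel = panel
        self.scope = scope
        n = len(y)
        C = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("covariate matrix is rank deficient after adding intercept")
        self.covariates = C
        if variant_ids is None:
            self._cols = np.arange(panel.n_variants)
        else:
            idx = pd.Index(panel.variants.variant_id)
            self._cols = idx.get_indexer(list(variant_ids))
            if (self._cols < 0).any():
                raise KeyError("variant id(s) not in panel")

    def fit(self, chunk_size: int = 4_096) -> GWASResults:
        y = self.endog
        C = self.covariates
        n = len(y)
        df = n - C.shape[1] - 1
        Q, _ = np.linalg.qr(C)
        y_r = y - Q @ (Q.T @ y)
        yss = float(y_r @ y_r)

        m = len(self._cols)
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        p = np.full(m, np.nan)
        converged = np.zeros(m, dtype=bool)
        freq = np.empty(m)

        for s in range(0, m, chunk_size):
            cols = self._cols[s : s + chunk_size]
            G = self.panel.dosage[:, cols].astype(np.float64)
            freq[s : s + chunk_size] = G.mean(axis=0) / 2.0
            G_r = G - Q @ (Q.T @ G)
            gg = np.einsum("ij,ij->j", G_r, G_r)
            ok = gg > 1e-12
            b = np.where(ok, (G_r.T @ y_r) / np.where(ok, gg, 1.0), np.nan)
            rss = np.maximum(yss - b**2 * gg, 0.0)
            sigma2 = rss / df
            s_e = np.sqrt(np.where(ok, sigma2 / np.where(ok, gg, 1.0), np.nan))
            sl = slice(s, s + len(cols))
            beta[sl], se[sl], converged[sl] = b, s_e, ok
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.abs(b / s_e)
            p[sl] = np.where(ok, 2.0 * stats.norm.sf(z), np.nan)

        frame = _variant_meta(self.panel, self._cols)
        frame["freq"] = freq
        frame["n"] = n
        frame["beta"] = beta
        frame["se"] = se
        frame["p"] = p
        frame["converged"] = converged
        return GWASResults(frame, scope=self.scope, trait_type="continuous")


class LogisticGWAS:
    """Per-variant logistic regression by IRLS (max 25 iterations,
    convergence |delta loglik| < 1e-8); Wald beta/se/p.  Separation or
    non-convergence is reported via ``converged = False`` with no p-value,
    not repaired."""

    MAX_ITER = 25
    TOL = 1e-8

    def __init__(self, endog, panel: GenotypePanel, covariates=None, variant_ids=None, scope="pooled"):
        y = endog.values if isinstance(endog, PhenotypeSet) else np.asarray(endog)
        y = y.astype(np.float64)
        if len(y) == 0:
            raise ValueError("empty phenotype")
        if len(y) != panel.n_samples:
            raise ValueError("phenotype and panel sample counts differ")
        classes = np.unique(y)
        if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
            raise ValueError("binary outcome must contain both classes 0 and 1")
        self.endog = y
        self.panel = panel
        self.scope = scope
        n = len(y)
        C = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("covariate matrix is rank deficient after adding intercept")
        self.covariates = C
        if variant_ids is None:
            self._cols = np.arange(panel.n_variants)
        else:
            idx = pd.Index(panel.variants.variant_id)
            self._cols = idx.get_indexer(list(variant_ids))
            if (self._cols < 0).any():
                raise KeyError("variant id(s) not in panel")

    def _fit_one(self, X: np.ndarray) -> tuple[float, float, bool]:
        y = self.endog
        k = X.shape[1]
        b = np.zeros(k)
        b[0] = np.log(y.mean() / (1.0 - y.mean()))
        ll_old = -np.inf
        for _ in range(self.MAX_ITER):
            eta = np.clip(X @ b, -30.0, 30.0)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            if w.max() < 1e-10:
                return np.nan, np.nan, False
            XtW = X.T * w
            H = XtW @ X
            grad = X.T @ (y - mu)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                return np.nan, np.nan, False
            b = b + step
            ll = float(y @ np.clip(X @ b, -30, 30) - np.logaddexp(0.0, np.clip(X @ b, -30, 30)).sum())
            if abs(ll - ll_old) < self.TOL:
                try:
                    cov = np.linalg.inv(H)
                except np.linalg.LinAlgError:
                    return np.nan, np.nan, False
                se = float(np.sqrt(cov[-1, -1]))
                if not np.isfinite(b[-1]) or not np.isfinite(se) or abs(b[-1]) > 20:
                    return float(b[-1]), se, False
                return float(b[-1]), se, True
            ll_old = ll
        return np.nan, np.nan, False

    def fit(self) -> GWASResults:
        m = len(self._cols)
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        p = np.full(m, np.nan)
        converged = np.zeros(m, dtype=bool)
        freq = np.empty(m)
        C = self.covariates
        for i, col in enumerate(self._cols):
            g = self.panel.dosage[:, col].astype(np.float64)
            freq[i] = g.mean() / 2.0
            if g.var() < 1e-12:
                continue
            X = np.column_stack([C, g])
            b, s_e, ok = self._fit_one(X)
            beta[i], se[i], converged[i] = b, s_e, ok
            if ok:
                p[i] = 2.0 * stats.norm.sf(abs(b / s_e))

        frame = _variant_meta(self.panel, self._cols)
        frame["freq"] = freq
        frame["n"] = len(self.endog)
        frame["beta"] = beta
        frame["se"] = se
        frame["p"] = p
        frame["converged"] = converged
        return GWASResults(frame, scope=self.scope, trait_type="binary")


def run_gwas_linear(panel_subset, phenotype, covariates=None, variant_ids=None, scope="pooled") -> GWASResults:
    """Functional wrapper over :class:`LinearGWAS`."""
    return LinearGWAS(phenotype, panel_subset, covariates, variant_ids, scope).fit()


def run_gwas_logistic(panel_subset, phenotype, covariates=None, variant_ids=None, scope="pooled") -> GWASResults:
    """Functional wrapper over :class:`LogisticGWAS`."""
    return LogisticGWAS(phenotype, panel_subset, covariates, variant_ids, scope).fit()


def _base_covariates(panel: GenotypePanel) -> np.ndarray:
    return np.column_stack([panel.age, panel.sex])


def _group_freq_table(panel: GenotypePanel) -> VariantTable:
    """Variant table whose freq columns cover every labeled group in the
    panel, falling back to empirical group frequencies when a group (e.g.
    an admixed cohort) has no model frequencies."""
    vt = panel.variants
    if all(g in vt.freq.columns for g in panel.groups):
        return vt
    return VariantTable(vt.variants, panel.sample_frequencies(by_group=True))


def _align_phenotype(panel: GenotypePanel, phenotype) -> np.ndarray:
    if isinstance(phenotype, PhenotypeSet):
        order = {s: i for i, s in enumerate(phenotype.sample_id)}
        rows = [order[s] for s in panel.sample_id]
        return phenotype.values[rows]
    y = np.asarray(phenotype)
    if len(y) != panel.n_samples:
        raise ValueError("phenotype and panel sample counts differ")
    return y


def run_strategy_pooled(
    panel: GenotypePanel,
    phenotype,
    pcs: PCSet,
    trait_type: str = "continuous",
    maf_threshold: float = 0.01,
    n_pcs: int = 10,
    adjust_age_sex: bool = True,
) -> GWASResults:
    """Pooled analysis: one GWAS on all samples, adjusted for the top
    cross-group PCs (plus age and sex), on variants with MAF > threshold in
    at least one ancestry group."""
    if not pcs.scope.startswith("cross_group"):
        raise ValueError("pooled strategy requires cross_group PCs")
    y = _align_phenotype(panel, phenotype)
    keep = maf_inclusion(_group_freq_table(panel), "any_group", maf_threshold)
    order = {s: i for i, s in enumerate(pcs.sample_id)}
    rows = [order[s] for s in panel.sample_id]
    cov = pcs.scores[rows, :n_pcs]
    if adjust_age_sex:
        cov = np.column_stack([_base_covariates(panel), cov])
    engine = LinearGWAS if trait_type == "continuous" else LogisticGWAS
    return engine(y, panel, cov, keep, scope="pooled").fit()


def run_strategy_pergroup(
    panel: GenotypePanel,
    phenotype,
    pcs_by_group: dict[str, PCSet],
    trait_type: str = "continuous",
    maf_threshold: float = 0.01,
    n_pcs: int = 10,
    min_group_n: int = 50,
    adjust_age_sex: bool = True,
) -> list[StudyStats]:
    """Ancestry-group-specific GWAS: one analysis per group with its own
    PCs, on variants with MAF > threshold within that group.  Groups below
    ``min_group_n`` samples are skipped with a log entry."""
    y_all = _align_phenotype(panel, phenotype)
    freq_table = _group_freq_table(panel)
    out: list[StudyStats] = []
    for g in panel.groups:
        mask = panel.group_mask(g)
        n_g = int(mask.sum())
        if n_g < min_group_n:
            logger.info("skipping group %s with n=%d < %d", g, n_g, min_group_n)
            continue
        sub = panel.subset_samples(np.flatnonzero(mask))
        keep = maf_inclusion(freq_table, "this_group", maf_threshold, group=g)
        pcs = pcs_by_group[g]
        order = {s: i for i, s in enumerate(pcs.sample_id)}
        rows = [order[s] for s in sub.sample_id]
        cov = pcs.scores[rows, :n_pcs]
        if adjust_age_sex:
            cov = np.column_stack([_base_covariates(sub), cov])
        y = y_all[mask]
        if trait_type == "binary" and len(np.unique(y)) < 2:
            logger.info("skipping group %s: single outcome class", g)
            continue
        engine = LinearGWAS if trait_type == "continuous" else LogisticGWAS
        res = engine(y, sub, cov, keep, scope=f"group:{g}").fit()
        freq = pd.Series(
            res.frame["freq"].to_numpy(), index=res.frame["variant_id"].to_numpy()
        )
        out.append(StudyStats(group=g, results=res, freq=freq, n=n_g))
    return out
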