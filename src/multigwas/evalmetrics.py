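"""Evaluation layer: power, type-I error, genomic inflation, LD clumping.

Power is measured two ways against a known causal set: exact recovery (the
causal variant itself reaches genome-wide significance, default threshold
5e-8) and LD-based recovery (some significant variant on the same
chromosome lies within +/-500 kb of the causal variant).  Type-I error is
the empirical exceedance rate of null p-values at nominal levels with
Wilson 95% intervals.  Genomic inflation is the median-chi-square lambda;
lambda_1000 rescales it to an effective study of 1,000 cases and 1,000
controls (or n = 1,000 for quantitative traits).  Clumping greedily groups
significant variants into independent signals by genotype r^2 within a
physical radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from multigwas.popsim import GenotypePanel

logger = logging.getLogger(__name__)

GENOME_WIDE = 5e-8
_CHI2_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.4549...


@dataclass
class EvalReport:
    """Aggregate evaluation of one analysis against a known causal set."""

    power_exact: float
    power_ld: float
    n_causal: int
    n_significant: int
    n_independent_significant: int | None = None
    type1_table: pd.DataFrame | None = None
    lambda_gc: float | None = None
    lambda_1000: float | None = None
    threshold: float = GENOME_WIDE

    def to_dict(self) -> dict:
        return {
            "power_exact": self.power_exact,
            "power_ld": self.power_ld,
            "n_causal": self.n_causal,
            "n_significant": self.n_significant,
            "n_independent_significant": self.n_independent_significant,
            "lambda_gc": self.lambda_gc,
            "lambda_1000": self.lambda_1000,
            "threshold": self.threshold,
        }


def _pframe(assoc_results) -> pd.DataFrame:
    """Accept GWASResults, MetaResults, or a raw frame; normalize to
    columns variant_id, chrom, pos_bp, p."""
    frame = getattr(assoc_results, "frame", assoc_results)
    pcol = "p" if "p" in frame.columns else "p_assoc"
    out = frame[["variant_id"]].copy()
    out["p"] = frame[pcol]
    for c in ("chrom", "pos_bp"):
        if c in frame.columns:
            out[c] = frame[c]
    return out


def power_exact(assoc_results, causal_ids, threshold: float = GENOME_WIDE) -> float:
    """Fraction of causal variants that are themselves significant; causal
    variants absent from the output count as not recovered."""
    causal_ids = list(causal_ids)
    if not causal_ids:
        raise ValueError("causal set is empty")
    f = _pframe(assoc_results)
    sig = set(f.loc[f["p"].notna() & (f["p"] <= threshold), "variant_id"])
    return sum(v in sig for v in causal_ids) / len(causal_ids)


def power_ld(
    assoc_results,
    causal_ids,
    positions: pd.DataFrame,
    window_bp: int = 500_000,
    threshold: float = GENOME_WIDE,
) -> float:
    """Fraction of causal variants with a significant variant within
    +/-window_bp on the same chromosome.

    ``positions`` maps variant_id -> (chrom, pos_bp) for at least the
    causal set and all output variants (a variant-table frame works).
    """
    causal_ids = list(causal_ids)
    if not causal_ids:
        raise ValueError("causal set is empty")
    pos = positions.set_index("variant_id") if "variant_id" in positions.columns else positions
    f = _pframe(assoc_results)
    if "pos_bp" not in f.columns:
        loc = pos.reindex(f["variant_id"])
        f["chrom"], f["pos_bp"] = loc["chrom"].to_numpy(), loc["pos_bp"].to_numpy()
    sig = f[f["p"].notna() & (f["p"] <= threshold)]
    by_chrom = {c: np.sort(sub["pos_bp"].to_numpy()) for c, sub in sig.groupby("chrom")}

    hits = 0
    for v in causal_ids:
        c, q = pos.loc[v, "chrom"], pos.loc[v, "pos_bp"]
        arr = by_chrom.get(c)
        if arr is None or len(arr) == 0:
            continue
        i = np.searchsorted(arr, q)
        near = []
        if i < len(arr):
            near.append(arr[i] - q)
        if i > 0:
            near.append(q - arr[i - 1])
        if near and min(near) <= window_bp:
            hits += 1
    return hits / len(causal_ids)


def type1_error(pvalues, nominal_levels=(0.05, 1e-3)) -> pd.DataFrame:
    """Empirical type-I error rates with Wilson 95% CIs.

    One row per nominal level: the exceedance rate ``mean(p <= level)``,
    the Wilson interval, ``flag`` set when the interval excludes the
    nominal rate (calibration failure in either direction), and
    ``inflated`` set only when the interval lies wholly above it.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    rows = []
    z = stats.norm.ppf(0.975)
    n = len(p)
    for a in nominal_levels:
        k = int((p <= a).sum())
        phat = k / n
        denom = 1.0 + z**2 / n
        centre = (phat + z**2 / (2 * n)) / denom
        half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
        lo, hi = centre - half, centre + half
        rows.append(
            {
                "level": a,
                "n_tests": n,
                "n_exceed": k,
                "rate": phat,
                "ci_low": lo,
                "ci_high": hi,
                "flag": not (lo <= a <= hi),
                "inflated": lo > a,
            }
        )
    return pd.DataFrame(rows)


def genomic_inflation(
    pvalues,
    n_cases: int | None = None,
    n_controls: int | None = None,
    n_quantitative: int | None = None,
) -> tuple[float, float]:
    """Median-based genomic inflation factor and its lambda_1000 rescaling.

    ``lambda = median(chi2_1 quantile of 1-p) / 0.4549``.  For binary
    traits ``lambda_1000 = 1 + (lambda - 1) (1/n_cases + 1/n_controls) /
    (2/1000)``; for quantitative traits the two reciprocal terms are
    replaced by ``2/n`` against ``2/1000``.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    chi = stats.chi2.isf(p, 1)
    lam = float(np.median(chi) / _CHI2_MEDIAN)

    if n_cases is not None and n_controls is not None:
        factor = (1.0 / n_cases + 1.0 / n_controls) / (2.0 / 1000.0)
    elif n_quantitative is not None:
        factor = (2.0 / n_quantitative) / (2.0 / 1000.0)
    else:
        raise ValueError("supply n_cases/n_controls or n_quantitative")
    lam1000 = 1.0 + (lam - 1.0) * factor
    return lam, lam1000


def ld_clump(
    assoc_results,
    panel: GenotypePanel,
    r2_threshold: float = 0.1,
    radius_bp: int = 500_000,
    threshold: float = GENOME_WIDE,
) -> list[str]:
    """Greedy LD clumping of significant variants into independent signals.

    Repeatedly takes the most significant remaining variant as an index
    (ties broken by position), removes significant variants within
    ``radius_bp`` whose genotype r^2 with the index exceeds the threshold,
    and returns the index variants in selection order.
    """
    f = _pframe(assoc_results)
    if "pos_bp" not in f.columns:
        v = panel.variants.variants.set_index("variant_id")
        loc = v.reindex(f["variant_id"])
        f["chrom"], f["pos_bp"] = loc["chrom"].to_numpy(), loc["pos_bp"].to_numpy()
    sig = f[f["p"].notna() & (f["p"] <= threshold)].copy()
    if sig.empty:
        return []
    sig = sig.sort_values(["p", "pos_bp"], kind="mergesort").reset_index(drop=True)

    idx = pd.Index(panel.variants.variant_id)
    cols = idx.get_indexer(sig["variant_id"])
    G = panel.dosage[:, cols].astype(np.float64)
    Gc = G - G.mean(axis=0)
    norms = np.sqrt((Gc**2).sum(axis=0))

    alive = np.ones(len(sig), dtype=bool)
    chrom = sig["chrom"].to_numpy()
    pos = sig["pos_bp"].to_numpy()
    out: list[str] = []
    for i in range(len(sig)):
        if not alive[i]:
            continue
        out.append(sig["variant_id"].iloc[i])
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= radius_bp)
        near[i] = False
        cand = np.flatnonzero(near)
        if len(cand):
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (Gc[:, cand].T @ Gc[:, i]) / (norms[cand] * norms[i])
            r2 = np.nan_to_num(r**2)
            alive[cand[r2 > r2_threshold]] = False
        alive[i] = False
    return out


def evaluate(
    assoc_results,
    causal_ids,
    panel: GenotypePanel | None = None,
    threshold: float = GENOME_WIDE,
    window_bp: int = 500_000,
    clump: bool = False,
    n_quantitative: int | None = None,
) -> EvalReport:
    """One-stop evaluation of a result set against a known causal set."""
    positions = panel.variants.variants if panel is not None else None
    f = _pframe(assoc_results)
    n_sig = int((f["p"].notna() & (f["p"] <= threshold)).sum())
    p_exact = power_exact(assoc_results, causal_ids, threshold)
    p_ld = power_ld(assoc_results, causal_ids, positions, window_bp, threshold) if positions is not None else float("nan")
    n_indep = len(ld_clump(assoc_results, panel, threshold=threshold)) if clump and panel is not None else None
    lam = lam1000 = None
    if n_quantitative is not None and f["p"].notna().sum() >= 100:
        lam, lam1000 = genomic_inflation(f["p"], n_quantitative=n_quantitative)
    return EvalReport(
        power_exact=p_exact,
        power_ld=p_ld,
        n_causal=len(list(causal_ids)),
        n_significant=n_sig,
        n_independent_significant=n_indep,
        lambda_gc=lam,
        lambda_1000=lam1000,
        threshold=threshold,
    )
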