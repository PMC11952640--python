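"""Scenario orchestration: end-to-end power and type-I-error comparisons.

A :class:`ScenarioConfig` describes one study design -- equal group sizes,
a fixed reference-group size, a fixed total size, an admixed four-group
design, or a null (type-I) grid -- at desk scale: thousands of samples and
tens of thousands of variants rather than the biobank-scale setting the
designs emulate.  :func:`run_scenario` simulates genotypes, computes PCs at
both scopes, generates phenotypes, runs the pooled, per-group and combined
analyses, and evaluates each replicate, returning per-replicate reports and
an aggregate table.  All randomness descends deterministically from
``base_seed``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from multigwas.assoc import maf_inclusion, run_strategy_pergroup, run_strategy_pooled, _group_freq_table
from multigwas.combine import MRMEGA, ivw_meta, select_num_axes
from multigwas.evalmetrics import EvalReport, evaluate, genomic_inflation, type1_error
from multigwas.phenosim import (
    make_stratification,
    sample_case_control,
    simulate_binary,
    simulate_continuous,
    simulate_null_phenotype,
)
from multigwas.popsim import (
    AdmixtureSpec,
    GenotypePanel,
    LDBlockSpec,
    concat_panels,
    simulate_admixed_panel,
    simulate_frequencies,
    simulate_panel,
)
from multigwas.structure import compute_pcs, ld_prune

logger = logging.getLogger(__name__)

DESIGNS = ("equal_sizes", "fixed_eur", "fixed_total", "admixed", "type1")


@dataclass
class ScenarioConfig:
    """Configuration of one simulation scenario."""

    design: str = "equal_sizes"
    group_sizes: dict = field(default_factory=lambda: {g: 2_000 for g in ("AFR", "AMR", "EAS", "EUR", "SAS")})
    n_variants: int = 20_000
    causal_fraction: float | None = None
    n_causal: int | None = 100
    h2: float = 0.4
    trait_type: str = "continuous"
    alpha_grid: tuple = (0.0, 0.002, 0.005, 0.01, 0.02, 0.05)
    strat_scope: str = "group_specific"
    fst_per_group: dict = field(
        default_factory=lambda: {"AFR": 0.15, "AMR": 0.10, "EAS": 0.12, "EUR": 0.08, "SAS": 0.10}
    )
    n_replicates: int = 10
    base_seed: int = 0
    significance: float = 5e-8
    maf_threshold: float = 0.01
    prune_r2: float = 0.1
    prune_window_bp: int = 500_000
    ld_window_bp: int = 500_000
    n_pcs: int = 10
    ld_block_bp: int = 100_000
    ld_rho: float = 0.8
    spacing_bp: int = 5_000
    # hierarchical within-group substructure, standing in for the internal
    # admixture gradients of real continental ancestry groups
    n_subpops: int = 3
    sub_fst: float = 0.02
    pc_strat_alpha: float = 0.0026  # group-specific PC variance in power designs
    n_pc_strat: int = 2
    target_prevalence: float = 0.1
    case_pool_multiplier: int = 20
    admix_proportions: tuple = (0.5, 0.2)  # first-source share of the two admixed groups
    admix_generations: int = 10
    min_group_n: int = 50
    # Replicates redraw phenotypes on one fixed genotype panel (the study
    # design being emulated); set True to resimulate genotypes every time.
    refresh_genotypes_each_replicate: bool = False

    def validate(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be nonnegative")
        if self.n_variants < 10:
            raise ValueError("n_variants too small")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("alpha_grid", "admix_proportions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    aggregate: pd.DataFrame
    reports: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _seed(base: int, *tags: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base)] + [int(t) for t in tags])


def _simulate_design_panel(cfg: ScenarioConfig, rep: int) -> GenotypePanel:
    if cfg.design == "admixed":
        groups = ["EUR", "AFR"]
        fst = {g: cfg.fst_per_group.get(g, 0.1) for g in groups}
        vt = simulate_frequencies(
            cfg.n_variants, groups, fst, seed=_seed(cfg.base_seed, 1, rep),
            spacing_bp=cfg.spacing_bp, n_subpops=cfg.n_subpops, sub_fst=cfg.sub_fst,
        )
        n_each = next(iter(cfg.group_sizes.values()))
        ld = LDBlockSpec(cfg.ld_block_bp, cfg.ld_rho)
        ref = simulate_panel(vt, {"EUR": n_each, "AFR": n_each}, ld, seed=_seed(cfg.base_seed, 2, rep))
        adm = []
        for i, prop in enumerate(cfg.admix_proportions):
            spec = AdmixtureSpec(("EUR", "AFR"), prop, cfg.admix_generations)
            adm.append(
                simulate_admixed_panel(
                    vt, spec, n_each, seed=_seed(cfg.base_seed, 3 + i, rep),
                    group_label=f"ADMIX{int(prop * 100)}",
                )
            )
        return concat_panels([ref] + adm)

    groups = list(cfg.group_sizes)
    fst = {g: cfg.fst_per_group.get(g, 0.1) for g in groups}
    vt = simulate_frequencies(
        cfg.n_variants, groups, fst, seed=_seed(cfg.base_seed, 1, rep),
        spacing_bp=cfg.spacing_bp, n_subpops=cfg.n_subpops, sub_fst=cfg.sub_fst,
    )
    ld = LDBlockSpec(cfg.ld_block_bp, cfg.ld_rho)
    return simulate_panel(vt, cfg.group_sizes, ld, seed=_seed(cfg.base_seed, 2, rep))


def _compute_all_pcs(panel: GenotypePanel, cfg: ScenarioConfig):
    pruned = ld_prune(panel, cfg.prune_r2, cfg.prune_window_bp)
    pcs_cross = compute_pcs(panel, cfg.n_pcs, "cross_group", pruned)
    pcs_group = {
        g: compute_pcs(panel, cfg.n_pcs, f"per_group:{g}", pruned)
        for g, n in panel.group_sizes.items()
        if n > cfg.n_pcs
    }
    return pruned, pcs_cross, pcs_group


def _run_strategies(panel, pheno, pcs_cross, pcs_group, cfg):
    """Pooled, IVW and (if >=4 groups) MR-MEGA result sets."""
    pooled = run_strategy_pooled(
        panel, pheno, pcs_cross, cfg.trait_type, cfg.maf_threshold, cfg.n_pcs
    )
    studies = run_strategy_pergroup(
        panel, pheno, pcs_group, cfg.trait_type, cfg.maf_threshold, cfg.n_pcs, cfg.min_group_n
    )
    out = {"pooled": pooled, "ivw": ivw_meta(studies)}
    T = select_num_axes(len(studies))
    if T is not None:
        common = maf_inclusion(_group_freq_table(panel), "all_groups", cfg.maf_threshold)
        out["mrmega"] = MRMEGA(studies, T=T).fit(variant_ids=common).frame
    return out, studies


def _power_replicate(cfg: ScenarioConfig, rep: int, genotypes=None) -> dict[str, EvalReport]:
    if genotypes is None:
        panel = _simulate_design_panel(cfg, rep)
        _, pcs_cross, pcs_group = _compute_all_pcs(panel, cfg)
    else:
        panel, pcs_cross, pcs_group = genotypes

    pc_effects = None
    if cfg.pc_strat_alpha > 0 and cfg.n_pc_strat > 0:
        spec = make_stratification(pcs_group, cfg.pc_strat_alpha, "group_specific", k=cfg.n_pc_strat)
        pc_effects = (pcs_group, spec)

    if cfg.trait_type == "continuous":
        pheno = simulate_continuous(
            panel, None, cfg.causal_fraction, cfg.h2, pc_effects,
            seed=_seed(cfg.base_seed, 10, rep), n_causal=cfg.n_causal,
        )
        analysis_panel = panel
    else:
        pheno = simulate_binary(
            panel, None, cfg.causal_fraction, cfg.h2, cfg.target_prevalence, pc_effects,
            seed=_seed(cfg.base_seed, 10, rep), n_causal=cfg.n_causal,
        )
        idx = sample_case_control(pheno, 1.0, seed=_seed(cfg.base_seed, 11, rep))
        analysis_panel = panel.subset_samples(idx)
        pheno = pheno  # PhenotypeSet aligns by sample_id inside the engines

    results, _ = _run_strategies(analysis_panel, pheno, pcs_cross, pcs_group, cfg)
    reports = {}
    for name, res in results.items():
        reports[name] = evaluate(
            res, pheno.causal_ids, panel, cfg.significance, cfg.ld_window_bp
        )
    return reports


def _type1_replicate(cfg: ScenarioConfig, rep: int, genotypes=None) -> pd.DataFrame:
    if genotypes is None:
        panel = _simulate_design_panel(cfg, rep)
        _, pcs_cross, pcs_group = _compute_all_pcs(panel, cfg)
    else:
        panel, pcs_cross, pcs_group = genotypes
    rows = []
    for scope in ("cross_group", "group_specific"):
        pcs = pcs_cross if scope == "cross_group" else pcs_group
        for a_i, alpha in enumerate(cfg.alpha_grid):
            spec = make_stratification(pcs, alpha, scope, k=cfg.n_pcs)
            pheno = simulate_null_phenotype(pcs, spec, seed=_seed(cfg.base_seed, 20, rep, a_i))
            results, _ = _run_strategies(panel, pheno, pcs_cross, pcs_group, cfg)
            for name, res in results.items():
                frame = getattr(res, "frame", res)
                pcol = "p" if "p" in frame.columns else "p_assoc"
                pvals = frame[pcol].dropna().to_numpy()
                tab = type1_error(pvals, (0.05, 1e-3))
                lam, lam1000 = genomic_inflation(pvals, n_quantitative=panel.n_samples)
                for _, r in tab.iterrows():
                    rows.append(
                        {
                            "replicate": rep,
                            "scope": scope,
                            "alpha": alpha,
                            "strategy": name,
                            "level": r["level"],
                            "rate": r["rate"],
                            "ci_low": r["ci_low"],
                            "ci_high": r["ci_high"],
                            "flag": r["flag"],
                            "inflated": r["inflated"],
                            "lambda_gc": lam,
                            "lambda_1000": lam1000,
                        }
                    )
    return pd.DataFrame(rows)


def run_scenario(config: ScenarioConfig, out_dir=None) -> ScenarioResult:
    """Run all replicates of a scenario and aggregate.

    Power designs produce one row per (replicate, strategy) with both
    power metrics; the type1 design produces the per-level calibration
    table.  Failed replicates are logged and skipped; the rest proceed.
    """
    config.validate()
    genotypes = None
    if not config.refresh_genotypes_each_replicate:
        panel = _simulate_design_panel(config, 0)
        _, pcs_cross, pcs_group = _compute_all_pcs(panel, config)
        genotypes = (panel, pcs_cross, pcs_group)
    reports, rows = [], []
    for rep in range(config.n_replicates):
        try:
            if config.design == "type1":
                tab = _type1_replicate(config, rep, genotypes)
                reports.append(tab)
                rows.append(tab)
            else:
                rep_reports = _power_replicate(config, rep, genotypes)
                reports.append(rep_reports)
                for name, r in rep_reports.items():
                    rows.append(
                        pd.DataFrame(
                            [
                                {
                                    "replicate": rep,
                                    "strategy": name,
                                    "power_exact": r.power_exact,
                                    "power_ld": r.power_ld,
                                    "n_causal": r.n_causal,
                                    "n_significant": r.n_significant,
                                }
                            ]
                        )
                    )
        except Exception:  # noqa: BLE001 - a replicate failure must not kill the run
            logger.exception("replicate %d failed; continuing", rep)
    if not rows:
        raise RuntimeError("all replicates failed")
    aggregate = pd.concat(rows, ignore_index=True)

    manifest = {
        "config": asdict(config),
        "version": "0.1.0",
        "n_replicates_completed": len(reports),
        "aggregate_sha256": hashlib.sha256(
            aggregate.to_csv(index=False).encode()
        ).hexdigest(),
    }
    result = ScenarioResult(config=config, aggregate=aggregate, reports=reports, manifest=manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        aggregate.to_csv(out / "aggregate.tsv", sep="\t", index=False)
        config.to_yaml(out / "config.yaml")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return result


def relative_efficiency_table(aggregate: pd.DataFrame) -> pd.DataFrame:
    """Power of each strategy relative to pooled analysis.

    One row per (strategy, metric): the ratio of mean power to mean pooled
    power.  Cells where pooled power is zero are flagged undefined.
    """
    if "strategy" not in aggregate.columns:
        raise ValueError("expected a power aggregate table")
    means = aggregate.groupby("strategy")[["power_exact", "power_ld"]].mean()
    if "pooled" not in means.index:
        raise ValueError("aggregate lacks pooled results")
    rows = []
    for strat in means.index:
        for metric in ("power_exact", "power_ld"):
            base = means.loc["pooled", metric]
            val = means.loc[strat, metric]
            rows.append(
                {
                    "strategy": strat,
                    "metric": metric,
                    "power": val,
                    "pooled_power": base,
                    "relative_efficiency": val / base if base > 0 else np.nan,
                    "undefined": base == 0,
                }
            )
    return pd.DataFrame(rows)
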