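"""Synthetic multi-population genotype panels.

Allele frequencies diverge across ancestry groups under the Balding-Nichols
model: around an ancestral frequency ``p`` the group frequency is
``f_j ~ Beta(p(1-F_j)/F_j, (1-p)(1-F_j)/F_j)`` so that
``E[f_j] = p`` and ``Var(f_j) = F_j p (1-p)``.

Local linkage disequilibrium is produced by first-order haplotype chains:
within a physical block, neighbouring alleles have correlation ``rho`` while
every variant keeps its marginal group frequency; blocks are independent.
Admixed cohorts are generated by drawing ancestry switch points along the
genetic map as a Poisson process with rate ``n_generations`` per Morgan and
sampling alleles from the segment-ancestry group frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six continental ancestry group codes used throughout; free-form extra
#: codes are accepted everywhere a group label appears.
ANCESTRY_CODES = ("AFR", "AMR", "EAS", "EUR", "MID", "SAS")


@dataclass
class VariantTable:
    """Per-variant metadata plus per-ancestry-group allele frequencies.

    Attributes
    ----------
    variants : pandas.DataFrame
        Columns ``variant_id, chrom, pos_bp, allele_ref, allele_alt,
        ancestral_freq, genetic_pos_cM``; one row per variant, positions
        strictly increasing within a chromosome.
    freq : pandas.DataFrame
        Group allele frequencies ``f_jl`` (rows aligned with ``variants``,
        one column per ancestry group), strictly inside (0, 1).
    """

    variants: pd.DataFrame
    freq: pd.DataFrame
    subpop_freq: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.freq = self.freq.reset_index(drop=True)
        if len(self.variants) != len(self.freq):
            raise ValueError("variants and freq must have the same length")
        if self.subpop_freq is not None:
            self.subpop_freq = self.subpop_freq.reset_index(drop=True)

    @property
    def variant_id(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def groups(self) -> list[str]:
        return list(self.freq.columns)

    def genetic_positions(self, map_rate_cM_per_Mb: float | None = None) -> np.ndarray:
        """Genetic positions in centimorgans, deriving them from ``pos_bp``
        at a constant rate when the table carries none."""
        cm = self.variants.get("genetic_pos_cM")
        if cm is not None and cm.notna().all():
            return cm.to_numpy(dtype=float)
        if map_rate_cM_per_Mb is None:
            raise ValueError(
                "variant table has no genetic map; set map_rate_cM_per_Mb "
                "(cM per Mb) to derive one from physical positions"
            )
        return self.variants["pos_bp"].to_numpy(dtype=float) * map_rate_cM_per_Mb / 1e6

    def subset(self, mask_or_ids) -> "VariantTable":
        if isinstance(mask_or_ids, (list, tuple, set)) or (
            isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype.kind in "US"
        ):
            keep = self.variants["variant_id"].isin(list(mask_or_ids)).to_numpy()
        else:
            keep = np.asarray(mask_or_ids, dtype=bool)
        return VariantTable(
            self.variants.loc[keep],
            self.freq.loc[keep],
            None if self.subpop_freq is None else self.subpop_freq.loc[keep],
        )


@dataclass
class LDBlockSpec:
    """Block-LD parameters for haplotype chains.

    ``block_length_bp`` delimits independent blocks; ``rho`` is the target
    correlation between adjacent haplotype alleles inside a block (clipped
    variant-by-variant to the Frechet-feasible range implied by the two
    marginal frequencies).
    """

    block_length_bp: int = 100_000
    rho: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.block_length_bp <= 0:
            raise ValueError("block_length_bp must be positive")


@dataclass
class AdmixtureSpec:
    """Two-way admixture: `source_groups[0]` contributes `target_proportion`
    of ancestry on average, mixing over ``n_generations``."""

    source_groups: tuple[str, str]
    target_proportion: float
    n_generations: int = 10
    map_rate_cM_per_Mb: float | None = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_proportion <= 1.0:
            raise ValueError("target_proportion must be in [0, 1]")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if len(self.source_groups) != 2:
            raise ValueError("exactly two source groups required")


@dataclass
class GenotypePanel:
    """Diploid dosage matrix with ancestry labels and covariate analogues.

    ``dosage`` holds ALT-allele counts in {0, 1, 2} (samples x variants,
    int8).  ``local_ancestry``, when present, is samples x variants x 2 with
    entries indexing ``ancestry_sources``; ``haplotypes`` (samples x variants
    x 2, 0/1) is kept when the simulation is phased so that dosage equals
    the haplotype sum.
    """

    dosage: np.ndarray
    sample_id: np.ndarray
    group_label: np.ndarray
    variants: VariantTable
    age: np.ndarray
    sex: np.ndarray
    local_ancestry: np.ndarray | None = None
    ancestry_sources: tuple[str, ...] | None = None
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_id = np.asarray(self.sample_id)
        self.group_label = np.asarray(self.group_label)
        n, m = self.dosage.shape
        if len(self.sample_id) != n or len(self.group_label) != n:
            raise ValueError("sample arrays must match dosage rows")
        if m != self.variants.n_variants:
            raise ValueError("variant table must match dosage columns")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.group_label:
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def group_sizes(self) -> dict[str, int]:
        labels, counts = np.unique(self.group_label, return_counts=True)
        sizes = dict(zip(labels.tolist(), counts.tolist()))
        return {g: sizes[g] for g in self.groups}

    def group_mask(self, group: str) -> np.ndarray:
        return self.group_label == group

    def sample_frequencies(self, by_group: bool = False):
        """Empirical ALT-allele frequencies, pooled or per group."""
        if not by_group:
            return self.dosage.mean(axis=0) / 2.0
        out = {}
        for g in self.groups:
            out[g] = self.dosage[self.group_mask(g)].mean(axis=0) / 2.0
        return pd.DataFrame(out)

    def subset_samples(self, index) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            dosage=self.dosage[index],
            sample_id=self.sample_id[index],
            group_label=self.group_label[index],
            variants=self.variants,
            age=self.age[index],
            sex=self.sex[index],
            local_ancestry=None if self.local_ancestry is None else self.local_ancestry[index],
            ancestry_sources=self.ancestry_sources,
            haplotypes=None if self.haplotypes is None else self.haplotypes[index],
        )

    def subset_variants(self, variant_ids) -> "GenotypePanel":
        idx = pd.Index(self.variants.variant_id)
        cols = idx.get_indexer(list(variant_ids))
        if (cols < 0).any():
            raise KeyError("unknown variant id(s) requested")
        vt = VariantTable(
            self.variants.variants.iloc[cols], self.variants.freq.iloc[cols]
        )
        return GenotypePanel(
            dosage=self.dosage[:, cols],
            sample_id=self.sample_id,
            group_label=self.group_label,
            variants=vt,
            age=self.age,
            sex=self.sex,
            local_ancestry=None if self.local_ancestry is None else self.local_ancestry[:, cols],
            ancestry_sources=self.ancestry_sources,
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, cols],
        )


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_frequencies(
    n_variants: int,
    groups=ANCESTRY_CODES[:5],
    fst_per_group=None,
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95),
    seed=None,
    *,
    chrom: str = "1",
    spacing_bp: int = 5_000,
    start_bp: int = 10_000,
    map_rate_cM_per_Mb: float = 1.0,
    n_subpops: int = 1,
    sub_fst: float = 0.0,
) -> VariantTable:
    """Draw ancestral and per-group allele frequencies.

    Ancestral frequencies are uniform on ``ancestral_freq_range``; per-group
    frequencies follow the Balding-Nichols Beta around the ancestral value at
    the group's F_ST.  ``fst_per_group`` maps group code to F in [0, 1);
    F = 0 returns the ancestral frequency exactly.  Variants are laid out on
    a single chromosome every ``spacing_bp`` bases with a uniform genetic
    map.  Variants that come out numerically monomorphic are dropped (and
    the count logged).

    ``n_subpops > 1`` adds hierarchical within-group substructure: each
    group is composed of that many subpopulations whose frequencies are a
    second Balding-Nichols draw around the group frequency at ``sub_fst``,
    emulating the internal structure (admixture gradients, fine-scale
    ancestry) that real continental ancestry groups carry.  Group labels and
    group-level frequencies are unchanged; the subpopulation frequencies are
    stored in ``subpop_freq`` and consumed by :func:`simulate_panel`.
    """
    lo, hi = ancestral_freq_range
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("ancestral_freq_range must satisfy 0 < min < max < 1")
    groups = list(groups)
    if fst_per_group is None:
        fst_per_group = {g: 0.1 for g in groups}
    for g in groups:
        f = fst_per_group[g]
        if not 0.0 <= f < 1.0:
            raise ValueError(f"F_ST for {g} must be in [0, 1)")

    rng = _rng(seed)
    p = rng.uniform(lo, hi, size=n_variants)
    freq = {}
    for g in groups:
        F = fst_per_group[g]
        if F == 0.0:
            freq[g] = p.copy()
        else:
            c = (1.0 - F) / F
            freq[g] = rng.beta(p * c, (1.0 - p) * c)
    freq = pd.DataFrame(freq)

    subpop = None
    if n_subpops > 1:
        if not 0.0 < sub_fst < 1.0:
            raise ValueError("sub_fst must be in (0, 1) when n_subpops > 1")
        cs = (1.0 - sub_fst) / sub_fst
        cols = {}
        for g in groups:
            fg = freq[g].to_numpy()
            for i in range(n_subpops):
                cols[f"{g}.{i}"] = np.clip(rng.beta(fg * cs, (1.0 - fg) * cs), 1e-6, 1 - 1e-6)
        subpop = pd.DataFrame(cols)

    pos = start_bp + spacing_bp * np.arange(n_variants)
    variants = pd.DataFrame(
        {
            "variant_id": [f"{chrom}:{q}" for q in pos],
            "chrom": chrom,
            "pos_bp": pos,
            "allele_ref": "A",
            "allele_alt": "G",
            "ancestral_freq": p,
            "genetic_pos_cM": pos * map_rate_cM_per_Mb / 1e6,
        }
    )

    poly = ((freq > 0.0) & (freq < 1.0)).all(axis=1).to_numpy()
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.info("dropping %d monomorphic simulated variants", n_dropped)
    return VariantTable(
        variants.loc[poly], freq.loc[poly], None if subpop is None else subpop.loc[poly]
    )


def _chain_haplotypes(
    freqs: np.ndarray,
    n_hap: int,
    new_block: np.ndarray,
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """First-order Markov haplotype chain with marginal frequencies ``freqs``.

    At a block start the allele is Bernoulli(f); inside a block the joint
    distribution of neighbouring alleles targets correlation ``rho``, with
    the joint probability clipped to the Frechet bounds so marginals are
    always honoured.
    """
    m = len(freqs)
    # variant-major layout keeps the chain's row accesses contiguous
    hap = np.empty((m, n_hap), dtype=np.int8)
    u = rng.random((m, n_hap), dtype=np.float32)
    hap[0] = u[0] < freqs[0]
    for l in range(1, m):
        q = freqs[l]
        if new_block[l] or rho == 0.0:
            hap[l] = u[l] < q
            continue
        pprev = freqs[l - 1]
        p11 = pprev * q + rho * np.sqrt(pprev * (1 - pprev) * q * (1 - q))
        p11 = min(max(p11, max(0.0, pprev + q - 1.0)), min(pprev, q))
        cond1 = p11 / pprev
        cond0 = (q - p11) / (1.0 - pprev)
        thresh = np.where(hap[l - 1] == 1, cond1, cond0)
        hap[l] = u[l] < thresh
    return np.ascontiguousarray(hap.T)


def simulate_panel(
    variant_table: VariantTable,
    group_sizes: dict[str, int],
    ld_block_spec: LDBlockSpec | None = None,
    seed=None,
    *,
    keep_haplotypes: bool = False,
) -> GenotypePanel:
    """Simulate a multi-population diploid panel.

    Each group's haplotypes are drawn from its own allele frequencies with
    block-structured first-order LD; dosage is the sum of two haplotypes, so
    with ``rho = 0`` the genotype at variant l in group j is Binomial(2,
    f_jl).  Groups with size 0 are simply absent.  Age and sex covariate
    analogues are attached per sample.
    """
    if ld_block_spec is None:
        ld_block_spec = LDBlockSpec()
    for g, n in group_sizes.items():
        if n < 0:
            raise ValueError(f"negative group size for {g}")
        if n > 0 and g not in variant_table.freq.columns:
            raise KeyError(f"no frequencies for group {g}")
    rng = _rng(seed)

    pos = variant_table.variants["pos_bp"].to_numpy()
    chroms = variant_table.variants["chrom"].to_numpy()
    block_id = pos // ld_block_spec.block_length_bp
    new_block = np.ones(len(pos), dtype=bool)
    if len(pos) > 1:
        new_block[1:] = (block_id[1:] != block_id[:-1]) | (chroms[1:] != chroms[:-1])

    sp = variant_table.subpop_freq
    dosages, labels, haps = [], [], []
    for g, n in group_sizes.items():
        if n == 0:
            continue
        sub_cols = [] if sp is None else [c for c in sp.columns if c.startswith(f"{g}.")]
        if sub_cols:
            # split the group across its subpopulations (remainder to the first)
            base, rem = divmod(n, len(sub_cols))
            sizes = [base + (1 if i < rem else 0) for i in range(len(sub_cols))]
            for col, n_sub in zip(sub_cols, sizes):
                if n_sub == 0:
                    continue
                f = sp[col].to_numpy()
                hap = _chain_haplotypes(f, 2 * n_sub, new_block, ld_block_spec.rho, rng)
                dosages.append(hap[0::2] + hap[1::2])
                if keep_haplotypes:
                    haps.append(np.stack([hap[0::2], hap[1::2]], axis=2))
        else:
            f = variant_table.freq[g].to_numpy()
            hap = _chain_haplotypes(f, 2 * n, new_block, ld_block_spec.rho, rng)
            dosages.append(hap[0::2] + hap[1::2])
            if keep_haplotypes:
                haps.append(np.stack([hap[0::2], hap[1::2]], axis=2))
        labels.extend([g] * n)

    if not dosages:
        raise ValueError("all group sizes are zero")
    dosage = np.concatenate(dosages, axis=0).astype(np.int8)
    n_total = dosage.shape[0]
    return GenotypePanel(
        dosage=dosage,
        sample_id=np.array([f"S{i:06d}" for i in range(n_total)]),
        group_label=np.array(labels),
        variants=variant_table,
        age=np.round(rng.normal(55.0, 8.0, size=n_total), 1),
        sex=rng.integers(0, 2, size=n_total).astype(np.int8),
        haplotypes=np.concatenate(haps, axis=0).astype(np.int8) if keep_haplotypes else None,
    )


def concat_panels(panels: list[GenotypePanel]) -> GenotypePanel:
    """Stack panels sample-wise on a shared variant table.

    All panels must carry identical variant ids; sample ids are prefixed
    with the panel index when duplicated.  Local ancestry and haplotypes
    are kept only if every panel has them.
    """
    first = panels[0]
    for p in panels[1:]:
        if not np.array_equal(p.variants.variant_id, first.variants.variant_id):
            raise ValueError("panels must share an identical variant set")
    ids = np.concatenate([p.sample_id for p in panels])
    if len(set(ids)) < len(ids):
        ids = np.concatenate(
            [np.array([f"P{i}_{s}" for s in p.sample_id]) for i, p in enumerate(panels)]
        )
    keep_la = all(p.local_ancestry is not None for p in panels)
    keep_h = all(p.haplotypes is not None for p in panels)
    return GenotypePanel(
        dosage=np.concatenate([p.dosage for p in panels], axis=0),
        sample_id=ids,
        group_label=np.concatenate([p.group_label for p in panels]),
        variants=first.variants,
        age=np.concatenate([p.age for p in panels]),
        sex=np.concatenate([p.sex for p in panels]),
        local_ancestry=np.concatenate([p.local_ancestry for p in panels], axis=0) if keep_la else None,
        ancestry_sources=first.ancestry_sources,
        haplotypes=np.concatenate([p.haplotypes for p in panels], axis=0) if keep_h else None,
    )


def simulate_admixed_panel(
    variant_table: VariantTable,
    admixture_spec: AdmixtureSpec,
    n_samples: int,
    seed=None,
    *,
    group_label: str = "ADMIX",
    source_haplotypes: dict[str, np.ndarray] | None = None,
) -> GenotypePanel:
    """Simulate a two-way admixed cohort with tracked local ancestry.

    Per haplotype and chromosome, ancestry switch points are a Poisson
    process along genetic distance with rate ``n_generations`` per Morgan;
    each segment's ancestry is the first source with probability
    ``target_proportion``.  Alleles come from the segment-ancestry group
    frequency, or are copied from ``source_haplotypes`` pools (group code ->
    haplotype matrix) when provided.
    """
    src = admixture_spec.source_groups
    for g in src:
        if g not in variant_table.freq.columns:
            raise KeyError(f"source group {g} missing from variant table frequencies")
    cm = variant_table.genetic_positions(admixture_spec.map_rate_cM_per_Mb)
    morgans = cm / 100.0
    chroms = variant_table.variants["chrom"].to_numpy()
    m = variant_table.n_variants
    rng = _rng(seed)

    f_by_src = np.stack([variant_table.freq[g].to_numpy() for g in src])
    chrom_names = list(dict.fromkeys(chroms.tolist()))
    chrom_slices = [(np.flatnonzero(chroms == c)) for c in chrom_names]

    hap_anc = np.empty((2 * n_samples, m), dtype=np.int8)
    rate = float(admixture_spec.n_generations)
    prop = admixture_spec.target_proportion
    for h in range(2 * n_samples):
        for idx in chrom_slices:
            g0, g1 = morgans[idx[0]], morgans[idx[-1]]
            length = g1 - g0
            n_switch = rng.poisson(rate * length)
            cuts = np.sort(rng.uniform(g0, g1, size=n_switch))
            seg_anc = (rng.random(n_switch + 1) >= prop).astype(np.int8)  # 0 = first source
            seg_of_variant = np.searchsorted(cuts, morgans[idx], side="right")
            hap_anc[h, idx] = seg_anc[seg_of_variant]

    if source_haplotypes is not None:
        hap_alleles = np.empty((2 * n_samples, m), dtype=np.int8)
        pools = [np.asarray(source_haplotypes[g], dtype=np.int8) for g in src]
        for h in range(2 * n_samples):
            donor = [pools[0][rng.integers(len(pools[0]))], pools[1][rng.integers(len(pools[1]))]]
            anc = hap_anc[h]
            hap_alleles[h] = np.where(anc == 0, donor[0], donor[1])
    else:
        f = f_by_src[hap_anc.astype(np.intp), np.arange(m)[None, :]]
        hap_alleles = (rng.random((2 * n_samples, m)) < f).astype(np.int8)

    h1, h2 = hap_alleles[0::2], hap_alleles[1::2]
    a1, a2 = hap_anc[0::2], hap_anc[1::2]
    return GenotypePanel(
        dosage=(h1 + h2).astype(np.int8),
        sample_id=np.array([f"ADM{i:06d}" for i in range(n_samples)]),
        group_label=np.array([group_label] * n_samples),
        variants=variant_table,
        age=np.round(rng.normal(55.0, 8.0, size=n_samples), 1),
        sex=rng.integers(0, 2, size=n_samples).astype(np.int8),
        local_ancestry=np.stack([a1, a2], axis=2),
        ancestry_sources=tuple(src),
        haplotypes=np.stack([h1, h2], axis=2),
    )
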