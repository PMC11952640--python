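"""File round-trips: VCF 4.2 genotype panels with sidecar sample TSVs,
summary-statistics TSVs, and PC-score tables."""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from multigwas.assoc import GWASResults, StudyStats
from multigwas.popsim import GenotypePanel, VariantTable
from multigwas.structure import PCSet

_GT_UNPHASED = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as VCF 4.2 with GT fields.

    Genotypes are unphased (0/0, 0/1, 1/1) unless the panel carries
    haplotypes, in which case phased calls (a|b) are written.
    """
    path = Path(path)
    v = panel.variants.variants
    phased = panel.haplotypes is not None
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=multigwas\n")
        for c in dict.fromkeys(v["chrom"].tolist()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_id)
            + "\n"
        )
        for l in range(panel.n_variants):
            row = v.iloc[l]
            if phased:
                h = panel.haplotypes[:, l, :]
                calls = [f"{a}|{b}" for a, b in h]
            else:
                calls = [_GT_UNPHASED[int(d)] for d in panel.dosage[:, l]]
            fh.write(
                f"{row['chrom']}\t{row['pos_bp']}\t{row['variant_id']}\t"
                f"{row['allele_ref']}\t{row['allele_alt']}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def write_samples_tsv(panel: GenotypePanel, path) -> None:
    """Sidecar table of per-sample metadata (group label, age, sex)."""
    pd.DataFrame(
        {
            "sample_id": panel.sample_id,
            "group": panel.group_label,
            "age": panel.age,
            "sex": panel.sex,
        }
    ).to_csv(path, sep="\t", index=False)


def write_local_ancestry_tsv(panel: GenotypePanel, path) -> None:
    """Local ancestry as one 'a|b' code pair per sample x variant."""
    if panel.local_ancestry is None:
        raise ValueError("panel has no local ancestry")
    la = panel.local_ancestry
    cols = {"sample_id": panel.sample_id}
    for l, vid in enumerate(panel.variants.variant_id):
        cols[vid] = [f"{a}|{b}" for a, b in la[:, l, :]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_vcf(path, samples_tsv=None) -> GenotypePanel:
    """Read a VCF (plain or gzip) written by :func:`write_vcf` back into a
    panel, restoring group labels and covariates from the sidecar TSV.

    Uses cyvcf2 when importable; falls back to a text parse of the GT-only
    dialect this package writes.
    """
    path = Path(path)
    try:
        from cyvcf2 import VCF  # optional accelerated reader

        vcf = VCF(str(path))
        samples = np.array(vcf.samples)
        rows, dosages = [], []
        for var in vcf:
            rows.append((var.ID, var.CHROM, var.POS, var.REF, var.ALT[0]))
            gts = np.array(var.genotypes)[:, :2]
            dosages.append(gts.sum(axis=1))
        vcf.close()
    except ImportError:
        opener = gzip.open if path.suffix == ".gz" else open
        rows, dosages = [], []
        with opener(path, "rt") as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    samples = np.array(parts[9:])
                    continue
                rows.append((parts[2], parts[0], int(parts[1]), parts[3], parts[4]))
                calls = parts[9:]
                dosages.append(
                    [int(c[0] != "0") + int(c[2] != "0") for c in calls]
                )

    dosage = np.asarray(dosages, dtype=np.int8).T
    variants = pd.DataFrame(
        rows, columns=["variant_id", "chrom", "pos_bp", "allele_ref", "allele_alt"]
    )
    variants["ancestral_freq"] = dosage.mean(axis=0) / 2.0
    variants["genetic_pos_cM"] = np.nan

    if samples_tsv is not None:
        meta = pd.read_csv(samples_tsv, sep="\t").set_index("sample_id").loc[samples]
        group = meta["group"].to_numpy()
        age = meta["age"].to_numpy()
        sex = meta["sex"].to_numpy()
    else:
        group = np.array(["ALL"] * len(samples))
        age = np.zeros(len(samples))
        sex = np.zeros(len(samples), dtype=np.int8)

    freq = {}
    for g in dict.fromkeys(group.tolist()):
        freq[g] = dosage[group == g].mean(axis=0) / 2.0
    vt = VariantTable(variants, pd.DataFrame(freq))
    return GenotypePanel(
        dosage=dosage,
        sample_id=samples,
        group_label=group,
        variants=vt,
        age=age,
        sex=sex,
    )


def read_sumstats(path, scope=None) -> GWASResults:
    """Read the summary-statistics TSV dialect back into results."""
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    return GWASResults.from_sumstats(frame, scope=scope)


def read_study(path, group: str) -> StudyStats:
    res = read_sumstats(path, scope=f"group:{group}")
    freq = pd.Series(res.frame["freq"].to_numpy(), index=res.frame["variant_id"].to_numpy())
    return StudyStats(group=group, results=res, freq=freq, n=int(res.frame["n"].iloc[0]))


def write_pcs_tsv(pcs: PCSet, path) -> None:
    frame = pcs.to_frame()
    frame.to_csv(path, sep="\t", index=False)


def write_eigenvalues_tsv(pcs: PCSet, path) -> None:
    pd.DataFrame(
        {"component": [f"PC{i + 1}" for i in range(pcs.k)], "eigenvalue": pcs.eigenvalues}
    ).to_csv(path, sep="\t", index=False)
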