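"""Readers and writers for on-disk formats.

Count matrices travel as MatrixMarket MTX triplets (matrix + peaks TSV +
barcodes TSV) or, for tiny fixtures, a dense TSV. Genotypes come from VCF
(biallelic SNPs, GT field, via cyvcf2); peak coordinates from BED (0-based
half-open) or GFF3 (1-based inclusive), unified internally to 1-based
inclusive with midpoint = floor((start + end) / 2). Every dropped
cell/peak/SNP is counted and logged — silent filtering is forbidden.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .datasets import CountDataset
from .sim_population import GenotypeTable, GroundTruth

__all__ = [
    "read_counts",
    "write_counts",
    "read_vcf_genotypes",
    "read_peak_annotations",
    "write_ground_truth",
    "read_ground_truth",
    "write_vcf",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# count matrices


def write_counts(data: CountDataset, out_dir: str) -> None:
    """Write MTX + peaks.tsv + barcodes.tsv into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    sio.mmwrite(os.path.join(out_dir, "matrix.mtx"), data.counts.tocoo(), field="integer")
    data.peaks.to_csv(os.path.join(out_dir, "peaks.tsv"), sep="\t")
    data.cells.to_csv(os.path.join(out_dir, "barcodes.tsv"), sep="\t")


def read_counts(path: str) -> CountDataset:
    """Read a count dataset from an MTX directory or a dense TSV file.

    A directory must contain ``matrix.mtx``, ``peaks.tsv`` and
    ``barcodes.tsv``. A TSV file holds peaks as rows (index = peak ids) and
    cells as columns.
    """
    if os.path.isdir(path):
        mtx_path = os.path.join(path, "matrix.mtx")
        mat = sio.mmread(mtx_path)
        peaks = pd.read_csv(os.path.join(path, "peaks.tsv"), sep="\t", index_col=0)
        cells = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t", index_col=0)
        if mat.shape != (len(peaks), len(cells)):
            raise ValueError(
                f"dimension mismatch: matrix.mtx is {mat.shape} but peaks.tsv has "
                f"{len(peaks)} rows and barcodes.tsv has {len(cells)} rows"
            )
        return CountDataset(sp.csr_matrix(mat), peaks=peaks, cells=cells)
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.to_numpy()
    if not np.allclose(mat, np.round(mat)):
        raise ValueError(f"non-integer entries in {path}")
    return CountDataset(
        sp.csr_matrix(mat.astype(np.int64)),
        peaks=pd.DataFrame(index=df.index),
        cells=pd.DataFrame(index=pd.Index(df.columns, name="cell_id")),
    )


# ---------------------------------------------------------------------------
# genotypes


def read_vcf_genotypes(
    path: str,
    maf_range: tuple[float, float] = (0.0, 0.5),
    max_missing: float = 0.1,
) -> GenotypeTable:
    """Load biallelic-SNP dosages from a VCF.

    Dosage = number of alternate alleles (0/1/2); phased and unphased
    genotypes are equivalent. Sites with more than ``max_missing`` missing
    genotypes are dropped; remaining missing dosages are imputed to the
    site's modal dosage. MAF is the folded alternate-allele frequency;
    sites outside ``maf_range`` are dropped. All drops are logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} has no samples")
    rows, meta = [], []
    n_multi = n_missing = n_maf = n_malformed = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_multi += 1
            continue
        try:
            geno = np.array([g[0] + g[1] if g[0] >= 0 and g[1] >= 0 else -1
                             for g in var.genotypes])
        except (TypeError, IndexError):
            n_malformed += 1
            continue
        miss = geno < 0
        if miss.mean() > max_missing:
            n_missing += 1
            continue
        if miss.any():
            vals, counts = np.unique(geno[~miss], return_counts=True)
            geno[miss] = vals[np.argmax(counts)]
        alt_freq = geno.mean() / 2.0
        maf = min(alt_freq, 1.0 - alt_freq)
        if not (maf_range[0] <= maf <= maf_range[1]) or maf == 0:
            n_maf += 1
            continue
        rows.append(geno)
        meta.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}",
                     var.REF, var.ALT[0], maf))
    for label, n in (("non-biallelic/non-SNP", n_multi), ("high-missingness", n_missing),
                     ("MAF-filtered", n_maf), ("malformed-GT", n_malformed)):
        if n:
            logger.info("read_vcf_genotypes: dropped %d %s records", n, label)
    snps = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt", "maf"])
    dosages = (np.array(rows).T if rows else np.empty((len(samples), 0), dtype=int))
    return GenotypeTable(
        individuals=samples,
        snps=snps[["chrom", "pos", "id", "ref", "alt"]],
        dosages=dosages.astype(int),
        maf=snps["maf"].to_numpy(),
    )


def write_vcf(geno: GenotypeTable, path: str) -> None:
    """Write a GenotypeTable as a minimal VCF v4.2 with GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(geno.snps["chrom"]) if len(geno.snps) else []
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.individuals) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for k, row in enumerate(geno.snps.itertuples(index=False)):
            gts = "\t".join(gt_map[int(d)] for d in geno.dosages[:, k])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t"
                f"{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# peak coordinates


def read_peak_annotations(path: str, fmt: str | None = None) -> pd.DataFrame:
    """Read peak coordinates from BED or GFF3 into a unified table.

    Returns a DataFrame indexed by peak id with columns ``chrom``, ``start``,
    ``end`` (1-based inclusive) and ``midpoint`` (floor((start+end)/2)).
    Strand is ignored: chromatin accessibility is unstranded.
    """
    if fmt is None:
        fmt = "gff" if path.endswith((".gff", ".gff3")) else "bed"
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 3:
            raise ValueError(f"BED file {path} needs at least 3 columns")
        chrom = df[0].astype(str)
        start = df[1].astype(int) + 1  # 0-based half-open -> 1-based inclusive
        end = df[2].astype(int)
        names = df[3].astype(str) if df.shape[1] > 3 else pd.Series(
            [f"peak{i + 1}" for i in range(len(df))]
        )
    elif fmt == "gff":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 5:
            raise ValueError(f"GFF file {path} needs at least 5 columns")
        chrom = df[0].astype(str)
        start = df[3].astype(int)
        end = df[4].astype(int)
        if df.shape[1] >= 9:
            names = df[8].astype(str).str.extract(r"ID=([^;]+)", expand=False)
            names = names.fillna(pd.Series([f"peak{i + 1}" for i in range(len(df))]))
        else:
            names = pd.Series([f"peak{i + 1}" for i in range(len(df))])
    else:
        raise ValueError(f"unknown peak annotation format {fmt!r}")
    if (end < start).any():
        bad = int((end < start).sum())
        raise ValueError(f"{bad} zero- or negative-length intervals in {path}")
    out = pd.DataFrame(
        {
            "chrom": chrom.to_numpy(),
            "start": start.to_numpy(),
            "end": end.to_numpy(),
        },
        index=pd.Index(names.to_numpy(), name="peak_id"),
    )
    out["midpoint"] = (out["start"] + out["end"]) // 2
    return out


# ---------------------------------------------------------------------------
# ground truth


def write_ground_truth(truth: GroundTruth, out_dir: str) -> None:
    """Serialize truth tables (caQTL, DA, batch, condition) as TSVs."""
    os.makedirs(out_dir, exist_ok=True)
    caqtl = pd.DataFrame(
        [
            {
                "peak_id": a.peak_id,
                "snp_id": a.snp_id,
                "effect_size": a.effect_size,
                "sign": a.sign,
                "distance": a.distance,
                "affected_groups": a.affected_groups,
                "affected_conditions": a.affected_conditions,
            }
            for a in truth.caqtl
        ],
        columns=[
            "peak_id", "snp_id", "effect_size", "sign", "distance",
            "affected_groups", "affected_conditions",
        ],
    )
    caqtl.to_csv(os.path.join(out_dir, "caqtl_assignments.tsv"), sep="\t", index=False)
    if truth.da_factors is not None:
        truth.da_factors.to_csv(os.path.join(out_dir, "da_factors.tsv"), sep="\t")
    if truth.batch_factors is not None:
        truth.batch_factors.to_csv(os.path.join(out_dir, "batch_factors.tsv"), sep="\t")
    if truth.condition_factors is not None:
        truth.condition_factors.to_csv(
            os.path.join(out_dir, "condition_factors.tsv"), sep="\t"
        )
    if truth.baselines is not None:
        truth.baselines.baselines.to_csv(
            os.path.join(out_dir, "individual_baselines.tsv"), sep="\t"
        )


def read_ground_truth(out_dir: str) -> GroundTruth:
    """Read back the TSVs written by :func:`write_ground_truth`."""
    from .sim_population import CaQTLAssignment

    caqtl_df = pd.read_csv(os.path.join(out_dir, "caqtl_assignments.tsv"), sep="\t")
    caqtl = [
        CaQTLAssignment(
            peak_id=str(r.peak_id),
            snp_id=str(r.snp_id),
            effect_size=float(r.effect_size),
            sign=int(r.sign),
            distance=int(r.distance),
            affected_groups=str(r.affected_groups),
            affected_conditions=str(r.affected_conditions),
        )
        for r in caqtl_df.itertuples()
    ]
    def _maybe(name):
        p = os.path.join(out_dir, name)
        return pd.read_csv(p, sep="\t", index_col=0) if os.path.exists(p) else None

    return GroundTruth(
        caqtl=caqtl,
        da_factors=_maybe("da_factors.tsv"),
        batch_factors=_maybe("batch_factors.tsv"),
        condition_factors=_maybe("condition_factors.tsv"),
    )
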