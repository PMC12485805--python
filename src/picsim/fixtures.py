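"""Synthetic inputs with known truth: counts, genotypes, peak annotations.

Everything the package needs for development and testing is generated here
from the generative model itself — no downloads. Count fixtures are exact
forward simulations with the true parameters attached; genotype fixtures are
Hardy-Weinberg draws with uniform SNP positions; peak fixtures are sorted
non-overlapping intervals written as matched BED and GFF3.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .params import LibSizeParams, PeakMeanParams, SimParamsSingle, SparsityParams
from .sim_population import GenotypeTable
from .sim_single import SimulatedDataset, simulate_single

__all__ = [
    "FixtureSpec",
    "generate_counts_fixture",
    "generate_genotype_fixture",
    "generate_peak_fixture",
    "PRESETS",
]


@dataclass
class FixtureSpec:
    """True parameter values and sizes for a synthetic dataset.

    Defaults mirror a mid-depth droplet scATAC-seq library: median ~5,000
    fragments per cell (log-library mu=8.5, sigma=0.35), heavy-tailed
    Weibull peak means (shape 0.8 < 1), ~80% zero entries per cell.
    """

    n_peaks: int = 2000
    n_cells: int = 500
    n_individuals: int = 20
    n_snps: int = 500
    lib_mu: float = 8.5
    lib_sigma: float = 0.35
    peak_family: str = "weibull"
    peak_shape: float = 0.8
    peak_scale: float = 0.3
    #: target zero fraction per cell; the string "structural" sets pi_j to the
    #: Poisson layer's own zero fraction (Bernoulli top-up inactive) — the
    #: self-consistent regime that estimation from well-fit real data
    #: approaches, and the right condition for parameter-recovery checks
    pi: float | str = 0.8
    chrom: str = "chr22"
    chrom_length: int = 50_000_000
    maf_lo: float = 0.05
    maf_hi: float = 0.5
    seed: int = 0

    def sim_params(self) -> SimParamsSingle:
        pi = 0.0 if self.pi == "structural" else float(self.pi)
        return SimParamsSingle(
            n_peaks=self.n_peaks,
            n_cells=self.n_cells,
            lib=LibSizeParams(self.lib_mu, self.lib_sigma),
            peak=PeakMeanParams(
                family=self.peak_family, shape=self.peak_shape, scale=self.peak_scale
            ),
            sparsity=SparsityParams(np.array([pi])),
            seed=self.seed,
        )


def generate_counts_fixture(spec: FixtureSpec) -> SimulatedDataset:
    """Exact forward simulation from the generative model, truth attached.

    With ``pi="structural"`` the recorded truth pi equals each cell's
    realized Poisson zero fraction and the masking step is a no-op.
    """
    sim = simulate_single(spec.sim_params())
    if spec.pi == "structural":
        realized = sim.data.cells["realized_pi"].to_numpy()
        sim.truth["pi"] = realized
        sim.data.cells["target_pi"] = realized
        sim.truth["params"].sparsity = SparsityParams(realized)
    return sim


def generate_genotype_fixture(
    n_individuals: int,
    n_snps: int,
    chrom: str = "chr22",
    chrom_length: int = 50_000_000,
    maf_lo: float = 0.05,
    maf_hi: float = 0.5,
    seed: int = 0,
    out_vcf: str | None = None,
) -> GenotypeTable:
    """Hardy-Weinberg genotypes at uniformly placed biallelic SNPs.

    Per SNP, MAF p ~ Uniform(maf_lo, maf_hi) and genotype probabilities
    are ((1-p)^2, 2p(1-p), p^2). Optionally written as a VCF.
    """
    rng = substream(seed, "genotype-fixture")
    individuals = [f"ind{j + 1}" for j in range(n_individuals)]
    if n_snps > 0:
        pos = np.sort(rng.choice(np.arange(1, chrom_length + 1), size=n_snps, replace=False))
        p = rng.uniform(maf_lo, maf_hi, size=n_snps)
        probs = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)
        cum = np.cumsum(probs, axis=1)  # thresholds for dosages 0/1/2
        u = rng.random((n_individuals, n_snps))
        dosages = (u[:, :, None] > cum[None, :, :2]).sum(axis=2)
        alt_freq = dosages.mean(axis=0) / 2.0
        maf = np.minimum(alt_freq, 1 - alt_freq)
        # HWE draws can be monomorphic at small n; such SNPs are never
        # caQTL-eligible but stay in the table like real monomorphic sites
        refs = rng.choice(list("ACGT"), size=n_snps)
        alts = np.array(
            [rng.choice([b for b in "ACGT" if b != r]) for r in refs]
        )
        snps = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos.astype(int),
                "id": [f"snp{k + 1}" for k in range(n_snps)],
                "ref": refs,
                "alt": alts,
            }
        )
    else:
        snps = pd.DataFrame(columns=["chrom", "pos", "id", "ref", "alt"])
        dosages = np.empty((n_individuals, 0), dtype=int)
        maf = np.empty(0)
    table = GenotypeTable(
        individuals=individuals, snps=snps, dosages=dosages.astype(int), maf=maf
    )
    if out_vcf is not None:
        from .io import write_vcf

        write_vcf(table, out_vcf)
    return table


def generate_peak_fixture(
    n_peaks: int,
    chrom: str = "chr22",
    chrom_length: int = 50_000_000,
    width_mean: int = 500,
    seed: int = 0,
    out_bed: str | None = None,
    out_gff: str | None = None,
) -> pd.DataFrame:
    """Sorted, non-overlapping peak intervals; matched BED and GFF3 output.

    Returns the unified 1-based coordinate table (as from
    :func:`picsim.io.read_peak_annotations`).
    """
    rng = substream(seed, "peak-fixture")
    widths = np.maximum(50, rng.poisson(width_mean, size=n_peaks))
    total = int(widths.sum())
    if total >= chrom_length:
        raise ValueError("peaks do not fit on the chromosome")
    gap_pool = chrom_length - total - 1
    cuts = np.sort(rng.choice(np.arange(1, gap_pool), size=n_peaks, replace=False))
    gaps = np.diff(np.concatenate([[0], cuts]))
    starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(widths[:-1])]) + 1
    ends = starts + widths - 1  # 1-based inclusive
    df = pd.DataFrame(
        {"chrom": chrom, "start": starts.astype(int), "end": ends.astype(int)},
        index=pd.Index([f"peak{i + 1}" for i in range(n_peaks)], name="peak_id"),
    )
    df["midpoint"] = (df["start"] + df["end"]) // 2
    if out_bed is not None:
        bed = pd.DataFrame(
            {"chrom": df["chrom"], "start": df["start"] - 1, "end": df["end"],
             "name": df.index}
        )
        bed.to_csv(out_bed, sep="\t", header=False, index=False)
    if out_gff is not None:
        with open(out_gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for pid, row in df.iterrows():
                fh.write(
                    f"{row['chrom']}\tpicsim\tpeak\t{row['start']}\t{row['end']}"
                    f"\t.\t.\t.\tID={pid}\n"
                )
    return df


PRESETS: dict[str, FixtureSpec] = {
    "tiny": FixtureSpec(n_peaks=10, n_cells=10, n_individuals=3, n_snps=20, seed=7),
    "single": FixtureSpec(n_peaks=2000, n_cells=500, seed=1),
    "population": FixtureSpec(
        n_peaks=2000, n_cells=50, n_individuals=20, n_snps=2000, seed=2
    ),
    "caqtl-bench": FixtureSpec(
        n_peaks=1000, n_cells=100, n_individuals=83, n_snps=4000, seed=3
    ),
}


def write_fixture_bundle(preset: str, out_dir: str) -> FixtureSpec:
    """Write counts + genotypes + peak annotations for a named preset."""
    from .io import write_counts

    spec = PRESETS[preset]
    os.makedirs(out_dir, exist_ok=True)
    sim = generate_counts_fixture(spec)
    write_counts(sim.data, os.path.join(out_dir, "counts"))
    generate_genotype_fixture(
        spec.n_individuals,
        spec.n_snps,
        chrom=spec.chrom,
        chrom_length=spec.chrom_length,
        maf_lo=spec.maf_lo,
        maf_hi=spec.maf_hi,
        seed=spec.seed,
        out_vcf=os.path.join(out_dir, "genotypes.vcf"),
    )
    generate_peak_fixture(
        spec.n_peaks,
        chrom=spec.chrom,
        chrom_length=spec.chrom_length,
        seed=spec.seed,
        out_bed=os.path.join(out_dir, "peaks.bed"),
        out_gff=os.path.join(out_dir, "peaks.gff3"),
    )
    return spec
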