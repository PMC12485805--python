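"""Population-scale simulation: individual baselines, caQTL and condition effects.

For a cohort of genotyped individuals the simulator draws population-wide
peak means ``lambda_i`` from the fitted peak-mean family, peak variability
``sigma_i`` from the mean-binned coefficient-of-variation gamma law (scaled
by ``var_scale``), and per-individual baselines
``lambda_{i,j} ~ N(lambda_i, sigma_i)`` clamped at zero. Chromatin
accessibility QTLs are assigned to a configured fraction of peaks: each
selected peak is linked to a SNP within ``ca_window`` bp of its midpoint and
in the configured MAF range; the effect multiplies the baseline as
``lambda_{i,j} * (1 + sign * omega_i * G_{i,j} / 2)`` (dosage-linear,
half-effect heterozygotes). Condition-level differential accessibility adds
log-normal fold changes for non-reference cohorts. Single-cell counts are
then generated per individual with the single-sample machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st

from ._rng import spawn_seed, substream
from .datasets import CountDataset
from .params import BatchConfig, BCVParams, GroupConfig, PopulationParams, SimParamsSingle
from .sim_single import SimulatedDataset, sample_peak_means
from .sim_structure import simulate_groups

__all__ = [
    "GenotypeTable",
    "CaQTLAssignment",
    "IndividualBaselines",
    "GroundTruth",
    "sample_population_baselines",
    "assign_caqtl_effects",
    "apply_genotype_effects",
    "apply_condition_da",
    "simulate_population",
    "aggregate_pseudobulk",
]

logger = logging.getLogger(__name__)


@dataclass
class GenotypeTable:
    """Individuals x SNPs dosage matrix (0/1/2) with positions and MAFs."""

    individuals: list[str]
    snps: pd.DataFrame  # columns: chrom, pos (1-based), id, ref, alt
    dosages: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.dosages.shape != (len(self.individuals), len(self.snps)):
            raise ValueError("dosage matrix shape must be (n_individuals, n_snps)")
        if self.dosages.size and not np.isin(self.dosages, [0, 1, 2]).all():
            raise ValueError("dosages must be in {0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class CaQTLAssignment:
    """One peak-SNP link with its multiplicative genetic effect."""

    peak_id: str
    snp_id: str
    effect_size: float
    sign: int
    distance: int
    affected_groups: str = "all"
    affected_conditions: str = "all"


@dataclass
class IndividualBaselines:
    """Peak-by-individual baseline accessibility with population latents."""

    baselines: pd.DataFrame  # peaks x individuals
    lam: np.ndarray  # population mean per peak
    sigma: np.ndarray  # population sd per peak
    var_scale: float = 1.0
    n_clamped: int = 0


@dataclass
class GroundTruth:
    """Everything needed to reconstruct expected accessibility analytically."""

    caqtl: list[CaQTLAssignment] = field(default_factory=list)
    condition_factors: pd.DataFrame | None = None  # peaks x conditions
    da_factors: pd.DataFrame | None = None  # peaks x groups
    batch_factors: pd.DataFrame | None = None  # cells: batch, factor
    baselines: IndividualBaselines | None = None


# ---------------------------------------------------------------------------
# baselines


def sample_population_baselines(
    pop: PopulationParams,
    n_peaks: int,
    individuals: list[str],
    rng: np.random.Generator,
    empirical_means: np.ndarray | None = None,
    empirical_sds: np.ndarray | None = None,
) -> IndividualBaselines:
    """Draw per-individual baseline accessibility for every peak.

    When ``empirical_means`` (and optionally ``empirical_sds``) are supplied
    the sampling of population latents is bypassed and the empirical values
    are used directly.
    """
    if empirical_means is not None:
        lam = np.asarray(empirical_means, dtype=float)
        if lam.size != n_peaks:
            raise ValueError("empirical_means length must equal n_peaks")
        if empirical_sds is not None:
            sigma = np.asarray(empirical_sds, dtype=float) * pop.var_scale
        else:
            sigma = np.zeros(n_peaks)
    else:
        lam, _ = sample_peak_means(n_peaks, pop.mean_peak_fit(), rng)
        cv = _sample_bin_cvs(lam, pop, rng)
        sigma = cv * lam * pop.var_scale

    base = lam[:, None] + rng.normal(size=(n_peaks, len(individuals))) * sigma[:, None]
    n_clamped = int((base < 0).sum())
    if n_clamped:
        logger.warning("clamped %d negative baseline draws to 0", n_clamped)
    base = np.maximum(base, 0.0)
    df = pd.DataFrame(
        base,
        index=pd.Index([f"peak{i + 1}" for i in range(n_peaks)], name="peak_id"),
        columns=list(individuals),
    )
    return IndividualBaselines(
        baselines=df, lam=lam, sigma=sigma, var_scale=pop.var_scale, n_clamped=n_clamped
    )


def _sample_bin_cvs(lam: np.ndarray, pop: PopulationParams, rng: np.random.Generator) -> np.ndarray:
    """Per-peak CV drawn from the gamma law of the bin containing its mean."""
    if not pop.cv_bins:
        raise ValueError("PopulationParams.cv_bins is empty")
    edges = np.array([b.lo for b in pop.cv_bins] + [pop.cv_bins[-1].hi])
    idx = np.clip(np.searchsorted(edges, lam, side="right") - 1, 0, len(pop.cv_bins) - 1)
    cv = np.empty(lam.size)
    for k, b in enumerate(pop.cv_bins):
        sel = idx == k
        if sel.any():
            cv[sel] = rng.gamma(b.alpha_v, 1.0 / b.beta_v, size=int(sel.sum()))
    return cv


# ---------------------------------------------------------------------------
# caQTL assignment and application


def assign_caqtl_effects(
    peaks: pd.DataFrame,
    geno: GenotypeTable,
    pop: PopulationParams,
    rng: np.random.Generator,
) -> list[CaQTLAssignment]:
    """Assign a caQTL to a ``ca_peaks`` fraction of peaks.

    ``peaks`` needs a ``midpoint`` column (1-based bp) or ``start``/``end``
    to derive one. Eligible SNPs lie within ``ca_window`` bp of the peak
    midpoint on the same chromosome and inside ``ca_maf_range``; one is
    chosen uniformly. Effect sizes are Gamma(alpha_c, rate beta_c); sign is
    negative with probability ``ca_neg_prob``. Peaks without an eligible SNP
    are skipped (with a warning) and replaced from the remaining pool where
    possible.
    """
    if geno.n_snps == 0:
        raise ValueError("genotype table has no SNPs")
    peaks = peaks.copy()
    if "midpoint" not in peaks.columns:
        if not {"start", "end"}.issubset(peaks.columns):
            raise ValueError("peaks need a 'midpoint' or 'start'/'end' columns")
        peaks["midpoint"] = (peaks["start"] + peaks["end"]) // 2
    n_target = int(round(pop.ca_peaks * len(peaks)))
    if n_target == 0:
        return []

    lo, hi = pop.ca_maf_range
    maf_ok = (geno.maf >= lo) & (geno.maf <= hi)
    snp_pos = geno.snps["pos"].to_numpy()
    snp_chrom = geno.snps["chrom"].to_numpy()
    snp_ids = geno.snps["id"].to_numpy()

    order = rng.permutation(len(peaks))
    assignments: list[CaQTLAssignment] = []
    n_skipped = 0
    for pidx in order:
        if len(assignments) >= n_target:
            break
        row = peaks.iloc[pidx]
        mid = int(row["midpoint"])
        chrom = row.get("chrom", None)
        dist = np.abs(snp_pos - mid)
        eligible = maf_ok & (dist <= pop.ca_window)
        if chrom is not None and "chrom" in geno.snps.columns:
            eligible &= snp_chrom == chrom
        cand = np.flatnonzero(eligible)
        if cand.size == 0:
            n_skipped += 1
            continue
        snp_idx = int(rng.choice(cand))
        omega = float(rng.gamma(pop.alpha_c, 1.0 / pop.beta_c))
        sign = -1 if rng.random() < pop.ca_neg_prob else 1
        assignments.append(
            CaQTLAssignment(
                peak_id=str(peaks.index[pidx]),
                snp_id=str(snp_ids[snp_idx]),
                effect_size=omega,
                sign=sign,
                distance=int(dist[snp_idx]),
            )
        )
    if n_skipped:
        logger.warning(
            "%d peaks had no eligible SNP (window=%d bp, MAF in [%g, %g]) and were skipped",
            n_skipped, pop.ca_window, lo, hi,
        )
    if not assignments:
        raise ValueError(
            f"no peak has an eligible SNP (window={pop.ca_window} bp, "
            f"MAF range [{lo}, {hi}])"
        )
    return assignments


def apply_genotype_effects(
    base: IndividualBaselines,
    geno: GenotypeTable,
    assignments: list[CaQTLAssignment],
) -> IndividualBaselines:
    """Multiply baselines by (1 + sign * omega * G / 2) per assignment."""
    df = base.baselines.copy()
    snp_index = {str(s): k for k, s in enumerate(geno.snps["id"])}
    ind_cols = [c for c in df.columns]
    dosage_order = [geno.individuals.index(str(c)) for c in ind_cols]
    n_clamped = 0
    for a in assignments:
        if a.peak_id not in df.index:
            raise KeyError(f"assignment references unknown peak {a.peak_id!r}")
        g = geno.dosages[dosage_order, snp_index[a.snp_id]].astype(float)
        factor = 1.0 + a.sign * a.effect_size * g / 2.0
        neg = factor < 0
        if neg.any():
            n_clamped += int(neg.sum())
            factor = np.maximum(factor, 0.0)
        df.loc[a.peak_id] = df.loc[a.peak_id].to_numpy() * factor
    if n_clamped:
        logger.warning("clamped %d negative genotype-adjusted baselines to 0", n_clamped)
    return IndividualBaselines(
        baselines=df, lam=base.lam, sigma=base.sigma, var_scale=base.var_scale,
        n_clamped=base.n_clamped + n_clamped,
    )


def apply_condition_da(
    base: IndividualBaselines,
    cohorts: dict[str, str] | pd.Series,
    pop: PopulationParams,
    rng: np.random.Generator,
) -> tuple[IndividualBaselines, pd.DataFrame]:
    """Condition-specific differential accessibility for non-reference cohorts.

    ``cohorts`` maps individual -> condition label; the first label in sorted
    order is the reference. For every other condition a ``da_prob`` fraction
    of peaks receives a log-normal factor (reciprocal for the ``down_prob``
    fraction). Returns the adjusted baselines and the peaks x conditions
    factor table (1 where unaffected).
    """
    cohorts = pd.Series(dict(cohorts) if not isinstance(cohorts, pd.Series) else cohorts)
    missing = [c for c in base.baselines.columns if c not in cohorts.index]
    if missing:
        raise ValueError(f"cohort labels missing for individuals: {missing}")
    conditions = sorted(cohorts.unique())
    cfg = pop.da_condition
    n_peaks = len(base.baselines)
    table = pd.DataFrame(1.0, index=base.baselines.index, columns=conditions)
    df = base.baselines.copy()
    for cond in conditions[1:]:
        is_da = rng.random(n_peaks) < cfg.da_prob
        n_da = int(is_da.sum())
        f = np.exp(rng.normal(cfg.loc, cfg.scale, size=n_da))
        down = rng.random(n_da) < cfg.down_prob
        f[down] = 1.0 / f[down]
        table.loc[is_da, cond] = f
        cols = [c for c in df.columns if cohorts[c] == cond]
        df.loc[:, cols] = df.loc[:, cols].to_numpy() * table[cond].to_numpy()[:, None]
    out = IndividualBaselines(
        baselines=df, lam=base.lam, sigma=base.sigma, var_scale=base.var_scale,
        n_clamped=base.n_clamped,
    )
    return out, table


# ---------------------------------------------------------------------------
# full cohort simulation


def simulate_population(
    pop: PopulationParams,
    geno: GenotypeTable,
    peaks: pd.DataFrame,
    cells_per_individual: int,
    lib=None,
    sparsity=None,
    gcfg: GroupConfig | None = None,
    bcfg: BatchConfig | None = None,
    bcv: BCVParams | None = None,
    cohorts: dict[str, str] | None = None,
    seed: int = 0,
) -> tuple[SimulatedDataset, GroundTruth]:
    """Simulate single-cell counts for a genotyped cohort.

    Pipeline: population baselines -> caQTL effects -> condition DA ->
    per-individual single-cell simulation using that individual's baseline
    vector as peak means. Cells are labeled by individual (and group/batch
    when configured); the full ground truth is returned alongside.
    """
    from .params import LibSizeParams, SparsityParams

    lib = lib or LibSizeParams(8.5, 0.35)
    sparsity = sparsity or SparsityParams(np.array([0.8]))
    individuals = list(geno.individuals)
    n_peaks = len(peaks)

    base = sample_population_baselines(
        pop, n_peaks, individuals, substream(seed, "pop-baselines")
    )
    base.baselines.index = peaks.index.astype(str)

    if pop.ca_peaks > 0:
        assignments = assign_caqtl_effects(peaks, geno, pop, substream(seed, "caqtl"))
        base = apply_genotype_effects(base, geno, assignments)
    else:
        assignments = []

    cond_table = None
    if cohorts is not None:
        base, cond_table = apply_condition_da(
            base, cohorts, pop, substream(seed, "condition-da")
        )

    blocks: list[sp.csr_matrix] = []
    cell_frames: list[pd.DataFrame] = []
    da_truth = None
    batch_truth_frames = []
    for j, ind in enumerate(individuals):
        lam_j = base.baselines[ind].to_numpy()
        if lam_j.sum() <= 0:
            raise ValueError(f"individual {ind} has an all-zero baseline profile")
        params_j = SimParamsSingle(
            n_peaks=n_peaks,
            n_cells=cells_per_individual,
            lib=lib,
            sparsity=sparsity,
            seed=spawn_seed(seed, f"individual-{ind}"),
        )
        sim = simulate_groups(params_j, gcfg=gcfg, bcfg=bcfg, bcv=bcv, peak_means=lam_j)
        blocks.append(sim.data.counts)
        cf = sim.data.cells.copy()
        cf.insert(0, "individual", ind)
        cf.index = [f"{ind}_cell{k + 1}" for k in range(cells_per_individual)]
        cell_frames.append(cf)
        if da_truth is None:
            da_truth = sim.truth["da_factors"]
        batch_truth_frames.append(
            pd.DataFrame(
                {"individual": ind, "batch": sim.truth["batch_labels"],
                 "factor": sim.truth["batch_factors"]},
                index=cf.index,
            )
        )

    counts = sp.hstack(blocks, format="csr")
    cells = pd.concat(cell_frames)
    cells.index.name = "cell_id"
    if cohorts is not None:
        cells["condition"] = cells["individual"].map(cohorts)
    peak_meta = peaks.copy()
    peak_meta.index = peak_meta.index.astype(str)
    data = CountDataset(counts, peaks=peak_meta, cells=cells)

    n_groups = (gcfg or GroupConfig()).n_groups
    truth = GroundTruth(
        caqtl=assignments,
        condition_factors=cond_table,
        da_factors=pd.DataFrame(
            da_truth,
            index=peak_meta.index,
            columns=[f"group{g + 1}" for g in range(n_groups)],
        ),
        batch_factors=pd.concat(batch_truth_frames),
        baselines=base,
    )
    sim_ds = SimulatedDataset(data=data, truth={"ground_truth": truth, "population": pop})
    return sim_ds, truth


# ---------------------------------------------------------------------------
# pseudobulk


def aggregate_pseudobulk(
    dataset: CountDataset | SimulatedDataset,
    method: str = "mean",
    quantile_normalize: bool = False,
    normalize_cells: bool = True,
) -> pd.DataFrame:
    """Aggregate cells by individual into a peak-by-individual matrix.

    Cells are optionally depth-normalized (to the median library size)
    before per-peak ``mean`` aggregation. With ``quantile_normalize`` each
    peak's values are rank-transformed to a standard normal across
    individuals — the conventional input transform for QTL mapping.
    """
    data = dataset.data if isinstance(dataset, SimulatedDataset) else dataset
    if "individual" not in data.cells.columns:
        raise ValueError("cells must carry an 'individual' label")
    if method != "mean":
        raise ValueError(f"unsupported aggregation method {method!r}")
    mat = data.counts.astype(float)
    if normalize_cells:
        totals = np.asarray(mat.sum(axis=0)).ravel()
        med = np.median(totals[totals > 0])
        scale = np.where(totals > 0, med / totals, 0.0)
        mat = mat.multiply(sp.csr_matrix(scale[None, :])).tocsr()
    individuals = data.cells["individual"].to_numpy()
    uniq = list(pd.unique(individuals))
    cols = {}
    for ind in uniq:
        sel = np.flatnonzero(individuals == ind)
        cols[ind] = np.asarray(mat[:, sel].mean(axis=1)).ravel()
    pb = pd.DataFrame(cols, index=data.peaks.index)
    if quantile_normalize:
        n = pb.shape[1]
        ranks = pb.rank(axis=1, method="average")
        z = st.norm.ppf((ranks - 0.5) / n)
        # standardize each peak so rows are exactly mean-0 / sd-1 (ties permitting)
        mu = z.mean(axis=1, keepdims=True)
        sd = z.std(axis=1, ddof=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        pb = pd.DataFrame((z - mu) / sd, index=pb.index, columns=pb.columns)
    return pb
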