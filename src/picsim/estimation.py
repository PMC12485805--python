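"""Fit the generative model's parameters from a peak-by-cell count matrix.

Single-sample estimation recovers four interpretable pieces: a log-normal fit
to library sizes, a generalized-gamma-family fit (Weibull by default) to
normalized nonzero peak means, per-cell zero proportions for the Bernoulli
sparsity layer, and a common dispersion (biological coefficient of variation)
with its prior degrees of freedom. Population-level estimation fits
per-individual peak-mean distributions, mean-binned coefficient-of-variation
gamma laws, and a gamma law for caQTL effect sizes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st

from .datasets import CountDataset
from .params import (
    BCVParams,
    CVBin,
    LibSizeParams,
    PeakMeanParams,
    PopulationParams,
    SparsityParams,
)

__all__ = [
    "filter_peaks",
    "estimate_library_size",
    "estimate_peak_means",
    "estimate_sparsity",
    "estimate_dispersion",
    "correct_dispersion",
    "estimate_population",
    "estimate_caqtl_effect_params",
    "estimate_single",
    "fit_peak_mean_family",
    "median_library_size",
    "normalized_peak_means",
]

logger = logging.getLogger(__name__)

#: positivity clamp applied when the linear dispersion correction crosses zero
EPS_PHI = 1e-4

#: slope/intercept of the linear correction applied to the raw common dispersion
DISPERSION_SLOPE = 0.15
DISPERSION_INTERCEPT = -0.3


# ---------------------------------------------------------------------------
# filtering


def filter_peaks(counts: CountDataset, min_cell_frac: float = 0.01) -> CountDataset:
    """Keep peaks detected (nonzero) in at least ``min_cell_frac`` of cells.

    The boundary is inclusive: with 100 cells and ``min_cell_frac=0.01`` a
    peak seen in exactly one cell survives. Idempotent for a fixed threshold.
    """
    if counts.n_peaks == 0 or counts.n_cells == 0:
        raise ValueError("empty input")
    if not 0 <= min_cell_frac <= 1:
        raise ValueError("min_cell_frac must lie in [0, 1]")
    threshold = int(np.ceil(min_cell_frac * counts.n_cells))
    detected = counts.cells_detected_per_peak()
    keep = detected >= threshold
    if not keep.any():
        raise ValueError(
            f"all {counts.n_peaks} peaks removed by filter "
            f"(min_cell_frac={min_cell_frac}, threshold={threshold} cells)"
        )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_peaks: dropped %d/%d peaks", n_dropped, counts.n_peaks)
    return counts.subset_peaks(keep)


# ---------------------------------------------------------------------------
# library size


def _drop_zero_total_cells(counts: CountDataset) -> CountDataset:
    totals = counts.library_sizes()
    if (totals == 0).any():
        n0 = int((totals == 0).sum())
        logger.warning("dropping %d cells with zero total counts", n0)
        counts = counts.subset_cells(totals > 0)
    return counts


def estimate_library_size(counts: CountDataset) -> LibSizeParams:
    """MLE of the log-normal library-size model on column totals."""
    counts = _drop_zero_total_cells(counts)
    totals = counts.library_sizes()
    if totals.size < 2:
        raise ValueError("need at least 2 cells with positive totals")
    logs = np.log(totals)
    return LibSizeParams(mu=float(logs.mean()), sigma=float(logs.std(ddof=0)))


# ---------------------------------------------------------------------------
# peak means


def median_library_size(counts: CountDataset) -> float:
    """Median total count over cells with positive totals (lower median)."""
    totals = counts.library_sizes()
    totals = np.sort(totals[totals > 0])
    if totals.size == 0:
        raise ValueError("no cells with positive totals")
    # lower median for determinism on even lengths
    return float(totals[(totals.size - 1) // 2])


def normalized_peak_means(counts: CountDataset) -> np.ndarray:
    """Per-peak mean after scaling each cell to the median total count."""
    totals = counts.library_sizes().astype(float)
    med = median_library_size(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(totals > 0, med / totals, 0.0)
    scaled = counts.counts.multiply(sp.csr_matrix(factors[None, :]))
    return np.asarray(scaled.mean(axis=1)).ravel()


def _fit_weibull(x: np.ndarray) -> tuple[float, float]:
    shape, _, scale = st.weibull_min.fit(x, floc=0)
    return float(shape), float(scale)


def _fit_gamma(x: np.ndarray) -> tuple[float, float]:
    shape, _, scale = st.gamma.fit(x, floc=0)
    return float(shape), float(scale)


def _fit_pareto(x: np.ndarray) -> tuple[float, float]:
    # Pareto with support [scale, inf); scale pinned to the sample minimum
    scale = float(x.min())
    shape = x.size / np.sum(np.log(x / scale))
    return float(shape), scale


def _fit_lognorm_gamma_mixture(x: np.ndarray, max_iter: int = 300, tol: float = 1e-8) -> dict:
    """EM fit of w*LogNormal + (1-w)*Gamma to positive data."""
    logx = np.log(x)
    # moment-based split initialization: lognormal on the lower half
    med = np.median(x)
    w = 0.5
    lo, hi = x[x <= med], x[x > med]
    mu, sig = float(np.log(lo).mean()), max(float(np.log(lo).std()), 1e-3)
    g_shape, _, g_scale = st.gamma.fit(hi, floc=0)
    prev_ll = -np.inf
    for _ in range(max_iter):
        ln_pdf = st.lognorm.pdf(x, s=sig, scale=np.exp(mu))
        g_pdf = st.gamma.pdf(x, a=g_shape, scale=g_scale)
        num = w * ln_pdf
        den = num + (1 - w) * g_pdf
        den = np.where(den > 0, den, np.finfo(float).tiny)
        r = num / den
        w = float(np.clip(r.mean(), 1e-6, 1 - 1e-6))
        rs = r.sum()
        mu = float((r * logx).sum() / rs)
        sig = max(float(np.sqrt((r * (logx - mu) ** 2).sum() / rs)), 1e-4)
        # weighted gamma via moment matching on the responsibilities
        gw = 1 - r
        gm = (gw * x).sum() / gw.sum()
        gv = (gw * (x - gm) ** 2).sum() / gw.sum()
        if gv <= 0:
            break
        g_shape = max(gm**2 / gv, 1e-4)
        g_scale = max(gv / gm, np.finfo(float).tiny)
        ll = float(np.log(w * ln_pdf + (1 - w) * g_pdf + np.finfo(float).tiny).sum())
        if abs(ll - prev_ll) < tol * (1 + abs(prev_ll)):
            break
        prev_ll = ll
    return {
        "shape": float(g_shape),
        "scale": float(g_scale),
        "extra": {"weight": w, "lognorm_mu": mu, "lognorm_sigma": sig},
    }


def fit_peak_mean_family(x: np.ndarray, family: str = "weibull") -> PeakMeanParams:
    """Maximum-likelihood fit of the chosen family to positive values."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("peak means must be positive and finite")
    if x.size < 3:
        raise ValueError("need at least 3 nonzero peak means to fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all peak means identical")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if family == "weibull":
            shape, scale = _fit_weibull(x)
            extra: dict = {}
        elif family == "gamma":
            shape, scale = _fit_gamma(x)
            extra = {}
        elif family == "pareto":
            shape, scale = _fit_pareto(x)
            extra = {}
        elif family == "lognormal-gamma-mixture":
            fit = _fit_lognorm_gamma_mixture(x)
            shape, scale, extra = fit["shape"], fit["scale"], fit["extra"]
        else:
            raise ValueError(f"unknown peak-mean family {family!r}")
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        raise RuntimeError(
            f"peak-mean fit failed to converge for family {family!r}: "
            f"shape={shape}, scale={scale}"
        )
    return PeakMeanParams(family=family, shape=shape, scale=scale, extra=extra)


def estimate_peak_means(counts: CountDataset, family: str = "weibull") -> PeakMeanParams:
    """Fit the peak-mean distribution to normalized nonzero peak means."""
    means = normalized_peak_means(counts)
    nonzero = means[means > 0]
    if nonzero.size == 0:
        raise ValueError("no peaks with nonzero counts")
    return fit_peak_mean_family(nonzero, family=family)


# ---------------------------------------------------------------------------
# sparsity


def estimate_sparsity(counts: CountDataset) -> SparsityParams:
    """Per-cell zero proportions pi_j."""
    if counts.n_peaks == 0 or counts.n_cells == 0:
        raise ValueError("empty input")
    counts = _drop_zero_total_cells(counts)
    return SparsityParams(pi=counts.zero_fraction_per_cell())


# ---------------------------------------------------------------------------
# dispersion (BCV)


def correct_dispersion(phi_raw: float, clamp: bool = True) -> float:
    """Linear correction of the raw common dispersion.

    ``phi = -0.3 + 0.15 * phi_raw``, clamped below at ``EPS_PHI`` when
    ``clamp`` is true (the line crosses zero at phi_raw = 2).
    """
    phi = DISPERSION_INTERCEPT + DISPERSION_SLOPE * float(phi_raw)
    if clamp:
        phi = max(EPS_PHI, phi)
    return phi


def _raw_common_dispersion(counts: CountDataset) -> tuple[float, np.ndarray]:
    """Two-stage method-of-moments common dispersion.

    Per-peak dispersion ``(var - mean) / mean^2`` on library-size-normalized
    counts, then a precision-weighted 10%-trimmed mean across peaks (weights
    proportional to peak mean, since low-mean peaks estimate dispersion
    noisily).
    """
    totals = counts.library_sizes().astype(float)
    pos = totals > 0
    mat = counts.counts[:, pos].astype(float)
    totals = totals[pos]
    med = np.median(totals)
    norm = mat.multiply(sp.csr_matrix((med / totals)[None, :])).tocsr()
    m = np.asarray(norm.mean(axis=1)).ravel()
    # sparse-friendly variance: E[x^2] - (E[x])^2, population variance
    m2 = np.asarray(norm.multiply(norm).mean(axis=1)).ravel()
    n = norm.shape[1]
    v = (m2 - m**2) * n / max(n - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (v - m) / m**2
    ok = np.isfinite(d) & (m > 0)
    d, w = d[ok], m[ok]
    if d.size == 0 or np.all(v[ok] <= 1e-10 * m[ok] ** 2):
        raise ValueError("no dispersion signal: counts show no extra-Poisson variance")
    lo, hi = np.quantile(d, [0.1, 0.9])
    inlier = (d >= lo) & (d <= hi)
    if inlier.sum() < 3:
        inlier = np.ones_like(d, dtype=bool)
    phi_raw = float(np.average(d[inlier], weights=w[inlier]))
    return phi_raw, d


def _estimate_df0(dispersions: np.ndarray, phi_raw: float) -> float:
    """Method-of-moments df of a scaled inverse chi-squared around phi_raw.

    If d_i = phi * df0 / chisq(df0), then phi/d_i ~ chisq(df0)/df0 with
    variance 2/df0.
    """
    pos = dispersions > 0
    if phi_raw <= 0 or pos.sum() < 10:
        return 8.0
    ratios = phi_raw / dispersions[pos]
    # trim extreme ratios; near-Poisson peaks give huge ratios
    lo, hi = np.quantile(ratios, [0.05, 0.95])
    ratios = ratios[(ratios >= lo) & (ratios <= hi)]
    v = float(np.var(ratios, ddof=1)) if ratios.size > 2 else 0.0
    if not np.isfinite(v) or v <= 0:
        return 8.0
    return float(np.clip(2.0 / v, 1.0, 100.0))


def estimate_dispersion(counts: CountDataset, groups: np.ndarray | None = None) -> BCVParams:
    """Common BCV phi (after linear correction and clamping) and prior df0.

    With group labels the raw dispersion is estimated within each group and
    combined weighted by group size, so between-group mean shifts do not
    inflate the estimate.
    """
    if counts.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if groups is None:
        phi_raw, disp = _raw_common_dispersion(counts)
    else:
        groups = np.asarray(groups)
        phis, disps, weights = [], [], []
        for g in np.unique(groups):
            sub = counts.subset_cells(groups == g)
            if sub.n_cells < 2:
                continue
            p, d = _raw_common_dispersion(sub)
            phis.append(p)
            disps.append(d)
            weights.append(sub.n_cells)
        if not phis:
            raise ValueError("no group with >= 2 cells")
        phi_raw = float(np.average(phis, weights=weights))
        disp = np.concatenate(disps)
    phi = correct_dispersion(phi_raw, clamp=True)
    df0 = _estimate_df0(disp, phi_raw)
    out = BCVParams(phi=phi, df0=df0)
    out.phi_raw = phi_raw  # type: ignore[attr-defined]  # diagnostic extra
    return out


# ---------------------------------------------------------------------------
# population-level estimation


def estimate_population(
    pseudobulk: pd.DataFrame,
    n_bins_size: int = 50,
    family: str = "weibull",
    **kwargs,
) -> PopulationParams:
    """Fit population parameters from a peak-by-individual matrix.

    Per individual: a peak-mean family fit to that individual's nonzero peak
    means. Across individuals: peaks sorted by mean accessibility, chunked
    into consecutive bins of ``n_bins_size``, and a gamma distribution fit to
    each bin's across-individual coefficients of variation. A trailing bin
    with fewer than 3 peaks merges into its predecessor.
    """
    pseudobulk = pd.DataFrame(pseudobulk)
    if pseudobulk.shape[1] < 3:
        raise ValueError("need at least 3 individuals")
    sample_fits: dict[str, PeakMeanParams] = {}
    for ind in pseudobulk.columns:
        vals = pseudobulk[ind].to_numpy(dtype=float)
        vals = vals[vals > 0]
        sample_fits[str(ind)] = fit_peak_mean_family(vals, family=family)

    mat = pseudobulk.to_numpy(dtype=float)
    means = mat.mean(axis=1)
    sds = mat.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means > 0, sds / means, 0.0)

    order = np.argsort(means, kind="stable")
    n_peaks = means.size
    if n_peaks < n_bins_size:
        logger.warning(
            "only %d peaks for bin size %d: using a single bin", n_peaks, n_bins_size
        )
    edges = list(range(0, n_peaks, n_bins_size))
    chunks = [order[s : s + n_bins_size] for s in edges]
    if len(chunks) > 1 and chunks[-1].size < 3:
        chunks[-2] = np.concatenate([chunks[-2], chunks[-1]])
        chunks = chunks[:-1]

    cv_bins: list[CVBin] = []
    for idx in chunks:
        bin_means = means[idx]
        bin_cvs = cvs[idx]
        lo, hi = float(bin_means.min()), float(bin_means.max())
        if hi <= lo:
            hi = lo + max(abs(lo), 1.0) * 1e-9
        pos_cvs = bin_cvs[bin_cvs > 0]
        if pos_cvs.size < 3 or np.ptp(pos_cvs) == 0:
            logger.warning(
                "degenerate CV bin [%g, %g]: zero across-individual variance; "
                "using sentinel gamma", lo, hi,
            )
            alpha_v, beta_v = 1.0, 1e6  # mean CV 1e-6: effectively no variability
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                a, _, sc = st.gamma.fit(pos_cvs, floc=0)
            alpha_v, beta_v = float(a), float(1.0 / sc)
        cv_bins.append(CVBin(lo=lo, hi=hi, alpha_v=alpha_v, beta_v=beta_v, n_peaks=idx.size))

    return PopulationParams(sample_fits=sample_fits, cv_bins=cv_bins, family=family, **kwargs)


def estimate_caqtl_effect_params(effect_sizes: np.ndarray) -> tuple[float, float]:
    """Gamma (shape, rate) fit to caQTL effect-size magnitudes."""
    x = np.asarray(effect_sizes, dtype=float)
    if np.any(x < 0):
        logger.warning("negative effect sizes supplied: absolute values taken")
        x = np.abs(x)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("no positive effect sizes")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance effect sizes")
    if x.size < 10:
        logger.warning("only %d effect sizes: falling back to method of moments", x.size)
        m, v = x.mean(), x.var(ddof=1)
        if v <= 0:
            raise ValueError("zero-variance effect sizes")
        return float(m**2 / v), float(m / v)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a, _, sc = st.gamma.fit(x, floc=0)
    return float(a), float(1.0 / sc)


# ---------------------------------------------------------------------------
# one-call convenience


def estimate_single(
    counts: CountDataset,
    family: str = "weibull",
    min_cell_frac: float = 0.01,
    groups: np.ndarray | None = None,
):
    """Filter peaks and estimate all single-sample parameters.

    Returns a :class:`~picsim.params.SimParamsSingle` sized like the input.
    """
    from .params import SimParamsSingle

    filtered = filter_peaks(counts, min_cell_frac=min_cell_frac)
    lib = estimate_library_size(filtered)
    peak = estimate_peak_means(filtered, family=family)
    pi = estimate_sparsity(filtered)
    return SimParamsSingle(
        n_peaks=filtered.n_peaks, n_cells=filtered.n_cells, lib=lib, peak=peak, sparsity=pi
    )
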