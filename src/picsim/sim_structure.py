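"""Multi-group and multi-batch simulation within one sample.

Cell groups differ by multiplicative per-peak differential-accessibility (DA)
factors (log-normal magnitudes, reciprocal for down-regulated peaks; exactly 1
for non-DA peaks). Technical batches apply per-cell log-normal scaling
factors. An optional biological-coefficient-of-variation (BCV) layer draws
cell-specific accessibility means from a gamma distribution whose CV follows
a scaled inverse chi-squared law decreasing with peak mean.

Order of multiplicative effects: DA first (applied to the baseline peak
mean), then batch, then normalization and library-size scaling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import substream
from .datasets import CountDataset
from .params import BatchConfig, BCVParams, GroupConfig, SimParamsSingle
from .sim_single import (
    SimulatedDataset,
    _resolve_pi,
    apply_sparsity,
    sample_library_sizes,
    sample_peak_means,
)

__all__ = [
    "assign_groups",
    "sample_da_factors",
    "sample_batch_factors",
    "sample_cell_means_bcv",
    "sample_gamma_cv",
    "simulate_groups",
]


def assign_groups(
    n_cells: int, group_probs, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. categorical group assignment; labels 1..n_groups."""
    probs = np.asarray(group_probs, dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("group_probs must be non-negative and sum to 1")
    return rng.choice(np.arange(1, probs.size + 1), size=n_cells, p=probs)


def sample_da_factors(
    n_peaks: int, cfg: GroupConfig, rng: np.random.Generator
) -> np.ndarray:
    """Peak-by-group matrix of multiplicative DA factors.

    Per group each peak is differentially accessible with probability
    ``da_prob``; its factor is ``exp(N(da_loc, da_scale))``, replaced by its
    reciprocal for a ``da_down_prob`` fraction. Non-DA peaks get exactly 1.
    """
    factors = np.ones((n_peaks, cfg.n_groups))
    for g in range(cfg.n_groups):
        is_da = rng.random(n_peaks) < cfg.da_prob
        n_da = int(is_da.sum())
        f = np.exp(rng.normal(cfg.da_loc, cfg.da_scale, size=n_da))
        down = rng.random(n_da) < cfg.da_down_prob
        f[down] = 1.0 / f[down]
        factors[is_da, g] = f
    return factors


def sample_batch_factors(
    cfg: BatchConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell batch labels (1..n_batches) and scaling factors omega_jb."""
    if not cfg.batch_cells:
        raise ValueError("batch_cells must be set to sample batch factors")
    labels = np.repeat(np.arange(1, cfg.n_batches + 1), cfg.batch_cells)
    factors = np.empty(labels.size)
    for b in range(cfg.n_batches):
        sel = labels == b + 1
        factors[sel] = np.exp(rng.normal(cfg.mu_b[b], cfg.sigma_b[b], size=int(sel.sum())))
    return labels, factors


def sample_gamma_cv(
    mean: np.ndarray, cv: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gamma draws with E = mean and CV = cv (shape 1/cv^2, scale mean*cv^2).

    Zero means (and zero CVs) pass through unchanged.
    """
    mean = np.asarray(mean, dtype=float)
    cv = np.broadcast_to(np.asarray(cv, dtype=float), mean.shape)
    out = mean.copy()
    active = (mean > 0) & (cv > 0)
    shape = 1.0 / cv[active] ** 2
    scale = mean[active] * cv[active] ** 2
    out[active] = rng.gamma(shape, scale)
    return out


def sample_cell_means_bcv(
    adjusted_means: np.ndarray, bcv: BCVParams, rng: np.random.Generator
) -> np.ndarray:
    """Cell-specific accessibility means with trended biological variation.

    Per peak, ``BCV_i = (phi + 1/sqrt(mean_i)) * sqrt(df0 / chisq(df0))``
    where ``mean_i`` is the peak's average adjusted mean — larger means get
    lower BCV. Cell means are then gamma draws with that CV around the
    adjusted means.
    """
    adjusted = np.asarray(adjusted_means, dtype=float)
    if np.any(adjusted < 0):
        raise ValueError("adjusted means must be >= 0")
    peak_mean = adjusted.mean(axis=1)
    trend = np.where(peak_mean > 0, bcv.phi + 1.0 / np.sqrt(np.maximum(peak_mean, 1e-12)), 0.0)
    chi2 = rng.chisquare(bcv.df0, size=adjusted.shape[0])
    bcv_i = trend * np.sqrt(bcv.df0 / np.maximum(chi2, 1e-12))
    return sample_gamma_cv(adjusted, bcv_i[:, None], rng)


def simulate_groups(
    params: SimParamsSingle,
    gcfg: GroupConfig | None = None,
    bcfg: BatchConfig | None = None,
    bcv: BCVParams | None = None,
    peak_means: np.ndarray | None = None,
) -> SimulatedDataset:
    """Simulate a sample with cell groups, batches and optional BCV noise.

    Pipeline: sample baseline peak means (or use ``peak_means`` if given,
    e.g. an individual's baselines in a population run); apply each cell's
    group DA factor and batch factor; normalize each cell's mean vector and
    scale by its library size to get adjusted means ``lambda_{i,j}``;
    optionally add gamma BCV noise; Poisson counts; calibrated sparsity.

    With one group, no DA, one unit batch and ``bcv=None`` this reduces
    exactly (same seed streams) to :func:`picsim.sim_single.simulate_single`.
    """
    gcfg = gcfg or GroupConfig()
    n_cells, n_peaks, seed = params.n_cells, params.n_peaks, params.seed
    if bcfg is None:
        bcfg = BatchConfig(n_batches=1, batch_cells=(n_cells,))
    if sum(bcfg.batch_cells) != n_cells:
        raise ValueError("sum(batch_cells) must equal n_cells")

    L = sample_library_sizes(n_cells, params.lib, substream(seed, "lib"))
    if peak_means is None:
        lam, _ = sample_peak_means(n_peaks, params.peak, substream(seed, "peak"))
    else:
        lam = np.asarray(peak_means, dtype=float)
        if lam.size != n_peaks:
            raise ValueError("peak_means length must equal n_peaks")

    groups = assign_groups(n_cells, gcfg.group_probs, substream(seed, "groups"))
    da = sample_da_factors(n_peaks, gcfg, substream(seed, "da"))
    batch_labels, batch_factors = sample_batch_factors(bcfg, substream(seed, "batch"))

    # per-cell mean profile: baseline x DA(group); normalized per cell, then
    # scaled by library size and the batch factor. The batch factor must act
    # after normalization — a per-cell scalar applied before it would cancel
    # — so it shifts the cell's effective sequencing depth.
    mean_mat = lam[:, None] * da[:, groups - 1]
    colsum = mean_mat.sum(axis=0)
    adjusted = mean_mat / colsum[None, :] * (L * batch_factors)[None, :]

    if bcv is not None:
        adjusted = sample_cell_means_bcv(adjusted, bcv, substream(seed, "bcv"))

    counts = substream(seed, "counts").poisson(adjusted)
    pi = _resolve_pi(params.sparsity, n_cells, substream(seed, "pi"), L=L)
    final = apply_sparsity(counts, pi, substream(seed, "mask"))

    cells = pd.DataFrame(
        {
            "group": groups,
            "batch": batch_labels,
            "batch_factor": batch_factors,
            "library_size": L,
            "target_pi": pi,
            "realized_pi": (final == 0).mean(axis=0),
        },
        index=pd.Index([f"cell{j + 1}" for j in range(n_cells)], name="cell_id"),
    )
    peaks = pd.DataFrame(
        {"lam": lam, **{f"da_factor_group{g + 1}": da[:, g] for g in range(gcfg.n_groups)}},
        index=pd.Index([f"peak{i + 1}" for i in range(n_peaks)], name="peak_id"),
    )
    data = CountDataset(sp.csr_matrix(final), peaks=peaks, cells=cells)
    truth = {
        "params": params,
        "group_config": gcfg,
        "batch_config": bcfg,
        "L": L,
        "lam": lam,
        "da_factors": da,
        "groups": groups,
        "batch_labels": batch_labels,
        "batch_factors": batch_factors,
        "pi": pi,
        "adjusted_means": adjusted,
    }
    return SimulatedDataset(data=data, truth=truth)
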