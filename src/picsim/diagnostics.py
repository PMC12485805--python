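"""Real-vs-simulated summary statistics and distributional similarity metrics.

For each key characteristic (library size, peak mean, cell sparsity) the
real and simulated values are sorted and compared elementwise; four metrics
summarize the absolute differences: MAD (median absolute deviation — the
median of absolute differences), MAE, RMSE and 1 − Pearson correlation of
the sorted vectors.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import CountDataset

__all__ = ["SummaryStats", "summarize_dataset", "compare_distributions", "compare_report"]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("mad", "mae", "rmse", "one_minus_pcc")


@dataclass
class SummaryStats:
    """Per-cell and per-peak summary statistics of a count matrix."""

    library_size: np.ndarray
    log_library_size: np.ndarray
    cell_sparsity: np.ndarray
    peak_mean: np.ndarray
    peak_variance: np.ndarray
    peak_zero_prop: np.ndarray
    peak_nonzero_prop: np.ndarray

    def peak_table(self) -> pd.DataFrame:
        """Paired per-peak relations: (mean, variance, %zeros, nonzero prop)."""
        return pd.DataFrame(
            {
                "mean": self.peak_mean,
                "variance": self.peak_variance,
                "zero_prop": self.peak_zero_prop,
                "nonzero_prop": self.peak_nonzero_prop,
            }
        )


def summarize_dataset(counts: CountDataset) -> SummaryStats:
    """Compute all summary statistics on raw counts."""
    if counts.n_peaks == 0 or counts.n_cells == 0:
        raise ValueError("empty input")
    lib = counts.library_sizes().astype(float)
    mat = counts.counts
    n = counts.n_cells
    mean = np.asarray(mat.mean(axis=1)).ravel()
    mean2 = np.asarray(mat.multiply(mat).mean(axis=1)).ravel()
    var = (mean2 - mean**2) * n / max(n - 1, 1)
    nz = np.asarray((mat > 0).sum(axis=1)).ravel() / n
    with np.errstate(divide="ignore"):
        loglib = np.where(lib > 0, np.log(np.maximum(lib, 1)), 0.0)
    return SummaryStats(
        library_size=lib,
        log_library_size=loglib,
        cell_sparsity=counts.zero_fraction_per_cell(),
        peak_mean=mean,
        peak_variance=var,
        peak_zero_prop=1.0 - nz,
        peak_nonzero_prop=nz,
    )


def _match_length(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reduce the longer sorted vector to the shorter's length by linear
    quantile interpolation."""
    if a.size == b.size:
        return a, b
    short, long_ = (a, b) if a.size < b.size else (b, a)
    q = np.linspace(0, 1, short.size)
    long_q = np.interp(q, np.linspace(0, 1, long_.size), long_)
    return (short, long_q) if a.size < b.size else (long_q, short)


def compare_distributions(real: np.ndarray, sim: np.ndarray) -> dict[str, float]:
    """MAD / MAE / RMSE / 1−PCC between two sorted value distributions.

    Input ordering is irrelevant (both vectors are sorted first) and the
    metrics are symmetric in their arguments. With a zero-variance vector
    the correlation is undefined and reported as NaN.
    """
    real = np.sort(np.asarray(real, dtype=float))
    sim = np.sort(np.asarray(sim, dtype=float))
    if real.size == 0 or sim.size == 0:
        raise ValueError("both vectors must be nonempty")
    real, sim = _match_length(real, sim)
    d = np.abs(real - sim)
    out = {
        "mad": float(np.median(d)),
        "mae": float(d.mean()),
        "rmse": float(np.sqrt((d**2).mean())),
    }
    if real.size < 2 or np.ptp(real) == 0 or np.ptp(sim) == 0:
        logger.warning("zero-variance vector: 1-PCC undefined, reported as NaN")
        out["one_minus_pcc"] = float("nan")
    else:
        out["one_minus_pcc"] = float(1.0 - np.corrcoef(real, sim)[0, 1])
    return out


def compare_report(
    real: CountDataset,
    sim: CountDataset,
    out_dir: str | None = None,
    log_library: bool = True,
) -> pd.DataFrame:
    """Metric table over library size, peak mean and cell sparsity.

    When ``out_dir`` is given, writes the table as TSV plus overlay and
    mean-relationship diagnostic plots (PNG).
    """
    rs, ss = summarize_dataset(real), summarize_dataset(sim)
    pairs = {
        "library_size": (rs.log_library_size, ss.log_library_size)
        if log_library
        else (rs.library_size, ss.library_size),
        "peak_mean": (rs.peak_mean, ss.peak_mean),
        "cell_sparsity": (rs.cell_sparsity, ss.cell_sparsity),
    }
    table = pd.DataFrame(
        {name: compare_distributions(a, b) for name, (a, b) in pairs.items()}
    ).T
    table.index.name = "characteristic"
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "metrics.tsv"), sep="\t")
        _write_plots(rs, ss, pairs, out_dir)
    return table


def _write_plots(rs: SummaryStats, ss: SummaryStats, pairs, out_dir: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.2))
    for ax, (name, (a, b)) in zip(np.atleast_1d(axes), pairs.items()):
        ax.boxplot([a, b], tick_labels=["real", "sim"])
        ax.set_title(name)
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "distributions.png"), dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    for stats, label, color in ((rs, "real", "tab:red"), (ss, "sim", "tab:blue")):
        axes[0].scatter(stats.peak_mean, stats.peak_zero_prop, s=4, alpha=0.4,
                        label=label, color=color)
        axes[1].scatter(stats.peak_mean, stats.peak_variance, s=4, alpha=0.4,
                        label=label, color=color)
    axes[0].set_xlabel("peak mean"); axes[0].set_ylabel("zero proportion")
    axes[1].set_xlabel("peak mean"); axes[1].set_ylabel("peak variance")
    axes[1].set_xscale("log"); axes[1].set_yscale("log")
    for ax in axes:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "mean_relationships.png"), dpi=120)
    plt.close(fig)
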