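"""Simulate a peak-by-cell count matrix for one homogeneous cell type.

The generative chain:

1. ``L_j ~ LogNormal(mu, sigma)`` — library sizes
2. ``lambda_i`` from the peak-mean family; normalized so the
   ``lambda_bar_i`` sum to one
3. ``Y_ij ~ Poisson(lambda_bar_i * L_j)`` — true counts (column sums are
   unbiased for ``L_j``)
4. calibrated Bernoulli masking so cell ``j``'s final zero fraction matches
   the target ``pi_j``

Each step draws from its own named RNG substream, so the full run is
bit-reproducible under a seed and steps are mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import substream
from .datasets import CountDataset
from .params import LibSizeParams, PeakMeanParams, SimParamsSingle, SparsityParams

__all__ = [
    "sample_library_sizes",
    "sample_peak_means",
    "simulate_true_counts",
    "apply_sparsity",
    "simulate_single",
    "SimulatedDataset",
]


@dataclass
class SimulatedDataset:
    """A simulated count matrix together with its realized latent truth."""

    data: CountDataset
    truth: dict

    @property
    def counts(self) -> sp.csr_matrix:
        return self.data.counts


def sample_library_sizes(
    n_cells: int, lib: LibSizeParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw L_j = exp(N(mu, sigma)) for each cell."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return np.exp(rng.normal(lib.mu, lib.sigma, size=n_cells))


def sample_peak_means(
    n_peaks: int, peak: PeakMeanParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-peak means lambda_i and their normalized version.

    Returns ``(lam, lam_bar)`` with ``lam_bar = lam / lam.sum()``.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    fam = peak.family
    if fam == "weibull":
        lam = peak.scale * rng.weibull(peak.shape, size=n_peaks)
    elif fam == "gamma":
        lam = rng.gamma(peak.shape, peak.scale, size=n_peaks)
    elif fam == "pareto":
        lam = peak.scale * (1.0 + rng.pareto(peak.shape, size=n_peaks))
    elif fam == "lognormal-gamma-mixture":
        w = peak.extra.get("weight", 0.5)
        mu = peak.extra.get("lognorm_mu", 0.0)
        sig = peak.extra.get("lognorm_sigma", 1.0)
        from_ln = rng.random(n_peaks) < w
        lam = rng.gamma(peak.shape, peak.scale, size=n_peaks)
        lam[from_ln] = np.exp(rng.normal(mu, sig, size=int(from_ln.sum())))
    else:  # pragma: no cover - guarded by PeakMeanParams
        raise ValueError(f"unknown family {fam!r}")
    # Weibull draws can be exactly 0 at float resolution for tiny shapes
    lam = np.maximum(lam, np.finfo(float).tiny)
    return lam, lam / lam.sum()


def simulate_true_counts(
    lam_bar: np.ndarray, L: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Poisson counts with mean lambda_bar_i * L_j (peaks x cells)."""
    lam_bar = np.asarray(lam_bar, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(lam_bar < 0) or np.any(L <= 0):
        raise ValueError("require lam_bar >= 0 and L > 0")
    return rng.poisson(np.outer(lam_bar, L))


def apply_sparsity(
    counts: np.ndarray, pi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Zero extra entries so each cell's expected zero fraction reaches pi_j.

    The Poisson layer already produces structural zeros at rate ``z0_j``;
    among the remaining nonzero entries each is masked independently with
    probability ``q_j = max(0, (pi_j - z0_j) / (1 - z0_j))``, so pi is the
    target *final* zero fraction, matching how it is estimated. Counts never
    increase; cells already at or above target are untouched.
    """
    counts = np.asarray(counts)
    n_peaks, n_cells = counts.shape
    pi = np.broadcast_to(np.asarray(pi, dtype=float), (n_cells,))
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi must lie in [0, 1]")
    z0 = (counts == 0).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(z0 < 1, np.maximum(0.0, (pi - z0) / (1.0 - z0)), 0.0)
    mask = rng.random(counts.shape) < q[None, :]
    out = counts.copy()
    out[mask & (out > 0)] = 0
    return out


def _resolve_pi(
    sparsity: SparsityParams,
    n_cells: int,
    rng: np.random.Generator,
    L: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell sparsity targets, assigned to cells by depth rank.

    The empirical pi vector is resampled with replacement when the cell
    count differs from the number of estimates. Targets are then matched to
    cells by library-size rank (deepest cell gets the smallest target),
    preserving the strong depth-sparsity anticorrelation of real data; a
    random pairing would mask deep cells at high rates and distort the
    library-size distribution.
    """
    pi = sparsity.pi
    if pi.size == 1:
        return np.full(n_cells, float(pi[0]))
    if pi.size == n_cells:
        pi = pi.astype(float)
    else:
        pi = rng.choice(pi, size=n_cells, replace=True).astype(float)
    if L is None:
        return pi
    ranks = np.argsort(np.argsort(L))  # 0 = shallowest cell
    return np.sort(pi)[::-1][ranks]


def simulate_single(params: SimParamsSingle) -> SimulatedDataset:
    """Run the full single-cell-type generative chain."""
    seed = params.seed
    L = sample_library_sizes(params.n_cells, params.lib, substream(seed, "lib"))
    lam, lam_bar = sample_peak_means(params.n_peaks, params.peak, substream(seed, "peak"))
    true_counts = simulate_true_counts(lam_bar, L, substream(seed, "counts"))
    pi = _resolve_pi(params.sparsity, params.n_cells, substream(seed, "pi"), L=L)
    final = apply_sparsity(true_counts, pi, substream(seed, "mask"))

    cells = pd.DataFrame(
        {
            "library_size": L,
            "target_pi": pi,
            "realized_pi": (final == 0).mean(axis=0),
        },
        index=pd.Index([f"cell{j + 1}" for j in range(params.n_cells)], name="cell_id"),
    )
    peaks = pd.DataFrame(
        {"lam": lam, "lam_bar": lam_bar},
        index=pd.Index([f"peak{i + 1}" for i in range(params.n_peaks)], name="peak_id"),
    )
    data = CountDataset(sp.csr_matrix(final), peaks=peaks, cells=cells)
    truth = {"params": params, "L": L, "lam": lam, "lam_bar": lam_bar, "pi": pi}
    return SimulatedDataset(data=data, truth=truth)
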