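"""Parameter containers for the generative model.

The model for a single homogeneous cell type:

* library size  ``L_j ~ LogNormal(mu, sigma)``
* peak mean     ``lambda_i ~ Weibull(shape, scale)`` (or another member of the
  generalized-gamma family), normalized to ``lambda_bar_i = lambda_i / sum``
* counts        ``Y_ij ~ Poisson(lambda_bar_i * L_j)``
* sparsity      extra zeros so cell ``j`` reaches zero fraction ``pi_j``

Multi-group / batch runs add per-peak multiplicative differential-accessibility
(DA) factors, per-cell batch factors and a biological-coefficient-of-variation
(BCV) layer; population runs add per-individual baselines and genotype-driven
caQTL effects. All containers serialize to plain JSON and round-trip
losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LibSizeParams",
    "PeakMeanParams",
    "SparsityParams",
    "BCVParams",
    "CVBin",
    "PopulationParams",
    "SimParamsSingle",
    "GroupConfig",
    "BatchConfig",
    "save_params",
    "load_params",
]

SCHEMA_VERSION = 1

PEAK_MEAN_FAMILIES = ("weibull", "gamma", "pareto", "lognormal-gamma-mixture")


@dataclass
class LibSizeParams:
    """Log-normal library-size model: ln L_j ~ N(mu, sigma^2)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class PeakMeanParams:
    """Peak-mean distribution: a member of the generalized gamma family.

    ``shape``/``scale`` parameterize the named family. For the
    lognormal-gamma mixture they refer to the gamma component and ``extra``
    carries ``weight`` (lognormal mixing weight), ``lognorm_mu`` and
    ``lognorm_sigma``.
    """

    family: str = "weibull"
    shape: float = 0.8
    scale: float = 0.3
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in PEAK_MEAN_FAMILIES:
            raise ValueError(
                f"unknown peak-mean family {self.family!r}; supported: {PEAK_MEAN_FAMILIES}"
            )
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be > 0")


@dataclass
class SparsityParams:
    """Per-cell target zero fractions pi_j (Bernoulli sparsity layer)."""

    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        if np.any((self.pi < 0) | (self.pi > 1)):
            raise ValueError("all pi must lie in [0, 1]")


@dataclass
class BCVParams:
    """Common biological coefficient of variation and its prior df.

    Per-peak BCV is drawn from a scaled inverse chi-squared distribution with
    ``df0`` degrees of freedom around a mean-dependent trend anchored at
    ``phi``; larger peak means get lower BCV.
    """

    phi: float
    df0: float = 8.0

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        if self.df0 <= 0:
            raise ValueError("df0 must be > 0")


@dataclass
class CVBin:
    """Gamma fit to coefficients of variation within one peak-mean bin."""

    lo: float
    hi: float
    alpha_v: float
    beta_v: float
    n_peaks: int = 0

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("bin requires lo < hi")
        if self.alpha_v <= 0 or self.beta_v <= 0:
            raise ValueError("alpha_v, beta_v must be > 0")


@dataclass
class ConditionDAConfig:
    """Condition/cohort differential accessibility settings."""

    da_prob: float = 0.1
    loc: float = 0.1
    scale: float = 0.4
    down_prob: float = 0.5


@dataclass
class PopulationParams:
    """Everything needed for a multi-individual cohort simulation."""

    sample_fits: dict[str, PeakMeanParams] = field(default_factory=dict)
    cv_bins: list[CVBin] = field(default_factory=list)
    var_scale: float = 1.0
    alpha_c: float = 2.0
    beta_c: float = 4.0
    ca_peaks: float = 0.5
    ca_maf_range: tuple[float, float] = (0.05, 0.5)
    ca_window: int = 100_000
    ca_neg_prob: float = 0.5
    da_condition: ConditionDAConfig = field(default_factory=ConditionDAConfig)
    family: str = "weibull"

    def __post_init__(self) -> None:
        if not 0 <= self.ca_peaks <= 1:
            raise ValueError("ca_peaks must lie in [0, 1]")
        if self.ca_window <= 0:
            raise ValueError("ca_window must be > 0")
        if self.alpha_c <= 0 or self.beta_c <= 0:
            raise ValueError("alpha_c, beta_c must be > 0")
        lo, hi = self.ca_maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("ca_maf_range must satisfy 0 < lo < hi <= 0.5")

    def mean_peak_fit(self) -> PeakMeanParams:
        """Across-individual average of the per-individual fits."""
        if not self.sample_fits:
            return PeakMeanParams(family=self.family)
        shapes = [p.shape for p in self.sample_fits.values()]
        scales = [p.scale for p in self.sample_fits.values()]
        return PeakMeanParams(
            family=self.family, shape=float(np.mean(shapes)), scale=float(np.mean(scales))
        )


@dataclass
class SimParamsSingle:
    """All parameters for a single-cell-type simulation."""

    n_peaks: int = 5000
    n_cells: int = 700
    lib: LibSizeParams = field(default_factory=lambda: LibSizeParams(8.5, 0.35))
    peak: PeakMeanParams = field(default_factory=PeakMeanParams)
    sparsity: SparsityParams = field(default_factory=lambda: SparsityParams(np.array([0.8])))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 1 or self.n_cells < 1:
            raise ValueError("n_peaks and n_cells must be >= 1")


@dataclass
class GroupConfig:
    """Cell-group structure and differential accessibility settings.

    Defaults: roughly 13% of peaks carry a non-unit DA factor, with
    log-normal magnitudes symmetric in log space (half up, half down).
    """

    n_groups: int = 1
    group_probs: Sequence[float] = (1.0,)
    da_prob: float = 0.13
    da_loc: float = 0.1
    da_scale: float = 0.4
    da_down_prob: float = 0.5

    def __post_init__(self) -> None:
        self.group_probs = tuple(float(p) for p in self.group_probs)
        if len(self.group_probs) != self.n_groups:
            raise ValueError("group_probs length must equal n_groups")
        if abs(sum(self.group_probs) - 1.0) > 1e-9:
            raise ValueError("group_probs must sum to 1")
        if not 0 <= self.da_prob <= 1:
            raise ValueError("da_prob must lie in [0, 1]")


@dataclass
class BatchConfig:
    """Technical batches: cells per batch and log-normal factor parameters."""

    n_batches: int = 1
    batch_cells: Sequence[int] = ()
    mu_b: Sequence[float] = (0.0,)
    sigma_b: Sequence[float] = (0.0,)

    def __post_init__(self) -> None:
        self.batch_cells = tuple(int(c) for c in self.batch_cells)
        self.mu_b = tuple(float(m) for m in np.broadcast_to(self.mu_b, (self.n_batches,)))
        self.sigma_b = tuple(float(s) for s in np.broadcast_to(self.sigma_b, (self.n_batches,)))
        if any(s < 0 for s in self.sigma_b):
            raise ValueError("sigma_b must be >= 0")
        if self.batch_cells and len(self.batch_cells) != self.n_batches:
            raise ValueError("batch_cells length must equal n_batches")


# ---------------------------------------------------------------------------
# JSON (de)serialization


def _encode(obj):
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "__dataclass__": type(obj).__name__,
            "fields": {f.name: _encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)},
        }
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


_CLASSES = {
    c.__name__: c
    for c in (
        LibSizeParams,
        PeakMeanParams,
        SparsityParams,
        BCVParams,
        CVBin,
        ConditionDAConfig,
        PopulationParams,
        SimParamsSingle,
        GroupConfig,
        BatchConfig,
    )
}


def _decode(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"])
        if "__dataclass__" in obj:
            cls = _CLASSES[obj["__dataclass__"]]
            kwargs = {k: _decode(v) for k, v in obj["fields"].items()}
            return cls(**kwargs)
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def save_params(obj, path) -> None:
    """Serialize any parameter container to a human-readable JSON file."""
    payload = {"schema_version": SCHEMA_VERSION, "params": _encode(obj)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_params(path):
    """Read a parameter file written by :func:`save_params`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported parameter schema version {payload.get('schema_version')}")
    obj = _decode(payload["params"])
    # tuples are stored as lists; dataclass __post_init__ re-normalizes where
    # it matters, but ca_maf_range needs re-tupling for equality round-trips
    if isinstance(obj, PopulationParams):
        obj.ca_maf_range = tuple(obj.ca_maf_range)
    return obj
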