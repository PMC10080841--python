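"""Label-distribution-smoothing (LDS) sample weights for imbalanced regression.

Daily admission counts are imbalanced: extreme days (peaks and troughs) are
rare, so a squared-error fit concentrates on the bulk of the label range and
under-serves exactly the days that matter most operationally.  LDS extends
inverse-frequency re-weighting to continuous targets: the empirical label
histogram is convolved with a symmetric kernel, producing an *effective*
density that credits each label with the information carried by its
neighbours, and each training row is weighted by the inverse of the effective
density at its label.  Because the counts trend upward from year to year, the
density is estimated within each calendar year by default, so that a count
that is ordinary for one year but rare for another is weighted accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LDSConfig",
    "SampleWeights",
    "kernel_window",
    "bin_labels",
    "smooth_density",
    "compute_weights",
]

KERNELS = ("gaussian", "triangular", "laplace", "delta")


@dataclass(frozen=True)
class LDSConfig:
    """Parameters of the label-density smoother.

    bin_width is in label units (1 count, since labels are integer counts);
    kernel_size and sigma are in bins.
    """

    bin_width: float = 1.0
    kernel: str = "gaussian"
    kernel_size: int = 5
    sigma: float = 2.0
    per_year: bool = True
    normalize_mean_to_one: bool = True
    max_weight: float | None = None

    def __post_init__(self):
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be an odd positive integer")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.max_weight is not None and self.max_weight <= 0:
            raise ValueError("max_weight must be positive")


@dataclass
class SampleWeights:
    """Per-row weights plus the density tables they were derived from."""

    weights: pd.Series
    effective_density: pd.Series  # per row, density of its label bin
    strata: pd.Series  # per row, the year stratum
    density_tables: dict[int | str, pd.DataFrame]  # stratum -> bin tables


def kernel_window(config: LDSConfig) -> np.ndarray:
    """Symmetric kernel weights over ``kernel_size`` bins, summing to one."""
    half = config.kernel_size // 2
    x = np.arange(-half, half + 1, dtype=float)
    if config.kernel == "delta":
        w = (x == 0).astype(float)
    elif config.kernel == "gaussian":
        w = np.exp(-0.5 * (x / config.sigma) ** 2)
    elif config.kernel == "triangular":
        w = np.maximum(1.0 - np.abs(x) / (half + 1), 0.0)
    elif config.kernel == "laplace":
        w = np.exp(-np.abs(x) / config.sigma)
    else:  # pragma: no cover
        raise ValueError(config.kernel)
    return w / w.sum()


def bin_labels(y: np.ndarray | pd.Series, bin_width: float = 1.0
               ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram the labels: bin edges spanning [floor(min), ceil(max)].

    Returns ``(bin_centers, densities)`` with densities summing to one.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty label vector")
    if not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")
    lo = np.floor(y.min())
    # one half-open bin per width step; the maximum label gets its own bin
    n_bins = int(np.floor((y.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(y, bins=edges)
    centers = edges[:-1] + bin_width / 2.0
    return centers, counts / y.size


def smooth_density(densities: np.ndarray, config: LDSConfig) -> np.ndarray:
    """Convolve the empirical density with the kernel window.

    The kernel is truncated at the label-range boundary without
    renormalization ('same'-mode convolution); the output is non-negative
    but need not sum to one at the edges.
    """
    window = kernel_window(config)
    dens = np.asarray(densities, dtype=float)
    half = config.kernel_size // 2
    # centered slice of the full convolution ('same' regardless of whether
    # the kernel is longer than the density vector)
    return np.convolve(dens, window, mode="full")[half:half + len(dens)]


def _bin_of(y: np.ndarray, centers: np.ndarray, bin_width: float) -> np.ndarray:
    idx = np.floor((y - (centers[0] - bin_width / 2.0)) / bin_width).astype(int)
    return np.clip(idx, 0, len(centers) - 1)


def compute_weights(y_train: pd.Series | np.ndarray,
                    years: pd.Series | np.ndarray | None = None,
                    config: LDSConfig | None = None) -> SampleWeights:
    """Inverse-effective-density weights, estimated per year stratum.

    Within each stratum the labels are binned, the empirical density is
    kernel-smoothed, and each row receives ``1 / effective_density`` at its
    label bin.  Weights are then clipped at ``max_weight`` (if set) and
    rescaled globally to mean one, so strata whose labels are rarer overall
    genuinely up-weight relative to the rest.
    """
    config = config or LDSConfig()
    y = pd.Series(np.asarray(y_train, dtype=float))
    index = y_train.index if isinstance(y_train, pd.Series) else y.index

    if config.per_year:
        if years is None:
            if isinstance(index, pd.DatetimeIndex):
                strata = pd.Series(index.year, index=index)
            else:
                raise ValueError("per_year requires a years vector or a date index")
        else:
            years = np.asarray(years)
            if len(years) != len(y):
                raise ValueError("years vector misaligned with labels")
            strata = pd.Series(years, index=index)
    else:
        strata = pd.Series(["all"] * len(y), index=index)
    y.index = index

    raw = pd.Series(np.nan, index=index, dtype=float)
    eff = pd.Series(np.nan, index=index, dtype=float)
    tables: dict[int | str, pd.DataFrame] = {}
    for stratum, idx in strata.groupby(strata).groups.items():
        yv = y.loc[idx].to_numpy()
        if len(np.unique(yv)) < 2:
            logger.warning("stratum %r has fewer than 2 distinct labels; "
                           "using uniform weights there", stratum)
            raw.loc[idx] = 1.0
            eff.loc[idx] = 1.0
            continue
        centers, emp = bin_labels(yv, config.bin_width)
        effective = smooth_density(emp, config)
        bins = _bin_of(yv, centers, config.bin_width)
        dens = effective[bins]
        raw.loc[idx] = 1.0 / dens
        eff.loc[idx] = dens
        tables[stratum] = pd.DataFrame(
            {"bin_center": centers, "empirical": emp, "effective": effective})

    if config.max_weight is not None:
        raw = raw.clip(upper=config.max_weight)
    if config.normalize_mean_to_one:
        raw = raw / raw.mean()
    return SampleWeights(weights=raw, effective_density=eff,
                         strata=strata, density_tables=tables)
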