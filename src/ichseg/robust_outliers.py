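"""Univariate Minimum Covariance Determinant statistics and outlier maps.

Intensity hypo-/hyper-intensity detection is cast as robust outlier detection:
a robust mean and standard deviation are estimated inside a region of interest
with the univariate MCD estimator, and voxels beyond the chi-squared cut-off
(Hubert-Debruyne rule, one degree of freedom) are flagged.

In one dimension the MCD has an exact solution: the h-subset of minimal
variance is always contiguous in the sorted sample, so a sliding-window scan
over the order statistics finds it in O(n log n).  This makes the estimate
deterministic and identical to exhaustive subset search at every sample size;
no iterative FAST-MCD approximation is needed.  The raw subset standard
deviation is rescaled by the asymptotic normal-consistency factor for the
achieved coverage h/n; the finite-sample correction is omitted since the
estimator is applied to voxel samples of order 1e5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .volume_core import BinaryMask, IntensityVolume

log = logging.getLogger(__name__)

#: default fraction of the sample the estimator must cover (resists 40% outliers)
DEFAULT_SUPPORT_FRACTION = 0.6
#: default chi-squared quantile (1 dof) for the outlier cut-off
DEFAULT_CUTOFF_QUANTILE = 0.975
#: above this many in-ROI voxels the fit uses a seeded uniform subsample
DEFAULT_SUBSAMPLE_SIZE = 200_000


class DegenerateDistributionError(ValueError):
    """The minimal-variance subset has zero spread; no scale can be estimated."""


def consistency_factor(coverage: float) -> float:
    """Multiplier taking the raw MCD standard deviation to normal consistency.

    For a standard normal, the variance of the central ``coverage`` mass is
    F_chi2(3)(q) / coverage with q the chi-squared(1) quantile at ``coverage``;
    the factor is the inverse square root of that ratio.
    """
    q = chi2.ppf(coverage, df=1)
    trimmed_var = chi2.cdf(q, df=3) / coverage
    return 1.0 / math.sqrt(trimmed_var)


def mcd_location_scale(
    samples, support_fraction: float = DEFAULT_SUPPORT_FRACTION, consistency_correction: bool = True
) -> tuple[float, float]:
    """Exact univariate MCD location and (consistency-corrected) scale.

    With h = ceil(support_fraction * n), the size-h subset of minimal variance
    is found exactly among the contiguous windows of the sorted sample; ties
    are broken toward the smallest window start, which makes the estimate
    deterministic.  Returns (mu, sigma) with sigma rescaled for normal
    consistency at coverage h/n unless ``consistency_correction`` is False
    (raw subset standard deviation, population convention).

    Raises :class:`DegenerateDistributionError` when the best subset is
    constant, and ``ValueError`` for invalid inputs.
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    n = x.size
    if n < 2 or np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct sample values")
    if not (0.5 < support_fraction <= 1.0):
        raise ValueError(f"support_fraction must be in (0.5, 1], got {support_fraction}")
    h = int(math.ceil(support_fraction * n))
    h = max(h, 2)
    mu, raw_sigma = _min_variance_window(x, h)
    if raw_sigma <= 0.0:
        raise DegenerateDistributionError(
            f"minimal-variance subset of size {h} is constant (value {mu}); cannot estimate scale"
        )
    if not consistency_correction:
        return mu, raw_sigma
    return mu, raw_sigma * consistency_factor(h / n)


def _min_variance_window(x: np.ndarray, h: int) -> tuple[float, float]:
    """Mean and population sd of the minimal-variance h-window of sorted x."""
    xs = np.sort(x)
    cs = np.concatenate(([0.0], np.cumsum(xs)))
    cs2 = np.concatenate(([0.0], np.cumsum(xs * xs)))
    s1 = cs[h:] - cs[:-h]
    s2 = cs2[h:] - cs2[:-h]
    var = s2 / h - (s1 / h) ** 2
    i = int(np.argmin(var))  # argmin takes the first minimum: smallest start wins ties
    return float(s1[i] / h), float(math.sqrt(max(var[i], 0.0)))


@dataclass
class RobustStats:
    """Robust location/scale of an ROI and the derived outlier thresholds.

    ``T_low``/``T_high`` are mu -/+ c*sigma with c the square root of the
    chi-squared(1) quantile at ``cutoff_quantile``.
    """

    mu: float
    sigma: float
    support_fraction: float
    cutoff_quantile: float
    T_low: float
    T_high: float
    n_samples: int = 0
    subsampled: bool = False

    @classmethod
    def from_location_scale(
        cls,
        mu: float,
        sigma: float,
        support_fraction: float = DEFAULT_SUPPORT_FRACTION,
        cutoff_quantile: float = DEFAULT_CUTOFF_QUANTILE,
        n_samples: int = 0,
        subsampled: bool = False,
    ) -> "RobustStats":
        if sigma < 0:
            raise ValueError("sigma must be non-negative")
        c = math.sqrt(chi2.ppf(cutoff_quantile, df=1))
        return cls(
            mu=mu,
            sigma=sigma,
            support_fraction=support_fraction,
            cutoff_quantile=cutoff_quantile,
            T_low=mu - c * sigma,
            T_high=mu + c * sigma,
            n_samples=n_samples,
            subsampled=subsampled,
        )

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "support_fraction": self.support_fraction,
            "cutoff_quantile": self.cutoff_quantile,
            "T_low": self.T_low,
            "T_high": self.T_high,
            "n_samples": self.n_samples,
            "subsampled": self.subsampled,
        }


def fit_robust_stats(
    vol: IntensityVolume,
    roi: BinaryMask,
    support_fraction: float = DEFAULT_SUPPORT_FRACTION,
    cutoff_quantile: float = DEFAULT_CUTOFF_QUANTILE,
    subsample_size: int = DEFAULT_SUBSAMPLE_SIZE,
    rng_seed: int = 0,
) -> RobustStats:
    """Fit the univariate MCD on the volume's intensities inside the ROI.

    Beyond ``subsample_size`` in-ROI voxels the fit runs on a seeded uniform
    random subsample of that size (the thresholds still apply to all voxels);
    the seed is logged for reproducibility.
    """
    if vol.shape != roi.shape:
        raise ValueError("volume and ROI must share one grid")
    values = vol.data[roi.data]
    if values.size == 0:
        raise ValueError("ROI is empty")
    subsampled = False
    if subsample_size is not None and values.size > subsample_size:
        rng = np.random.default_rng(rng_seed)
        values = rng.choice(values, size=subsample_size, replace=False)
        subsampled = True
        log.info("MCD fit on %d-voxel subsample (seed %d) of %d in-ROI voxels", subsample_size, rng_seed, roi.count)
    mu, sigma = mcd_location_scale(values, support_fraction)
    return RobustStats.from_location_scale(
        mu, sigma, support_fraction, cutoff_quantile, n_samples=values.size, subsampled=subsampled
    )


def outlier_map(vol: IntensityVolume, roi: BinaryMask, stats: RobustStats, direction: str) -> BinaryMask:
    """Binary map of hypo- (< T_low) or hyper- (> T_high) intense ROI voxels."""
    if vol.shape != roi.shape:
        raise ValueError("volume and ROI must share one grid")
    if direction == "hypo":
        data = (vol.data < stats.T_low) & roi.data
    elif direction == "hyper":
        data = (vol.data > stats.T_high) & roi.data
    else:
        raise ValueError(f"direction must be 'hypo' or 'hyper', got {direction!r}")
    return roi.like(data)
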