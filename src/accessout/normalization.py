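"""Size-factor normalization, log transform and the inverse count transform."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regions import CountMatrix

#: floor applied to expected counts so the NB mean stays positive
EXPECTED_FLOOR = 1e-8


@dataclass
class NormalizedMatrix:
    """Centered log-normalized counts with the pieces needed to invert them.

    ``x`` is samples x regions with each column centered at zero;
    ``region_log_means`` holds the per-region means that were subtracted;
    ``size_factors`` the per-sample scaling constants.
    """

    x: np.ndarray
    region_log_means: np.ndarray
    size_factors: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    @property
    def n_regions(self) -> int:
        return self.x.shape[1]

    def region_sd(self) -> np.ndarray:
        return self.x.std(axis=0)


def size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (DESeq2 style).

    The reference for each region is its geometric mean across samples;
    regions containing any zero are excluded from the reference set.  The
    size factor of a sample is the median over reference regions of
    count / reference.
    """
    k = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    if np.any(k < 0):
        raise ValueError("counts must be non-negative")
    positive = np.all(k > 0, axis=0)
    if not positive.any():
        raise ValueError(
            "no region has strictly positive counts in every sample; "
            "apply a looser replication filter before normalizing"
        )
    ref = k[:, positive].astype(np.float64)
    log_geo_mean = np.mean(np.log(ref), axis=0)
    sf = np.exp(np.median(np.log(ref) - log_geo_mean, axis=1))
    if not np.all(np.isfinite(sf)) or np.any(sf <= 0):
        raise ValueError("size factors are not finite and positive")
    return sf


def log_normalize(
    counts: CountMatrix | np.ndarray, sf: np.ndarray | None = None
) -> NormalizedMatrix:
    """Log-transform and center counts: ``x = ln((k+1)/s) - per-region mean``."""
    k = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    if sf is None:
        sf = size_factors(k)
    sf = np.asarray(sf, dtype=np.float64)
    if sf.shape != (k.shape[0],):
        raise ValueError("size factor length must equal number of samples")
    if np.any(sf <= 0) or not np.all(np.isfinite(sf)):
        raise ValueError("size factors must be finite and positive")
    n = np.log((k + 1.0) / sf[:, None])
    nbar = n.mean(axis=0)
    return NormalizedMatrix(x=n - nbar, region_log_means=nbar, size_factors=sf)


def back_transform(
    xhat: np.ndarray,
    region_log_means: np.ndarray,
    sf: np.ndarray,
    floor: float = EXPECTED_FLOOR,
) -> np.ndarray:
    """Invert :func:`log_normalize`: ``exp(xhat + log_mean) * s - 1``, floored."""
    xhat = np.asarray(xhat, dtype=np.float64)
    sf = np.asarray(sf, dtype=np.float64)
    with np.errstate(over="ignore"):  # callers cap overflow downstream
        raw = np.exp(xhat + np.asarray(region_log_means)[None, :]) * sf[:, None] - 1.0
    return np.maximum(raw, floor)
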