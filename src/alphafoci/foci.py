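"""Gamma-H2AX focus formation at DSB loci.

The number of foci induced in a nucleus is Poisson around a fixed yield
per gray of nucleus dose (default 8 foci/Gy).  Focus image areas are
drawn i.i.d. from a size distribution truncated to the observable
0.205-16.7 um^2 interval; the default is a truncated lognormal whose
parameters were fixed once by the shipped calibration script against
the reported dose-dependent overlap statistics (the source size
histogram is available only graphically).  A focus is a
sphere whose equatorial cross-section equals the sampled image area, so
its projection is a circle of radius sqrt(area / pi) from any viewing
angle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "FociYieldConfig",
    "FocusSizeDistribution",
    "sample_focus_count",
    "select_foci_loci",
    "sample_focus_size",
]

log = logging.getLogger(__name__)

TRUNCATION_BOUNDS_UM2 = (0.205, 16.7)


@dataclass(frozen=True)
class FociYieldConfig:
    """Mean number of foci induced per gray of nucleus dose."""

    yield_per_gy: float = 8.0

    def __post_init__(self) -> None:
        if self.yield_per_gy < 0:
            raise ValueError("yield must be non-negative")


@dataclass(frozen=True)
class FocusSizeDistribution:
    """Distribution of the 2D image area of a single focus, um^2.

    ``form`` is ``lognormal`` (median area and geometric standard
    deviation) or ``discrete_histogram`` (per-bin weights over
    ``histogram_edges``).  Samples are truncated to ``bounds``.
    """

    form: str = "lognormal"
    median_um2: float = 1.2
    geometric_sd: float = 3.0
    histogram_edges: tuple = ()
    histogram_weights: tuple = ()
    bounds: tuple[float, float] = TRUNCATION_BOUNDS_UM2

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not 0 < lo < hi:
            raise ValueError("bounds must satisfy 0 < low < high")
        if self.form == "lognormal":
            if self.median_um2 <= 0 or self.geometric_sd <= 1:
                raise ValueError("median > 0 and geometric SD > 1 required")
        elif self.form == "discrete_histogram":
            w = np.asarray(self.histogram_weights, float)
            e = np.asarray(self.histogram_edges, float)
            if e.size != w.size + 1 or np.any(np.diff(e) <= 0):
                raise ValueError("need increasing edges, one more than weights")
            if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("weights must be non-negative and sum to 1")
        else:
            raise ValueError("form must be 'lognormal' or 'discrete_histogram'")

    # -- truncated-lognormal helpers -------------------------------------
    @property
    def _mu_sigma(self) -> tuple[float, float]:
        return math.log(self.median_um2), math.log(self.geometric_sd)

    def cdf(self, area_um2) -> np.ndarray:
        """CDF of the truncated distribution (lognormal form only)."""
        if self.form != "lognormal":
            raise NotImplementedError("cdf available for the lognormal form")
        mu, sigma = self._mu_sigma
        lo, hi = self.bounds
        a = np.clip(np.asarray(area_um2, float), lo, hi)
        f = norm.cdf((np.log(a) - mu) / sigma)
        f_lo = norm.cdf((math.log(lo) - mu) / sigma)
        f_hi = norm.cdf((math.log(hi) - mu) / sigma)
        return (f - f_lo) / (f_hi - f_lo)

    def sample(self, n: int, rng: np.random.Generator | None = None
               ) -> np.ndarray:
        """Draw ``n`` i.i.d. areas (um^2), always inside ``bounds``."""
        rng = np.random.default_rng(rng)
        lo, hi = self.bounds
        if self.form == "lognormal":
            mu, sigma = self._mu_sigma
            f_lo = norm.cdf((math.log(lo) - mu) / sigma)
            f_hi = norm.cdf((math.log(hi) - mu) / sigma)
            u = rng.uniform(f_lo, f_hi, n)
            return np.exp(mu + sigma * norm.ppf(u))
        w = np.asarray(self.histogram_weights, float)
        e = np.asarray(self.histogram_edges, float)
        bins = rng.choice(w.size, size=n, p=w)
        areas = rng.uniform(e[bins], e[bins + 1])
        return np.clip(areas, lo, hi)


def sample_focus_count(nucleus_dose_gy, config: FociYieldConfig = FociYieldConfig(),
                       rng: np.random.Generator | None = None):
    """Poisson number of induced foci at the given nucleus dose(s)."""
    rng = np.random.default_rng(rng)
    dose = np.asarray(nucleus_dose_gy, float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    return rng.poisson(config.yield_per_gy * dose)


def select_foci_loci(dsb_centroids_nm, n: int,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Pick ``n`` focus loci uniformly without replacement from DSB sites.

    Returns positions in um.  If fewer DSBs than requested foci exist,
    all DSBs are used and the shortfall is logged.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(rng)
    cents = np.asarray(dsb_centroids_nm, float).reshape(-1, 3)
    if n > cents.shape[0]:
        log.warning("requested %d foci but only %d DSBs available",
                    n, cents.shape[0])
        n = cents.shape[0]
    idx = rng.choice(cents.shape[0], size=n, replace=False) if n else []
    return cents[idx] * 1e-3


def sample_focus_size(dist: FocusSizeDistribution,
                      rng: np.random.Generator | None = None,
                      n: int = 1) -> np.ndarray:
    """I.i.d. focus image areas from ``dist`` (um^2)."""
    return dist.sample(n, rng)
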