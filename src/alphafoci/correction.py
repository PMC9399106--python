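"""Dose-specific overlap correction of counted focal images.

Conventional 2D scoring counts focal images, not foci: overlapping foci
projected into one connected bright region are counted once.  The
simulation supplies, per size group A_i and dose D, the mean number of
true foci per focal image m(D; A_i) ("multiplication factor").  Combined
with the experimentally observed share of focal images per size group
r(D; A_i), the dose-specific correction factor is the weighted sum

    CF(D) = sum_i m(D; A_i) * r(D; A_i),

and the corrected mean number of induced foci per nucleus is CF(D)
times the observed mean number of focal images per nucleus.  When the
observed ratios are the simulated ones, CF(D) reduces algebraically to
total simulated foci / total simulated images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import DEFAULT_SIZE_GROUPS, SizeGroupScheme

__all__ = [
    "MultiplicityTable",
    "ObservedFociTable",
    "CorrectionResult",
    "build_multiplicity_table",
    "correction_factor",
    "corrected_foci_count",
    "overlap_fraction",
    "read_observed_tables",
    "write_observed_tables",
]

log = logging.getLogger(__name__)

RATIO_SUM_TOL = 1e-6


@dataclass(frozen=True)
class MultiplicityTable:
    """Mean foci per focal image, per size group, at one dose.

    ``mean_multiplicity`` holds NaN for groups without any image (missing,
    not zero); ``counts`` are group occupancies.
    """

    dose_gy: float
    mean_multiplicity: np.ndarray   # (9,) float, NaN = missing
    counts: np.ndarray              # (9,) int

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_multiplicity, float)
        c = np.asarray(self.counts, int)
        if m.shape != c.shape:
            raise ValueError("mismatched group arrays")
        if np.any(m[c > 0] < 1):
            raise ValueError("mean multiplicity below 1 in a populated group")
        object.__setattr__(self, "mean_multiplicity", m)
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class ObservedFociTable:
    """Observed per-size-group image ratios and mean images per nucleus."""

    dose_gy: float
    ratios: np.ndarray              # (9,) summing to 1
    mean_focal_images: float

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, float)
        if np.any(r < 0):
            raise ValueError("ratios must be non-negative")
        if abs(r.sum() - 1.0) > RATIO_SUM_TOL:
            raise ValueError(f"ratios sum to {r.sum():.8f}, expected 1")
        if self.mean_focal_images < 0:
            raise ValueError("mean focal images must be non-negative")
        object.__setattr__(self, "ratios", r)


@dataclass(frozen=True)
class CorrectionResult:
    dose_gy: float
    correction_factor: float
    observed_mean_images: float
    corrected_mean_foci: float


def build_multiplicity_table(images: pd.DataFrame, dose_gy: float,
                             scheme: SizeGroupScheme = DEFAULT_SIZE_GROUPS
                             ) -> MultiplicityTable:
    """Group-wise mean multiplicity from simulated focal images.

    ``images`` needs ``multiplicity`` and ``size_group`` columns.  Empty
    groups are recorded as missing (NaN) with a warning.
    """
    n = scheme.n_groups
    counts = np.zeros(n, dtype=int)
    sums = np.zeros(n)
    if len(images):
        grp = images["size_group"].to_numpy()
        counts = np.bincount(grp, minlength=n)
        sums = np.bincount(grp, weights=images["multiplicity"].to_numpy(),
                           minlength=n)
    m = np.full(n, np.nan)
    np.divide(sums, counts, out=m, where=counts > 0)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        log.warning("size group(s) %s have no focal images at %g Gy",
                    empty.tolist(), dose_gy)
    return MultiplicityTable(dose_gy, m, counts)


def correction_factor(m_table: MultiplicityTable,
                      observed: ObservedFociTable) -> float:
    """CF(D) = sum_i m(D; A_i) x r(D; A_i) over the nine size groups."""
    if abs(m_table.dose_gy - observed.dose_gy) > 1e-9:
        raise ValueError("multiplicity table and observed table disagree "
                         f"on dose ({m_table.dose_gy} vs {observed.dose_gy} Gy)")
    m = m_table.mean_multiplicity
    r = observed.ratios
    if m.shape != r.shape:
        raise ValueError("group schemes differ")
    needed = r > 0
    if np.any(np.isnan(m[needed])):
        missing = np.flatnonzero(needed & np.isnan(m))
        raise ValueError(
            "no simulated multiplicity for populated observed group(s) "
            f"{missing.tolist()}; rerun the simulation with more nuclei")
    return float(np.nansum(m[needed] * r[needed]))


def corrected_foci_count(cf: float, observed_mean_images: float) -> float:
    """Mean induced foci per nucleus = CF x observed focal images."""
    if cf < 0 or observed_mean_images < 0:
        raise ValueError("inputs must be non-negative")
    return cf * observed_mean_images


def overlap_fraction(images: pd.DataFrame) -> float:
    """Percentage of focal images containing two or more foci."""
    if len(images) == 0:
        raise ValueError("no focal images")
    return 100.0 * float((images["multiplicity"] >= 2).mean())


# ---------------------------------------------------------------------------
# delimited-text interfaces for observed data

def read_observed_tables(ratios_csv, means_csv,
                         scheme: SizeGroupScheme = DEFAULT_SIZE_GROUPS
                         ) -> list[ObservedFociTable]:
    """Load observed tables from delimited text.

    ``ratios_csv`` needs columns ``dose_Gy, group_index, ratio`` (group
    indices 1-9); ``means_csv`` needs ``dose_Gy, mean_focal_images``.
    """
    ratios = pd.read_csv(ratios_csv)
    means = pd.read_csv(means_csv)
    for col in ("dose_Gy", "group_index", "ratio"):
        if col not in ratios.columns:
            raise ValueError(f"ratio table lacks column {col!r}")
    for col in ("dose_Gy", "mean_focal_images"):
        if col not in means.columns:
            raise ValueError(f"means table lacks column {col!r}")
    means = means.set_index("dose_Gy")["mean_focal_images"]
    out = []
    for dose, sub in ratios.groupby("dose_Gy"):
        r = np.zeros(scheme.n_groups)
        idx = sub["group_index"].to_numpy(dtype=int) - 1
        if np.any((idx < 0) | (idx >= scheme.n_groups)):
            raise ValueError("group_index must be 1..9")
        r[idx] = sub["ratio"].to_numpy()
        if dose not in means.index:
            raise ValueError(f"no mean focal-image count for {dose} Gy")
        out.append(ObservedFociTable(float(dose), r, float(means.loc[dose])))
    return out


def write_observed_tables(tables: list[ObservedFociTable],
                          ratios_csv, means_csv) -> None:
    """Inverse of :func:`read_observed_tables`."""
    rows = [(t.dose_gy, i + 1, t.ratios[i])
            for t in tables for i in range(t.ratios.size)]
    pd.DataFrame(rows, columns=["dose_Gy", "group_index", "ratio"]).to_csv(
        ratios_csv, index=False)
    pd.DataFrame(
        [(t.dose_gy, t.mean_focal_images) for t in tables],
        columns=["dose_Gy", "mean_focal_images"]).to_csv(means_csv, index=False)
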