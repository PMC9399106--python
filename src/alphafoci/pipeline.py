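"""End-to-end runs: irradiate, damage, form foci, project, tabulate.

Each dose runs on independent random substreams derived from the master
seed and keyed by the dose value, so adding or removing a dose from the
list leaves the other doses' results untouched.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .correction import (
    CorrectionResult,
    MultiplicityTable,
    ObservedFociTable,
    build_multiplicity_table,
    correction_factor,
    corrected_foci_count,
    overlap_fraction,
)
from .damage import ClusteringParams, TrackEmulatorConfig, dsbs_for_nuclei
from .foci import FociYieldConfig, FocusSizeDistribution, sample_focus_count, select_foci_loci
from .geometry import IrradiatorConfig, nucleus_doses, sample_traversals_for_dose
from .imaging import DEFAULT_SIZE_GROUPS, SizeGroupScheme, analyze_images, random_orientation

__all__ = ["RunConfig", "DoseResult", "PipelineResult", "run_pipeline",
           "make_fixture"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulation run."""

    doses_gy: tuple[float, ...] = (0.05, 0.2, 0.5, 1.0)
    n_nuclei: int = 2000
    master_seed: int = 0
    nucleus_diameter_um: float = 10.0
    cell_diameter_um: float = 15.0
    irradiator: IrradiatorConfig = field(default_factory=IrradiatorConfig)
    track: TrackEmulatorConfig = field(default_factory=TrackEmulatorConfig)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    foci_yield: FociYieldConfig = field(default_factory=FociYieldConfig)
    size_distribution: FocusSizeDistribution = field(
        default_factory=FocusSizeDistribution)
    size_groups: SizeGroupScheme = field(
        default_factory=lambda: DEFAULT_SIZE_GROUPS)

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.doses_gy):
            raise ValueError("doses must be non-negative")
        if self.n_nuclei <= 0:
            raise ValueError("n_nuclei must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        sub = {"irradiator": IrradiatorConfig, "track": TrackEmulatorConfig,
               "clustering": ClusteringParams, "foci_yield": FociYieldConfig,
               "size_distribution": FocusSizeDistribution,
               "size_groups": SizeGroupScheme}
        for key, value in raw.items():
            if key in sub:
                if key == "irradiator" and "emission_lines" in value:
                    value["emission_lines"] = tuple(
                        tuple(line) for line in value["emission_lines"])
                for tup_key in ("histogram_edges", "histogram_weights",
                                "bounds", "edges"):
                    if tup_key in value:
                        value[tup_key] = tuple(value[tup_key])
                kw[key] = sub[key](**value)
            elif key == "doses_gy":
                kw[key] = tuple(value)
            else:
                kw[key] = value
        return cls(**kw)


@dataclass
class DoseResult:
    """Per-dose tables and summary statistics."""

    dose_gy: float
    nuclei: pd.DataFrame      # nucleus_id, radial?, dose_Gy, n_hits, n_dsbs, n_foci
    foci: pd.DataFrame        # nucleus_id, x_um, y_um, z_um, area_um2
    images: pd.DataFrame      # nucleus_id, multiplicity, union_area_um2, ...
    multiplicity_table: MultiplicityTable
    summary: dict

    @property
    def image_ratios(self) -> np.ndarray:
        """Simulated share of focal images per size group."""
        counts = self.multiplicity_table.counts
        return counts / counts.sum()

    def as_observed(self) -> ObservedFociTable:
        """This run's own statistics cast as an observed-data table."""
        return ObservedFociTable(self.dose_gy, self.image_ratios,
                                 self.summary["mean_images_per_nucleus"])


@dataclass
class PipelineResult:
    config: RunConfig
    per_dose: dict[float, DoseResult]

    def observed_tables(self) -> list[ObservedFociTable]:
        return [r.as_observed() for r in self.per_dose.values()]

    def correction_results(self, observed: list[ObservedFociTable] | None = None
                           ) -> list[CorrectionResult]:
        """Apply the correction equations per dose.

        With no explicit observed data the run's own simulated ratios and
        image counts are used (self-consistent mode).
        """
        if observed is None:
            observed = self.observed_tables()
        out = []
        for obs in observed:
            if obs.dose_gy not in self.per_dose:
                raise ValueError(
                    f"no simulation at {obs.dose_gy} Gy; simulated doses are "
                    f"{sorted(self.per_dose)}")
            cf = correction_factor(
                self.per_dose[obs.dose_gy].multiplicity_table, obs)
            out.append(CorrectionResult(
                obs.dose_gy, cf, obs.mean_focal_images,
                corrected_foci_count(cf, obs.mean_focal_images)))
        return out

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summaries = {}
        for dose, res in self.per_dose.items():
            tag = f"{dose:g}Gy"
            res.nuclei.to_csv(out / f"nuclei_{tag}.csv", index=False)
            res.foci.to_csv(out / f"foci_{tag}.csv", index=False)
            res.images.to_csv(out / f"images_{tag}.csv", index=False)
            summaries[tag] = res.summary
        with open(out / "summary.json", "w") as fh:
            json.dump({"config": _config_dict(self.config),
                       "per_dose": summaries}, fh, indent=2)


def _config_dict(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.ndarray, tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj
    return enc(config)


def _dose_stream(master_seed: int, dose_gy: float, stage: int
                 ) -> np.random.Generator:
    # substream keyed by (seed, dose value, stage), not by list position
    dose_key = int(round(dose_gy * 1e6))
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, dose_key, stage]))


def _simulate_dose(config: RunConfig, dose_gy: float) -> DoseResult:
    rng_geom = _dose_stream(config.master_seed, dose_gy, 1)
    rng_damage = _dose_stream(config.master_seed, dose_gy, 2)
    rng_foci = _dose_stream(config.master_seed, dose_gy, 3)
    rng_img = _dose_stream(config.master_seed, dose_gy, 4)
    n = config.n_nuclei

    tset = sample_traversals_for_dose(
        dose_gy, n, config.irradiator, config.nucleus_diameter_um,
        config.cell_diameter_um, rng_geom)
    doses, hits = nucleus_doses(tset, n, config.nucleus_diameter_um)
    dsbs = dsbs_for_nuclei(tset, config.track, config.clustering, rng_damage,
                           config.nucleus_diameter_um)
    dsb_counts = np.bincount(dsbs.nucleus_id, minlength=n)

    n_foci = sample_focus_count(doses, config.foci_yield, rng_foci)
    foci_rows, image_frames = [], []
    order = np.argsort(dsbs.nucleus_id, kind="stable")
    cent_sorted = dsbs.centroid[order]
    bounds = np.searchsorted(dsbs.nucleus_id[order],
                             np.arange(n + 1))
    for i in np.flatnonzero(n_foci):
        cents = cent_sorted[bounds[i]:bounds[i + 1]]
        if cents.shape[0] == 0:
            if n_foci[i]:
                log.warning("nucleus %d: %d foci requested but no DSBs", i,
                            n_foci[i])
            continue
        loci = select_foci_loci(cents, int(n_foci[i]), rng_foci)
        areas = config.size_distribution.sample(loci.shape[0], rng_foci)
        img = analyze_images(loci, areas, random_orientation(rng_img),
                             config.size_groups)
        img.insert(0, "nucleus_id", i)
        image_frames.append(img)
        foci_rows.append(pd.DataFrame({
            "nucleus_id": i, "x_um": loci[:, 0], "y_um": loci[:, 1],
            "z_um": loci[:, 2], "area_um2": areas}))

    empty_foci = pd.DataFrame(columns=["nucleus_id", "x_um", "y_um", "z_um",
                                       "area_um2"])
    empty_img = pd.DataFrame(columns=["nucleus_id", "multiplicity",
                                      "union_area_um2", "boundary_class",
                                      "size_group"])
    foci_df = (pd.concat(foci_rows, ignore_index=True) if foci_rows
               else empty_foci)
    images_df = (pd.concat(image_frames, ignore_index=True) if image_frames
                 else empty_img)

    nuclei_df = pd.DataFrame({
        "nucleus_id": np.arange(n), "dose_Gy": doses, "n_hits": hits,
        "n_dsbs": dsb_counts,
        "n_foci": np.bincount(foci_df["nucleus_id"].to_numpy(dtype=int),
                              minlength=n) if len(foci_df) else
        np.zeros(n, dtype=int),
    })
    m_table = build_multiplicity_table(images_df, dose_gy, config.size_groups)
    n_img = len(images_df)
    summary = {
        "dose_Gy": dose_gy,
        "n_nuclei": n,
        "mean_nucleus_dose_Gy": float(doses.mean()),
        "mean_hits_per_nucleus": float(hits.mean()),
        "mean_dsbs_per_nucleus": float(dsb_counts.mean()),
        "mean_foci_per_nucleus": float(len(foci_df) / n),
        "mean_images_per_nucleus": float(n_img / n),
        "mean_image_area_um2": (float(images_df["union_area_um2"].mean())
                                if n_img else float("nan")),
        "overlap_fraction_pct": (overlap_fraction(images_df) if n_img
                                 else float("nan")),
        "overlap_fraction_boundary_pct": (
            100.0 * float((images_df["boundary_class"] == "multi_arc").mean())
            if n_img else float("nan")),
    }
    return DoseResult(dose_gy, nuclei_df, foci_df, images_df, m_table, summary)


def run_pipeline(config: RunConfig = RunConfig()) -> PipelineResult:
    """Simulate every dose in the configuration (deterministic per seed)."""
    per_dose = {}
    for dose in config.doses_gy:
        log.info("simulating %g Gy x %d nuclei", dose, config.n_nuclei)
        per_dose[dose] = _simulate_dose(config, dose)
    return PipelineResult(config, per_dose)


def make_fixture(config: RunConfig = RunConfig(), seed: int = 0):
    """Synthetic 'observed' tables from an independent simulation run.

    Runs the pipeline on a seed derived from ``seed`` (independent of any
    analysis run with the same master seed) and returns
    ``(observed_tables, truth)`` where ``truth`` maps dose to the mean
    number of actually induced foci per nucleus.
    """
    fix_seed = int(np.random.SeedSequence([seed, 0x0F1C]).generate_state(1)[0]
                   % (2 ** 31))
    result = run_pipeline(dataclasses.replace(config, master_seed=fix_seed))
    observed = result.observed_tables()
    truth = {d: r.summary["mean_foci_per_nucleus"]
             for d, r in result.per_dose.items()}
    return observed, truth
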