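"""ROI statistics, CT-number conversion and image-quality summaries
(RMSE of ROI means versus a reference scan, contrast-to-noise ratio).

The CT-number convention here is linear with water at 1024 HU and vacuum
at 0.  A bundled reference table of published Catphan-600 ROI
measurements (mean, SD and CNR for eight sensitometry inserts under four
reconstructions) ships with the package for summary-arithmetic checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .materials import _data_path
from .recon import HU_WATER, ReconVolume

__all__ = [
    "ROISpec",
    "ROIStats",
    "MetricsReport",
    "to_hu",
    "hu_cross_normalize",
    "roi_stats",
    "rmse",
    "cnr",
    "metrics_report",
    "load_reference_table",
    "summary_from_table",
    "AIR_ROIS",
]

AIR_ROIS = ("Air 1", "Air 2")


@dataclass(frozen=True)
class ROISpec:
    """Circular in-slice region of interest in voxel coordinates."""

    center: tuple[float, float]  # (ix, iy) voxel coordinates
    radius: float  # voxels
    slice_index: int
    label: str = ""

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        ix, iy = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        return ((ix - self.center[0]) ** 2 + (iy - self.center[1]) ** 2
                <= self.radius ** 2)


@dataclass(frozen=True)
class ROIStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n < 1:
            raise ValueError("invalid ROI statistics")


def to_hu(volume: ReconVolume | np.ndarray, mu_water: float | None = None
          ) -> np.ndarray:
    """Linear CT-number conversion: HU = 1024 * mu / mu_water."""
    if isinstance(volume, ReconVolume):
        mu = volume.mu
        mu_water = volume.hu_scale if mu_water is None else mu_water
    else:
        mu = np.asarray(volume, dtype=float)
    if mu_water is None or mu_water <= 0:
        raise ValueError("mu_water must be positive")
    return HU_WATER * mu / mu_water


def roi_stats(volume_hu: np.ndarray, roi: ROISpec,
              population_sd: bool = True) -> ROIStats:
    """Mean and SD of CT numbers over a circular ROI in one slice."""
    if not (0 <= roi.slice_index < volume_hu.shape[2]):
        raise ValueError("ROI slice outside volume")
    lo0 = roi.center[0] - roi.radius
    hi0 = roi.center[0] + roi.radius
    lo1 = roi.center[1] - roi.radius
    hi1 = roi.center[1] + roi.radius
    if lo0 < -0.5 or lo1 < -0.5 or hi0 > volume_hu.shape[0] - 0.5 \
            or hi1 > volume_hu.shape[1] - 0.5:
        raise ValueError("ROI extends outside volume")
    sl = volume_hu[:, :, roi.slice_index]
    m = roi.mask(sl.shape)
    vals = sl[m]
    ddof = 0 if population_sd else 1
    return ROIStats(float(vals.mean()), float(vals.std(ddof=ddof)), int(vals.size))


def hu_cross_normalize(volume_hu: np.ndarray, reference_hu: np.ndarray,
                       water_roi: ROISpec) -> np.ndarray:
    """Rescale a volume by the single multiplicative factor that makes its
    water-ROI mean match the reference volume's."""
    mv = roi_stats(volume_hu, water_roi).mean
    mr = roi_stats(reference_hu, water_roi).mean
    if mv == 0:
        raise ValueError("zero water-ROI mean in volume to normalize")
    return volume_hu * (mr / mv)


def rmse(means, ref_means) -> float:
    """Root-mean-square difference of paired ROI means."""
    a = np.asarray(means, dtype=float)
    b = np.asarray(ref_means, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("means and ref_means must have equal length >= 1")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def cnr(a: ROIStats, b: ROIStats) -> float:
    """Contrast-to-noise ratio |mean_a - mean_b| / sqrt(sd_a^2 + sd_b^2)."""
    denom = a.sd ** 2 + b.sd ** 2
    if denom <= 0:
        raise ValueError("CNR undefined: both SDs are zero")
    return abs(a.mean - b.mean) / float(np.sqrt(denom))


@dataclass
class MetricsReport:
    """Per-scan, per-ROI statistics plus overall summaries."""

    per_roi: pd.DataFrame  # columns: scan, roi, mean_hu, sd_hu, delta_hu, cnr
    summary: pd.DataFrame  # columns: scan, rmse_hu, rmse_no_excluded_hu, mean_sd_hu, mean_cnr

    def rounded(self) -> "MetricsReport":
        """One-decimal presentation copy (raw values stay available)."""
        return MetricsReport(self.per_roi.round(1), self.summary.round(1))


def metrics_report(volumes: dict[str, np.ndarray], rois: list[ROISpec],
                   reference_label: str,
                   background_rois: dict[str, ROISpec] | None = None,
                   exclude_from_rmse: tuple[str, ...] = AIR_ROIS
                   ) -> MetricsReport:
    """Assemble per-ROI statistics and summaries for a set of HU volumes.

    ``background_rois`` maps each insert label to the background ROI used
    as the CNR reference; when omitted CNR is skipped.  ``delta_hu`` is
    signed volume-minus-reference.
    """
    if reference_label not in volumes:
        raise ValueError(f"missing reference volume {reference_label!r}")
    rows = []
    for scan, vol in volumes.items():
        for roi in rois:
            st = roi_stats(vol, roi)
            c = np.nan
            if background_rois and roi.label in background_rois:
                c = cnr(st, roi_stats(vol, background_rois[roi.label]))
            rows.append({"scan": scan, "roi": roi.label, "mean_hu": st.mean,
                         "sd_hu": st.sd, "n": st.n, "cnr": c})
    per_roi = pd.DataFrame(rows)
    ref = per_roi[per_roi.scan == reference_label].set_index("roi").mean_hu
    per_roi["delta_hu"] = per_roi.apply(
        lambda r: r.mean_hu - ref[r.roi], axis=1)
    summary = summary_from_table(per_roi, reference_label, exclude_from_rmse)
    return MetricsReport(per_roi, summary)


def load_reference_table(path: str | Path | None = None) -> pd.DataFrame:
    """Published Catphan-600 ROI measurements (mean, SD, CNR per insert for
    the planning CT, raw CBCT, scatter-corrected CBCT and the vendor
    reconstruction)."""
    return pd.read_csv(path or _data_path("catphan_roi_reference.csv"))


def summary_from_table(table: pd.DataFrame, reference_label: str = "pCT",
                       exclude_from_rmse: tuple[str, ...] = AIR_ROIS
                       ) -> pd.DataFrame:
    """RMSE / mean-SD / mean-CNR summary rows from a per-ROI table with
    columns (scan, roi, mean_hu, sd_hu, cnr)."""
    ref = table[table.scan == reference_label].set_index("roi")
    out = []
    for scan in table.scan.unique():
        sub = table[table.scan == scan].set_index("roi")
        aligned = ref.loc[sub.index]
        row = {"scan": scan,
               "mean_sd_hu": float(sub.sd_hu.mean()),
               "mean_cnr": float(sub.cnr.mean())}
        if scan == reference_label:
            row["rmse_hu"] = np.nan
            row["rmse_no_excluded_hu"] = np.nan
        else:
            row["rmse_hu"] = rmse(sub.mean_hu, aligned.mean_hu)
            keep = [r for r in sub.index if r not in exclude_from_rmse]
            row["rmse_no_excluded_hu"] = rmse(sub.loc[keep].mean_hu,
                                              aligned.loc[keep].mean_hu)
        out.append(row)
    return pd.DataFrame(out)[
        ["scan", "rmse_hu", "rmse_no_excluded_hu", "mean_sd_hu", "mean_cnr"]
    ]
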