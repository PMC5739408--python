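"""Quantitative evaluation: HU conversion, ROI statistics, RMSE reports.

The reconstructed attenuation map is converted to CT numbers
(HU = 1000 * (mu - mu_water) / mu_water) and compared against the
ground-truth phantom volume — the synthetic stand-in for the diagnostic-CT
benchmark — inside user-defined regions of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import AttenuationVolume

MU_WATER_DEFAULT = 0.02  # mm^-1, config-exposed


def to_hu(vol: AttenuationVolume, mu_water: float = MU_WATER_DEFAULT
          ) -> np.ndarray:
    """CT numbers in Hounsfield units: water -> 0, air -> -1000."""
    if mu_water <= 0:
        raise ValueError("mu_water must be positive")
    return 1000.0 * (vol.values - mu_water) / mu_water


def from_hu(hu: np.ndarray, mu_water: float = MU_WATER_DEFAULT) -> np.ndarray:
    return mu_water * (1.0 + np.asarray(hu, float) / 1000.0)


@dataclass
class ROISpec:
    """Cylinder or box region in volume mm coordinates.

    Cylinder: radius in xy around ``center``, half-height ``half_z``.
    Box: half-sizes per axis around ``center``.
    """

    label: str
    kind: str                     # "cylinder" | "box"
    center: Sequence[float]
    radius: Optional[float] = None
    half_z: Optional[float] = None
    half_sizes: Optional[Sequence[float]] = None

    def voxel_mask(self, vol: AttenuationVolume) -> np.ndarray:
        x, y, z = vol.voxel_centers()
        cx, cy, cz = self.center
        if self.kind == "cylinder":
            m = ((x - cx) ** 2 + (y - cy) ** 2 <= self.radius ** 2) \
                & (np.abs(z - cz) <= self.half_z)
        elif self.kind == "box":
            hx, hy, hz = self.half_sizes
            m = (np.abs(x - cx) <= hx) & (np.abs(y - cy) <= hy) \
                & (np.abs(z - cz) <= hz)
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if not np.any(m):
            raise ValueError(f"ROI {self.label!r} contains no voxels")
        return m

    def to_dict(self) -> dict:
        d = {"label": self.label, "kind": self.kind,
             "center_mm": list(self.center)}
        if self.kind == "cylinder":
            d.update(radius_mm=self.radius, half_z_mm=self.half_z)
        else:
            d.update(half_sizes_mm=list(self.half_sizes))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ROISpec":
        if d["kind"] == "cylinder":
            return cls(d["label"], "cylinder", d["center_mm"],
                       radius=d["radius_mm"], half_z=d["half_z_mm"])
        return cls(d["label"], "box", d["center_mm"],
                   half_sizes=d["half_sizes_mm"])


def roi_stats(hu: np.ndarray, vol: AttenuationVolume,
              roi: ROISpec) -> tuple:
    """(mean, population STD) of CT numbers over the ROI voxels."""
    m = roi.voxel_mask(vol)
    vals = np.asarray(hu)[m]
    return float(vals.mean()), float(vals.std())


def roi_rmse(hu: np.ndarray, ref_hu: np.ndarray, vol: AttenuationVolume,
             roi: ROISpec) -> float:
    """sqrt(mean squared CT-number difference) over the ROI voxels."""
    m = roi.voxel_mask(vol)
    d = np.asarray(hu)[m] - np.asarray(ref_hu)[m]
    return float(np.sqrt(np.mean(d * d)))


def compare_methods(truth_vol: AttenuationVolume,
                    recon_runs: dict,
                    rois: Sequence[ROISpec],
                    mu_water: float = MU_WATER_DEFAULT) -> pd.DataFrame:
    """Mean / STD / RMSE table per ROI per labelled reconstruction.

    ``recon_runs`` maps a method label to a reconstructed volume on the
    same grid as the ground-truth volume.  The truth itself is tabulated
    first as the reference row set.
    """
    truth_hu = to_hu(truth_vol, mu_water)
    rows = []
    for roi in rois:
        mean, std = roi_stats(truth_hu, truth_vol, roi)
        rows.append({"ROI": roi.label, "method": "truth",
                     "mean": mean, "STD": std, "RMSE": 0.0})
    for label, vol in recon_runs.items():
        if vol.shape != truth_vol.shape:
            raise ValueError(f"run {label!r} grid mismatch with truth")
        hu = to_hu(vol, mu_water)
        for roi in rois:
            mean, std = roi_stats(hu, truth_vol, roi)
            rows.append({"ROI": roi.label, "method": label,
                         "mean": mean, "STD": std,
                         "RMSE": roi_rmse(hu, truth_hu, truth_vol, roi)})
    return pd.DataFrame(rows, columns=["ROI", "method", "mean", "STD",
                                       "RMSE"])
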