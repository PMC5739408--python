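"""File formats: float TIFF stacks + JSON sidecars, MetaImage volumes, CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

from .simulate import (AttenuationVolume, BlockerTrajectory, MaskSet,
                       ProjectionStack, ScanGeometry)


def _geometry_dict(geom: ScanGeometry) -> dict:
    return {"sad_mm": geom.sad, "sdd_mm": geom.sdd,
            "angles_deg": geom.angles_deg.tolist(),
            "det_rows": geom.det_rows, "det_cols": geom.det_cols,
            "pixel_pitch_mm": geom.pixel_pitch}


def geometry_from_dict(d: dict) -> ScanGeometry:
    return ScanGeometry(sad=d["sad_mm"], sdd=d["sdd_mm"],
                        angles_deg=np.asarray(d["angles_deg"]),
                        det_rows=d["det_rows"], det_cols=d["det_cols"],
                        pixel_pitch=d["pixel_pitch_mm"])


def trajectory_dict(traj: BlockerTrajectory) -> dict:
    d = {"strip_width_det_mm": traj.strip_width_det,
         "strip_gap_det_mm": traj.strip_gap_det,
         "amplitude_mm": traj.amplitude,
         "period_views": traj.period_views,
         "penumbra_margin_px": traj.penumbra_margin,
         "phase0_mm": traj.phase0,
         "coverage_mm": [None if not np.isfinite(c) else c
                         for c in traj.coverage]}
    if traj.offset_per_view is not None:
        d["offset_per_view_mm"] = traj.offset_per_view.tolist()
    return d


def trajectory_from_dict(d: dict) -> BlockerTrajectory:
    cov = tuple(-np.inf if c is None else c
                for c in d.get("coverage_mm", [None, None]))
    cov = (cov[0], np.inf if d.get("coverage_mm", [None, None])[1] is None
           else d["coverage_mm"][1])
    return BlockerTrajectory(
        strip_width_det=d["strip_width_det_mm"],
        strip_gap_det=d["strip_gap_det_mm"],
        amplitude=d["amplitude_mm"], period_views=d["period_views"],
        penumbra_margin=d.get("penumbra_margin_px", 2),
        phase0=d.get("phase0_mm", 0.0), coverage=cov,
        offset_per_view=(np.asarray(d["offset_per_view_mm"])
                         if "offset_per_view_mm" in d else None))


def write_projection_stack(path, stack: ProjectionStack,
                           traj: BlockerTrajectory = None,
                           seed: int = None) -> None:
    """32-bit float multi-page TIFF (one page per view) + JSON sidecar;
    ground truth as companion .primary.tif / .scatter.tif."""
    path = Path(path)
    tifffile.imwrite(path, stack.intensities.astype(np.float32))
    sidecar = {"i0": np.asarray(stack.i0).tolist(),
               "geometry": _geometry_dict(stack.geometry)}
    if traj is not None:
        sidecar["blocker"] = trajectory_dict(traj)
    if seed is not None:
        sidecar["seed"] = seed
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    gt = stack.ground_truth or {}
    for key in ("primary", "scatter"):
        if key in gt and gt[key] is not None:
            tifffile.imwrite(path.with_suffix(f".{key}.tif"),
                             gt[key].astype(np.float32))


def read_projection_stack(path) -> tuple:
    """Returns (ProjectionStack, BlockerTrajectory | None, seed | None)."""
    path = Path(path)
    data = tifffile.imread(path).astype(np.float64)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    geom = geometry_from_dict(sidecar["geometry"])
    i0 = np.asarray(sidecar["i0"], float)
    i0 = float(i0) if i0.ndim == 0 else i0
    gt = {}
    for key in ("primary", "scatter"):
        p = path.with_suffix(f".{key}.tif")
        if p.exists():
            gt[key] = tifffile.imread(p).astype(np.float64)
    stack = ProjectionStack(data, i0, geom, ground_truth=gt or None)
    traj = (trajectory_from_dict(sidecar["blocker"])
            if "blocker" in sidecar else None)
    return stack, traj, sidecar.get("seed")


def write_masks(path, masks: MaskSet) -> None:
    tifffile.imwrite(Path(path), masks.blocked.astype(np.uint8) * 255)
    p = Path(path)
    tifffile.imwrite(p.with_name(p.stem + ".eroded.tif"),
                     masks.eroded.astype(np.uint8) * 255)


def write_volume_mha(path, vol: AttenuationVolume) -> None:
    """MetaImage with mm spacing; array axes (x, y, z) -> ITK (z, y, x)."""
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.transpose(vol.values, (2, 1, 0))))
    img.SetSpacing((vol.voxel_size,) * 3)
    img.SetOrigin(tuple(vol.origin + 0.5 * vol.voxel_size))
    sitk.WriteImage(img, str(path))


def read_volume_mha(path) -> AttenuationVolume:
    img = sitk.ReadImage(str(path))
    values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    spacing = img.GetSpacing()[0]
    origin = np.asarray(img.GetOrigin()) - 0.5 * spacing
    return AttenuationVolume(values.astype(np.float64), spacing, origin)
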