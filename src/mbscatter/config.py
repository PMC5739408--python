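"""Run configuration, the end-to-end pipeline, and canned fixtures.

A run executes simulate -> detect -> correct -> reconstruct -> evaluate.
All randomness flows from the single master seed; each stage derives its own
sub-seed deterministically (``stage_seed``), so any stage can be regenerated
in isolation.

Three fixtures reproduce the method's study conditions synthetically:

* ``clean``    — high-contrast water cylinder with a central air insert,
  full blocker coverage; the baseline on which single-view and multi-view
  correction should agree and beat no correction.
* ``boundary`` — the object shadow ends axially beyond the blocker board,
  so one end of the axis has no blocked band in the evaluated view while
  the scatter still varies there; single-view estimation must extrapolate
  and fails, adjacent views carry the missing samples.
* ``robustness`` — a wide low-contrast phantom plus an injected two-point
  edge-detection fault (+3 rows at the second probe) in 10% of views; the
  straight-line edge tilts and the error grows with lateral distance,
  while the minimum-envelope path never uses the faulty points.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as mbio
from .detect import (EdgeErrorInjection, detect_edges_adaptive,
                     detect_edges_two_point)
from .evaluate import MU_WATER_DEFAULT, ROISpec, compare_methods
from .recon import ReconParams, reconstruct
from .scatter import (correct_and_log, estimate_scatter_mvsc)
from .simulate import (AttenuationVolume, BlockerTrajectory, PhantomSpec,
                       ProjectionStack, ScanGeometry, ScatterSimParams,
                       acquire, build_masks, make_phantom)

log = logging.getLogger("mbscatter")

CONFIG_SCHEMA_VERSION = 1


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the master seed."""
    return (zlib.crc32(stage.encode()) ^ (master * 2654435761)) % (2 ** 31)


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    shape: tuple = (64, 64, 64)
    voxel_size_mm: float = 3.0
    origin_mm: Optional[tuple] = None   # None -> centered on the axis

    def origin(self) -> np.ndarray:
        if self.origin_mm is not None:
            return np.asarray(self.origin_mm, float)
        return -0.5 * self.voxel_size_mm * np.asarray(self.shape, float)


def _grid_dict(g: GridSpec) -> dict:
    return {"shape": list(g.shape), "voxel_size_mm": g.voxel_size_mm,
            "origin_mm": (list(g.origin_mm) if g.origin_mm is not None
                          else None)}


def _grid_from_dict(d: dict) -> GridSpec:
    return GridSpec(shape=tuple(d["shape"]),
                    voxel_size_mm=d["voxel_size_mm"],
                    origin_mm=(tuple(d["origin_mm"])
                               if d["origin_mm"] is not None else None))


@dataclass
class DetectionConfig:
    method: str = "adaptive"          # adaptive | twopoint | truth
    n_adjacent: int = 5
    alpha: float = 0.5
    probe_cols: tuple = (4, 24)
    threshold_frac: float = 0.35      # two-point threshold as i0 fraction
    inject_fraction: float = 0.0      # synthetic two-point fault rate
    inject_delta_rows: float = 0.0


@dataclass
class CorrectionConfig:
    method: str = "mvsc"              # none | svsc | mvsc
    n_adjacent: int = 5
    max_span_deg: float = 3.0
    n_basis: Optional[int] = None     # None -> rows/strip-period + 4


@dataclass
class RunConfig:
    geometry: ScanGeometry
    phantom: PhantomSpec
    blocker: Optional[BlockerTrajectory]
    scatter: ScatterSimParams
    detection: DetectionConfig
    correction: CorrectionConfig
    recon: ReconParams
    grid: GridSpec
    rois: list
    seed: int
    i0: float = 1e5
    mu_water: float = MU_WATER_DEFAULT
    name: str = "run"
    # acquisition is simulated on its own (finer, axially extended) grid so
    # the forward data are not generated from the reconstruction grid and
    # every detector row sees fully covered ray paths
    sim_grid: GridSpec = field(default_factory=lambda: GridSpec(
        shape=(128, 128, 96), voxel_size_mm=2.5))

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": CONFIG_SCHEMA_VERSION,
            "name": self.name,
            "seed": self.seed,
            "i0": self.i0,
            "mu_water_per_mm": self.mu_water,
            "geometry": mbio._geometry_dict(self.geometry),
            "phantom": [{"shape": p.shape, "center_mm": list(p.center),
                         "semi_axes_mm": list(p.semi_axes),
                         "mu_per_mm": p.mu}
                        for p in self.phantom.primitives],
            "blocker": (mbio.trajectory_dict(self.blocker)
                        if self.blocker is not None else None),
            "scatter": {"spr": self.scatter.spr,
                        "blur_sigma_mm": self.scatter.blur_sigma,
                        "apply_poisson": self.scatter.apply_poisson},
            "detection": dataclasses.asdict(self.detection),
            "correction": dataclasses.asdict(self.correction),
            "recon": dataclasses.asdict(self.recon),
            "grid": _grid_dict(self.grid),
            "sim_grid": _grid_dict(self.sim_grid),
            "rois": [r.to_dict() for r in self.rois],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        phantom = PhantomSpec()
        for p in d["phantom"]:
            phantom.add(p["shape"], tuple(p["center_mm"]),
                        tuple(p["semi_axes_mm"]), p["mu_per_mm"])
        det = DetectionConfig(**{k: (tuple(v) if k == "probe_cols" else v)
                                 for k, v in d["detection"].items()})
        grid = _grid_from_dict(d["grid"])
        return cls(
            sim_grid=_grid_from_dict(d["sim_grid"]),
            geometry=mbio.geometry_from_dict(d["geometry"]),
            phantom=phantom,
            blocker=(mbio.trajectory_from_dict(d["blocker"])
                     if d["blocker"] is not None else None),
            scatter=ScatterSimParams(spr=d["scatter"]["spr"],
                                     blur_sigma=d["scatter"]["blur_sigma_mm"],
                                     apply_poisson=d["scatter"]["apply_poisson"]),
            detection=det,
            correction=CorrectionConfig(**d["correction"]),
            recon=ReconParams(**d["recon"]),
            grid=grid,
            rois=[ROISpec.from_dict(r) for r in d["rois"]],
            seed=d["seed"], i0=d["i0"],
            mu_water=d["mu_water_per_mm"], name=d.get("name", "run"))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def simulate_stage(config: RunConfig) -> ProjectionStack:
    vol = make_phantom(config.phantom, config.sim_grid.shape,
                       config.sim_grid.voxel_size_mm,
                       config.sim_grid.origin())
    params = dataclasses.replace(
        config.scatter, noise_seed=stage_seed(config.seed, "acquire"))
    return acquire(vol, config.geometry, config.blocker, params,
                   i0=config.i0)


def detect_stage(config: RunConfig, stack: ProjectionStack):
    """Blocked/unblocked masks for every view, by the configured detector."""
    if config.blocker is None:
        return None
    margin = config.blocker.penumbra_margin
    if config.detection.method == "truth":
        return build_masks(config.blocker, config.geometry)
    if config.detection.method == "adaptive":
        model = detect_edges_adaptive(stack,
                                      n_adjacent=config.detection.n_adjacent,
                                      alpha=config.detection.alpha)
        return model.to_masks(config.geometry, margin)
    if config.detection.method == "twopoint":
        inject = None
        if config.detection.inject_fraction > 0:
            inject = EdgeErrorInjection(
                fraction=config.detection.inject_fraction,
                delta_rows=config.detection.inject_delta_rows,
                seed=stage_seed(config.seed, "detect"))
        model = detect_edges_two_point(
            stack, config.detection.probe_cols,
            config.detection.threshold_frac * config.i0, inject=inject)
        return model.to_masks(config.geometry, margin)
    raise ValueError(f"unknown detection method "
                     f"{config.detection.method!r}")


def correct_stage(config: RunConfig, stack: ProjectionStack, masks):
    """Per-view scatter fields and the log-transformed corrected stack."""
    shape = stack.intensities.shape
    if config.correction.method == "none" or masks is None:
        scatter = np.zeros(shape)
    else:
        n_adj = (1 if config.correction.method == "svsc"
                 else config.correction.n_adjacent)
        scatter = np.empty(shape)
        for v in range(stack.n_views):
            scatter[v] = estimate_scatter_mvsc(
                stack, masks, v, n_adjacent=n_adj,
                K=config.correction.n_basis,
                max_span_deg=(np.inf if n_adj == 1
                              else config.correction.max_span_deg))
    corrected = correct_and_log(stack, scatter, masks)
    return scatter, corrected


def reconstruct_stage(config: RunConfig, corrected):
    params = dataclasses.replace(
        config.recon, seed=stage_seed(config.seed, "recon"))
    return reconstruct(corrected, config.geometry, config.grid.shape,
                       config.grid.voxel_size_mm, params,
                       origin=config.grid.origin(), return_history=True)


def evaluate_stage(config: RunConfig, vol: AttenuationVolume):
    truth = make_phantom(config.phantom, config.grid.shape,
                         config.grid.voxel_size_mm, config.grid.origin())
    label = config.correction.method
    return compare_methods(truth, {label: vol}, config.rois,
                           mu_water=config.mu_water)


def run_pipeline(config: RunConfig, outdir=None):
    """Full simulate -> detect -> correct -> reconstruct -> evaluate run.

    Returns (EvalReport DataFrame, dict of in-memory stage products).
    When ``outdir`` is given every stage's output is persisted there.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "config.json")
    runlog = []
    products = {}

    def _stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception:
            log.error("stage %s failed; artifacts so far: %s", name,
                      sorted(products))
            raise
        runlog.append({"stage": name,
                       "seconds": round(time.perf_counter() - t0, 3)})
        return result

    stack = _stage("simulate", simulate_stage, config)
    products["stack"] = stack
    masks = _stage("detect", detect_stage, config, stack)
    products["masks"] = masks
    scatter, corrected = _stage("correct", correct_stage, config, stack,
                                masks)
    products["scatter"] = scatter
    products["corrected"] = corrected
    runlog[-1]["clamp_count"] = corrected.clamp_count
    vol, hist = _stage("reconstruct", reconstruct_stage, config, corrected)
    products["volume"] = vol
    products["history"] = hist
    report = _stage("evaluate", evaluate_stage, config, vol)
    products["report"] = report

    if out is not None:
        mbio.write_projection_stack(out / "projections.tif", stack,
                                    config.blocker, seed=config.seed)
        if masks is not None:
            mbio.write_masks(out / "masks.tif", masks)
        import tifffile
        tifffile.imwrite(out / "scatter_estimate.tif",
                         scatter.astype(np.float32))
        tifffile.imwrite(out / "p_tilde.tif",
                         np.nan_to_num(corrected.p_tilde).astype(np.float32))
        mbio.write_volume_mha(out / "volume_mu.mha", vol)
        hu_vol = AttenuationVolume(
            1000.0 * (vol.values - config.mu_water) / config.mu_water,
            vol.voxel_size, vol.origin)
        mbio.write_volume_mha(out / "volume_hu.mha", hu_vol)
        np.savetxt(out / "iterations.csv",
                   np.column_stack([hist.resid_rms, hist.tv,
                                    hist.update_norm]),
                   delimiter=",", header="resid_rms,tv,update_norm",
                   comments="")
        report.to_csv(out / "report.csv", index=False)
        (out / "run_log.json").write_text(json.dumps(runlog, indent=1))
    return report, products


def compare_corrections(config: RunConfig,
                        methods=("none", "svsc", "mvsc")):
    """Reconstruct the same scan with several correction strategies.

    ``none`` is the no-blocker reference acquisition (scatter left in, all
    rays used); ``svsc``/``mvsc`` share one simulated moving-blocker scan
    and one detection pass.  Returns (EvalReport, dict of volumes).
    """
    stack = simulate_stage(config)
    masks = detect_stage(config, stack)
    truth = make_phantom(config.phantom, config.grid.shape,
                         config.grid.voxel_size_mm, config.grid.origin())
    vols = {}
    for m in methods:
        if m == "none":
            cfg_m = dataclasses.replace(
                config, blocker=None,
                correction=dataclasses.replace(config.correction,
                                               method="none"))
            stack_m, masks_m = simulate_stage(cfg_m), None
        else:
            cfg_m = dataclasses.replace(
                config,
                correction=dataclasses.replace(config.correction, method=m))
            stack_m, masks_m = stack, masks
        _, corrected = correct_stage(cfg_m, stack_m, masks_m)
        vols[m], _ = reconstruct_stage(cfg_m, corrected)
    report = compare_methods(truth, vols, config.rois,
                             mu_water=config.mu_water)
    return report, vols


# ---------------------------------------------------------------------------
# canned fixtures
# ---------------------------------------------------------------------------

def _fixture_geometry() -> ScanGeometry:
    # desk-scale scan: same sad/sdd as the clinical acquisition, fewer
    # views and a coarser detector so a full run stays in the minutes range
    return ScanGeometry.uniform(60, sad=1000.0, sdd=1500.0,
                                det_rows=144, det_cols=144,
                                pixel_pitch=2.0)


def _fixture_recon() -> ReconParams:
    return ReconParams(lam=0.5, n_iterations=30, tv_steps=10,
                       tv_step_scale=0.2, nonneg=True)


def make_fixture(name: str, seed: int = 1) -> RunConfig:
    """Canned end-to-end run configurations: clean | boundary | robustness."""
    geom = _fixture_geometry()
    if name == "clean":
        phantom = PhantomSpec()
        phantom.add("cylinder", (0, 0, 0), (80, 80, 150), 0.02)
        phantom.add("cylinder", (0, 0, 0), (22, 22, 150), 0.0)
        blocker = BlockerTrajectory(strip_width_det=16.0, strip_gap_det=16.0,
                                    amplitude=32.0, period_views=20,
                                    penumbra_margin=2)
        rois = [
            ROISpec("air", "cylinder", (0, 0, 0), radius=12, half_z=24),
            ROISpec("tissue_right", "cylinder", (48, 0, 0), radius=14,
                    half_z=24),
            ROISpec("tissue_left", "cylinder", (-48, 0, 0), radius=14,
                    half_z=24),
        ]
        scatter = ScatterSimParams(spr=1.0, blur_sigma=40.0)
        detection = DetectionConfig(method="adaptive", n_adjacent=5)
    elif name == "boundary":
        # shadow of a short offset cylinder ends where the blocker board
        # does not reach in the evaluated view; adjacent views carry the
        # board (and its strips) into that end region
        phantom = PhantomSpec()
        phantom.add("cylinder", (0, 0, -30), (80, 80, 60), 0.02)
        blocker = BlockerTrajectory(strip_width_det=16.0, strip_gap_det=16.0,
                                    amplitude=64.0, period_views=8,
                                    penumbra_margin=2,
                                    coverage=(-np.inf, 214.0))
        rois = [ROISpec("tissue", "cylinder", (0, 0, -30), radius=14,
                        half_z=20)]
        scatter = ScatterSimParams(spr=1.0, blur_sigma=20.0)
        detection = DetectionConfig(method="truth")
    elif name == "robustness":
        phantom = PhantomSpec()
        phantom.add("cylinder", (0, 0, 0), (95, 95, 150), 0.02)
        blocker = BlockerTrajectory(strip_width_det=16.0, strip_gap_det=16.0,
                                    amplitude=32.0, period_views=20,
                                    penumbra_margin=2)
        rois = [ROISpec("tissue", "cylinder", (60, 0, 0), radius=14,
                        half_z=24)]
        scatter = ScatterSimParams(spr=1.0, blur_sigma=40.0)
        detection = DetectionConfig(method="twopoint", probe_cols=(4, 24),
                                    threshold_frac=0.11,
                                    inject_fraction=0.1,
                                    inject_delta_rows=3.0)
    else:
        raise ValueError(f"unknown fixture {name!r}")
    # the 60-view desk scan spaces views 6 deg apart, so a 5-view neighbor
    # set spans 24 deg; the simulator's scatter varies slowly with angle,
    # hence the raised span cap (a dense clinical scan keeps the 3 deg cap)
    correction = CorrectionConfig(method="mvsc", n_adjacent=5,
                                  max_span_deg=30.0)
    return RunConfig(geometry=geom, phantom=phantom, blocker=blocker,
                     scatter=ScatterSimParams(spr=scatter.spr,
                                              blur_sigma=scatter.blur_sigma,
                                              apply_poisson=True),
                     detection=detection, correction=correction,
                     recon=_fixture_recon(), grid=GridSpec(),
                     rois=rois, seed=seed, i0=1e5, name=name)
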