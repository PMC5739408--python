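"""Voxel phantoms and moving-blocker CBCT acquisition simulation.

The simulator produces per-view detector intensity stacks with the
statistical structure of a moving-blocker scan: ray-traced primary fluence,
a smooth low-frequency scatter field, lead-strip masking that translates
axially view to view, and optional Poisson counting noise.  Ground truth
(primary, scatter, line integrals) is retained on the stack so every
downstream stage can be tested against it.

Geometry conventions: the rotation axis is z; detector rows run along z
(the blocker motion direction), columns are lateral.  Indices are 0-based;
the axial detector coordinate of row ``r`` is ``(r + 0.5) * pixel_pitch``
measured from the row-0 edge.  Angles are in degrees, view 0 at 0 deg.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from ._ray import forward_view_kernel


# ---------------------------------------------------------------------------
# scan geometry
# ---------------------------------------------------------------------------

@dataclass
class ScanGeometry:
    """Circular-orbit cone-beam geometry with a flat centered detector.

    Parameters
    ----------
    sad : source-to-axis distance, mm.
    sdd : source-to-detector distance, mm.
    angles_deg : gantry angle per view, ascending in [0, 360).
    det_rows, det_cols : detector grid (rows = axial z, cols = lateral).
    pixel_pitch : detector pixel size, mm (isotropic).
    """

    sad: float = 1000.0
    sdd: float = 1500.0
    angles_deg: np.ndarray = field(
        default_factory=lambda: np.arange(670) * (360.0 / 670.0))
    det_rows: int = 512
    det_cols: int = 512
    pixel_pitch: float = 0.8

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if not (self.sdd > self.sad > 0):
            raise ValueError("require sdd > sad > 0")
        if self.det_rows <= 0 or self.det_cols <= 0 or self.pixel_pitch <= 0:
            raise ValueError("detector dimensions and pitch must be positive")
        a = self.angles_deg
        if a.ndim != 1 or a.size == 0:
            raise ValueError("angles_deg must be a non-empty 1-D array")
        if np.any(np.diff(a) <= 0) or a[0] < 0 or a[-1] >= 360.0:
            raise ValueError("angles must be ascending over [0, 360)")

    @classmethod
    def uniform(cls, n_views: int, **kwargs) -> "ScanGeometry":
        return cls(angles_deg=np.arange(n_views) * (360.0 / n_views), **kwargs)

    @property
    def n_views(self) -> int:
        return len(self.angles_deg)

    @property
    def magnification(self) -> float:
        return self.sdd / self.sad

    @property
    def det_height_mm(self) -> float:
        return self.det_rows * self.pixel_pitch

    def source_position(self, view: int) -> np.ndarray:
        a = np.deg2rad(self.angles_deg[view])
        return np.array([self.sad * np.cos(a), self.sad * np.sin(a), 0.0])

    def detector_pixel_positions(self, view: int) -> np.ndarray:
        """3-D positions (det_rows, det_cols, 3) of all pixel centers, mm."""
        a = np.deg2rad(self.angles_deg[view])
        center = np.array([-(self.sdd - self.sad) * np.cos(a),
                           -(self.sdd - self.sad) * np.sin(a), 0.0])
        u = np.array([-np.sin(a), np.cos(a), 0.0])     # lateral (columns)
        v = np.array([0.0, 0.0, 1.0])                  # axial (rows)
        cc = (np.arange(self.det_cols) - (self.det_cols - 1) / 2.0) \
            * self.pixel_pitch
        rr = (np.arange(self.det_rows) - (self.det_rows - 1) / 2.0) \
            * self.pixel_pitch
        return (center[None, None, :]
                + rr[:, None, None] * v[None, None, :]
                + cc[None, :, None] * u[None, None, :])

    def axial_coords(self) -> np.ndarray:
        """Axial detector coordinate of each row center, mm from row-0 edge."""
        return (np.arange(self.det_rows) + 0.5) * self.pixel_pitch


# ---------------------------------------------------------------------------
# volumes and phantoms
# ---------------------------------------------------------------------------

@dataclass
class AttenuationVolume:
    """3-D linear attenuation map, mm^-1, indexed (x, y, z).

    ``origin`` is the mm offset of the corner of voxel (0, 0, 0) from the
    rotation axis (x, y) and the central detector plane (z).
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (x, y, z)")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @classmethod
    def zeros(cls, shape, voxel_size, origin=None) -> "AttenuationVolume":
        shape = tuple(shape)
        if origin is None:
            origin = -0.5 * voxel_size * np.asarray(shape, dtype=float)
        return cls(np.zeros(shape), voxel_size, origin)

    @property
    def shape(self):
        return self.values.shape

    def voxel_centers(self):
        """Meshgrid (X, Y, Z) of voxel center coordinates, mm."""
        ax = [self.origin[i] + (np.arange(self.shape[i]) + 0.5) * self.voxel_size
              for i in range(3)]
        return np.meshgrid(*ax, indexing="ij")

    def copy(self) -> "AttenuationVolume":
        return AttenuationVolume(self.values.copy(), self.voxel_size,
                                 self.origin.copy())


@dataclass
class Primitive:
    shape: str                  # "ellipsoid" | "cylinder"
    center: Sequence[float]    # mm
    semi_axes: Sequence[float]  # mm; cylinder: (a, b, half_length_z)
    mu: float                   # mm^-1

    def __post_init__(self):
        if self.shape not in ("ellipsoid", "cylinder"):
            raise ValueError(f"unknown primitive shape {self.shape!r}")
        if np.any(np.asarray(self.semi_axes, dtype=float) <= 0):
            raise ValueError("semi-axes must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")


@dataclass
class PhantomSpec:
    """Stack of geometric primitives; later primitives overwrite earlier."""

    primitives: list = field(default_factory=list)

    def add(self, shape, center, semi_axes, mu) -> "PhantomSpec":
        self.primitives.append(Primitive(shape, center, semi_axes, mu))
        return self


def make_phantom(spec: PhantomSpec, shape, voxel_size,
                 origin=None) -> AttenuationVolume:
    """Rasterize a phantom spec onto a voxel grid (center-point inclusion)."""
    if not spec.primitives:
        raise ValueError("phantom spec contains no primitives")
    vol = AttenuationVolume.zeros(shape, voxel_size, origin)
    x, y, z = vol.voxel_centers()
    for p in spec.primitives:
        cx, cy, cz = p.center
        a, b, c = p.semi_axes
        if p.shape == "ellipsoid":
            inside = (((x - cx) / a) ** 2 + ((y - cy) / b) ** 2
                      + ((z - cz) / c) ** 2) <= 1.0
        else:  # cylinder: elliptical cross-section in xy, extent c in z
            inside = ((((x - cx) / a) ** 2 + ((y - cy) / b) ** 2) <= 1.0) \
                & (np.abs(z - cz) <= c)
        vol.values[inside] = p.mu
    return vol


# ---------------------------------------------------------------------------
# forward projection
# ---------------------------------------------------------------------------

def forward_project(vol: AttenuationVolume, geom: ScanGeometry,
                    view: int) -> np.ndarray:
    """Line integrals of mu (dimensionless) for every detector pixel."""
    src = geom.source_position(view)
    lo = vol.origin
    hi = vol.origin + vol.voxel_size * np.asarray(vol.shape)
    if np.all(src > lo) and np.all(src < hi):
        raise ValueError("source position lies inside the volume support")
    pix = np.ascontiguousarray(geom.detector_pixel_positions(view))
    out = np.empty((geom.det_rows, geom.det_cols), dtype=np.float64)
    nx, ny, nz = vol.shape
    forward_view_kernel(np.ascontiguousarray(vol.values.ravel()),
                        nx, ny, nz,
                        lo[0], lo[1], lo[2], vol.voxel_size,
                        src[0], src[1], src[2], pix, out)
    return out


def project_stack(vol: AttenuationVolume, geom: ScanGeometry) -> np.ndarray:
    """Line integrals for every view: array (n_views, det_rows, det_cols)."""
    return np.stack([forward_project(vol, geom, v)
                     for v in range(geom.n_views)])


# ---------------------------------------------------------------------------
# moving blocker
# ---------------------------------------------------------------------------

def projected_strip_width(physical_mm: float, sdd: float,
                          source_blocker_mm: float) -> float:
    """Physical strip size at the blocker plane -> size at the detector."""
    if not (0 < source_blocker_mm < sdd):
        raise ValueError("blocker must sit between source and detector")
    return physical_mm * sdd / source_blocker_mm


def physical_strip_width(projected_mm: float, sdd: float,
                         source_blocker_mm: float) -> float:
    return projected_mm * source_blocker_mm / sdd


@dataclass
class BlockerTrajectory:
    """Lead-strip layout (projected to the detector plane) and axial motion.

    ``strip_width_det`` / ``strip_gap_det`` are the blocked strip width and
    the unblocked gap at the detector, mm; the pattern period is their sum.
    Motion is a triangular back-and-forth wave of the pattern offset:
    ``amplitude`` mm peak, ``period_views`` views per cycle.  ``coverage``
    bounds the physical blocker board in the pattern frame (before the
    offset is applied); outside it no strips exist.
    """

    strip_width_det: float = 16.0
    strip_gap_det: float = 16.0
    amplitude: float = 32.0
    period_views: int = 40
    penumbra_margin: int = 2
    phase0: float = 0.0
    coverage: tuple = (-np.inf, np.inf)
    offset_per_view: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.strip_width_det <= 0 or self.strip_gap_det <= 0:
            raise ValueError("strip width and gap must be positive")
        if self.offset_per_view is not None:
            self.offset_per_view = np.asarray(self.offset_per_view, float)
            if np.any(np.abs(self.offset_per_view) > self.amplitude + 1e-9):
                raise ValueError("|offset| must not exceed amplitude")

    @property
    def period_mm(self) -> float:
        return self.strip_width_det + self.strip_gap_det

    def offsets(self, n_views: int) -> np.ndarray:
        """Axial pattern offset per view, mm (triangular wave)."""
        if self.offset_per_view is not None:
            if len(self.offset_per_view) != n_views:
                raise ValueError("offset_per_view length mismatch")
            return self.offset_per_view
        v = np.arange(n_views)
        phase = 2.0 * np.pi * v / self.period_views
        return self.amplitude * (2.0 / np.pi) * np.arcsin(np.sin(phase))


@dataclass
class MaskSet:
    """Per-view boolean detector masks, True = blocked.

    ``eroded`` is the penumbra-trimmed variant used for scatter sampling;
    it is always a subset of ``blocked``.
    """

    blocked: np.ndarray   # (n_views, det_rows, det_cols) bool
    eroded: np.ndarray

    def __post_init__(self):
        if self.blocked.shape != self.eroded.shape:
            raise ValueError("blocked/eroded shape mismatch")
        if np.any(self.eroded & ~self.blocked):
            raise ValueError("eroded mask must be a subset of blocked")

    @property
    def unblocked(self) -> np.ndarray:
        return ~self.blocked

    def band_bounds(self, view: int, col: int = 0):
        """(start, end) row-index pairs of blocked runs at one column."""
        return _runs(self.blocked[view, :, col])


def _runs(mask_1d: np.ndarray):
    """Half-open (start, end) index pairs of True runs."""
    padded = np.concatenate(([False], mask_1d, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def erode_rows(rows_blocked: np.ndarray, margin: int) -> np.ndarray:
    """Shrink each blocked run by ``margin`` rows on both sides."""
    if margin <= 0:
        return rows_blocked.copy()
    return ndimage.binary_erosion(rows_blocked,
                                  structure=np.ones(3, bool),
                                  iterations=margin)


def build_masks(traj: BlockerTrajectory, geom: ScanGeometry) -> MaskSet:
    """Blocked/eroded masks for every view from the strip trajectory."""
    if traj.period_mm >= geom.det_height_mm:
        raise ValueError("strip period must be smaller than the detector "
                         "axial extent")
    zc = geom.axial_coords()
    blocked = np.zeros((geom.n_views, geom.det_rows, geom.det_cols), bool)
    eroded = np.zeros_like(blocked)
    offs = traj.offsets(geom.n_views)
    lo, hi = traj.coverage
    for v in range(geom.n_views):
        rel = np.mod(zc - traj.phase0 - offs[v], traj.period_mm)
        rows = rel < traj.strip_width_det
        rows &= (zc >= lo + offs[v]) & (zc < hi + offs[v])
        blocked[v] = rows[:, None]
        eroded[v] = erode_rows(rows, traj.penumbra_margin)[:, None]
    return MaskSet(blocked, eroded)


# ---------------------------------------------------------------------------
# scatter model and acquisition
# ---------------------------------------------------------------------------

@dataclass
class ScatterSimParams:
    """Scatter generator: SPR-scaled Gaussian low-pass of the fluence deficit.

    spr : scatter-to-primary ratio, mean scatter / mean primary over the
        object shadow (dimensionless).
    blur_sigma : Gaussian width at the detector, mm.
    """

    spr: float = 1.0
    blur_sigma: float = 40.0
    noise_seed: int = 0
    apply_poisson: bool = True

    def __post_init__(self):
        if self.spr < 0:
            raise ValueError("spr must be non-negative")
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be positive")


def simulate_scatter(primary: np.ndarray, i0, params: ScatterSimParams,
                     pixel_pitch: float) -> np.ndarray:
    """Smooth low-frequency scatter field for each view.

    scatter = spr-scaled Gaussian blur of the primary fluence deficit
    (i0 - primary), normalized so mean(scatter)/mean(primary) == spr over
    the object shadow (pixels with > 10% fluence deficit).
    """
    primary = np.asarray(primary, dtype=np.float64)
    if np.any(primary < 0):
        raise ValueError("primary fluence must be non-negative")
    deficit = np.maximum(np.asarray(i0, dtype=np.float64) - primary, 0.0)
    single = primary.ndim == 2
    if single:
        primary = primary[None]
        deficit = deficit[None]
    sigma_px = params.blur_sigma / pixel_pitch
    raw = np.empty_like(deficit)
    for v in range(deficit.shape[0]):
        raw[v] = ndimage.gaussian_filter(deficit[v], sigma_px,
                                         mode="nearest")
    shadow = deficit > 0.1 * np.mean(np.broadcast_to(i0, primary.shape))
    if params.spr == 0 or not np.any(shadow) or np.mean(raw[shadow]) <= 0:
        scatter = np.zeros_like(raw)
    else:
        scale = params.spr * np.mean(primary[shadow]) / np.mean(raw[shadow])
        scatter = scale * raw
    return scatter[0] if single else scatter


@dataclass
class ProjectionStack:
    """Per-view detector intensities (total = primary + scatter), fluence.

    ``ground_truth`` optionally carries the simulator's noise-free primary,
    scatter and line-integral arrays for closure tests.
    """

    intensities: np.ndarray      # (n_views, det_rows, det_cols)
    i0: float | np.ndarray
    geometry: ScanGeometry
    ground_truth: Optional[dict] = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        expected = (self.geometry.n_views, self.geometry.det_rows,
                    self.geometry.det_cols)
        if self.intensities.shape != expected:
            raise ValueError(f"intensities shape {self.intensities.shape} "
                             f"inconsistent with geometry {expected}")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_views(self) -> int:
        return self.geometry.n_views


def acquire(vol: AttenuationVolume, geom: ScanGeometry,
            traj: Optional[BlockerTrajectory],
            params: ScatterSimParams, i0: float = 1e5) -> ProjectionStack:
    """Simulate a full moving-blocker acquisition.

    Blocked pixels receive scatter only; unblocked pixels receive
    primary + scatter.  ``traj=None`` simulates the same scan without the
    blocker (the no-correction reference acquisition).  Poisson noise is
    applied to the total fluence with the seed in ``params``.
    """
    li = project_stack(vol, geom)
    primary = i0 * np.exp(-li)
    scatter = simulate_scatter(primary, i0, params, geom.pixel_pitch)
    if traj is not None:
        masks = build_masks(traj, geom)
        total = np.where(masks.blocked, 0.0, primary) + scatter
    else:
        masks = None
        total = primary + scatter
    if params.apply_poisson:
        rng = np.random.default_rng(params.noise_seed)
        total = rng.poisson(total).astype(np.float64)
    return ProjectionStack(total, i0, geom,
                           ground_truth={"primary": primary,
                                         "scatter": scatter,
                                         "line_integrals": li,
                                         "masks": masks})
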