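"""Blocker edge detection in the projection domain.

Two detectors are provided:

* the naive "two-point" method — threshold crossings of the axial profile
  at two probe columns, joined by a straight line.  Accurate when both
  probes sit in high-contrast regions, but a small error at one probe tilts
  the whole line and grows linearly with lateral distance;
* the robust multi-view method — the pointwise *minimum envelope* of axial
  profiles from a few adjacent views approximates the scatter profile
  without any prior edge knowledge (each row is blocked in at least one
  nearby view), and an *adaptive threshold* interpolated between that
  scatter proxy and the local total-signal level separates blocked from
  unblocked rows even when the intensity falls off strongly along the
  detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .simulate import MaskSet, ProjectionStack, ScanGeometry, _runs, erode_rows


class EdgeDetectionError(RuntimeError):
    """Raised when blocker edges cannot be located in a view."""

    def __init__(self, message: str, view: Optional[int] = None):
        super().__init__(message)
        self.view = view


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Edge:
    """Straight blocker edge: row = slope * col + intercept (row units)."""

    slope: float
    intercept: float
    kind: str  # "start" | "end"

    def row_at(self, col) -> np.ndarray:
        return self.slope * np.asarray(col, float) + self.intercept


@dataclass
class EdgeModel:
    """Per-view blocker bands, each a (start, end) pair of edge lines."""

    bands: dict = field(default_factory=dict)  # view -> list[(Edge, Edge)]

    def views(self):
        return sorted(self.bands)

    def band_bounds(self, view: int, col: int) -> np.ndarray:
        """(n_bands, 2) float rows of band [start, end) at one column."""
        out = [(s.row_at(col), e.row_at(col)) for s, e in self.bands[view]]
        return np.asarray(out, float).reshape(-1, 2)

    def to_masks(self, geom: ScanGeometry, penumbra_margin: int = 2) -> MaskSet:
        """Rasterize the edge lines into blocked/eroded detector masks."""
        blocked = np.zeros((geom.n_views, geom.det_rows, geom.det_cols), bool)
        eroded = np.zeros_like(blocked)
        rows = np.arange(geom.det_rows)
        for v, bands in self.bands.items():
            for c in range(geom.det_cols):
                col_rows = np.zeros(geom.det_rows, bool)
                for s, e in bands:
                    r0, r1 = s.row_at(c), e.row_at(c)
                    col_rows |= (rows >= np.round(r0)) & (rows < np.round(r1))
                blocked[v, :, c] = col_rows
                eroded[v, :, c] = erode_rows(col_rows, penumbra_margin)
        return MaskSet(blocked, eroded)

    def to_json(self, path):
        payload = {str(v): [{"start": {"slope": s.slope, "intercept": s.intercept},
                             "end": {"slope": e.slope, "intercept": e.intercept}}
                            for s, e in bands]
                   for v, bands in self.bands.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EdgeModel":
        with open(path) as fh:
            payload = json.load(fh)
        bands = {int(v): [(Edge(b["start"]["slope"], b["start"]["intercept"], "start"),
                           Edge(b["end"]["slope"], b["end"]["intercept"], "end"))
                          for b in blist]
                 for v, blist in payload.items()}
        return cls(bands)


@dataclass
class AxialProfile:
    """Intensity vs detector row at one lateral position of one view.

    ``views`` records which views contributed (more than one after
    min-envelope composition); ``col`` the lateral column it was taken at.
    """

    values: np.ndarray
    view: int
    col: Optional[int] = None
    views: tuple = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not self.views:
            self.views = (self.view,)


def axial_profile(stack: ProjectionStack, view: int, col: int,
                  half_width: int = 2) -> AxialProfile:
    """Median axial profile over a small lateral band (noise suppression)."""
    c0 = max(0, col - half_width)
    c1 = min(stack.geometry.det_cols, col + half_width + 1)
    vals = np.median(stack.intensities[view, :, c0:c1], axis=1)
    return AxialProfile(vals, view, col=col)


# ---------------------------------------------------------------------------
# two-point method
# ---------------------------------------------------------------------------

@dataclass
class EdgeErrorInjection:
    """Synthetic detection fault: shift the rows found at the second probe
    column by ``delta_rows`` in a random ``fraction`` of views."""

    fraction: float = 0.1
    delta_rows: float = 3.0
    seed: int = 0

    def affected_views(self, n_views: int) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        k = max(1, int(round(self.fraction * n_views)))
        return np.sort(rng.choice(n_views, size=k, replace=False))


def _threshold_runs(profile: np.ndarray, threshold: float):
    return _runs(profile < threshold)


def detect_edges_two_point(stack: ProjectionStack,
                           probe_cols: Sequence[int],
                           threshold: float,
                           inject: Optional[EdgeErrorInjection] = None
                           ) -> EdgeModel:
    """Blocker edges as straight lines through two per-column detections.

    At each probe column the axial profile is thresholded; each blocked run
    yields one (start, end) point pair, and each edge is the line through
    its two probe points extended across the detector.  A crossing-count
    mismatch between the two probes raises ``EdgeDetectionError`` carrying
    the view index.
    """
    c1, c2 = probe_cols
    geom = stack.geometry
    for c in (c1, c2):
        if not (0 <= c < geom.det_cols):
            raise ValueError(f"probe column {c} outside detector")
    if c1 == c2:
        raise ValueError("probe columns must differ")
    affected = set()
    if inject is not None:
        affected = set(inject.affected_views(stack.n_views).tolist())
    model = EdgeModel()
    for v in range(stack.n_views):
        runs1 = _threshold_runs(axial_profile(stack, v, c1).values, threshold)
        runs2 = _threshold_runs(axial_profile(stack, v, c2).values, threshold)
        if len(runs1) != len(runs2):
            raise EdgeDetectionError(
                f"view {v}: {len(runs1)} blocked runs at column {c1} vs "
                f"{len(runs2)} at column {c2}", view=v)
        delta = inject.delta_rows if v in affected else 0.0
        bands = []
        for (s1, e1), (s2, e2) in zip(runs1, runs2):
            s2 = s2 + delta
            e2 = e2 + delta
            ms = (s2 - s1) / (c2 - c1)
            me = (e2 - e1) / (c2 - c1)
            bands.append((Edge(ms, s1 - ms * c1, "start"),
                          Edge(me, e1 - me * c1, "end")))
        model.bands[v] = bands
    return model


# ---------------------------------------------------------------------------
# minimum envelope + adaptive threshold
# ---------------------------------------------------------------------------

def min_envelope(profiles: Sequence[AxialProfile]) -> AxialProfile:
    """Pointwise minimum of axial profiles from adjacent views.

    Keeping the lower signal at each row approximates the scatter profile:
    every row is blocked (scatter-only) in at least one contributing view
    when the blocker motion covers the strip period.
    """
    if len(profiles) < 2:
        raise ValueError("min_envelope needs at least two profiles")
    n = len(profiles[0].values)
    for p in profiles[1:]:
        if len(p.values) != n:
            raise ValueError("profile length mismatch")
    vals = np.min(np.stack([p.values for p in profiles]), axis=0)
    views = tuple(sorted({w for p in profiles for w in p.views}))
    center = profiles[len(profiles) // 2].view
    return AxialProfile(vals, center, col=profiles[0].col, views=views)


def _band_period_px(blocked: np.ndarray) -> float:
    """Crude strip-period estimate (rows) from a provisional blocked mask."""
    runs = _runs(blocked)
    if len(runs) >= 2:
        starts = np.array([s for s, _ in runs], float)
        return float(np.median(np.diff(starts)))
    if runs:
        return 2.0 * (runs[0][1] - runs[0][0])
    return max(4.0, len(blocked) / 4.0)


def adaptive_threshold_edges(envelope: AxialProfile, stack: ProjectionStack,
                             view: int, alpha: float = 0.5,
                             period_px: Optional[float] = None,
                             refine_range: int = 3) -> EdgeModel:
    """Blocker bands from the scatter-proxy envelope and a per-row threshold.

    The threshold is t(z) = S(z) + alpha * (U(z) - S(z)) with S the smoothed
    minimum envelope (scatter proxy) and U the running maximum of the view's
    own profile over one strip period (local total-signal level).  Rows with
    profile < t are blocked; runs become bands, band boundaries are refined
    per column within ``refine_range`` rows, and each edge is the
    least-squares line through its per-column points.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    geom = stack.geometry
    med = ndimage.median_filter(stack.intensities[view], size=(1, 5),
                                mode="nearest")
    # per-column envelopes over the same contributing views
    env2d = np.min(np.stack([
        ndimage.median_filter(stack.intensities[j], size=(1, 5),
                              mode="nearest")
        for j in envelope.views]), axis=0)

    center_col = geom.det_cols // 2 if envelope.col is None else envelope.col
    prof_c = med[:, center_col]
    if period_px is None:
        # provisional threshold from robust levels (a plain max is thrown
        # off by bright rows where the object shadow falls off axially)
        lo_level = np.median(envelope.values)
        hi_level = np.percentile(prof_c, 70)
        prov = prof_c < 0.5 * (lo_level + hi_level)
        period_px = _band_period_px(prov)
    win = max(3, int(round(period_px)) | 1)
    smooth_win = max(3, int(round(period_px / 2)) | 1)

    s2d = ndimage.uniform_filter1d(env2d, smooth_win, axis=0, mode="nearest")
    # local total-signal level: grey closing over one strip period fills
    # the dark blocked bands (anything narrower than the window) and
    # recovers the unblocked envelope even for bands cut off at the
    # detector edge, without latching onto narrow bright outliers the way
    # a running maximum would
    u2d = ndimage.grey_closing(med, size=(win, 1), mode="reflect")
    contrast = u2d - s2d
    if np.max(contrast) < 0.05 * max(np.max(u2d), 1e-30):
        raise EdgeDetectionError(
            f"view {view}: no blocker contrast (total ~ scatter everywhere)",
            view=view)
    t2d = s2d + alpha * contrast
    blocked2d = med < t2d

    # central band structure, then per-column refinement of each boundary
    s_env = ndimage.uniform_filter1d(envelope.values, smooth_win,
                                     mode="nearest")
    u_c = u2d[:, center_col]
    t_c = s_env + alpha * (u_c - s_env)
    runs = _runs(prof_c < t_c)
    if not runs:
        raise EdgeDetectionError(f"view {view}: no blocked bands found",
                                 view=view)
    cols = np.arange(geom.det_cols)
    bands = []
    for (r0, r1) in runs:
        pts = {"start": [], "end": []}
        for c in cols:
            cruns = _runs(blocked2d[:, c])
            if not cruns:
                continue
            cstarts = np.array([s for s, _ in cruns])
            cends = np.array([e for _, e in cruns])
            ks = np.argmin(np.abs(cstarts - r0))
            ke = np.argmin(np.abs(cends - r1))
            if abs(cstarts[ks] - r0) <= refine_range:
                pts["start"].append((c, cstarts[ks]))
            if abs(cends[ke] - r1) <= refine_range:
                pts["end"].append((c, cends[ke]))
        edges = {}
        for kind, fallback in (("start", r0), ("end", r1)):
            p = np.asarray(pts[kind], float)
            if len(p) >= 2 and np.ptp(p[:, 0]) > 0:
                slope, intercept = np.polyfit(p[:, 0], p[:, 1], 1)
            else:
                slope, intercept = 0.0, float(fallback)
            edges[kind] = Edge(float(slope), float(intercept), kind)
        bands.append((edges["start"], edges["end"]))
    return EdgeModel({view: bands})


def detect_edges_adaptive(stack: ProjectionStack, n_adjacent: int = 5,
                          alpha: float = 0.5,
                          period_px: Optional[float] = None,
                          col: Optional[int] = None) -> EdgeModel:
    """Run the minimum-envelope + adaptive-threshold detector on all views."""
    if n_adjacent < 2:
        raise ValueError("need at least 2 adjacent views for the envelope")
    geom = stack.geometry
    if col is None:
        col = geom.det_cols // 2
    half = n_adjacent // 2
    n = stack.n_views
    model = EdgeModel()
    for v in range(n):
        lo = min(max(0, v - half), max(0, n - n_adjacent))
        members = range(lo, min(n, lo + n_adjacent))
        env = min_envelope([axial_profile(stack, j, col) for j in members])
        one = adaptive_threshold_edges(env, stack, v, alpha=alpha,
                                       period_px=period_px)
        model.bands[v] = one.bands[v]
    return model
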