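"""Scatter-field estimation from blocked-region samples (SVSC and MVSC).

The scatter field behind the unblocked detector regions is recovered by a
least-squares cubic B-spline fit along the axial (blocker-motion)
direction.  Single-view estimation (SVSC) uses only the current view's
blocked bands; multi-view estimation (MVSC) pools the blocked samples of a
few adjacent views — the blocker sits at a different axial offset in each,
so the pooled sample set covers the axis several times more densely, which
matters most near object boundaries where the scatter transitions quickly
or where one end of the axis has no blocked band at all.

The fitted model for view i is  S_i(z) = sum_k a_k W_k(z)  with cubic
B-spline bases W_k on uniform knots, the weights minimizing the summed
squared residual over all blocked-region samples of the neighbor views.
With the neighbor set reduced to {i} the fit collapses exactly to SVSC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.interpolate import BSpline

from .simulate import MaskSet, ProjectionStack, ScanGeometry, _runs

log = logging.getLogger("mbscatter")

RIDGE = 1e-8          # Tikhonov term on the normal equations (conditioning)
LOG_FLOOR_FRAC = 1e-6  # fluence floor before the log transform, as i0 fraction


class SpanError(ValueError):
    """Neighbor set spans a larger gantry arc than allowed."""


class SplineFitError(RuntimeError):
    """Least-squares spline fit is infeasible (rank-deficient or too few
    samples)."""


# ---------------------------------------------------------------------------
# neighbor sets and samples
# ---------------------------------------------------------------------------

@dataclass
class NeighborSet:
    """Contiguous views pooled for one view's scatter fit (includes center)."""

    center: int
    members: np.ndarray
    span_deg: float


def neighbor_set(geom: ScanGeometry, view: int, n_adjacent: int,
                 max_span_deg: float = 3.0) -> NeighborSet:
    """Centered contiguous window of ``n_adjacent`` views (shifted at the
    ends of the scan), checked against the angular span limit.

    Adjacent views only share scatter when the gantry barely moves between
    them; the span cap rejects neighbor sets over which the scatter field
    can no longer be treated as common.
    """
    if n_adjacent < 1 or n_adjacent % 2 == 0:
        raise ValueError("n_adjacent must be a positive odd count")
    n = geom.n_views
    if n_adjacent > n:
        raise ValueError("n_adjacent exceeds number of views")
    half = n_adjacent // 2
    lo = min(max(0, view - half), n - n_adjacent)
    members = np.arange(lo, lo + n_adjacent)
    span = float(np.ptp(geom.angles_deg[members]))
    if span > max_span_deg + 1e-9:
        raise SpanError(f"neighbor views span {span:.3g} deg, "
                        f"limit {max_span_deg:.3g} deg")
    return NeighborSet(view, members, span)


@dataclass
class ScatterSamples:
    """Blocked-region scatter samples pooled over a neighbor set.

    z : axial sample positions, mm (detector row-center coordinates);
    values : sampled fluence; view_of / band_of : provenance per sample.
    """

    z: np.ndarray
    values: np.ndarray
    view_of: np.ndarray
    band_of: np.ndarray
    col: int

    def __len__(self):
        return len(self.z)


def _eroded_rows(masks: MaskSet, view: int, col: int) -> np.ndarray:
    return np.flatnonzero(masks.eroded[view, :, col])


def collect_samples(stack: ProjectionStack, masks: MaskSet,
                    nbr: NeighborSet, col: int) -> ScatterSamples:
    """Scatter samples at one lateral column from every neighbor view's
    eroded blocked bands."""
    geom = stack.geometry
    zc = geom.axial_coords()
    zs, vals, view_of, band_of = [], [], [], []
    for j in nbr.members:
        rows = _eroded_rows(masks, j, col)
        if rows.size == 0:
            raise SplineFitError(f"view {j} has no blocked pixels at "
                                 f"column {col}")
        runs = _runs(masks.eroded[j, :, col])
        band_idx = np.zeros(geom.det_rows, int)
        for b, (s, e) in enumerate(runs):
            band_idx[s:e] = b
        zs.append(zc[rows])
        vals.append(stack.intensities[j, rows, col])
        view_of.append(np.full(rows.size, j))
        band_of.append(band_idx[rows])
    return ScatterSamples(np.concatenate(zs), np.concatenate(vals),
                          np.concatenate(view_of), np.concatenate(band_of),
                          col)


# ---------------------------------------------------------------------------
# spline fitting
# ---------------------------------------------------------------------------

@dataclass
class SplineModel:
    """Cubic B-spline scatter profile S(z) = sum_k a_k W_k(z).

    ``knots`` is the full clamped knot vector; ``weights`` the fitted a_k
    (one column per lateral detector column when fitted jointly).
    Evaluation clamps z to the sampled range [z_lo, z_hi] — beyond the
    outermost sample the profile holds its end value.
    """

    knots: np.ndarray
    weights: np.ndarray
    z_lo: float
    z_hi: float
    degree: int = 3

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    def evaluate(self, z: np.ndarray) -> np.ndarray:
        zc = np.clip(np.asarray(z, float), self.z_lo, self.z_hi)
        dm = BSpline.design_matrix(zc, self.knots, self.degree)
        return dm @ self.weights


def _knot_vector(n_basis: int, z0: float, z1: float,
                 degree: int = 3) -> np.ndarray:
    if n_basis < degree + 1:
        raise ValueError(f"need at least {degree + 1} basis functions")
    interior = np.linspace(z0, z1, n_basis - degree + 1)
    return np.concatenate([np.full(degree, z0), interior,
                           np.full(degree, z1)])


def _solve_spline(z: np.ndarray, y: np.ndarray, knots: np.ndarray,
                  degree: int = 3) -> np.ndarray:
    """Penalized-ridge normal-equations solve; y may be (n,) or (n, m)."""
    dm = BSpline.design_matrix(z, knots, degree)
    coverage = np.asarray((dm != 0).sum(axis=0)).ravel()
    if np.any(coverage == 0):
        k = int(np.flatnonzero(coverage == 0)[0])
        span = (knots[k], knots[k + degree + 1])
        raise SplineFitError(
            f"no samples support basis function {k} "
            f"(knot span {span[0]:.1f}..{span[1]:.1f} mm)")
    a = dm.toarray()
    gram0 = a.T @ a
    gram = gram0.copy()
    gram[np.diag_indices_from(gram)] += RIDGE * np.trace(gram0) / len(gram0)
    rhs = a.T @ y
    w = np.linalg.solve(gram, rhs)
    # two refinement steps against the unridged normal equations remove the
    # ridge bias while the regularized factor keeps the solve conditioned
    for _ in range(2):
        w = w + np.linalg.solve(gram, rhs - gram0 @ w)
    return w


def fit_spline(samples: ScatterSamples, K: int,
               z_range: Optional[tuple] = None) -> SplineModel:
    """Least-squares cubic B-spline fit of pooled scatter samples.

    Minimizes sum_j sum_n (S_j(z_jn) - sum_k a_k W_k(z_jn))^2 over the
    weights; the direct ridge-stabilized normal-equations solution equals
    the QR solution of the same design matrix to high precision.
    """
    if len(samples) < K:
        raise SplineFitError(f"{len(samples)} samples < {K} basis functions")
    if z_range is None:
        z_range = (float(samples.z.min()), float(samples.z.max()))
    knots = _knot_vector(K, z_range[0], z_range[1])
    z = np.clip(samples.z, z_range[0], z_range[1])
    weights = _solve_spline(z, samples.values, knots)
    return SplineModel(knots, weights,
                       float(samples.z.min()), float(samples.z.max()))


# ---------------------------------------------------------------------------
# per-view scatter fields
# ---------------------------------------------------------------------------

def _strip_period_mm(geom: ScanGeometry, masks: MaskSet, view: int) -> float:
    """Strip period read off the blocked mask of one view, mm."""
    runs = _runs(masks.blocked[view, :, masks.blocked.shape[2] // 2])
    if len(runs) >= 2:
        period_px = float(np.median(np.diff([s for s, _ in runs])))
    elif runs:
        period_px = 2.0 * (runs[0][1] - runs[0][0])
    else:
        period_px = geom.det_rows / 4.0
    return period_px * geom.pixel_pitch


def estimate_scatter_mvsc(stack: ProjectionStack, masks: MaskSet, view: int,
                          n_adjacent: int = 5, K: Optional[int] = None,
                          max_span_deg: float = 3.0,
                          smooth_cols: int = 11) -> np.ndarray:
    """Multi-view scatter field for one view (2-D detector array).

    Per lateral column, the blocked-region samples of ``n_adjacent``
    centered views are pooled and spline-fitted along the axis; the fits
    are evaluated on every row (end-value clamped beyond the outermost
    sample) and smoothed laterally by a moving average.  The knot span
    covers the sampled axial range; the default basis count is one
    function per strip period over that span plus four.
    ``n_adjacent=1`` is exactly SVSC.
    """
    geom = stack.geometry
    nbr = neighbor_set(geom, view, n_adjacent, max_span_deg)
    zc = geom.axial_coords()
    period_mm = _strip_period_mm(geom, masks, view)
    # group columns sharing an identical sampling pattern: one joint
    # multi-column solve per pattern
    patterns: dict = {}
    for c in range(geom.det_cols):
        key = tuple(int(r) for j in nbr.members
                    for r in _eroded_rows(masks, j, c))
        patterns.setdefault(key, []).append(c)
    field = np.empty((geom.det_rows, geom.det_cols))
    for key, cols in patterns.items():
        if not key:
            raise SplineFitError(f"no blocked samples for view {view} at "
                                 f"column {cols[0]}")
        c0 = cols[0]
        rows_per_member = [_eroded_rows(masks, j, c0) for j in nbr.members]
        for j, rows in zip(nbr.members, rows_per_member):
            if rows.size == 0:
                raise SplineFitError(f"view {j} has no blocked pixels at "
                                     f"column {c0}")
        zs = np.concatenate([zc[rows] for rows in rows_per_member])
        z_lo, z_hi = float(zs.min()), float(zs.max())
        n_basis = K if K is not None else \
            max(4, int(round((z_hi - z_lo) / period_mm)) + 4)
        if len(zs) < n_basis:
            raise SplineFitError(f"view {view}: {len(zs)} samples < "
                                 f"{n_basis} basis functions")
        knots = _knot_vector(n_basis, z_lo, z_hi)
        ys = np.stack([np.concatenate(
            [stack.intensities[j, rows, c]
             for j, rows in zip(nbr.members, rows_per_member)])
            for c in cols], axis=1)
        weights = _solve_spline(np.clip(zs, z_lo, z_hi), ys, knots)
        model = SplineModel(knots, weights, z_lo, z_hi)
        field[:, cols] = model.evaluate(zc)
    if smooth_cols > 1:
        field = ndimage.uniform_filter1d(field, smooth_cols, axis=1,
                                         mode="nearest")
    return np.maximum(field, 0.0)


def estimate_scatter_svsc(stack: ProjectionStack, masks: MaskSet,
                          view: int, K: Optional[int] = None,
                          smooth_cols: int = 11) -> np.ndarray:
    """Single-view scatter field: the MVSC path with neighbor set {view}."""
    return estimate_scatter_mvsc(stack, masks, view, n_adjacent=1, K=K,
                                 max_span_deg=np.inf,
                                 smooth_cols=smooth_cols)


# ---------------------------------------------------------------------------
# correction and log transform
# ---------------------------------------------------------------------------

@dataclass
class CorrectedProjection:
    """Log-transformed scatter-corrected line integrals, unblocked pixels
    only (``valid`` marks where p_tilde is defined)."""

    p_tilde: np.ndarray   # (n_views, det_rows, det_cols)
    valid: np.ndarray     # bool, same shape
    clamp_count: int = 0


def correct_and_log(stack: ProjectionStack, scatter: np.ndarray,
                    masks: Optional[MaskSet],
                    guard_px: int = 1) -> CorrectedProjection:
    """p_tilde = -ln(max(total - scatter, floor) / i0) on unblocked pixels.

    ``guard_px`` dilates the blocked mask before computing validity so that
    pixels within a small band of an (imperfectly detected) edge are not
    fed to the reconstruction.  The fluence floor is 1e-6 * i0; pixels that
    hit it are counted and reported.
    """
    total = stack.intensities
    scatter = np.broadcast_to(np.asarray(scatter, float), total.shape)
    if masks is None:
        valid = np.ones(total.shape, bool)
    else:
        blocked = masks.blocked
        if guard_px > 0:
            st = np.ones((1, 2 * guard_px + 1, 1), bool)
            blocked = ndimage.binary_dilation(blocked, structure=st)
        valid = ~blocked
    i0 = float(np.mean(np.asarray(stack.i0, float)))
    floor = LOG_FLOOR_FRAC * i0
    net = total - scatter
    over = (scatter > total) & valid
    if over.sum() > 0.5 * valid.sum():
        log.warning("scatter exceeds total on %.0f%% of unblocked pixels",
                    100.0 * over.sum() / valid.sum())
    clamped = np.maximum(net, floor)
    clamp_count = int(np.count_nonzero((net < floor) & valid))
    if clamp_count:
        log.info("fluence floor applied on %d unblocked pixels", clamp_count)
    p = -np.log(clamped / i0)
    p[~valid] = np.nan
    return CorrectedProjection(p, valid, clamp_count)
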