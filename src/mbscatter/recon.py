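"""TV-constrained algebraic reconstruction from partially masked projections.

The attenuation volume minimizes the image total variation subject to data
fidelity and non-negativity: sequential Kaczmarz (ART) sweeps enforce
|A mu - p| <= eps on the unblocked rays, a non-negativity clamp follows
each sweep, and a few steepest-descent steps on the TV functional follow
each pass, with the TV step size tied to the magnitude of the preceding
ART update (adaptive-steepest-descent coupling).  Because the blocked rows
move axially view to view, the masked acquisition is equivalent to a
few-ray scan whose missing data the TV prior compensates.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from ._ray import art_view_kernel
from .scatter import CorrectedProjection
from .simulate import AttenuationVolume, ScanGeometry

TV_DELTA = 1e-8   # smoothing constant inside the TV root
PLATEAU_RTOL = 1e-4
DIVERGENCE_RTOL = 1.01


class ReconDivergenceError(RuntimeError):
    def __init__(self, trace):
        super().__init__(f"data residual diverged; trace: {trace}")
        self.trace = trace


@dataclass
class ReconParams:
    """Iteration controls for the alternating ART / TV-descent scheme.

    lam : ART relaxation factor in (0, 1].
    epsilon : optional data-residual (RMS, line-integral units) stopping
        bound; when None, iteration stops on a residual plateau instead.
    tv_step_scale : TV step as a fraction of the ART update magnitude.
    """

    lam: float = 0.5
    epsilon: Optional[float] = None
    n_iterations: int = 30
    tv_steps: int = 10
    tv_step_scale: float = 0.2
    nonneg: bool = True
    seed: int = 0
    shuffle_views: bool = False

    def __post_init__(self):
        if not (0 < self.lam <= 1):
            raise ValueError("lam must lie in (0, 1]")
        if self.n_iterations < 0 or self.tv_steps < 0:
            raise ValueError("iteration counts must be non-negative")
        if self.tv_step_scale <= 0:
            raise ValueError("tv_step_scale must be positive")


def bit_reversed_order(n: int) -> np.ndarray:
    """Multilevel view ordering: successive views maximally separated."""
    bits = max(1, int(np.ceil(np.log2(max(n, 2)))))
    idx = np.arange(2 ** bits)
    rev = np.zeros_like(idx)
    for b in range(bits):
        rev |= ((idx >> b) & 1) << (bits - 1 - b)
    return rev[rev < n]


def view_order(n_views: int, params: ReconParams) -> np.ndarray:
    order = bit_reversed_order(n_views)
    if params.shuffle_views:
        rng = np.random.default_rng(params.seed)
        order = rng.permutation(n_views)
    return order


# ---------------------------------------------------------------------------
# ART
# ---------------------------------------------------------------------------

def art_pass(vol: AttenuationVolume, proj: CorrectedProjection,
             geom: ScanGeometry, params: ReconParams) -> tuple:
    """One full Kaczmarz sweep over all valid rays of all views.

    Views are visited in bit-reversed order, rays row-major within a view.
    Returns (updated volume, stats dict with pre-update residual RMS and
    skipped-ray count).
    """
    out = vol.copy()
    mu_flat = out.values.ravel()   # view into out.values
    nx, ny, nz = out.shape
    lo = out.origin
    resid_sq = 0.0
    used = 0
    skipped = 0
    for v in view_order(geom.n_views, params):
        src = geom.source_position(v)
        pix = np.ascontiguousarray(geom.detector_pixel_positions(v))
        p = np.ascontiguousarray(np.nan_to_num(proj.p_tilde[v]))
        valid = np.ascontiguousarray(proj.valid[v])
        rs, u, s = art_view_kernel(mu_flat, nx, ny, nz,
                                   lo[0], lo[1], lo[2], out.voxel_size,
                                   src[0], src[1], src[2], pix, p, valid,
                                   params.lam)
        resid_sq += rs
        used += u
        skipped += s
    if params.nonneg:
        np.maximum(out.values, 0.0, out=out.values)
    rms = float(np.sqrt(resid_sq / used)) if used else 0.0
    return out, {"resid_rms": rms, "n_used": used, "n_skipped": skipped}


# ---------------------------------------------------------------------------
# total variation
# ---------------------------------------------------------------------------

def _grad_terms(u: np.ndarray):
    """Backward differences (zero on the low-index faces) and root terms."""
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gz = np.zeros_like(u)
    gx[1:, :, :] = u[1:, :, :] - u[:-1, :, :]
    gy[:, 1:, :] = u[:, 1:, :] - u[:, :-1, :]
    gz[:, :, 1:] = u[:, :, 1:] - u[:, :, :-1]
    root = np.sqrt(gx * gx + gy * gy + gz * gz + TV_DELTA ** 2)
    return gx, gy, gz, root


def tv_value(vol: AttenuationVolume) -> float:
    """Isotropic total variation: sum over voxels of the local backward
    gradient magnitude (smoothed with a tiny constant inside the root so a
    constant volume evaluates to zero to machine precision)."""
    u = vol.values
    if min(u.shape) < 2:
        raise ValueError("volume must span at least 2 voxels per axis")
    _, _, _, root = _grad_terms(u)
    return float(np.sum(root - TV_DELTA))


def tv_gradient(vol: AttenuationVolume) -> np.ndarray:
    """Analytic gradient of the smoothed TV functional."""
    u = vol.values
    gx, gy, gz, root = _grad_terms(u)
    g = (gx + gy + gz) / root
    # own-term contribution minus forward-neighbor terms
    g[:-1, :, :] -= gx[1:, :, :] / root[1:, :, :]
    g[:, :-1, :] -= gy[:, 1:, :] / root[:, 1:, :]
    g[:, :, :-1] -= gz[:, :, 1:] / root[:, :, 1:]
    return g


def tv_descent(vol: AttenuationVolume, params: ReconParams,
               ref_update_norm: float) -> AttenuationVolume:
    """``tv_steps`` normalized steepest-descent steps on the TV functional.

    The step length is ``tv_step_scale * ref_update_norm`` (the norm of the
    preceding ART update).  Each step is safeguarded by halving-on-increase
    so the TV value never rises across the call.
    """
    out = vol.copy()
    if params.tv_steps == 0 or ref_update_norm <= 0:
        return out
    step = params.tv_step_scale * ref_update_norm
    f = tv_value(out)
    for _ in range(params.tv_steps):
        g = tv_gradient(out)
        gn = float(np.linalg.norm(g))
        if gn == 0.0:
            break
        s = step
        for _ in range(8):
            trial = out.values - s * g / gn
            f_trial = float(np.sum(_grad_terms(trial)[3] - TV_DELTA))
            if f_trial <= f:
                break
            s *= 0.5
        else:
            break
        out.values = trial
        f = f_trial
    return out


# ---------------------------------------------------------------------------
# full reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ReconHistory:
    resid_rms: list = dc_field(default_factory=list)
    tv: list = dc_field(default_factory=list)
    update_norm: list = dc_field(default_factory=list)


def reconstruct(proj: CorrectedProjection, geom: ScanGeometry,
                shape, voxel_size: float, params: ReconParams,
                origin=None, return_history: bool = False):
    """Alternating ART / TV-descent reconstruction from a masked stack.

    Starts from a zero volume; each pass runs one full ART sweep over the
    valid rays, clamps to non-negative, then applies TV descent scaled by
    the ART update norm.  Stops early when the residual RMS drops below
    ``params.epsilon`` (when given) or plateaus; three consecutive
    materially increasing residuals raise ``ReconDivergenceError``.
    """
    vol = AttenuationVolume.zeros(shape, voxel_size, origin)
    hist = ReconHistory()
    rising = 0
    for it in range(params.n_iterations):
        new_vol, stats = art_pass(vol, proj, geom, params)
        upd = float(np.linalg.norm(new_vol.values - vol.values))
        vol = new_vol
        hist.resid_rms.append(stats["resid_rms"])
        hist.update_norm.append(upd)
        if len(hist.resid_rms) > 1:
            prev = hist.resid_rms[-2]
            if hist.resid_rms[-1] > DIVERGENCE_RTOL * prev:
                rising += 1
                if rising >= 3:
                    raise ReconDivergenceError(hist.resid_rms)
            else:
                rising = 0
        vol = tv_descent(vol, params, upd)
        if params.nonneg:
            np.maximum(vol.values, 0.0, out=vol.values)
        hist.tv.append(tv_value(vol))
        if params.epsilon is not None \
                and stats["resid_rms"] <= params.epsilon:
            break
        if params.epsilon is None and len(hist.resid_rms) > 1:
            prev = hist.resid_rms[-2]
            if prev > 0 and abs(prev - hist.resid_rms[-1]) \
                    < PLATEAU_RTOL * prev:
                break
    if return_history:
        return vol, hist
    return vol
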