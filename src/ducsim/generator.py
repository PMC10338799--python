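"""Contrast-driven delineation-uncertainty contour generator.

Given a CT volume and a clinically accepted binary organ mask, the generator
displaces every boundary voxel of every axial slice along its outward
in-plane normal by a signed magnitude

    D(s) = W(s) * TG(s, s0, w0) * F~ct(s)

built from three ingredients:

* **Random variation** ``W(s)``: i.i.d. draws from the inverse standard
  normal CDF of a uniform probability, i.e. Gaussian(0, (C*sigma)^2).  The
  variation constant ``C`` scales the whole deformation; ``sigma`` is an
  ROI-specific base standard deviation.
* **Localization** ``TG(s, s0, w0)``: a truncated Gaussian over the minimal
  circular index distance along the boundary list ``L`` from an anchor
  ``s0``, so the deformation concentrates in one region instead of being
  scattered around the whole contour.  The anchor is placed where the image
  gradient is lowest (least visual evidence of the true boundary), matched
  across slices by the nearest-neighbour chain algorithm.
* **Contrast response** ``F~ct(s)``: a / (|G| + a) of the Sobel gradient
  magnitude, window-averaged along the contour; close to 1 where the image
  is flat (uncertain boundary, large displacements allowed) and small on
  crisp edges.

Displacement magnitudes are interpreted in millimetres and converted to
voxel units through the in-plane spacing.  The displaced boundary is
repaired (largest simple polygon), rasterized and re-traced so the output is
again a valid binary mask; an optional two-plane Gaussian smoothing pass
(see :mod:`ducsim.smoothing`) finishes the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy import ndimage as ndi
from scipy.stats import norm
from shapely.geometry import MultiPolygon, Polygon

from .contours import (
    SliceSurface,
    extract_slice_surface,
    fill_loop,
    trace_boundary,
)
from .errors import (
    CollapsedContourError,
    DucsimError,
    GeometryError,
    NoSurfaceError,
    SurfaceTooSmallError,
)
from .grids import CTVolume, ROIMask
from .smoothing import SmoothingParams, smooth_mask

__all__ = [
    "DUParams",
    "SurfaceFieldValues",
    "AnchorResult",
    "SIGMA_DEFAULTS",
    "C_SCHEDULE",
    "sobel_gradient",
    "contrast_response",
    "averaged_response",
    "sample_variation",
    "truncated_gaussian",
    "tg_profile",
    "perturbation_anchor",
    "displacement_magnitudes",
    "apply_displacement",
    "generate_du_contour",
]

log = logging.getLogger(__name__)

#: Variation-constant schedule used throughout the evaluation experiments.
C_SCHEDULE = (5, 50, 100, 200, 300)

#: Shipped per-ROI base standard deviations (calibration choices; see docs).
SIGMA_DEFAULTS = {"bladder": 0.02, "prostate": 0.03, "rectum": 0.04, "other": 0.03}


@dataclass
class DUParams:
    """All knobs of the delineation-uncertainty generator.

    Parameters
    ----------
    C
        Positive variation constant; larger C means larger deformations.
    sigma_roi
        ROI-specific base standard deviation multiplying C.  ``None`` picks
        the shipped default for the mask's ``roi_name``.
    a
        Base gradient of the contrast response, HU/mm scale (default 50).
    k
        Half-width of the circular averaging window (default 15, i.e. the
        voxel plus 30 neighbours).
    w0_fraction
        Truncated-Gaussian width as a fraction of the boundary length R
        (default 1/5).
    seed
        RNG seed; per-slice streams are derived from it so results do not
        depend on slice processing order or parallelism.
    smoothing_sigma
        Standard deviation of the two-plane Gaussian smoothing layer.
        The default 25 is the clinical-grid value; small working grids want
        a proportionally smaller sigma.
    smooth
        Whether the smoothing layer runs inside :func:`generate_du_contour`.
    tg_mode
        ``"normalized"`` (default) rescales the truncated Gaussian to peak 1
        so displacement scale is independent of contour length;
        ``"verbatim"`` keeps the 1/(sqrt(2*pi)*w0) prefactor.
    crop_margin
        Bounding-box crop margin in voxels for the gradient/displacement
        work (``None`` disables cropping).  Output is identical either way.
    on_collapse
        Per-slice policy when displacement collapses a contour:
        ``"keep-original"`` (default) leaves that slice unperturbed,
        ``"raise"`` propagates :class:`CollapsedContourError`.
    """

    C: float
    sigma_roi: float | None = None
    a: float = 50.0
    k: int = 15
    w0_fraction: float = 0.2
    seed: int = 0
    smoothing_sigma: float = 25.0
    smooth: bool = True
    tg_mode: str = "normalized"
    crop_margin: int | None = 20
    on_collapse: str = "keep-original"

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.sigma_roi is not None and self.sigma_roi <= 0:
            raise ValueError("sigma_roi must be > 0")
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0 < self.w0_fraction <= 1:
            raise ValueError("w0_fraction must be in (0, 1]")
        if self.tg_mode not in ("normalized", "verbatim"):
            raise ValueError("tg_mode must be 'normalized' or 'verbatim'")

    def sigma_for(self, roi_name: str) -> float:
        if self.sigma_roi is not None:
            return self.sigma_roi
        return SIGMA_DEFAULTS.get(roi_name, SIGMA_DEFAULTS["other"])


@dataclass
class SurfaceFieldValues:
    """Per-boundary-voxel fields of one slice, aligned to ``SliceSurface.L``."""

    grad: np.ndarray      # |G(s)|, HU/mm
    f_ct: np.ndarray      # contrast response a/(|G|+a), in (0, 1]
    f_avg: np.ndarray     # circularly window-averaged response, in (0, 1]
    w: np.ndarray         # random variation draws, Gaussian(0, (C sigma)^2)
    tg: np.ndarray        # localization weights, > 0
    d: np.ndarray         # signed displacement magnitudes (mm)


@dataclass
class AnchorResult:
    """Outcome of the cross-slice anchor search.

    ``chains[r]`` lists, for starting-slice boundary voxel ``r``, the index
    of its nearest-neighbour match in each slice's boundary list; ``s0`` is
    the chain with the smallest mean gradient magnitude.
    """

    s0: int
    chains: np.ndarray          # (R0, n_slices) int
    avg_gradients: np.ndarray   # (R0,) mean |G| along each chain


def sobel_gradient(ct_slice: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    """Sobel gradient-magnitude map of one axial slice, in HU/mm.

    Uses the separable 3x3 Sobel kernels with edge replication at the
    border.  The raw kernel response to a unit-per-voxel ramp is 8, so the
    x/y responses are divided by ``8*dx`` / ``8*dy`` to land on HU/mm
    before combining as sqrt(Gx^2 + Gy^2).
    """
    ct_slice = np.asarray(ct_slice, dtype=float)
    if ct_slice.ndim != 2 or min(ct_slice.shape) < 3:
        raise GeometryError("slice must be 2D and at least 3x3")
    dx, dy = spacing
    gx = ndi.sobel(ct_slice, axis=0, mode="nearest") / (8.0 * dx)
    gy = ndi.sobel(ct_slice, axis=1, mode="nearest") / (8.0 * dy)
    return np.hypot(gx, gy)


def contrast_response(grad_mag, a: float = 50.0):
    """Map gradient magnitude to the contrast response a / (|G| + a).

    Equals 1 on flat image regions and decreases monotonically with |G|,
    reaching 0.5 at |G| = a.  Accepts scalars or arrays.
    """
    if a <= 0:
        raise ValueError("a must be > 0")
    g = np.asarray(grad_mag, dtype=float)
    if np.any(g < 0):
        raise ValueError("gradient magnitude must be >= 0")
    out = a / (g + a)
    return float(out) if np.isscalar(grad_mag) else out


def averaged_response(fct: np.ndarray, k: int = 15) -> np.ndarray:
    """Circular moving mean over the 2k+1 window centred at each index.

    For boundaries shorter than 2k+1, k is clamped to floor((R-1)/2) so the
    window never wraps onto itself.
    """
    fct = np.asarray(fct, dtype=float)
    if fct.size == 0:
        raise ValueError("empty sequence")
    k_eff = min(int(k), (fct.size - 1) // 2)
    if k_eff == 0:
        return fct.copy()
    return ndi.uniform_filter1d(fct, size=2 * k_eff + 1, mode="wrap")


def sample_variation(R: int, C: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Draw R i.i.d. variation values W = norminv(p; 0, C*sigma), p ~ U(0,1).

    Equivalent to Gaussian(0, (C*sigma)^2) draws; expressed through the
    inverse normal CDF of uniform probabilities so that p = 0.5 maps to
    exactly 0.
    """
    if C <= 0 or sigma <= 0:
        raise ValueError("C and sigma must be > 0")
    p = rng.random(int(R))
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0 - 1e-16)
    return norm.ppf(p) * (C * sigma)


def _circular_distance(s, s0: int, R: int):
    d = np.abs(np.asarray(s) - s0)
    return np.minimum(d, R - d)


def truncated_gaussian(s, s0: int, R: int, w0: float):
    """Truncated-Gaussian localization weight over circular index distance.

    TG(s, s0, w0) = 1/(sqrt(2*pi)*w0) * exp(-min(|s-s0|, R-|s-s0|)^2 / (2*w0^2))

    with peak value 1/(sqrt(2*pi)*w0) at s = s0 and circular symmetry
    TG(s0 + d) = TG(s0 - d mod R).
    """
    if w0 <= 0:
        raise ValueError("w0 must be > 0")
    s_arr = np.asarray(s)
    if np.any(s_arr < 0) or np.any(s_arr >= R) or not 0 <= s0 < R:
        raise ValueError("indices must lie in [0, R)")
    d = _circular_distance(s_arr, s0, R)
    out = np.exp(-(d.astype(float) ** 2) / (2.0 * w0**2)) / (np.sqrt(2.0 * np.pi) * w0)
    return float(out) if np.isscalar(s) else out


def tg_profile(R: int, s0: int, w0: float, mode: str = "normalized") -> np.ndarray:
    """Localization weights for all s in [0, R); optionally peak-normalized.

    ``"verbatim"`` keeps the closed form of :func:`truncated_gaussian`;
    ``"normalized"`` divides by the peak so TG(s0) = 1 and displacement
    scale decouples from contour length.
    """
    tg = truncated_gaussian(np.arange(R), s0, R, w0)
    if mode == "normalized":
        tg = tg / (1.0 / (np.sqrt(2.0 * np.pi) * w0))
    elif mode != "verbatim":
        raise ValueError("mode must be 'normalized' or 'verbatim'")
    return tg


def _gradient_cache(ct: CTVolume):
    dx, dy, _ = ct.spacing
    cache: dict[int, np.ndarray] = {}

    def get(z: int) -> np.ndarray:
        if z not in cache:
            cache[z] = sobel_gradient(ct.axial_slice(z), (dx, dy))
        return cache[z]

    return get


def perturbation_anchor(ct: CTVolume, surfaces: list[SliceSurface]) -> AnchorResult:
    """Find the low-contrast anchor voxel and its cross-slice chains.

    Starting from the first slice, each boundary voxel r is matched to its
    nearest (Euclidean, voxel units) boundary voxel on the next slice,
    repeatedly, producing a chain with one voxel per slice.  The chain with
    the smallest mean Sobel gradient magnitude defines the anchor ``s0``
    (ties broken toward the smaller starting index).
    """
    if not surfaces:
        raise NoSurfaceError("no surfaces supplied")
    grad_at = _gradient_cache(ct)

    R0 = surfaces[0].R
    n_slices = len(surfaces)
    chains = np.empty((R0, n_slices), dtype=int)
    chains[:, 0] = np.arange(R0)
    # Per-slice-pair nearest-neighbour index map, shared by all chains.
    for i in range(n_slices - 1):
        a = surfaces[i].L.astype(float)
        b = surfaces[i + 1].L.astype(float)
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        nxt = np.argmin(d2, axis=1)  # ties -> smallest index
        chains[:, i + 1] = nxt[chains[:, i]]

    sums = np.zeros(R0)
    for i, surf in enumerate(surfaces):
        g = grad_at(surf.z)
        pts = surf.L[chains[:, i]]
        sums += g[pts[:, 0], pts[:, 1]]
    avg = sums / n_slices
    s0 = int(np.argmin(avg))  # argmin ties -> smallest index
    return AnchorResult(s0=s0, chains=chains, avg_gradients=avg)


def displacement_magnitudes(
    surface: SliceSurface,
    grad_slice: np.ndarray,
    params: DUParams,
    s0: int,
    rng: np.random.Generator,
    sigma: float | None = None,
) -> SurfaceFieldValues:
    """Per-voxel signed displacement magnitudes D = W * TG * F~ct for a slice.

    ``grad_slice`` is the Sobel gradient-magnitude map of the matching CT
    slice (HU/mm); ``s0`` the anchor index mapped into this slice's list.
    All intermediate sequences are returned for inspection.
    """
    R = surface.R
    sigma = params.sigma_roi if sigma is None else sigma
    if sigma is None:
        sigma = SIGMA_DEFAULTS["other"]
    g = grad_slice[surface.L[:, 0], surface.L[:, 1]]
    f_ct = contrast_response(g, params.a)
    f_avg = averaged_response(f_ct, params.k)
    w = sample_variation(R, params.C, sigma, rng)
    w0 = max(params.w0_fraction * R, 1e-9)
    tg = tg_profile(R, int(s0), w0, mode=params.tg_mode)
    d = w * tg * f_avg
    return SurfaceFieldValues(grad=g, f_ct=f_ct, f_avg=f_avg, w=w, tg=tg, d=d)


def _outward_normals(loop: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """Unit outward normals (mm frame) of a CCW closed voxel loop."""
    pts = loop.astype(float) * np.asarray(spacing)[None, :]
    tang = np.roll(pts, -2, axis=0) - np.roll(pts, 2, axis=0)
    norms = np.linalg.norm(tang, axis=1)
    short = norms < 1e-12
    if short.any():  # fall back to +/-1 neighbours on degenerate tangents
        tang1 = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
        tang[short] = tang1[short]
        norms = np.linalg.norm(tang, axis=1)
        norms[norms < 1e-12] = 1.0
    tang /= norms[:, None]
    # CCW loop: rotating the tangent by -90 deg points away from the interior.
    return np.column_stack([tang[:, 1], -tang[:, 0]])


def _largest_simple_polygon(coords: np.ndarray) -> Polygon | None:
    poly = Polygon(coords)
    if not poly.is_valid:
        poly = shapely.make_valid(poly)
    if isinstance(poly, (MultiPolygon,)):
        parts = list(poly.geoms)
    elif isinstance(poly, Polygon):
        parts = [poly]
    else:  # GeometryCollection etc.
        parts = [g for g in getattr(poly, "geoms", []) if isinstance(g, Polygon)]
    parts = [p for p in parts if p.area > 0]
    if not parts:
        return None
    return max(parts, key=lambda p: p.area)


def apply_displacement(
    surface: SliceSurface,
    magnitudes: np.ndarray,
    spacing: tuple[float, float],
    slice_shape: tuple[int, int],
) -> SliceSurface:
    """Move each boundary voxel along its outward normal and re-trace.

    Positive magnitudes (mm) expand the contour, negative ones contract it.
    The displaced points are treated as a polygon in continuous (x, y),
    repaired for self-intersection by keeping the largest simple
    sub-polygon, rasterized, and re-traced into a valid boundary list.
    """
    mags = np.asarray(magnitudes, dtype=float)
    if mags.shape != (surface.R,):
        raise ValueError("magnitudes must have length R")
    if np.all(mags == 0):
        return SliceSurface(z=surface.z, L=surface.L.copy())

    normals = _outward_normals(surface.L, spacing)
    pts_mm = surface.L.astype(float) * np.asarray(spacing)[None, :]
    disp_mm = pts_mm + mags[:, None] * normals
    disp_vox = disp_mm / np.asarray(spacing)[None, :]
    disp_vox[:, 0] = np.clip(disp_vox[:, 0], 0, slice_shape[0] - 1)
    disp_vox[:, 1] = np.clip(disp_vox[:, 1], 0, slice_shape[1] - 1)

    poly = _largest_simple_polygon(disp_vox)
    if poly is None or poly.area < 1.0:
        raise CollapsedContourError(
            f"slice {surface.z}: displaced contour interior below one voxel"
        )
    exterior = np.asarray(poly.exterior.coords)
    fg = fill_loop(exterior, slice_shape)
    # Rasterization of a thin polygon can split; keep the largest piece.
    labels, n = ndi.label(fg, structure=np.ones((3, 3), bool))
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndi.binary_fill_holes(fg)
    loop = trace_boundary(fg)
    if len(loop) < 4:
        raise CollapsedContourError(f"slice {surface.z}: re-traced contour degenerate")
    return SliceSurface(z=surface.z, L=loop)


def _crop_box(mask: ROIMask, margin: int):
    idx = np.nonzero(mask.voxels)
    lo = [max(0, int(i.min()) - margin) for i in idx[:2]]
    hi = [min(n, int(i.max()) + margin + 1) for i, n in zip(idx[:2], mask.shape[:2])]
    return (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(None))


def generate_du_contour(ct: CTVolume, mask: ROIMask, params: DUParams) -> ROIMask:
    """Run the full generator pipeline on one ROI and return the new mask.

    anchor search -> per-slice displacement fields -> normal displacement ->
    polygon repair & rasterization -> optional two-plane smoothing.
    Deterministic for identical inputs and params (including seed); the
    bounding-box cropping optimization never changes the output.
    """
    mask.check_alignment(ct)
    mask.validate()
    if mask.is_empty():
        raise NoSurfaceError("mask is empty")
    sigma = params.sigma_for(mask.roi_name)

    if params.crop_margin is not None:
        box = _crop_box(mask, int(params.crop_margin))
        ct_w = CTVolume(ct.intensities[box], ct.spacing)
        mask_w = ROIMask(mask.voxels[box], mask.spacing, mask.roi_name)
    else:
        box = None
        ct_w, mask_w = ct, mask

    zs = mask_w.nonempty_slices()
    surfaces, passthrough = [], []
    for z in zs:
        try:
            surfaces.append(extract_slice_surface(mask_w, int(z)))
        except SurfaceTooSmallError:
            passthrough.append(int(z))

    out = np.zeros(mask_w.shape, dtype=bool)
    for z in passthrough:
        out[:, :, z] = mask_w.voxels[:, :, z]

    if surfaces:
        anchor = perturbation_anchor(ct_w, surfaces)
        grad_at = _gradient_cache(ct_w)
        dx, dy, _ = ct.spacing
        # One derived, order-independent RNG stream per slice.
        children = np.random.SeedSequence(params.seed).spawn(len(surfaces))
        for i, surf in enumerate(surfaces):
            rng = np.random.default_rng(children[i])
            s0_z = int(anchor.chains[anchor.s0, i])
            fields = displacement_magnitudes(
                surf, grad_at(surf.z), params, s0_z, rng, sigma=sigma
            )
            try:
                new_surf = apply_displacement(
                    surf, fields.d, (dx, dy), mask_w.shape[:2]
                )
            except CollapsedContourError:
                if params.on_collapse == "raise":
                    raise
                log.warning("slice %d collapsed at C=%g; keeping original", surf.z, params.C)
                new_surf = surf
            out[:, :, surf.z] = fill_loop(new_surf.L, mask_w.shape[:2])
            log.debug(
                "slice z=%d R=%d s0=%d mean|D|=%.3f mm",
                surf.z, surf.R, s0_z, float(np.mean(np.abs(fields.d))),
            )

    if box is not None:
        full = np.zeros(mask.shape, dtype=bool)
        full[box] = out
        out = full
    result = ROIMask(out, mask.spacing, mask.roi_name)
    if params.smooth:
        result = smooth_mask(result, SmoothingParams(sigma=params.smoothing_sigma))
    return result
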