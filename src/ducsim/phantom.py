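"""Seeded lower-abdomen CT phantoms and simulated review datasets.

Every other module is testable without patient data: :func:`make_phantom`
builds a small CT-like volume (soft-tissue background, additive Gaussian
noise) containing three roughly convex organs with exact ground-truth
masks — a bladder-like high-contrast ellipsoid, a prostate-like
low-contrast ellipsoid and a rectum-like bent tube.  Organ edges are
sigmoidal in signed distance with a configurable sharpness in HU/mm, and a
low-contrast arc can be carved into any organ's edge to give the anchor
search a known target.  :func:`simulate_reviews` stands in for the clinical
review sessions, drawing minor/major editing labels from a documented
logistic truth model and back-filling consistent CSC/RSC score pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import expit

from .errors import OverlappingOrgansError
from .grids import CTVolume, ROIMask

__all__ = [
    "OrganSpec",
    "LowContrastArc",
    "PhantomSpec",
    "pelvis_spec",
    "make_phantom",
    "simulate_reviews",
    "REVIEW_TRUTH_DEFAULT",
]

#: Smoothing sigma (pixels) calibrated for the default 96x96x40 phantom grid:
#: large enough to remove slice-to-slice roughness, small enough to keep the
#: small organs' volume change under ~10%.  The clinical-grid default of 25
#: belongs to full-resolution CT.
WORKING_SMOOTHING_SIGMA = 1.5

#: Default logistic truth model P(minor) = expit(b0 + bC*C + bdsc*surface_dsc),
#: chosen so the minor-editing fraction declines across the C schedule the way
#: clinical reviewers grade increasingly deformed contours.
REVIEW_TRUTH_DEFAULT = {"intercept": -4.0, "C": -0.05, "surface_dsc": 8.0}


@dataclass
class OrganSpec:
    """One phantom organ.

    ``family`` is ``"ellipsoid"`` (center + radii, mm) or ``"tube"`` (a bent
    tube whose in-plane centre follows a sinusoidal path along z).
    ``edge_sharpness`` is the peak intensity slope across the organ edge in
    HU/mm; the edge is a logistic sigmoid in signed distance.
    """

    name: str
    family: str = "ellipsoid"
    center: tuple = (0.0, 0.0, 0.0)   # mm
    radii: tuple = (10.0, 10.0, 10.0)  # mm (tube: radii[0] = tube radius)
    interior_hu: float = 100.0
    edge_sharpness: float = 50.0       # HU/mm
    z_range: tuple | None = None       # tube only: (z_lo_mm, z_hi_mm)
    bend_amplitude: float = 0.0        # tube only: mm of in-plane x-sway
    bend_period: float = 60.0          # tube only: mm along z per sway cycle

    def __post_init__(self):
        if self.edge_sharpness <= 0:
            raise ValueError("edge_sharpness must be > 0")


@dataclass
class LowContrastArc:
    """Locally reduced edge contrast over an angular range of one organ.

    Angles are radians of atan2(y - cy, x - cx) in the axial plane; within
    [theta_lo, theta_hi] the organ's HU step is multiplied by ``factor``
    (cosine-tapered over ``taper`` radians at the edges of the range).
    """

    organ: str
    theta_lo: float
    theta_hi: float
    factor: float = 0.2
    taper: float = 0.3


@dataclass
class PhantomSpec:
    shape: tuple = (96, 96, 40)
    spacing: tuple = (1.0, 1.0, 2.5)
    background_hu: float = 30.0
    noise_sd: float = 5.0
    organs: tuple = ()
    low_contrast_arcs: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def pelvis_spec(seed: int = 0, noise_sd: float = 5.0, arcs=()) -> PhantomSpec:
    """Default lower-abdomen preset on a 96x96x40 grid at 1x1x2.5 mm.

    Bladder: high-contrast ellipsoid (~300 HU step); prostate: low-contrast
    ellipsoid (~40 HU step); rectum: bent elongated tube.
    """
    organs = (
        OrganSpec(
            name="bladder", family="ellipsoid", center=(48.0, 32.0, 55.0),
            radii=(17.0, 14.0, 20.0), interior_hu=330.0, edge_sharpness=120.0,
        ),
        OrganSpec(
            name="prostate", family="ellipsoid", center=(48.0, 62.0, 35.0),
            radii=(13.0, 11.0, 14.0), interior_hu=70.0, edge_sharpness=12.0,
        ),
        OrganSpec(
            name="rectum", family="tube", center=(70.0, 80.0, 0.0),
            radii=(7.0, 7.0, 0.0), interior_hu=-20.0, edge_sharpness=25.0,
            z_range=(10.0, 85.0), bend_amplitude=6.0, bend_period=75.0,
        ),
    )
    return PhantomSpec(organs=organs, low_contrast_arcs=tuple(arcs),
                       noise_sd=noise_sd, seed=seed)


def _grids_mm(spec: PhantomSpec):
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    z = np.arange(nz) * dz
    return np.meshgrid(x, y, z, indexing="ij")


def _organ_mask(organ: OrganSpec, spec: PhantomSpec, xx, yy, zz) -> np.ndarray:
    if organ.family == "ellipsoid":
        cx, cy, cz = organ.center
        rx, ry, rz = organ.radii
        f = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2
        return f <= 1.0
    if organ.family == "tube":
        cx, cy, _ = organ.center
        r = organ.radii[0]
        z_lo, z_hi = organ.z_range if organ.z_range else (zz.min(), zz.max())
        path_x = cx + organ.bend_amplitude * np.sin(2 * np.pi * zz / organ.bend_period)
        in_plane = np.hypot(xx - path_x, yy - cy) <= r
        return in_plane & (zz >= z_lo) & (zz <= z_hi)
    raise ValueError(f"unknown organ family {organ.family!r}")


def _signed_distance_mm(mask: np.ndarray, spacing) -> np.ndarray:
    """Positive outside the mask, negative inside, in mm (via EDTs)."""
    d_out = ndi.distance_transform_edt(~mask, sampling=spacing)
    d_in = ndi.distance_transform_edt(mask, sampling=spacing)
    return d_out - d_in


def make_phantom(spec: PhantomSpec) -> tuple[CTVolume, dict[str, ROIMask]]:
    """Build the phantom volume and its exact ground-truth masks.

    The intensity is background + per-organ HU steps shaped as logistic
    sigmoids of signed distance (slope = edge_sharpness at the boundary),
    plus Gaussian noise; masks are the exact geometric level sets,
    independent of noise.  Deterministic per seed.  Raises
    :class:`OverlappingOrgansError` when organ masks intersect.
    """
    xx, yy, zz = _grids_mm(spec)
    vol = np.full(spec.shape, float(spec.background_hu))
    masks: dict[str, ROIMask] = {}
    arcs_by_organ: dict[str, list[LowContrastArc]] = {}
    for arc in spec.low_contrast_arcs:
        arcs_by_organ.setdefault(arc.organ, []).append(arc)

    occupied = np.zeros(spec.shape, dtype=bool)
    for organ in spec.organs:
        mask = _organ_mask(organ, spec, xx, yy, zz)
        if (mask & occupied).any():
            raise OverlappingOrgansError(f"organ {organ.name!r} overlaps another organ")
        occupied |= mask
        masks[organ.name] = ROIMask(mask, spec.spacing, roi_name=organ.name)

        delta = organ.interior_hu - spec.background_hu
        # logistic edge: slope at the boundary is |delta|/(4 w) = sharpness
        w = max(abs(delta) / (4.0 * organ.edge_sharpness), 1e-6)
        sd = _signed_distance_mm(mask, spec.spacing)
        step = expit(-sd / w)

        factor = np.ones(spec.shape)
        for arc in arcs_by_organ.get(organ.name, []):
            cx, cy = organ.center[0], organ.center[1]
            theta = np.arctan2(yy - cy, xx - cx)
            mid = (arc.theta_lo + arc.theta_hi) / 2.0
            half = (arc.theta_hi - arc.theta_lo) / 2.0
            dtheta = np.abs(np.angle(np.exp(1j * (theta - mid))))
            taper = np.clip((half + arc.taper - dtheta) / arc.taper, 0.0, 1.0)
            weight = np.where(dtheta <= half, 1.0, 0.5 - 0.5 * np.cos(np.pi * taper))
            factor = np.minimum(factor, 1.0 - (1.0 - arc.factor) * weight)
        vol += delta * step * factor

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return CTVolume(vol, spec.spacing), masks


def _scores_for_label(label: int, rng: np.random.Generator) -> tuple[int, int]:
    band = {0: (5, 5), 1: (3, 4), 2: (1, 2)}[label]
    return int(rng.integers(band[0], band[1] + 1)), int(rng.integers(band[0], band[1] + 1))


def simulate_reviews(
    features: pd.DataFrame,
    truth: dict | None = None,
    seed: int = 0,
    reviewer_agreement: float = 0.925,
) -> pd.DataFrame:
    """Simulate a two-reviewer scoring session over generated contours.

    ``features`` needs columns ``subject``, ``roi``, ``C``, ``surface_dsc``
    (``hd95`` passed through when present).  A true editing label (1 minor /
    2 major) is drawn per row from the logistic truth model
    ``P(minor) = expit(b0 + bC*C + bdsc*surface_dsc)``; each reviewer
    reports the true label with probability ``reviewer_agreement`` and the
    other label otherwise, then CSC/RSC pairs are drawn inside that label's
    score band, so ``editing_level(csc_r, rsc_r)`` always reproduces the
    reviewer's label.

    Returns a copy of ``features`` with per-reviewer scores/levels, the
    consensus ``level``, and the latent ``true_level``.
    """
    truth = dict(REVIEW_TRUTH_DEFAULT if truth is None else truth)
    rng = np.random.default_rng(seed)
    df = features.copy().reset_index(drop=True)
    eta = (
        truth["intercept"]
        + truth["C"] * df["C"].to_numpy(float)
        + truth["surface_dsc"] * df["surface_dsc"].to_numpy(float)
    )
    p_minor = expit(eta)
    true_level = np.where(rng.random(len(df)) < p_minor, 1, 2)

    rows = []
    for lab in true_level:
        rec = {}
        for r in (1, 2):
            rep = int(lab) if rng.random() < reviewer_agreement else 3 - int(lab)
            csc, rsc = _scores_for_label(rep, rng)
            rec[f"csc_r{r}"], rec[f"rsc_r{r}"] = csc, rsc
            rec[f"level_r{r}"] = rep
        rows.append(rec)
    scores = pd.DataFrame(rows)
    df = pd.concat([df, scores], axis=1)
    df["true_level"] = true_level
    from .filtering import consensus_level

    df["level"] = [
        consensus_level([(a, b), (c, d)])
        for a, b, c, d in zip(df.csc_r1, df.rsc_r1, df.csc_r2, df.rsc_r2)
    ]
    return df
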