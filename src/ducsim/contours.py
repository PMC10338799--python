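"""Conversion between binary masks and ordered per-slice boundary voxel lists.

The perturbation model indexes every quantity by a position ``s`` along a
closed, circular list ``L`` of boundary voxels of one axial slice.  This
module builds that list (Moore-neighbour tracing, counter-clockwise, starting
at the lexicographically smallest boundary voxel) and rebuilds filled masks
from such lists.

Conventions
-----------
* Slice arrays are indexed ``[x, y]``; a loop is an ``(R, 2)`` integer array
  of ``(x, y)`` voxel indices.
* Consecutive loop entries are 8-neighbours and the loop is closed (the last
  entry is an 8-neighbour of the first).
* Orientation is counter-clockwise in the (x, y) frame (positive shoelace
  area), identical for every slice of an ROI.
* Interior holes are filled before tracing: the model deforms only the outer
  boundary, and a single circular list cannot represent multiple loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as _sk_polygon

from .errors import (
    DisconnectedSliceError,
    NoSurfaceError,
    SurfaceTooSmallError,
)
from .grids import ROIMask

__all__ = [
    "SliceSurface",
    "extract_slice_surface",
    "surfaces_for_roi",
    "mask_from_surfaces",
    "trace_boundary",
    "fill_loop",
    "boundary_voxels_2d",
]

_STRUCT_8 = np.ones((3, 3), dtype=bool)

# Moore neighbourhood in clockwise order for y-axis-up (x, y) coordinates:
# E, SE, S, SW, W, NW, N, NE.  Scanning this ring clockwise from the
# backtrack direction keeps the exterior background on the walker's left.
_DIRS = np.array(
    [(1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1)],
    dtype=int,
)
_DIR_INDEX = {tuple(d): i for i, d in enumerate(_DIRS)}


@dataclass
class SliceSurface:
    """Ordered circular boundary voxel list of one axial slice of one ROI.

    ``L`` is an ``(R, 2)`` int array of (x, y) indices; ``z`` the slice index.
    """

    z: int
    L: np.ndarray

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=int)
        if self.L.ndim != 2 or self.L.shape[1] != 2:
            raise ValueError("L must be an (R, 2) array of (x, y) indices")

    @property
    def R(self) -> int:
        return len(self.L)

    def signed_area(self) -> float:
        x, y = self.L[:, 0].astype(float), self.L[:, 1].astype(float)
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def boundary_voxels_2d(fg: np.ndarray) -> np.ndarray:
    """Boolean map of foreground voxels with >=1 background 4-neighbour.

    Out-of-array positions count as background.  This is the brute-force
    boundary definition the traced list is checked against.
    """
    fg = np.asarray(fg, dtype=bool)
    padded = np.pad(fg, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    return fg & ~interior


def _is_fg(fg: np.ndarray, p) -> bool:
    x, y = p
    return 0 <= x < fg.shape[0] and 0 <= y < fg.shape[1] and bool(fg[x, y])


def trace_boundary(fg: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a single connected foreground region.

    Moore-neighbour tracing with Jacob's stopping criterion.  The walk starts
    at the lexicographically smallest (x, y) foreground voxel — necessarily a
    boundary voxel — and the returned loop is normalized to counter-clockwise
    orientation with that voxel first.  Deterministic for a given input.
    """
    xs, ys = np.nonzero(fg)
    if xs.size == 0:
        raise NoSurfaceError("empty slice: nothing to trace")
    k0 = np.lexsort((ys, xs))[0]
    start = (int(xs[k0]), int(ys[k0]))
    if xs.size == 1:
        return np.array([start], dtype=int)

    # The voxel just below the lexicographic minimum is background.
    start_back = (start[0], start[1] - 1)
    loop = [start]
    cur, back = start, start_back
    # The walk is a deterministic map on (current, backtrack) states, so it
    # must eventually cycle; stop at the first repeated state and keep the
    # cycle (the pre-cycle tail, if any, is re-entered and discarded).
    seen = {(cur, back): 0}
    max_steps = 8 * (xs.size + 4) + 16
    for _ in range(max_steps):
        d = (back[0] - cur[0], back[1] - cur[1])
        i = _DIR_INDEX[d]
        nxt = None
        for k in range(1, 9):
            dd = _DIRS[(i + k) % 8]
            cand = (cur[0] + int(dd[0]), cur[1] + int(dd[1]))
            if _is_fg(fg, cand):
                nxt = cand
                prev = _DIRS[(i + k - 1) % 8]
                new_back = (cur[0] + int(prev[0]), cur[1] + int(prev[1]))
                break
        if nxt is None:  # isolated voxel reached through a spur; shouldn't happen
            break
        cur, back = nxt, new_back
        state = (cur, back)
        if state in seen:
            loop = loop[seen[state]:]
            break
        seen[state] = len(loop)
        loop.append(cur)
    loop = np.array(loop, dtype=int)

    # Canonical start: rotate the cycle so the lexicographically smallest
    # (x, y) member comes first (it may differ from `start` if a pre-cycle
    # tail was discarded).
    k0 = np.lexsort((loop[:, 1], loop[:, 0]))[0]
    loop = np.roll(loop, -k0, axis=0)

    # Normalize to counter-clockwise (positive shoelace area), keep start first.
    x, y = loop[:, 0].astype(float), loop[:, 1].astype(float)
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area < 0:
        loop = np.vstack([loop[:1], loop[1:][::-1]])
    return loop


def extract_slice_surface(
    mask: ROIMask,
    z: int,
    *,
    fill_holes: bool = True,
    on_multiple: str = "error",
) -> SliceSurface:
    """Trace the ordered closed boundary of one axial slice of ``mask``.

    Parameters
    ----------
    on_multiple
        ``"error"`` (default) raises :class:`DisconnectedSliceError` when the
        slice holds several 8-connected components; ``"largest"`` keeps only
        the largest component.
    """
    fg = mask.voxels[:, :, z]
    if not fg.any():
        raise NoSurfaceError(f"slice {z} has no foreground")
    labels, n = ndi.label(fg, structure=_STRUCT_8)
    if n > 1:
        if on_multiple == "largest":
            sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
            fg = labels == (1 + int(np.argmax(sizes)))
        else:
            raise DisconnectedSliceError([int(z)])
    if fill_holes:
        fg = ndi.binary_fill_holes(fg)
    loop = trace_boundary(fg)
    if len(loop) < 4:
        raise SurfaceTooSmallError(
            f"slice {z}: boundary has only {len(loop)} voxels (< 4)"
        )
    return SliceSurface(z=int(z), L=loop)


def surfaces_for_roi(
    mask: ROIMask,
    *,
    fill_holes: bool = True,
    on_multiple: str = "error",
    on_too_small: str = "error",
) -> list[SliceSurface]:
    """One :class:`SliceSurface` per nonempty axial slice, ordered by z.

    Disconnected slices are collected and reported together in a single
    :class:`DisconnectedSliceError`.  Slices whose boundary is shorter than
    4 voxels (e.g. single-voxel pole caps) raise by default;
    ``on_too_small="skip"`` drops them instead.
    """
    zs = mask.nonempty_slices()
    if zs.size == 0:
        raise NoSurfaceError("mask is empty")
    surfaces, bad = [], []
    for z in zs:
        try:
            surfaces.append(
                extract_slice_surface(mask, int(z), fill_holes=fill_holes, on_multiple=on_multiple)
            )
        except DisconnectedSliceError:
            bad.append(int(z))
        except SurfaceTooSmallError:
            if on_too_small != "skip":
                raise
    if bad:
        raise DisconnectedSliceError(bad)
    return surfaces


def fill_loop(loop: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed voxel loop into a filled 2D boolean mask.

    The polygon through the loop's voxel centres is filled and the (rounded,
    clipped) vertices themselves are included, so integer loops produced by
    :func:`trace_boundary` round-trip exactly.
    """
    loop = np.asarray(loop, dtype=float)
    out = np.zeros(shape, dtype=bool)
    rr, cc = _sk_polygon(loop[:, 0], loop[:, 1], shape=shape)
    out[rr, cc] = True
    vx = np.clip(np.rint(loop[:, 0]).astype(int), 0, shape[0] - 1)
    vy = np.clip(np.rint(loop[:, 1]).astype(int), 0, shape[1] - 1)
    out[vx, vy] = True
    return out


def mask_from_surfaces(
    surfaces: list[SliceSurface],
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    roi_name: str = "other",
) -> ROIMask:
    """Rebuild a filled binary mask from per-slice boundary loops.

    Inverse of :func:`surfaces_for_roi` for masks that satisfy the ROI
    contract (one simply connected component per slice).
    """
    voxels = np.zeros(shape, dtype=bool)
    for surf in surfaces:
        voxels[:, :, surf.z] = fill_loop(surf.L, shape[:2])
    return ROIMask(voxels, spacing, roi_name)
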