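import numpy as np
import pytest
from scipy import ndimage as ndi

import ducsim as ds
from ducsim.grids import ROIMask


@pytest.fixture(scope="session")
def pelvis():
    """Default lower-abdomen phantom shared by slow integration tests."""
    ct, masks = ds.make_phantom(ds.pelvis_spec(seed=1))
    return ct, masks


def random_blob(seed: int, shape=(48, 48, 20), spacing=(1.0, 1.0, 2.5),
                smooth=(6.0, 6.0, 2.5), frac=80) -> ROIMask:
    """Seeded smooth random blob satisfying the ROI mask contract.

    Retries with derived seeds until the blob is thick enough (>= 4 slices,
    >= 1000 voxels) to survive the smoothing experiments; deterministic per
    seed.
    """
    for attempt in range(20):
        m = _blob_once(seed * 1009 + attempt, shape, spacing, smooth, frac)
        if m.voxels.sum() >= 1000 and m.nonempty_slices().size >= 4:
            return m
    raise RuntimeError("could not build a suitable blob")


def _blob_once(seed, shape, spacing, smooth, frac) -> ROIMask:
    rng = np.random.default_rng(seed)
    noise = ndi.gaussian_filter(rng.normal(size=shape), smooth)
    m = noise > np.percentile(noise, frac)
    labels, n = ndi.label(m)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        m = labels == (1 + int(np.argmax(sizes)))
    m = ndi.binary_fill_holes(m)
    # keep only z-slices whose in-plane component count is 1 and drop tiny caps
    keep = np.zeros(shape[2], dtype=bool)
    for z in range(shape[2]):
        sl = m[:, :, z]
        if sl.sum() < 9:
            continue
        _, k = ndi.label(sl, structure=np.ones((3, 3), bool))
        keep[z] = k == 1
    # restrict to the longest contiguous kept run so the z-range is contiguous
    best, cur, best_span, span = 0, 0, (0, 0), (0, 0)
    i = 0
    while i < shape[2]:
        if keep[i]:
            j = i
            while j < shape[2] and keep[j]:
                j += 1
            if j - i > best:
                best, best_span = j - i, (i, j)
            i = j
        else:
            i += 1
    out = np.zeros(shape, dtype=bool)
    lo, hi = best_span
    out[:, :, lo:hi] = m[:, :, lo:hi]
    return ROIMask(out, spacing)
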