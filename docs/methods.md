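# Methods

This note documents the model implemented by `ducsim`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not establish.

## Model and assumptions

The simulator treats delineation uncertainty as a boundary-displacement
process on 2D axial slices, mirroring how clinicians contour slice by
slice.  Assumptions baked into the data model:

* every axial slice of an ROI holds exactly one connected foreground
  component, and nonempty slices form one contiguous z-range;
* only the outer boundary matters — interior holes are filled before
  tracing, because a single circular voxel list cannot represent multiple
  loops;
* voxel thickness is fixed, so displacement vectors live in the axial
  plane only.

Per slice, the boundary is traced into an ordered, counter-clockwise
circular list `L` (Moore-neighbour tracing; start voxel = lexicographically
smallest boundary voxel; orientation and start are normalized so the trace
is deterministic).  Each boundary voxel `s` moves along its outward
in-plane normal (estimated from the ±2-neighbour tangent of the
counter-clockwise loop) by `D(s) = W(s) · TG(s, s0, w0) · F̃ct(s)`,
interpreted in millimetres and converted to voxels through the in-plane
spacing.

The anchor `s0` is found once per ROI: starting-slice boundary voxels are
chained slice-to-slice by nearest Euclidean matching, the mean Sobel
gradient magnitude is averaged along each chain, and the chain with the
smallest mean (ties → smallest index) becomes the anchor; its chain maps
`s0` into every other slice's list, which is how the localization term
carries cross-slice information.

After displacement the points form a polygon in continuous (x, y); it is
repaired for self-intersection by keeping the largest simple sub-polygon
(shapely `make_valid`), rasterized (polygon fill plus rounded vertices, so
zero displacement is exactly the identity), re-traced, and the largest
8-connected component kept.

## Parameters

| name | meaning | default | units |
| --- | --- | --- | --- |
| `C` | variation constant; schedule {5, 50, 100, 200, 300} | — | dimensionless |
| `sigma_roi` | ROI base SD multiplying C | bladder 0.02, prostate 0.03, rectum 0.04 | mm per unit C·W |
| `a` | base gradient of the contrast response | 50 | HU/mm |
| `k` | half-width of the circular averaging window | 15 (31-voxel window) | voxels |
| `w0_fraction` | truncated-Gaussian width as a fraction of R | 1/5 | — |
| `smoothing_sigma` | Gaussian SD of the smoothing layer | 25 (clinical grid); 1.5 on the phantom grid | pixels |
| `threshold` | re-binarization level after blurring | 0.5 | — |
| `crop_margin` | bounding-box crop for the gradient work | 20 | voxels |

`a = 50` balances sensitivity: much smaller values saturate at very low
gradients, much larger ones stop discriminating contrast levels at all.

**Truncated-Gaussian normalization.**  The closed form
`TG = 1/(√(2π)w0)·exp(−d²/2w0²)` ties the displacement scale to the
contour length: with `w0 = R/5` and a typical `R ≈ 100`, the peak weight is
≈ 0.02, which would make even `C = 300` deformations sub-voxel at any
plausible `sigma_roi`.  The pipeline therefore uses the peak-normalized
profile `exp(−d²/2w0²)` by default (`tg_mode="normalized"`), keeping the
shape of the localization while decoupling its scale from `R`; the
verbatim form remains available (`tg_mode="verbatim"`) and is what the
`truncated_gaussian` function computes.  With normalized TG the shipped
`sigma_roi` values put typical near-anchor displacements around 1–3 mm at
`C` = 50–100, the range a reviewer would call minor editing, and several
millimetres at `C ≥ 200`.

**Smoothing sigma.**  σ = 25 pixels is the clinical full-resolution-grid
value and remains the dataclass default, but it scales with the working
grid: on the 96×96×40 phantom (organ radii 7–17 voxels) a 3σ = 75-voxel
kernel would erase the organs outright.  Phantom-scale experiments use
`phantom.WORKING_SMOOTHING_SIGMA = 1.5`, chosen so the blur removes
slice-to-slice roughness while changing organ volume by at most ~10 %
(measured: bladder 5.9 %, prostate 9.7 %, rectum 10.1 %).

## Randomness and determinism

All draws flow from a single seed through `numpy` `SeedSequence` spawning:
one independent stream per slice (so slice-level parallelism cannot change
results) and, in the batch pipeline, one derived seed per
(ROI, C, replicate) item fixed before any worker starts (so thread-count
changes nothing).  `W` is drawn as `Φ⁻¹(p)` of uniform probabilities, which
makes `p = 0.5 → W = 0` exact.  The bounding-box crop (margin 20 voxels ≥
both the Sobel stencil and the averaging window) is verified in tests to
change no output voxel; smoothing always runs on the full grid for the
same reason.

## Degenerate inputs and failure policy

* Slices whose boundary has fewer than 4 voxels (single-voxel pole caps of
  an ellipsoid) cannot be deformed; the generator copies them through
  unchanged rather than failing the ROI.
* If displacement collapses a slice's interior below one voxel, the
  default policy keeps that slice's original contour (logged); a strict
  `on_collapse="raise"` mode propagates the error.
* Disconnected slices are rejected with the offending slice indices; an
  opt-in mode keeps the largest component.
* A smoothing pass that empties a nonempty mask raises rather than
  silently returning nothing.

## Metrics

Boundaries are foreground voxels with a background 6-neighbour, at voxel
centres; distances come from physical-space Euclidean distance transforms,
so anisotropic spacing is honoured.  Surface DSC at tolerance τ is the
symmetric overlap `(|S_a within τ of S_b| + |S_b within τ of S_a|) /
(|S_a| + |S_b|)`; several surface-DSC variants exist in the literature and
this symmetric voxel-centre form is the one implemented.  HD95 defaults to
the 95th percentile (linear interpolation) of the two directional distance
sets pooled; a directional-max variant is available behind a flag.  Both
are validated against O(n²) brute-force pairwise distances on small grids.

## Quality filter and review statistics

Reviewer scores band as: both scores 5 → no edits; both in 3–4 → minor;
both in 1–2 → major.  Pairs straddling bands are resolved to the worse
(higher) level — conservative for clinical use.  Consensus averages the
two reviewers' scores, rounds half-up, then bands.  The filter is an
ML logistic regression (statsmodels) of minor-vs-major on the model
family's covariates, fitted on an 80:20 split grouped by subject; on
separation it falls back to a small ridge penalty and flags the model.
No-edit records are excluded from fitting with a warning (deformed
contours essentially never earn double 5s).  AUC is the rank/midrank
(Mann–Whitney) form; Cohen's kappa is unweighted by default with a
linear-weighted option; the ordinal association between C and editing
level uses the linear-to-linear trend statistic `M² = (N−1)r²` with
chi-square(1) p-values.

## Synthetic phantom and simulated reviews

The phantom emulates a lower-abdomen CT at 96×96×40, 1×1×2.5 mm: soft
tissue background (30 HU), additive Gaussian noise (SD 5 HU), and three
non-overlapping organs whose edges are logistic sigmoids in signed
distance with per-organ sharpness — bladder-like ellipsoid (+300 HU step,
sharp), prostate-like ellipsoid (+40 HU, shallow), rectum-like bent tube.
Masks are exact geometric level sets, independent of the noise.  Optional
low-contrast arcs locally scale an organ's HU step over an angular range,
giving the anchor search a constructed target.  Edge sharpness values were
chosen so the contrast response at `a = 50` spans roughly 0.3–0.8 across
organs.

Simulated reviews draw a latent minor/major label per contour from
`P(minor) = expit(−4 − 0.05·C + 8·surface_dsc)` — coefficients fixed so
the minor fraction declines across the C schedule roughly the way clinical
reviewers grade increasingly deformed contours — then each of two
reviewers reports the true label with probability 0.925 (putting their
kappa near 0.7) and backfills score pairs inside the label's band, so the
band mapping round-trips by construction.

What the phantom does **not** model: anatomically realistic organ shapes
and tissue textures, streak/beam-hardening artefacts, inter-patient
anatomical variability (subjects differ only by noise realization), or
reviewer biases beyond symmetric disagreement.  Passing tests therefore
establish the mechanics and the qualitative behaviour of the method
(variability grows with C, concentrates in low-contrast regions, regular
high-contrast organs fare best), not clinical performance on patient CT.

## Problem sizes used in tests and the acceptance script

Monte-Carlo assertions use 20–50 seeds per condition on the default
phantom; displacement-field statistics are computed from the field values
(no rasterization) where only magnitudes are asserted; the acceptance
script simulates a 14-subject cohort with 2 replicates per
(subject, organ, C) — 420 generated contours — and 10 split seeds per
filter model.  These sizes give stable means for the monotone/ordering
assertions while keeping any single run in the minutes range on one CPU.

## Known limitations

* The displacement direction (outward normal, signed by W) is one
  reasonable reading of a scalar-magnitude model; curl-free or
  tangential components of real observer variability are not modelled.
* Self-intersection repair keeps the largest simple sub-polygon, so at
  extreme C a pinched-off lobe is discarded rather than split into a
  second component (the data model is single-component per slice).
* `σ = 25` smoothing on small working grids must be rescaled by the user;
  no automatic grid-relative calibration is attempted.
* RT-STRUCT support is read-only and assumes an axis-aligned CT grid.
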