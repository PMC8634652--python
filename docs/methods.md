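# Methods

## Scope and model

`synseek` operates on pre-aligned serial-section stacks: stitching and
elastic alignment are upstream concerns, and per-section alignment
enters only as an invertible planar affine transform mapping
section-local pixels to global slide coordinates (micrometres). The
pipeline's unit of work is one section plane per channel; axial
information exists only as the ordering of 90 nm sections, so axial
resolution equals section thickness.

The detection model is deliberately simple: a putative synapse is any
place where presynaptic (axon) and postsynaptic (dendrite) foreground
overlap at survey resolution. This over-detects by construction —
bypassing neurites separated by a sub-resolution gap also overlap at
20x — and that is the point: the shortlist bounds the set of locations
the super-resolution microscope must visit, and adjudication of contact
vs bypass happens there, not here. Near-miss bypasses are therefore
*expected* to be detected and scheduled; they are resolved at the SIM
stage (emulated in the phantom's ground truth by the `is_true_synapse`
flag).

## Preprocessing

Normalization applies the affine map `Img/std(Img)·σ − mean(·) + μ`
per plane, with the sample (n−1) standard-deviation convention (the
choice is a documented convention; nothing downstream depends on it
beyond a fixed scale). It is exactly idempotent and preserves rank
order. Constant planes are rejected as degenerate rather than silently
divided by zero.

Background flattening subtracts a Gaussian-blur estimate of the local
brightness tendency (`background_sigma` = 50 px by default — large
compared to neurite cross-sections of 1–2 px, small compared to the
plane). The blur uses reflective padding. Note a consequence of
reflective padding: a global linear ramp is *not* annihilated when the
blur scale exceeds the image size (blurring the reflected ramp tends to
its mean); it is annihilated in the interior whenever the kernel
support fits inside the image, which is the operating regime. Negative
values after flattening are retained — clipping would bias the
threshold histogram — and the thresholder's histogram spans the
per-plane min–max range so negatives are representable.

Order is fixed: normalize, then flatten. Flattening commutes with
constant offsets, so the composition is well defined.

## Thresholding

Each channel is binarized at the cut `t` maximizing
`H_α(bins ≤ t) + H_α(bins > t)` over a 256-bin histogram of the plane's
min–max range, where `H_α` is the order-α Rényi entropy of the
class-normalized distribution. A single order (α = 2, configurable) is
used rather than the three-order combination rule found in some ImageJ
ports; the single-order criterion is the textbook form, converges to
the Shannon/Kapur criterion as α → 1 (verified within ±1 bin on bimodal
histograms at α = 1.001), and leaves one interpretable knob. Zero-count
bins contribute nothing to `Σ p^α`, avoiding `0^α` for α < 1. Ties
resolve to the lowest cut within a 1e-9 relative tolerance of the
maximum, so symmetric histograms threshold identically regardless of
floating-point evaluation order.

The entropy criterion presumes a mixed background/foreground histogram.
On a structure-free plane it would simply balance the noise
distribution and mark ~30% of pixels foreground. A noise floor
therefore backstops the cut: it never drops below
`median + 3 × 1.4826 × MAD`. On structured planes the entropy cut sits
at ~3σ robust or above, so the floor is inactive there; on noise-only
planes it limits foreground to the extreme shot-noise tail (~0.1–0.4%
of pixels). Set `noise_floor_sigmas = 0` to disable.

Dilation uses a 3×3 square structuring element — one positive pixel
becomes a 9-pixel block — to absorb the survey's localization error and
protect detection recall. Dilated masks are used for overlap detection
only; areas are measured and continuity is judged on the undilated
masks (a dilated single-pixel noise speck would otherwise count as
9 pixels of structural evidence in a neighbouring section).

## Detection and scheduling

Overlap components use 8-connectivity. Each component gets a FOV-sized
box centred at its rounded centroid, clamped to the image by shifting
(never shrinking), so every exported box has the exact SIM field
dimensions. Coordinates are 0-based and pixel-centred; boxes are
half-open `[x0, x1) × [y0, y1)`.

Minimal-overlap merging is greedy: repeatedly place the box position
covering the most still-uncovered overlap pixels until none remain.
Optimal rectangle cover is NP-hard; the greedy cover is deterministic
(ties: topmost, then leftmost), complete by construction, and within
one box of the exhaustive optimum on all tested ≤10-pixel instances.
Candidate positions are restricted to canonical anchors whose top/left
edges coincide with (clamped) overlap-pixel coordinates; any box can be
shifted onto an anchor without losing coverage, so per-step greedy
coverage is unaffected.

Interior rejection flags a candidate whose every overlap pixel lies
deeper than `interior_margin` (default 5 px) from the background of
*both* masks — an overlap in the middle of two thick structures is a
crossing, not a surface contact. Margin 0 flags nothing; an arbitrarily
large margin flags everything.

The continuity filter maps each candidate's centroid through its
section's transform to slide coordinates and back into each
neighbouring section's frame; the candidate survives if any neighbour
(±1 section by default, ±2 as an option) shows axon *and* dendrite
foreground within `match_radius` (default: dilation radius + 2 = 3 px).
End sections use their single neighbour; a one-section stack shortlists
nothing, with a logged warning. Shortlisted candidates are bound into
series: the same slide coordinate on 1–2 preceding/following sections,
3–5 entries truncated at stack ends.

Count conservation — shortlisted = detected − interior-rejected −
continuity-rejected — is asserted on every run.

## Quantification

Areas are foreground pixel counts × pixel area on the *undilated*
masks, summed per section inside the target-area polygon (z-projection
is available as an option but per-section summation is the default:
dilation and projection both inflate areas, and the intersection area
must stay ≤ min(axon, dendrite)). Densities are counts per 100 µm² of
each structure class — dendrite area is the headline denominator, axon
and intersection denominators are also reported — with zero areas
reported as undefined, never infinity. Fold ratios are computed unrounded;
presentation rounding (1 decimal for area folds, whole multiples for
count folds) happens only in the formatter.

Imaging cost: a full grid needs `ceil(width/fov) × ceil(height/fov)`
tiles per section; the targeted plan counts scheduled tiles (merged
covers × series entries). Percent saved is rounded to the nearest
integer and may be negative on dense toy volumes where the targeted
plan exceeds the tiny full grid.

FWHM uses the profile minimum as baseline and linear interpolation at
the half level on each side of the peak; it is exactly scale-invariant
and matches `2√(2 ln 2)·σ` within 1% on sampled Gaussians. Line
profiles are bilinear samples at unit-pixel spacing,
`ceil(length) + 1` points inclusive of both endpoints.

## The phantom

The generator emulates the specimen geometry the pipeline targets: a
resin-embedded volume (default 50 × 50 × 3.15 µm → 35 sections at
90 nm) sampled at 0.31 µm lateral pixels — a documented stand-in for
20x survey sampling, not a measured value. Neurites are capsule tubes
with Gaussian cross-sectional intensity (FWHM = tube diameter),
emulating sub-resolution blur at the survey scale. True synapses are
tube pairs whose surfaces touch (gap exactly 0, constructed so both
lines are perpendicular to the common normal at closest approach);
near-misses are bypasses with a 0.1–0.3 µm gap. Only true synapses
carry a synaptic-marker punctum (3-D Gaussian, FWHM 0.3 µm). Each event
consumes one axon; events are hosted on dendrites round-robin with
≥3 µm separation inside an interior margin. Default counts (24 true,
24 near-miss, 10 dendrites, 48 axons) give a dense but placeable
configuration.

Nuisance signals, applied in order: a smooth planar background gradient
(amplitude 10 on a background of 20), per-tile multiplicative
brightness factors (4 × 4 grid, CV 0.1, redrawn per section), Poisson
shot noise, then Gaussian read noise (sd 2). Signal amplitude is 100.
All randomness flows from one `numpy` generator seeded by the config,
so identical configs are byte-identical.

What the phantom does *not* model: optical PSF of the SIM
reconstruction, immunostaining chemistry, section wrinkles or folds,
and elastic misalignment (its sections are perfectly registered, so
pipeline transforms default to a pixel-size scaling). Passing tests
therefore demonstrate the algorithmic contracts — recall of rendered
contacts, noise rejection, count conservation, arithmetic — not
robustness to real staining variability or alignment error.

Two consequences of realistic rendering are worth knowing. First,
because tubes are only 1–2 px wide and blurred, the measured mask area
exceeds the geometric tube projection by a threshold-dependent factor
(~1.5×); fold *ratios* are unaffected. Second, shot-noise specks above
the threshold floor occasionally coincide across channels and sections,
so a structure-free stack can yield a few candidates and rarely a
shortlisted one; this is the irreducible noise floor of the method and
mirrors why the acquisition stage retains a visual verification step.

## Problem sizes

The bundled phantoms are sized for fast iteration: the default
end-to-end stack is 35 sections of 162 × 162 px (seconds to render and
detect), unit-test phantoms are 10 sections of 65 × 65 px, and the
cover-optimality suite uses ≤10-pixel instances on 200 × 200 grids
where exhaustive search is exact. Larger volumes scale linearly in
sections × pixels.
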