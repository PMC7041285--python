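# Methods

This note documents the models and numerical choices behind
`meniscus3d`: what each stage computes, the defaults and their units,
what the synthetic data emulate (and what they do not), and the
limitations a user should know before trusting a number.

## Anatomical frame and measurement model

All meshes live in a right-handed canonical frame in millimetres:
x = anterior–posterior (length), y = medio-lateral (width),
z = inferior–superior (height). Left menisci are mirrored to right
surface models by reflecting across the sagittal (x–z) plane (y → −y,
triangle winding flipped). Any reflection plane would do — the
subsequent box measurement and ICP alignment are reflection-agnostic —
but with width on the y-axis the sagittal plane is the natural choice.

Width/length/height are the extents of a root-aligned oriented bounding
box: the z-axis is taken from the frame (estimating "up" from an
isolated meniscus is ill-posed, so meshes are required to arrive in, or
be transformed to, the canonical frame); the box is rotated about z
until its x-axis is parallel to the x–y projection of the line from the
anterior to the posterior root landmark; extents are the min/max vertex
projections on the three axes. An interactive tool would seed this box
automatically and let the operator adjust it, but once the two axes are
fixed the tightened box has no residual freedom, so the seeding step is
omitted and the measurement is fully automatic. Consequences worth
noting:

* the measurement is exactly invariant under rotations about z plus
  translations (the admissible poses of the canonical frame), and under
  uniform scaling it is exactly homogeneous;
* root landmarks are trusted as given (two points, not attachment
  areas); roots closer than 1 mm cannot orient the box and raise an
  error;
* the 2D measurement (the in-silico analogue of the axial-slice MRI
  box) is the same box applied to the x–y footprint; for the synthetic
  wedge shapes, which never overhang, it equals the 3D width/length
  identically. Optional Gaussian noise (off by default) emulates manual
  2D reading error.

## Surface distance

Two meshes are compared after rigid superimposition by point-to-point
ICP: area-uniform stratified samples (default 4 points/mm²; one
deterministic sub-seed per mesh derived from its identifier, which
makes all-pairs caching possible and results order-independent),
closed-form Kabsch solve per iteration, no trimming or outlier
rejection — menisci overlap fully, so trimming would only bias the
fit. Initialization aligns centroids and the principal (covariance)
axes of the two sample clouds, trying the four proper axis-sign
combinations and keeping the lowest initial RMS; principal axes rather
than the measurement box are used because they are pose-equivariant,
which preserves rigid-motion invariance for meshes in arbitrary poses.
Iteration stops when the RMS change drops below 1e-6 mm (100 iterations
maximum; non-convergence returns the best transform with a warning, it
is not an error). For large batch runs the validation pipeline relaxes
the tolerance to 1e-4 mm and caps ICP at 400 points per side — the
resulting MeSD shift is below 0.005 mm, far under the effects being
measured — while the final distances always use the full sample.

After registration, distances are exact point-to-triangle distances
(not point-to-vertex, which overestimates on coarse meshes) from each
mesh's samples to the other surface, evaluated with a branch-and-bound
AABB-BVH traversal that is exact to round-off (verified against brute
force at 1e-9). Directed means and maxima are combined conservatively:

* MeSD = max(mean(A→B), mean(B→A)) — the "Hausdorff" reading applied
  to the mean, so MeSD is still a mean but never flattered by an
  asymmetric comparison;
* MaSD = max(max(A→B), max(B→A)) — the classical Hausdorff distance.

Each unordered pair is registered in a canonical identifier order, so
MeSD/MaSD are exactly symmetric in argument order. A useful rule of
thumb exposed as `fit_quality_good`: a very good allograft fit shows
MeSD < 1 mm together with MaSD < 3 × MeSD.

Caveat: a *sampled* maximum is intrinsically less stable than a sampled
mean. MeSD is reproducible to ~0.01 mm under resampling at the default
density; MaSD can move by a few tenths of a millimetre because the
Hausdorff supremum is attained in a small region. Selection therefore
uses MeSD, as the clinical method does.

## Sizing rules

* **3D-MRI**: template = mirrored contralateral surface; score =
  MeSD(template, candidate); argmin wins.
* **2D-MRI**: target = contralateral 2D width/length; score =
  (Δwidth)² + (Δlength)² in mm² (equal weighting).
* **2D-RX**: target derived from the ipsilateral tibia plateau via
  Pollard (width = plateau width for both sides; length = 0.8 ×
  plateau length medial, 0.7 × lateral), then the same score.

2D targets are scored against the bank's 3D (OBB) width/length by
default — the bank side of the comparison is a measured allograft
dimension — with a switch to use the bank's 2D measurement on both
sides. Ties are broken by the smaller candidate identifier, making
every selection deterministic. Scores are never compared across
methods (mm vs mm²).

## Leave-one-out validation

The bilateral patients form the validation group. For each of their
menisci: both same-side menisci of that patient are removed from the
pool (the contralateral template itself is never selectable — with 50
bilateral + 40 unilateral donors this is the 140 → 138 arithmetic);
the gold standard selects by MeSD with the *original* meniscus as
template (best possible allograft, 100 × 138 = 13,800 scored
candidacies per side); each sizing rule then selects via its own
template; and every selected meniscus is compared with the original by
MeSD/MaSD and absolute dimension differences. Outliers use strict
inequalities: |Δw| > 5 mm, |Δl| > 5 mm, |Δh| > 4 mm, or MaSD > 5 mm.
Dimension differences are reported as absolute values.

All pairwise surface distances within a side are computed once and
cached by unordered pair — the dominant cost — and reused by the gold
standard, the 3D-MRI selector, the final comparisons, and the
diversity summary (n(n−1) ordered pairs per side). Summary tables
report mean/min/max/SD per side × method × metric plus pairwise Welch
t tests. The tests are independent-sample for fidelity to the clinical
analysis even though the values are matched by case (a paired option
exists but is off by default), Bonferroni-multiplied over the method
pairs per metric and capped at 1.0 — the capping is why a summary
table can print p = 1.000.

## Synthetic data: what it emulates, and what it does not

The generator produces C-shaped wedge menisci: an elliptical crescent
centerline (arc span 300° medial, 330° lateral — medial longer and
more open, lateral rounder), swept with a triangular wedge
cross-section that is tall and deep at mid-body and tapers toward the
roots, modulated by a smooth low-order (4 trigonometric modes) random
radial/height field windowed to vanish at the roots. Roots are the cap
centroids of the two arc ends, so the root line is exactly the x-axis,
and a final per-axis rescale makes the OBB dimensions match the drawn
(w, l, h) exactly (the stated contract is within 2%; the construction
achieves round-off). Meshes are watertight, single-component,
~1,300 vertices / ~2,600 faces at the default tessellation (72 arc
sections × 18 profile points), at which the OBB dimensions are
resolution-stable.

Population defaults (mm): medial w 31.6 ± 3.3, l 46.8 ± 3.7,
h 9.3 ± 1.4; lateral w 31.7 ± 3.7, l 35.3 ± 2.8, h 9.9 ± 1.4;
width–length correlation r = √0.310 (medial) and √0.304 (lateral)
via a bivariate normal draw; height independent (no w–h or l–h
correlation is reported for real menisci, so independence is the
least-assumptive choice). A virtual patient draws right-side
dimensions, builds the right meshes, and creates the left side as the
same base shape plus an independent perturbation at the contralateral
asymmetry amplitude (default 0.4 mm; dimension jitter SD = amplitude/3),
mirrored into the left frame. Tibia plateau measurements are
back-computed per compartment by inverting the Pollard relations from
each meniscus's true dimensions plus Gaussian noise at the published
prediction SDs (2.9 mm width, 3.8 mm length) — the radiograph model
realizes exactly that prediction error and nothing more anatomical.

The shape-perturbation amplitude (default 1.6 mm) is the one free
knob: it was calibrated once so the all-pairs inter-subject MeSD mean
of a default bank falls in the 1.0–1.8 mm range observed for real
menisci, and it creates the degeneracy that makes the study question
non-trivial — menisci with the same width and length but different 3D
shape. What the generator does *not* emulate: real segmentation noise
and smoothing artefacts, attachment-area root geometry, ligament
remnants that inflate MaSD, or any anatomical correlation beyond the
three dimensions. Passing tests therefore demonstrate the pipeline's
correctness and the direction of the method ranking under realistic
population statistics, not the magnitudes that would be obtained on
patient meshes.

## Problem sizes and determinism

The test suite runs the full default experiment — 50 bilateral + 40
unilateral patients, 140 menisci per side — at a sampling density of
1 point/mm² (≈ 2,300 samples per meniscus), the density at which the
two-sided distances are stable to ~0.01 mm in MeSD; unit and property
tests use coarser meshes (12 × 8 tessellation) where brute-force
oracles are affordable. Every random draw flows from explicit seeds
(per-patient and per-mesh sub-seeds derived by CRC from identifiers,
kept below 2³¹), so banks, selections, and summaries are byte-stable
across runs and platforms.

## Known limitations

* The absolute MeSD/MaSD level of the synthetic banks tracks the
  chosen perturbation family; only its calibrated mean (1.0–1.8 mm
  inter-subject) is matched to reality, not the full distribution.
* MaSD inherits sampled-maximum noise (see above); consumers needing a
  tight Hausdorff bound should raise the sampling density.
* ICC is implemented in its two-way absolute-agreement forms ICC(A,1)
  (default) and ICC(A,k); with only two raters the single- vs
  average-measures choice cannot be disambiguated from the data, and
  rater reliability tables from the original study cannot be
  reproduced without the human measurements.
* The scale-adapted matching sometimes discussed clinically (shrinking
  or enlarging the template to compensate expected extrusion) is
  exposed only as a pre-scale factor on the query mesh in the CLI, not
  as an optimization.
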