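# Methods

`hippofuse` implements an automated hippocampal segmentation and volumetry
pipeline of the multi-atlas label-propagation family: many labelled template
images are registered to a new scan, and their propagated labels are fused
into a consensus segmentation by a STAPLE-type expectation–maximization in
which templates are ranked *per voxel* by local image similarity, so that
only the locally best-matching subset votes at each location. This local
ranking is what lets a heterogeneous template database (normal and sclerotic
hippocampi of varying severity) segment pathological anatomy that any single
template would miss.

## Pipeline

1. **Groupwise template.** An average anatomy and per-side probabilistic
   label prior are built by iterative register-and-average: iteration 1
   affinely registers every database entry to one arbitrary reference (the
   first entry by sorted id, for reproducibility) and takes the voxelwise
   mean; later iterations register all entries — including the original
   reference — nonrigidly to the current average and re-average, until the
   mean absolute change of the average falls below 1% of the brain-mean
   intensity or an iteration cap (default 4; the reference phantom study
   uses a fixed 3-iteration schedule). The convergence criterion is ours;
   the construction scheme assumes only that the arbitrary-reference bias
   decays once nonrigid iterations begin, which the ordering-invariance
   test checks.
2. **Prior propagation and ROI.** The template is registered
   (affine + coarse nonrigid) to the subject; the label priors follow. Each
   side's region of interest is the bounding box of the propagated prior's
   0.5-level set plus a 4-voxel margin. An empty prior aborts the side —
   it signals an upstream registration failure.
3. **Coarse selection.** Every template is brought near the ROI through the
   composed groupwise transforms, refined by an affine registration, and
   ranked by global normalized cross-correlation (NCC) over the ROI brain
   mask (voxels above 5% of the ROI maximum — background would otherwise
   dominate the score). The top `k_coarse` (default 75; a smaller database
   is used whole, with a warning) proceed. Ties break by ascending template
   id so the ranking is a pure function of its inputs.
4. **Fine registration.** Each selected template is registered nonrigidly to
   the ROI and its manual label is propagated as a *continuous* probability
   map (linear interpolation of the label indicator — binarizing here would
   discard propagation uncertainty). Labels travel the same two-step path
   the registration optimized (coarse map onto a padded patch, fine
   deformation onto the ROI); composing the two maps into one degrades for
   strongly deformed templates because the coarse field must then be
   interpolated at far-displaced points.
5. **Locally ranked fusion.** At every voxel the `k_local` (default 15)
   templates with the highest locally normalized cross-correlation (LNCC,
   Gaussian window of sd 2 voxels, truncated at 3 sigma; zero-variance
   windows score 0) are selected. A STAPLE EM then alternates: E-step —
   consensus probability from the selected templates' probabilities, their
   current sensitivities/specificities and the spatial prior; M-step —
   per-template global sensitivity p_j and specificity q_j re-estimated
   over the voxels where that template is selected. A mean-field Markov
   random field (6-connected, beta = 0.5) updates the spatial prior after
   every iteration. The consensus is thresholded at 0.5 (ties count as
   foreground) and reduced to its largest connected component per side.

## Key numerical choices

- **EM support.** The E/M updates run only where the locally selected
  templates *disagree* (any selected probability in (0.05, 0.95) range
  between templates); consensus voxels keep their agreed value and still
  inform the MRF. Estimating performance over the vast agreement region
  dilutes specificity toward 1 for every template and biases the consensus
  toward systematically oversegmenting templates — measured on the phantom
  study, the restriction raises fused Dice by 0.02–0.06 on every probed
  side. Classic whole-volume estimation remains available
  (`FusionConfig.disputed_only=False`) and is what the generative-model
  parameter-recovery experiment uses, since *global* rater
  sensitivity/specificity is only identifiable from whole-volume sums.
- **EM initialization and stopping.** p_j = q_j = 0.95; spatial prior =
  propagated groupwise prior blended 50/50 with a flat 0.5; stop when the
  mean absolute consensus change is below 1e-4 or after 50 iterations.
  p_j, q_j are clamped to [0.05, 0.999]. When `staple_em` is called without
  a prior field it defaults to the classic global foreground-prevalence
  prior; a flat 0.5 on a background-dominated volume provably drives the EM
  to a union-like consensus.
- **With the MRF disabled** the EM log-likelihood is non-decreasing (the
  classic STAPLE guarantee); the suite asserts this on every such run.

## Registration

- **Affine stage:** SimpleITK's registration framework (correlation metric,
  deterministic regular-grid sampling, center-of-mass or identity
  initialization, regular-step gradient descent with physical-shift
  scaling). A result is accepted only if it improves NCC over the
  initialization; otherwise the initialization is returned with
  `converged=False`.
- **Nonrigid stage:** a self-contained demons-style dense free-form engine.
  Intensities are first locally standardized (Gaussian window, sd 4
  voxels), so the residual force behaves like a local-correlation mismatch
  and is insensitive to smooth bias fields and global gain — the reason NCC
  is used everywhere else. Each iteration takes an optical-flow step along
  the warped moving-image gradient, smooths the update (fluid, sd 1 voxel)
  and the accumulated field (elastic), over a coarse-to-fine schedule of
  image/elastic smoothing with a per-level iteration budget (heavily
  smoothed levels drift if run long, so they get less); the whole schedule
  is then *restarted* from the warped position and the fields composed
  (default 2 passes), because a single additive pass cannot absorb the
  large local contractions severe atrophy requires. Three safeguards bound
  the estimate: the displacement magnitude is capped (8 voxels per pass) so
  an unmatched structure cannot be "solved" by dragging anatomy in from far
  away; a pass is kept only if it improves NCC; and a pass is rejected when
  it maps too much of the target outside the moving image domain. A folding
  guard warns when the map's Jacobian determinant is positive on fewer than
  99% of voxels. This engine was chosen after a B-spline control-grid
  optimizer (dense NCC + bending energy, L-BFGS-B with analytic gradients)
  plateaued well short of the label overlap needed for severe shape change;
  the demons fixed-point iteration converges in a fraction of the time on
  these images. All steps are deterministic.
- **Presets.** "Coarse" (groupwise/prior steps): one heavily smoothed level
  (sigma 3, elastic 2.5), one pass. "Fine" (per-template ROI): four levels
  from sigma 4 down to 0.5 with budgets (6, 10, 16, 16), two passes.
- **Context matters.** The fine registration runs on the *padded* ROI for
  both images (5 extra voxels each side): smoothing a tight ROI without its
  surroundings manufactures boundary pseudo-structure whose gradients drag
  the deformation coherently off target — measured, this single change
  moved fused Dice on severely atrophic sides from ~0.55 to ~0.9.

## Volumetry and evaluation

Contours are per-slice closed polygons; a voxel is included when the
contours enclose at least half of its in-plane footprint (exactly half is
inside), decided on a 16x16 supersampled point grid with the even-odd rule
(a 256x oracle agrees voxel-for-voxel in tests). Alternate-slice
segmentations are expanded by duplicating each segmented slice onto its
lower unsegmented neighbour, and their volumes doubled (sum of per-slice
areas x slice thickness x 2). Intracranial volume (ICV) is estimated by
running the identical selection-and-fusion pipeline with whole-head masks
as labels; because head-scale deformations are smooth, the ICV run uses the
coarse nonrigid preset for its per-template refinements. Hippocampal
volumes are corrected as `corrected = raw − Grad·(ICV − mean ICV)` with
`Grad` the OLS slope of control volume on ICV — the form that makes
corrected control volumes exactly ICV-orthogonal; the reference range is
the control mean ± 1.96 SD of corrected volumes and a side is flagged
atrophic below the lower bound (a volumetric surrogate for a radiological
reading). Dice uses the exact set formula after nearest-neighbour
resampling onto the automated grid; empty-vs-empty is defined as 1,
empty-vs-nonempty as 0.

## Synthetic phantoms

The generator emulates the data regime the pipeline assumes, not MRI
physics. Each phantom is a head ellipsoid (the ICV proxy, default
44x50x36 mm semi-axes) with a CSF rim, two ventricle-like CSF bodies, and
two hippocampus-like structures, each a banana-like union of three
overlapping ellipsoids (base semi-axes 5.8x7.6x6.7 mm, ~3.3 cm³ — a curved,
non-convex shape stresses registration more than one ellipsoid). Atrophy
scales a structure isotropically about its centroid (volume goes as the
cube of the factor) and moves its intensity halfway toward CSF, emulating
the combination of volume loss and signal change seen in sclerosis.
Intensity images get partial-volume (~1 voxel soft) edges — the sub-voxel
gradient information real MRI provides and intensity-driven registration
needs — while label volumes are hard center-in rasterizations. A smooth
multiplicative bias field (3 random low-frequency cosines, ±10%) and
additive Gaussian noise (sd 5 on a 0–150 intensity scale) complete the
image. Databases sample pose jitter (Gaussian sd 3 mm / 3°, truncated at
2 sigma so anatomy provably stays in the field of view), global size
(sd 5%), and an atrophy-class mix realized exactly by largest-remainder
rounding; atrophic sides draw their factor from (0.55, 0.8), covering the
severe end of sclerosis. The default grid is 64x64x48 at 2 mm — desk scale;
all sizes below are the package's reference study conditions, stated here
as its own design choices.

What passing phantom tests does **not** show: performance on real tissue
contrast (no cortical folding, no Rician noise, no partial-volume mixing of
more than two tissues per edge), on scanner-specific artifacts, or at
clinical resolution cohort sizes. The phantom study validates the
*mechanics* — that local ranking plus EM fusion degrades gracefully under
anatomical heterogeneity — not clinical accuracy numbers.

## Reference study conditions

20-template database (normal/left/right/bilateral atrophy in exact 25%
shares), 10 evaluation subjects from the same population, `k_local` 15,
LNCC sigma 2 voxels, MRF beta 0.5, 3 groupwise iterations. The
parameter-recovery experiment simulates 5 raters (sensitivity 0.9,
specificity 0.98) on a 48³ 1 mm phantom truth, 5 times. The atrophy
experiment compares paired subjects differing only in bilateral atrophy
factor (1.0 vs 0.6). The ICV experiment uses a compact 4-template setup on
a 48x48x36 grid. Every random draw derives from one integer seed through
fixed-offset child streams.

## Known limitations

- The demons engine optimizes a locally standardized SSD, not the NCC it is
  scored by; acceptance checks guard against regressions but the two can
  disagree marginally for poorly matched templates.
- Performance parameters are global per template (estimated over that
  template's locally selected, disputed voxels); no spatially varying
  performance model.
- Two labels only (left/right hippocampus as independent binary problems);
  no multi-structure generality.
- Contour handling requires axis-aligned voxel grids.
- The local-selection count is static across EM iterations.
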