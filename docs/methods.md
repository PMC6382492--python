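# Methods

This note records the model, the parameter choices, the numerical
conventions, and the deliberate design decisions behind `ichseg`, plus what
the synthetic phantoms do and do not establish about behaviour on real data.

## Problem model

Spontaneous intracerebral haemorrhage in the acute/early-subacute phase has
a characteristic dual-contrast signature: the blood collection is
hypo-intense on T2\* GRE (susceptibility of deoxy/met-haemoglobin) while the
perihaematomal oedema is hyper-intense on FLAIR. Two systematic confounds
prevent naive thresholding:

* **susceptibility blooming** — the T2\* signal void extends beyond the true
  haematoma and appears in unrelated regions (skull base, orbitofrontal and
  temporal cortex, cerebellum), so the hypo-intensity map over-segments and
  contains decoys;
* **leukoaraiosis** — chronic small-vessel white-matter lesions are
  FLAIR-hyper-intense exactly like oedema, so the hyper-intensity map
  over-segments far from the haematoma.

The pipeline assumes the four inputs (T2\* GRE, FLAIR, label map, SVD
probability map) are already resampled onto one voxel grid; it never
registers or resamples, and a grid mismatch is a hard error.

## Robust intensity statistics

Hypo-/hyper-intensity is defined as statistical outlyingness of a voxel's
intensity relative to normal-appearing white and grey matter. Location and
scale are estimated with the Minimum Covariance Determinant estimator
applied univariately per sequence inside the WM-GM mask, with support
fraction 0.6 — i.e. the estimate tolerates up to 40 % of in-mask voxels
being lesion or artefact.

In one dimension the minimal-variance h-subset is always contiguous in the
sorted sample, so the estimator is computed *exactly* by a sliding-window
scan over order statistics (O(n log n)), rather than by the approximate
FAST-MCD iteration needed in higher dimensions. Ties between windows go to
the lowest window start, making the estimate deterministic. The raw subset
standard deviation is multiplied by the asymptotic normal-consistency factor
`1/sqrt(F_{χ²₃}(q)/α)` with `α = h/n` and `q = F⁻¹_{χ²₁}(α)`; the
finite-sample correction is omitted because the estimator always sees voxel
samples of order 10⁴–10⁵ here, where it is negligible. Outlier cut-offs use
the χ² rule at quantile 0.975 on one degree of freedom
(`c = √5.0239 ≈ 2.241`); the quantile is configurable.

Above 200 000 in-mask voxels the fit runs on a seeded uniform subsample of
that size (the thresholds are then applied to every voxel). The seed is a
pipeline parameter and is recorded in the provenance sidecar, so runs are
bit-reproducible. A constant minimal-variance subset (zero spread) is a
degenerate-distribution error rather than a silent σ̂ = 0.

## Haematoma stage — conventions and tie-breaks

* Connected components of the hypo-intensity map use 6-connectivity; after
  weak-link removal, the re-grouping uses 26-connectivity, because the
  removed bridges are defined on the 26-neighbourhood. Component ordering is
  deterministic (volume-descending, then lexicographically smallest voxel),
  so every argmax has a reproducible tie-break.
* The weak-link patterns are the three axis-aligned opposite face-neighbour
  pairs: a voxel is removed when exactly those two neighbours are true and
  the remaining 24 of its 26-neighbourhood are false. Diagonal lines are not
  broken. Detection is simultaneous on the input mask and removal happens in
  one pass, so the result is order-independent and anti-extensive.
* The FLAIR statistics μ, ν, σ inside the selected component use the
  population convention (divide by n). The corrected branch
  `H = μ + 6(μ−ν)` is algebraically `μ + 2kσ` with `k = 3(μ−ν)/σ`
  (Pearson's second skewness coefficient), i.e. the threshold sits 2k
  standard deviations below the mean when susceptibility blooming drags the
  mean above the median. Voxels exactly equal to H are excluded (strict
  comparison).
* Hole-filling-closing = N dilations with the full 3×3×3 (26-neighbour)
  box, 6-connected cavity filling, N erosions with the same box. The closing
  erosions treat outside-grid as foreground (the adjoint of the dilation),
  which makes the operator extensive for every mask including
  border-touching ones; the two stand-alone erosions that finish the
  whole-brain mask use the standard outside-as-background convention. A
  cavity is a 3-D background region not 6-connected to the grid border;
  filling is volumetric, never slice-wise.
* The final mask removes all ventricle-labelled voxels: intraventricular
  haemorrhage is deliberately out of scope.

## Oedema stage

The dynamic threshold is `T·(D·L + λ)/(2λ)`: half the scalar hyper-intensity
threshold on the haematoma boundary (D = 0), rising linearly with the
SVD-weighted geodesic distance and crossing `T` at `D·L = λ`. The source
formula admits a second algebraic reading, `T·((D·L + λ)/λ)²`; the linear
form is the default because it reproduces the intended "steepness around the
haematoma" behaviour and the T/2 boundary value, while the squared variant
remains available behind `eq_variant="squared"` for cross-checking.

λ defaults to 15; larger λ flattens the threshold and (provably, for the
linear form) enlarges the pre-morphology oedema set monotonically. Raising
the SVD map voxel-wise can only shrink it. Distances are measured in
voxel-lengths by default — inputs are assumed resampled to an isotropic T1
grid — with a millimetre mode (`distance_mode="mm"`) for anisotropic grids.
Geodesic distances use 26-neighbour steps of cost 1, √2, √3 (the
quasi-euclidean chamfer metric) through the traversable set
`hyper-intensity ∪ haematoma`, computed with a Dijkstra-family minimum-cost
front (`skimage.graph.MCP_Geometric`); the test suite validates it against
an independent sparse-graph Dijkstra oracle to 10⁻⁹, including agreement of
the unreachable (+∞) set.

The whole-brain mask (not WM-GM) bounds the hyper-intensity map here because
oedema can extend beyond deep white matter. The final oedema mask explicitly
excludes haematoma voxels, making the two labels disjoint by construction.

## Anatomical masks

The default susceptibility, lesion, and ventricle label sets are the
standard MALP-EM indices for those regions (32, 17, and 6 labels
respectively; CSF = 18). They are plain configuration so reduced catalogues
(such as the phantoms') or label maps extended with a manual lesion label
work unchanged. The label-derived brain mask is binarised as any-nonzero;
hole-filling-closing (1 iteration) is applied to the T2\* and FLAIR nonzero
masks only, exactly as specified for recovering zero-valued parenchymal
voxels, and the two finishing erosions happen after the three-way
intersection, not per mask.

## Synthetic phantoms

The generator emulates the dual-contrast structure, not MR physics: no bias
fields, no partial-volume averaging, no motion, and a minimal label
catalogue (one label per needed region). Geometry is ellipsoidal; intensity
levels are arbitrary units chosen so that the 0.975-quantile outlier
thresholds separate classes cleanly up to an acquisition-noise σ of about
10 % of the tissue–lesion contrast (defaults: tissue 100, T2\* haematoma 30,
FLAIR haematoma 60, oedema/leukoaraiosis 200, CSF 40 on FLAIR).

Brain tissue carries a deterministic Gaussian heterogeneity field
(σ = 3, seeded from the case seed) in addition to optional acquisition noise
(σ = 5 by default): real tissue is never uniform, and a robust scale
estimate requires non-zero spread, so "noise-free" cases retain the
heterogeneity field with acquisition noise switched off. Structures keep a
4-voxel margin from the grid border so morphology never interacts with the
boundary.

The default haematoma (radii 10×9×8 voxels ≈ 3 mL at 1 mm³) with a 1-voxel
susceptibility bloom keeps the bloom shell a clear minority of the selected
component, matching the usual positive-skew regime. The negative-skew
fixture instead uses a 4-voxel bloom with a thin oedema rim, so the selected
component is dominated by swept-in normal tissue: the median sits at tissue
intensity while the dark haematoma drags the mean below it, exercising the
corrected threshold branch. The decoy fixture paints the decoy mildly
FLAIR-hypo-intense so that, by construction, no hyper-intensity falls inside
it and its selection weight is exactly zero.

Passing the phantom suite shows the algorithm's logic is implemented
faithfully under its own assumptions — it does not establish clinical
accuracy: real haematomas are non-ellipsoidal, intensity distributions are
heavier-tailed, registration and label maps carry error, and oedema-like
hyper-intensity can be contiguous with leukoaraiosis in ways the weighting
only attenuates.

## Problem sizes and runtime

The test fixtures use 64³ grids (one 80×64×64 decoy case); the
doubled-geometry verification case is 128³, on which a full pipeline run
takes a few seconds on one CPU. The MCD subsample cap (2×10⁵) only engages
on the 128³ case.

## Known limitations

* Intraventricular haemorrhage is excluded by design, so the reported
  haematoma volume underestimates total blood volume when IVH is present.
* The scalar FLAIR threshold `T` is fitted in WM-GM but applied brain-wide;
  systematic cortical/deep intensity gradients (no bias-field correction is
  performed here) would bias the hyper-intensity map.
* The dynamic threshold's exact algebraic form follows the default reading
  above; results with the squared variant differ mainly far from the
  haematoma.
* Empty-vs-empty Dice is defined as 1 (with a warning); it never arises in
  the shipped pipeline because an empty haematoma is an error upstream.
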