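# Methods

This note documents the models and conventions `segqc` implements, the
choices made where a convention was genuinely open, and what the synthetic
phantoms do and do not establish about real data.

## Label volumes and orientation

Input masks are integer NIfTI-1 volumes with 0 = background, 1 = right
lung, 2 = left lung (other codes can be remapped via `--right-label` /
`--left-label`). On read, volumes are reoriented to a canonical RAS-like
axis order — array axis 0 runs L→R, axis 1 P→A, axis 2 I→S — using the
file's affine, so "axial" (collapse I-S) and "coronal" (collapse P-A) are
unambiguous everywhere downstream. Because label maps are categorical,
sheared or oblique grids are rejected rather than resampled: any
interpolation would invent labels. Header voxel sizes are rounded to six
decimals on read so that a written spacing such as 1.4 mm survives the
float32 NIfTI header round trip exactly.

## Projection images

All three panel variants operate on per-lung binary masks:

- **Slice selection.** For each orientation, the stack is cropped to the
  smallest slice interval [lo, hi) containing foreground of *either* lung.
  Using the union gives both lungs one shared depth range, so their depth
  colors are comparable within a panel.
- **Depth colorization (pseudo-chromadepth).** Slice lo+i of an N-slice
  stack colors its foreground pixels with colormap(i/(N−1)) (argument 0
  when N = 1); background is black. Right lung: viridis; left lung: plasma.
  The depth argument runs inferior→superior (axial) and posterior→anterior
  (coronal). An alternative yellow/cyan palette pair intended to remain
  distinguishable under common color-vision deficiencies is available via
  `--palette cvd`; it is not part of the evaluated defaults.
- **`colored_mip`** projects the depth-colorized *solid* masks with a
  per-channel maximum: out(x,y,c) = max_i I_i(x,y,c).
- **`colored_outline` / `gray_outline`** project *surface voxels* —
  foreground voxels with at least one background (or out-of-volume)
  6-connected neighbour; face connectivity gives the thinnest closed shell
  and makes tests exact — with the per-channel sample standard deviation,
  σ = sqrt(Σ(I_i − μ)²/(N−1)). For N = 1 the projection is defined as zero
  (no variation). `gray_outline` encodes surface voxels white instead of
  depth colors, so its panels are grayscale.
- **Composition.** The two lungs' projections are combined per-channel by
  maximum (black is neutral, the operation is symmetric, and lungs are
  disjoint in well-formed volumes). Axial and coronal projections are
  placed side by side — axial left, coronal right, vertically centered on
  a black background with an 8-px gap. σ panels are min–max rescaled to
  [0, 1] *per composed panel* (not per lung or per orientation) so left
  and right brightness stay comparable; an all-zero panel stays black.
- **Aspect correction.** Projections are resampled by nearest neighbour so
  pixels are isotropic in mm (coronal rows carry the 3.0-mm slice spacing
  against 1.4-mm columns). Nearest neighbour preserves categorical color
  identity; a smoother resampler would blend depth colors into values that
  lie on neither lung's spectrum.
- **Output.** 8-bit PNG, linearly quantized from [0, 1], one file per case
  and method (`<case_id>__<method>.png`) plus a JSON sidecar recording
  method, depth ranges, palette and label conventions. Rendering is fully
  deterministic.

Consequences worth knowing: per-channel MIP of a colormapped stack can
produce channelwise mixtures of two depth colors where structures overlap
in depth — that is inherent to the method, not a bug; and translating a
volume along a projection axis does not change that projection (the crop
re-centers), while the orthogonal view shifts accordingly.

## Ensemble uncertainty

For m candidate masks of one structure, U = 1 − (1/k) Σ_{i<j} Dice(i,j),
k = m(m−1)/2, Dice = 2|A∩B|/(|A|+|B|). The sum runs over unordered pairs;
the ordered-pair reading gives the identical value because Dice is
symmetric. Two empty masks get Dice 1 (perfect agreement on absence), one
empty against one non-empty gets 0; this keeps U within [0, 1]. For a
two-label case U is computed per lung and combined as the unweighted mean —
the simplest symmetric choice; both per-lung values are always reported
alongside.

Stratified review sampling takes the n cases with the highest U, then the n
with the lowest, then the n whose U is nearest the median of *all* cases
among those not already taken; all ties break on case_id, so the selection
is deterministic.

## Rater-study statistics

- **Majority rating:** flag when more than R/2 raters flag. For even R an
  explicit tie rule is required.
- **Proportion CIs:** exact Clopper–Pearson via beta quantiles, with the
  conventional endpoints lo = 0 at 0/n and hi = 1 at n/n.
- **ROC over rating sums:** operating points at half-integer cutoffs
  c = −0.5 … R+0.5 (predict "error" when the sum exceeds c); AUC is the
  trapezoid area over the staircase, which equals the tie-corrected
  rank-statistic (Mann–Whitney) AUC. The AUC interval uses DeLong placement
  values with a normal approximation, truncated to [0, 1]; the variance is
  conditional on the class sizes. The Youden index J = sens + spec − 1 is
  reported per threshold together with the sens%+spec% scale some reports
  print; both are maximized at the same threshold (ties resolve to the
  lowest cutoff).
- **Method comparison:** Cochran's Q on correctness indicators
  (majority rating == reference), run separately within reference-positive
  cases (a sensitivity comparison) and reference-negative cases
  (specificity), with df = methods − 1; all-unanimous input yields Q = 0,
  p = 1 by convention. Pairwise McNemar tests use the exact binomial form
  below 25 discordant pairs and the continuity-corrected chi-squared form
  otherwise — the test's common convention — with Bonferroni adjustment
  (multiply by the number of pairs, cap at 1).
- **Agreement:** Fleiss' kappa over the two categories, Cohen's kappa for
  paired reads; both raise an error when expected agreement is 1 (kappa
  undefined) and carry the Landis–Koch interpretation bands (<0 poor,
  0–0.20 slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80
  substantial, 0.81–1.00 almost perfect).

Standard pieces are delegated to established libraries (scipy's beta
distribution, statsmodels' Fleiss kappa / Cochran's Q / McNemar,
scikit-learn's Cohen kappa); the ROC-over-sums construction and the DeLong
variance are implemented here and cross-checked in the test suite against
independent rank-statistic and bootstrap oracles.

## Synthetic phantoms

The phantom generator emulates what the method's inputs *are* — paired
smooth lung-shaped label regions on an anisotropic grid — without claiming
anatomy. Defaults: 128×128×64 voxels at 1.4×1.4×3.0 mm (the acquisition
grid whose anisotropy the aspect-correction logic must handle), per-lung
ellipsoid semi-axes 28×42×68 mm (≈335 mL per lung, within the adult range),
centers at 30%/70% of the L-R extent, and a smooth random boundary
perturbation of 5% relative amplitude. Semi-axes scale with the grid when a
smaller grid is requested, so tests can run on 48³-sized volumes. All
generators are deterministic given their seed.

Error injectors implement the six observed categories; magnitudes are
mm or voxels as appropriate (see `inject_error`). Cohort generation plans
exactly round(prevalence·n) error cases. Each error case draws a primary
category from the normalized observed counts (61:34:5:4:3:1) and adds
secondary categories with top-up probabilities chosen so the *marginal*
frequency of each category among error cases equals the observed frequency
(80.3%, 44.7%, 6.6%, 5.3%, 3.9%, 1.3%) while at least one category is
guaranteed — matching the real co-occurrence pattern in which frequencies
sum to more than 100%. Cohort cases are lightweight plans (phantom seed +
injections); voxels materialize on `CohortCase.build()`, so truth-table
studies (rater simulation, parameter recovery) cost milliseconds per
cohort.

Ensembles are simulated by perturbing each lung's signed-distance level set
with smooth Gaussian random fields (σ = 3 voxels, unit variance) of chosen
strength; overlap between the two perturbed lungs resolves to the larger
level-set value. Raters are conditionally independent given the reference:
flag probability `sens` on error cases, `1 − spec` on clean ones. There is
no difficulty covariate, so simulated raters cannot reproduce
error-category-dependent sensitivity differences between projection
methods; passing tests establish the correctness of the statistics and
renderers, not the human-reader performance of any projection variant on
real anatomy.

## Numerical conventions and problem sizes

Depth-color stacks are float64 RGB in [0, 1]; PNG quantization is the only
lossy step (≤ 0.5/255 per channel). The monotonicity study of U uses 20
seeded two-member ensembles per magnitude on a 48×48×24 phantom; the
parameter-recovery study uses 100 replicate 300-case truth tables with five
raters at sensitivity 0.88 / specificity 0.97 — the recovery target for the
majority rating is the majority-rule-implied rate (binomial tail of the
per-rater rate), since majority voting deliberately exceeds per-rater
accuracy. Bootstrap cross-checks of the DeLong variance resample within
classes, matching that variance's conditioning on class sizes.

## Known limitations

- Phantoms are smoothed ellipsoids; hilum anatomy, lobar shape and
  MRI-specific artifacts are not modeled, and no image intensities are
  synthesized (the QC method itself uses masks only).
- Sagittal projections and overlay of the underlying imaging data are out
  of scope.
- The uncertainty metric is a disagreement score; it is not calibrated
  against true mask accuracy.
- Simulated raters are exchangeable and memoryless; reading-order, recall
  and fatigue effects of human studies are not represented.
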