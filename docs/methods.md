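# Methods

This note records the models, conventions and design choices behind
`lodgemap`, in the order the pipeline runs them.

## Dual-pol SAR features

All SAR parameters derive from the per-pixel 2×2 Hermitian covariance matrix
of a (VV, VH) acquisition, C2 with diagonal powers C11 (VV), C22 (VH) and
complex inter-channel term C12.

- **dB conversion** is 10·log₁₀(power); non-positive pixels are floored at a
  configurable −50 dB and counted in the log.
- **Eigendecomposition** uses the closed 2×2 form (trace/determinant
  quadratic); eigenvectors solve (C2 − λI)v = 0.  The per-eigenvector alpha
  angle is arccos of the magnitude of the first (VV) component — the
  standard dual-pol convention, since no canonical αᵢ exists for the
  two-channel case.  When C12 = 0 and an eigenvalue coincides with C11 the
  direction is degenerate; the dominant eigenvector is taken as the VV axis
  (α₁ = 0, α₂ = π/2).  Mean alpha, entropy (base-2 logs, 0·log 0 := 0) and
  anisotropy follow from the eigenvalues' pseudo-probabilities.
- **Span** defaults to the trace convention C11 + C22 reported in dB — the
  physical total power, consistent with the reference table's dB span
  values.  A "squared" mode (C11² + 2|C12|² + C22²) exists for comparison;
  the mode is recorded in stack metadata.
- **Shannon entropy** uses the two-term natural-log form
  SE = 2 ln(πe·Tr/2) + ln(4·det/Tr²): an intensity term plus a polarimetric
  term.  The determinant is floored at 10⁻¹² (relative to Tr²/4) so rank-1
  pixels give a finite, strongly negative polarimetry term.  Absolute SE
  values depend on the calibration scale of C2 (adding 2 ln k under C2 → k·C2),
  so only contrasts are meaningful — the screening statistic is scale-free
  in exactly the way that matters.
- **VH/VV** is the ratio of the *dB* values, not of linear powers; this is
  the reading consistent with the reference statistics (−17.13/−12.25 ≈ 1.40).
- **Speckle filtering** is the classic local-statistics Lee filter
  (minimum-MSE weight W = var_x/var_y with noise variance from the ENL,
  reflection padding, odd window ≥ 3).  The edge-aligned refined variant is
  out of scope; on the synthetic scenes' stationary fields the two behave
  similarly away from patch borders.  C12 is boxcar-smoothed with the same
  window and its magnitude clipped to preserve positive semidefiniteness.

## Plot statistics

Plot reduction uses pixel-centre membership (a pixel belongs to a plot iff
its centre lies strictly inside the polygon — the shapely `contains` rule,
so boundary centres resolve to outside).  No sub-pixel area weighting is
attempted.  Quartiles of the ten after-event plot values use inclusive
linear interpolation (`numpy.quantile(..., method="linear")`); the rule is
configurable and recorded on the table, since ten-point quartiles differ
visibly between conventions.

## OSPL screening

The γ statistic is implemented with absolute values on both numerators and
denominators ("magnitude convention"): γ compares the *relative* magnitude
of the lodged-class change against 1.5× that of the healthy class.  This is
the only reading that reproduces the reference screening values (e.g. VV:
1.15/23.35 − 1.5·0.61/23.93 = 0.011; B4: 0.467 − 1.5·0.419 = −0.161) and it
keeps γ well-defined for negative-valued dB parameters.

β counts the majority sign of the ten lodged-plot differences; exact zeros
belong to neither sign (the convention is undocumented in the field — zeros
are treated as "no evidence").  The selection threshold is β ≥ 9.  Step 3
is the mirrored quartile/extremum separation test.  On tables built from
published aggregates only (no per-plot values) steps 2–3 are flagged
`insufficient_data` rather than guessed, and no parameter is marked
selected.

The pipeline partitions selected parameters into OSF (SAR) and OSI
(optical) by a domain tag.  If a domain's selection is empty the classifier
falls back to that domain's step-1 set, then to all its parameters, with a
logged warning — screening should inform, never silently disable, a case.

## Synthetic scenes

The generator emulates the data situation the analysis assumes, not a
radiative-transfer model:

- **Land cover**: a coarse patch grid (16 px patches by default) sampled
  from class fractions {lodged rice 0.28, healthy rice 0.52, water,
  building, wood, bare 0.05 each} — rice ≈ 80% of the scene with ≈ 35% of
  it lodged, matching the reference scenario's reported shares.  Ten lodged
  (L1–L10) and ten healthy (H1–H10) circular plots (radius 4 px = 40 m) are
  stamped on top.
- **SAR**: class-mean σ⁰ in dB per epoch (rice classes from the reference
  before/after table; non-rice classes are fixed plausible constants —
  water −22/−28 dB, buildings −4/−10 dB, etc. — with a ±0.3 dB epoch
  drift), converted to linear power and multiplied by Gamma(ENL, 1/ENL)
  speckle with ENL = 4 (a typical multi-looked product; CV = 0.5).  C12 has
  coherence magnitude 0.3 and uniform phase.
- **Optical**: class-mean reflectance per band and epoch plus independent
  Gaussian noise, σ = 0.08 — chosen as a realistic per-pixel heterogeneity
  giving band-level contrast-to-noise ratios of roughly 1–2.5 for the
  lodged/healthy pair.  The healthy class drifts between epochs by its
  reference deltas, emulating the illumination difference between
  acquisitions so that screening faces realistic confounding.
- **Pixel sets**: the lodged/healthy train (2876) and validation (1427)
  sets are crop-only — matching the reference campaign, whose validation
  marginals are all rice — disjoint, and exclude every sample plot.  A
  separate all-class stratified set (900 pixels) fits the crop-mask
  classifier, since mask training is not specified by the campaign.

What the generator does *not* model: spatially or spectrally correlated
reflectance variability (within-class optical noise is iid per pixel and
band), topography, mixed pixels, clouds, or acquisition geometry.  The main
visible consequence is that plot means are very precise (noise averages
over ~50 pixels), so the step-2/3 screening passes more optical bands than
a real campaign would, and the optical-only classifier is stronger relative
to SAR (~96–97% vs ~84% OA) than on real scenes.  Passing tests therefore
demonstrate the correctness and the qualitative behaviour of the method —
sensitivity screening, masking, fusion — not absolute real-scene accuracies.

## Classification

The **crop mask** comes from a class-conditional Gaussian maximum-likelihood
classifier on the ten after-event optical bands with equal priors;
covariances are regularised with δ·I, δ = 10⁻⁶ × mean feature variance, so
degenerate classes still fit.  Crop = union of the two rice classes; masked
pixels carry the sentinel label 255.

The **Random Forest** is a 100-tree bootstrap ensemble, Gini criterion, 2
candidate features per split, majority vote per pixel.  The "0.2 min
impurity" setting is interpreted as a node-split threshold: a node whose
Gini impurity is ≤ 0.2 is treated as a leaf.  Standard scikit-learn trees
provide the fitted ensemble and the rule is applied as an early-stopped
descent at prediction time, which is equivalent to pruning every subtree
rooted at a node with impurity ≤ 0.2 (growth under the rule and descent
under the rule stop at the same first qualifying node on any root path).
The alternative reading — minimum impurity *decrease* of 0.2 — would forbid
nearly every split of a binary Gini tree (maximum 0.5) and is exposed as
`impurity_mode="decrease"` for completeness.  The threshold caps leaf
purity at roughly 89/11, which is the main accuracy-limiting mechanism on
clean synthetic scenes.

Accuracy is assessed on the validation pixels (crop-only by construction)
directly against the Random-Forest predictions; the MLC mask shapes the map
product but does not enter the 2×2 lodged/healthy contingency table, so the
three feature cases are compared on identical pixels.

## Evaluation

The contingency table is rows = classification (CC), columns = ground truth
(GT).  PA_c = diag_c / column total (recall), UA_c = diag_c / row total
(precision), OA = trace/total, and kappa = (p_o − p_e)/(1 − p_e) with
p_e = Σ_c (row_c·col_c)/total².  Display rounding is nearest-percent for
accuracies and two decimals for kappa; full precision is always retained.
On the reference contingency tables this reproduces every published cell,
with one documented divergence: the optical-case kappa computes to 0.7671
from the published counts (rounds to 0.77, not the published 0.76); the
count-derived value is reported.

## Determinism and problem sizes

Every stochastic stage consumes a `numpy.random.default_rng` seeded from the
run seed; the forest uses the same seed via scikit-learn's `random_state`
with single-threaded fitting, so a fixed seed reproduces scenes, screenings
and maps bit-for-bit.  Library tests run on 64–128 px scenes with reduced
pixel sets; the end-to-end experiments (analysis scripts, ranking test) use
the default 256×256 scene, 2876/1427 pixel sets and ten seeds — sizes at
which plot statistics, screening behaviour and the case ranking are stable.
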