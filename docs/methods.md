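# Methods

This note documents the models implemented in `histomarkers`, the
parameter choices that matter, what the synthetic data generators emulate
(and what they do not), and the numerical decisions taken where the
design was genuinely open.

## Seed detection by multi-scale cone voting

**Model.** Nuclei stained with hematoxylin are darker than their
surroundings, so at a nucleus boundary the image gradient points outward
and the negative gradient points toward the nucleus interior. Each
*voting point* — a boundary-like pixel — casts votes into a cone of
radial extent `[r_min, r_max]` and angular half-width Δ opening along its
negative gradient direction. The vote deposited at a receiving pixel is a
2-D isotropic Gaussian `K(x, y; μ, σ²I)` whose mean μ sits at distance
`(r_min + r_max)/2` from the voter along the voting direction; the
accumulated kernel mass at each pixel is multiplied by the Euclidean
distance map `g_D` of the binarized foreground (distance to the nearest
background pixel) and divided by the number of voters `C₁`, making maps
comparable across images. Summation over several scales makes the
detector robust to nucleus size variation. Final seeds are modes of the
map under weighted flat-kernel mean shift (each candidate moves to the
weighted mean of candidates within one bandwidth until displacement
< 1e-3; converged positions within one bandwidth merge, so no two seeds
can be closer than the bandwidth).

**Parameters.**

| parameter | default | meaning / rationale |
|---|---|---|
| scales | (4,8), (8,16), (16,32) px | geometric ladder covering 4–32 px radii; pick the subset bracketing the expected radius |
| Δ | π/4 | wide enough to hit the center of eccentric nuclei, narrow enough to keep votes inside one nucleus |
| σ | r_max/3 | Gaussian bump covers the center zone of the cone |
| smoothing σ | 2 px | gradient and Otsu binarization computed on the smoothed luminance |
| gradient quantile | 0.5 | voting points are foreground pixels above the median foreground gradient magnitude; stricter cuts (e.g. top 20%) starve weak-edged nuclei of voters and cause misses |
| keep quantile | 0.2 | mean shift runs on the top 20% of positive-vote pixels |
| bandwidth | 8 px | on the order of a nucleus radius; smaller bandwidths fragment a nucleus into several modes |

Foreground binarization is Otsu on smoothed luminance with nuclei as the
dark class; the distance map is left unsmoothed. Coordinates are 0-based
`(x=column, y=row)`; seed positions are subpixel after mean shift.
Detection evaluation uses greedy one-to-one matching (detections in
decreasing vote order, each matched to the nearest unmatched truth seed
within 8 px); the false-positive rate is normalized by the number of
detections.

## Repulsive balloon-snake segmentation

**Model.** One closed contour per seed, initialized as a small circle
(radius 4 px, 24 points), evolves by explicit Euler steps under
(i) internal force `α v″(s) − β v⁗(s)` via cyclic finite differences
(the canonical deformable-model internal energy; α = 0.1, β = 0.01),
(ii) pressure `γ n(s)` along the outward normal (γ = 1), (iii) image
force `−λ∇E_ext` with `E_ext = −‖∇I‖²` computed on the smoothed
luminance and sampled bilinearly (λ = 0.05), and (iv) repulsion from
every point of every other contour with the inverse-square profile
`f(x) = x⁻²`, direction along `(v_i(s) − v_j(t))/d_ij`, the integral over
the other contour discretized as a mean over its sampled points, and the
distance floored at 0.5 px to bound the singularity (ω = 100).

The repulsion weight matters most: it must beat the pressure force in
the weak-gradient corridor between two touching cells (where only
balloon vs. repulsion compete) without crushing isolated contours.
ω = 100 with the mean-over-points discretization achieves zero polygon
overlap on touching pairs while keeping isolated-cell areas within 10%
of truth; ω = 0 reproduces the failure mode where both contours inflate
through each other and cover the union of the pair.

Contours are resampled to uniform 2-px arc-length spacing each
iteration; evolution stops when the maximum point displacement stays
below 0.05 px for five consecutive iterations or at 500 iterations
(returned with a convergence flag — near-contact oscillation at the
force balance can leave the flag false with a perfectly usable result).
Post-processing rasterizes contours to a label partition (contested
pixels go to the contour with the nearest sampled boundary point) and
removes non-tumor objects: area < 80 px² (lymphocytes and debris are
much smaller than tumor nuclei) or mean luminance outside [40, 220]
(over-dark lymphocyte clusters, background-bright artifacts).
Segmentation is scored per cell against the ground-truth mask by pixel
precision `|seg∩gt|/|seg|` and recall `|seg∩gt|/|gt|` after maximum-
overlap matching, summarized by mean, variance and the 80th percentile.

## The 166-entry patient feature vector

Per cell, 15 scalars: area (pixel count), perimeter (contour arc length,
or Crofton estimate from the mask), circularity `4πA/P²`, major/minor
axis ratio from second moments, solidity (area over the lattice-point
count of the convex hull of pixel centers — exact 1 for convex digitized
shapes), and Lab-L intensity mean, SD, skewness, excess kurtosis,
histogram entropy and energy (32 bins over [0, 256)), plus Haralick
contrast, correlation, energy and homogeneity from a symmetric 32-level
co-occurrence matrix averaged over the (0,1) and (1,0) offsets.

Texture histograms per cell (all computed on the bounding-box patch with
non-cell pixels excluded): 8-neighbor LBP codes pooled into 8 equal
code-range bins (ties compare as ≥); TFCM codes from 3-level
comparisons (tolerance ε = 2 gray levels) of the two neighbors along
each of four directions, combined base-9 into a texture feature number
pooled into 8 bins; CSAC statistics SCOV, SVR, WVAR, BVAR over the four
center-symmetric pairs of every 3×3 unit, per Lab channel (12 values);
and a 4-bin texton histogram from nearest-center assignment in the
response space of a small Gaussian-derivative filter bank (Gaussian,
x/y first derivatives, LoG at σ = 1 and 2), with textons fitted by
seeded k-means and sorted by first coordinate for determinism.

Aggregation to the patient level: each scalar contributes its across-cell
mean, median, population variance and the three frequencies of a 3-bin
histogram spanning the per-patient min–max (suffixes 1–6); LBP and TFCM
contribute per-bin mean, median and variance (24 each, statistic-major
order: bins 1–8 means, then medians, then variances); CSAC contributes
per-statistic mean and variance (24); textons their per-bin mean (4).
15×6 + 24 + 24 + 24 + 4 = 166. Tables of patient vectors are z-scored
per column before classification or survival analysis; zero-variance
columns map to zero and are flagged.

Intensity and single-channel texture use the L channel of Lab rescaled
to [0, 255]; a and b enter only the 3-channel CSAC block.

## Classification benchmarking

Stratified random splits at the 62:60 train:test proportion (scaled to
the cohort), repeated (default 5×), reporting mean recall, precision and
accuracy of the positive class (first class alphabetically, i.e. AC, by
default). Base learners are scikit-learn's linear SVM, L1 logistic
regression, Gaussian naive Bayes, random forest (200 trees) and a
depth-1-stump adaboost. Two importance rankings are implemented here:
MSVM-RFE (per elimination round, linear SVMs on bootstrap subsamples
score surviving features by summed squared weights; the worst feature —
or worst 20% for speed — is removed; reversed elimination order gives
ranks) and adaboost selection frequency (explicit discrete-adaboost
reweighting loop with stump weak learners, so each round selects exactly
one feature; a stump with zero weighted error absorbs the remaining
rounds, keeping the frequencies summing to the round count).

## Survival analysis

The Cox model `λ(t|x) = λ₀(t) exp(βᵀx)` is fitted through the Breslow
partial log-likelihood (tied event times share one risk-set
denominator). Component-wise likelihood-based boosting proceeds from
β = 0; at each step, for each candidate covariate j, a single Newton
step of the L2-penalized partial likelihood with the current linear
predictor as offset gives the update `δ_j = U_j/(I_j + λ)` (U, I the
componentwise score and information); the covariate with the largest
penalized score statistic `U_j²/(I_j + λ)` — the quadratic improvement
of its update — is committed. Mandatory covariates, when given, are
refit unpenalized each step and never compete. The penalty λ sets the
step size; λ = 9·(#events) is a conventional default (the acceptance
simulations use 5·#events with their stated cohort), and the number of
steps M is chosen by event-stratified 6-fold cross-validation maximizing
the mean held-out partial log-likelihood (computed on the validation
fold alone — equivalently minimizing its negative).

Candidate markers are prescreened by univariate Cox Wald tests,
retaining p ≤ 0.25 by default — a permissive filter that keeps roughly
the expected quarter of pure-noise features while passing any real
signal; the direction is switchable.

Risk scores are the fitted linear predictor `βᵀx`. The discrimination
threshold maximizes the Youden index of the time-dependent ROC at an
evaluation time (median follow-up by default), using the
cumulative/dynamic definition restricted to subjects informative at t:
cases experienced the event by t, controls survive beyond t, and
subjects censored before t are excluded — the definition under which a
perfect anti-concordant score attains AUC 1 and the AUC equals the
case-vs-control pairwise concordance. Low/high groups are compared by
the product-limit estimator and the two-sample log-rank chi-square
(1 df), both implemented directly and cross-checked against lifelines
in the test-suite. Bootstrap stability resamples subjects with
replacement (replicates without events are redrawn), refits the
boosting selection, and reports per-feature selection frequencies. The
multivariate comparison model (clinical covariates ± risk score) is
delegated to lifelines, reporting coefficients, hazard ratios
`exp(coef)`, SEs, Wald p, `AIC = −2ℓ + 2k` and `BIC = −2ℓ + k·log(#events)`.

## Synthetic data: what it emulates and what it does not

The image generator renders elliptical nuclei (radius 8–12 px, axis
ratio up to 1.5) darker than the background (90 vs. 200 gray levels),
with multiplicative smoothed texture inside nuclei (amplitude 30),
1-px boundary softening, additive Gaussian noise (σ = 4), and a fixed
purple-vs-pink channel balance. Overlap is realized geometrically — a
chosen fraction of cells is placed with center distance below the sum
of radii — and resolved to a label partition by nearest generating
center, giving unambiguous ground truth for precision/recall. The
generator does **not** emulate stain variability, out-of-focus blur,
nuclear chromatin structure, stromal textures or imaging artifacts;
passing the synthetic suites demonstrates the correctness and the
geometric robustness of the algorithms, not clinical-grade performance
on slides.

The survival generator draws event times from a Weibull baseline
(shape 1.5, scale 365 days) under the exact proportional-hazards
construction with standard-normal covariates, and calibrates an
independent Weibull censoring time by bisection on the drawn sample to
hit the target censoring fraction. The classification generator shifts
a chosen feature subset by a fixed standardized effect between classes.
Both are pure functions of their spec and seed.

## Problem sizes and numerical choices

The test-suite and `scripts/acceptance.py` run on deliberately modest
problem sizes — 256×256 tiles with 20 nuclei (50 images in the detection
suite, 20 in the script), 12 six-cell tiles for segmentation fidelity,
survival cohorts of n = 200 with p = 50, 100 bootstrap replicates, and
10 (tests) or 5 (script) recovery seeds — chosen so a complete run
finishes in minutes on one CPU while leaving every statistical
conclusion comfortably clear of its threshold. Voting-map correctness
is established by exact (1e-10) agreement with an O(pixels × voters)
double-loop oracle on 48×48 tiles; texture operators by exhaustive
brute-force enumeration on 9×9 patches; partial likelihoods by
hand-expanded formulas (1e-12) and by lifelines (1e-8).

Other numerical decisions: explicit Euler step 0.2 with per-iteration
arc-length resampling; the mean-shift convergence tolerance 1e-3 px;
Newton-Raphson with tolerance 1e-9 for univariate Cox fits; skewness
and kurtosis defined as 0 for constant regions (entropy 0, energy 1);
GLCM correlation defined as 0 at zero variance; SVR defined as 0 for
zero-variance CSAC channels; the axis ratio capped at 100 for
degenerate line-like regions; all-equal per-cell values fall into the
lowest 3-bin histogram bin.

## Known limitations

* The snake's explicit integrator can oscillate at the repulsion
  contact zone; results are returned with a convergence flag rather
  than dampened adaptively.
* Contour rasterization resolves contested pixels by distance to
  sampled boundary points, an approximation at 2-px sampling.
* The detector assumes nuclei darker than background; bright-field
  stains with inverted polarity require inverting the image first.
* No stain normalization or color deconvolution is performed; Lab
  conversion assumes reasonably white-balanced RGB.
* The time-dependent ROC uses the cumulative/dynamic definition without
  censoring-weight correction, so heavily censored cohorts bias the
  AUC toward the uncensored subpopulation.
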