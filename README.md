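# histomarkers

Quantitative image markers for histopathology: from raw H&E-like tiles to
per-patient morphometric profiles and survival prediction. The toolkit was
built around the analysis needs of non-small cell lung cancer (NSCLC)
pathology — separating densely touching tumor nuclei, profiling their
morphology, distinguishing adenocarcinoma from squamous cell carcinoma, and
discovering which image markers carry prognostic signal — but every stage is
generic image/statistics code usable on other tissue.

The pipeline has five stages, each an importable module:

1. **Seed detection** (`histomarkers.detection`) — every boundary pixel of a
   dark nucleus casts votes into a cone opening along its negative gradient
   direction (into the nucleus). Votes are weighted by a Gaussian bump
   `K(x, y; μ, σ²I)` centered a mean radius into the cone and by the
   Euclidean distance map `g_D` of the foreground, summed over multiple
   radial scales `(r_min, r_max)` and normalized:

   `V(x, y) = (1/C₁) Σ_{(m,n)∈S} Σ_c 1[(x,y) ∈ A_c(m,n)] · K(x,y; μ, σ²I) · g_D(x,y)`

   Seeds are the modes of `V`, found by weighted flat-kernel mean shift.
2. **Repulsive balloon-snake segmentation** (`histomarkers.segmentation`) —
   one closed contour `v_i(s)` per seed evolves under internal
   tension/rigidity, an outward pressure force `γ·n(s)`, an image force
   `−λ∇E_ext` with `E_ext = −‖∇I‖²`, and an inverse-square repulsion
   `ω Σ_j ∮ f(d_ij(s,t)) dt` with `f(x) = x⁻²` between points of different
   contours. Repulsion is what keeps touching cells from merging: the
   contour count never changes, so cell topology is preserved.
3. **Morphometric features** (`histomarkers.features`) — 15 per-cell scalar
   descriptors (geometry, Lab-intensity statistics, Haralick co-occurrence)
   plus LBP, TFCM, CSAC and texton texture histograms, aggregated across
   cells into a named 166-entry patient vector (`area1..6`, …, `t1..4`).
4. **Subtype classification** (`histomarkers.classify`) — repeated
   stratified-split benchmarking of five classifiers, plus feature
   importance by stump-adaboost selection frequency and MSVM-RFE backward
   elimination.
5. **Survival analysis** (`histomarkers.survival`) — Cox proportional
   hazards `λ(t|x) = λ₀(t)·exp(βᵀx)` fitted by component-wise
   likelihood-based boosting: each step updates the single coefficient
   maximizing the L2-penalized partial log-likelihood with the current
   linear predictor as an offset, giving a sparse β. Step count by 6-fold
   cross-validation; risk stratification via time-dependent ROC;
   Kaplan-Meier/log-rank comparison; bootstrap selection stability; and
   multivariate Cox reporting with AIC/BIC.

A synthetic-data module (`histomarkers.synthetic`) generates the three
input types with exact ground truth — textured touching-nuclei tiles,
two-class feature cohorts, right-censored Cox-Weibull cohorts — so the
entire pipeline is testable without any slide data.

## Worked example

```bash
python examples/01_detect_nuclei.py
```

```
nuclei in tile : 20
seeds detected : 20
mean distance  : 0.21 px
miss rate      : 0.000
false positives: 0.000
```

Twenty textured nuclei are synthesized with known centers; the voting
detector finds all twenty with sub-pixel mean localization error and no
false positives at the 8-pixel match criterion.

```bash
python examples/05_survival_boosting.py
```

```
cohort: n=200, events=140, censored=60
prescreen: 17 of 50 markers retained
cross-validated boosting steps: M = 50
selected markers and coefficients:
x1     0.4982
x2    -0.3881
x3     0.4589
x4    -0.3947
x5     0.4008
...
time-dependent AUC at t=195: 0.898
log-rank p between risk groups: 1.25e-30
AIC clinical only     : 1286.91
AIC with risk score   : 1092.78
```

The five truly prognostic markers (`x1..x5`) dominate the selected set with
correctly signed, shrunken coefficients; the resulting risk score separates
the cohort into groups with sharply different survival and improves the
multivariate Cox model far beyond clinical covariates alone (AIC drop
≈ 194).

The other examples cover touching-cell segmentation
(`02_segment_touching_cells.py`), the 166-entry patient profile
(`03_patient_features.py`) and classifier benchmarking
(`04_classify_subtypes.py`).

## Command line

Each stage is also exposed as a thin CLI over the library:

```bash
histomarkers simulate --kind image --seed 5 --out-dir sim
histomarkers detect   --image sim/image.png --out seeds.csv
histomarkers segment  --image sim/image.png --seeds seeds.csv \
                      --out mask.png --contours contours.csv
histomarkers features --image sim/image.png --mask mask.png --out features.csv
histomarkers classify --features f.csv --labels l.csv --out report.csv
histomarkers survival --features cohort.csv --steps auto --out-dir out
```

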