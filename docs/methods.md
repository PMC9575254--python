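# Methods

This note documents the models, conventions and numerical choices behind
`pasmri`, in the order data flow through the package.

## 1. Digital phantom (`pasmri.phantom`)

The phantom is a voxel label grid (0 background, 1 placenta, 2 DIB
lesion, 3 myometrium) built from analytic shapes, so every downstream
measurement has exact ground truth.

**Geometry.** The uterine cavity is an ellipsoid; the myometrium is the
shell between the cavity and an outer ellipsoid enlarged by the base
thickness (default 6 mm) and displaced down the z axis, so the shell
thins to a controlled minimum (default 3 mm) at the top pole — the
placental bed, where thinning is clinically expected. The placenta is an
ellipsoid tangent to the cavity wall at that pole; DIB lesions are
axis-aligned ellipsoids placed inside it. "Interruption" is a
spherical-cap hole (default radius 8 mm) punched through the shell at the
pole; the test suite verifies by flood-fill that the interrupted shell no
longer separates the cavity from the exterior. The default grid is a
96 mm cube at 1 mm isotropic spacing — a scaled-down uterus chosen to
keep phantom construction fast; accuracy-critical tests use 0.5 mm
spacing on a 192³ grid.

**Voxelisation convention.** A voxel belongs to a structure iff its
center lies inside the analytic shape; voxel *i* has center
`(i + 0.5) · spacing`. Axis order is (x = sagittal normal, y = coronal
normal, z = axial normal), right-handed, 0-based indices.

**Ground-truth lesion volume.** Pairwise-separated lesions sum
analytically (4/3 π abc). Lesions that may overlap are merged — a reader
outlines visible regions, not constituent shapes — and the union volume
is evaluated on a 0.25 mm reference grid restricted to the union bounding
box (voxel-center rule). At 0.5 mm phantom spacing the voxel-count volume
of an r ≥ 8 mm sphere agrees with the analytic value to < 2%.

**Slicing convention.** Slice *i* of a plane covers
`[i·(t+g), i·(t+g) + t)` along the plane normal (t = thickness, g = gap);
stacks are anchored at grid coordinate 0 with no half-slice offset (the
anchoring is arbitrary in reality; a fixed convention keeps runs
reproducible). Each slice's ROI is the voxel layer containing the slice
**midplane** — the displayed image is taken to represent the center of
the excited slab (central-section convention). A lesion confined to a gap
is invisible; a lesion thicker than one slab appears once per slab. We
deliberately do *not* use the union (maximum cross-section) of the slab:
that convention inflates Cavalieri volumes of convex lesions by
+15–25% at 2.5–5 mm slabs, far beyond the accuracy the estimator is known
to deliver, whereas midplane sampling is unbiased to first order.

## 2. Volumetry (`pasmri.volumetry`)

`plane_volume` implements `V_p = (t_p + g_p) Σ_i S_pi` with areas as
pixel count × pixel area on binary masks (no sub-pixel contour
integration — matching how a PACS reports areas inside closed curves).
Slices with no lesion contribute zero and are retained. `dib_volume`
averages the three orthogonal planes and refuses fewer than three (the
estimator is never rescaled for missing planes). `rater_average` takes
the mean of two readers' per-subject values; since the mean of two errors
is never larger in magnitude than the worse of them, averaging can only
help. Units are mm/mm²/mm³ throughout.

Accuracy at the protocol geometries (verified on spheres and ellipsoids
with all semi-axes ≥ 8 mm): single-plane error ≤ 5% at 2.5 mm slices /
0.5 mm gap; three-plane mean error ≤ 8% at 5 mm / 1 mm. With a 6 mm
period on a ~16 mm lesion a *single* plane can err ~±5–8% purely from
slice alignment; averaging three orthogonal stacks cancels most of it.

## 3. MT grading (`pasmri.grading`)

`compute_l_min` takes the minimum voxel edge (both in-plane edges and the
slice thickness) across all acquired planes — the most conservative
reading of "shortest edge of the MRI voxel"; with a 400 mm FOV on a 256
matrix this gives 1.5625 mm, inside the expected 1.5–2.0 mm band.

Grading: interrupted ⇒ G0; else the arithmetic mean of the repeat
measurements is compared with L_min, with the boundary value graded G2
("≥ L_min" is inclusive). The number of repeats is a parameter
(default 3) since protocols are ambiguous about it. The ordinal coding
G0 = 0 < G1 = 1 < G2 = 2 is fixed package-wide; correlation and ROC code
relies on it.

**Consensus rule.** Real readers negotiate; the package substitutes a
deterministic, symmetric proxy: identical grades pass through; an
interruption seen by either reader dominates (G0); a G1/G2 split is
re-graded on the pooled measurement set (or the mean of the two readers'
means when no pooled set is supplied). This is a stand-in for an
unalgorithmic human step and is labelled as such here.

`measure_thinnest` simulates a reader: truth plus Gaussian reading error
(default sd 0.2 mm). The misgrading probability then has a closed form
(normal tail of the mean of repeats), which the test suite checks by
Monte Carlo.

## 4. Cohort generator (`pasmri.cohort`)

The generator emulates the study conditions of a 75-patient PAS caesarean
cohort. Marginals default to the published counts: invasion depth
15/44/16 (accreta/increta/percreta), MT grade 37/14/24, attachment
position 0/6/6/3/60, zero-DIB probability 19/75, haemostasis probabilities
per group proportional to the published rows (the printed highest-loss
column sums to 25 of 24 patients — presumably a patient with two
procedures; we normalise to probabilities).

**DIB volume**: zero with p = 19/75, else lognormal with log-mean
8.85 + 0.8 · depth and log-sd 1.4 — reproducing the published right-skew
(non-zero median ≈ 15,700 mm³, quartile ratio ≈ 8).

**EBL link**: `log EBL = 6.73 − 0.45·G + 0.105·log1p(V) + 0.08·D + ε`,
ε ~ N(0, 0.24). This is the simplest monotone model consistent with the
reported associations; all coefficients are config-exposed. The defaults
were calibrated once, by grid search at n = 3–5·10⁵, to the study regime:
population Spearman −0.603 (grade vs EBL) and +0.644 (volume vs EBL)
against the reported −0.604 / +0.653, and group shares 0.333/0.349/0.318
against 25/26/24 ÷ 75. Group EBL means fall at ≈ 670/1430/2830 ml versus
the reported 624/1227/2875.

**Transfusion**: RBC units follow a saturating monotone curve of EBL,
`7·(1 − exp(−(EBL−700)/900)) + N(0,1)`, rounded to half units and clipped
at zero — group medians ≈ 0 / 4 / 6.5 units.

**Readers**: reader 2's grade moves one grade with probability 0.18
(kappa ≈ 0.72 regime); both readers' volumes carry multiplicative
lognormal error with log-sd 0.4 (ICC(2,1) ≈ 0.84 regime at n = 75, with
considerable sampling spread — raw-scale ICC of a heavy-tailed quantity
is itself noisy). Zero volumes stay zero for both readers: an absent band
is absent for everyone.

`estimate_ebl` implements haematocrit-dilution accounting,
`fluid · hct_mixture / hct_antenatal + gauze_g / 1.06`; the 1.06 g/ml
blood density and the formula itself are package conventions — source
descriptions list only the ingredients.

The exclusion cascade tallies multi-flag candidates under the first
applicable reason in the published listing order (arbitrary but
deterministic).

**What the generator does not emulate**: real lesion segmentation
variability (reader error is a single multiplicative term, not a spatial
process), correlated covariates beyond the EBL link (grade, volume and
depth are drawn independently), institution effects, or any causal
structure for haemostasis choice. Passing tests therefore demonstrate
that the *pipeline* is correct and calibrated, not that the clinical
effect sizes would replicate in new patients.

## 5. Statistics (`pasmri.stats`)

All statistics are implemented from their formulas; scipy/sklearn/
pingouin/statsmodels appear only as independent oracles in the test
suite (agreement to 1e-8 on statistics, 1e-6 on p-values, ≥ 50 random
instances each).

Choices that were genuinely open:

* **Chi-square**: Yates' correction only on 2×2 tables (clamped at
  zero), never on larger tables. The published 2×2 balloon comparison is
  reproduced only *with* the correction (p = 0.002 vs 0.001 uncorrected),
  so corrected is the default inference for 2×2.
* **Spearman**: mid-ranks for ties; p via the t approximation on n − 2
  df, with an exact permutation p available for n ≤ 10 (evaluated in
  chunks).
* **ROC**: ties grouped at one threshold; trapezoidal AUC, which then
  equals the Mann-Whitney probability with half credit for ties — the
  identity is asserted exactly on random instances. Orientation: higher
  score predicts the event; MT grade is sign-flipped by the caller.
* **Kappa**: unweighted by default (linear/quadratic weights behind a
  flag for ordinal scales).
* **ICC**: ICC(2,1) — two-way random effects, absolute agreement, single
  measure — the standard choice for interchangeable readers; ICC(3,1)
  behind a flag. Zero between-subject variance reports 0 with a note.
* **Kruskal-Wallis**: tie-corrected H, chi-square p with g − 1 df.
* **K-S normality**: parameters estimated from the sample (ddof = 1), so
  the naive asymptotic p is anti-conservative; the default p uses the
  Dallal-Wilkinson closed-form Lilliefors approximation (accurate in the
  rejection region, clipped at 1 elsewhere — never changes a decision at
  conventional α). The naive p remains available for comparison.
* No multiple-testing correction anywhere; every p-value stands alone.

Degenerate inputs: constant samples, one-class labels, zero margins and
single-rater-constant tables are rejected or reported as undefined with
an explanatory note rather than returning a number.

## 6. Study model (`pasmri.study`)

`PASStudy` / `PASStudyResults` follow the model/results convention:
construction binds data and configuration, `fit()` computes everything,
the results object carries its inputs so every reported number can be
recomputed (asserted in tests to 1e-9).

The per-variable presentation follows a normality gate: Lilliefors-
corrected K-S at α = 0.05 on the pooled variable decides mean ± sd +
ANOVA versus median (Q1, Q3) + Kruskal-Wallis; quartiles use linear
interpolation (numpy's default — conventions differ between packages, so
the rule is fixed and documented). ROC events are EBL ≥ 1000 and
≥ 2000 ml. A group with fewer than two patients skips the between-group
test with a note; all other blocks still run. The distribution figure
shows both box summaries and jittered per-patient points.

CSV/JSON reports are deterministically formatted (fixed float formats,
sorted keys): re-running with the same cohort is byte-identical.

## 7. Problem sizes

Defaults keep the full test suite under ~1 minute on one CPU: phantoms at
1 mm (96³) except accuracy tests at 0.5 mm (192³) with a 0.25 mm
reference grid for union volumes; oracle cross-checks at 50 instances per
statistic; calibration checks at 200 cohorts of n = 75 plus single large
cohorts (n = 10⁴ for coefficient recovery, 1.2–2·10⁵ for population
Spearman values). These sizes were chosen as the smallest that leave
Monte-Carlo error well below the tolerances being asserted.

## 8. Known limitations

* Masks only — no MR contrast, noise, motion or bias fields; "detection"
  of a lesion is purely geometric.
* Axis-aligned ellipsoidal lesions; no irregular or banded shapes.
* The myometrial minimum thickness is controlled at one pole; thickness
  elsewhere is not calibrated.
* The consensus rule is a proxy for human negotiation.
* ICC on raw volumes is heavy-tail sensitive; at n = 75 its sampling
  spread is wide (roughly ±0.05–0.10 around the regime value).
* The generator's independence assumptions (grade ⊥ volume ⊥ depth) are
  a simplification; real cohorts likely correlate all three.
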