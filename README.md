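# pasmri

Quantitative MRI features for predicting postpartum haemorrhage in
placenta accreta spectrum (PAS) pregnancies — implemented as a fully
testable pipeline driven by digital phantoms and synthetic cohorts.

## The problem

In PAS the chorion invades the myometrium, and blood loss at caesarean
section ranges from routine to life-threatening. Two preoperative MRI
features carry most of the predictive signal:

* **Myometrial thickness (MT) grade.** The myometrium over the placental
  bed is measured at its thinnest site and graded against L_min, the
  shortest edge length of the MRI voxel (1.5–2.0 mm for typical placental
  protocols): `G0` — focal interruption; `G1` — continuous but thinner
  than L_min; `G2` — at or above L_min. Thinner myometrium ⇒ more
  bleeding, so the grade correlates *negatively* with blood loss.
* **Dark intraplacental band (DIB) volume.** Low-signal fibrin-rich
  bands are outlined on each plane of a T2-weighted acquisition; the
  volume follows the gap-aware Cavalieri estimator

  ```
  V_p   = (thickness_p + gap_p) · Σ_i S_pi
  V_DIB = (V_axial + V_sagittal + V_coronal) / 3
  ```

  with `S_pi` the outlined area of slice *i* on plane *p*, and the final
  value the mean over two independent readers. Larger DIB volume ⇒ more
  bleeding.

Patients are stratified by estimated blood loss (EBL, from aspirator
fluid via haematocrit dilution plus weighed gauze) into GBL (< 1000 ml),
MBL (1000–< 2000 ml) and ex-MBL (≥ 2000 ml). The analysis asks how well
grade and volume predict the ≥ 1000 ml and ≥ 2000 ml events (ROC/AUC),
how strongly they track EBL (Spearman), and how reproducible the
measurements are across readers (Cohen's kappa, ICC(2,1)).

Patient-level data for this kind of study are not public, so the package
ships two synthetic test beds with exact ground truth: 3-D uterus/placenta
phantoms (for the measurement chain) and a calibrated cohort generator
(for the statistics chain). Every statistic is implemented from its
formula and cross-checked against an independent reference implementation
in the test suite.

## Worked example

```python
from pasmri import stats
from pasmri import reference_tables as ref
from pasmri.study import PASStudy

# 1. published aggregate tables analysed exactly
r = stats.chi_square(ref.ATTACHMENT_BY_GROUP)
print(f"attachment x group: chi2={r.statistic:.3f}, df={r.df}, p={r.p_value:.3f}")
r = stats.chi_square(ref.BALLOON_EXMBL_VS_REST, continuity_correction=True)
print(f"balloon occlusion (Yates): chi2={r.statistic:.3f}, p={r.p_value:.3f}")

# 2. a full synthetic study
res = PASStudy.from_simulation(seed=7).fit()
print(res.summary())
```

prints

```
attachment x group: chi2=10.604, df=6, p=0.101
balloon occlusion (Yates): chi2=9.516, p=0.002
```

— the placental attachment position does not differ between blood-loss
groups (p = 0.101), while prophylactic balloon occlusion is used more in
the highest-loss group (p = 0.002). The fitted study summary then reports,
for this seed, ρ = −0.662 (MT grade vs EBL), ρ = +0.724 (DIB volume vs
EBL), AUCs of 0.852 / 0.815 for predicting EBL ≥ 2000 ml from grade and
volume, two-reader kappa 0.719 and ICC(2,1) 0.863 — a single-cohort draw
from the calibrated generator (population values ρ ≈ −0.60 / +0.65).

The same pipeline is scriptable from the shell:

```
pas-mri run --out results/ --seed 7        # cohort + full report
pas-mri phantom --out ph.nii --seed 1      # digital phantom with ground truth
pas-mri cohort --out cohort.csv --seed 7   # cohort table only
```

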