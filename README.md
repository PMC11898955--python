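# prostaspec

Spectral/statistical assessment of prostate tumors on biparametric MRI
(BP-MRI), for researchers who want a transparent, fully quantitative
alternative — or complement — to deep-learning lesion detectors.

Instead of spatial textures, the method treats each voxel of a spatially
registered (ADC, high b-value, T2) image cube as a 3-band *spectrum* `x`,
borrowing target-detection machinery from hyperspectral remote sensing:

- **Background model.** Normal prostate voxels inside an expert-drawn mask
  are modelled as Gaussian with mean `m` and covariance `CM`, optionally
  conditioned by principal-component filtering (eigen pseudo-inverse over
  the leading components) or shrinkage regularization
  `CM(γ) = (1−γ)·CM + γ·T` with a scaled-identity or `diag(CM)` target.
- **Contrast scores.** Per-band z-score `z_b = (S_b − m_b)/σ_b` (RMS
  combined) and the signal-to-clutter ratio
  `SCR = (S − m)ᵀ CM⁻¹ (S − m)`, where `S` is the in-scene tumor
  signature.
- **Detection.** The adaptive cosine estimator
  `ACE(x) = [(x−m)ᵀCM⁻¹(S−m)]² / ([(x−m)ᵀCM⁻¹(x−m)]·[(S−m)ᵀCM⁻¹(S−m)])`,
  the squared cosine between whitened voxel and whitened signature,
  thresholded at 0.9.
- **Morphometrics.** Connected components ("blobs", 26-connectivity,
  ≥ 5 voxels) of the thresholded map; per blob the volume in mL and the
  eccentricity `E = (l − s)/l` from the square roots of the two leading
  eigenvalues of the voxel-coordinate scatter matrix (0 = sphere,
  1 = line).
- **Statistics.** Univariate/multivariate OLS of features against ISUP
  grade (R, F-test p, coefficient CIs), Pearson cross-correlations, and
  logistic regression against clinical significance (CsPCa ⇔ ISUP ≥ 2)
  over 1000 seeded stratified train/test splits, summarized by the
  2.5–97.5 percentile AUROC interval. AI likelihoods can be calibrated to
  a continuous ISUP grade piecewise-linearly through (0, 0), (0.5, 2),
  (1, 5) or via `ISUP = c·atanh(p)`, `c = 2/atanh(0.5) ≈ 3.6409`.

Because the clinical cohorts this pipeline targets are access-controlled,
the package ships a first-class synthetic-cohort generator: ellipsoidal
prostates filled with correlated Gaussian tissue, planted ellipsoidal
tumors whose contrast, volume and eccentricity follow grade-conditional
models, per-sequence grids that genuinely exercise registration, and
surrogate AI likelihoods/detection maps. See `docs/methods.md`.

## Worked example

```python
from prostaspec import SyntheticCohortSpec, generate_cohort, univariate_fit
from prostaspec.cli import PipelineConfig, features_for_cohort

cohort = generate_cohort(SyntheticCohortSpec(n_patients=50, seed=11))
table, failures = features_for_cohort(cohort, PipelineConfig())
for col in ("scr", "total_volume", "ecc_largest"):
    fit = univariate_fit(table[col], table["isup"])
    print(f"{col:>14}: r = {fit.r_signed:+.3f}, p = {fit.p_value:.3g}")
```

prints

```
           scr: r = +0.923, p = 1.4e-21
  total_volume: r = +0.971, p = 2.37e-31
   ecc_largest: r = -0.369, p = 0.00844
```

i.e. on a 50-patient phantom cohort the whitened tumor contrast and the
detected tumor volume rise strongly with grade, and lesion eccentricity
shows the moderate anti-correlation with grade expected of adenocarcinomas
(higher-grade lesions are more spherical).

The same analysis runs from the shell:

```sh
prostaspec simulate --out cohort/ --n-patients 50 --seed 11
prostaspec features --cohort cohort/ --out out/
prostaspec fit --features out/features.csv --out out/
```

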