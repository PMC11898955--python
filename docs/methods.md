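# Methods

## The model

Each patient's BP-MRI exam is reduced to a registered 4D lattice
`voxels[row, column, slice, band]` with bands fixed as (ADC, HBV, T2) —
the red/green/blue assignment of the usual colour composite.  Registration
is intentionally minimal: every sequence is resampled (trilinear; nearest
neighbour for masks) to the coarsest transverse spacing among the three,
header-origin differences are rounded to whole voxels and applied as
integer translations (plus optional per-sequence manual shifts), and all
sequences are cropped to the intersection of their fields of view.
Sub-voxel and deformable registration are out of scope; voxel indices are
0-based, crop windows half-open, and the world coordinate of a voxel
centre is `origin + index × spacing` (mm).

Normal prostate tissue inside the expert outline is modelled as a 3-band
Gaussian `N(m, CM)`, `CM` estimated with the unbiased (n−1) sample
covariance from at least 30 mask voxels (an estimation-stability floor).
Three conditioned variants of `CM⁻¹` feed the detector statistics:

* **raw** — ordinary inverse;
* **pc_filtered** — eigen pseudo-inverse over the 3−k leading principal
  components, `Σ λ_i⁻¹ v_i v_iᵀ`; removing low-eigenvalue components
  suppresses noise amplification in the inversion;
* **regularized / modified_regularized** — shrinkage
  `CM(γ) = (1−γ)CM + γT` with `T = (trace CM/3)·I` (trace-preserving) or
  `T = diag(CM)`.  The weight γ is grid-searched over {0, 0.05, …, 1}
  by exact leave-one-out Gaussian negative log-likelihood of the mask
  voxels (rank-one downdates give each held-out voxel's mean and
  covariance in closed form; with fewer than 4 voxels the in-sample
  likelihood is scored instead, which forces γ > 0 for singular samples).
  Leave-one-out likelihood is the standard selection criterion in the
  regularized-discriminant literature; the selection is deterministic and
  ties break toward the smallest γ.

Scores follow the remote-sensing formulation.  The z-score is per-band
contrast over per-band σ, combined by root-mean-square (sign-insensitive,
because tumor contrast has opposite signs across bands: ADC low, HBV
high, T2 low).  The SCR is the Mahalanobis quadratic form of the
signature contrast under the selected variant's effective inverse,
reported as the quadratic form itself.  The ACE score is the squared
cosine of the whitened angle between voxel and signature; voxels with
`x = m` score 0 by convention, and the detection map uses the same
covariance variant as the SCR within a run.

Blob analysis thresholds the ACE map at τ = 0.9 (boundary inclusive),
labels 26-connected components (6/18 available for sensitivity checks;
labels run in raster order of each component's first voxel), and discards
components under 5 voxels.  Volume is voxel count × voxel volume (mL).
Eccentricity derives from the second-central-moment matrix of voxel-centre
coordinates in mm: with eigenvalues λ1 ≥ λ2 ≥ λ3, the axis lengths are
`l = √λ1`, `s = √λ2` and `E = (l − s)/l`, which maps a ball to 0 and a
line to 1; single-voxel blobs have undefined (missing) eccentricity.
Per-patient aggregates are blob count, max/average/total volume, the
eccentricity of the largest-volume blob (ties to the smallest label), the
unweighted mean eccentricity, and a voxel-count-weighted mean.  An
externally supplied AI detection map runs through the identical chain.

One modelling choice deserves emphasis: **lesion search is confined to the
gland** (the hole-filled normal-tissue outline).  Under the Gaussian
background the whitened voxel direction is uniform on the sphere, so the
ACE tail `P(score > 0.9) = 1 − √0.9 ≈ 5.1%` per voxel *independently of
the signature*; outside the gland the tissue direction is nearly constant
and can cross the cone threshold wholesale.  Restricting to the gland is
also what outlining the prostate means operationally.  The residual ~5%
in-gland salt survives only as scattered clusters mostly below the 5-voxel
floor.

The statistical layer excludes missing values pairwise (patients with no
surviving blob have missing eccentricities, never zeros).  Univariate OLS
reports signed Pearson r and the two-sided F-test p (equivalent to the
slope t-test); multivariate OLS reports the multiple correlation R of
fitted vs observed, the overall F-test p, and per-coefficient 95% CIs.
Logistic fits to CsPCa use unpenalized maximum likelihood with a tiny
ridge fallback for separable training sets (the AUROC is rank-based and
insensitive to coefficient scale); each of the default 1000 iterations
draws a seeded stratified 70/30 train/test split (fraction configurable —
the split protocol preserves the heavy class imbalance of a screening
cohort), and the 2.5th/97.5th percentiles of the test AUROCs form the 95%
interval.  Splits leaving a class empty are redrawn a bounded number of
times, then skipped with a logged count.  All randomness fans out from
one root seed via `numpy.random.SeedSequence`, so every output is
bit-reproducible from (config, seed).

Likelihood→grade calibration uses the three anchors (0, 0), (0.5, 2),
(1, 5): piecewise-linear (slope 4 then 6) or `c·atanh(p)` with
`c = 2/atanh(0.5) = 3.640957…` (the commonly printed 3.6409 is this value
truncated at four decimals).  Since atanh diverges at p → 1 while the
grade scale is bounded, the atanh map is capped at grade 5, reached at
`p = tanh(5/c) ≈ 0.8808`.  Inferred grades stay continuous for
regression.

## The synthetic cohort

The generator emulates the *structure* of a PI-CAI-style biopsy cohort,
not its images.  Defaults (the study conditions): 42 patients; grades
drawn from a histogram skewed low ({0: .31, 1: .43, 2: .10, 3: .07,
4: .05, 5: .04}; mean ≈ 1.2, ~74% clinically insignificant, echoing a
cohort with mean grade 1.12 and 31/42 insignificant cases); an
ellipsoidal gland with semi-axes (30, 24, 20) mm (≈ 60 mL, the typical
mean gland volume); background mean (1200, 150, 500) a.u. with per-band σ
(100, 20, 60) and inter-band correlations (−0.45, 0.35, −0.25) giving the
ADC/HBV anti-correlation real diffusion data shows.  ADC/HBV sit on a
2×2×3 mm grid, T2 on 0.5×0.5×3 mm, and HBV's origin is offset by one
voxel, so cube assembly genuinely resamples, translates, and crops.

Patients with grade ≥ 1 carry one ellipsoidal tumor (configurably more)
with grade-conditional linear models: spectral shift
(3.0 + 0.4·(g−1) ± 0.15) σ-units along (−ADC, +HBV, −T2); volume
(0.8 + 0.7·g ± 0.2) mL; eccentricity (0.68 − 0.08·g ± 0.05), anti-
correlated with grade as adenocarcinoma morphology suggests.  The
eccentricity draw is capped so the major axis stays within 70% of the
smallest gland semi-axis — thinner lesions would rasterize to 1–2-voxel
needles whose measured moments no longer reflect the planted shape — and
the lesion centre is jittered ±3 mm so lesions remain strictly interior,
which keeps the gland outline hole-fillable.  The written mask is the
normal-tissue outline (gland minus tumor), as an expert would outline
"normal prostate" for covariance estimation; including lesion voxels
would inflate the background covariance along the signature direction and
destroy the SCR–grade relationship the cohort plants.

Surrogate AI outputs: a per-patient likelihood `σ(0.9·(g−2) + ε)`,
ε ~ N(0, 0.5²), anchoring grade 2 near 0.5; and a detection map equal to
the ground-truth lesion mask at score 0.95, optionally perturbed by one
dilation/erosion round and a one-voxel shift to mimic an imperfect
detector.

What the phantoms deliberately omit: MRI physics (bias fields, Rician
noise, partial-volume gradients), zonal anatomy, multi-focal disease by
default, non-Gaussian tissue texture, and sub-voxel misregistration.
Passing tests therefore demonstrate that the *pipeline* recovers planted
effects under its own model assumptions, not that the method attains any
particular performance on clinical data.

## Problem sizes and numerical choices

Tests and examples use 32³–48²×20 voxel grids and cohorts of 8–50
patients, with end-to-end recovery checked over 20 root seeds; these sizes
keep a full suite run comfortably on one CPU while leaving every stage's
statistics meaningful.  Symmetry of covariance matrices is enforced to
1e-10 and eigendecompositions are recomputed after every covariance
transformation.  ACE outputs are clipped to [0, 1] only against
floating-point overshoot.  Degenerate cases are contracts, not crashes:
constant backgrounds flag singularity; an all-principal-component filter,
a signature equal to the background mean, a single-class outcome, and
collinear predictors each raise typed errors; the pipeline records
per-patient failures in a manifest and continues.

## Known limitations

Registration is integer-voxel only and trusts header geometry.  The
background model is global (no peripheral/transition-zone split).  The γ
criterion is a reasonable stand-in where the literature leaves the
discriminant unspecified; other choices (e.g. Ledoit–Wolf) would select
similar weights for well-conditioned samples but are not implemented.
Blob analysis is volumetric; per-slice (2D) labeling is available via the
connectivity option but untested against clinical conventions.  The
eccentricity uses square roots of moment eigenvalues; a variant using the
eigenvalues directly shares the 0/1 endpoints but differs in between.
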