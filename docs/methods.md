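# Methods

## Model and rationale

The package estimates stimulus-driven coupling between cortical
networks and thalamic voxels in subjects exposed to the same
time-locked naturalistic stimulus.  Within-subject functional
connectivity mixes three sources — stimulus-induced responses,
intrinsic neural dynamics, and non-neuronal artefacts.  Correlating a
seed time course from one subject with target time courses from
*different* subjects removes the last two, because they are
statistically independent across brains; only the stimulus-locked
component is shared.  That is the inter-subject functional correlation
(ISFC); inter-subject correlation (ISC) is its same-region special
case.

Subjects are analysed in age bins so that leave-one-out averaging pairs
each subject with age peers: subject *i*'s K×V matrix averages the n−1
Pearson matrices of *i*'s network seeds against each other member's
thalamic voxels, then is Fisher z-transformed.  The direction is
deliberately asymmetric (seeds from *i*, targets from the others), as
the averaging is defined per seed subject; a `symmetrize` flag averages
both directions for sensitivity analyses.

Group inference proceeds in two stages on the z scale:

1. **Analysis mask** — a two-sided one-sample *t* per edge over all
   subjects (pooled across bins), BH-FDR at q = 0.05 across the full
   K×V family.  Only masked edges are modelled further.
2. **Edge-wise GLMs** — ordinary least squares of z on
   `[1, age_c, age_c², sex, education, mFD, volume]` (age model) and
   `[1, behavior, sex, education, mFD, volume]` (behaviour model).
   Behaviour gets its own model because age and fluid intelligence are
   strongly collinear.  T statistics for the age terms and the
   behaviour slope are BH-corrected per (network, coefficient) family
   by default — each network's thalamic map carries its own corrected
   threshold — with a `global` scope available.  Covariate coefficients
   are reported unadjusted.

Rejected voxels are grouped into connected components on the integer
voxel grid (face adjacency by default; 18/26 by flag), positive and
negative effects separately, and components smaller than 23 voxels are
discarded.  Split-half validation redraws ⌊n/2⌋ subjects (seeded),
re-runs binning → ISFC → mask → GLM on the half, and reports the
fraction of full-run rejected edges whose half-run coefficient sign
agrees.

## Preprocessing

The temporal chain, in fixed order: trim 5 initial volumes → framewise
displacement (Power formulation, rotations converted on a 50 mm sphere;
no radius is standard-free, 50 mm is the scrubbing convention) with
censoring at FD > 0.5 mm → linear detrend → zero-phase band-pass
0.01–0.08 Hz (second-order Butterworth run forward and backward, so the
effective order is doubled) → OLS regression of the 12 motion
parameters (6 + backward differences) and optional WM/CSF channels.
Nuisance regressors are filtered identically to the data first so the
projection cannot reintroduce out-of-band variance.  Boundary
conventions are strict inequalities throughout (a frame at FD = 0.5 mm
is retained; a subject at exactly 2.5 mm translation is kept).
Censored frames are masked rather than deleted: ISFC pairs frames
across subjects, so indices must stay aligned; each subject pair
correlates over the intersection of the two masks, and fewer than 10
joint frames is an error.  The FD-based rule is frame-level censoring;
an `mfd_exclusion` option instead drops whole subjects above an mFD
cut, for cohorts where that reading is preferred.

Subject-level exclusion uses max |translation| > 2.5 mm or max
|rotation| > 2.5°.  Spatial preprocessing (realignment estimation,
normalisation, smoothing, segmentation) is out of scope; the package
consumes its outputs (motion parameters, voxel series, masks,
parcellation labels).

## Synthetic generator

Each network seed and thalamic voxel is a unit-variance mixture

    y_k = sqrt(c_k)·s_k + sqrt(b)·g_i + sqrt(1−c_k−b)·ε
    x_v = sqrt(a_v(age))·s_{k(v)} + sqrt(b)·g_i + sqrt(1−a_v−b)·η

with s_k the stimulus signals shared by all subjects, g_i a
subject-specific intrinsic signal, and ε, η white noise.  Expected
cross-subject correlation at a coupled edge is sqrt(c_k·a_v(age_j)),
zero elsewhere — the closed-form oracle every ISFC test uses.  Voxel
coupling is a clipped quadratic in standardised age
u = (age − 52)/17, so linear declines and concave profiles (and nulls)
are all expressible; clipping keeps a_v in [0, 0.95] and the variance
budget requires c + b < 1 and a + b < 1.

Stimulus signals are white Gaussian and independent per network — this
makes the closed form exact and cross-network expected ISFC zero; an
AR(1) flag adds temporal smoothness for realism but defaults off, since
the movie-evoked signal's spectral content is a modelling choice, not a
measured property.  Voxels are assigned to networks in contiguous
blocks (compact territories under the C-order grid coordinates), so
planted effects form spatial clusters the extent filter can see.
Defaults mirror the study conditions being emulated: 17 networks × 620
voxels, T = 193 retained frames at TR 2.47 s (8 min 13 s minus 5
trimmed volumes), ages uniform over 18–87, fluid intelligence
43.2 − 0.23·age plus N(0, 5.4²) noise clipped to the 0–46 Cattell
range (reproducing the observed ≈ −0.65 age–FI correlation and the
group means of a lifespan cohort), education ≈ N(20.6, 3.5²) years,
brain volume ≈ N(1.4×10⁶, (1.2×10⁵)²) mm³.  Ages are uniform rather
than matched to any published group sizes because uniform coverage
strengthens effect-recovery tests.  Motion is a Gaussian random walk
(0.02 mm / 4×10⁻⁴ rad steps) with optional planted spikes; WM/CSF are
white-noise channels.  One global seed is expanded into per-stage,
per-subject streams via `SeedSequence` spawn keys, so any stage can be
regenerated in isolation.

What the generator does **not** emulate: hemodynamics, physiological
noise spectra, spatial autocorrelation, anatomy.  Passing tests
therefore demonstrate the statistical machinery — estimator
correctness, error control, recovery power under the stated SNR — not
robustness to those real-data complications.

## Numerical choices

- Fisher transform clips |r| at 1 − 10⁻⁷ before atanh so degenerate
  identical-data cases stay finite.
- Zero-variance columns yield missing pairwise entries; a subject's
  average skips them with count tracking, and edges missing in > 20 %
  of subjects are dropped from the mask with a logged count.
- A zero-variance edge with nonzero mean is an exact effect (p = 0);
  with zero mean it is excluded.
- Age is centred at the sample mean before squaring, which largely
  decorrelates the linear and quadratic regressors; the centring
  constant is recorded.  Note the consequence: a "purely quadratic"
  ground-truth profile is one that is even about the *design's*
  centring age — a profile centred elsewhere genuinely contains a small
  linear component, which a large cohort will detect.
- Cluster labels are ordered by minimum coordinate (lexicographic) for
  determinism; statistics TSVs are written with fixed float formatting
  so identical config + seed reproduces files byte for byte.
- GLM edges with non-finite values drop subjects pairwise (logged);
  residual degrees of freedom below 10 is an error.

## Validation design

The validation quantities (test suite and `scripts/acceptance.py`) are
measured at the sizes stated in their docstrings — e.g. closed-form
agreement at n = 20 / T = 2000, null FDR over 100 cohorts of 70
subjects, effect recovery over cohorts of 140 subjects at T = 193,
split-half concordance at n = 200.  Rejection-rate quantities are
averaged over repeated simulated cohorts because the false-discovery
rate is an expectation: under BH with the positively dependent edges
this design produces (subjects in the same age bin share leave-one-out
pairs), single-cohort false-rejection proportions are bursty — usually
zero, occasionally large — while the mean respects the nominal level.
Where a bound on such an expectation is asserted from a finite Monte
Carlo sample, the estimate carries a two-standard-error allowance.

## Known limitations

- Group-structured residual correlation (shared pairs within a bin)
  mildly inflates single-cohort GLM t statistics; inference is
  edge-wise OLS, as in the emulated design, not a mixed model.
- Cross-network edges are exactly null only in expectation over
  stimulus realisations; any finite stimulus sample induces a small
  shared correlation between network signals, so with one fixed movie
  those edges can legitimately enter the analysis mask — and, when the
  voxel carries an age effect, show a scaled age trend.
- Real-data mode expects preprocessed, spatially normalised inputs;
  no volume registration or segmentation is performed.
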