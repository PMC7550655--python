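# Methods

`ivimr2` implements the quantitative-MRI analysis chain used to evaluate
treatment response in a four-arm tumor xenograft study: voxelwise IVIM
(intravoxel incoherent motion) diffusion modelling, R2* relaxometry,
caliper volumetrics with inhibition rates, and the longitudinal group
statistics, all exercised on synthetic phantoms and study tables.

## Signal models

**IVIM.** Diffusion-weighted signal over b-values (s/mm²) follows the
bi-exponential

S(b) = S₀ · [(1 − f)·exp(−b·D) + f·exp(−b·D\*)],

with true diffusion coefficient D (mm²/s, restricted by cellularity),
pseudo-diffusion coefficient D\* (mm²/s, capillary blood motion, with
D\* > D for identifiability), and perfusion fraction f ∈ [0, 1]. The
default acquisition is the 13-b-value schedule 0, 25, 50, 75, 100, 150,
200, 400, 600, 800, 1000, 1200, 1500 s/mm².

**R2\*.** Multi-echo gradient-echo magnitude decays mono-exponentially,
S(TE) = S₀·exp(−R2\*·TE), with R2\* in 1/s an effective transverse
relaxation rate elevated by deoxyhemoglobin (hypoxia surrogate). The
default schedule is 16 echoes from 3.4 to 92.1 ms (TR 160 ms carried as
metadata only). Echo times are declared in ms; the single ms→s factor
lives in `acquisition.MS_PER_S`. D and D\* are stored in mm²/s and only
converted to the display unit 10⁻³ mm²/s (and f to %) at formatting
time.

## Segmented IVIM fitting

The four-parameter joint fit is ill-conditioned, so estimation is
segmented with a boundary of 200 s/mm² (b ≥ 200 counts as high-b, which
gives 7 of 13 points to the diffusion segment):

1. **Diffusion step.** Least squares of ln S on b over the high-b
   segment: D = −slope, intercept ≈ ln[S₀(1 − f)]. Non-positive signals
   are dropped with a warning; a constant signal yields D = 0.
2. **Perfusion step.** Bounded nonlinear least squares
   (`scipy.optimize.least_squares`, trust-region reflective) of the full
   bi-exponential over all b-values with D held fixed, estimating S₀,
   f ∈ [0, 1] and D\* ∈ [D, 0.5] mm²/s. Initial values: f₀ from the
   high-b intercept (clipped to [0.01, 0.5]), D\*₀ = 10·D. A variant
   restricted to the low-b segment only is available
   (`FitConfig(step2_all_b=False)`).
3. **Refinement.** With this schedule the perfusion compartment still
   contributes a few percent of the signal at b = 200–400, biasing the
   step-1 slope by about +4% at tumor-baseline parameters, which in turn
   biases D\* and f. The fitted perfusion compartment
   S₀·f·exp(−b·D\*) is therefore subtracted from the high-b signal and D
   re-estimated by signal-weighted log-linear least squares (signal
   weighting on the log scale is the Gauss–Newton linearization of the
   exponential fit, i.e. the efficient weighting for additive
   constant-variance noise), after which the perfusion step is repeated.
   Two refinement rounds are the default (`FitConfig(n_refine=2)`).

At **map level** the refinement subtracts the perfusion compartment
scaled by the ROI-median f and D\* instead of each voxel's own
estimates. D\* is the notoriously unstable IVIM parameter; using its
robust ROI median decontaminates the diffusion segment without
propagating per-voxel perfusion noise into D. For a single-voxel mask
the median is the voxel's own estimate and the map fit reduces exactly
to the voxel fit. On the default phantom this brings the noiseless
ROI-mean D error under 1% while keeping the SNR-50 median relative
error of D under 5%; per-voxel de-biasing alternatives (iterated
self-correction, parametric bias subtraction, narrow-band joint fits)
were all found to inject 2–3% extra noise into D and were rejected.

Degenerate inputs: an all-zero voxel or a high-b segment with fewer
than two positive points returns a flagged failure result rather than
raising; estimates violating the parameter invariants mark the voxel
unconverged. Reported rss is always on the full b schedule.

## R2* fitting

Voxelwise least squares of ln S on TE; R2\* = −slope (converted to
1/s), S₀ = exp(intercept); negative slopes are clamped to R2\* = 0 and
flagged. The default uses SI²-weighted least squares on the log scale
(see above for the rationale; plain OLS via `R2starConfig(weighted=False)`).
Echoes at or below a noise floor of 3·σ_bg are excluded before the log
transform, because at R2\* ≈ 25 /s the TE ≈ 92 ms echo sits near the
Rician floor and would bias the slope; σ_bg can be given (it is known
in simulation) or estimated from the corner background patches of the
volume, with a guard that disables the floor when the "background"
clearly contains tissue signal. A `max_echoes` option truncates the
echo train, since vendor tools differ on whether all 16 echoes enter
the fit.

## Synthetic phantoms

`PhantomSpec` places an ellipsoidal tumor (default 656 voxels ≈ the
largest-cross-section ROI scale) in an 18×18×8 tissue background. Each
region's parameters are drawn voxelwise from Normal(mean, SD), redrawn
up to 100 times into their physical ranges (f ∈ [0, 1], D\* > D) and
then clamped with a warning. Tumor means default to the reference
study's baseline ROI values — D = 0.556·10⁻³ mm²/s,
D\* = 8.53·10⁻³ mm²/s, f = 16.75%, R2\* = 24.74 /s — with the
between-animal baseline SDs reused as a realistic voxelwise
heterogeneity scale; the background is muscle-like (D = 1.4·10⁻³ mm²/s,
f = 5%, R2\* = 30 /s). Noise is Rician —
√((s+ε₁)² + ε₂²), ε ~ N(0, σ²) — with σ defaulting to S₀/50 (b = 0
tumor SNR 50, typical preclinical DWI). All generators are pure
functions of (spec, seed); the seed expands into named per-component
substreams (truth vs noise, IVIM vs GRE) via `numpy.random.SeedSequence`
so enabling noise never shifts the truth draws. The phantom emulates
region-scale parameter contrast and magnitude noise only: no partial
volume, motion, EPI distortion, or anatomically realistic geometry, so
recovery results bound estimator behaviour, not scanner behaviour.

## Synthetic study tables

`StudyDesign` carries per-cell Normal targets (mean ± SD, n = 8) for
each quantity × group × time point; the packaged reference cells are the
defaults. Quantities are drawn independently per animal (the published
tables report no covariance, so none is imposed — within-animal
correlation over time and between quantities is absent by construction,
which makes the end-to-end pattern test conservative about nothing but
the means and SDs). Draws are redrawn/clamped into physical ranges
(volumes positive, percentages in [0, 100]).

## Statistics

* One-way fixed-effects ANOVA, both on raw samples and reconstructed
  from summary cells (SS_between from n-weighted means, MS_within by
  pooling (nᵢ−1)·sᵢ²) — the latter lets the published F statistics be
  recomputed from printed mean ± SD alone, and agrees exactly with the
  raw-sample ANOVA when the cells come from data. Zero within-variance
  with unequal means reports F = ∞, flagged.
* ANOVA across time points treats repeated measures on the same animals
  as independent groups. That mirrors the screening practice the
  reference tables embody and is kept deliberately; it is a statistical
  caveat, not an oversight.
* Student–Newman–Keuls post hoc: means rank-ordered, pairs spanning r
  means compared against studentized-range quantiles q(α, r, df_within)
  computed from `scipy.stats.studentized_range` (cached; no hard-coded
  table), stepping from the widest span inward with the standard
  protection rule (pairs inside a non-rejected span are not tested).
  Unequal n uses the harmonic-mean standard error; tied means keep
  stable input order.
* Normality screening: Kolmogorov–Smirnov with parameters estimated
  from the sample, i.e. Lilliefors-corrected p (statsmodels); testing
  against a fully specified normal would be anti-conservative.
* Pearson correlation with the study's strength labels: |r| > 0.8 high,
  0.5–0.8 moderate, otherwise weak.

## Reproduction of the printed tables

`reproduce_tables()` recomputes all 24 published F statistics from the
packaged cells plus the three week-3 inhibition rates
((V_A − V_g)/V_A·100 on the week-3 volume means; formula
V = a²·b·0.5 on caliper diameters). Recomputed F values differ from
printed ones only through display rounding of the inputs; for the
low-F rows, where that rounding propagates to more than 1%, the report
checks that the printed F lies inside the interval of F values
attainable when every printed mean and SD hides ±½ unit in its last
printed place (Monte-Carlo over uniform perturbations). Well-conditioned
rows agree within 1%; inhibition rates match exactly at one decimal.

## Problem sizes and numerical defaults

Default problem sizes (656 phantom voxels, 2000 null-ANOVA replicates,
100 study replicates, 2000–4000 rounding-interval draws) were chosen so
every sampling error is small against the margins being tested while a
full run stays interactive. Optimizer tolerances are 1e-10
(xtol/ftol/gtol); the D\* upper bound of 0.5 mm²/s is generous against
physiology; NaN is the missing-value sentinel in all maps.

## Known limitations

* Segmented fitting is not globally optimal in (S₀, D, D\*, f); the
  tests assert step-2 optimality and agreement with an exhaustive
  D\*×f lattice oracle instead.
* D\* recovery at SNR 50 has ~16–18% median relative error — inherent
  to voxelwise IVIM at this schedule, not an implementation artifact.
* The study simulator reproduces first and second moments per cell
  only; correlations computed from it reflect between-group structure,
  not within-animal physiology.
* Caliper volumes and MRI ROIs are treated as independent measurements;
  3D MRI volumetry and automated segmentation are out of scope.
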