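# ivimr2

Quantitative-MRI analysis of tumor treatment response: segmented
bi-exponential IVIM-DWI fitting, multi-echo R2\* relaxometry, caliper
tumor volumetrics, and the longitudinal group statistics of a four-arm
xenograft study — with synthetic phantoms and study tables so the whole
chain runs and validates without any scanner or animal data.

It is aimed at imaging scientists who monitor therapy response with
functional MRI: the package gives them a tested reference
implementation of the voxelwise model inversions and of the statistics
layer those studies report, plus simulators to characterize estimator
behaviour at a chosen SNR.

## Models

Diffusion-weighted signal over b-values (s/mm²) follows the intravoxel
incoherent motion (IVIM) bi-exponential

    S(b) = S0·[(1 − f)·e^(−b·D) + f·e^(−b·D*)]

with true diffusion coefficient D, pseudo-diffusion coefficient D\*
(capillary blood motion; D\* > D) and perfusion fraction f. Estimation
is segmented at b = 200 s/mm²: D from a log-linear fit of the
diffusion-dominated high-b segment, then f and D\* by bounded nonlinear
least squares with D fixed, with an iterated perfusion-compartment
correction of the diffusion segment (ROI-median-informed at map level).
Multi-echo gradient-echo magnitude decays as S(TE) = S0·e^(−R2\*·TE);
R2\* (1/s) comes from weighted least squares of ln S on TE. Tumor
volume is V = a²·b·0.5 from caliper diameters, inhibition rate
(V_control − V_treated)/V_control·100%, and groups are compared with
one-way ANOVA (raw samples or reconstructed from mean ± SD cells),
Student–Newman–Keuls post hoc, and Pearson correlation against
pathology staining rates. See `docs/methods.md` for details and design
rationale.

## Worked example

Fit one tumor-baseline voxel and recompute a published table row:

```python
>>> import ivimr2 as iv
>>> dwi, gre = iv.default_protocols()          # 13 b-values, 16 TEs
>>> truth = iv.IVIMParams(S0=1000, D=0.556e-3, Dstar=8.53e-3, f=0.1675)
>>> fit = iv.fit_ivim_voxel(iv.ivim_signal(truth, dwi), dwi)
>>> round(fit.params.D * 1e3, 4), round(fit.params.f * 100, 2)
(0.5604, 16.46)
>>> cells = [iv.SummaryCell(m, s, 8) for m, s in
...          [(217.5, 60.1), (436.3, 59.6), (702.5, 42.9), (1039.8, 93.9)]]
>>> round(iv.anova_from_summary(cells).F, 2)   # printed value: 225.693
225.66
>>> round(iv.inhibition_rate(1039.8, 547.4), 1)
47.4
```

The fitted D (0.5604·10⁻³ mm²/s) and f (16.46%) recover the noiseless
truth to ~1%; the F statistic recomputed from the mean ± SD cells
matches the published 225.693 to 0.01%; the week-3 inhibition rate of
the high-dose nanoparticle arm reproduces the reported 47.4% exactly.

The end-to-end analysis lives in `analysis/` as numbered drivers:

```sh
python analysis/01_simulate_phantom.py --seed 1    # volumes -> scratch/
python analysis/02_fit_parameter_maps.py           # recovery -> results/
python analysis/03_simulate_study.py --seed 1
python analysis/04_group_statistics.py
python analysis/05_reproduce_reference_tables.py
```

`02` prints, for the default SNR-50 phantom (656 tumor voxels):

```
quantity  roi_mean    roi_sd  n_voxels  median_rel_err_pct
       D 0.0005582 4.461e-05       656               4.655
   Dstar  0.009235  0.002781       656               16.36
       f    0.1664    0.0288       656               11.59
  R2star     24.41    0.8395       656                1.81
```

i.e. D and R2\* are recovered to a few percent per voxel at SNR 50
while D\* — the unstable IVIM parameter — carries ~16% median error;
`05` ends with `27/27 printed values reproduced`.

A `ivimr2` console command exposes the same steps
(`simulate-phantom`, `simulate-study`, `fit-ivim`, `fit-r2star`,
`roi-stats`, `study-stats`, `correlate`, `longitudinal-summary`,
`reproduce-tables`); every run writes a manifest with its options and
seed next to its outputs.

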