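# glandscan

Quantitative fluorescence-image analysis of *Drosophila* larval
salivary-gland hypertrophy.

Chronic growth signaling (e.g. constitutive Ras activation) drives larval
salivary glands into extra endoreplication cycles: nuclei swell, the gland
surface recruits hemocytes, and an antimicrobial-peptide reporter
(Drosomycin, *Drs*) lights up with a marked proximal–distal asymmetry.
`glandscan` implements the measurement workflow behind such studies as a
tested, reusable Python library plus CLI, for researchers who quantify
gland phenotypes from confocal images:

* **Axial profiling** — a gland's longitudinal axis is its Feret axis (the
  maximum-caliper vertex pair of the outline polygon). Mean fluorescence of
  each 1-px slab perpendicular to that axis gives the profile *I(s)*,
  *s ∈ [0, 1]*; profiles from many glands are pooled by binning on the
  relative axis (default 256 bins), per-gland mean normalization, and a
  degree-2 tricube loess (span 0.05) on the cross-gland mean.
* **3D nuclear morphometry** — DAPI stacks are thresholded (Otsu), labeled
  as 26-connected components, and measured as calibrated volumes
  *V = n·dz·dy·dx*; nuclei are assigned to the proximal (PP) or distal (DP)
  compartment by a 2D point-in-polygon test of their centroid. Hypertrophy
  between cohorts is the fold-change of per-gland mean volumes.
* **Hemocyte attachment** — the log-ratio statistic
  `ln(hemocyte area) / ln(gland area)` with areas in pixels, plus effect
  sizes normalized so the reference-group mean is anchored at 1.
* **Per-nucleus correlation** — nuclear outlines transferred onto two
  marker channels; Pearson *r* and an OLS fit of the log10 accumulated
  (summed) per-nucleus intensities, per compartment.
* **Statistics battery** — Shapiro–Wilk and a parametric KS bootstrap for
  normality, Bartlett-gated Student/Welch t-tests, tie-corrected
  Kruskal–Wallis with Dunn post-hoc tests, and the star convention
  (\*\*\* p<0.001, \*\* p<0.01, \* p<0.05, n.s. p≥0.05).
* **Synthetic glands** — because such raw microscopy data are rarely
  deposited, the package ships a generator of capsule-shaped gland images,
  hemocyte patches and nuclei z-stacks with *exact* ground truth (masks,
  axial positions, voxel counts, channel totals), on which every stage is
  validated.

## Worked example

Simulate the demo study (5 control + 5 "hypertrophic" glands, generated at
a nuclear-volume fold of 5.66) and run every stage:

```bash
glandscan run --out demo_run --seed 7
```

prints the per-stage row counts

```
{
 "profiles": 254,
 "nuclei": 240,
 "gland_summaries": 10,
 "attachment": 30,
 "correlation": 6,
 "stats": 2
}
```

and `demo_run/results/stats.csv` contains (abridged):

```
comparison,method,statistic,df,p_value,stars,fold_change
mean_nuclear_volume: hypertrophic vs control,welch-t,72.58,4.43,5.6e-08,***,5.57
hemocyte_attachment: hypertrophic vs control,student-t (pooled),2329.5,8,1.3e-24,***,0.878
```

Read: the pipeline segmented 240 nuclei from the 10 stacks, recovered a
mean-nuclear-volume fold-change of 5.57 (the study was generated at 5.66;
the Bartlett gate chose Welch's t because per-gland variances scale with
volume), and the hemocyte-attachment statistic differs strongly between
cohorts. Re-running with the same seed reproduces every CSV byte for byte.

The same stages are available piecewise (`glandscan profile`, `nuclei`,
`attach`, `correlate`, `stats`, `simulate`) and as library functions; see
`docs/methods.md` for the models and conventions.

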