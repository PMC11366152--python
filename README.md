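# ppcv — peripapillary capillary volume from dense B-scan OCTA

`ppcv` is a Python package for quantifying the three-dimensional volume of
retinal capillary flow beside the optic disc (**peripapillary capillary
volume, PPCV**) from dense B-scan OCT-angiography volume scans, together
with the cohort statistics used to analyze such measurements in clinical
studies of diabetic retinopathy (DR). It is aimed at ophthalmic-imaging
researchers who want a reproducible, scriptable version of the usual
manual ImageJ/MATLAB workflow — and at methodologists who want to test
that workflow against phantoms with known ground truth.

## What it computes

A DART-style volume scan covers a ~3 mm × 0.15 mm peripapillary strip with
`n + 1 = 25` densely spaced B-scans (512 A-scans each, inter-slice spacing
Δh ≈ 6 μm). On every B-scan the capillary flow signal is segmented
(brightness normalization → intensity threshold → polygon ROI →
large-vessel exclusion) and its cross-sectional area A(xᵢ) is measured in
μm². The capillary volume is then the composite trapezoidal approximation
of the slice integral

```
V = ∫ₐᵇ A(x) dx  ≈  Δh · Σᵢ₌₁ⁿ [A(xᵢ) + A(xᵢ₊₁)] / 2        [μm³]
```

Because no clinical OCTA data ship with the package, a first-class
synthetic module generates (a) 3-plexus vascular phantoms with exactly
known capillary volume, rendered into realistic noisy B-scan stacks, and
(b) study-structured cohorts (healthy subjects plus anti-VEGF / laser /
surgery treatment arms) with configurable age, hemisphere, disease and
treatment effects. Every pipeline stage is validated against these ground
truths.

The statistics module provides pooled/Welch t tests,
Student–Newman–Keuls homogeneous subsets, Fisher-LSD baseline
comparisons, OLS regression with variance-inflation factors, a
GEE-style cluster-robust group comparison (two eyes of one subject are
correlated), ICC(2,1) inter-rater agreement and Cohen's κ.

## Worked example

```python
import ppcv

geom = ppcv.ScanGeometry()                       # 3 mm x 0.15 mm, 25 slices
net = ppcv.generate_network(ppcv.NetworkParams(), geom, seed=1)
truth = ppcv.analytic_capillary_volume(net, geom)
stack = ppcv.render_stack(net, geom, ppcv.RenderParams(), seed=101)

result = ppcv.compute_ppcv(stack, ppcv.SegmentationSettings())
print(f"true capillary volume: {truth.capillary_volume_um3:,.0f} um^3")
print(f"recovered PPCV:        {result.volume_um3:,.0f} um^3 "
      f"({result.volume_nl:.4f} nL)")
```

prints

```
true capillary volume: 1,095,518 um^3
recovered PPCV:        1,141,161 um^3 (1.1412 nL)
```

i.e. the full segmentation + integration chain recovers this phantom's
exact capillary volume to within ~4% (across random phantoms the error
stays within ±10%; see `tests/test_acceptance.py`). A cohort analysis is
one call away:

```python
cohort = ppcv.generate_cohort(ppcv.CohortDesign(), seed=7)
fit = ppcv.fit_linear_model(cohort[cohort.group == "healthy"],
                            "ppcv_um3", ["age_years", "sex", "hemisphere"])
print(fit.params["age_years"], fit.pvalues["age_years"])
```

The same stages are scriptable from the shell:

```sh
ppcv-pipeline simulate stack --seed 1 --out run/
ppcv-pipeline segment --stack run/stack_TS_seed1.tif --out run/profile.csv
ppcv-pipeline ppcv --profile run/profile.csv
ppcv-pipeline simulate cohort --seed 1 --out cohort.csv
ppcv-pipeline stats regress --cohort cohort.csv --group healthy
ppcv-pipeline run --config cfg.json --out run/     # full pipeline + manifest
```

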