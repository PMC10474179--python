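# dtialps

Diffusion-tensor analysis along the perivascular space (DTI-ALPS) and the
multidomain association screen around it, as a tested, reproducible Python
package.

## The problem

The glymphatic system clears interstitial waste from the brain through
perivascular channels controlled by astrocytic aquaporin-4. Its activity
can be probed non-invasively with diffusion MRI: at the level of the
lateral-ventricle body, deep medullary veins — and the perivascular spaces
along them — run left–right (x), perpendicular both to the projection
fibers of the corona radiata (inferior–superior, z) and to the association
fibers of the superior longitudinal fasciculus (anterior–posterior, y).
Perivascular water movement therefore shows up as extra x-axis diffusivity
in both fiber regions. The DTI-ALPS index is the ratio

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

where each term is a ROI mean of a diagonal element of the fitted
diffusion tensor in atlas axes. An index near 1 means no preferential
perivascular diffusion; healthy older adults typically sit around 1.2–1.5.
In epidemiological use, the index is screened against demographics, blood
chemistry, biomarkers (e.g. plasma GFAP for astrocytic injury),
questionnaires and cognitive scores with Pearson correlations, group
comparisons (Cohen's d), and Benjamini–Hochberg FDR control.

The package is aimed at imaging/biostatistics researchers who want the
full chain — tensor fit, ROI selection, index, association screen — under
test, with synthetic ground truth for every stage.

## What is in the box

| module | contents |
| --- | --- |
| `dtialps.gradients` | FSL bval/bvec gradient tables, single-shell builders |
| `dtialps.tensor` | weighted-least-squares tensor fit, FA maps |
| `dtialps.alps` | atlas-label ROI selection (FA > 0.2, hemisphere, x-band), the ALPS index |
| `dtialps.phantom` | two-fiber tensor phantoms with analytic ALPS, Stejskal–Tanner DWI simulation with Rician noise |
| `dtialps.cohort` | Gaussian-copula cohort generator with exact correlation and SMD targets; the published 71-subject effect preset |
| `dtialps.stats` | Pearson tests with mixed tails, pooled t-test + SMD, BH-FDR, Lilliefors normality (Monte-Carlo p) |
| `dtialps.clinical` | metabolic syndrome (3-of-5 rule), CKD, BMI/overweight, lab ratios, with explicit indeterminate semantics |
| `dtialps.pipeline`, `dtialps.cli` | per-subject ALPS batches, the association screen, `dtialps` command-line verbs |

## Worked example

```python
import dtialps as d

# a phantom whose true ALPS index is (d_perp + d_x_boost) / d_perp = 1.24
tensor, labels, truth = d.make_tensor_phantom(d.default_phantom_spec())

# simulate a 1 b0 + 32-direction b=1500 acquisition with 1% Rician noise,
# refit the tensor by WLS and recompute the index from the atlas labels
gtab = d.single_shell_table(n_dirs=32, b=1500.0)
dwi = d.simulate_dwi(tensor, gtab, s0=1000.0, sigma=10.0, seed=7)
fitted = d.fit_tensor_wls(dwi)
result = d.alps_from_volumes(fitted, labels, d.ROIConfig())
print(f"true {truth.alps_index:.4f}  recovered {result.alps_index:.4f}")
# true 1.2400  recovered 1.2392

# a 71-subject cohort carrying the published effect structure, screened
table = d.make_cohort(d.published_screen_spec(), seed=1)
report = d.run_association_screen(table, d.published_battery(), q=0.05)
print(report.continuous.loc[report.continuous.variable == "age",
                            ["n", "r", "p", "p_fdr"]].round(4))
#     n      r    p  p_fdr
# 0  71 -0.533  0.0    0.0
print(sorted(report.rejected_variables())[:5])
# ['age', 'anion_gap', 'bmi', 'bun', 'creatinine']
```

The recovered index sits on the phantom's analytic truth (noiselessly the
round trip is exact to 1e-9; 1% Rician noise moves it by well under 1%),
and the screen recovers the injected age effect (target r = −0.434; this
seed's 71-subject draw happens to sample r = −0.533) as a strongly
significant FDR survivor.

The same flow is available from a shell:

```bash
dtialps all --out run/ --seed 3 --sigma 10 --n 71
```

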