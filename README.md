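# petradiomics

Integrated metabolic radiomics for FDG-PET tumor volumes: texture
feature extraction, unsupervised tumor clustering, and outcome
association — with a synthetic phantom generator so the whole pipeline
runs and validates without any patient data.

Intratumoral heterogeneity (ITH) on FDG-PET is commonly quantified by
texture features (TFs), but no single feature is an agreed ITH marker.
The integrated approach implemented here sidesteps that: every tumor is
summarized by a 109-feature vector spanning nine matrix families, the
cohort's z-scored feature matrix is clustered without supervision, and
the resulting tumor clusters (TCs) — rather than any individual
feature — are associated with histopathology, pathologic complete
response (pCR) after neoadjuvant chemotherapy, and recurrence.

## Pipeline

1. **Delineation** — 26-connected component of voxels with SUV ≥ 2.5;
   MTV = voxel count × voxel volume, TLG = SUV_mean × MTV,
   CV = SD/SUV_mean.
2. **Discretization** — fixed bin width of 0.4 SUV on the window 0–25
   (64 gray levels): `level = ⌊SUV/0.4⌋ + 1`.
3. **Texture** — GLCM, GLRLM, GLSZM, NGTDM, NGLDM, SUV statistics,
   texture spectrum, texture feature coding (TFC) and the TFC
   co-occurrence matrix; exactly 109 features, e.g.
   NL_Entropy^GLCM = −Σ p·log p, NL_Homogeneity^GLCM = Σ p/(1+|i−j|),
   ZP^GLSZM = zones/voxels, HILZE^GLSZM = Σ z(i,s)·i²·s² / zones.
4. **Clustering** — per-feature z-scores, Euclidean hierarchical
   clustering cut at k = 3 with small-branch outlier ejection; Pearson
   correlogram with Bonferroni correction (0.05/109 ≈ 5·10⁻⁴).
5. **Association** — Kruskal–Wallis feature summaries, chi-square
   proportions, odds ratios (Wald CI, Haldane correction on zero
   cells), logistic regression, Kaplan–Meier/log-rank and Cox models.

Phantom tumors are ellipsoids with a log-normal heterogeneity field on
a realistic PET grid (3.91 × 3.91 × 3.27 mm voxels); the three default
archetypes are calibrated to the published per-cluster medians (large
heterogeneous, medium intense heterogeneous, small homogeneous) with
cluster-conditional pCR rates 20.0% / 48.0% / 5.4%.

## Worked example

```sh
petradiomics report --seed 0 --out report/
```

runs the full synthetic study (10/25/37 patients per archetype) and
prints:

```
72 patients, 109 features, 3 clusters (+0 outlier), ARI vs planted 1.000
report written to report/
```

`report/summary.json` holds every number produced. For seed 0:

* `cluster_sizes: {tc1: 10, tc2: 25, tc3: 37}` and
  `adjusted_rand_index_vs_planted: 1.0` — clustering recovered the
  planted phenotypes exactly; clusters are ordered by median MTV.
* `pcr_chi2: 17.28, p: 1.8e-4` — pCR rates differ across clusters
  (simulated rates this draw: 20% / 40% / 0%).
* `or_tc2_vs_others: 15.0 (2.95–76.3)` — the medium-size, intense,
  heterogeneous cluster carries the pCR signal, as designed.
* `cox_tc1: flagged` — with a single simulated recurrence the Cox fit
  has a monotone likelihood and is flagged, not silently reported.

The same stages are available separately (`simulate`, `segment`,
`extract`, `cluster`, `associate`) and as library functions
(`petradiomics.extract_all_features`, `petradiomics.pipeline.run_pipeline`).

Equivalent library call:

```python
from petradiomics import PhantomSpec, make_tumor_phantom, \
    segment_fixed_threshold, extract_all_features

vol, _ = make_tumor_phantom(PhantomSpec(semi_axes=(25, 25, 25),
                                        base_suv=8.0,
                                        heterogeneity_sd=0.4, seed=3))
seg = segment_fixed_threshold(vol)          # MTV 64.4 cm^3, 1288 voxels
feats = extract_all_features(vol, seg.mask)  # dict of 109 named features
```

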