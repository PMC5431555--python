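# Methods

`petradiomics` implements an integrated metabolic-radiomics analysis for
FDG-PET tumor volumes in SUV units: fixed-threshold delineation,
fixed-bin-width gray-level discretization, a 109-feature texture panel
over nine matrix families, unsupervised hierarchical clustering of the
cohort feature matrix, and association of the resulting tumor clusters
with histopathology, pathologic complete response (pCR) and
disease-free survival (DFS). Because no patient imaging ships with the
package, a synthetic phantom generator provides the study conditions
end to end.

## Segmentation and discretization

The primary tumor is the 26-connected component of voxels with
SUV >= 2.5 (closed threshold, so a voxel at exactly 2.5 is included)
containing an optional seed point, else the largest component. If no
voxel reaches the cutoff the tumor is reported as undelineable rather
than returning an empty mask. MTV (cm^3) is voxel count x voxel volume;
TLG = SUV_mean x MTV; CV = population SD / mean of the masked SUVs.

Gray levels use a fixed bin width of 0.4 SUV on the window 0–25 with
64 levels: `level = floor(SUV/0.4) + 1`, left-closed/right-open bins.
The nominal triplet (width 0.4, window 0–25, 64 levels) is arithmetically
over-determined (25/0.4 = 62.5); the bin width is treated as
authoritative, the level count is fixed at 64, and SUVs at or above
25.2 are clipped into the top level (logged when it happens). All three
knobs are config-exposed.

## Texture matrices and features

All matrices are lattice-based (spacing never enters) and use the
conventions dominant in 3D PET radiomics:

* **GLCM** — distance-1 pairs over all 26 offsets accumulated into one
  symmetric matrix, normalized to probabilities. The `NL_` prefix means
  "computed from the probability-normalized matrix", not range-rescaled.
* **GLRLM** — maximal collinear runs along the 13 unique directions,
  summed into one matrix. Run percentage divides total runs by
  voxels x directions.
* **GLSZM** — maximal 26-connected equal-level zones. Note that under
  26-connectivity a two-level 3D checkerboard has exactly two zones
  (the parity classes touch diagonally), not n singletons.
* **NGTDM** — Amadasun–King occurrence probabilities and summed
  deviations from the in-mask 26-neighborhood mean. Coarseness and
  strength carry an epsilon guard (1e-6) so constant tumors stay finite.
* **NGLDM** — a 26-neighbor is dependent when its level differs from
  the center by at most the tolerance (default 0); emphasis features
  weight the dependence count k+1.
* **Texture spectrum** — each voxel's 26 neighbors coded ternary
  (less/equal/greater); the ordered 26-vector is the texture unit.
  Features: maximum and entropy of the unit spectrum, black–white
  symmetry (spectrum overlap with the gray-inverted image) and geometric
  symmetry (overlap with the point-reflected neighborhood).
* **TFC / TFCCM** — per voxel, the two first differences along each of
  the 13 opposite-offset pairs grade into a connection class (0 flat,
  1 one-sided, 2 monotone, 3 extremum); the voxel code is the class sum
  over valid pairs (0–39), and the TFCCM is the symmetric distance-1
  co-occurrence of codes. The classical schemes are two-dimensional;
  these 3D analogues are this package's own operationalization, chosen
  to preserve the constructions' intent (neighborhood ordering,
  graded gradients) under the 26-neighborhood.

Neighborhoods are truncated at the mask boundary: only in-mask
neighbors are counted, so background never contaminates a feature.
Texture-spectrum units are formed on interior voxels when any exist,
otherwise on the valid-neighborhood subset with missing neighbors coded
"equal".

Entropies default to base-2 logarithms; the base is config-exposed
(`ExtractionSettings.log_base`). Natural-log units reproduce the
clinically reported per-cluster entropy scale (archetype phantoms land
at about 5.1/5.5/3.3 nats, matching the published 5.4/5.8/3.7 medians),
which is evidence that the originating toolchain used `ln`; the base-2
default follows this package's documented closed-form examples.

Zero-variance conventions: skewness, kurtosis and every
correlation-type feature are defined as 0 on constant input, keeping
the 109-vector total and finite; extraction raises, naming the feature,
if any value is non-finite.

### The 109-feature registry

The exact member list of the original 109-feature panel is not
published; the registry in `petradiomics.registry` is the package's
single source of truth, validated at import: 16 first-order/volumetric
features, 23 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM, 14 NGLDM, 4 texture
spectrum, 6 TFC and 9 TFCCM features (109 total), including all eleven
features that appear individually in the clinical summaries (SUV_max,
SUV_mean, MTV, TLG, CV, Skewness, NL_Entropy^GLCM, NL_Homogeneity^GLCM,
NL_Dissimilarity^GLCM, ZP^GLSZM, HILZE^GLSZM). Family allocations follow
the standard 3D radiomics lists; any divergence from the original
toolchain is a documented property of this registry, not a claim about
that tool.

## Synthetic phantoms

A phantom is an ellipsoidal tumor on a background of low parenchymal
uptake (0.5 SUV plus N(0, 0.05) noise, clipped at 0), on a 28x28x32
grid at 3.91 x 3.91 x 3.27 mm voxels (a typical whole-body PET
geometry). Tumor heterogeneity is a log-normal multiplicative field:
Gaussian white noise smoothed with an isotropic kernel of width
`correlation_length` (default 8 mm, on the order of PET resolution),
standardized over the tumor voxels, and exponentiated with the variance
correction that makes the field's mean exactly 1 and its SD exactly
`heterogeneity_sd`. Standardizing over the tumor (not the grid) is what
makes the realized tumor CV track the parameter; grid-wide
standardization undershoots by ~40% because boundary-mode smoothing
inflates edge variance.

The three default archetypes are spheres calibrated to the published
per-cluster medians (MTV / SUV_mean / CV): 62.9 cm^3 / 4.9 / 0.42,
18.4 / 6.1 / 0.45, and 2.9 / 3.6 / 0.21. Only the medians are targeted —
the source reports no distributional form — and SUV_max is emergent
from the field (realized medians ~12/14/5.5 against the published
13.2/13.3/5.8). Cohorts draw per-patient log-normal jitter (15%) on
semi-axes and base uptake, a Bernoulli pCR per archetype
(0.200/0.480/0.054), an exponential recurrence time per archetype
(hazards 0.008/0/0.0007 per month, chosen to reproduce the observed
3-of-10 / 0 / 1-of-35 recurrence pattern), uniform censoring on 16–57
months, and clinical markers at the published per-cluster prevalences.
All randomness flows from explicit integer seeds.

What the phantoms do **not** emulate: scanner physics (PSF, attenuation,
reconstruction artifacts), respiratory motion, multifocal disease,
irregular tumor shapes, or necrotic cores. Passing tests therefore
demonstrate the correctness and calibration of the pipeline under a
controlled generative model, not clinical performance on real PET.

## Clustering and statistics

Features are z-scored per column (population SD; zero-variance columns
dropped with a warning). Pairwise Pearson correlations get two-sided
p-values from the t transform and a Bonferroni mask with a configurable
denominator (default 109, giving the conventional 4.6e-4 threshold);
the correlogram is ordered by hierarchical clustering of 1 − r.

Patients are clustered agglomeratively (Euclidean metric) and the tree
cut to k = 3. Branches smaller than `min_cluster_size` (default 2) are
ejected as outliers and the cut re-taken among the rest — the
operational version of the occasional single case that fits no
phenotype group. The default linkage is **Ward**: the originating
analysis does not state its criterion, and on default synthetic cohorts
Ward recovers planted archetypes with ARI >= 0.8 in 9/10 seeds where
complete linkage manages 5/10 (complete and average remain available in
the config). Dendrogram ties resolve by patient index order, making the
assignment deterministic and invariant to row/column order. Recovered
clusters are relabelled by decreasing median MTV so group I is the
large-tumor phenotype.

Outcome statistics: Kruskal–Wallis (tie-corrected) for per-cluster
feature summaries; Pearson chi-square without continuity correction for
marker proportions; odds ratios as (ad)/(bc) with Wald 95% CIs on the
log scale using the conventional z = 1.96 (the coefficient that
reproduces the published intervals to three decimals) and
Haldane–Anscombe +0.5 on zero cells, tagged in the result; logistic
regression by maximum likelihood with separation detected and flagged
(quasi-Newton fallback, never a silent estimate); Kaplan–Meier with a
multi-group log-rank test and an explicit "no events" result when the
statistic is undefined; Cox proportional hazards with Efron tie
handling, flagging monotone-likelihood fits (e.g. a no-event stratum)
and stabilizing them with a small ridge penalty rather than suppressing
them.

## Problem sizes and runtime choices

Validation experiments run at sizes chosen to keep the full suite fast
while leaving the statistics well-resolved: oracle equivalence on 50
random ROIs up to 6x6x6 against pure per-voxel enumerators; cluster
recovery over 10 cohort seeds at the default 10/25/37 design; log-rank
type-I calibration over 1000 null simulations at n = 100; Cox recovery
of a planted HR = 3 over 200 cohorts at n = 300 (mean estimate ~3.0,
well inside [2.5, 3.6]). A single phantom extraction takes on the order
of 10 ms, a full default cohort report about 3 s.

## Known limitations

* The registry's family allocation cannot be verified against the
  unpublished original list; features are named by construction, not by
  provenance.
* The 2D-to-3D generalizations of the texture spectrum and TFC families
  are package-specific; their absolute values are not comparable to 2D
  implementations.
* The fixed 2.5-SUV cutoff under-segments very heterogeneous or faint
  tumors (by design, matching the protocol it implements); phantoms
  with base uptake near the cutoff lose their low-field tail.
* Cohort-level clinical conclusions (per-cluster medians, hazard ratios
  on 4 events, and similar patient-level quantities) depend on the
  unavailable clinical cohort and are outside what the synthetic suite
  can reproduce.
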