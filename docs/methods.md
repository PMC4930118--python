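# Methods

This note records the models behind each analysis engine, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical conventions a maintainer needs to know.
No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Label-free differential abundance

The analysis unit is the NPC line: technical replicates (default three
injections per line) are averaged before testing, so the *t*-test degrees
of freedom reflect biological lines (6 control + 8 case by default), not
injections. A per-replicate mode exists
(`DifferentialAbundanceModel(..., collapse_replicates=False)`) but inflates
effective *n*.

**Missingness and imputation.** LFQ missingness is treated as
left-censored (missing-not-at-random): the generator drops a measurement
with probability `logistic(slope · (x₀ − intensity))`, with `x₀` solved so
the overall rate matches the requested fraction. Imputation draws each
missing value in sample *s* from `N(μ_s − d·σ_s, (w·σ_s)²)` with defaults
`d = 1.8`, `w = 0.3` — the de facto convention for left-censored
proteomics imputation; the moments are exercised directly in the tests
(10⁴ imputed cells recover mean μ−1.8σ and s.d. 0.3σ to ±0.02). Imputation
requires at least two observed values per sample; fewer is an error, not
a silent fallback.

**Testing.** Classical pooled-variance two-sided Student's *t*
(`equal_var=False` switches to Welch). Zero-variance ties: identical
groups give t = 0, p = 1; separated constant groups give p = 0.

**Permutation FDR.** Group labels are permuted at the line level
(n_perm ≥ 100 enforced; 100–1000 used in practice). For the threshold at
the k-th smallest observed p, `FDR(k) = mean_perm(#{p_perm ≤ p_(k)}) / k`;
the flagged set is the largest prefix with estimated FDR ≤ α. This is the
plug-in estimator; no variance-shrinkage fudge factor (s₀) is applied.
Measured behaviour at the study design (2000 proteins, 6+8 lines,
triplicates, 10% missingness): on pure nulls the flagged set is almost
always empty (mean false-discovery proportion ≤ 0.05 over 20 runs); with
10% of proteins shifted one log2 unit at noise σ = 0.5, sensitivity is
≈ 0.8 at the 5% FDR level.

**Enrichment arithmetic.** The 2×2 table keeps family and non-family
disjoint; the fold compares the family up-fraction to the global
up-fraction *including* the family. This is the only construction that
jointly reproduces the fixture tables' printed counts, percentages,
folds and Fisher p-values, and it is frozen in the acceptance tests. The
Fisher test is one-sided (upper tail) because the hypothesis is
directional over-representation among increased proteins. Printed-style
percentages round half away from zero; folds display to one decimal.

**Family classification.** Prefix rules (EIF*/EEF*/RPL*/RPS*) plus an
explicit override list (RPN, RPN2, RPA3, PRPS1 → ribosomal; ELAV →
initiation factor) covering symbols that published tables group with
these families outside the canonical patterns. The overrides record
table membership, not biological endorsement.

## Weighted coexpression network

Unsigned adjacency `|r|^β` is the default: β = 6.5 is non-integer, so
negative correlations must be rectified before powering, and the unsigned
network is the historical default; a signed variant `((1+r)/2)^β` is
available. The adjacency diagonal is stored as zero so row sums are node
connectivities.

**Scale-free criterion.** Connectivities are binned (equal-width, 10
bins) and log10 frequency is regressed on log10 mean connectivity. The
criterion uses the *signed* fit `−sign(slope)·R²`: an unsigned R² would
reward distributions with many hubs and few weakly connected nodes —
the opposite of scale-free — and push β selection toward arbitrary large
values. `pick_soft_threshold` returns the smallest candidate with signed
R² ≥ 0.8 (configurable), falling back to the best-fitting candidate with
a diagnostic table. On data constructed with exponential hub propensities
(`gen_scale_free_correlation`) the criterion selects β = 6.5 exactly; on
factor-model planted-module data no β reaches 0.8 (block-correlation
structure is genuinely not scale-free — connectivity is bimodal, not
power-law), the fallback applies, and module recovery is unaffected
(ARI ≈ 0.99 in the acceptance run).

**TOM and clustering.** `TOM_ij = (Σ_u a_iu a_uj + a_ij) /
(min(k_i,k_j) + 1 − a_ij)`, diagonal 1, nonpositive denominators mapped
to 0 with the pair effectively disconnected. Modules come from
average-linkage clustering of `1 − TOM` with a two-stage branch cut: a
static cut at `cut_height = 0.99`, then recursive within-cluster cuts at
a height interpolated toward the cluster's minimum merge height by
`0.2 × deep_split` (deep_split 0–4, default 2); a deeper split is accepted
only when every resulting branch meets `min_module_size` (default 18).
This "tree" variant is deterministic and conservative — it never shreds
a valid module to satisfy a split. No PAM-like reassignment stage is
implemented. Colors follow a fixed palette in decreasing size order
(ties broken by first member index); grey is reserved for unassigned.

**Input convention.** The model takes any proteins × conditions matrix
and computes pairwise-complete Pearson correlations (minimum 3 shared
observations per pair); columns may mix per-line LFQ values and pairwise
SILAC log2 ratios. Zero-variance rows are dropped with a warning.

## Morphometry

All coordinates are pixel-centred, origin top-left, x rightward,
y downward; contours are closed polygons in pixel units.

- **Normalization**: robust 1st/99th percentile clamp to [0, 1]; when the
  percentile range collapses (signal sparser than 1% of pixels) the true
  min/max is used so single-cell fields are not zeroed out.
- **Nuclear enhancement**: three difference-of-Gaussians bands with outer
  scales at 0.5×, 1× and 2× the expected nucleus radius (default 10 px)
  and inner scales a quarter of that, combined by pixelwise maximum,
  negatives clipped.
- **Marker enhancement**: subtract a least-squares illumination plane
  (computed in closed form from row/column means; exact for linear
  gradients and immune to Gaussian edge artifacts), then a wide Gaussian
  (σ = 20 px, nearest-edge padding) of the remainder; clip at zero.
- **Segmentation**: Otsu threshold, connected components, sieve by area
  (40–5000 px²) and circularity (4πA/P² ≥ 0.5), moment-based ellipse
  fit. Touching nuclei are not split (no watershed); the generator
  enforces a minimum centre spacing instead, so benchmark numbers do not
  speak to clumped-field performance.
- **Classification**: mean enhanced marker intensity in a circular
  annulus (inner margin 2 px outside the equivalent-radius circle, width
  6 px) against `median + 3 × σ_robust` of the whole channel, judged per
  marker independently. σ_robust is the MAD scaled to a normal sigma;
  when zero-clipping has collapsed the MAD, the 84.13th percentile above
  the median (the one-sigma point of a normal, insensitive to the clipped
  lower tail) substitutes.
- **Metrics**: effective diameter is the geometric mean of the ellipse
  axes — equal to the equal-area circle diameter — with an arithmetic-mean
  alternative selectable; aspect ratio (oblongness) is major/minor.

Measured on the default synthetic spec (50 cells/field, diameter
20 ± 3 px, moderate noise): detection recall and precision 1.0, marker
classification accuracy 1.0, mean-diameter relative error ≈ 4%
(systematic: the enhanced-and-thresholded mask slightly pads the true
ellipse). Two groups simulated from one spec give diameter and aspect
folds within [0.99, 1.01] at ~2000 cells/group — the testable analog of
a no-size-difference result.

## Phenotype statistics

- **HPG positivity**: threshold at the negative (no-label) control's 99th
  percentile (q configurable); percent-positive of a sample matching the
  control therefore reads ≈ 1% by construction. MFI is the plain median.
- **Batch normalization**: divide by the within-batch mean of the
  reference condition; idempotent, maps the reference mean to 1 per
  batch. Batch effects are modeled (and generated) as multiplicative
  because FACS intensity scales with laser/detector gain.
- **Fold sign convention**: suppressive effects are reported as −1/ratio
  (a ratio of 0.71 prints as −1.4-fold), matching the field's reporting
  style for inhibitor experiments.
- **Box–Cox**: λ from the profile-likelihood MLE (scipy), applied
  per-comparison when requested; the raw-scale fold is reported
  regardless of the transform. A Shapiro–Wilk flag on residuals is
  advisory output only — no decision rule branches on it, because none
  is specified for this analysis style.
- **Nested analysis**: replicate values collapse to one mean per patient,
  then a two-sample *t* across patients. Degrees of freedom depend only
  on patient counts — deliberately conservative relative to a pooled
  fixed-effects fit, and robust to unbalanced replicate numbers.
- **Bradford calibration**: linear fit through the BSA standard series;
  curvature correction is out of scope.

## Synthetic-data generators

The generators emulate the study conditions the pipelines target: a
6-control / 8-case NPC-line cohort in technical triplicate (42 samples)
with log2 intensities around 26 ± 2; four pairwise SILAC comparisons
whose pooled significant entries follow configurable direction fractions
(defaults 0.97 family-up, 0.64 global-up); planted coexpression modules
driven by one latent factor each (realized within-module correlation
within ±0.05 of target); microscopy fields of blurred ellipse nuclei with
annular soma rings over a smooth background gradient; and log-normal FACS
fluorescence with a 2.4× default case fold and multiplicative batch
factors. An optional whole-sample dropout count emulates failed runs
without asserting a dropout mechanism.

What they do **not** emulate — and hence what passing tests do not show
about real data: peptide-level evidence and protein inference, retention
time structure, correlated protein–protein abundance noise within the
proteome, cell clumping and focus variation in imagery, dendrites or
cytoskeletal texture beyond the annular soma, FACS spillover or
autofluorescence, or inter-patient biological heterogeneity beyond a
single group effect. Every generated object carries exactly one
serialized ground-truth record, and identical spec + seed yields
byte-identical output (each generator draws from a single seeded
`numpy` generator; no global state).

## Numerical conventions and degenerate inputs

- Invalid specs fail fast with the violated invariant named.
- Correlations require ≥ 4 conditions; imputation requires ≥ 2 observed
  values per sample; FDR requires ≥ 100 permutations; group comparisons
  require ≥ 2 values per group (≥ 2 patients per group when nested).
- Hub ranking breaks kIM ties deterministically by protein id; module
  color order breaks size ties by first member index.
- Blank images segment to empty lists rather than erroring; a zero-nuclei
  actin field reports the mean area per cell as absent.
- Problem sizes in the acceptance script (2000-protein cohorts, 20 null
  runs, 5 network seeds, ~4000 measured cells for the null-size
  comparison, 2×10⁴ FACS events) were chosen so that binomial/Monte-Carlo
  error is comfortably inside each check's tolerance.

## Known limitations

- The permutation FDR at 6+8 lines has a discrete permutation space
  (C(14,6) = 3003 distinct label splits); sampled permutations suffice
  for the 5% level but quantiles below ~1/3003 are not resolvable.
- The tree-variant branch cut under-splits relative to the hybrid
  dynamic cut when modules merge below the static cut height; planted
  benchmarks here are insensitive, strongly nested real dendrograms may
  not be.
- Fisher enrichment treats pooled per-comparison counts as independent
  entries, exactly as published total rows do; proteins recurring across
  comparisons are counted per occurrence.
- Morphometry assumes one focal plane and non-touching nuclei; there is
  no illumination correction beyond the plane/band-pass filters.
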