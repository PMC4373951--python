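# Methods

This note documents the models, statistics and design choices behind
`fibrosig`. The package reconstructs a complete analysis chain for
matched fibroblast expression profiling — disease classification by a
gene signature, differential expression across a nested
site × serum × disease design, variance-structure analyses, and
causal-network activation scoring — together with a synthetic-data
generator that provides ground truth for every stage.

## The study design being modelled

Fibroblast lines are cultured from three anatomical sites (synovium,
bone marrow, skin) of each patient in two disease groups (rheumatoid
arthritis, RA, n = 12; osteoarthritis, OA, n = 6), and each line is
profiled under low (0.1% FCS) and high (10% FCS) serum. The full
crossing gives 108 arrays; a quality-control dropout parameter can
remove a configurable number (six reproduces the usual attrition).
The scientific phenomena of interest are:

1. a **hierarchy of transcriptional control** — anatomical site
   explains the most differential expression, then serum response,
   then disease;
2. a **synovium-specific, serum-dependent disease signal** — RA and OA
   synovial fibroblasts differ under low serum but converge when serum
   stimulated, while skin and bone marrow carry stable disease
   differences in both serum states.

## Synthetic data generator

Expression is additive on the log2 scale:

```
x_gs = baseline_g + patient_p(s) + site_g(tissue_s) + serum_g(serum_s)
       + disease_g(disease_s, tissue_s) + oa_syn_g(disease_s, tissue_s, serum_s)
       + N(0, noise_sd)
```

* `baseline_g ~ N(8, 2)` log2 units, the typical range of normalized
  arrays after detection filtering.
* `patient_p ~ N(0, 0.3)` per patient and gene, shared across all six
  of a patient's samples: the matched design. The within-patient
  correlation of cultured fibroblast lines is not an estimated
  quantity; 0.3 (smaller than the noise floor's spread but non-trivial)
  is a package choice.
* **Site genes** (600 of 2000 by default): each gene carries three
  *distinct* per-tissue offsets — a permutation of (−1, 0, +1) scaled
  by the site effect, cycling deterministically over the six
  permutations — so tissues separate in the leading principal
  components rather than along a single degenerate axis.
* **Serum genes** (200): shifted in high serum; direction alternates
  by gene index (half up, half down), again avoiding a degenerate PC1.
* **Disease genes** (60): shifted in RA lines from bone marrow and
  skin. Synovial disease differences are deliberately *not* planted
  here: in the modelled system they are serum-state-dependent and are
  carried entirely by the interaction set below. This matches the
  empirical pattern of per-tissue disease counts (stable skin/marrow
  differences under both serum states; synovial differences in low
  serum only) and keeps the per-cell counts interpretable.
* **OA-synovium genes** (50): altered in OA synovial lines under low
  serum only; under high serum the OA mean returns to the RA level.
  88% of the set is elevated at low serum (hence down-regulated on
  serum stimulation), 12% depressed, mirroring the predominance of
  down-regulation in the serum response of this compartment.

Effect sizes default to 2.0 (site), 1.8 (serum), 2.0 (disease and
OA-synovium interaction) log2 units with `noise_sd = 0.4`. The calling
rule downstream is FDR plus a two-fold (1 log2 unit) filter, so every
planted effect is ≥ 4 × noise and well clear of the fold threshold:
recovery of a planted set then measures the method, not sampling luck.
An effect placed *at* the fold threshold would be called for only half
its genes in expectation, which is a statement about thresholding, not
about the pipeline.

What the generator does **not** emulate: probe-level effects, batch
structure, missing values within retained samples, heavy-tailed or
intensity-dependent noise, and correlated co-expression modules.
Passing tests on this generator therefore demonstrate correctness of
the statistical machinery under the declared model, not performance on
raw array data.

A companion causal network generator links synthetic functional terms
to the planted serum-response genes with edge directions that agree
with the planted direction of change 90% of the time (curated networks
are mostly, not perfectly, consistent with any one experiment), plus
null functions over random genes. Finding counts are small random
integers.

## SAM differential expression

The moderated statistic for gene *g* is `d_g = r_g / (s_g + s0)`.

Two-class (unpaired): `r_g = mean2 − mean1` and
`s_g = sqrt((1/n1 + 1/n2)(SS1 + SS2)/(n1 + n2 − 2))` — at `s0 = 0`
this is exactly the pooled-variance t statistic (tested to 1e-10
against an independent implementation).

Multiclass: `r_g = sqrt((Σ_k 1/n_k) · Σ_k n_k(m_k − m)²)`,
`s_g = sqrt((Σ_k 1/n_k) · SSW/(n − K))`. The scaling constant is
chosen so the K = 2 case reduces *exactly* to the absolute two-class
d (a tested identity), which also makes `d² = (K−1)·F`, i.e. the
statistic is rank-identical to the one-way F at `s0 = 0`.

The fudge factor `s0` follows the automatic rule: candidates are the
5-percent percentiles of `{s_g}`; genes are windowed by `s_g`
quantiles; the candidate minimizing the coefficient of variation of
the per-window MAD/0.64 of d wins, ties to the smallest percentile.
A constant matrix yields `s0 = 0`.

FDR is estimated by label permutation. Candidate cutoffs are the
observed |d| values; at cutoff c,

```
FDR(c) = pi0 · median_perm #{|d_perm| >= c} / #{|d_obs| >= c}
```

capped at one, and a gene's q-value is the minimum FDR over cutoffs at
which it is called, which enforces monotonicity in |d| by
construction. Cutoffs are symmetric in |d| — a simplification of the
asymmetric delta-band machinery, adequate for count-based analyses and
recorded as a deviation from it. `pi0` is estimated as
`min(1, 2 · fraction of observed d inside the IQR of pooled permuted d)`;
a conservative `pi0 = 1` is available by flag. 500 permutations by
default, with full enumeration of distinct label assignments whenever
there are at most that many; with strata present labels are shuffled
within each stratum (and always sampled). Serum and disease
comparisons are run "two class unpaired" even though low/high serum
samples come from the same lines — the simpler test is deliberately
retained for comparability across the nested cells.

The hierarchy driver runs the multiclass site test, the two top-level
two-class tests, and all per-tissue × per-disease (serum response) and
per-tissue × per-serum (disease) cells, calling genes at
`q ≤ FDR` **and** fold change ≥ 2 (or ≤ ½). A cell with fewer than two
samples per level is reported as unavailable (NaN), never as zero.
Default thresholds follow the printed convention of the modelled
study: FDR < 3% + 2-fold for the multiclass signature, FDR < 5% +
2-fold for level and nested comparisons.

## KNN/LOOCV classification

Distances are Euclidean over the signature genes after per-gene
z-scoring, with the scaling statistics recomputed from the n−1
training samples of each fold so the held-out sample never leaks into
its own scaling. No metric or standardization is inherited from the
modelled study (none is stated there); z-scored Euclidean is this
package's choice, flagged as such, and raw Euclidean is available via
`standardize=False` (where the implementation is cross-checked against
scikit-learn per fold). Majority vote over the k nearest; vote ties
break to the tied class with the smallest mean neighbour distance,
then lexicographically; distance ties resolve in stable sample order.
The k sweep defaults to 3..9 ("2 < k < 10"), reporting per-k accuracy
and its standard deviation, with the headline confusion matrix taken
at the (lower) median k.

A subtlety the tests account for: under label permutation the expected
LOOCV accuracy is *not* exactly 1/(number of classes), because leaving
a sample out depletes its own label in the voting pool (9 of 29 for
three balanced classes of ten). The exact chance level is enumerable
from the multivariate hypergeometric vote counts (0.2931 for ten per
class at k = 5) and that is the value the calibration test targets.

## PCA, convergence, overlap

PCA is gene-wise mean-centred (no variance scaling) via SVD of the
sample × gene matrix; at most five components (or the rank) are
reported. Signs are fixed by requiring the largest-|loading| gene of
each component to be positive. "Most contributing" genes of a
component are those with |loading| above mean + 2 SD of the
|loading| distribution (the extraction rule in the modelled study is
unstated; a top-n rule is also provided).

Serum convergence is formalized as the ratio of Euclidean distances
between disease centroids, high serum over low serum, in the space of
a chosen gene set; a ratio < 1 means convergence. The underlying
observation is visual in origin, so this metric is a formalization,
not a reproduction. The 0/0 case (identical groups) is reported as
absent rather than as a number.

Set overlaps are exact intersection arithmetic; the overlap fraction
is |intersection of all| / |union of all| by default, with
intersection-over-smallest-set available because both conventions
occur in practice.

## Activation z-score

Edge weight `w_i = |M_act − M_inh| / (M_act + M_inh + 1)` discounts
conflicting literature evidence (equal counts → weight 0) and is
bounded in [0, 1). Each *called* gene on a function contributes
`x_i = sign(log fold change) × (+1 activating / −1 inhibiting)`; genes
with fold change exactly 1 are excluded; duplicate (gene, function)
edges are collapsed by summing finding counts first. The score is

```
z = Σ w_i x_i / sqrt(Σ w_i²)
```

The denominator is read as the root of the *sum of squared weights*:
this is the only reading under which z has unit variance when the x_i
are independent fair ±1 signs, i.e. the only one that makes z a
standardized score against the stated null. Significance is reported
both by Monte-Carlo draws from that null (10 000 by default) and by
the normal approximation, with Benjamini–Hochberg adjustment across
functions; |z| ≥ 2 calls a function increased or decreased. Edge
direction may be supplied or derived from the finding counts — both
conventions exist in curated networks, so both are supported.

## Pipeline and reproducibility

The six stages (data, preprocess, classify, de, hierarchy, effects)
consume named seeds fanned out from the single config seed as
`seed_i = (seed + 1000003·(i+1)) mod 2³¹`, so any stage can be rerun in
isolation. Every output is TSV (or GMT/JSON) with Unix line endings
and full-precision floats; the matrix reader uses an exact round-trip
float parser, so write → read → write is byte-identical, and the run
manifest records SHA-256 checksums per stage — two runs with the same
config produce identical checksums, which is the tested determinism
contract.

Detection filtering removes genes whose mean log2 expression falls
strictly below the matrix-wide quantile threshold (numpy's `higher`
rule; ties at the threshold retained; default quantile 0.2). No
within-matrix quantile rule can be idempotent — re-filtering recomputes
the quantile on the filtered distribution — so the tested invariant is
monotonicity: a higher quantile always retains a subset. An all-tied
(constant) matrix is rejected as undefined. Probe collapsing keeps the
maximal-variance probe per gene verbatim (rank-preserving for the test
statistics, unlike averaging).

## Problem sizes used in tests

The test and acceptance runs use the generator defaults (2000 genes,
108 samples) for the hierarchy and convergence checks, 500
permutations for FDR estimation, 20 replicate null simulations of
2000 genes for FDR-control calibration, 200 label permutations for
classifier chance calibration, and 10 000–20 000 Monte-Carlo draws for
the activation null — sizes at which every Monte-Carlo tolerance in
the suite is a 3-standard-error band of the corresponding exact or
enumerated oracle.

## Known limitations

* The permutation FDR is a count-based estimate; with few distinct
  permutations (tiny groups) q-values are coarse.
* The multiclass statistic tests a global mean difference; it does not
  identify which level drives a call.
* The convergence ratio depends on the gene set it is computed over;
  it is reported alongside the set size for that reason.
* Real-data idiosyncrasies (batch effects, probe saturation,
  intensity-dependent variance) are out of the generator's scope, and
  no normalization is performed — inputs are assumed normalized and
  log-scale.
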