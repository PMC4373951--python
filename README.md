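# fibrosig

Analysis toolkit for matched fibroblast expression profiling: where a
fibroblast comes from (synovium, bone marrow, skin), how it responds to
serum stimulation, and what its disease of origin (rheumatoid vs.
osteoarthritis) still explains after the first two are accounted for.

Fibroblast-like synoviocytes drive the persistence of joint
inflammation in rheumatoid arthritis (RA), and their serum-response
programme overlaps the wound-healing/neoplasia signatures first
described for skin fibroblasts. This package implements the full
statistical chain needed to dissect such a design — and a synthetic
data generator that replicates it with known ground truth, so every
stage of the chain is testable end to end. It is aimed at
computational biologists analysing factorial bulk-expression designs
(site × treatment × disease) and at anyone who needs a transparent,
dependency-light SAM or activation-score implementation.

## What's inside

* **`fibrosig.sam`** — Significance Analysis of Microarrays from
  scratch: moderated statistic `d_g = r_g/(s_g + s0)` for two-class
  unpaired and multiclass comparisons, automatic fudge-factor `s0`
  selection, permutation-based FDR (q-values), fold-change filtering,
  and a driver producing the nested site/serum/disease count tables.
  At `s0 = 0` the two-class d is exactly the pooled-variance t, and the
  multiclass d is rank-identical to the one-way F (`d² = (K−1)F`).
* **`fibrosig.classify`** — k-nearest-neighbour classification of
  samples by a gene signature with leave-one-out cross-validation,
  per-class sensitivity/specificity, and a k-robustness sweep.
* **`fibrosig.hierarchy`** — gene-wise mean-centred PCA (SVD, fixed
  sign convention), top-loading-gene extraction, the serum-convergence
  ratio (between-disease centroid distance, high over low serum), and
  exact Venn overlap arithmetic.
* **`fibrosig.effects`** — weighted activation z-score against a
  causal gene→function network: edge weight
  `w_i = |M_act − M_inh|/(M_act + M_inh + 1)`,
  `z = Σ w_i x_i / sqrt(Σ w_i²)`, Monte-Carlo ±1 null significance,
  Benjamini–Hochberg adjustment.
* **`fibrosig.simulate`** — the synthetic study: 12 RA + 6 OA patients
  × 3 tissues × 2 serum states (108 arrays, optional QC dropout), with
  planted site/serum/disease gene sets in the ratio 600:200:60 and a
  50-gene OA-synovium set that is disease-specific under low serum
  only and converges under serum stimulation.
* **`fibrosig.preprocess` / `fibrosig.io`** — detection-level
  filtering, probe→gene collapsing, signature ID mapping, TSV/GMT
  readers and writers with byte-exact round trips.
* **`fibrosig.pipeline` / CLI** — six-stage orchestration
  (`simulate → preprocess → classify → de → hierarchy → effects`) with
  a seed registry and a checksummed run manifest.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import fibrosig as fs

config = fs.SimulationConfig()   # 12 RA + 6 OA patients, 3 tissues, 2 serum states
dataset, truth = fs.generate_expression(config)

counts = fs.hierarchy_counts(dataset, fdr=0.05, fc=2.0, n_perm=500, seed=101)
print("top-level DE counts:", counts.top_level)
print("RA-vs-OA calls in synovium (low vs high serum):",
      int(counts.disease_within.loc["synovium", "low"]), "vs",
      int(counts.disease_within.loc["synovium", "high"]))

syn = dataset.subset_where(tissue="synovium")
called = counts.results["disease|synovium|low"].called_genes
print(f"synovium convergence ratio: {fs.serum_convergence(syn, sorted(called)):.3f}")

signature = fs.GeneSignature(
    "disease_signature",
    tuple(sorted(truth.disease_genes | truth.oa_synovium_genes)))
report = fs.k_sweep(dataset, signature, dataset.annotation["disease"], range(3, 10))
print(f"KNN/LOOCV disease accuracy at k={report.headline_k}: {report.accuracy:.3f}")
```

prints

```
top-level DE counts: {'site': 660, 'serum': 200, 'disease': 58}
RA-vs-OA calls in synovium (low vs high serum): 50 vs 0
synovium convergence ratio: 0.103
KNN/LOOCV disease accuracy at k=6: 0.926
```

Reading the numbers: differential-expression counts recover the
planted hierarchy — anatomical site dominates (660 calls, the 600
planted site genes plus the disease genes, whose tissue-restricted
pattern also differentiates tissues), then serum response (200), then
disease (58 of 60 planted). All 50 OA-synovium genes are called
between RA and OA in low-serum synovium and none in high serum, and
the convergence ratio of 0.10 says the disease centroids in synovium
sit ten times closer together after serum stimulation. The planted
disease signature classifies patients' disease at 92.6% LOOCV accuracy,
with misclassifications concentrated where the design makes samples
genuinely ambiguous (high-serum synovial OA lines match RA profiles).

The same operations are available from the shell:

```sh
fibrosig simulate --out sim/ --seed 17
fibrosig de --expr sim/expression.tsv --annot sim/annotation.tsv \
    --factor disease --levels OA,RA --strata tissue=synovium,serum=low \
    --fdr 0.05 --fc 2 --perms 500 --seed 7 --out de.tsv
fibrosig run-all --out run/ --seed 17
```

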