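"""Significance Analysis of Microarrays (SAM), from scratch.

The SAM statistic for gene *g* is a regularized mean difference

    d_g = r_g / (s_g + s0)

where ``r_g`` is the (signed) between-group contrast, ``s_g`` the
pooled standard error, and ``s0`` a small "fudge factor" added so that
genes with tiny variance cannot produce arbitrarily large statistics.

Two-class (unpaired):

    r_g = mean2_g - mean1_g
    s_g = sqrt((1/n1 + 1/n2) * (SS1_g + SS2_g) / (n1 + n2 - 2))

Multiclass (K groups):

    r_g = sqrt( (sum_k 1/n_k) * sum_k n_k (m_kg - m_g)^2 )
    s_g = sqrt( (sum_k 1/n_k) * SSW_g / (n - K) )

The multiclass scaling is chosen so that at K=2 the statistic reduces
exactly to |two-class d|; at s0=0 it is a monotone transform of the
one-way F statistic (d^2 = (K-1) F), hence rank-identical to F.

False-discovery rates come from label permutations: for each candidate
cutoff c on |d|, FDR(c) = pi0 * median_perm #{|d_perm| >= c} / #{|d_obs| >= c},
and a gene's q-value is the minimum FDR over the cutoffs at which it is
called.  Cutoffs are symmetric in |d| (a deliberate simplification of
SAM's asymmetric delta bands, adequate for count-based analyses).
pi0 is estimated as min(1, 2 * fraction of observed d inside the
interquartile range of the pooled permuted d).

The comparison driver nests these tests over the study design —
multiclass over tissue, two-class over serum and disease, then the
per-tissue and per-serum/disease cells — producing the count tables
that express the site > serum > disease hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sympy.utilities.iterables import multiset_permutations

from .dataset import ExpressionDataset


class DEError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonSpec:
    """What to compare: an annotation factor, its levels, optional strata
    (annotation column → fixed value, applied as a subset before testing),
    and the calling thresholds."""

    factor: str
    levels: tuple[str, ...]
    strata: tuple[tuple[str, str], ...] = ()
    fdr_threshold: float = 0.05
    fold_change_min: float = 2.0

    def __post_init__(self) -> None:
        if len(set(self.levels)) != len(self.levels) or len(self.levels) < 2:
            raise DEError("levels must be >= 2 distinct labels")
        if not 0 < self.fdr_threshold < 1:
            raise DEError("fdr_threshold must be in (0, 1)")
        if self.fold_change_min < 1:
            raise DEError("fold_change_min must be >= 1")

    @property
    def is_multiclass(self) -> bool:
        return len(self.levels) > 2

    def describe(self) -> str:
        strata = ",".join(f"{k}={v}" for k, v in self.strata) or "all"
        return f"{self.factor}[{'/'.join(self.levels)}] within {strata}"


@dataclass
class DEResult:
    """Per-gene SAM output plus the comparison that produced it."""

    table: pd.DataFrame  # gene_id (index), d, fold_change, q_value, called
    spec: ComparisonSpec
    n_permutations: int
    s0: float
    seed: int
    pi0: float = 1.0

    @property
    def called_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["called"]])

    @property
    def n_called(self) -> int:
        return int(self.table["called"].sum())


# -- statistics ---------------------------------------------------------------

def _group_indicator(groups: np.ndarray, levels) -> np.ndarray:
    G = np.stack([(groups == lv).astype(float) for lv in levels], axis=1)
    return G  # n_samples × K


def _two_class_parts(values: np.ndarray, G: np.ndarray):
    n = G.sum(axis=0)
    if (n < 2).any():
        raise DEError(f"each group needs >= 2 samples, got sizes {n.astype(int)}")
    sums = values @ G
    means = sums / n
    ss = (values ** 2) @ G - n * means ** 2
    r = means[:, 1] - means[:, 0]
    dof = n.sum() - 2
    s = np.sqrt((1 / n[0] + 1 / n[1]) * (ss[:, 0] + ss[:, 1]) / dof)
    return r, s


def _multiclass_parts(values: np.ndarray, G: np.ndarray):
    n = G.sum(axis=0)
    if (n < 2).any():
        raise DEError(f"each group needs >= 2 samples, got sizes {n.astype(int)}")
    N = n.sum()
    K = G.shape[1]
    sums = values @ G
    means = sums / n
    grand = values.mean(axis=1, keepdims=True)
    ssb = (n * (means - grand) ** 2).sum(axis=1)
    ssw = ((values ** 2) @ G - n * means ** 2).sum(axis=1)
    inv = (1.0 / n).sum()
    r = np.sqrt(inv * ssb)
    s = np.sqrt(inv * np.maximum(ssw, 0.0) / (N - K))
    return r, s


def _contrast_parts(values: np.ndarray, groups: np.ndarray, levels):
    G = _group_indicator(groups, levels)
    if len(levels) == 2:
        return _two_class_parts(values, G)
    return _multiclass_parts(values, G)


def sam_statistic_two_class(values, groups, s0: float = 0.0) -> np.ndarray:
    """Two-class unpaired SAM d; sign = mean(level2) − mean(level1).

    ``groups`` is a binary label vector; levels are taken in order of
    first appearance.  With ``s0=0`` this is exactly the pooled-variance
    t statistic.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise DEError(f"two-class statistic needs exactly 2 levels, got {levels}")
    if s0 < 0:
        raise DEError("s0 must be >= 0")
    r, s = _contrast_parts(values, groups, levels)
    return _safe_ratio(r, s + s0)


def sam_statistic_multiclass(values, groups, s0: float = 0.0) -> np.ndarray:
    """Multiclass SAM d (non-negative); zero iff all group means coincide."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 3:
        raise DEError(f"multiclass statistic needs >= 3 levels, got {levels}")
    if s0 < 0:
        raise DEError("s0 must be >= 0")
    r, s = _contrast_parts(values, groups, levels)
    return _safe_ratio(r, s + s0)


def _safe_ratio(r: np.ndarray, denom: np.ndarray) -> np.ndarray:
    out = np.zeros_like(r)
    ok = denom > 0
    out[ok] = r[ok] / denom[ok]
    return out


# -- fudge factor -------------------------------------------------------------

S0_PERCENTILES = np.arange(0, 101, 5)


def select_s0(values, groups, levels=None) -> float:
    """SAM's automatic fudge-factor rule.

    Candidates are the percentiles (0, 5, ..., 100) of the per-gene
    standard errors ``s_g``.  For each candidate, genes are binned into
    windows by ``s_g`` quantile and the spread of d within each window
    summarized by MAD/0.64; the candidate minimizing the coefficient of
    variation of these window spreads wins (ties → smallest percentile).
    Deterministic.  A constant matrix (all s_g = 0) returns 0.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if levels is None:
        levels = list(pd.unique(groups))
    r, s = _contrast_parts(values, groups, levels)
    if np.allclose(s, 0):
        return 0.0
    candidates = np.percentile(s, S0_PERCENTILES)
    n_windows = min(100, max(2, len(s) // 20))
    edges = np.quantile(s, np.linspace(0, 1, n_windows + 1))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
    best_alpha, best_cv = None, np.inf
    for alpha, s0 in zip(S0_PERCENTILES, candidates):
        d = _safe_ratio(r, s + s0)
        spreads = []
        for w in range(n_windows):
            dw = d[window == w]
            if dw.size:
                spreads.append(np.median(np.abs(dw - np.median(dw))) / 0.64)
        spreads = np.array(spreads)
        mean = spreads.mean()
        cv = spreads.std() / mean if mean > 0 else np.inf
        if cv < best_cv - 1e-12:
            best_cv, best_alpha = cv, alpha
    if best_alpha is None:
        return 0.0
    return float(np.percentile(s, best_alpha))


# -- fold change --------------------------------------------------------------

def fold_change(values, groups, levels=None) -> np.ndarray:
    """Per-gene ratio 2^(mean2 − mean1) for log2-scale input (two-class)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if levels is None:
        levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise DEError("fold_change is two-class; use fold_change_multiclass")
    m1 = values[:, groups == levels[0]].mean(axis=1)
    m2 = values[:, groups == levels[1]].mean(axis=1)
    return 2.0 ** (m2 - m1)


def fold_change_multiclass(values, groups, levels=None) -> np.ndarray:
    """Max over level pairs of the (>=1) fold-change ratio."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if levels is None:
        levels = list(pd.unique(groups))
    means = np.stack([values[:, groups == lv].mean(axis=1) for lv in levels])
    spread = means.max(axis=0) - means.min(axis=0)
    return 2.0 ** spread


# -- permutation FDR ----------------------------------------------------------

def _count_permutations(groups: np.ndarray) -> float:
    from math import factorial
    _, counts = np.unique(groups, return_counts=True)
    total = factorial(int(counts.sum()))
    for c in counts:
        total //= factorial(int(c))
    return total


def _permuted_labels(groups, n_perm, seed, strata=None):
    """Yield permuted label vectors; full enumeration when feasible.

    Without strata: if the number of distinct label orderings is at most
    ``n_perm``, all are enumerated; otherwise ``n_perm`` uniform shuffles
    are drawn.  With strata, labels are shuffled within each stratum
    (always sampled).
    """
    rng = np.random.default_rng(seed)
    groups = np.asarray(groups)
    if strata is None:
        if _count_permutations(groups) <= n_perm:
            for perm in multiset_permutations(list(groups)):
                yield np.asarray(perm)
            return
        for _ in range(n_perm):
            yield rng.permutation(groups)
        return
    strata = np.asarray(strata)
    blocks = [np.flatnonzero(strata == b) for b in pd.unique(strata)]
    for _ in range(n_perm):
        perm = groups.copy()
        for idx in blocks:
            perm[idx] = rng.permutation(groups[idx])
        yield perm


def permutation_fdr(
    values,
    groups,
    d_observed,
    *,
    s0: float = 0.0,
    n_perm: int = 500,
    seed: int = 0,
    strata=None,
    conservative_pi0: bool = False,
) -> tuple[np.ndarray, dict]:
    """Per-gene q-values from label-permutation null distributions.

    Candidate cutoffs are the observed |d| values; the FDR at cutoff c is
    ``pi0 * median_perm #{|d_perm| >= c} / #{|d_obs| >= c}`` capped at 1,
    and q_g is the minimum FDR over cutoffs c <= |d_g| (which also makes
    q monotone non-decreasing as |d| decreases).  Returns (q, info) with
    info holding pi0 and the number of permutations actually used.
    """
    if n_perm < 100:
        raise DEError("n_perm must be >= 100")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    d_obs = np.asarray(d_observed, dtype=float)

    perm_stats = []
    for perm in _permuted_labels(groups, n_perm, seed, strata=strata):
        r, s = _contrast_parts(values, perm, levels)
        perm_stats.append(_safe_ratio(r, s + s0))
    D = np.abs(np.stack(perm_stats))          # n_perm_used × n_genes
    n_used = D.shape[0]

    if conservative_pi0:
        pi0 = 1.0
    else:
        pooled = np.concatenate([np.ravel(p) for p in perm_stats])
        q25, q75 = np.percentile(pooled, [25, 75])
        pi0 = min(1.0, 2.0 * float(np.mean((d_obs >= q25) & (d_obs <= q75))))

    ad = np.abs(d_obs)
    order = np.argsort(-ad, kind="stable")
    cut = ad[order]
    asc = np.sort(ad)
    n_genes = len(ad)
    R = n_genes - np.searchsorted(asc, cut, side="left")

    counts = np.empty((n_used, n_genes), dtype=np.int64)
    for p in range(n_used):
        row = np.sort(D[p])
        counts[p] = n_genes - np.searchsorted(row, cut, side="left")
    V = np.median(counts, axis=0)

    fdr = np.minimum(1.0, pi0 * V / R)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n_genes)
    q[order] = q_sorted
    return q, {"pi0": pi0, "n_permutations": n_used}


# -- comparison driver --------------------------------------------------------

def run_comparison(
    data: ExpressionDataset,
    spec: ComparisonSpec,
    *,
    n_perm: int = 500,
    seed: int = 0,
    s0: float | None = None,
    conservative_pi0: bool = False,
) -> DEResult:
    """Execute one SAM comparison described by ``spec`` on the dataset."""
    sub = data
    for col, val in spec.strata:
        sub = sub.subset_where(**{col: val})
    if spec.factor not in sub.annotation.columns:
        raise DEError(f"annotation has no column {spec.factor!r}")
    labels = sub.annotation[spec.factor]
    keep = labels.isin(spec.levels)
    sub = sub.subset_samples(labels.index[keep])
    groups = sub.annotation[spec.factor].to_numpy()
    for lv in spec.levels:
        if (groups == lv).sum() < 2:
            raise DEError(
                f"comparison {spec.describe()}: level {lv!r} has "
                f"{(groups == lv).sum()} sample(s), need >= 2"
            )
    values = sub.values.to_numpy()
    levels = list(spec.levels)

    if s0 is None:
        s0 = select_s0(values, groups, levels)
    r, s = _contrast_parts(values, groups, levels)
    d = _safe_ratio(r, s + s0)
    if spec.is_multiclass:
        fc = fold_change_multiclass(values, groups, levels)
    else:
        fc = fold_change(values, groups, levels)
    q, info = permutation_fdr(
        values, groups, d, s0=s0, n_perm=n_perm, seed=seed,
        conservative_pi0=conservative_pi0,
    )
    called = (q <= spec.fdr_threshold) & (
        (fc >= spec.fold_change_min) | (fc <= 1.0 / spec.fold_change_min)
    )
    table = pd.DataFrame(
        {"d": d, "fold_change": fc, "q_value": q, "called": called},
        index=pd.Index(sub.values.index, name="gene_id"),
    )
    return DEResult(
        table=table, spec=spec, n_permutations=info["n_permutations"],
        s0=float(s0), seed=seed, pi0=info["pi0"],
    )


@dataclass
class HierarchyCounts:
    """DE gene counts across the nested study design.

    ``top_level`` holds the three headline counts (multiclass over
    tissue; two-class over serum; two-class over disease).
    ``serum_within``: tissues × diseases, low-vs-high serum counts.
    ``disease_within``: tissues × serum levels, RA-vs-OA counts.
    Cells with under two samples per level are NaN (unavailable),
    never zero.  ``results`` retains every underlying DEResult.
    """

    top_level: dict[str, int]
    serum_within: pd.DataFrame
    disease_within: pd.DataFrame
    results: dict[str, DEResult] = field(default_factory=dict)


def hierarchy_counts(
    data: ExpressionDataset,
    fdr: float = 0.05,
    fc: float = 2.0,
    *,
    n_perm: int = 500,
    seed: int = 0,
    serum_levels: tuple[str, str] = ("low", "high"),
    disease_levels: tuple[str, str] = ("OA", "RA"),
) -> HierarchyCounts:
    """Count called genes at every level of the site/serum/disease design."""
    annot = data.annotation
    for col in ("tissue", "disease", "serum"):
        if col not in annot.columns:
            raise DEError(f"annotation missing column {col!r}")
    tissues = tuple(pd.unique(annot["tissue"]))
    results: dict[str, DEResult] = {}

    def run(name: str, make_spec, sub_seed: int):
        try:
            spec = make_spec()
            res = run_comparison(data, spec, n_perm=n_perm, seed=sub_seed)
        except DEError:
            return None
        results[name] = res
        return res.n_called

    top = {}
    top["site"] = run("site", lambda: ComparisonSpec(
        "tissue", tissues, fdr_threshold=fdr, fold_change_min=fc), seed)
    top["serum"] = run("serum", lambda: ComparisonSpec(
        "serum", serum_levels, fdr_threshold=fdr, fold_change_min=fc), seed + 1)
    top["disease"] = run("disease", lambda: ComparisonSpec(
        "disease", disease_levels, fdr_threshold=fdr, fold_change_min=fc), seed + 2)

    diseases = tuple(pd.unique(annot["disease"]))
    serum_within = pd.DataFrame(index=list(tissues), columns=list(diseases),
                                dtype=float)
    disease_within = pd.DataFrame(index=list(tissues), columns=list(serum_levels),
                                  dtype=float)
    counter = 10
    for tissue in tissues:
        for disease in diseases:
            n = run(
                f"serum|{tissue}|{disease}",
                lambda t=tissue, d=disease: ComparisonSpec(
                    "serum", serum_levels,
                    strata=(("tissue", t), ("disease", d)),
                    fdr_threshold=fdr, fold_change_min=fc),
                seed + counter,
            )
            serum_within.loc[tissue, disease] = np.nan if n is None else n
            counter += 1
        for serum in serum_levels:
            n = run(
                f"disease|{tissue}|{serum}",
                lambda t=tissue, s=serum: ComparisonSpec(
                    "disease", disease_levels,
                    strata=(("tissue", t), ("serum", s)),
                    fdr_threshold=fdr, fold_change_min=fc),
                seed + counter,
            )
            disease_within.loc[tissue, serum] = np.nan if n is None else n
            counter += 1

    return HierarchyCounts(
        top_level=top, serum_within=serum_within,
        disease_within=disease_within, results=results,
    )
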