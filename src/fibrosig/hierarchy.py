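"""PCA trajectories, serum convergence, and gene-set overlap analysis.

Mean-centred PCA (gene-wise centring, no scaling, SVD of the
sample × gene matrix) summarizes which design factors dominate the
transcriptional variance.  The serum-convergence ratio formalizes the
visual observation that RA and OA synovial fibroblasts grow *more
similar* under serum stimulation: it compares the distance between
disease centroids in high versus low serum.  Venn arithmetic quantifies
how much differential-expression programs share between conditions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset


class HierarchyError(ValueError):
    pass


@dataclass
class PCAResult:
    """Scores (samples × components), loadings (genes × components,
    orthonormal columns), and per-component variance fractions."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_fit(
    data: ExpressionDataset,
    gene_subset=None,
    n_components: int = 5,
) -> PCAResult:
    """Gene-wise mean-centred PCA via SVD; no variance scaling.

    Components reported: the smaller of ``n_components`` and the matrix
    rank.  Sign convention: within each component the gene with the
    largest |loading| has a positive loading, fixing the otherwise
    arbitrary SVD signs for reproducibility.
    """
    if data.n_samples < 2:
        raise HierarchyError("PCA needs >= 2 samples")
    if gene_subset is not None:
        sub = data.subset_genes(gene_subset)
        if sub.n_genes == 0:
            raise HierarchyError("gene subset shares no genes with the matrix")
    else:
        sub = data
    X = sub.values.to_numpy().T                    # samples × genes
    Xc = X - X.mean(axis=0, keepdims=True)         # centre each gene
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S.max(initial=0.0) * max(Xc.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    k = min(n_components, rank) if rank else 1
    total = float((S ** 2).sum()) or 1.0

    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    for j in range(k):                             # deterministic signs
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    comp_names = [f"PC{j+1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=sub.samples, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=sub.genes, columns=comp_names),
        variance_fraction=(S[:k] ** 2) / total,
    )


def top_loading_genes(
    pca: PCAResult, component: int = 1, rule: str = "mean_2sd", n: int | None = None
) -> frozenset[str]:
    """Extract the most contributing genes of one component (1-based).

    ``rule="mean_2sd"`` keeps genes with |loading| above
    mean(|loading|) + 2·sd(|loading|); ``rule="top_n"`` keeps the ``n``
    largest |loading| genes.
    """
    if not 1 <= component <= pca.n_components:
        raise HierarchyError(
            f"component {component} outside fitted range 1..{pca.n_components}"
        )
    load = pca.loadings.iloc[:, component - 1].abs()
    if rule == "mean_2sd":
        threshold = load.mean() + 2 * load.std(ddof=1)
        return frozenset(load.index[load > threshold])
    if rule == "top_n":
        if n is None:
            raise HierarchyError("rule='top_n' requires n")
        return frozenset(load.sort_values(ascending=False, kind="stable").index[:n])
    raise HierarchyError(f"unknown rule {rule!r}")


def serum_convergence(
    data: ExpressionDataset,
    gene_subset=None,
    disease_column: str = "disease",
    serum_column: str = "serum",
    serum_levels: tuple[str, str] = ("low", "high"),
    eps: float = 1e-9,
) -> float | None:
    """Between-disease centroid distance ratio, high serum / low serum.

    A ratio < 1 means the two disease groups are closer under high serum
    than under low serum — convergence.  Computed by Euclidean distance
    between disease centroids in the space of ``gene_subset`` (all genes
    when None).  Returns None when both distances are numerically zero
    (identical groups: the ratio is 0/0).  A missing disease × serum
    cell is an error.
    """
    sub = data if gene_subset is None else data.subset_genes(gene_subset)
    if sub.n_genes == 0:
        raise HierarchyError("gene subset shares no genes with the matrix")
    annot = sub.annotation
    diseases = list(pd.unique(annot[disease_column]))
    if len(diseases) != 2:
        raise HierarchyError(f"need exactly 2 disease levels, got {diseases}")
    centroids: dict[tuple[str, str], np.ndarray] = {}
    for disease in diseases:
        for serum in serum_levels:
            mask = (annot[disease_column] == disease) & (annot[serum_column] == serum)
            if not mask.any():
                raise HierarchyError(
                    f"no samples for disease={disease!r}, serum={serum!r}"
                )
            centroids[disease, serum] = (
                sub.values.loc[:, mask.to_numpy()].mean(axis=1).to_numpy()
            )
    low, high = serum_levels
    d_low = float(np.linalg.norm(centroids[diseases[0], low]
                                 - centroids[diseases[1], low]))
    d_high = float(np.linalg.norm(centroids[diseases[0], high]
                                  - centroids[diseases[1], high]))
    scale = eps * np.sqrt(sub.n_genes)
    if d_low <= scale:
        return None
    return d_high / d_low


@dataclass
class OverlapReport:
    """Exact Venn arithmetic over 2 or 3 gene sets."""

    set_sizes: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    common: int                    # size of the intersection of all sets
    union: int
    overlap_fraction: float

    def check_inclusion_exclusion(self) -> bool:
        """|union| must satisfy inclusion–exclusion exactly (2 or 3 sets)."""
        sizes = list(self.set_sizes.values())
        pair = list(self.pairwise.values())
        if len(sizes) == 2:
            return self.union == sizes[0] + sizes[1] - pair[0]
        return self.union == sum(sizes) - sum(pair) + self.common


def venn_overlap(sets: dict[str, set], mode: str = "union") -> OverlapReport:
    """Pairwise/triple intersections of 2 or 3 gene sets.

    ``overlap_fraction`` is |intersection of all| / |union of all| by
    default; ``mode="smallest"`` divides by the smallest set instead
    (both conventions appear in the literature).
    """
    if not 2 <= len(sets) <= 3:
        raise HierarchyError("venn_overlap takes 2 or 3 sets")
    names = list(sets)
    sets = {k: set(v) for k, v in sets.items()}
    pairwise = {
        (a, b): len(sets[a] & sets[b])
        for a, b in itertools.combinations(names, 2)
    }
    common_set = set.intersection(*sets.values())
    union_set = set.union(*sets.values())
    if mode == "union":
        denom = len(union_set)
    elif mode == "smallest":
        denom = min(len(s) for s in sets.values())
    else:
        raise HierarchyError(f"unknown overlap mode {mode!r}")
    fraction = len(common_set) / denom if denom else 0.0
    return OverlapReport(
        set_sizes={k: len(v) for k, v in sets.items()},
        pairwise=pairwise,
        common=len(common_set),
        union=len(union_set),
        overlap_fraction=fraction,
    )
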