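"""Bring matrices and gene signatures to analysis-ready form.

Three standard steps precede every analysis here: removal of genes
expressed near the array detection floor, collapsing multiple probes
per gene to a single row, and translating signature gene IDs through a
user-supplied mapping table (microarray signatures are routinely
published against a different ID namespace than the matrix at hand).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered gene set."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise PreprocessError(f"signature {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise PreprocessError(f"signature {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


class IdMapping:
    """Many-to-many ID mapping; duplicated pairs are collapsed."""

    def __init__(self, pairs) -> None:
        seen: set[tuple[str, str]] = set()
        fwd: dict[str, list[str]] = {}
        for source, target in pairs:
            if not source or not target or pd.isna(source) or pd.isna(target):
                raise PreprocessError("mapping contains an empty ID")
            key = (str(source), str(target))
            if key in seen:
                continue
            seen.add(key)
            fwd.setdefault(key[0], []).append(key[1])
        self._fwd = fwd

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IdMapping":
        return cls(zip(df["source_id"], df["target_id"]))

    def targets(self, source_id: str) -> list[str]:
        return self._fwd.get(source_id, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._fwd.values())


def filter_low_expression(
    data: ExpressionDataset, quantile: float = 0.2
) -> ExpressionDataset:
    """Drop genes whose mean expression sits below a quantile threshold.

    The per-gene statistic is the mean over samples (the natural choice
    for log-scale array data); the threshold is the ``quantile`` of all
    gene means under the 'higher' rank rule, and only genes strictly
    below it are removed — ties at the threshold are retained.  Gene
    order is preserved.  ``quantile=0`` is the identity.
    """
    if not 0 <= quantile < 1:
        raise PreprocessError(f"quantile must be in [0, 1), got {quantile}")
    if quantile == 0:
        return data
    means = data.values.mean(axis=1)
    threshold = float(np.quantile(means.to_numpy(), quantile, method="higher"))
    keep = means >= threshold
    if not keep.any():
        raise PreprocessError(
            "detection filter would remove every gene; lower the quantile"
        )
    if keep.all() and means.nunique() == 1:
        raise PreprocessError(
            "all gene means are identical; detection filtering is undefined "
            "on a constant matrix"
        )
    return ExpressionDataset(data.values.loc[keep], data.annotation)


def map_signature(
    sig: GeneSignature, mapping: IdMapping, universe
) -> tuple[GeneSignature | None, float]:
    """Translate a signature into the matrix's ID namespace.

    Each source member contributes *all* its mapped targets that exist
    in ``universe`` (deduplicated, order of first appearance).  The
    returned fraction is the share of original members with at least one
    surviving target.  Zero mapped members yields ``(None, 0.0)`` with a
    warning rather than an error: an unmappable signature is a data
    problem the caller should surface, not a crash.
    """
    universe = set(universe)
    mapped: list[str] = []
    seen: set[str] = set()
    n_hit = 0
    for member in sig.members:
        targets = [t for t in mapping.targets(member) if t in universe]
        if targets:
            n_hit += 1
        for t in targets:
            if t not in seen:
                seen.add(t)
                mapped.append(t)
    fraction = n_hit / len(sig.members)
    if not mapped:
        logger.warning("signature %r: no members mapped into the universe", sig.name)
        return None, 0.0
    return GeneSignature(sig.name, tuple(mapped)), fraction


def collapse_probes(data: ExpressionDataset, mapping: IdMapping) -> ExpressionDataset:
    """Collapse probe-level rows to one row per gene.

    For each gene, the probe with maximal variance across samples is
    kept verbatim (rank-preserving for downstream test statistics, since
    the retained row is an actual measurement, not an average).  Probes
    without a mapping are dropped; a probe mapping to several genes is a
    candidate for each.  Ties in variance resolve to the first probe in
    matrix order.
    """
    variances = data.values.var(axis=1, ddof=1)
    best: dict[str, tuple[float, int, str]] = {}
    for pos, probe in enumerate(data.values.index):
        for gene in mapping.targets(probe):
            var = float(variances.iloc[pos])
            incumbent = best.get(gene)
            if incumbent is None or var > incumbent[0]:
                best[gene] = (var, pos, probe)
    if not best:
        raise PreprocessError("no probe mapped to any gene")
    genes = sorted(best, key=lambda g: best[g][1])  # stable matrix order
    rows = data.values.iloc[[best[g][1] for g in genes]].to_numpy()
    values = pd.DataFrame(rows, index=genes, columns=data.values.columns)
    return ExpressionDataset(values, data.annotation)
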