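"""Synthetic fibroblast expression data with a planted effect hierarchy.

The generator emulates the matched study design that motivates this
package: fibroblast lines from 12 rheumatoid-arthritis (RA) and 6
osteoarthritis (OA) patients, each sampled from three anatomical sites
(synovium, bone marrow, skin) and cultured under low and high serum —
108 arrays, optionally thinned by a quality-control dropout count.

Planted structure, additive on the log2 scale:

* **site genes** — each carries three distinct per-tissue offsets, so
  anatomical origin dominates the variance (and PC1 of a PCA).
* **serum genes** — shifted in high-serum culture, half up / half down.
* **disease genes** — shifted in RA lines from bone marrow and skin.
  Synovial disease differences are deliberately *not* planted here:
  in the study system they are serum-dependent and are carried by the
  interaction set below.
* **OA-synovium genes** — altered in OA synovial lines under *low*
  serum only; under high serum the OA value returns to the RA level,
  producing the convergence of RA and OA synovial fibroblasts upon
  serum stimulation.  By default 88% of the set is elevated at low
  serum (hence down-regulated low→high), 12% depressed.

A per-patient random intercept shared across that patient's samples
models the matched design.  Everything is driven by a single seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset

_SITE_PATTERNS = [p for p in itertools.permutations((-1.0, 0.0, 1.0))]


class SimulationError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """All generator parameters; defaults reproduce the study design.

    Effect sizes are in log2 units.  The defaults put every planted
    effect comfortably above the 2-fold (1 log2-unit) calling threshold
    relative to the noise floor (all ≥ 4 × ``noise_sd``) so that
    downstream recovery of the planted sets is a property of the method,
    not of sampling luck.
    """

    n_genes: int = 2000
    n_ra_patients: int = 12
    n_oa_patients: int = 6
    tissues: tuple[str, ...] = ("synovium", "bone_marrow", "skin")
    serum_levels: tuple[str, ...] = ("low", "high")
    n_site_genes: int = 600
    n_serum_genes: int = 200
    n_disease_genes: int = 60
    n_oa_synovium_genes: int = 50
    effect_size_site: float = 2.0
    effect_size_serum: float = 1.8
    effect_size_disease: float = 2.0
    effect_size_oa_synovium: float = 2.0
    noise_sd: float = 0.4
    patient_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    frac_oa_synovium_down: float = 0.88
    dropout_samples: int = 0
    seed: int = 17

    def __post_init__(self) -> None:
        counts = dict(
            n_genes=self.n_genes,
            n_ra_patients=self.n_ra_patients,
            n_oa_patients=self.n_oa_patients,
            n_site_genes=self.n_site_genes,
            n_serum_genes=self.n_serum_genes,
            n_disease_genes=self.n_disease_genes,
            n_oa_synovium_genes=self.n_oa_synovium_genes,
            dropout_samples=self.dropout_samples,
        )
        for name, val in counts.items():
            if val < 0:
                raise SimulationError(f"{name} must be >= 0, got {val}")
        n_effect = (self.n_site_genes + self.n_serum_genes
                    + self.n_disease_genes + self.n_oa_synovium_genes)
        if n_effect > self.n_genes:
            raise SimulationError(
                f"effect sets are disjoint: need <= {self.n_genes} genes, "
                f"got {n_effect}"
            )
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be > 0")
        if not self.tissues or not self.serum_levels:
            raise SimulationError("tissues and serum_levels must be non-empty")
        if len(set(self.tissues)) != len(self.tissues):
            raise SimulationError("tissue labels must be unique")
        if not 0.0 <= self.frac_oa_synovium_down <= 1.0:
            raise SimulationError("frac_oa_synovium_down must be in [0, 1]")
        total = ((self.n_ra_patients + self.n_oa_patients)
                 * len(self.tissues) * len(self.serum_levels))
        if total > 0 and self.dropout_samples >= total:
            raise SimulationError(
                f"dropout_samples={self.dropout_samples} would remove all "
                f"{total} samples"
            )

    @property
    def total_samples(self) -> int:
        return ((self.n_ra_patients + self.n_oa_patients)
                * len(self.tissues) * len(self.serum_levels))


@dataclass
class GroundTruth:
    """Planted gene sets; the recovery targets for downstream analyses."""

    site_genes: frozenset[str]
    serum_genes: frozenset[str]
    disease_genes: frozenset[str]
    oa_synovium_genes: frozenset[str]

    def as_dict(self) -> dict[str, list[str]]:
        return {
            "site_genes": sorted(self.site_genes),
            "serum_genes": sorted(self.serum_genes),
            "disease_genes": sorted(self.disease_genes),
            "oa_synovium_genes": sorted(self.oa_synovium_genes),
        }


def generate_design(config: SimulationConfig) -> pd.DataFrame:
    """Build the sample annotation table (one row per retained array).

    One sample per patient × tissue × serum combination; RA patients are
    labelled ``RA``, OA patients ``OA``.  ``dropout_samples`` rows are
    removed uniformly at random (seeded), emulating arrays failing QC.
    """
    patients = ([f"RA{i+1:02d}" for i in range(config.n_ra_patients)]
                + [f"OA{i+1:02d}" for i in range(config.n_oa_patients)])
    rows = []
    for pat in patients:
        disease = "RA" if pat.startswith("RA") else "OA"
        for tissue in config.tissues:
            for serum in config.serum_levels:
                rows.append({
                    "sample_id": f"{pat}_{tissue}_{serum}",
                    "patient": pat,
                    "tissue": tissue,
                    "disease": disease,
                    "serum": serum,
                })
    annot = pd.DataFrame(rows).set_index("sample_id")
    if config.dropout_samples:
        rng = np.random.default_rng(config.seed)
        drop = rng.choice(len(annot), size=config.dropout_samples, replace=False)
        annot = annot.drop(annot.index[np.sort(drop)])
    return annot


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a dataset with planted site/serum/disease structure.

    Returns the dataset together with the ground-truth gene sets.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    annot = generate_design(config)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]

    idx = 0
    site_idx = np.arange(idx, idx + config.n_site_genes); idx += config.n_site_genes
    serum_idx = np.arange(idx, idx + config.n_serum_genes); idx += config.n_serum_genes
    disease_idx = np.arange(idx, idx + config.n_disease_genes); idx += config.n_disease_genes
    oa_idx = np.arange(idx, idx + config.n_oa_synovium_genes)

    n_samples = len(annot)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    X = np.tile(baseline[:, None], (1, n_samples))

    # patient random intercept, shared across a patient's tissue/serum samples
    patients = annot["patient"].unique()
    intercepts = {p: rng.normal(0.0, config.patient_sd, config.n_genes)
                  for p in patients}
    for j, sid in enumerate(annot.index):
        X[:, j] += intercepts[annot.at[sid, "patient"]]

    tissue_of = annot["tissue"].to_numpy()
    serum_of = annot["serum"].to_numpy()
    disease_of = annot["disease"].to_numpy()
    high_level = config.serum_levels[-1]
    low_level = config.serum_levels[0]

    # site genes: three distinct per-tissue offsets, pattern cycling by index
    tissue_pos = {t: k % 3 for k, t in enumerate(config.tissues)}
    for row_g, g in enumerate(site_idx):
        pattern = _SITE_PATTERNS[row_g % len(_SITE_PATTERNS)]
        offs = np.array([pattern[tissue_pos[t]] for t in tissue_of])
        X[g, :] += config.effect_size_site * offs

    # serum genes: shift in high serum, direction split by gene index parity
    for row_g, g in enumerate(serum_idx):
        direction = 1.0 if row_g % 2 == 0 else -1.0
        X[g, serum_of == high_level] += direction * config.effect_size_serum

    # disease genes: shift in RA lines from bone marrow and skin
    disease_tissues = [t for t in config.tissues if t != "synovium"]
    in_disease_tissue = np.isin(tissue_of, disease_tissues)
    for row_g, g in enumerate(disease_idx):
        direction = 1.0 if row_g % 2 == 0 else -1.0
        mask = (disease_of == "RA") & in_disease_tissue
        X[g, mask] += direction * config.effect_size_disease

    # OA-synovium interaction: altered in OA synovium at low serum only
    n_down = int(round(config.frac_oa_synovium_down * len(oa_idx)))
    oa_mask = ((disease_of == "OA") & (tissue_of == "synovium")
               & (serum_of == low_level))
    for row_g, g in enumerate(oa_idx):
        direction = 1.0 if row_g < n_down else -1.0  # elevated vs depressed at low serum
        X[g, oa_mask] += direction * config.effect_size_oa_synovium

    X += rng.normal(0.0, config.noise_sd, X.shape)

    values = pd.DataFrame(X, index=genes, columns=annot.index)
    truth = GroundTruth(
        site_genes=frozenset(genes[i] for i in site_idx),
        serum_genes=frozenset(genes[i] for i in serum_idx),
        disease_genes=frozenset(genes[i] for i in disease_idx),
        oa_synovium_genes=frozenset(genes[i] for i in oa_idx),
    )
    return ExpressionDataset(values, annot), truth


def oa_synovium_directions(config: SimulationConfig) -> dict[str, float]:
    """Planted low-serum sign (+1 elevated / −1 depressed) per OA-synovium gene."""
    start = config.n_site_genes + config.n_serum_genes + config.n_disease_genes
    n_down = int(round(config.frac_oa_synovium_down * config.n_oa_synovium_genes))
    return {
        f"g{start + i:05d}": (1.0 if i < n_down else -1.0)
        for i in range(config.n_oa_synovium_genes)
    }


def serum_directions(config: SimulationConfig) -> dict[str, float]:
    """Planted high-serum sign (+1 up / −1 down) per serum-response gene."""
    start = config.n_site_genes
    return {
        f"g{start + i:05d}": (1.0 if i % 2 == 0 else -1.0)
        for i in range(config.n_serum_genes)
    }


def generate_causal_network(
    truth: GroundTruth, config: SimulationConfig, n_functions: int = 12,
    genes_per_function: int = 20, concordance: float = 0.9,
    seed: int | None = None,
) -> pd.DataFrame:
    """Build a synthetic gene→function causal network over planted genes.

    Alternating functions draw their members from the planted serum-
    response set with edge directions that agree with the planted serum
    direction at the given ``concordance`` (a literature base is mostly,
    not perfectly, consistent with true biology), so a serum-response
    differential-expression result should score them as increased
    activity.  The remaining functions draw random genes with random
    directions and act as nulls.  Finding counts are random small
    integers, as in curated causal networks.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    serum_genes = sorted(truth.serum_genes)
    serum_sign = serum_directions(config)
    all_genes = [f"g{i:05d}" for i in range(config.n_genes)]
    rows = []
    for f in range(n_functions):
        serum_linked = f % 2 == 0 and serum_genes
        pool = serum_genes if serum_linked else all_genes
        size = min(genes_per_function, len(pool))
        members = rng.choice(pool, size=size, replace=False)
        for g in members:
            m_hi = int(rng.integers(2, 9))
            m_lo = int(rng.integers(0, max(2, m_hi)))
            if serum_linked:
                concordant = rng.random() < concordance
                up = serum_sign.get(g, 1.0) > 0
                direction = ("activating" if up == concordant
                             else "inhibiting")
            else:
                direction = ("activating" if rng.random() < 0.5
                             else "inhibiting")
            m_act, m_inh = (m_hi, m_lo) if direction == "activating" \
                else (m_lo, m_hi)
            rows.append({
                "gene_id": g,
                "function_id": f"function_{f:02d}",
                "direction": direction,
                "m_activating": m_act,
                "m_inhibiting": m_inh,
            })
    return pd.DataFrame(rows)


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a (YAML-derived) dict, tolerating list fields."""
    d = dict(d)
    for key in ("tissues", "serum_levels"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["tissues"] = list(d["tissues"])
    d["serum_levels"] = list(d["serum_levels"])
    return d
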