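"""End-to-end orchestration of the study replica.

Stages run in the order of the underlying study: simulate (or load) →
preprocess → classify → differential-expression hierarchy → PCA/overlap
→ downstream effects.  Each stage consumes a named seed derived from
the single config seed through a fixed counter scheme, writes its
outputs as TSV, and records SHA-256 checksums in a run manifest, so a
rerun with the same config is verifiably identical and any stage can be
reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as fio
from .classify import k_sweep
from .dataset import ExpressionDataset
from .effects import CausalNetwork, score_all_functions
from .hierarchy import pca_fit, serum_convergence, venn_overlap
from .preprocess import GeneSignature, filter_low_expression
from .sam import ComparisonSpec, hierarchy_counts, run_comparison
from .simulate import (SimulationConfig, config_from_dict, config_to_dict,
                       generate_causal_network, generate_expression)

logger = logging.getLogger(__name__)

STAGES = ("data", "preprocess", "classify", "de", "hierarchy", "effects")


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated run configuration (from YAML or built in code)."""

    outdir: str
    simulation: SimulationConfig | None = None
    inputs: dict | None = None           # expression / annotation / signature / network
    filter_quantile: float = 0.2
    signature_fdr: float = 0.03
    level_fdr: float = 0.05
    fold_change: float = 2.0
    z_call: float = 2.0
    knn_k: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9)
    label_column: str = "disease"
    n_permutations: int = 500
    n_draws: int = 10000
    seed: int = 17

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise PipelineError(
                "config must contain exactly one of a simulation block or "
                "input paths"
            )
        if self.inputs is not None:
            for key in ("expression", "annotation"):
                if key not in self.inputs:
                    raise PipelineError(f"inputs block missing {key!r}")
        for name, val in (("filter_quantile", self.filter_quantile),
                          ("signature_fdr", self.signature_fdr),
                          ("level_fdr", self.level_fdr)):
            if not 0 <= val < 1:
                raise PipelineError(f"{name} out of range [0, 1): {val}")
        if self.fold_change < 1:
            raise PipelineError("fold_change must be >= 1")
        if not self.knn_k:
            raise PipelineError("knn_k must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = config_from_dict(sim)
        if "knn_k" in raw:
            raw["knn_k"] = tuple(int(k) for k in raw["knn_k"])
        return cls(simulation=sim, **raw)

    def stage_seed(self, stage: str) -> int:
        """Documented fan-out: seed_i = (seed + 1000003·(i+1)) mod 2^31."""
        i = STAGES.index(stage)
        return (self.seed + 1000003 * (i + 1)) % 2**31

    def snapshot(self) -> dict:
        d = {
            "outdir": self.outdir,
            "filter_quantile": self.filter_quantile,
            "signature_fdr": self.signature_fdr,
            "level_fdr": self.level_fdr,
            "fold_change": self.fold_change,
            "z_call": self.z_call,
            "knn_k": list(self.knn_k),
            "label_column": self.label_column,
            "n_permutations": self.n_permutations,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "version": __version__,
        }
        if self.simulation is not None:
            d["simulation"] = config_to_dict(self.simulation)
        if self.inputs is not None:
            d["inputs"] = dict(self.inputs)
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[dict] = dc_field(default_factory=list)

    def checksums(self) -> dict[str, str]:
        out = {}
        for stage in self.stages:
            out.update(stage["outputs"])
        return out

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"config": self.config, "version": self.version,
                       "stages": self.stages}, fh, indent=2)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all six stages; halt on the first failure naming the stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot(), version=__version__)

    state: dict = {}
    for stage in STAGES:
        started = time.perf_counter()
        seed = config.stage_seed(stage)
        logger.info("stage=%s seed=%d fdr=(%.3g,%.3g) fc=%.3g", stage, seed,
                    config.signature_fdr, config.level_fdr, config.fold_change)
        try:
            outputs = _STAGE_FUNCS[stage](config, state, outdir, seed)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest.stages.append({
            "stage": stage,
            "seed": seed,
            "duration_s": round(time.perf_counter() - started, 3),
            "outputs": {name: _sha256(outdir / name) for name in outputs},
        })
    manifest.write(outdir / "manifest.json")
    return manifest


# -- stage implementations ----------------------------------------------------

def _stage_data(config, state, outdir: Path, seed: int) -> list[str]:
    if config.simulation is not None:
        dataset, truth = generate_expression(config.simulation)
        network = generate_causal_network(truth, config.simulation, seed=seed)
        state["dataset"], state["truth"], state["network_frame"] = (
            dataset, truth, network)
        fio.write_expression(dataset, outdir / "expression.tsv",
                             outdir / "annotation.tsv")
        fio.write_gmt(truth.as_dict(), outdir / "truth.gmt")
        fio.write_table(network, outdir / "network.tsv", index=False)
        return ["expression.tsv", "annotation.tsv", "truth.gmt", "network.tsv"]
    inputs = config.inputs
    state["dataset"] = fio.read_expression(inputs["expression"],
                                           inputs["annotation"])
    state["truth"] = None
    if "network" in inputs:
        state["network_frame"] = fio.read_network(inputs["network"])
    if "signature" in inputs:
        sets = fio.read_gmt(inputs["signature"])
        name, members = next(iter(sets.items()))
        state["signature"] = GeneSignature(name, tuple(members))
    return []


def _stage_preprocess(config, state, outdir: Path, seed: int) -> list[str]:
    filtered = filter_low_expression(state["dataset"], config.filter_quantile)
    state["filtered"] = filtered
    fio.write_expression(filtered, outdir / "expression_filtered.tsv",
                         outdir / "annotation_filtered.tsv")
    return ["expression_filtered.tsv", "annotation_filtered.tsv"]


def _stage_classify(config, state, outdir: Path, seed: int) -> list[str]:
    data = state["filtered"]
    signature = state.get("signature")
    if signature is None:
        truth = state["truth"]
        if truth is None:
            raise PipelineError("no signature provided and no simulation truth")
        members = sorted(truth.disease_genes | truth.oa_synovium_genes)
        signature = GeneSignature("planted_disease_signature", tuple(members))
    labels = data.annotation[config.label_column]
    report = k_sweep(data, signature, labels, config.knn_k)
    state["classification"] = report
    fio.write_table(report.to_frame(), outdir / "classification.tsv", index=False)
    fio.write_table(report.confusion, outdir / "confusion.tsv")
    return ["classification.tsv", "confusion.tsv"]


def _stage_de(config, state, outdir: Path, seed: int) -> list[str]:
    data = state["filtered"]
    tissues = tuple(pd.unique(data.annotation["tissue"]))
    signature_spec = ComparisonSpec(
        "tissue", tissues, fdr_threshold=config.signature_fdr,
        fold_change_min=config.fold_change,
    )
    signature_de = run_comparison(
        data, signature_spec, n_perm=config.n_permutations, seed=seed)
    counts = hierarchy_counts(
        data, fdr=config.level_fdr, fc=config.fold_change,
        n_perm=config.n_permutations, seed=seed + 1,
    )
    state["signature_de"], state["counts"] = signature_de, counts

    outputs = []
    fio.write_table(signature_de.table, outdir / "de_signature_multiclass.tsv")
    outputs.append("de_signature_multiclass.tsv")
    rows = [{"comparison": "top:" + k, "n_called": v}
            for k, v in counts.top_level.items()]
    for name, res in counts.results.items():
        if name in counts.top_level:
            continue
        rows.append({"comparison": name, "n_called": res.n_called})
    fio.write_table(pd.DataFrame(rows), outdir / "hierarchy_counts.tsv",
                    index=False)
    outputs.append("hierarchy_counts.tsv")
    for name, res in counts.results.items():
        fname = "de_" + name.replace("|", "_") + ".tsv"
        fio.write_table(res.table, outdir / fname)
        outputs.append(fname)
    return outputs


def _stage_hierarchy(config, state, outdir: Path, seed: int) -> list[str]:
    data = state["filtered"]
    signature_de = state["signature_de"]
    counts = state["counts"]
    genes = sorted(signature_de.called_genes) or list(data.genes)
    pca = pca_fit(data, genes)
    fio.write_table(pca.scores, outdir / "pca_scores.tsv")
    fio.write_table(pca.loadings, outdir / "pca_loadings.tsv")

    tissues = list(pd.unique(data.annotation["tissue"]))
    conv_rows, serum_sets = [], {}
    for tissue in tissues:
        sub = data.subset_where(tissue=tissue)
        disease_genes: set[str] = set()
        serum_genes: set[str] = set()
        for name, res in counts.results.items():
            if name.startswith(f"disease|{tissue}|"):
                disease_genes |= res.called_genes
            if name.startswith(f"serum|{tissue}|"):
                serum_genes |= res.called_genes
        serum_sets[tissue] = serum_genes
        ratio = None
        if disease_genes:
            ratio = serum_convergence(sub, sorted(disease_genes))
        conv_rows.append({"tissue": tissue,
                          "n_genes": len(disease_genes),
                          "convergence_ratio": ratio})
    fio.write_table(pd.DataFrame(conv_rows), outdir / "convergence.tsv",
                    index=False)

    outputs = ["pca_scores.tsv", "pca_loadings.tsv", "convergence.tsv"]
    nonempty = {t: s for t, s in serum_sets.items() if s}
    if len(nonempty) >= 2:
        report = venn_overlap(nonempty)
        rows = [{"measure": f"size:{k}", "value": v}
                for k, v in report.set_sizes.items()]
        rows += [{"measure": f"pair:{a}&{b}", "value": v}
                 for (a, b), v in report.pairwise.items()]
        rows += [{"measure": "common", "value": report.common},
                 {"measure": "union", "value": report.union},
                 {"measure": "overlap_fraction",
                  "value": report.overlap_fraction}]
        fio.write_table(pd.DataFrame(rows), outdir / "overlap.tsv", index=False)
        outputs.append("overlap.tsv")
    state["convergence"] = {r["tissue"]: r["convergence_ratio"] for r in conv_rows}
    return outputs


def _stage_effects(config, state, outdir: Path, seed: int) -> list[str]:
    frame = state.get("network_frame")
    if frame is None:
        raise PipelineError("no causal network available for the effects stage")
    network = CausalNetwork(frame)
    de = state["counts"].results.get("serum")
    if de is None:
        raise PipelineError("top-level serum comparison unavailable")
    result = score_all_functions(
        de, network, z_call=config.z_call, n_draws=config.n_draws, seed=seed)
    state["effects"] = result
    fio.write_table(result.table, outdir / "effects.tsv", index=False)
    return ["effects.tsv"]


_STAGE_FUNCS = {
    "data": _stage_data,
    "preprocess": _stage_preprocess,
    "classify": _stage_classify,
    "de": _stage_de,
    "hierarchy": _stage_hierarchy,
    "effects": _stage_effects,
}


def default_synthetic_config(outdir: str, seed: int = 17,
                             **overrides) -> PipelineConfig:
    """Convenience: a run-all config over the default generator."""
    sim = overrides.pop("simulation", SimulationConfig(seed=seed))
    return PipelineConfig(outdir=outdir, simulation=sim, seed=seed, **overrides)
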