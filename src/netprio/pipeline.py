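"""End-to-end orchestration: synth -> NGR -> combine -> modules.

A single :class:`PipelineConfig` (loadable from YAML) drives the whole
run.  One global seed determines every stochastic choice — synthetic
draws, per-model negative samples, CV folds, and Louvain order — so a
rerun with the same config reproduces byte-identical score tables.
Each run writes a ``manifest.json`` recording the seed, stage
parameters, and SHA-256 hashes of all inputs and outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from netprio import io as nio
from netprio.combine import combined_score, positional_score
from netprio.datatypes import ValidationError
from netprio.netmodules import detect_modules, extract_subnetwork
from netprio.ngr import TrainingConfig, run_ngr
from netprio.synth import SynthConfig, generate_network, generate_pvalues

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Either the three real-input paths (``network_path``, ``risk_path``,
    ``endo_path``) or a ``synth`` block must be present.  ``seed``
    overrides the seeds of the nested blocks so one number controls
    the full run.
    """

    outdir: str = "results/run"
    seed: int = 0
    network_path: str | None = None
    risk_path: str | None = None
    endo_path: str | None = None
    synth: SynthConfig | None = None
    training: TrainingConfig = field(default_factory=TrainingConfig)
    alpha: float = 0.01
    fs_threshold: float = 2.0
    edge_min: float = 0.25
    top_k: int = 10

    def __post_init__(self) -> None:
        real = all(p is not None for p in
                   (self.network_path, self.risk_path, self.endo_path))
        if not real and self.synth is None:
            raise ValidationError(
                "config needs either network/risk/endo paths or a synth block"
            )
        if not (0.0 < self.alpha <= 1.0):
            raise ValidationError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.edge_min < 0:
            raise ValidationError("edge_min must be >= 0")
        # one global seed rules every stage
        self.training = dataclasses.replace(self.training, seed=self.seed)
        if self.synth is not None:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "synth" in raw and isinstance(raw["synth"], dict):
            raw["synth"] = SynthConfig(**raw["synth"])
        if "training" in raw and isinstance(raw["training"], dict):
            raw["training"] = TrainingConfig(**raw["training"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha,
            "fs_threshold": config.fs_threshold,
            "edge_min": config.edge_min,
            "n_models": config.training.n_models,
            "c_grid": list(config.training.c_grid),
            "n_folds": config.training.n_folds,
            "top_k": config.top_k,
        },
        "stages": {},
        "inputs": {},
        "outputs": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "inputs"
    try:
        if config.synth is not None:
            stage = "synth"
            network, truth = generate_network(config.synth)
            risk = generate_pvalues(truth, config.synth, "risk")
            endo = generate_pvalues(truth, config.synth, "endo")
            nio.write_network(network, outdir / "network.tsv")
            nio.write_gene_pvalues(risk, outdir / "risk_pvalues.tsv")
            nio.write_gene_pvalues(endo, outdir / "endo_pvalues.tsv")
            nio.write_truth(truth, outdir / "truth.tsv")
            for name in ("network.tsv", "risk_pvalues.tsv",
                         "endo_pvalues.tsv", "truth.tsv"):
                record(name, outdir / name)
            manifest["stages"]["synth"] = dataclasses.asdict(config.synth)
        else:
            network = nio.read_network(config.network_path)
            risk = nio.read_gene_pvalues(config.risk_path, "risk")
            endo = nio.read_gene_pvalues(config.endo_path, "endo")
            for label, p in (("network", config.network_path),
                             ("risk", config.risk_path),
                             ("endo", config.endo_path)):
                manifest["inputs"][label] = {
                    "path": str(p), "sha256": _sha256(Path(p))
                }

        stage = "ngr"
        fs = run_ngr(network, risk, config.training, alpha=config.alpha)
        nio.write_functional_scores(fs, outdir / "functional_scores.tsv")
        record("functional_scores.tsv", outdir / "functional_scores.tsv")
        manifest["stages"]["ngr"] = {
            "n_positives": fs.scores.attrs.get("n_positives"),
            "chosen_C": fs.scores.attrs.get("chosen_C"),
        }

        stage = "combine"
        ps = positional_score(endo)
        cs = combined_score(fs, ps)
        shared = cs.scores.index
        cs.scores["p"] = endo.pvalues.loc[shared]
        nio.write_combined_scores(cs, outdir / "combined_scores.tsv")
        record("combined_scores.tsv", outdir / "combined_scores.tsv")
        cs.top(config.top_k).rename_axis("gene").reset_index().to_csv(
            outdir / "top_genes.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        record("top_genes.tsv", outdir / "top_genes.tsv")
        manifest["stages"]["combine"] = {"n_jointly_scored": cs.n}

        stage = "modules"
        sub = extract_subnetwork(network, fs, config.fs_threshold, config.edge_min)
        partition = detect_modules(sub, seed=config.seed)
        nio.write_network(sub, outdir / "subnetwork.tsv")
        record("subnetwork.tsv", outdir / "subnetwork.tsv")
        nio.write_module_assignment(partition, fs, outdir / "modules.tsv")
        record("modules.tsv", outdir / "modules.tsv")
        manifest["stages"]["modules"] = {
            "n_nodes": sub.number_of_nodes(),
            "n_edges": sub.number_of_edges(),
            "n_modules": partition.n_modules,
            "modularity": partition.q,
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = json.loads(json.dumps(manifest))  # JSON-native types only
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
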