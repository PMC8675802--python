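"""End-to-end runs: read -> (rank/select) -> normalize -> train -> network.

:func:`run_pipeline` wires the stages together for one or two conditions,
writes every artifact (candidate table, network exports, edges-vs-theta
table, comparison report) plus a JSON manifest recording the exact
configuration, and is byte-reproducible for equal configs and seeds.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .expression import (
    ExpressionMatrix,
    read_expression_table,
    read_geo_soft_gds,
    select_genes,
    wilcoxon_rank_genes,
)
from .model import GeneInteractionModel, GeneInteractionResults
from .network import DEFAULT_THETA, export_network
from .paired_rbm import RBMPairConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one reproducible run depends on."""

    inputs: list[str]
    output_dir: str
    condition_labels: list[str] = field(default_factory=list)
    genes: list[str] | None = None
    theta: float = DEFAULT_THETA
    learning_rate: float = 0.1
    max_epochs: int = 1000
    error_tol: float = 0.01
    weight_diff_break: float = 0.01
    seed: int = 0
    formats: list[str] = field(default_factory=lambda: ["tsv"])
    theta_grid: list[float] = field(
        default_factory=lambda: [round(0.004 + 0.002 * i, 3) for i in range(7)]
    )
    delimiter: str = "\t"

    def rbm_config(self) -> RBMPairConfig:
        return RBMPairConfig(
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            error_tol=self.error_tol,
            weight_diff_break=self.weight_diff_break,
            seed=self.seed,
        )


def _load(path: str, delimiter: str) -> ExpressionMatrix:
    if path.lower().endswith(".soft") or path.lower().endswith(".soft.txt"):
        return read_geo_soft_gds(path)
    return read_expression_table(path, delimiter=delimiter)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full procedure and write artifacts to ``output_dir``.

    Returns the manifest dict (also written as ``manifest.json``).
    With two inputs, both conditions are fitted on the same gene set and a
    comparison report partitioning their edge pairs is emitted.
    """
    if not config.inputs:
        raise PipelineError("stage 'read' failed: no input files")
    if len(config.inputs) > 2:
        raise PipelineError("stage 'read' failed: at most two conditions supported")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    labels = list(config.condition_labels)
    while len(labels) < len(config.inputs):
        labels.append(f"condition{len(labels) + 1}")

    matrices = [
        _stage("read")(_load, path, config.delimiter) for path in config.inputs
    ]
    if config.genes:
        matrices = [_stage("select")(select_genes, m, config.genes) for m in matrices]

    results: list[GeneInteractionResults] = []
    artifact_paths: list[str] = []
    for matrix, label in zip(matrices, labels):
        model = _stage("train")(
            GeneInteractionModel,
            matrix,
            config.rbm_config(),
            None,
            label,
        )
        res = _stage("train")(model.fit, config.theta)
        results.append(res)

        cand_path = out / f"candidates_{label}.tsv"
        frame = res.candidates_frame()
        frame.to_csv(cand_path, sep="\t", index=False, float_format="%.17g")
        artifact_paths.append(str(cand_path))

        for fmt in config.formats:
            suffix = {"tsv": "tsv", "graphml": "graphml", "dot": "dot"}.get(fmt)
            if suffix is None:
                raise PipelineError(f"stage 'export' failed: unknown format {fmt!r}")
            net_path = out / f"network_{label}.{suffix}"
            _stage("export")(export_network, res.network, net_path, fmt)
            artifact_paths.append(str(net_path))

        curve = res.edges_vs_threshold(config.theta_grid)
        curve_path = out / f"edges_vs_theta_{label}.tsv"
        pd.DataFrame(curve, columns=["theta", "edges"]).to_csv(
            curve_path, sep="\t", index=False
        )
        artifact_paths.append(str(curve_path))

    if len(results) == 2:
        report = results[0].compare(results[1])
        report_path = out / "comparison.json"
        report_path.write_text(report.to_json() + "\n")
        artifact_paths.append(str(report_path))

    manifest = {
        "tool": "rbmgrn",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": {
            "inputs": list(config.inputs),
            "condition_labels": labels,
            "genes": list(config.genes) if config.genes else None,
            "theta": config.theta,
            "learning_rate": config.learning_rate,
            "max_epochs": config.max_epochs,
            "error_tol": config.error_tol,
            "weight_diff_break": config.weight_diff_break,
            "seed": config.seed,
            "formats": list(config.formats),
            "theta_grid": list(config.theta_grid),
        },
        "artifacts": artifact_paths,
        "edges": {
            label: len(res.network.edges) for label, res in zip(labels, results)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline finished; %d artifact(s) in %s", len(artifact_paths), out)
    return manifest
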