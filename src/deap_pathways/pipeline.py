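"""End-to-end orchestration: study + pathway collection -> results table."""

from __future__ import annotations

import json
import hashlib
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path as FsPath
from typing import IO, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .expression import ExpressionStudy, expression_summary
from .inference import RotationConfig, rotated_summaries, storey_qvalues
from .pathway import PathwayGraph
from .scoring import DeapResult, deap_score, deap_statistic

logger = logging.getLogger(__name__)

__all__ = ["analyze_study", "results_table", "write_results", "RunManifest"]

RESULT_COLUMNS = ("pathway_id", "score", "signed_score", "path",
                  "p_value", "q_value", "n_measured", "n_proteins")


def analyze_study(study: ExpressionStudy, graphs: Sequence[PathwayGraph],
                  config: RotationConfig | None = None) -> list[DeapResult]:
    """Score every pathway against one study and attach p- and q-values.

    One rotation stream is drawn for the dataset and shared across all
    pathways (as permutation tests share shuffles), so the joint null
    preserves cross-pathway correlation.  Results are sorted by q-value,
    then p-value, then pathway_id.
    """
    if not graphs:
        raise ValueError("no pathways supplied")
    if config is None:
        config = RotationConfig.for_study(study)
    summary = expression_summary(study)
    measured = set(summary.values)
    overlap = [g for g in graphs if g.member_proteins() & measured]
    if not overlap:
        pathway_examples = sorted(graphs[0].member_proteins())[:3]
        study_examples = list(study.values.index[:3])
        raise ValueError(
            "no overlap between expression identifiers and pathway members "
            f"(pathway IDs look like {pathway_examples}, study IDs look "
            f"like {study_examples})")

    rng = np.random.default_rng(config.seed)
    null_summaries = rotated_summaries(study, config, rng)
    results = []
    for graph in graphs:
        result = deap_score(graph, summary)
        null_stats = np.fromiter(
            (deap_statistic(graph, s) for s in null_summaries),
            dtype=float, count=config.n_rotations)
        exceed = int(np.sum(null_stats >= result.statistic))
        if config.plus_one:
            result.p_value = (1.0 + exceed) / (config.n_rotations + 1.0)
        else:
            result.p_value = exceed / config.n_rotations
        logger.info("pathway %s: coverage %d/%d measured proteins",
                    graph.pathway_id, result.n_measured, result.n_proteins)
        results.append(result)
    qvalues = storey_qvalues([r.p_value for r in results])
    for result, q in zip(results, qvalues):
        result.q_value = float(q)
    results.sort(key=lambda r: (r.q_value, r.p_value, r.pathway_id))
    return results


def results_table(results: Sequence[DeapResult]) -> pd.DataFrame:
    rows = [{
        "pathway_id": r.pathway_id,
        "score": r.statistic,
        "signed_score": r.signed_score,
        "path": r.path_string(),
        "p_value": r.p_value,
        "q_value": r.q_value,
        "n_measured": r.n_measured,
        "n_proteins": r.n_proteins,
    } for r in results]
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(results: Sequence[DeapResult], stream: IO[str],
                  provenance: dict | None = None) -> None:
    """Write the results TSV with provenance comment headers."""
    for key, value in (provenance or {}).items():
        stream.write(f"# {key}: {value}\n")
    table = results_table(results)
    table.to_csv(stream, sep="\t", index=False, float_format="%.6g",
                 lineterminator="\n")


@dataclass
class RunManifest:
    """Reproducibility record written alongside every output."""

    inputs: dict[str, str]
    parameters: dict
    seed: int | None
    versions: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    @staticmethod
    def file_digest(path: str | FsPath) -> str:
        digest = hashlib.sha256()
        with open(path, "rb") as handle:
            for chunk in iter(lambda: handle.read(65536), b""):
                digest.update(chunk)
        return digest.hexdigest()

    @classmethod
    def create(cls, input_paths: dict[str, str], parameters: dict,
               seed: int | None) -> "RunManifest":
        versions = {"deap_pathways": __version__,
                    "python": platform.python_version(),
                    "numpy": np.__version__, "pandas": pd.__version__}
        inputs = {name: f"{path}:sha256:{cls.file_digest(path)}"
                  for name, path in input_paths.items()}
        return cls(inputs=inputs, parameters=parameters, seed=seed,
                   versions=versions,
                   timestamp=datetime.now(timezone.utc).isoformat())

    def write(self, path: str | FsPath) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.__dict__, handle, indent=2, sort_keys=True)
            handle.write("\n")
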