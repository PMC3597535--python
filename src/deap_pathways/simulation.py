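"""Synthetic expression data on pathway fixtures.

Each gene *i* in a pathway is simulated as

    x_ij = d_i * (mu + g_i) + e_ij

where ``d_i`` in {-1, 0, +1} says whether the gene is 'on' and in which
direction, ``mu >= 0`` is the pathway effect (the mean absolute expression of
'on' genes), ``g_i ~ Normal(0, sigma2_g)`` is a per-gene deviation drawn once
and shared across replicate samples, and ``e_ij ~ Normal(0, 1)`` is fresh
noise per gene and sample.  Values are treated as paired log-ratios (zero-
centred under the null), so the per-protein summary is the row mean.

Five pathway fixtures ship with the package (see ``fixtures/``): a catalytic
string, an inhibitory string with alternating up/down regulation, a string
mixing both edge types, a branched crossroads where only one 3-node route is
'on', and a 14-protein pathway whose designed differentially expressed path
covers only 4 proteins while a long alternate route of background genes
connects the same endpoints.  Each fixture designates its true path, which
the recovery benchmarks compare against the reported maximal path.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path as FsPath

import numpy as np
import pandas as pd
import yaml

from .expression import PAIRED, ExpressionStudy
from .pathway import PathwayGraph, parse_pathway_table

__all__ = [
    "SimulationSpec",
    "PathwayFixture",
    "simulate_study",
    "fixture_registry",
    "load_fixture_config",
]


@dataclass
class SimulationSpec:
    """Parameters of one simulated study."""

    mu: float = 0.0
    sigma2_g: float = 0.0
    n_samples: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.sigma2_g < 0:
            raise ValueError("sigma2_g must be >= 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


@dataclass
class PathwayFixture:
    """A pathway topology bound to its d assignment and designed true path."""

    name: str
    graph: PathwayGraph
    d: dict[str, int]
    true_path_nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        known = self.graph.member_proteins()
        for protein, value in self.d.items():
            if protein not in known:
                raise ValueError(
                    f"fixture {self.name!r}: d assigned to unknown protein "
                    f"{protein!r}")
            if value not in (-1, 0, 1):
                raise ValueError(
                    f"fixture {self.name!r}: d[{protein!r}] = {value} "
                    "not in {-1, 0, +1}")
        for node in self.true_path_nodes:
            if node not in self.graph.nodes:
                raise ValueError(
                    f"fixture {self.name!r}: true path references unknown "
                    f"node {node!r}")

    @property
    def proteins(self) -> list[str]:
        """Simulation gene order: sorted member proteins."""
        return sorted(self.graph.member_proteins())

    @property
    def true_path_set(self) -> frozenset[str]:
        return frozenset(self.true_path_nodes)


def simulate_study(fixture: PathwayFixture, spec: SimulationSpec,
                   rng: np.random.Generator | None = None) -> ExpressionStudy:
    """Draw one study on a fixture (paired mode, ``spec.n_samples`` columns).

    With an explicit ``rng`` the spec's seed is ignored, which lets a caller
    stream many replicates from one generator.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    proteins = fixture.proteins
    d = np.array([fixture.d.get(p, 0) for p in proteins], dtype=float)
    g = rng.normal(0.0, np.sqrt(spec.sigma2_g), size=len(proteins))
    e = rng.standard_normal((len(proteins), spec.n_samples))
    values = d[:, None] * (spec.mu + g)[:, None] + e
    columns = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    frame = pd.DataFrame(values, index=proteins, columns=columns)
    design = pd.DataFrame({"condition": "log-ratio"}, index=frame.columns)
    design.index.name = "sample_id"
    return ExpressionStudy(frame, design, mode=PAIRED)


def _load_fixtures(pathway_stream, node_table: pd.DataFrame
                   ) -> list[PathwayFixture]:
    graphs = {g.pathway_id: g for g in parse_pathway_table(pathway_stream)}
    fixtures = []
    for name, group in node_table.groupby("pathway_id", sort=False):
        if name not in graphs:
            raise ValueError(f"node table references unknown pathway {name!r}")
        d = dict(zip(group["protein"].astype(str), group["d"].astype(int)))
        on_path = group[group["true_path_order"] > 0]
        ordered = on_path.sort_values("true_path_order")["protein"].astype(str)
        fixtures.append(PathwayFixture(str(name), graphs[name], d,
                                       tuple(ordered)))
    return fixtures


def fixture_registry() -> list[PathwayFixture]:
    """The five built-in simulated pathway fixtures."""
    package = importlib.resources.files("deap_pathways") / "fixtures"
    with (package / "simulated_pathways.tsv").open() as handle:
        pathway_stream = handle.read().splitlines(keepends=True)
    with (package / "simulated_nodes.tsv").open() as handle:
        nodes = pd.read_csv(handle, sep="\t", comment="#")
    return _load_fixtures(iter(pathway_stream), nodes)


def load_fixture_config(path: str | FsPath) -> list[PathwayFixture]:
    """Load user-supplied fixtures from a YAML config.

    The config maps ``pathways`` and ``nodes`` to TSV paths in the same
    formats as the built-in fixture files, enabling recovery/power scenarios
    on arbitrary (e.g. database-derived) topologies.
    """
    path = FsPath(path)
    with open(path, encoding="utf-8") as handle:
        config = yaml.safe_load(handle)
    for key in ("pathways", "nodes"):
        if key not in config:
            raise ValueError(f"fixture config missing {key!r} entry")
    base = path.parent
    pathway_path = base / config["pathways"]
    nodes = pd.read_csv(base / config["nodes"], sep="\t", comment="#")
    with open(pathway_path, encoding="utf-8") as handle:
        return _load_fixtures(handle, nodes)
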