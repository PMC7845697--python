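"""Synthetic data with a planted, recoverable compound–disease signal.

The generators emulate the real inputs of the pipeline at desk scale: a
scale-free-like protein network (preferential attachment) with disease
modules planted as connected balls, compounds whose targets sit near (their
disease's) module or are drawn uniformly (negatives), class-conditionally
shifted descriptor tables, and a name-embedding table with group structure
aligned to the labels.  Every generator is a pure function of its config:
reruns under a fixed seed are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io_core
from .chemical_features import DescriptorSchema, SchemaColumn
from .io_core import CompoundProfile, LabelMatrix
from .knowledge_embedding import VectorTable, write_vector_table

__all__ = [
    "FixtureConfig",
    "FixtureData",
    "generate_network",
    "plant_disease_modules",
    "generate_compounds_with_signal",
    "generate_descriptor_table",
    "generate_embedding_table",
    "fixture_schema",
    "generate_fixture",
    "write_fixture",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions of the synthetic benchmark.

    Defaults give a 300-node network with 3 planted disease modules and 150
    compounds (5 targets each), 40% of which carry a signal for exactly one
    disease; labels are noise-free by default.
    """

    n_nodes: int = 300
    edges_per_node: int = 3
    n_diseases: int = 3
    module_size: int = 12
    n_compounds: int = 150
    targets_per_compound: int = 5
    positive_fraction: float = 0.4
    noise_rate: float = 0.0
    embedding_dim: int = 300
    descriptor_shift: float = 1.0
    direct_target_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size >= self.n_nodes:
            raise ValueError("module_size must be smaller than n_nodes")
        if not 0 <= self.noise_rate <= 0.5:
            raise ValueError("noise_rate must be in [0, 0.5]")
        if not 0 <= self.positive_fraction <= 1:
            raise ValueError("positive_fraction must be a probability")


def _rng(config: FixtureConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generator
    return np.random.default_rng([config.seed % (2**31), stream])


def _node_name(i: int) -> str:
    return f"P{i:05d}"


def generate_network(config: FixtureConfig) -> nx.Graph:
    """Connected simple undirected graph grown by preferential attachment.

    Mimics the degree heterogeneity of protein-interaction networks: each new
    node attaches to ``edges_per_node`` existing nodes chosen proportionally
    to degree.
    """
    if config.n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    rng = _rng(config, 1)
    seed_int = int(rng.integers(2**31))
    graph = nx.barabasi_albert_graph(
        config.n_nodes, config.edges_per_node, seed=seed_int
    )
    return nx.relabel_nodes(graph, {i: _node_name(i) for i in graph.nodes})


def plant_disease_modules(
    graph: nx.Graph, config: FixtureConfig
) -> dict[str, set[str]]:
    """Breadth-first balls around random roots: connected, possibly overlapping."""
    if config.module_size < 3:
        raise ValueError("module_size must be at least 3")
    rng = _rng(config, 2)
    nodes = sorted(graph.nodes)
    modules = {}
    for d in range(config.n_diseases):
        root = nodes[int(rng.integers(len(nodes)))]
        members = [root]
        seen = {root}
        frontier = [root]
        while len(members) < config.module_size and frontier:
            nxt = []
            for node in frontier:
                for nb in sorted(graph.neighbors(node)):
                    if nb not in seen:
                        seen.add(nb)
                        members.append(nb)
                        nxt.append(nb)
                        if len(members) >= config.module_size:
                            break
                if len(members) >= config.module_size:
                    break
            frontier = nxt
        modules[f"D{d + 1:03d}"] = set(members)
    return modules


def generate_compounds_with_signal(
    graph: nx.Graph,
    modules: dict[str, set[str]],
    config: FixtureConfig,
) -> tuple[list[CompoundProfile], LabelMatrix]:
    """Compound target profiles plus the binary label matrix.

    A positive compound is assigned one disease and draws at least half its
    targets from within distance 1 of that disease's module; negatives draw
    targets uniformly.  Each label is then flipped independently with
    probability ``noise_rate``.
    """
    if config.targets_per_compound < 1:
        raise ValueError("need at least one target per compound")
    rng = _rng(config, 3)
    nodes = sorted(graph.nodes)
    disease_ids = sorted(modules)
    halo = {}  # module plus its distance-1 neighborhood
    for d in disease_ids:
        ball = set(modules[d])
        for g in modules[d]:
            ball.update(graph.neighbors(g))
        halo[d] = sorted(ball)

    profiles = []
    values = np.zeros((config.n_compounds, len(disease_ids)), dtype=int)
    for i in range(config.n_compounds):
        cid = f"C{i:04d}"
        is_pos = rng.random() < config.positive_fraction
        if is_pos:
            d_idx = int(rng.integers(len(disease_ids)))
            values[i, d_idx] = 1
            n_near = int(np.ceil(config.targets_per_compound / 2))
            # plant the signal inside the module itself (distance 0 ≤ 1);
            # the distance-1 halo is hub-contaminated in scale-free graphs
            pool = sorted(modules[disease_ids[d_idx]])
            if len(pool) < n_near:
                pool = halo[disease_ids[d_idx]]
            near = rng.choice(pool, size=min(n_near, len(pool)), replace=False)
            rest = rng.choice(nodes, size=config.targets_per_compound - len(near),
                              replace=False)
            targets = list(dict.fromkeys([*near, *rest]))
        else:
            targets = list(
                rng.choice(nodes, size=config.targets_per_compound, replace=False)
            )
        n_direct = max(1, int(round(config.direct_target_fraction * len(targets))))
        profiles.append(
            CompoundProfile(
                id=cid,
                direct_targets=set(targets[:n_direct]),
                indirect_targets=set(targets[n_direct:]),
                name=f"compound-{i:04d}",
            )
        )
    flips = rng.random(values.shape) < config.noise_rate
    noisy = np.where(flips, 1 - values, values)
    labels = LabelMatrix(
        compound_ids=[p.id for p in profiles],
        disease_ids=disease_ids,
        values=noisy,
    )
    return profiles, labels


def fixture_schema() -> DescriptorSchema:
    """Compact descriptor schema used by the synthetic tables."""
    return DescriptorSchema(
        columns=(
            SchemaColumn("mw", "zscore"),
            SchemaColumn("heavy_atoms", "zscore"),
            SchemaColumn("rotatable_bonds", "zscore"),
            SchemaColumn("hba", "zscore"),
            SchemaColumn("hbd", "zscore"),
            SchemaColumn("molar_refractivity", "zscore"),
            SchemaColumn("consensus_logp", "passthrough"),
            SchemaColumn("esol_logs", "passthrough"),
            SchemaColumn("gi_absorption", "categorical", ("low", "high")),
            SchemaColumn("lipinski_violations", "categorical", (0, 1, 2)),
        )
    )


def generate_descriptor_table(
    labels: LabelMatrix, config: FixtureConfig
) -> pd.DataFrame:
    """Class-conditional descriptor table over the fixture schema.

    Numeric descriptors are Gaussian with mean shifted by ``descriptor_shift``
    (in SD units) for compounds positive for any disease; categorical
    descriptors are drawn from class-conditional multinomials.
    """
    rng = _rng(config, 4)
    schema = fixture_schema()
    positive = labels.values.any(axis=1)
    n = len(labels.compound_ids)
    data: dict[str, list] = {"id": list(labels.compound_ids)}
    for col in schema.columns:
        if col.kind in ("zscore", "passthrough"):
            shift = np.where(positive, config.descriptor_shift, 0.0)
            data[col.name] = list(rng.normal(loc=shift, scale=1.0, size=n))
        else:
            k = len(col.categories)
            # positives lean toward the last category, negatives the first
            p_pos = np.full(k, 0.5 / (k - 1)) if k > 1 else np.ones(1)
            p_neg = p_pos.copy()
            if k > 1:
                p_pos[-1] = 0.5
                p_neg[:] = 0.5 / (k - 1)
                p_neg[0] = 0.5
            draws = [
                col.categories[int(rng.choice(k, p=p_pos if positive[i] else p_neg))]
                for i in range(n)
            ]
            data[col.name] = draws
    return pd.DataFrame(data)


def generate_embedding_table(
    names: dict[str, str],
    groups: dict[str, int],
    n_groups: int,
    dim: int = 300,
    seed: int = 0,
    noise_sd: float = 0.35,
) -> VectorTable:
    """Name-vector table with group structure: centroid + isotropic noise.

    ``groups`` maps each id in ``names`` to a group index < ``n_groups``;
    each name's vector is its group centroid plus Gaussian noise, emulating a
    literature-trained embedding in which therapeutically related compounds
    cluster.
    """
    rng = np.random.default_rng([seed % (2**31), 5])
    centroids = rng.standard_normal((n_groups, dim))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    entries = {}
    for cid, name in names.items():
        g = groups[cid]
        vec = centroids[g] + noise_sd * rng.standard_normal(dim) / np.sqrt(dim)
        token = " ".join(preprocess_name(name))
        entries[token] = vec
    return VectorTable(dim=dim, entries=entries)


def preprocess_name(name: str) -> list[str]:
    from .knowledge_embedding import preprocess

    return preprocess(name)


@dataclass
class FixtureData:
    """All artifacts of one synthetic study, plus generator bookkeeping."""

    config: FixtureConfig
    graph: nx.Graph
    modules: dict[str, set[str]]
    profiles: list[CompoundProfile]
    labels: LabelMatrix
    descriptors: pd.DataFrame
    embeddings: VectorTable
    report: dict = field(default_factory=dict)


def generate_fixture(config: FixtureConfig | None = None) -> FixtureData:
    """Run every generator under one config (single source of randomness)."""
    config = config or FixtureConfig()
    graph = generate_network(config)
    modules = plant_disease_modules(graph, config)
    profiles, labels = generate_compounds_with_signal(graph, modules, config)
    descriptors = generate_descriptor_table(labels, config)
    # group 0 = no indication; group d = positive for disease d
    groups = {}
    for i, cid in enumerate(labels.compound_ids):
        row = labels.values[i]
        groups[cid] = int(np.argmax(row)) + 1 if row.any() else 0
    names = {p.id: p.name for p in profiles}
    embeddings = generate_embedding_table(
        names,
        groups,
        n_groups=config.n_diseases + 1,
        dim=config.embedding_dim,
        seed=config.seed,
    )
    report = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "n_compounds": len(profiles),
        "targets_per_compound": {
            p.id: len(p.targets) for p in profiles
        },
        "positives_per_disease": labels.values.sum(axis=0).tolist(),
    }
    return FixtureData(
        config=config,
        graph=graph,
        modules=modules,
        profiles=profiles,
        labels=labels,
        descriptors=descriptors,
        embeddings=embeddings,
        report=report,
    )


def write_fixture(data: FixtureData, out_dir: str | Path) -> dict[str, Path]:
    """Write all five artifacts in the package's text formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network.tsv",
        "targets": out / "targets.tsv",
        "disease_genes": out / "disease_genes.tsv",
        "labels": out / "labels.tsv",
        "descriptors": out / "descriptors.csv",
        "embeddings": out / "vectors.txt",
    }
    io_core.write_edge_list(data.graph, paths["network"])
    io_core.write_targets(
        {p.id: (p.direct_targets, p.indirect_targets) for p in data.profiles},
        paths["targets"],
    )
    io_core.write_disease_genes(data.modules, paths["disease_genes"])
    pairs = [
        (c, d)
        for i, c in enumerate(data.labels.compound_ids)
        for j, d in enumerate(data.labels.disease_ids)
        if data.labels.values[i, j]
    ]
    io_core.write_label_pairs(pairs, paths["labels"])
    data.descriptors.to_csv(paths["descriptors"], index=False)
    write_vector_table(data.embeddings, paths["embeddings"])
    return paths
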