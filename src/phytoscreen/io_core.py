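"""Readers/writers for the tabular and graph formats used across the package.

All tables are UTF-8 text, tab- or comma-separated, with ``#`` comment lines.
The module also owns label-matrix construction from drug→MeSH mappings and the
assembly of named feature blocks into the single model input matrix.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CompoundProfile",
    "LabelMatrix",
    "FeatureMatrix",
    "read_edge_list",
    "write_edge_list",
    "read_targets",
    "write_targets",
    "profiles_from_targets",
    "filter_min_targets",
    "read_label_pairs",
    "write_label_pairs",
    "build_label_matrix",
    "assemble_features",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_disease_genes",
    "write_disease_genes",
]

#: fixed concatenation order of the three feature blocks
BLOCK_ORDER = ("latent", "interaction", "chemical")


@dataclass
class CompoundProfile:
    """One compound or drug with its target annotation.

    ``direct_targets`` are physical binding targets; ``indirect_targets`` are
    downstream molecular effects (expression changes, metabolite action).  The
    two sets are disjoint: a protein annotated both ways is kept as direct.
    """

    id: str
    direct_targets: set[str] = field(default_factory=set)
    indirect_targets: set[str] = field(default_factory=set)
    name: str = ""
    descriptor_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indirect_targets -= self.direct_targets

    @property
    def targets(self) -> set[str]:
        return self.direct_targets | self.indirect_targets


@dataclass
class LabelMatrix:
    """Binary compound × disease indication matrix."""

    compound_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.compound_ids), len(self.disease_ids)):
            raise ValueError("label matrix shape does not match id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("label matrix must be binary")

    def column(self, disease_id: str) -> np.ndarray:
        return self.values[:, self.disease_ids.index(disease_id)]


@dataclass
class FeatureMatrix:
    """Row-indexed numeric matrix partitioned into named column blocks."""

    row_ids: list[str]
    block_spans: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        total = sum(w for _, w in self.block_spans)
        if total != self.values.shape[1]:
            raise ValueError(
                f"block widths sum to {total} but matrix has "
                f"{self.values.shape[1]} columns"
            )
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def block(self, name: str) -> np.ndarray:
        """Column slice of one named block."""
        start = 0
        for bname, w in self.block_spans:
            if bname == name:
                return self.values[:, start : start + w]
            start += w
        raise KeyError(name)

    def rows(self, ids: Sequence[str]) -> np.ndarray:
        index = {r: i for i, r in enumerate(self.row_ids)}
        return self.values[[index[i] for i in ids]]


# ---------------------------------------------------------------------------
# graph I/O


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a two-column whitespace-separated edge list into an undirected graph.

    Self-loops are dropped and duplicate edges collapsed; the node set is the
    union of all endpoints (so a node appearing only in a self-loop survives).
    """
    graph = nx.Graph()
    n_lines = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed edge line {lineno}: {line!r}")
            n_lines += 1
            u, v = parts[0], parts[1]
            graph.add_node(u)
            graph.add_node(v)
            if u != v:
                graph.add_edge(u, v)
    if n_lines == 0:
        raise ValueError("no edges")
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")
        for n in sorted(graph.nodes):
            if graph.degree(n) == 0:
                fh.write(f"{n}\t{n}\n")  # keep isolated nodes round-trippable


# ---------------------------------------------------------------------------
# target tables

_BINDING_TYPES = {"direct", "indirect"}


def read_targets(path: str | Path) -> dict[str, tuple[set[str], set[str]]]:
    """Read a (compound, protein, binding_type) TSV into per-compound sets.

    A protein annotated both direct and indirect for one compound is kept as
    direct only.
    """
    direct: dict[str, set[str]] = defaultdict(set)
    indirect: dict[str, set[str]] = defaultdict(set)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:1] == ["compound_id"]:
                continue
            if len(parts) < 3:
                raise ValueError(f"target row {lineno} lacks a column: {line!r}")
            compound, protein, kind = parts[0], parts[1], parts[2]
            if kind not in _BINDING_TYPES:
                raise ValueError(
                    f"unknown binding type {kind!r} on row {lineno}"
                )
            if kind == "direct":
                direct[compound].add(protein)
            else:
                indirect[compound].add(protein)
    out = {}
    for compound in sorted(set(direct) | set(indirect)):
        d = direct.get(compound, set())
        i = indirect.get(compound, set()) - d
        out[compound] = (d, i)
    return out


def write_targets(
    targets: Mapping[str, tuple[set[str], set[str]]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("compound_id\tprotein_id\tbinding_type\n")
        for compound in sorted(targets):
            d, i = targets[compound]
            for protein in sorted(d):
                fh.write(f"{compound}\t{protein}\tdirect\n")
            for protein in sorted(i):
                fh.write(f"{compound}\t{protein}\tindirect\n")


def profiles_from_targets(
    targets: Mapping[str, tuple[set[str], set[str]]],
    names: Mapping[str, str] | None = None,
) -> list[CompoundProfile]:
    names = names or {}
    return [
        CompoundProfile(
            id=c,
            direct_targets=set(d),
            indirect_targets=set(i),
            name=names.get(c, c),
        )
        for c, (d, i) in targets.items()
    ]


def filter_min_targets(
    profiles: Iterable[CompoundProfile], k: int
) -> list[CompoundProfile]:
    """Keep profiles with at least ``k`` targets (direct ∪ indirect), order preserved."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [p for p in profiles if len(p.targets) >= k]


# ---------------------------------------------------------------------------
# labels


def read_label_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read (drug_id, disease_id) pairs, one per row."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:1] == ["drug_id"]:
                continue
            if len(parts) < 2:
                raise ValueError(f"label row {lineno} lacks a column: {line!r}")
            pairs.append((parts[0], parts[1]))
    return pairs


def write_label_pairs(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tdisease_id\n")
        for drug, disease in pairs:
            fh.write(f"{drug}\t{disease}\n")


def build_label_matrix(
    mapping: Iterable[tuple[str, str]] | Mapping[str, Iterable[str]],
    n_diseases: int = 15,
) -> LabelMatrix:
    """Build the binary label matrix over the most frequent disease terms.

    Selects the ``n_diseases`` disease identifiers mapped to the largest number
    of distinct drugs (ties broken lexicographically by id), the standard
    top-15 selection used for the indication labels.
    """
    if isinstance(mapping, Mapping):
        pairs = [(d, m) for d, ms in mapping.items() for m in ms]
    else:
        pairs = list(mapping)
    if not pairs:
        raise ValueError("empty drug-disease mapping")
    per_disease = defaultdict(set)
    for drug, disease in pairs:
        per_disease[disease].add(drug)
    if n_diseases > len(per_disease):
        raise ValueError(
            f"requested {n_diseases} diseases but mapping has {len(per_disease)}"
        )
    ranked = sorted(per_disease, key=lambda m: (-len(per_disease[m]), m))
    chosen = sorted(ranked[:n_diseases])
    drugs = sorted({d for d, _ in pairs})
    values = np.zeros((len(drugs), len(chosen)), dtype=int)
    row = {d: i for i, d in enumerate(drugs)}
    col = {m: j for j, m in enumerate(chosen)}
    for drug, disease in pairs:
        if disease in col:
            values[row[drug], col[disease]] = 1
    return LabelMatrix(compound_ids=drugs, disease_ids=chosen, values=values)


def align_labels(lm: LabelMatrix, ids: Sequence[str]) -> LabelMatrix:
    """Re-index a label matrix onto a compound universe.

    Compounds absent from the matrix get all-zero rows (no known indication);
    compounds absent from ``ids`` are dropped.
    """
    idx = {c: i for i, c in enumerate(lm.compound_ids)}
    values = np.zeros((len(ids), len(lm.disease_ids)), dtype=int)
    for i, c in enumerate(ids):
        if c in idx:
            values[i] = lm.values[idx[c]]
    return LabelMatrix(list(ids), list(lm.disease_ids), values)


# ---------------------------------------------------------------------------
# feature assembly and I/O


def assemble_features(
    blocks: Mapping[str, np.ndarray], row_ids: Sequence[str]
) -> FeatureMatrix:
    """Concatenate named blocks in the fixed order latent → interaction → chemical.

    Unknown block names are appended after the canonical three, in sorted
    order, so single-block matrices remain expressible.
    """
    order = [b for b in BLOCK_ORDER if b in blocks]
    order += sorted(b for b in blocks if b not in BLOCK_ORDER)
    n = len(row_ids)
    spans = []
    parts = []
    for name in order:
        mat = np.asarray(blocks[name], dtype=float)
        if mat.shape[0] != n:
            raise ValueError(
                f"block {name!r} has {mat.shape[0]} rows, expected {n}"
            )
        spans.append((name, mat.shape[1]))
        parts.append(mat)
    return FeatureMatrix(
        row_ids=list(row_ids), block_spans=spans, values=np.hstack(parts)
    )


def write_feature_matrix(fm: FeatureMatrix, csv_path: str | Path) -> None:
    """Write features as CSV (id column + named columns) with a JSON block sidecar."""
    csv_path = Path(csv_path)
    cols = []
    for name, width in fm.block_spans:
        cols += [f"{name}_{j}" for j in range(width)]
    df = pd.DataFrame(fm.values, columns=cols)
    df.insert(0, "id", fm.row_ids)
    df.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(csv_path.suffix + ".blocks.json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump({"block_spans": [list(s) for s in fm.block_spans]}, fh)


def read_feature_matrix(csv_path: str | Path) -> FeatureMatrix:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, comment="#")
    sidecar = csv_path.with_suffix(csv_path.suffix + ".blocks.json")
    with open(sidecar, encoding="utf-8") as fh:
        spans = [tuple(s) for s in json.load(fh)["block_spans"]]
    return FeatureMatrix(
        row_ids=[str(i) for i in df["id"]],
        block_spans=[(str(n), int(w)) for n, w in spans],
        values=df.drop(columns="id").to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# disease-gene sets


def read_disease_genes(path: str | Path) -> dict[str, set[str]]:
    """Read a (disease_id, gene_id) TSV into per-disease gene sets."""
    out: dict[str, set[str]] = defaultdict(set)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:1] == ["disease_id"]:
                continue
            if len(parts) < 2:
                raise ValueError(f"disease-gene row {lineno}: {line!r}")
            out[parts[0]].add(parts[1])
    return dict(out)


def write_disease_genes(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tgene_id\n")
        for disease in sorted(sets):
            for gene in sorted(sets[disease]):
                fh.write(f"{disease}\t{gene}\n")
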