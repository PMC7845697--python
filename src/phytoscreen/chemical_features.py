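"""Chemical-property feature block from SwissADME-style descriptor tables.

Physicochemical columns are Z-scored with statistics estimated on training
rows only; log-scale columns (lipophilicity, solubility, skin permeability,
synthetic accessibility) pass through unscaled; categorical columns
(pharmacokinetics flags, drug-likeness rules, alert counts) are one-hot
encoded against an enumerated category list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaColumn",
    "DescriptorSchema",
    "ScalingModel",
    "default_schema",
    "fit_scaling",
    "encode",
    "descriptor_similarity",
    "interquartile_overlap",
]

KINDS = ("zscore", "passthrough", "categorical")


@dataclass(frozen=True)
class SchemaColumn:
    name: str
    kind: str
    categories: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.kind == "categorical" and not self.categories:
            raise ValueError(f"categorical column {self.name!r} needs categories")

    @property
    def width(self) -> int:
        return len(self.categories) if self.kind == "categorical" else 1


@dataclass(frozen=True)
class DescriptorSchema:
    columns: tuple[SchemaColumn, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names in schema")

    @property
    def encoded_width(self) -> int:
        return sum(c.width for c in self.columns)

    def by_kind(self, kind: str) -> list[SchemaColumn]:
        return [c for c in self.columns if c.kind == kind]


@dataclass
class ScalingModel:
    """Per-column mean and sample (n−1) standard deviation from training rows."""

    means: dict[str, float]
    stds: dict[str, float]
    schema: DescriptorSchema  # schema with constant columns already dropped


_SOL_CLASSES = (
    "insoluble", "poorly", "moderately", "soluble", "very", "highly",
)


def default_schema() -> DescriptorSchema:
    """Default 101-column SwissADME-style schema.

    7 Z-scored physicochemical properties, 11 pass-through log-scale columns,
    and categorical columns one-hot encoded to 83 indicators (total width
    7 + 11 + 83 = 101).  The exact category inventory is configuration, not
    contract: real SwissADME exports can remap via a schema of their own.
    """
    z = [
        "mw", "heavy_atoms", "fraction_csp3", "rotatable_bonds",
        "hba", "hbd", "molar_refractivity",
    ]
    p = [
        "ilogp", "xlogp3", "wlogp", "mlogp", "silicos_it_logp",
        "consensus_logp", "esol_logs", "ali_logs", "silicos_it_logs",
        "log_kp", "synthetic_accessibility",
    ]
    yn = ("no", "yes")
    cat = [
        ("gi_absorption", ("low", "high")),
        ("bbb_permeant", yn),
        ("pgp_substrate", yn),
        ("cyp1a2_inhibitor", yn),
        ("cyp2c19_inhibitor", yn),
        ("cyp2c9_inhibitor", yn),
        ("cyp2d6_inhibitor", yn),
        ("cyp3a4_inhibitor", yn),
        ("lipinski_violations", tuple(range(5))),
        ("ghose_violations", tuple(range(5))),
        ("veber_violations", tuple(range(3))),
        ("egan_violations", tuple(range(3))),
        ("muegge_violations", tuple(range(6))),
        ("bioavailability_score", (0.11, 0.17, 0.55, 0.56, 0.85)),
        ("pains_alerts", tuple(range(5))),
        ("brenk_alerts", tuple(range(13))),
        ("leadlikeness_violations", tuple(range(4))),
        ("esol_class", _SOL_CLASSES),
        ("ali_class", _SOL_CLASSES),
        ("silicos_it_class", _SOL_CLASSES),
    ]
    cols = (
        [SchemaColumn(n, "zscore") for n in z]
        + [SchemaColumn(n, "passthrough") for n in p]
        + [SchemaColumn(n, "categorical", tuple(c)) for n, c in cat]
    )
    return DescriptorSchema(columns=tuple(cols))


def fit_scaling(
    table: pd.DataFrame,
    schema: DescriptorSchema,
    training_ids: Sequence[str] | None = None,
    id_column: str = "id",
) -> ScalingModel:
    """Estimate Z-scoring statistics from training rows only.

    Constant columns (zero standard deviation) are dropped from the returned
    model's schema with a warning.
    """
    rows = table
    if training_ids is not None:
        rows = table[table[id_column].astype(str).isin([str(i) for i in training_ids])]
    if len(rows) < 2:
        raise ValueError("need at least 2 training rows")
    means, stds, kept = {}, {}, []
    for col in schema.columns:
        if col.kind != "zscore":
            kept.append(col)
            continue
        values = pd.to_numeric(rows[col.name], errors="coerce")
        if values.isna().any():
            bad = rows.loc[values.isna()].index[0]
            raise ValueError(
                f"non-numeric value in zscore column {col.name!r} at row {bad}"
            )
        sd = float(values.std(ddof=1))
        if sd == 0:
            warnings.warn(f"constant column {col.name!r} dropped from schema")
            continue
        means[col.name] = float(values.mean())
        stds[col.name] = sd
        kept.append(col)
    return ScalingModel(means=means, stds=stds, schema=DescriptorSchema(tuple(kept)))


def encode(
    table: pd.DataFrame,
    model: ScalingModel,
    id_column: str = "id",
) -> tuple[list[str], np.ndarray]:
    """Encode a descriptor table into the numeric chemical block.

    Z-scored columns use the *stored* training statistics; categorical columns
    expand to exactly one indicator per row; unseen categories are an error
    (schemas must enumerate their categories).
    """
    schema = model.schema
    ids = [str(i) for i in table[id_column]]
    parts = []
    for col in schema.columns:
        if col.name not in table.columns:
            raise ValueError(f"table is missing schema column {col.name!r}")
        if col.kind == "zscore":
            vals = pd.to_numeric(table[col.name], errors="coerce").to_numpy()
            if np.isnan(vals).any():
                raise ValueError(f"non-numeric value in zscore column {col.name!r}")
            parts.append(((vals - model.means[col.name]) / model.stds[col.name])[:, None])
        elif col.kind == "passthrough":
            vals = pd.to_numeric(table[col.name], errors="coerce").to_numpy()
            if np.isnan(vals).any():
                raise ValueError(f"non-numeric value in column {col.name!r}")
            parts.append(vals[:, None])
        else:
            lookup = {str(c): j for j, c in enumerate(col.categories)}
            block = np.zeros((len(table), len(col.categories)))
            for i, raw in enumerate(table[col.name]):
                key = str(raw)
                if key not in lookup:
                    raise ValueError(
                        f"unseen category {raw!r} in column {col.name!r}"
                    )
                block[i, lookup[key]] = 1.0
            parts.append(block)
    return ids, np.hstack(parts)


def descriptor_similarity(
    block: np.ndarray,
    row_ids: Sequence[str],
    groups: Mapping[str, Sequence[str]],
    seed: int = 0,
) -> dict[str, float]:
    """Mean pairwise cosine similarity within groups vs size-matched random groups."""
    index = {r: i for i, r in enumerate(row_ids)}
    rng = np.random.default_rng(seed)

    def mean_cos(id_groups) -> float:
        sims = []
        for members in id_groups:
            for a, b in combinations(members, 2):
                u, v = block[index[a]], block[index[b]]
                denom = np.linalg.norm(u) * np.linalg.norm(v)
                if denom > 0:
                    sims.append(float(u @ v / denom))
        return float(np.mean(sims)) if sims else np.nan

    real = [list(m) for m in groups.values() if len(m) >= 2]
    if not real:
        raise ValueError("need at least one group of size >= 2")
    pool = list(row_ids)
    random_groups = [
        list(rng.choice(pool, size=len(m), replace=False)) for m in real
    ]
    return {
        "within_group": mean_cos(real),
        "random_group": mean_cos(random_groups),
    }


def interquartile_overlap(
    natural_table: pd.DataFrame,
    drug_table: pd.DataFrame,
    schema: DescriptorSchema,
) -> float:
    """Fraction of numeric descriptors whose natural-compound median lies
    inside the drug interquartile range (computed on raw, pre-encoding values)."""
    numeric = [c.name for c in schema.columns if c.kind in ("zscore", "passthrough")]
    if not numeric:
        raise ValueError("schema has no numeric columns")
    inside = 0
    for name in numeric:
        med = float(pd.to_numeric(natural_table[name]).median())
        q1, q3 = pd.to_numeric(drug_table[name]).quantile([0.25, 0.75])
        if q1 <= med <= q3:
            inside += 1
    return inside / len(numeric)
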