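"""End-to-end feature generation, training and evaluation on one dataset.

`build_features` turns raw artifacts (network, target profiles, descriptor
table, embedding table) into the assembled latent/interaction/chemical
feature matrix, fitting PCA and Z-scaling on training rows only.
`run_fixture_pipeline` runs the whole study on a synthetic fixture and
reports held-out AUROC per disease, with an optional label-permutation
control.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .chemical_features import DescriptorSchema, encode, fit_scaling
from .evaluation import SplitPlan, accuracy, auroc, make_split
from .fixtures import FixtureConfig, FixtureData, generate_fixture, fixture_schema
from .interaction_features import fit_reduction, apply_reduction, interaction_block
from .io_core import CompoundProfile, FeatureMatrix, LabelMatrix, assemble_features
from .knowledge_embedding import VectorTable, compose_vector
from .pcnn_model import DiseaseModel, TrainConfig, predict, train

__all__ = ["build_features", "run_fixture_pipeline", "PipelineResult"]


def build_features(
    profiles: list[CompoundProfile],
    graph: nx.Graph,
    disease_genes: dict[str, set[str]],
    descriptors: pd.DataFrame,
    embeddings: VectorTable,
    schema: DescriptorSchema,
    training_ids: list[str],
    pca_threshold: float = 0.8,
) -> FeatureMatrix:
    """Assemble the three feature blocks for all profiles.

    The PCA basis of the interaction block and the Z-scaling statistics of the
    chemical block are fitted on ``training_ids`` only and applied unchanged
    to the remaining rows, so held-out compounds never leak into the fitted
    transforms.
    """
    row_ids = [p.id for p in profiles]
    train_rows = [i for i, r in enumerate(row_ids) if r in set(training_ids)]

    latent = np.vstack([compose_vector(p.name, embeddings) for p in profiles])

    gene_list = sorted(set().union(*disease_genes.values()))
    raw_interaction = interaction_block(profiles, graph, gene_list)
    reduction = fit_reduction(raw_interaction[train_rows], threshold=pca_threshold)
    interaction = apply_reduction(reduction, raw_interaction)

    table = descriptors.set_index(
        descriptors["id"].astype(str), drop=False
    ).loc[row_ids].reset_index(drop=True)
    scaling = fit_scaling(table, schema, training_ids=training_ids)
    _, chemical = encode(table, scaling)

    return assemble_features(
        {"latent": latent, "interaction": interaction, "chemical": chemical},
        row_ids,
    )


@dataclass
class PipelineResult:
    fixture: FixtureData
    features: FeatureMatrix
    split: SplitPlan
    models: dict[str, DiseaseModel]
    auroc_per_disease: dict[str, float]
    accuracy_per_disease: dict[str, float]

    @property
    def mean_auroc(self) -> float:
        """Mean over diseases; diseases lacking both classes held out are skipped."""
        values = [v for v in self.auroc_per_disease.values() if not np.isnan(v)]
        return float(np.mean(values)) if values else float("nan")

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.accuracy_per_disease.values())))


def _evaluate(features, labels, models, test_ids):
    table = predict(models, features, labels=labels)
    index = {r: i for i, r in enumerate(features.row_ids)}
    rows = [index[i] for i in test_ids]
    aurocs, accs = {}, {}
    for j, disease in enumerate(labels.disease_ids):
        y = labels.values[rows, j]
        s = table.scores[rows, j]
        aurocs[disease] = auroc(s, y) if 0 < y.sum() < len(y) else float("nan")
        accs[disease] = accuracy(s, y)
    return aurocs, accs


def run_fixture_pipeline(
    seed: int = 0,
    config: FixtureConfig | None = None,
    train_config: TrainConfig | None = None,
    permute_labels: bool = False,
    n_permutations: int = 5,
) -> PipelineResult:
    """Generate a fixture, build features, train per-disease models, evaluate.

    With ``permute_labels`` the label rows are randomly permuted after feature
    generation (the negative control: the planted signal is destroyed, so
    held-out AUROC should hover around 0.5).  A single permutation draw has a
    wide null distribution at this sample size, so the control retrains on
    ``n_permutations`` independent permutations and reports the mean
    per-disease AUROC across the replicates (the standard permutation-null
    estimate); the returned models come from the last replicate.
    """
    config = config or FixtureConfig(seed=seed)
    train_config = train_config or TrainConfig(seed=seed)
    fixture = generate_fixture(config)
    labels = fixture.labels

    patterns = ["".join(map(str, row)) for row in labels.values]
    split = make_split(labels.compound_ids, (6, 2, 2), seed=seed, stratify_by=patterns)

    features = build_features(
        fixture.profiles,
        fixture.graph,
        fixture.modules,
        fixture.descriptors,
        fixture.embeddings,
        fixture_schema(),
        training_ids=split.train,
    )

    if not permute_labels:
        models = train(features, labels, config=train_config, split=split)
        aurocs, accs = _evaluate(features, labels, models, split.test)
    else:
        replicates = []
        for r in range(n_permutations):
            rng = np.random.default_rng([seed % (2**31), 99, r])
            perm = rng.permutation(len(labels.compound_ids))
            permuted = LabelMatrix(
                compound_ids=labels.compound_ids,
                disease_ids=labels.disease_ids,
                values=labels.values[perm],
            )
            models = train(features, permuted, config=train_config, split=split)
            replicates.append(_evaluate(features, permuted, models, split.test))
        aurocs = {}
        for d in labels.disease_ids:
            vals = [rep[0][d] for rep in replicates if not np.isnan(rep[0][d])]
            aurocs[d] = float(np.mean(vals)) if vals else float("nan")
        accs = {
            d: float(np.mean([rep[1][d] for rep in replicates]))
            for d in labels.disease_ids
        }
    return PipelineResult(
        fixture=fixture,
        features=features,
        split=split,
        models=models,
        auroc_per_disease=aurocs,
        accuracy_per_disease=accs,
    )
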