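"""phytoscreen: predicting medicinal uses of natural compounds.

Heterogeneous feature generation (literature-name embeddings, random-walk
network propagation, chemical descriptors), a block-masked partially
connected neural network trained on drug indications, network-proximity
baselines, and a literature-statistics validation suite — with a synthetic
fixture generator that plants a recoverable compound–disease signal.
"""

from importlib import resources
import json

from .io_core import (
    CompoundProfile,
    FeatureMatrix,
    LabelMatrix,
    assemble_features,
    build_label_matrix,
    filter_min_targets,
    read_edge_list,
    read_targets,
)
from .fixtures import FixtureConfig, generate_fixture, write_fixture
from .knowledge_embedding import (
    VectorTable,
    AtcCode,
    char_ngrams,
    compose_vector,
    preprocess,
)
from .interaction_features import (
    PropagationProblem,
    build_seed_vector,
    normalize_adjacency,
    rwr,
    disease_score,
    fit_reduction,
    apply_reduction,
)
from .chemical_features import DescriptorSchema, default_schema, encode, fit_scaling
from .pcnn_model import (
    BlockMaskSpec,
    DiseaseModel,
    PredictionTable,
    TrainConfig,
    build_mask,
    class_weights,
    default_mask_spec,
    edge_counts,
    predict,
    train,
    weighted_bce,
)
from .evaluation import (
    LiteratureIndex,
    SplitPlan,
    accuracy,
    auroc,
    fisher_exact,
    fisher_enrichment_p,
    jaccard,
    literature_report,
    make_kfold,
    make_split,
    mann_whitney,
    ranked_sets,
    summarize,
)
from .pipeline import build_features, run_fixture_pipeline

__version__ = "0.1.0"


def reference_benchmarks() -> dict:
    """Published benchmark values shipped with the package (worked examples)."""
    with resources.files("phytoscreen.data").joinpath(
        "reference_benchmarks.json"
    ).open() as fh:
        return json.load(fh)
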