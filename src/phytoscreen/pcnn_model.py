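"""Block-masked partially connected deep network for indication prediction.

The first two hidden layers are *partially connected*: their weight matrices
are masked block-diagonally so each hidden unit sees inputs from exactly one
feature block (latent / interaction / chemical).  With per-block widths nᵢ→mᵢ
a partial layer trains Σ nᵢ·mᵢ weights instead of the (Σnᵢ)·(Σmᵢ) of a fully
connected layer.  The block outputs are concatenated and passed through two
fully connected hidden layers to a single sigmoid unit; one independent
binary model is trained per disease with a class-weighted binary
cross-entropy loss, Adam, and early stopping on validation loss.

Every layer is plain numpy: masked affine → batch normalization → ReLU, with
hand-written backpropagation and He initialization whose fan-in counts only
unmasked inputs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_core import FeatureMatrix, LabelMatrix

__all__ = [
    "BlockMaskSpec",
    "TrainConfig",
    "DiseaseModel",
    "PredictionTable",
    "PAPER_HIDDEN_WIDTHS",
    "default_mask_spec",
    "build_mask",
    "edge_counts",
    "init_params",
    "class_weights",
    "weighted_bce",
    "train",
    "predict",
]

#: per-block hidden widths of the reference architecture, keyed by
#: (block name, input width): 300→200 latent, 285→160 interaction, 101→68 chemical
PAPER_HIDDEN_WIDTHS = {
    ("latent", 300): 200,
    ("interaction", 285): 160,
    ("chemical", 101): 68,
}

_CLIP = 1e-7
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class BlockMaskSpec:
    """Per-block (name, input width nᵢ, hidden width mᵢ) for one partial layer."""

    blocks: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for name, n, m in self.blocks:
            if n < 1 or m < 1:
                raise ValueError(f"non-positive width in block {name!r}")

    @property
    def input_width(self) -> int:
        return sum(n for _, n, _ in self.blocks)

    @property
    def hidden_width(self) -> int:
        return sum(m for _, _, m in self.blocks)

    def next_layer(self) -> "BlockMaskSpec":
        """Spec of the following partial layer (hidden widths reused)."""
        return BlockMaskSpec(tuple((name, m, m) for name, _, m in self.blocks))


def default_mask_spec(block_spans: Sequence[tuple[str, int]]) -> BlockMaskSpec:
    """Hidden widths for arbitrary block spans.

    The reference widths (68/160/200 for 101/285/300 inputs) are used when the
    spans match; otherwise each block gets ⌈2nᵢ/3⌉ hidden units (at least 4),
    the approximate ratio of the reference architecture.
    """
    blocks = []
    for name, n in block_spans:
        m = PAPER_HIDDEN_WIDTHS.get((name, n), max(4, int(np.ceil(2 * n / 3))))
        blocks.append((name, n, m))
    return BlockMaskSpec(tuple(blocks))


def build_mask(spec: BlockMaskSpec) -> np.ndarray:
    """Binary (hidden × input) mask, block-diagonal in the block ordering.

    Exactly Σ nᵢ·mᵢ entries are one.
    """
    mask = np.zeros((spec.hidden_width, spec.input_width))
    row = col = 0
    for _, n, m in spec.blocks:
        mask[row : row + m, col : col + n] = 1.0
        row += m
        col += n
    return mask


def edge_counts(spec: BlockMaskSpec) -> dict[str, float]:
    """Trainable-edge accounting for one partial layer.

    Reports the partial count Σ nᵢ·mᵢ, the fully connected count
    (Σnᵢ)·(Σmᵢ), and the ratio between them both ways (kept-fraction and
    reduction); with a single block the two counts coincide.
    """
    partial = sum(n * m for _, n, m in spec.blocks)
    full = spec.input_width * spec.hidden_width
    return {
        "partial": partial,
        "full": full,
        "kept_fraction": partial / full,
        "reduction_fraction": 1.0 - partial / full,
    }


def init_params(
    shape: tuple[int, int],
    seed: int | np.random.Generator,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """He-initialized weights: zero-mean Gaussian with SD √(2/nₗ) per unit.

    nₗ is the fan-in counted as the number of *unmasked* inputs of each unit;
    masked entries are zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m, n = shape
    W = rng.standard_normal((m, n))
    if mask is None:
        return W * np.sqrt(2.0 / n)
    fan_in = mask.sum(axis=1)
    sd = np.sqrt(2.0 / np.maximum(fan_in, 1.0))
    return W * sd[:, None] * mask


def class_weights(labels: np.ndarray) -> tuple[float, float]:
    """(w_pos, w_neg) inversely proportional to class frequencies.

    w_c = N/(2·N_c), so balanced labels give (1, 1) and the identity
    w_pos·N_pos = w_neg·N_neg = N/2 always holds.
    """
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels contain a single class")
    n = n_pos + n_neg
    return n / (2.0 * n_pos), n / (2.0 * n_neg)


def weighted_bce(
    y: np.ndarray,
    yhat: np.ndarray,
    w_pos: float = 1.0,
    w_neg: float = 1.0,
    reduction: str = "sum",
) -> float:
    """Class-weighted binary cross-entropy.

    L = −Σᵢ [w_pos·yᵢ·ln(ŷᵢ) + w_neg·(1−yᵢ)·ln(1−ŷᵢ)], with probabilities
    clipped at 1e−7; ``w_pos`` multiplies the positive-class (y=1) term.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(yhat, dtype=float)
    if y.shape != p.shape:
        raise ValueError("label/prediction length mismatch")
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    terms = w_pos * y * np.log(p) + w_neg * (1.0 - y) * np.log(1.0 - p)
    total = -float(terms.sum())
    if reduction == "mean":
        return total / len(y)
    return total


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 64
    max_epochs: int = 3000
    patience: int = 30
    seed: int = 0
    fc_widths: tuple[int, ...] = (256, 64)
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        for attr in ("learning_rate", "beta1", "beta2", "batch_size", "patience"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be strictly positive")


class _Layer:
    """Affine (optionally masked) → optional batch norm → optional ReLU."""

    def __init__(self, n_in, n_out, rng, mask=None, batchnorm=True, relu=True):
        self.mask = mask
        self.W = init_params((n_out, n_in), rng, mask)
        self.b = np.zeros(n_out)
        self.batchnorm = batchnorm
        self.relu = relu
        if batchnorm:
            self.gamma = np.ones(n_out)
            self.beta = np.zeros(n_out)
            self.running_mean = np.zeros(n_out)
            self.running_var = np.ones(n_out)
        self._cache = None

    def params(self):
        out = {"W": self.W, "b": self.b}
        if self.batchnorm:
            out["gamma"] = self.gamma
            out["beta"] = self.beta
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        z = x @ self.W.T + self.b
        if self.batchnorm:
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                self.running_mean = (
                    _BN_MOMENTUM * self.running_mean + (1 - _BN_MOMENTUM) * mu
                )
                self.running_var = (
                    _BN_MOMENTUM * self.running_var + (1 - _BN_MOMENTUM) * var
                )
            else:
                mu, var = self.running_mean, self.running_var
            xhat = (z - mu) / np.sqrt(var + _BN_EPS)
            h = self.gamma * xhat + self.beta
        else:
            xhat, mu, var = None, None, None
            h = z
        a = np.maximum(h, 0.0) if self.relu else h
        if not np.isfinite(a).all():
            raise FloatingPointError("non-finite activations in forward pass")
        if training:
            self._cache = (x, z, xhat, var, h)
        return a

    def backward(self, grad_a: np.ndarray):
        x, z, xhat, var, h = self._cache
        grads = {}
        dh = grad_a * (h > 0) if self.relu else grad_a
        if self.batchnorm:
            B = z.shape[0]
            grads["gamma"] = (dh * xhat).sum(axis=0)
            grads["beta"] = dh.sum(axis=0)
            dxhat = dh * self.gamma
            inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
            dz = (
                inv_sd
                / B
                * (
                    B * dxhat
                    - dxhat.sum(axis=0)
                    - xhat * (dxhat * xhat).sum(axis=0)
                )
            )
        else:
            dz = dh
        dW = dz.T @ x
        if self.mask is not None:
            dW *= self.mask
        grads["W"] = dW
        grads["b"] = dz.sum(axis=0)
        dx = dz @ (self.W if self.mask is None else self.W * self.mask)
        return dx, grads


class _Adam:
    def __init__(self, layers, config: TrainConfig):
        self.cfg = config
        self.t = 0
        self.state = [
            {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in layer.params().items()}
            for layer in layers
        ]

    def step(self, layers, grads_per_layer):
        self.t += 1
        c = self.cfg
        for layer, grads, state in zip(layers, grads_per_layer, self.state):
            for key, g in grads.items():
                m, v = state[key]
                m *= c.beta1
                m += (1 - c.beta1) * g
                v *= c.beta2
                v += (1 - c.beta2) * g * g
                mhat = m / (1 - c.beta1**self.t)
                vhat = v / (1 - c.beta2**self.t)
                layer.params()[key] -= c.learning_rate * mhat / (np.sqrt(vhat) + c.eps)
            if layer.mask is not None:
                layer.W *= layer.mask  # re-zero masked entries after the update


@dataclass
class DiseaseModel:
    """One trained binary model plus its mask specs and training history."""

    disease_id: str
    layers: list
    mask_specs: tuple[BlockMaskSpec, BlockMaskSpec]
    history: list = field(default_factory=list)  # (train_loss, val_loss) per epoch
    best_epoch: int = -1
    weights: tuple[float, float] = (1.0, 1.0)

    def forward(self, x: np.ndarray, training_mode: bool = False) -> np.ndarray:
        """Probability per row."""
        a = np.asarray(x, dtype=float)
        if a.ndim == 1:
            a = a[None, :]
        if a.shape[1] != self.mask_specs[0].input_width:
            raise ValueError(
                f"input width {a.shape[1]} != expected "
                f"{self.mask_specs[0].input_width}"
            )
        for layer in self.layers:
            a = layer.forward(a, training_mode)
        return _sigmoid(a[:, 0])

    def masked_weight_norm(self) -> float:
        """‖W ⊙ (1−mask)‖₁ over the partial layers; exactly 0 by invariant."""
        total = 0.0
        for layer in self.layers:
            if layer.mask is not None:
                total += float(np.abs(layer.W * (1 - layer.mask)).sum())
        return total


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _build_model(disease_id, spec1, config, rng):
    spec2 = spec1.next_layer()
    layers = [
        _Layer(spec1.input_width, spec1.hidden_width, rng, mask=build_mask(spec1)),
        _Layer(spec2.input_width, spec2.hidden_width, rng, mask=build_mask(spec2)),
    ]
    width = spec2.hidden_width
    for w in config.fc_widths:
        layers.append(_Layer(width, w, rng))
        width = w
    layers.append(_Layer(width, 1, rng, batchnorm=False, relu=False))
    return DiseaseModel(disease_id=disease_id, layers=layers, mask_specs=(spec1, spec2))


def _snapshot(layers):
    return [copy.deepcopy(layer.params()) | (
        {"running_mean": layer.running_mean.copy(), "running_var": layer.running_var.copy()}
        if layer.batchnorm else {}
    ) for layer in layers]


def _restore(layers, snapshot):
    for layer, saved in zip(layers, snapshot):
        layer.W[:] = saved["W"]
        layer.b[:] = saved["b"]
        if layer.batchnorm:
            layer.gamma[:] = saved["gamma"]
            layer.beta[:] = saved["beta"]
            layer.running_mean[:] = saved["running_mean"]
            layer.running_var[:] = saved["running_var"]


def _train_one(model, X_tr, y_tr, X_val, y_val, config, rng):
    w_pos, w_neg = class_weights(y_tr)
    model.weights = (w_pos, w_neg)
    opt = _Adam(model.layers, config)
    best_val = np.inf
    best_snapshot = _snapshot(model.layers)
    stale = 0
    n = len(y_tr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X_tr[idx], y_tr[idx]
            a = xb
            for layer in model.layers:
                a = layer.forward(a, training=True)
            p = np.clip(_sigmoid(a[:, 0]), _CLIP, 1 - _CLIP)
            loss = weighted_bce(yb, p, w_pos, w_neg, reduction="mean")
            if not np.isfinite(loss):
                raise FloatingPointError(f"divergent loss at epoch {epoch}")
            epoch_loss += loss * len(yb)
            # fused sigmoid + weighted-BCE gradient w.r.t. the output logit
            dz = ((w_neg * (1 - yb) * p - w_pos * yb * (1 - p)) / len(yb))[:, None]
            grads_per_layer = []
            grad = dz
            for layer in reversed(model.layers):
                grad, grads = layer.backward(grad)
                grads_per_layer.append(grads)
            opt.step(model.layers, list(reversed(grads_per_layer)))
        val_p = model.forward(X_val, training_mode=False)
        val_loss = weighted_bce(y_val, val_p, w_pos, w_neg, reduction="mean")
        model.history.append((epoch_loss / n, float(val_loss)))
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_snapshot = _snapshot(model.layers)
            model.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    _restore(model.layers, best_snapshot)
    return model


def train(
    features: FeatureMatrix,
    labels: LabelMatrix,
    spec: BlockMaskSpec | None = None,
    config: TrainConfig | None = None,
    split=None,
) -> dict[str, DiseaseModel]:
    """Train one independent binary model per disease.

    ``split`` is a SplitPlan from the evaluation module (its test ids are left
    untouched); if omitted, a stratified 6:2:2 split is drawn with the config
    seed.  Masked weights are re-zeroed after every optimizer step, early
    stopping monitors validation loss with the configured patience, and the
    best-epoch parameters are restored.
    """
    from .evaluation import make_split

    config = config or TrainConfig()
    spec = spec or default_mask_spec(features.block_spans)
    if spec.input_width != features.width:
        raise ValueError(
            f"mask spec width {spec.input_width} != feature width {features.width}"
        )
    if features.row_ids != labels.compound_ids:
        raise ValueError("feature and label rows are not aligned")
    if split is None:
        patterns = ["".join(map(str, row)) for row in labels.values]
        split = make_split(
            features.row_ids, (6, 2, 2), seed=config.seed, stratify_by=patterns
        )
    index = {r: i for i, r in enumerate(features.row_ids)}
    tr = [index[i] for i in split.train]
    va = [index[i] for i in split.validation]
    X_tr, X_val = features.values[tr], features.values[va]

    models = {}
    for d_idx, disease in enumerate(labels.disease_ids):
        rng = np.random.default_rng([config.seed % (2**31), d_idx])
        model = _build_model(disease, spec, config, rng)
        y = labels.values[:, d_idx].astype(float)
        _train_one(model, X_tr, y[tr], X_val, y[va], config, rng)
        models[disease] = model
    return models


@dataclass
class PredictionTable:
    """Compound × disease score matrix in (0,1), plus optional labels."""

    compound_ids: list[str]
    disease_ids: list[str]
    scores: np.ndarray
    labels: LabelMatrix | None = None

    def pairs(self):
        """All (compound, disease, score) cells."""
        for i, c in enumerate(self.compound_ids):
            for j, d in enumerate(self.disease_ids):
                yield c, d, float(self.scores[i, j])


def predict(
    models: Mapping[str, DiseaseModel],
    features: FeatureMatrix,
    labels: LabelMatrix | None = None,
) -> PredictionTable:
    """Score every compound against every disease model (inference mode)."""
    disease_ids = list(models)
    scores = np.column_stack(
        [models[d].forward(features.values, training_mode=False) for d in disease_ids]
    )
    return PredictionTable(
        compound_ids=list(features.row_ids),
        disease_ids=disease_ids,
        scores=scores,
        labels=labels,
    )
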