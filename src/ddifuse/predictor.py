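"""Pair feature aggregation and the softmax interaction-type classifier.

Drug-pair features come from one of three aggregation operators over the two
drugs' unified embeddings: elementwise (inner) product, elementwise sum, or
concatenation. A feed-forward network (linear -> batch-norm -> ReLU ->
dropout per hidden layer, softmax output) is trained with Adam on
cross-entropy, with early stopping on a stratified validation slice and
best-weight restoration.

Pairs are unordered but concatenation is orientation-dependent, so training
materializes both orientations of every concat sample and inference averages
the two orientations' probability vectors (then renormalizes); product and
sum are orientation-invariant by construction, so the reported score never
depends on how a pair is written down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import DDITable, DNNConfig, DrugCatalog
from .mda import UnifiedEmbedding
from .nn import (Adam, BatchNorm, Dense, Dropout, ReLU, Sequential, softmax,
                 softmax_cross_entropy)

logger = logging.getLogger("ddifuse")

OPERATORS = ("concat", "inner", "sum")


@dataclass
class PairFeatureMatrix:
    values: np.ndarray  # (n_pairs, p)
    operator_name: str
    pair_index: list[tuple[str, str]]


def aggregate_pairs(
    emb: UnifiedEmbedding,
    pairs: list[tuple[str, str]],
    operator: str,
    catalog: DrugCatalog,
) -> PairFeatureMatrix:
    """Combine the two drugs' embedding rows into one pair feature vector."""
    if operator not in OPERATORS:
        raise ValueError(f"unknown operator {operator!r}; expected one of {OPERATORS}")
    ia = np.array([catalog.index_of(a) for a, _ in pairs])
    ib = np.array([catalog.index_of(b) for _, b in pairs])
    ha, hb = emb.values[ia], emb.values[ib]
    if operator == "concat":
        x = np.hstack([ha, hb])
    elif operator == "inner":
        x = ha * hb
    else:
        x = ha + hb
    return PairFeatureMatrix(x, operator, list(pairs))


@dataclass
class DNNModel:
    net: Sequential
    n_types: int
    hidden_dims: tuple[int, ...]
    dropout: float
    feature_mean: np.ndarray = None  # type: ignore[assignment]
    feature_std: np.ndarray = None   # type: ignore[assignment]
    operator_name: str = "concat"
    training_log: list[dict] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        for layer in self.net.layers:
            if isinstance(layer, Dense):
                return layer.w.shape[0]
        raise AttributeError("model has no dense layer")


def _build_net(n_in: int, hidden: tuple[int, ...], n_out: int,
               dropout: float, rng: np.random.Generator) -> Sequential:
    layers: list = []
    d = n_in
    for h in hidden:
        layers += [Dense(d, h, rng), BatchNorm(h), ReLU(), Dropout(dropout, rng)]
        d = h
    layers.append(Dense(d, n_out, rng))
    return Sequential(layers)


def _stratified_holdout(y: np.ndarray, fraction: float,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split into train/validation index arrays."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_val = int(round(fraction * len(idx)))
        if len(idx) >= 2:
            n_val = min(max(n_val, 1), len(idx) - 1)
        else:
            n_val = 0
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def train_dnn(
    x: np.ndarray,
    y: np.ndarray,
    config: DNNConfig,
    seed: int,
    n_types: int | None = None,
) -> DNNModel:
    """Train the classifier; deterministic given the seed.

    Features are standardized per column with training-set statistics (the
    scaler is stored on the model and reapplied at inference), since
    embedding coordinates can differ in scale by orders of magnitude. Early
    stopping watches cross-entropy on a stratified 10% slice of the training
    data (patience in epochs), capped at the configured epoch count; the
    best validation weights are restored.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    l = int(n_types if n_types is not None else classes.max() + 1)
    mean = x.mean(axis=0)
    std = np.maximum(x.std(axis=0), 1e-8)
    x = (x - mean) / std
    rng = np.random.default_rng(seed)
    net = _build_net(x.shape[1], tuple(config.hidden_dims), l, config.dropout, rng)
    opt = Adam(net.params(), net.grads(), lr=config.lr)

    tr, va = _stratified_holdout(y, config.val_fraction, rng)
    x_tr, y_tr, x_va, y_va = x[tr], y[tr], x[va], y[va]
    best_state, best_val, since_best = net.state(), np.inf, 0
    model = DNNModel(net, l, tuple(config.hidden_dims), config.dropout,
                     feature_mean=mean, feature_std=std)
    for epoch in range(config.epochs):
        perm = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(x_tr), config.batch_size):
            idx = perm[start:start + config.batch_size]
            logits = net.forward(x_tr[idx], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_loss = np.nan
        if len(x_va):
            val_logits = net.forward(x_va, training=False)
            val_loss, _ = softmax_cross_entropy(val_logits, y_va)
        model.training_log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_loss": float(val_loss)}
        )
        if len(x_va):
            if val_loss < best_val:
                best_val, best_state, since_best = val_loss, net.state(), 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    logger.debug("early stop at epoch %d (best val %.4f)", epoch, best_val)
                    break
    if len(x_va):
        net.load_state(best_state)
    return model


def predict_proba(model: DNNModel, x: np.ndarray) -> np.ndarray:
    """Class probabilities (rows sum to 1); batch-norm in inference mode."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] != model.input_dim:
        raise ValueError(
            f"feature width {x.shape[1]} does not match model input {model.input_dim}"
        )
    if model.feature_mean is not None:
        x = (x - model.feature_mean) / model.feature_std
    return softmax(model.net.forward(x, training=False))


def pair_probabilities(
    model: DNNModel,
    emb: UnifiedEmbedding,
    pairs: list[tuple[str, str]],
    operator: str,
    catalog: DrugCatalog,
) -> np.ndarray:
    """Orientation-symmetric pair scores.

    For concat, the probabilities of both orientations are averaged and
    renormalized; inner/sum need a single pass.
    """
    x = aggregate_pairs(emb, pairs, operator, catalog).values
    p = predict_proba(model, x)
    if operator == "concat":
        x_rev = aggregate_pairs(emb, [(b, a) for a, b in pairs], operator, catalog).values
        p = (p + predict_proba(model, x_rev)) / 2.0
        p = p / p.sum(axis=1, keepdims=True)
    return p


def fit_pair_classifier(
    emb: UnifiedEmbedding,
    pairs: list[tuple[str, str, int]],
    config: DNNConfig,
    seed: int,
    operator: str,
    catalog: DrugCatalog,
    n_types: int,
) -> DNNModel:
    """Build pair features (both orientations for concat) and train."""
    ab = [(a, b) for a, b, _ in pairs]
    y = np.array([t for _, _, t in pairs], dtype=np.int64)
    x = aggregate_pairs(emb, ab, operator, catalog).values
    if operator == "concat":
        x_rev = aggregate_pairs(emb, [(b, a) for a, b in ab], operator, catalog).values
        x = np.vstack([x, x_rev])
        y = np.concatenate([y, y])
    model = train_dnn(x, y, config, seed, n_types=n_types)
    model.operator_name = operator
    return model


def rank_novel_pairs(
    model: DNNModel,
    emb: UnifiedEmbedding,
    known: DDITable,
    type_id: int,
    k: int,
    catalog: DrugCatalog,
    operator: str | None = None,
) -> list[tuple[tuple[str, str], float]]:
    """Top-k unlabeled unordered pairs by predicted probability of a type.

    Every pair in ``known`` is excluded from the candidates. Ties and order
    are deterministic (score descending, then pair order).
    """
    if not 0 <= type_id < model.n_types:
        raise ValueError(f"type_id {type_id} outside 0..{model.n_types - 1}")
    operator = operator or model.operator_name
    known_keys = known.pair_keys()
    ids = catalog.drug_ids
    candidates = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if frozenset((ids[i], ids[j])) not in known_keys
    ]
    if not candidates:
        return []
    scores = pair_probabilities(model, emb, candidates, operator, catalog)[:, type_id]
    order = np.argsort(-scores, kind="stable")[: min(k, len(candidates))]
    return [(candidates[i], float(scores[i])) for i in order]
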