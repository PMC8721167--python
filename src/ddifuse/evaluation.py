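"""Cross-validation scenes and multiclass evaluation metrics.

Three fivefold cross-validation scenes probe increasingly cold-start
regimes: S1 splits labeled pairs (both drugs seen in training), S2 holds out
drugs and tests pairs between a known and a held-out drug, S3 tests pairs
between two held-out drugs. In S2/S3 training pairs never touch a held-out
drug.

Metrics follow the one-vs-rest convention: accuracy is the mean over classes
of (TP_i + TN_i) / n; precision, recall and F1 are macro-averaged (F1 as the
harmonic mean of macro precision and macro recall); AUPR and AUC are
micro-averaged over the flattened one-vs-rest binarized labels against the
flattened probabilities. Plain multiclass accuracy, micro precision/recall
and the average-of-per-class-F1 variant are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .data import DDITable, DrugCatalog, PipelineConfig
from .mda import UnifiedEmbedding, encode, scale_networks, train_mda
from .netembed import build_all_networks
from .predictor import aggregate_pairs, fit_pair_classifier, pair_probabilities
from .similarity import build_all_similarities
from .synth import SynthDataset, child_seed

logger = logging.getLogger("ddifuse")

SCENES = ("S1", "S2", "S3")


@dataclass
class CVPlan:
    scene: str
    folds: list[tuple[list[int], list[int]]]  # (train pair idx, test pair idx)
    seed: int
    n_folds: int
    drug_partition: list[list[str]] | None = None  # S2/S3 held-out drug sets


def split_cv(
    ddis: DDITable,
    catalog: DrugCatalog,
    scene: str,
    n_folds: int = 5,
    seed: int = 0,
) -> CVPlan:
    """Build the fold plan for a scene; deterministic given the seed.

    S1 deals pairs into folds stratified by type (types with fewer members
    than folds are pooled unstratified with a warning). S2/S3 split the
    drugs into equal-size groups; each fold's test pairs touch exactly one
    (S2) or two (S3) held-out drugs, and its training pairs touch none.
    """
    if scene not in SCENES:
        raise ValueError(f"unknown scene {scene!r}; expected one of {SCENES}")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(child_seed(seed, f"cv/{scene}"))
    n = len(ddis.pairs)
    labels = np.array([t for _, _, t in ddis.pairs])

    if scene == "S1":
        test_folds: list[list[int]] = [[] for _ in range(n_folds)]
        leftovers: list[int] = []
        for cls in np.unique(labels):
            idx = rng.permutation(np.flatnonzero(labels == cls))
            if len(idx) < n_folds:
                logger.warning(
                    "type %s has %d pairs (< %d folds); left unstratified",
                    ddis.type_names[cls], len(idx), n_folds,
                )
                leftovers.extend(idx.tolist())
                continue
            for k, i in enumerate(idx):
                test_folds[k % n_folds].append(int(i))
        for k, i in enumerate(rng.permutation(leftovers)):
            test_folds[k % n_folds].append(int(i))
        folds = []
        for k in range(n_folds):
            test = sorted(test_folds[k])
            in_test = np.zeros(n, dtype=bool)
            in_test[test] = True
            folds.append((np.flatnonzero(~in_test).tolist(), test))
        return CVPlan(scene, folds, seed, n_folds)

    drugs = rng.permutation(np.array(catalog.drug_ids, dtype=object))
    held_sets = [set(chunk.tolist()) for chunk in np.array_split(drugs, n_folds)]
    folds = []
    for held in held_sets:
        train, test = [], []
        for i, (a, b, _) in enumerate(ddis.pairs):
            n_held = (a in held) + (b in held)
            if n_held == 0:
                train.append(i)
            elif scene == "S2" and n_held == 1:
                test.append(i)
            elif scene == "S3" and n_held == 2:
                test.append(i)
        folds.append((train, test))
    return CVPlan(scene, folds, seed, n_folds,
                  drug_partition=[sorted(h) for h in held_sets])


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    acc: float                 # mean over classes of (TP+TN)/n
    aupr_micro: float
    auc_micro: float
    f1_macro: float            # harmonic mean of macro precision and recall
    precision_macro: float
    recall_macro: float
    plain_accuracy: float
    precision_micro: float
    recall_micro: float
    f1_macro_per_class: float  # mean of per-class F1 scores
    counts: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "acc", "aupr_micro", "auc_micro", "f1_macro",
            "precision_macro", "recall_macro", "plain_accuracy",
            "precision_micro", "recall_micro", "f1_macro_per_class")}


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    # 0/0 -> 0 convention for classes absent from the evaluation slice
    return np.where(den > 0, num / np.where(den > 0, den, 1), 0.0)


def compute_metrics(y_true: np.ndarray, proba: np.ndarray, l: int) -> MetricsReport:
    """One-vs-rest multiclass metrics from true labels and probabilities."""
    y_true = np.asarray(y_true, dtype=np.int64)
    proba = np.asarray(proba, dtype=float)
    if proba.ndim != 2 or proba.shape != (len(y_true), l):
        raise ValueError(f"probability matrix must be ({len(y_true)}, {l})")
    sums = proba.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    n = len(y_true)
    y_pred = np.argmax(proba, axis=1)

    tp = np.zeros(l); fp = np.zeros(l); fn = np.zeros(l); tn = np.zeros(l)
    for c in range(l):
        tp[c] = np.sum((y_pred == c) & (y_true == c))
        fp[c] = np.sum((y_pred == c) & (y_true != c))
        fn[c] = np.sum((y_pred != c) & (y_true == c))
        tn[c] = n - tp[c] - fp[c] - fn[c]
    absent = np.flatnonzero((tp + fn) == 0)
    if absent.size:
        logger.debug("classes absent from evaluation slice: %s", absent.tolist())

    prec_c = _safe_div(tp, tp + fp)
    rec_c = _safe_div(tp, tp + fn)
    precision_macro = float(prec_c.mean())
    recall_macro = float(rec_c.mean())
    denom = precision_macro + recall_macro
    f1_macro = 2 * precision_macro * recall_macro / denom if denom > 0 else 0.0
    f1_c = _safe_div(2 * prec_c * rec_c, prec_c + rec_c)

    y_bin = np.eye(l)[y_true]
    aupr = float(average_precision_score(y_bin.ravel(), proba.ravel()))
    auc = float(roc_auc_score(y_bin.ravel(), proba.ravel()))

    return MetricsReport(
        acc=float(((tp + tn) / n).mean()),
        aupr_micro=aupr,
        auc_micro=auc,
        f1_macro=float(f1_macro),
        precision_macro=precision_macro,
        recall_macro=recall_macro,
        plain_accuracy=float(np.mean(y_pred == y_true)),
        precision_micro=float(_safe_div(tp.sum(), (tp + fp).sum())),
        recall_micro=float(_safe_div(tp.sum(), (tp + fn).sum())),
        f1_macro_per_class=float(f1_c.mean()),
        counts={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )


# ---------------------------------------------------------------------------
# full cross-validated pipeline run


VARIANTS = ("nmdadnn", "mdadnn", "dnn_avg", "no_atc")


@dataclass
class CVResult:
    scene: str
    variant: str
    per_fold: list[MetricsReport]
    aggregate: dict[str, float]
    aggregate_sd: dict[str, float]
    seed: int


def _aggregate(reports: list[MetricsReport]) -> tuple[dict, dict]:
    keys = reports[0].as_dict().keys()
    mean = {k: float(np.mean([r.as_dict()[k] for r in reports])) for k in keys}
    sd = {k: float(np.std([r.as_dict()[k] for r in reports])) for k in keys}
    return mean, sd


def build_drug_representation(
    dataset: SynthDataset | object,
    config: PipelineConfig,
    variant: str = "nmdadnn",
) -> UnifiedEmbedding:
    """Per-drug features for a pipeline variant (label-free, all drugs).

    nmdadnn: similarities -> RWR+PPMI -> scaled -> MDA bottleneck.
    no_atc:  same with the four Jaccard sources only.
    mdadnn:  MDA directly on the scaled similarity matrices (no diffusion).
    dnn_avg: rows of the average of the five similarity matrices.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    catalog = dataset.catalog
    atc = None if variant == "no_atc" else dataset.atc
    sims = build_all_similarities(dataset.features, atc, catalog)
    seed = child_seed(config.cv.seed, "mda")
    if variant == "dnn_avg":
        avg = np.mean([s.values for s in sims], axis=0)
        return UnifiedEmbedding(avg, catalog.drug_ids)
    if variant in ("nmdadnn", "no_atc"):
        nets = build_all_networks(sims, config.alpha, config.epsilon)
        scaled, _ = scale_networks(nets)
    else:  # mdadnn: fuse raw similarities
        from .netembed import PPMINetwork
        scaled, _ = scale_networks(
            [PPMINetwork(s.source_name, s.values) for s in sims]
        )
    model, _ = train_mda(scaled, config.mda, seed)
    return encode(model, scaled, catalog.drug_ids)


def run_cv(
    dataset,
    config: PipelineConfig,
    variant: str = "nmdadnn",
    plan: CVPlan | None = None,
) -> CVResult:
    """Cross-validated evaluation of a pipeline variant.

    Drug representations use no interaction labels and are computed once on
    all drugs; the classifier sees only training-fold pairs. Given the same
    seed, every variant shares the identical fold plan.
    """
    catalog, ddis = dataset.catalog, dataset.ddis
    cv = config.cv
    if plan is None:
        plan = split_cv(ddis, catalog, cv.scene, cv.folds, cv.seed)
    emb = build_drug_representation(dataset, config, variant)
    operator = config.operator
    reports = []
    for k, (train_idx, test_idx) in enumerate(plan.folds):
        train_pairs = [ddis.pairs[i] for i in train_idx]
        test_pairs = [ddis.pairs[i] for i in test_idx]
        if not test_pairs:
            logger.warning("fold %d has no test pairs; skipped", k)
            continue
        model = fit_pair_classifier(
            emb, train_pairs, config.dnn,
            child_seed(cv.seed, f"dnn/{plan.scene}/{k}"),
            operator, catalog, ddis.n_types,
        )
        proba = pair_probabilities(
            model, emb, [(a, b) for a, b, _ in test_pairs], operator, catalog
        )
        y_true = np.array([t for _, _, t in test_pairs])
        reports.append(compute_metrics(y_true, proba, ddis.n_types))
    mean, sd = _aggregate(reports)
    return CVResult(plan.scene, variant, reports, mean, sd, cv.seed)


def chance_macro_f1(
    ddis: DDITable, seed: int = 0, n_draws: int = 20
) -> float:
    """Macro-F1 of a frequency-matched random predictor on the label set.

    Predictions are drawn from the empirical type frequencies and scored
    with the same metric path as the model; averaged over draws.
    """
    y = np.array([t for _, _, t in ddis.pairs])
    l = ddis.n_types
    freq = np.bincount(y, minlength=l) / len(y)
    rng = np.random.default_rng(child_seed(seed, "chance"))
    vals = []
    for _ in range(n_draws):
        y_pred = rng.choice(l, size=len(y), p=freq)
        proba = np.full((len(y), l), 1e-9)
        proba[np.arange(len(y)), y_pred] = 1.0
        proba /= proba.sum(axis=1, keepdims=True)
        vals.append(compute_metrics(y, proba, l).f1_macro)
    return float(np.mean(vals))
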