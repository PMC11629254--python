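"""Train/test splitting, confusion-matrix metrics, and the end-to-end run.

The five evaluation metrics are the usual confusion-matrix ratios with the
Yanchi class (NX) as positive:

    precision = TP/(TP+FP)        recall = TP/(TP+FN)
    accuracy  = (TP+TN)/total     error rate = (FP+FN)/total
    F1        = 2TP/(2TP+FP+FN)

Ratios with a zero denominator are reported as 0 and flagged.

:func:`evaluate_pipeline` chains the whole analysis — synthetic generation
(or a CSV input), QC filtering, per-part screening, marker-panel
intersection, stepwise Fisher discriminant, and the three BP-network
variants on a stratified 4:1 split — into a single JSON-serializable
report that records every seed and threshold used.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import train_test_split

from . import discriminant, screening, swarmnet, synthetic_data
from .preprocess import FeatureTable, QCSpec, qc_filter, read_feature_table

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "metrics",
    "split_4to1",
    "PipelineConfig",
    "evaluate_pipeline",
]

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "NX"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true, y_pred, positive: str = POSITIVE_CLASS) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


@dataclass(frozen=True)
class MetricReport:
    precision: float
    recall: float
    accuracy: float
    error_rate: float
    f1: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return asdict(self)


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Precision, recall, accuracy, error rate and F1 from the counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    accuracy = (cm.tp + cm.tn) / cm.total
    error_rate = (cm.fp + cm.fn) / cm.total
    f1 = ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1")
    return MetricReport(precision, recall, accuracy, error_rate, f1, tuple(undefined))


def split_4to1(
    table: FeatureTable,
    seed: int | None = None,
    stratify: bool = True,
    max_redraws: int = 20,
) -> tuple[FeatureTable, FeatureTable]:
    """Random 4:1 split into train/test (|train| = floor(0.8 n)), stratified
    by the NX / non-NX label by default; deterministic under ``seed``.  If a
    class ends up absent from either side the split is re-drawn."""
    bio = table.subset(biological_only=True)
    n = bio.n_samples
    if n < 5:
        raise ValueError("need at least 5 samples for a 4:1 split")
    n_train = int(np.floor(0.8 * n))
    labels = bio.nx_labels().to_numpy()
    ids = np.array(bio.sample_ids)
    for attempt in range(max_redraws):
        rs = None if seed is None else seed + attempt
        train_ids, test_ids = train_test_split(
            ids,
            train_size=n_train,
            random_state=rs,
            shuffle=True,
            stratify=labels if stratify else None,
        )
        tr = bio.subset(samples=list(train_ids))
        te = bio.subset(samples=list(test_ids))
        if not stratify or (
            set(tr.nx_labels()) == set(labels) and set(te.nx_labels()) == set(labels)
        ):
            if attempt:
                logger.info("split re-drawn %d time(s) to keep both classes", attempt)
            return tr, te
    warnings.warn("could not keep both classes in both splits; returning last draw")
    return tr, te


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration; all stages record their seeds."""

    input_csv: str | None = None  # None → generate the default synthetic world
    seed: int = 0
    qc: QCSpec = field(default_factory=QCSpec)
    thresholds: screening.ScreeningThresholds = field(
        default_factory=screening.ScreeningThresholds
    )
    n_orthogonal: int = 1
    f_remove: float = discriminant.DEFAULT_F_REMOVE
    cv_tolerance: float = 0.0
    n_hidden: int = 6
    burn_in_epochs: int = 50


def _network_block(train: FeatureTable, test: FeatureTable, panel, cfg: PipelineConfig) -> dict:
    feats = panel.markers
    Xtr = train.abundances[feats].to_numpy(dtype=float)
    Xte = test.abundances[feats].to_numpy(dtype=float)
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xtr = (Xtr - mu) / sd
    Xte = (Xte - mu) / sd
    classes = ["nonNX", "NX"]  # index 1 = positive class
    ytr = (train.nx_labels().to_numpy() == "NX").astype(int)
    yte = (test.nx_labels().to_numpy() == "NX").astype(int)
    layers = swarmnet.LayerSizes(n_in=len(feats), n_hidden=cfg.n_hidden, n_out=2)

    out = {}
    runs = {
        "BP": lambda: swarmnet.train_bp(Xtr, ytr, layers, seed=cfg.seed)[0],
        "GA-BP": lambda: swarmnet.fit_hybrid(
            Xtr, ytr, "ga", seed=cfg.seed, layers=layers, burn_in_epochs=cfg.burn_in_epochs
        )[0],
        "PSO-BP": lambda: swarmnet.fit_hybrid(
            Xtr, ytr, "pso", seed=cfg.seed, layers=layers, burn_in_epochs=cfg.burn_in_epochs
        )[0],
    }
    for name, run in runs.items():
        t0 = time.perf_counter()
        params = run()
        block = {}
        for split_name, X, y in (("train", Xtr, ytr), ("test", Xte, yte)):
            pred = swarmnet.predict(params, X)
            cm = confusion(
                np.array([classes[i] for i in y]),
                np.array([classes[i] for i in pred]),
            )
            block[split_name] = {
                "confusion": asdict(cm),
                "metrics": metrics(cm).as_dict(),
            }
        block["seconds"] = round(time.perf_counter() - t0, 3)
        out[name] = block
        logger.info("%s trained in %.2fs", name, block["seconds"])
    return out


def evaluate_pipeline(config: PipelineConfig = PipelineConfig()) -> dict:
    """Run generate → QC → screen → stepwise LDA → BP/GA-BP/PSO-BP → metrics.

    Raises with the failing stage's name; an empty marker panel halts the
    pipeline with an informative error.
    """
    stage = "input"
    try:
        if config.input_csv is None:
            spec = synthetic_data.default_spec(seed=config.seed)
            table = synthetic_data.generate(spec, seed=config.seed)
            source = {"synthetic": True, "seed": config.seed, "n_lipids": spec.n_lipids}
        else:
            table = read_feature_table(config.input_csv)
            source = {"synthetic": False, "path": config.input_csv}

        stage = "qc"
        if table.is_qc().any():
            table = qc_filter(table, spec=config.qc)

        stage = "screening"
        lt = screening.screen_part(table, "LT", config.thresholds, config.n_orthogonal)
        km = screening.screen_part(table, "KM", config.thresholds, config.n_orthogonal)
        panel = screening.intersect_panel(lt, km)
        if len(panel) == 0:
            raise ValueError("marker panel is empty: per-part candidate sets are disjoint")

        stage = "discriminant"
        bio = table.subset(biological_only=True)
        trace, fisher = discriminant.stepwise_backward(
            bio,
            features=panel.markers,
            f_remove=config.f_remove,
            cv_tolerance=config.cv_tolerance,
        )
        resub = discriminant.resubstitution_accuracy(bio, model=fisher)
        loocv = discriminant.loocv_accuracy(bio, features=fisher.features)

        stage = "networks"
        train, test = split_4to1(table, seed=config.seed)
        networks = _network_block(train, test, panel, config)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"pipeline stage {stage!r}: missing input {exc.filename!r}") from exc
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r}: {exc}") from exc

    return {
        "config": {
            "seed": config.seed,
            "thresholds": asdict(config.thresholds),
            "qc": asdict(config.qc),
            "n_orthogonal": config.n_orthogonal,
            "f_remove": config.f_remove,
            "positive_class": POSITIVE_CLASS,
            "fc_orientation": "nonNX/NX",
        },
        "source": source,
        "screening": {
            "n_candidates_LT": len(lt.selected),
            "n_candidates_KM": len(km.selected),
            "panel": panel.markers,
            "panel_direction": panel.direction,
            "n_panel": len(panel),
        },
        "discriminant": {
            "selected_features": fisher.features,
            "canonical_correlation": fisher.canonical_correlation,
            "resubstitution_accuracy": resub,
            "loocv_accuracy": loocv,
            "n_steps": len(trace),
        },
        "networks": networks,
        "split": {"n_train": train.n_samples, "n_test": test.n_samples},
    }
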