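"""Patient-level classification harness: ORI vs HSI input comparison.

Implements the evaluation protocol around the cognitive-status classifier:
subject-level stratified 70/10/20 splits (all images of a subject stay in one
partition), label-preserving training-set augmentation, a desk-scale
neural-network backend (a small MLP head trained with Adam, batch size 32 and
early stopping on validation loss, patience 10), one-vs-rest per-class
metrics from the confusion matrix, and the fold-paired comparison of the two
input representations (original RGB renders vs 3-channel reductions of the
reconstructed hyperspectral cubes).  Heavier CNN backends can be plugged in
as a callable; the harness's contract is protocol fidelity, not any specific
architecture.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from skimage import morphology
from skimage.transform import resize, rotate
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger("retispec")

CLASS_ORDER = ("Dementia", "MCI", "Normal")

__all__ = [
    "CLASS_ORDER",
    "SplitPlan",
    "AugmentationPolicy",
    "TrainConfig",
    "ConfusionMatrix",
    "ClassMetrics",
    "FoldResult",
    "make_splits",
    "audit_no_leakage",
    "augment",
    "train_eval",
    "metrics_from_confusion",
    "compare_modalities",
    "build_modality_arrays",
    "transfer_recipe",
]


@dataclass
class SplitPlan:
    """One subject-level partition of the cohort."""

    fold: int
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    seed: int = 0

    def partition_of(self) -> dict[str, str]:
        out = {}
        for name, subjects in (("train", self.train), ("val", self.val), ("test", self.test)):
            for s in subjects:
                out[s] = name
        return out


def make_splits(cohort, n_folds: int = 5, seed: int = 0,
                fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                min_per_group: int = 5) -> list[SplitPlan]:
    """Seeded repeated subject-level splits, stratified by group.

    Each fold is an independent random 70/10/20 division of every group's
    subjects; all of a subject's images follow the subject.  Groups smaller
    than ``min_per_group`` subjects cannot be stratified and are rejected.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    by_group = cohort.subjects.groupby("group")["subject_id"].apply(list).to_dict()
    for g, subs in by_group.items():
        if len(subs) < min_per_group:
            raise ValueError(f"group {g} has {len(subs)} subjects; need >= {min_per_group}")
    plans = []
    for fold in range(n_folds):
        rng = np.random.default_rng([seed, fold])
        train, val, test = [], [], []
        for g in sorted(by_group):
            subs = np.array(sorted(by_group[g]))
            rng.shuffle(subs)
            n = len(subs)
            n_test = max(1, round(fractions[2] * n))
            n_val = max(1, round(fractions[1] * n))
            test.extend(subs[:n_test])
            val.extend(subs[n_test:n_test + n_val])
            train.extend(subs[n_test + n_val:])
        if not train:
            raise ValueError("split left no training subjects")
        plans.append(SplitPlan(fold=fold, train=tuple(sorted(train)),
                               val=tuple(sorted(val)), test=tuple(sorted(test)),
                               fractions=fractions, seed=seed))
    audit_no_leakage(plans)
    return plans


def audit_no_leakage(plans: list[SplitPlan]) -> bool:
    """Assert no subject appears in more than one partition of any fold."""
    for plan in plans:
        sets = [set(plan.train), set(plan.val), set(plan.test)]
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        if len(union) != total:
            dupes = [s for s in union
                     if sum(s in part for part in sets) > 1]
            raise AssertionError(f"fold {plan.fold}: subjects in multiple partitions: {dupes}")
    return True


@dataclass
class AugmentationPolicy:
    """Label-preserving training-set transforms (applied to train only)."""

    hflip: bool = True
    vflip: bool = True
    rotation_deg: float = 15.0
    green_channel: bool = True
    noise_amp: float = 0.01
    opening_radius: int = 0

    def enabled(self) -> bool:
        return (self.hflip or self.vflip or self.rotation_deg > 0
                or self.green_channel or self.noise_amp > 0 or self.opening_radius > 0)


def augment(image: np.ndarray, policy: AugmentationPolicy,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Seeded random composition of the enabled transforms; dims preserved."""
    rng = rng if rng is not None else np.random.default_rng(0)
    out = np.asarray(image, dtype=float)
    if policy.green_channel and out.ndim == 3 and rng.random() < 0.5:
        # middle-channel extraction (the classic fundus "green channel"),
        # applied to half the augmented copies
        out = np.repeat(out[:, :, 1:2], out.shape[2], axis=2)
    if policy.opening_radius > 0:
        footprint = morphology.disk(policy.opening_radius)
        if out.ndim == 3:
            out = np.stack([morphology.opening(out[:, :, c], footprint)
                            for c in range(out.shape[2])], axis=2)
        else:
            out = morphology.opening(out, footprint)
    if policy.hflip and rng.random() < 0.5:
        out = out[:, ::-1]
    if policy.vflip and rng.random() < 0.5:
        out = out[::-1, :]
    if policy.rotation_deg > 0:
        angle = rng.uniform(-policy.rotation_deg, policy.rotation_deg)
        out = rotate(out, angle, mode="edge", preserve_range=True)
    if policy.noise_amp > 0:
        out = out + rng.normal(0.0, policy.noise_amp, size=out.shape)
    return np.clip(out, 0.0, 1.0)


@dataclass
class TrainConfig:
    """Desk-scale training configuration.

    The serialized transfer-learning recipe (Adam, lr 1e-4, batch 32,
    max 50 epochs, patience 10) is available via :func:`transfer_recipe`;
    the desk default raises the learning rate and epoch budget because the
    MLP head trains from scratch on a few hundred samples.
    """

    backend: str = "mlp"  # "mlp" or a callable plug-in
    input_size: int = 8
    hidden: tuple[int, ...] = (16,)
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    alpha: float = 1e-4
    seed: int = 0
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    n_augment: int = 2  # augmented copies per training image (0 disables)
    class_order: tuple[str, ...] = CLASS_ORDER
    # optional callable(X_tr, y_tr, X_val, y_val, X_te, classes, seed) -> y_pred
    plugin: object = None


def transfer_recipe(**overrides) -> TrainConfig:
    """The published fine-tuning recipe: Adam, lr 1e-4, batch 32, 50 epochs."""
    cfg = TrainConfig(learning_rate=1e-4, batch_size=32, max_epochs=50, patience=10)
    return replace(cfg, **overrides)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (C, C), rows true, cols predicted
    class_order: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    """One-vs-rest per-class metrics plus overall and averaged scores."""

    table: pd.DataFrame  # index class; precision, recall, specificity, f1, support
    accuracy: float
    macro: dict
    weighted: dict

    def value(self, metric: str) -> float:
        if metric == "accuracy":
            return self.accuracy
        return self.macro[metric]


@dataclass
class FoldResult:
    fold: int
    confusion: ConfusionMatrix
    metrics: ClassMetrics


def _featurize(images: np.ndarray, input_size: int) -> np.ndarray:
    """Bicubic resize to the backend's input size, then flatten."""
    out = np.empty((len(images), input_size * input_size * images.shape[3]))
    for i, img in enumerate(images):
        small = resize(img, (input_size, input_size), order=3, anti_aliasing=True,
                       preserve_range=True)
        out[i] = small.ravel()
    return out


def _fit_mlp(X_tr, y_tr, X_val, y_val, classes, config: TrainConfig,
             seed: int) -> MLPClassifier:
    """Adam minibatch training with early stopping on validation loss."""
    rng = np.random.default_rng(seed)
    clf = MLPClassifier(hidden_layer_sizes=config.hidden, solver="adam",
                        learning_rate_init=config.learning_rate, alpha=config.alpha,
                        batch_size=min(config.batch_size, len(X_tr)),
                        max_iter=1, random_state=int(seed) & 0x7FFFFFFF)
    best_loss, best_state, stale = np.inf, None, 0
    n = len(X_tr)
    bs = min(config.batch_size, n)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        with warnings.catch_warnings():
            # each partial_fit is one optimizer step; the per-call iteration
            # cap is intentional, so sklearn's convergence warning is noise
            warnings.simplefilter("ignore")
            for b0 in range(0, n, bs):
                idx = order[b0:b0 + bs]
                clf.partial_fit(X_tr[idx], y_tr[idx], classes=classes)
        val_loss = log_loss(y_val, clf.predict_proba(X_val), labels=classes)
        if val_loss < best_loss - 1e-6:
            best_loss, stale = val_loss, 0
            best_state = (copy.deepcopy(clf.coefs_), copy.deepcopy(clf.intercepts_))
        else:
            stale += 1
            if stale >= config.patience:
                logger.debug("early stop at epoch %d (val loss %.4f)", epoch, best_loss)
                break
    if best_state is not None:
        clf.coefs_, clf.intercepts_ = best_state
    return clf


def train_eval(images: np.ndarray, labels: np.ndarray, subject_ids: np.ndarray,
               plan: SplitPlan, config: TrainConfig | None = None) -> FoldResult:
    """Train on the plan's train subjects and evaluate on its test subjects.

    Augmentation (if enabled) is applied to training images only; features
    are standardized with statistics fitted on the training set.
    """
    config = config or TrainConfig()
    labels = np.asarray(labels)
    subject_ids = np.asarray(subject_ids)
    part = plan.partition_of()
    member = np.array([part.get(s, "drop") for s in subject_ids])
    tr, va, te = member == "train", member == "val", member == "test"
    if len(np.unique(labels[tr])) < 2:
        raise ValueError("degenerate training set: fewer than two classes")
    classes = np.array([c for c in config.class_order if c in np.unique(labels)])

    rng = np.random.default_rng([config.seed, plan.fold, 17])
    X_imgs, y_tr = list(images[tr]), list(labels[tr])
    if config.n_augment > 0 and config.augmentation.enabled():
        for img, lab in zip(images[tr], labels[tr]):
            for _ in range(config.n_augment):
                X_imgs.append(augment(img, config.augmentation, rng))
                y_tr.append(lab)
    X_tr = _featurize(np.asarray(X_imgs), config.input_size)
    y_tr = np.asarray(y_tr)
    X_va = _featurize(images[va], config.input_size)
    X_te = _featurize(images[te], config.input_size)

    scaler = StandardScaler().fit(X_tr)
    X_tr, X_va, X_te = scaler.transform(X_tr), scaler.transform(X_va), scaler.transform(X_te)

    if callable(config.plugin):
        y_pred = config.plugin(X_tr, y_tr, X_va, labels[va], X_te, classes,
                               [config.seed, plan.fold])
    elif config.backend == "mlp":
        clf = _fit_mlp(X_tr, y_tr, X_va, labels[va], classes, config,
                       seed=(config.seed * 1000003 + plan.fold) & 0x7FFFFFFF)
        y_pred = clf.predict(X_te)
    else:
        raise ValueError(f"unknown backend {config.backend!r}")

    counts = _sk_confusion(labels[te], y_pred, labels=list(classes))
    cm = ConfusionMatrix(counts=counts, class_order=tuple(classes))
    return FoldResult(fold=plan.fold, confusion=cm, metrics=metrics_from_confusion(cm))


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("undefined %s (zero denominator); reported as NaN", what)
        return float("nan")
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest precision, recall (sensitivity), specificity and F1.

    Undefined ratios (zero denominators) are reported as NaN, never as 0;
    macro averages skip NaNs, weighted averages weight by class support.
    """
    counts = np.asarray(cm.counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    total = counts.sum()
    rows = {}
    for i, cls in enumerate(cm.class_order):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        precision = _safe_div(tp, tp + fp, f"precision[{cls}]")
        recall = _safe_div(tp, tp + fn, f"recall[{cls}]")
        specificity = _safe_div(tn, tn + fp, f"specificity[{cls}]")
        if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
            f1 = float("nan")
            logger.warning("undefined f1[%s]; reported as NaN", cls)
        else:
            f1 = 2 * precision * recall / (precision + recall)
        rows[cls] = dict(precision=precision, recall=recall,
                         specificity=specificity, f1=f1,
                         support=counts[i].sum())
    table = pd.DataFrame(rows).T
    accuracy = float(np.trace(counts) / total)
    support = table["support"].to_numpy()
    macro, weighted = {}, {}
    for m in ("precision", "recall", "specificity", "f1"):
        vals = table[m].to_numpy()
        macro[m] = float(np.nanmean(vals)) if not np.isnan(vals).all() else float("nan")
        ok = ~np.isnan(vals)
        weighted[m] = (float((vals[ok] * support[ok]).sum() / support[ok].sum())
                       if support[ok].sum() > 0 else float("nan"))
    return ClassMetrics(table=table, accuracy=accuracy, macro=macro, weighted=weighted)


def compare_modalities(metrics_a: list[ClassMetrics], metrics_b: list[ClassMetrics],
                       labels: tuple[str, str] = ("HSI", "ORI")) -> pd.DataFrame:
    """Fold-paired two-tailed t-tests on each summary metric.

    Requires matched folds (same split seeds) in the two lists.  Returns one
    row per metric with mean +/- SD per modality, the paired t statistic and
    p-value; identical metric vectors give t = 0, p = 1.
    """
    if len(metrics_a) != len(metrics_b):
        raise ValueError("fold counts differ between modalities")
    if len(metrics_a) < 2:
        raise ValueError("need >= 2 folds for a paired test")
    rows = []
    for metric in ("accuracy", "precision", "recall", "specificity", "f1"):
        a = np.array([m.value(metric) for m in metrics_a])
        b = np.array([m.value(metric) for m in metrics_b])
        d = a - b
        if np.allclose(d, 0.0):
            t, p = 0.0, 1.0
        elif np.std(d, ddof=1) == 0:
            t, p = np.inf * np.sign(d.mean()), 0.0
        else:
            t, p = stats.ttest_rel(a, b)
        rows.append({
            "metric": metric,
            f"mean_{labels[0]}": a.mean(), f"sd_{labels[0]}": a.std(ddof=1),
            f"mean_{labels[1]}": b.mean(), f"sd_{labels[1]}": b.std(ddof=1),
            "mean_diff": d.mean(), "t": float(t), "p": float(p),
        })
    return pd.DataFrame(rows)


def build_modality_arrays(cohort, cam=None, model=None, effect=None, seed: int = 0,
                          size: int = 64, hsi_range: tuple[float, float] = (550.0, 780.0),
                          strategy: str = "thirds",
                          max_images_per_subject: int | None = None) -> dict:
    """Render the cohort once and derive both classifier input sets.

    Returns ``{"ORI": X, "HSI": X, "labels": y, "subject_ids": s}`` where the
    two arrays come from the *same* phantoms, so an accuracy difference is
    attributable to the input representation only.  ``model`` is the fitted
    calibration used for the HSI arm.
    """
    from .reconstruction import cube_to_three_channel, reconstruct_cube, select_range
    from .synthetic import cohort_phantoms

    if model is None:
        raise ValueError("a CalibrationModel is required for the HSI arm")
    ori, hsi, y, sids = [], [], [], []
    for row, phantom in cohort_phantoms(cohort, cam=cam, effect=effect, seed=seed,
                                        size=size,
                                        max_images_per_subject=max_images_per_subject):
        rgb = phantom.rgb_image
        cube = reconstruct_cube(rgb, model, provenance={"image_id": row["image_id"]})
        sub = select_range(cube, *hsi_range)
        ori.append(rgb)
        hsi.append(cube_to_three_channel(sub, strategy=strategy))
        y.append(row["group"])
        sids.append(row["subject_id"])
    return {"ORI": np.asarray(ori), "HSI": np.asarray(hsi),
            "labels": np.asarray(y), "subject_ids": np.asarray(sids)}
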