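"""Template-based biometric identification (1:N) from thigh-ECG heartbeats.

Each subject is represented by a set of fixed-window heartbeat templates;
identification assigns a probe template to one of the enrolled subjects.
Two train/test protocols are supported:

* **random** — templates of each subject are randomly partitioned into
  train and test sets (default 2/3 train), reshuffled every repetition;
* **static** — train on the first 30 templates of each subject and test on
  the *last* 30/20/15, leaving a temporal gap that probes morphology drift.

Four classifiers share one interface: a linear one-vs-all SVM, Gaussian
naive Bayes, 3-nearest-neighbours, and the binarized CNN (which receives
templates quantized to 8-bit unsigned integers before standardization).
Performance (accuracy, macro recall, macro precision) is swept over
population sizes, drawing a fresh seeded subject subset per repetition so
metrics average over household composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from seatecg.bcnn import BinarizedConvNet
from seatecg.morphology import TemplateSet

__all__ = [
    "ProtocolSpec",
    "ClassifierSpec",
    "EvalResult",
    "quantize_templates",
    "split_templates",
    "train_classifier",
    "evaluate",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("BCNN", "SVM", "GaussianNB", "KNN3")


@dataclass
class ProtocolSpec:
    """Train/test template-selection protocol.

    In static mode the split is temporal and identical across repetitions:
    train on the first ``n_train`` templates per subject, test on the last
    ``n_test``.  In random mode a fraction ``test_fraction`` of each
    subject's templates is held out, re-drawn (seeded) every repetition.
    """

    mode: str = "random"
    n_train: int = 30
    n_test: int = 30
    test_fraction: float = 1.0 / 3.0
    n_repetitions: int = 30
    population_sizes: tuple[int, ...] = tuple(range(2, 18))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "static"):
            raise ValueError("mode must be 'random' or 'static'")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class ClassifierSpec:
    """One of the four identification classifiers plus its hyperparameters."""

    kind: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")


@dataclass
class EvalResult:
    """Aggregated identification performance for one configuration."""

    classifier: str
    protocol: str
    population_size: int
    accuracy: float
    recall: float
    precision: float
    accuracy_sd: float
    per_repetition: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m in (self.accuracy, self.recall, self.precision):
            if not 0.0 <= m <= 100.0:
                raise ValueError("metrics are percentages in [0, 100]")
        accs = self.per_repetition.get("accuracy")
        if accs and not (min(accs) - 1e-9 <= self.accuracy <= max(accs) + 1e-9):
            raise ValueError("mean accuracy outside the repetition range")


def quantize_templates(templates: np.ndarray) -> np.ndarray:
    """Per-template min–max quantization to 8-bit unsigned integers.

    Each template is mapped linearly so its minimum becomes 0 and its
    maximum 255; a constant template maps to all-128 by convention.  The
    round-trip error is bounded by range/255 per sample.
    """
    x = np.atleast_2d(np.asarray(templates, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("templates must be finite")
    lo = x.min(axis=1, keepdims=True)
    rng = x.max(axis=1, keepdims=True) - lo
    out = np.full(x.shape, 128, dtype=np.uint8)
    ok = rng[:, 0] > 0
    scaled = np.rint(255.0 * (x[ok] - lo[ok]) / rng[ok])
    out[ok] = scaled.astype(np.uint8)
    return out


def _subject_templates(tset: TemplateSet) -> np.ndarray:
    return tset.valid


def split_templates(
    sets: dict[str, TemplateSet],
    protocol: ProtocolSpec,
    rep: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Build labelled (train, test) collections for one repetition.

    Returns ``(X_train, y_train, X_test, y_test)`` with template rows and
    subject-id labels.  Static splits are identical for every ``rep``;
    random splits are seeded by ``(protocol.seed, rep)``.
    """
    xs_tr, ys_tr, xs_te, ys_te = [], [], [], []
    for sid, tset in sets.items():
        tpl = _subject_templates(tset)
        n = tpl.shape[0]
        if protocol.mode == "static":
            need = protocol.n_train + protocol.n_test
            if n < need:
                raise ValueError(
                    f"subject {sid}: {n} templates < {need} required for static split"
                )
            tr_idx = np.arange(protocol.n_train)
            te_idx = np.arange(n - protocol.n_test, n)
        else:
            if n < 10:
                raise ValueError(f"subject {sid}: needs >= 10 templates, has {n}")
            rng = np.random.default_rng([protocol.seed, rep, _sid_hash(sid)])
            perm = rng.permutation(n)
            n_test = max(1, int(round(protocol.test_fraction * n)))
            te_idx, tr_idx = perm[:n_test], perm[n_test:]
        xs_tr.append(tpl[tr_idx])
        ys_tr.extend([sid] * tr_idx.size)
        xs_te.append(tpl[te_idx])
        ys_te.extend([sid] * te_idx.size)
    return (
        np.vstack(xs_tr),
        np.asarray(ys_tr),
        np.vstack(xs_te),
        np.asarray(ys_te),
    )


def _sid_hash(sid: str) -> int:
    return sum(ord(c) * 31**i for i, c in enumerate(sid)) % (2**31)


class _TemplatePipeline:
    """Standardize (train-fitted), optionally quantize first, then classify."""

    def __init__(self, clf, quantize: bool) -> None:
        self.clf = clf
        self.quantize = quantize
        self.scaler = StandardScaler()

    def _prep(self, X: np.ndarray, fit: bool) -> np.ndarray:
        if self.quantize:
            X = quantize_templates(X).astype(float)
        return self.scaler.fit_transform(X) if fit else self.scaler.transform(X)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_TemplatePipeline":
        self.clf.fit(self._prep(X, fit=True), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict(self._prep(X, fit=False))


def train_classifier(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    seed: int = 0,
) -> _TemplatePipeline:
    """Fit one classifier on flattened, standardized training templates.

    The BCNN additionally sees its input quantized to uint8 before
    standardization; ``seed`` fixes its weight initialisation (fresh
    training every repetition).
    """
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain at least two classes")
    hp = spec.hyperparams
    if spec.kind == "SVM":
        clf = OneVsRestClassifier(SVC(kernel="linear", C=hp.get("C", 1.0)))
    elif spec.kind == "GaussianNB":
        clf = GaussianNB()
    elif spec.kind == "KNN3":
        clf = KNeighborsClassifier(n_neighbors=hp.get("k", 3))
    else:  # BCNN
        clf = BinarizedConvNet(
            n_epochs=hp.get("n_epochs", 30),
            batch_size=hp.get("batch_size", 32),
            lr=hp.get("lr", 1e-3),
            random_state=seed,
        )
    return _TemplatePipeline(clf, quantize=spec.kind == "BCNN").fit(X_train, y_train)


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    return (
        100.0 * accuracy_score(y_true, y_pred),
        100.0 * recall_score(y_true, y_pred, average="macro", zero_division=0),
        100.0 * precision_score(y_true, y_pred, average="macro", zero_division=0),
    )


def evaluate(
    sets: dict[str, TemplateSet],
    classifiers: list[ClassifierSpec],
    protocol: ProtocolSpec,
) -> list[EvalResult]:
    """Sweep classifiers over population sizes under one protocol.

    For every repetition a seeded subject subset of the target population
    size is drawn from the cohort, the protocol split is applied, the
    classifier is trained from scratch, and accuracy plus macro recall and
    precision are measured on the held-out templates.  Results are ordered
    by (classifier, population size).
    """
    subject_ids = sorted(sets)
    results: list[EvalResult] = []
    for spec in classifiers:
        for pop in protocol.population_sizes:
            if pop > len(subject_ids):
                raise ValueError(
                    f"population size {pop} exceeds cohort of {len(subject_ids)}"
                )
            per: dict[str, list[float]] = {
                "accuracy": [], "recall": [], "precision": []
            }
            for rep in range(protocol.n_repetitions):
                rng = np.random.default_rng([protocol.seed, pop, rep])
                chosen = rng.choice(subject_ids, size=pop, replace=False)
                subset = {sid: sets[sid] for sid in chosen}
                xtr, ytr, xte, yte = split_templates(subset, protocol, rep)
                model = train_classifier(
                    spec, xtr, ytr, seed=int(rng.integers(2**31))
                )
                acc, rec, prec = _metrics(yte, model.predict(xte))
                per["accuracy"].append(acc)
                per["recall"].append(rec)
                per["precision"].append(prec)
            accs = np.asarray(per["accuracy"])
            results.append(
                EvalResult(
                    classifier=spec.kind,
                    protocol=_protocol_label(protocol),
                    population_size=pop,
                    accuracy=float(accs.mean()),
                    recall=float(np.mean(per["recall"])),
                    precision=float(np.mean(per["precision"])),
                    accuracy_sd=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
                    per_repetition=per,
                )
            )
    return results


def _protocol_label(p: ProtocolSpec) -> str:
    if p.mode == "static":
        return f"static-{p.n_train}/{p.n_test}"
    return f"random-{1 - p.test_fraction:.2f}/{p.test_fraction:.2f}"
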