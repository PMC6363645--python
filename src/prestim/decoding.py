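"""Class-balanced repeated nested cross-validation with an ANN classifier.

The decoding engine mirrors a classical single-trial EEG classification
design:

1. **Rebalancing** - the majority class is randomly downsampled (without
   replacement) so both classes contribute the same number of trials, that
   number chosen divisible by the fold count; the whole procedure is repeated
   ``n_reps`` times with fresh random subsets to reduce selection bias.
2. **Nested sixfold CV** - per repetition, a stratified ``n_folds`` split;
   within each fold the non-test trials are further split into training and
   validation sets.  Feature selection (per-feature two-sample pooled-variance
   t-test, uncorrected, ``p < threshold``), [0, 1] min-max normalization and
   early stopping all see the training/validation data only.
3. **Classifier** - a two-layer feedforward network (10 tanh hidden units,
   two linear outputs, one-hot targets) trained by scaled conjugate gradient
   on mean squared error, stopping at the epoch budget, the MSE goal, or when
   validation error has risen for ``patience`` consecutive evaluations, and
   returning the weights at the validation minimum.
4. **Reporting** - accuracy, sensitivity (face hit rate) and specificity
   (no-face hit rate) per (repetition, fold) model, with the selected feature
   descriptors recorded for consistency analyses, plus the exact binomial
   empirical chance level for a given evaluation size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from .epochs_io import CLASSES, FACE, NOFACE
from .features import FeatureDescriptor, FeatureSet

__all__ = [
    "DecodingConfig",
    "FoldRecord",
    "CVRunResult",
    "Metrics",
    "downsample_balance",
    "ttest_rank",
    "select_by_threshold",
    "normalize01",
    "train_ann",
    "nested_cv_run",
    "evaluate",
    "empirical_chance",
    "pam_aggregate",
]

logger = logging.getLogger(__name__)

#: p-value thresholds swept in the original selection analysis.
P_THRESHOLD_SWEEP = (0.001,) + tuple(round(0.005 * k, 3) for k in range(1, 11))


@dataclass(frozen=True)
class DecodingConfig:
    """Settings of the balanced repeated nested CV run.

    ``per_class_n='auto'`` downsamples to ``floor(min_class / n_folds) * n_folds``
    trials per class.  ``max_epochs`` defaults to the full training budget;
    simulation studies typically reduce it (early stopping usually triggers
    long before either limit).
    """

    n_folds: int = 6
    n_reps: int = 25
    p_threshold: float = 0.05
    n_hidden: int = 10
    max_epochs: int = 10_000
    goal_mse: float = 1e-5
    patience: int = 6
    val_fraction: float = 0.2
    per_class_n: int | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        if isinstance(self.per_class_n, int):
            if self.per_class_n % self.n_folds:
                raise ValueError("fixed per_class_n must be divisible by n_folds")
        elif self.per_class_n != "auto":
            raise ValueError("per_class_n must be an int or 'auto'")


class Metrics(NamedTuple):
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class FoldRecord:
    """Metrics and selected features of one trained model (one rep, one fold)."""

    rep: int
    fold: int
    accuracy: float
    sensitivity: float
    specificity: float
    n_test: int
    selected: tuple[int, ...]  # column indices into the feature space


@dataclass
class CVRunResult:
    """All per-model records of one balanced repeated nested CV run."""

    records: tuple[FoldRecord, ...]
    descriptors: tuple[FeatureDescriptor, ...]
    config: DecodingConfig
    n_balanced: int

    @property
    def model_count(self) -> int:
        return len(self.records)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.records])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        a = self.accuracies
        return float(a.std(ddof=1)) if a.size > 1 else 0.0

    @property
    def mean_sensitivity(self) -> float:
        return float(np.nanmean([r.sensitivity for r in self.records]))

    @property
    def mean_specificity(self) -> float:
        return float(np.nanmean([r.specificity for r in self.records]))

    @property
    def rep_mean_accuracies(self) -> np.ndarray:
        reps = sorted({r.rep for r in self.records})
        return np.array(
            [np.mean([r.accuracy for r in self.records if r.rep == rep]) for rep in reps]
        )

    @property
    def sem_accuracy(self) -> float:
        """Standard error of the per-repetition mean accuracies."""
        m = self.rep_mean_accuracies
        return float(m.std(ddof=1) / np.sqrt(m.size)) if m.size > 1 else 0.0

    def selected_lists(self) -> list[tuple[FeatureDescriptor, ...]]:
        """Per-model selected feature descriptors (input to occurrence histograms)."""
        return [tuple(self.descriptors[i] for i in r.selected) for r in self.records]

    def summary(self) -> dict:
        return {
            "model_count": self.model_count,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "sem_accuracy": self.sem_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "n_balanced": self.n_balanced,
        }


# -- stage operations -------------------------------------------------------


def downsample_balance(
    labels: Sequence[str],
    n_folds: int,
    per_class_n: int | str = "auto",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Trial indices of a class-balanced random subsample.

    Both classes are sampled without replacement down to the same count,
    ``floor(min_class / n_folds) * n_folds`` when ``per_class_n='auto'`` so
    the balanced set divides evenly into folds.  E.g. 67 face / 193 no-face
    trials under sixfold CV give 66 per class.
    """
    labels = np.asarray(labels, dtype=object)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx_by_class = {c: np.flatnonzero(labels == c) for c in CLASSES}
    sizes = {c: len(v) for c, v in idx_by_class.items()}
    if min(sizes.values()) == 0:
        raise ValueError("both classes must be non-empty")
    if per_class_n == "auto":
        n = (min(sizes.values()) // n_folds) * n_folds
    else:
        n = int(per_class_n)
    if n < n_folds:
        raise ValueError(
            f"minority class too small for {n_folds}-fold CV (per-class n = {n})"
        )
    if n > min(sizes.values()):
        raise ValueError("per_class_n exceeds the minority class size")
    chosen = [rng.choice(idx_by_class[c], size=n, replace=False) for c in CLASSES]
    return np.sort(np.concatenate(chosen))


def ttest_rank(matrix: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """Two-sided pooled-variance two-sample t-test p-value per feature.

    Uncorrected p-values (the ranking is a filter, not an inference).  A
    feature with zero pooled variance gets p = 1 when the class means agree
    and p = 0 when they differ (logged).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    a = matrix[labels == FACE]
    b = matrix[labels == NOFACE]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two samples per class for the t-test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 0/0 on zero-variance columns, fixed below
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=True)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        same = np.isclose(a.mean(axis=0), b.mean(axis=0))
        p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
        logger.info("zero pooled variance on %d features", int(degenerate.sum()))
    return np.asarray(p, dtype=np.float64)


def select_by_threshold(p_values: np.ndarray, p_threshold: float) -> np.ndarray:
    """Indices of features with p strictly below the threshold (sorted)."""
    p_values = np.asarray(p_values, dtype=np.float64)
    return np.flatnonzero(p_values < p_threshold)


def normalize01(
    train: np.ndarray, *others: np.ndarray
) -> tuple[np.ndarray, ...]:
    """Per-feature min-max scaling fitted on the training matrix only.

    Training values map onto [0, 1] exactly; other matrices are scaled with
    the training parameters and clipped into [0, 1].  A constant training
    feature maps everything to 0.5.
    """
    train = np.asarray(train, dtype=np.float64)
    if train.size == 0:
        raise ValueError("training matrix is empty")
    lo = train.min(axis=0)
    hi = train.max(axis=0)
    span = hi - lo
    constant = span == 0
    span = np.where(constant, 1.0, span)

    def _apply(m: np.ndarray) -> np.ndarray:
        scaled = (np.asarray(m, dtype=np.float64) - lo) / span
        scaled = np.clip(scaled, 0.0, 1.0)
        scaled[:, constant] = 0.5
        return scaled

    return tuple(_apply(m) for m in (train, *others))


# -- the ANN classifier -----------------------------------------------------


class _TwoLayerNet:
    """input -> n_hidden tanh units -> 2 linear outputs, MSE on one-hot targets."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, 2
        self.shapes = [
            (n_in, n_hidden), (n_hidden,), (n_hidden, self.n_out), (self.n_out,)
        ]
        w1 = rng.standard_normal((n_in, n_hidden)) / np.sqrt(max(n_in, 1))
        b1 = np.zeros(n_hidden)
        w2 = rng.standard_normal((n_hidden, self.n_out)) / np.sqrt(n_hidden)
        b2 = np.zeros(self.n_out)
        self.w = self._pack([w1, b1, w2, b2])

    def _pack(self, parts: list[np.ndarray]) -> np.ndarray:
        return np.concatenate([p.ravel() for p in parts])

    def _unpack(self, w: np.ndarray) -> list[np.ndarray]:
        parts, k = [], 0
        for shape in self.shapes:
            size = int(np.prod(shape))
            parts.append(w[k : k + size].reshape(shape))
            k += size
        return parts

    def forward(self, w: np.ndarray, x: np.ndarray) -> np.ndarray:
        w1, b1, w2, b2 = self._unpack(w)
        h = np.tanh(x @ w1 + b1)
        return h @ w2 + b2

    def loss(self, w: np.ndarray, x: np.ndarray, t: np.ndarray) -> float:
        y = self.forward(w, x)
        return float(np.mean((y - t) ** 2))

    def loss_grad(
        self, w: np.ndarray, x: np.ndarray, t: np.ndarray
    ) -> tuple[float, np.ndarray]:
        w1, b1, w2, b2 = self._unpack(w)
        h = np.tanh(x @ w1 + b1)
        y = h @ w2 + b2
        err = y - t
        loss = float(np.mean(err**2))
        dy = 2.0 * err / err.size
        gw2 = h.T @ dy
        gb2 = dy.sum(axis=0)
        dh = (dy @ w2.T) * (1.0 - h**2)
        gw1 = x.T @ dh
        gb1 = dh.sum(axis=0)
        return loss, self._pack([gw1, gb1, gw2, gb2])


def _scg_train(
    net: _TwoLayerNet,
    x: np.ndarray,
    t: np.ndarray,
    *,
    max_epochs: int,
    goal_mse: float,
    on_epoch: Callable[[np.ndarray], bool],
) -> None:
    """Scaled conjugate gradient minimization of the training MSE.

    Moller's SCG: a conjugate-direction method whose step size comes from a
    scaled one-dimensional quadratic approximation instead of a line search,
    with a Levenberg-Marquardt style lambda keeping the local Hessian
    estimate positive definite.  ``on_epoch`` is called after every accepted
    weight update and may stop training (early stopping hook).
    """
    w = net.w
    n_params = w.size
    sigma0, lam, lam_bar = 5e-5, 5e-7, 0.0
    loss, grad = net.loss_grad(w, x, t)
    r = -grad
    p = r.copy()
    success = True
    norm_p2 = float(p @ p)
    delta = 0.0
    for k in range(1, max_epochs + 1):
        if success:
            norm_p2 = float(p @ p)
            if norm_p2 <= 1e-30:
                break
            sigma = sigma0 / np.sqrt(norm_p2)
            _, grad_sigma = net.loss_grad(w + sigma * p, x, t)
            s = (grad_sigma - grad) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * norm_p2
        if delta <= 0:  # make the Hessian estimate positive definite
            lam_bar = 2.0 * (lam - delta / norm_p2)
            delta = -delta + lam * norm_p2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        loss_new = net.loss(w + alpha * p, x, t)
        comparison = 2.0 * delta * (loss - loss_new) / mu**2
        if comparison >= 0:  # accepted step
            w = w + alpha * p
            loss, grad = net.loss_grad(w, x, t)
            r_new = -grad
            lam_bar, success = 0.0, True
            if k % n_params == 0:  # periodic restart in the gradient direction
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-20)
            net.w = w
            if on_epoch(w) or loss <= goal_mse or float(r @ r) < 1e-24:
                break
        else:
            lam_bar, success = lam, False
        if comparison < 0.25:
            lam += delta * (1.0 - comparison) / norm_p2
        lam = min(lam, 1e20)
    net.w = w


class ANNClassifier:
    """Trained two-layer network; predicts the argmax output class."""

    classes_ = (FACE, NOFACE)

    def __init__(self, net: _TwoLayerNet, weights: np.ndarray):
        self._net = net
        self._weights = weights

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        return self._net.forward(self._weights, np.asarray(x, dtype=np.float64))

    def predict(self, x: np.ndarray) -> np.ndarray:
        scores = self.decision_values(x)
        return np.array([self.classes_[i] for i in scores.argmax(axis=1)], dtype=object)


def _one_hot(labels: np.ndarray) -> np.ndarray:
    t = np.zeros((len(labels), 2))
    t[np.asarray(labels, dtype=object) == FACE, 0] = 1.0
    t[np.asarray(labels, dtype=object) == NOFACE, 1] = 1.0
    return t


def train_ann(
    train: tuple[np.ndarray, np.ndarray],
    validation: tuple[np.ndarray, np.ndarray],
    config: DecodingConfig,
    seed: int | np.random.Generator = 0,
) -> ANNClassifier:
    """Train the network with early stopping on the validation set.

    Training stops at ``config.max_epochs``, when training MSE reaches
    ``config.goal_mse``, or when validation MSE has not improved for
    ``config.patience`` consecutive epochs; the weights at the validation
    minimum are returned.  Weight initialization is seeded.
    """
    x_train, y_train = train
    x_val, y_val = validation
    x_train = np.asarray(x_train, dtype=np.float64)
    x_val = np.asarray(x_val, dtype=np.float64)
    if not (np.isfinite(x_train).all() and np.isfinite(x_val).all()):
        raise ValueError("non-finite values in classifier inputs")
    for name, y in (("training", y_train), ("validation", y_val)):
        present = set(np.asarray(y, dtype=object))
        if set(CLASSES) - present:
            raise ValueError(f"{name} set lacks a class: only {sorted(present)} present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    net = _TwoLayerNet(x_train.shape[1], config.n_hidden, rng)
    t_train = _one_hot(np.asarray(y_train, dtype=object))
    t_val = _one_hot(np.asarray(y_val, dtype=object))

    state = {
        "best_err": net.loss(net.w, x_val, t_val),
        "best_w": net.w.copy(),
        "fails": 0,
    }

    def on_epoch(w: np.ndarray) -> bool:
        err = net.loss(w, x_val, t_val)
        if err < state["best_err"]:
            state["best_err"] = err
            state["best_w"] = w.copy()
            state["fails"] = 0
        else:
            state["fails"] += 1
        return state["fails"] >= config.patience

    _scg_train(
        net, x_train, t_train,
        max_epochs=config.max_epochs, goal_mse=config.goal_mse, on_epoch=on_epoch,
    )
    return ANNClassifier(net, state["best_w"])


# -- evaluation -------------------------------------------------------------


def evaluate(predictions: Sequence[str], truth: Sequence[str]) -> Metrics:
    """Accuracy, sensitivity (face hit rate) and specificity, in percent.

    Sensitivity is the fraction of *face* trials classified as face;
    specificity the fraction of *no-face* trials classified as no-face.  A
    rate whose class is absent from ``truth`` is reported as NaN.
    """
    predictions = np.asarray(predictions, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth differ in length")
    correct = predictions == truth
    accuracy = 100.0 * correct.mean()
    face = truth == FACE
    noface = truth == NOFACE
    sensitivity = 100.0 * correct[face].mean() if face.any() else float("nan")
    specificity = 100.0 * correct[noface].mean() if noface.any() else float("nan")
    return Metrics(float(accuracy), float(sensitivity), float(specificity))


def empirical_chance(n_eval: int, alpha: float = 0.05, p0: float = 0.5) -> float:
    """Exact-binomial empirical chance accuracy, in percent.

    The smallest accuracy ``k / n_eval`` such that a random guesser
    (``Binomial(n_eval, p0)``) exceeds ``k`` correct with probability below
    ``alpha``; accuracies above this level are significant at ``alpha``.
    """
    if n_eval < 1:
        raise ValueError("n_eval must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    k = int(stats.binom.isf(alpha, n_eval, p0))
    # isf gives the smallest k with P(X > k) <= alpha; enforce strict < alpha
    while stats.binom.sf(k, n_eval, p0) >= alpha:
        k += 1
    while k > 0 and stats.binom.sf(k - 1, n_eval, p0) < alpha:
        k -= 1
    return 100.0 * k / n_eval


def pam_aggregate(results: Sequence["CVRunResult | float"]) -> dict:
    """Personalized-average-model summary across subjects.

    Unweighted mean and standard deviation (ddof = 1; zero for one subject)
    of the subject-level mean accuracies, plus mean sensitivity/specificity
    when full run results are given.
    """
    if len(results) == 0:
        raise ValueError("need at least one subject")

    def _acc(r):
        return r.mean_accuracy if isinstance(r, CVRunResult) else float(r)

    accs = np.array([_acc(r) for r in results])
    out = {
        "n_subjects": len(results),
        "accuracy_mean": float(accs.mean()),
        "accuracy_sd": float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
    }
    if all(isinstance(r, CVRunResult) for r in results):
        sens = np.array([r.mean_sensitivity for r in results])
        spec = np.array([r.mean_specificity for r in results])
        out["sensitivity_mean"] = float(np.nanmean(sens))
        out["specificity_mean"] = float(np.nanmean(spec))
    return out


# -- the nested CV loop -----------------------------------------------------


def _derive_int_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def nested_cv_run(
    f: FeatureSet,
    config: DecodingConfig,
    audit: Callable[[int, int, np.ndarray, np.ndarray, np.ndarray], None] | None = None,
) -> CVRunResult:
    """Run the full balanced repeated nested CV on a feature set.

    Per repetition: a fresh seeded class-balanced subsample and a stratified
    ``n_folds`` split.  Per fold: the held-out fold is the test set; the
    remaining trials are split (stratified) into training and validation;
    t-test ranking, threshold selection, min-max normalization and network
    training are all fitted on the training set only (validation drives early
    stopping); the model is then scored on the untouched test fold.

    ``audit``, if given, receives ``(rep, fold, train_idx, val_idx, test_idx)``
    in original trial indices after each fold is formed - a structural hook to
    verify fold coverage and the absence of information leakage.

    If no feature passes the threshold, the 10 smallest-p features are used
    instead (logged loudly); a fold with an empty selection even then is
    skipped with a warning and excluded from the aggregates.
    """
    labels = f.labels
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = ss.spawn(config.n_reps)
    records: list[FoldRecord] = []
    n_balanced = 0
    for rep, rep_ss in enumerate(rep_seeds):
        balance_ss, fold_ss, split_ss, init_ss = rep_ss.spawn(4)
        idx = downsample_balance(
            labels, config.n_folds, config.per_class_n,
            np.random.default_rng(balance_ss),
        )
        n_balanced = len(idx)
        y = labels[idx]
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True,
            random_state=_derive_int_seed(fold_ss),
        )
        for fold, (rest, test) in enumerate(skf.split(np.zeros(len(idx)), y.astype(str))):
            train, val = train_test_split(
                rest,
                test_size=config.val_fraction,
                stratify=y[rest].astype(str),
                random_state=_derive_int_seed(split_ss.spawn(1)[0]),
            )
            if audit is not None:
                audit(rep, fold, idx[train], idx[val], idx[test])
            x_train = f.matrix[idx[train]]
            p = ttest_rank(x_train, y[train])
            selected = select_by_threshold(p, config.p_threshold)
            if selected.size == 0:
                selected = np.argsort(p, kind="stable")[:10]
                logger.warning(
                    "rep %d fold %d: no feature below p<%g; falling back to the "
                    "10 smallest-p features", rep, fold, config.p_threshold,
                )
            if selected.size == 0:
                warnings.warn(
                    f"rep {rep} fold {fold}: empty feature selection, fold skipped"
                )
                continue
            x_tr, x_va, x_te = normalize01(
                x_train[:, selected],
                f.matrix[idx[val]][:, selected],
                f.matrix[idx[test]][:, selected],
            )
            model = train_ann(
                (x_tr, y[train]), (x_va, y[val]), config,
                np.random.default_rng(init_ss.spawn(1)[0]),
            )
            m = evaluate(model.predict(x_te), y[test])
            records.append(
                FoldRecord(
                    rep=rep, fold=fold,
                    accuracy=m.accuracy, sensitivity=m.sensitivity,
                    specificity=m.specificity, n_test=len(test),
                    selected=tuple(int(i) for i in selected),
                )
            )
    return CVRunResult(
        records=tuple(records),
        descriptors=f.descriptors,
        config=config,
        n_balanced=n_balanced,
    )
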