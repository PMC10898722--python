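"""Confound-controlled classification of wind pleasantness.

The protocol mirrors the study design end to end:

* trials are labelled pleasant (score > 5.0) / unpleasant (score < 5.0);
  score exactly 5.0 is excluded; a participant with fewer than 30 trials in
  either class is excluded;
* leave-one-velocity-out folds: the classifier is trained on three of the
  four wind velocities and tested on the held-out one, so the test velocity
  never occurs in training and velocity identity cannot drive the accuracy;
  a fold is skipped when either class has fewer than 30 trials in the
  original (pre-undersampling) training data;
* the majority class is randomly undersampled to balance training; the
  procedure is repeated five times with distinct discarded subsets whenever
  the surplus permits;
* features are z-scored with the undersampled training statistics only;
* hyperparameters are tuned per fit by seeded random search with a
  stratified 80/20 validation split of the undersampled training data;
* four classifier families: L2 logistic regression, linear-kernel SVM,
  RBF-kernel SVM, and a one-hidden-layer neural network (ReLU hidden layer,
  sigmoid output, binary cross-entropy, AdamW optimizer).

Per participant, accuracy is averaged over feasible folds and then over the
five repetitions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .exceptions import InvalidParameterError, NumericalError
from .features import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

FAMILIES = ("logreg", "svm_linear", "svm_rbf", "ann")

PLEASANT, UNPLEASANT = 1, 0
NEUTRAL_SCORE = 5.0
MIN_TRIALS_PER_CLASS = 30


@dataclass
class LabeledTrialSet:
    """Feature matrix with binary pleasantness labels and velocity conditions."""

    features: np.ndarray          # (n_trials, n_features)
    labels: np.ndarray            # (n_trials,) 1 = pleasant, 0 = unpleasant
    velocities: np.ndarray        # (n_trials,)
    scores: np.ndarray            # (n_trials,)
    feature_names: tuple[str, ...]

    @property
    def n_trials(self) -> int:
        return len(self.labels)

    def class_counts(self) -> tuple[int, int]:
        """(unpleasant, pleasant) trial counts."""
        return int((self.labels == UNPLEASANT).sum()), int((self.labels == PLEASANT).sum())

    def drop_features(self, names: tuple[str, ...]) -> "LabeledTrialSet":
        keep = [i for i, n in enumerate(self.feature_names) if n not in names]
        if len(keep) == len(self.feature_names):
            raise InvalidParameterError(f"no such feature(s): {names}")
        return LabeledTrialSet(
            features=self.features[:, keep],
            labels=self.labels,
            velocities=self.velocities,
            scores=self.scores,
            feature_names=tuple(self.feature_names[i] for i in keep),
        )


@dataclass
class FoldSpec:
    """One leave-one-velocity-out fold."""

    test_velocity: float
    train_velocities: tuple[float, ...]
    feasible: bool
    reason: str = ""


@dataclass
class ClassifierSpec:
    """A classifier family with (possibly tuned) hyperparameters."""

    family: str
    params: dict
    seed: int = 0


@dataclass
class ProtocolResult:
    """All accuracies of one participant's protocol run.

    ``accuracies[family]`` is (n_repetitions, n_folds) with NaN for skipped
    folds; ``per_family_mean`` averages feasible folds within repetition and
    then repetitions.
    """

    accuracies: dict[str, np.ndarray]
    fold_velocities: tuple[float, ...]
    per_family_mean: dict[str, float]
    skipped_folds: list[dict] = field(default_factory=list)
    tuned_params: dict = field(default_factory=dict)
    seed: int = 0
    n_repetitions: int = 5


def label_and_filter(
    feature_table: pd.DataFrame, min_per_class: int = MIN_TRIALS_PER_CLASS
) -> tuple[LabeledTrialSet, bool]:
    """Assign labels, drop neutral reports, and apply the inclusion rule.

    Returns the labelled set and a flag: False when either class has fewer
    than ``min_per_class`` trials (the participant is excluded from group
    analysis, mirroring the study's exclusion of two participants).
    """
    scores = feature_table["score"].to_numpy(float)
    if np.any((scores < 1.0) | (scores > 9.0)):
        raise InvalidParameterError("scores outside the 1.0-9.0 scale")
    keep = ~np.isclose(scores, NEUTRAL_SCORE)
    table = feature_table.loc[keep]
    scores = scores[keep]
    labels = np.where(scores > NEUTRAL_SCORE, PLEASANT, UNPLEASANT)

    labeled = LabeledTrialSet(
        features=table[list(FEATURE_COLUMNS)].to_numpy(float),
        labels=labels,
        velocities=table["velocity"].to_numpy(float),
        scores=scores,
        feature_names=FEATURE_COLUMNS,
    )
    n_unpl, n_pl = labeled.class_counts()
    included = n_unpl >= min_per_class and n_pl >= min_per_class
    if not included:
        logger.info(
            "participant excluded: class counts (unpleasant=%d, pleasant=%d) < %d",
            n_unpl, n_pl, min_per_class,
        )
    return labeled, included


def make_velocity_folds(
    labeled: LabeledTrialSet, min_per_class: int = MIN_TRIALS_PER_CLASS
) -> list[FoldSpec]:
    """One fold per velocity as test set; infeasible folds are marked, not run."""
    velocities = tuple(sorted(float(v) for v in set(labeled.velocities)))
    if len(velocities) < 4:
        raise InvalidParameterError(
            f"expected all four velocity conditions, found {velocities}"
        )
    folds = []
    for v in velocities:
        train_mask = labeled.velocities != v
        y = labeled.labels[train_mask]
        n_unpl = int((y == UNPLEASANT).sum())
        n_pl = int((y == PLEASANT).sum())
        feasible = n_unpl >= min_per_class and n_pl >= min_per_class
        reason = (
            ""
            if feasible
            else f"training class counts (unpleasant={n_unpl}, pleasant={n_pl}) < {min_per_class}"
        )
        folds.append(FoldSpec(
            test_velocity=v,
            train_velocities=tuple(w for w in velocities if w != v),
            feasible=feasible,
            reason=reason,
        ))
    return folds


def undersample_training(
    train_indices: np.ndarray,
    labels: np.ndarray,
    rng: np.random.Generator,
    used_discards: set[frozenset] | None = None,
    max_tries: int = 50,
) -> np.ndarray:
    """Balance classes by randomly discarding majority-class trials.

    When ``used_discards`` is given, the draw is retried until the discarded
    subset differs from all previous ones (so no training set is reused
    across repetitions); if the surplus does not permit a fresh subset, a
    fresh random draw is used with a warning.
    """
    train_indices = np.asarray(train_indices)
    y = labels[train_indices]
    n_unpl, n_pl = int((y == UNPLEASANT).sum()), int((y == PLEASANT).sum())
    if n_unpl == 0 or n_pl == 0:
        raise InvalidParameterError("both classes must be present for undersampling")
    if n_unpl == n_pl:
        return train_indices
    minority = UNPLEASANT if n_unpl < n_pl else PLEASANT
    n_min = min(n_unpl, n_pl)
    majority_idx = train_indices[y != minority]
    minority_idx = train_indices[y == minority]

    discard = None
    for attempt in range(max_tries):
        kept = rng.choice(majority_idx, size=n_min, replace=False)
        candidate = frozenset(np.setdiff1d(majority_idx, kept))
        if used_discards is None or candidate not in used_discards:
            discard = candidate
            break
    if discard is None:
        logger.warning(
            "could not find an unused undersampling subset in %d tries; "
            "falling back to a fresh random draw", max_tries,
        )
        kept = rng.choice(majority_idx, size=n_min, replace=False)
        discard = frozenset(np.setdiff1d(majority_idx, kept))
    if used_discards is not None:
        used_discards.add(discard)
    out = np.concatenate([minority_idx, np.setdiff1d(majority_idx, list(discard))])
    return np.sort(out)


def normalize_features(
    train: np.ndarray,
    test: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """z-score both partitions with the training mean/sd (no test statistics)."""
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        name = feature_names[zero[0]] if feature_names else f"column {zero[0]}"
        raise NumericalError(f"zero-variance training feature: {name}")
    return (train - mean) / sd, (test - mean) / sd


class AnnClassifier:
    """One-hidden-layer binary classifier trained with AdamW.

    ReLU hidden layer, sigmoid output unit, binary cross-entropy loss,
    minibatch AdamW with decoupled weight decay (decay applied to weights
    only, not biases).
    """

    def __init__(
        self,
        hidden_units: int = 16,
        batch_size: int = 16,
        learning_rate: float = 1e-2,
        weight_decay: float = 1e-4,
        epochs: int = 100,
        seed: int = 0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.hidden_units = int(hidden_units)
        self.batch_size = int(batch_size)
        self.learning_rate = float(learning_rate)
        self.weight_decay = float(weight_decay)
        self.epochs = int(epochs)
        self.seed = int(seed)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def fit(self, x: np.ndarray, y: np.ndarray) -> "AnnClassifier":
        x = np.asarray(x, np.float64)
        y = np.asarray(y, np.float64)
        rng = np.random.default_rng(self.seed)
        n, d = x.shape
        h = self.hidden_units
        # He initialisation for the ReLU layer, Glorot-ish for the output
        params = [
            rng.standard_normal((d, h)) * np.sqrt(2.0 / d),  # W1
            np.zeros(h),                                     # b1
            rng.standard_normal((h, 1)) * np.sqrt(1.0 / h),  # W2
            np.zeros(1),                                     # b2
        ]
        is_weight = [True, False, True, False]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = x[idx], y[idx]
                w1, b1, w2, b2 = params
                z1 = xb @ w1 + b1
                a1 = np.maximum(z1, 0.0)
                logits = (a1 @ w2 + b2).ravel()
                p = 1.0 / (1.0 + np.exp(-logits))
                # dBCE/dlogit = p - y
                delta = (p - yb)[:, None] / len(idx)
                grads = [
                    xb.T @ (((delta @ w2.T) * (z1 > 0.0))),
                    (((delta @ w2.T) * (z1 > 0.0))).sum(axis=0),
                    a1.T @ delta,
                    delta.sum(axis=0),
                ]
                t += 1
                lr = self.learning_rate
                for k, g in enumerate(grads):
                    m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                    v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                    m_hat = m[k] / (1 - self.beta1**t)
                    v_hat = v[k] / (1 - self.beta2**t)
                    params[k] = params[k] - lr * m_hat / (np.sqrt(v_hat) + self.eps)
                    if is_weight[k]:
                        params[k] = params[k] - lr * self.weight_decay * params[k]
        self._params = params
        return self

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        w1, b1, w2, b2 = self._params
        a1 = np.maximum(np.asarray(x, np.float64) @ w1 + b1, 0.0)
        return (a1 @ w2 + b2).ravel()

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(x)))
        return np.column_stack([1.0 - p, p])

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.decision_function(x) > 0.0).astype(int)

    def score(self, x: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(x) == np.asarray(y)).mean())


def sample_config(family: str, rng: np.random.Generator) -> dict:
    """Draw one hyperparameter configuration from the family's search space."""
    def log_uniform(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    if family == "logreg":
        return {"C": log_uniform(1e-3, 1e3)}
    if family == "svm_linear":
        return {"C": log_uniform(1e-3, 1e3)}
    if family == "svm_rbf":
        return {"C": log_uniform(1e-3, 1e3), "gamma": log_uniform(1e-3, 1e3)}
    if family == "ann":
        return {
            "hidden_units": int(rng.integers(4, 65)),
            "batch_size": int(rng.choice([8, 16, 32])),
            "learning_rate": log_uniform(1e-4, 1e-1),
            "weight_decay": log_uniform(1e-6, 1e-2),
            "epochs": int(rng.integers(10, 201)),
        }
    raise InvalidParameterError(f"unknown classifier family {family!r}")


def build_estimator(spec: ClassifierSpec):
    """Instantiate the model behind a spec (sklearn for all but the ANN)."""
    if spec.family == "logreg":
        # L2 penalty (the default) with strength 1/C
        return LogisticRegression(C=spec.params["C"], solver="lbfgs", max_iter=1000)
    if spec.family == "svm_linear":
        return SVC(kernel="linear", C=spec.params["C"])
    if spec.family == "svm_rbf":
        return SVC(kernel="rbf", C=spec.params["C"], gamma=spec.params["gamma"])
    if spec.family == "ann":
        return AnnClassifier(seed=spec.seed, **spec.params)
    raise InvalidParameterError(f"unknown classifier family {spec.family!r}")


def tune_hyperparameters(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    family: str,
    budget: int = 50,
    rng: np.random.Generator | None = None,
) -> ClassifierSpec:
    """Seeded random search maximising accuracy on a stratified 20% validation split."""
    if budget < 1:
        raise InvalidParameterError("tuning budget must be >= 1")
    if len(train_labels) < 10:
        raise InvalidParameterError("need at least 10 training trials for tuning")
    if rng is None:
        rng = np.random.default_rng(0)
    split_seed = int(rng.integers(2**31 - 1))
    x_fit, x_val, y_fit, y_val = train_test_split(
        train_features,
        train_labels,
        test_size=0.2,
        stratify=train_labels,
        random_state=split_seed,
    )
    best_spec, best_acc = None, -np.inf
    for _ in range(budget):
        params = sample_config(family, rng)
        spec = ClassifierSpec(family=family, params=params,
                              seed=int(rng.integers(2**31 - 1)))
        model = build_estimator(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(x_fit, y_fit)
        acc = float((model.predict(x_val) == y_val).mean())
        if acc > best_acc:
            best_spec, best_acc = spec, acc
    return best_spec


def train_and_test(
    spec: ClassifierSpec,
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    test_labels: np.ndarray,
) -> float:
    """Fit the tuned model on the full training partition; return test accuracy."""
    model = build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(train_features, train_labels)
    return float((model.predict(test_features) == test_labels).mean())


def run_protocol(
    labeled: LabeledTrialSet,
    families: tuple[str, ...] = FAMILIES,
    n_repetitions: int = 5,
    seed: int = 0,
    tuning_budget: int = 50,
    min_per_class: int = MIN_TRIALS_PER_CLASS,
) -> ProtocolResult:
    """Execute the full repeated leave-one-velocity-out protocol.

    For every repetition x feasible fold: undersample (shared across
    families), normalise with training statistics, then per family tune,
    fit and test. Seeds are derived deterministically from ``seed`` per
    (repetition, fold, family), so identical seeds give identical results.
    """
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise InvalidParameterError(f"unknown families: {sorted(unknown)}")
    folds = make_velocity_folds(labeled, min_per_class)
    n_folds = len(folds)
    accuracies = {f: np.full((n_repetitions, n_folds), np.nan) for f in families}
    skipped: list[dict] = []
    tuned: dict = {}
    used_discards: dict[int, set[frozenset]] = {i: set() for i in range(n_folds)}

    all_idx = np.arange(labeled.n_trials)
    for rep in range(n_repetitions):
        for fi, fold in enumerate(folds):
            if not fold.feasible:
                if rep == 0:
                    skipped.append(
                        {"test_velocity": fold.test_velocity, "reason": fold.reason}
                    )
                continue
            test_mask = labeled.velocities == fold.test_velocity
            train_idx = all_idx[~test_mask]
            test_idx = all_idx[test_mask]
            # leakage guard: velocity conditions must not overlap
            assert not set(labeled.velocities[train_idx]) & {fold.test_velocity}

            rng_us = np.random.default_rng(
                np.random.SeedSequence([seed, 0, rep, fi])
            )
            balanced = undersample_training(
                train_idx, labeled.labels, rng_us, used_discards[fi]
            )
            y_tr = labeled.labels[balanced]
            x_tr, x_te = normalize_features(
                labeled.features[balanced],
                labeled.features[test_idx],
                labeled.feature_names,
            )
            y_te = labeled.labels[test_idx]
            for gi, family in enumerate(families):
                rng_f = np.random.default_rng(
                    np.random.SeedSequence([seed, 1, rep, fi, gi])
                )
                spec = tune_hyperparameters(
                    x_tr, y_tr, family, budget=tuning_budget, rng=rng_f
                )
                accuracies[family][rep, fi] = train_and_test(
                    spec, x_tr, y_tr, x_te, y_te
                )
                tuned[(rep, fold.test_velocity, family)] = spec.params

    per_family_mean = {}
    for family in families:
        a = accuracies[family]
        if np.all(np.isnan(a)):
            per_family_mean[family] = np.nan
        else:
            per_family_mean[family] = float(np.nanmean(a, axis=1).mean())
    return ProtocolResult(
        accuracies=accuracies,
        fold_velocities=tuple(f.test_velocity for f in folds),
        per_family_mean=per_family_mean,
        skipped_folds=skipped,
        tuned_params=tuned,
        seed=seed,
        n_repetitions=n_repetitions,
    )
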