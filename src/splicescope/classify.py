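"""Self-labeled SVM classification of junction candidates.

Labels are obtained without any reference annotation:

* *training set* — positives are candidates with a shorter overhang > 20 nt
  AND offset entropy > 20; negatives have coverage skew < -1 OR shorter
  overhang <= 2 nt.  Up to 10 000 examples, equally split, are sampled.
* *development set* — candidates labeled by exact match to the introns of
  the ab initio gene predictions, disjoint from the training set.

An RBF-kernel SVM is fitted on the training set for every (ln c, ln gamma)
point of a lattice (default {-9..3} x {-9..3}); the point maximizing
W = TP - FP on the development set wins.  Decision values from a 5-fold
cross-validation on the training set calibrate a Platt sigmoid
``s = k / (1 + exp(A f + B))`` mapping decision values to posterior
probabilities; candidates with ``s > S`` (default S = 0.5) form the final
junction set.  The three selection features never enter the classifier's
input vector.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import CLASSIFIER_FEATURES, JunctionCandidate, JunctionFeatures

logger = logging.getLogger(__name__)

DEFAULT_LATTICE = tuple(range(-9, 4))


@dataclass
class LabeledExample:
    key: tuple            # junction key
    x: np.ndarray         # the six classifier features
    y: int                # 1 true / 0 false
    origin: str           # "train" or "dev"


@dataclass
class SvmConfig:
    c: float
    gamma: float


@dataclass
class PlattModel:
    A: float
    B: float
    k: float = 1.0
    cv_folds: int = 5

    def posterior(self, f: np.ndarray | float) -> np.ndarray | float:
        """Posterior probability of the true-junction class for decision
        value(s) f; clipped into [0, 1]."""
        z = self.A * np.asarray(f, dtype=float) + self.B
        s = self.k / (1.0 + np.exp(z))
        return np.clip(s, 0.0, 1.0)


@dataclass
class ClassifierModel:
    svm: SVC | None
    config: SvmConfig
    platt: PlattModel
    mean: np.ndarray      # training-set standardization
    scale: np.ndarray
    feature_names: tuple[str, ...] = CLASSIFIER_FEATURES

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.mean) / self.scale
        if self.svm is not None:
            return self.svm.decision_function(Xs)
        # explicit RBF expansion from the stored support data
        sv = self._support_vectors
        d2 = ((Xs[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-self.config.gamma * d2)
        return K @ self._dual_coef + self._intercept

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.platt.posterior(self.decision_values(X)))


def save_model(model: ClassifierModel, path) -> None:
    """Portable text (JSON) dump of the fitted classifier: support vectors
    and dual coefficients of the SVM, its (c, gamma), the Platt constants
    (A, B, k) and the feature standardization."""
    import json

    svm = model.svm
    if svm is None:
        raise ValueError("only a freshly fitted model can be saved")
    payload = {
        "feature_names": list(model.feature_names),
        "c": model.config.c,
        "gamma": model.config.gamma,
        "platt": {"A": model.platt.A, "B": model.platt.B,
                  "k": model.platt.k, "cv_folds": model.platt.cv_folds},
        "mean": model.mean.tolist(),
        "scale": model.scale.tolist(),
        "support_vectors": svm.support_vectors_.tolist(),
        "dual_coef": svm.dual_coef_[0].tolist(),
        "intercept": float(svm.intercept_[0]),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> ClassifierModel:
    """Inverse of :func:`save_model`; the loaded model scores through the
    stored support data (no refit)."""
    import json

    with open(path) as fh:
        p = json.load(fh)
    platt = PlattModel(A=p["platt"]["A"], B=p["platt"]["B"],
                       k=p["platt"]["k"], cv_folds=p["platt"]["cv_folds"])
    model = ClassifierModel(
        svm=None, config=SvmConfig(p["c"], p["gamma"]), platt=platt,
        mean=np.array(p["mean"]), scale=np.array(p["scale"]),
        feature_names=tuple(p["feature_names"]),
    )
    model._support_vectors = np.array(p["support_vectors"])
    model._dual_coef = np.array(p["dual_coef"])
    model._intercept = p["intercept"]
    return model


@dataclass
class ScoredJunction:
    candidate: JunctionCandidate
    features: JunctionFeatures
    decision_value: float
    score: float


# ---------------------------------------------------------------------------
# self-labeled set construction

POSITIVE_MIN_OVERHANG = 20   # strict: must exceed
POSITIVE_MIN_ENTROPY = 20.0  # strict: must exceed
NEGATIVE_MAX_SKEW = -1.0     # strict: must be below
NEGATIVE_MAX_OVERHANG = 2    # inclusive


def positive_rule(f: JunctionFeatures) -> bool:
    return f.min_overhang > POSITIVE_MIN_OVERHANG and f.entropy > POSITIVE_MIN_ENTROPY


def negative_rule(f: JunctionFeatures) -> bool:
    return f.skew < NEGATIVE_MAX_SKEW or f.min_overhang <= NEGATIVE_MAX_OVERHANG


def _sample(keys: list, n: int, rng: np.random.Generator) -> list:
    if len(keys) <= n:
        return list(keys)
    idx = rng.choice(len(keys), size=n, replace=False)
    return [keys[i] for i in sorted(idx)]


def select_training_set(
    candidates: Sequence[tuple[JunctionCandidate, JunctionFeatures]],
    size: int = 10_000,
    seed: int = 0,
) -> list[LabeledExample]:
    """Heuristically self-labeled training examples, up to ``size`` total,
    equally divided between classes.  Candidates matching both rules are
    left out; classes short of size/2 are taken in full with a warning."""
    pos_pool, neg_pool = [], []
    for cand, feats in candidates:
        p, n = positive_rule(feats), negative_rule(feats)
        if p and not n:
            pos_pool.append((cand, feats))
        elif n and not p:
            neg_pool.append((cand, feats))
    if not pos_pool or not neg_pool:
        raise ValueError(
            f"cannot build a training set: {len(pos_pool)} positive and "
            f"{len(neg_pool)} negative candidates match the labeling rules"
        )
    rng = np.random.default_rng(seed)
    half = size // 2
    chosen_pos = _sample(pos_pool, half, rng)
    chosen_neg = _sample(neg_pool, half, rng)
    for name, pool, chosen in (("positive", pos_pool, chosen_pos),
                               ("negative", neg_pool, chosen_neg)):
        if len(chosen) < half:
            logger.warning(
                "only %d %s candidates eligible (wanted %d); taking all",
                len(pool), name, half,
            )
    out = [LabeledExample(c.key(), f.vector(), 1, "train") for c, f in chosen_pos]
    out += [LabeledExample(c.key(), f.vector(), 0, "train") for c, f in chosen_neg]
    return out


def select_development_set(
    candidates: Sequence[tuple[JunctionCandidate, JunctionFeatures]],
    predicted_introns: set[tuple[str, int, int, str]],
    train: Sequence[LabeledExample],
    size_per_class: int = 5_000,
    seed: int = 1,
) -> list[LabeledExample]:
    """Development examples labeled by exact match (sequence, boundaries and
    strand) to ab initio predicted introns; disjoint from the training set."""
    if not predicted_introns:
        raise ValueError("empty ab initio intron set")
    train_keys = {ex.key for ex in train}
    pos_pool, neg_pool = [], []
    for cand, feats in candidates:
        if cand.key() in train_keys:
            continue
        if cand.key() in predicted_introns:
            pos_pool.append((cand, feats))
        else:
            neg_pool.append((cand, feats))
    rng = np.random.default_rng(seed)
    chosen_pos = _sample(pos_pool, size_per_class, rng)
    chosen_neg = _sample(neg_pool, size_per_class, rng)
    for name, pool, chosen in (("positive", pos_pool, chosen_pos),
                               ("negative", neg_pool, chosen_neg)):
        if len(chosen) < size_per_class:
            logger.warning(
                "development set: only %d %s examples available (wanted %d)",
                len(pool), name, size_per_class,
            )
    out = [LabeledExample(c.key(), f.vector(), 1, "dev") for c, f in chosen_pos]
    out += [LabeledExample(c.key(), f.vector(), 0, "dev") for c, f in chosen_neg]
    return out


# ---------------------------------------------------------------------------
# grid search and calibration

def _stack(examples: Sequence[LabeledExample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([ex.x for ex in examples])
    y = np.array([ex.y for ex in examples], dtype=int)
    return X, y


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def grid_search_svm(
    train: Sequence[LabeledExample],
    dev: Sequence[LabeledExample],
    lattice: Sequence[int] = DEFAULT_LATTICE,
) -> tuple[SvmConfig, np.ndarray]:
    """Fit an RBF-SVM at every (ln c, ln gamma) lattice point and score
    W = TP - FP on the development set.

    Returns the winning configuration (ties broken toward smaller gamma,
    then smaller c) and the full W map with shape (len(lattice),
    len(lattice)) indexed [i_ln_c, i_ln_gamma].
    """
    X_train, y_train = _stack(train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set has a single class")
    if not dev:
        raise ValueError("development set is empty")
    X_dev, y_dev = _stack(dev)
    mean, scale = _standardizer(X_train)
    Xt = (X_train - mean) / scale
    Xd = (X_dev - mean) / scale
    lattice = list(lattice)
    W = np.zeros((len(lattice), len(lattice)), dtype=int)
    best: tuple | None = None
    for i, ln_c in enumerate(lattice):
        for j, ln_g in enumerate(lattice):
            svm = SVC(C=math.exp(ln_c), gamma=math.exp(ln_g), kernel="rbf")
            svm.fit(Xt, y_train)
            pred = svm.predict(Xd)
            tp = int(np.sum((pred == 1) & (y_dev == 1)))
            fp = int(np.sum((pred == 1) & (y_dev == 0)))
            W[i, j] = tp - fp
            key = (-W[i, j], ln_g, ln_c)
            if best is None or key < best[0]:
                best = (key, SvmConfig(math.exp(ln_c), math.exp(ln_g)))
    assert best is not None
    return best[1], W


def fit_posterior(
    train: Sequence[LabeledExample],
    config: SvmConfig,
    cv_folds: int = 5,
    seed: int = 0,
    max_iter: int = 100,
) -> tuple[ClassifierModel, PlattModel]:
    """Fit the final SVM on the full training set and calibrate a Platt
    sigmoid on out-of-fold decision values from ``cv_folds``-fold CV.

    The sigmoid constants (A, B) maximize the likelihood of the training
    labels under Platt's smoothed targets, via Newton iterations with
    backtracking; k is 1 (standard Platt scaling).
    """
    X, y = _stack(train)
    mean, scale = _standardizer(X)
    Xs = (X - mean) / scale
    f = np.zeros(len(y))
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for tr_idx, te_idx in skf.split(Xs, y):
        svm = SVC(C=config.c, gamma=config.gamma, kernel="rbf")
        svm.fit(Xs[tr_idx], y[tr_idx])
        f[te_idx] = svm.decision_function(Xs[te_idx])
    A, B = _platt_fit(f, y, max_iter=max_iter)
    platt = PlattModel(A=A, B=B, k=1.0, cv_folds=cv_folds)
    final = SVC(C=config.c, gamma=config.gamma, kernel="rbf")
    final.fit(Xs, y)
    model = ClassifierModel(svm=final, config=config, platt=platt,
                            mean=mean, scale=scale)
    return model, platt


def _platt_fit(f: np.ndarray, y: np.ndarray, max_iter: int = 100) -> tuple[float, float]:
    """Platt's sigmoid fit: minimize the NLL of t against 1/(1+exp(A f + B))
    with the usual smoothed targets; Newton's method with backtracking."""
    n_pos = int(np.sum(y == 1))
    n_neg = len(y) - n_pos
    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(y == 1, hi, lo)
    A, B = 0.0, math.log((n_neg + 1.0) / (n_pos + 1.0))

    def nll(a: float, b: float) -> float:
        # p = 1/(1+exp(z)); NLL_i = log(1+exp(-z)) + t*z  (numerically stable)
        z = a * f + b
        return float(np.sum(np.logaddexp(0.0, -z) + t * z))

    current = nll(A, B)
    for _ in range(max_iter):
        z = A * f + B
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(z))
        # dNLL/dz = t - p
        g = t - p
        grad = np.array([np.sum(g * f), np.sum(g)])
        w = p * (1 - p)
        H = np.array([
            [np.sum(w * f * f), np.sum(w * f)],
            [np.sum(w * f), np.sum(w)],
        ]) + 1e-12 * np.eye(2)
        step = np.linalg.solve(H, grad)
        if not np.all(np.isfinite(step)):
            break
        lr = 1.0
        for _ in range(30):
            cand = nll(A - lr * step[0], B - lr * step[1])
            if cand < current + 1e-12:
                A -= lr * step[0]
                B -= lr * step[1]
                current = cand
                break
            lr *= 0.5
        else:
            break
        if np.linalg.norm(lr * step) < 1e-10:
            break
    return float(A), float(B)


# ---------------------------------------------------------------------------
# scoring and thresholding

def score_candidates(
    candidates: Sequence[tuple[JunctionCandidate, JunctionFeatures]],
    model: ClassifierModel,
) -> list[ScoredJunction]:
    if not candidates:
        return []
    X = np.stack([f.vector() for _, f in candidates])
    fvals = model.decision_values(X)
    svals = model.score(X)
    return [
        ScoredJunction(cand, feats, float(fv), float(sv))
        for (cand, feats), fv, sv in zip(candidates, fvals, svals)
    ]


def score_and_threshold(
    scored: Sequence[ScoredJunction], S: float = 0.5
) -> list[ScoredJunction]:
    """Final junction set: candidates with posterior score strictly above
    the threshold S."""
    return [sj for sj in scored if sj.score > S]
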