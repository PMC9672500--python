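"""Base-classifier ensembles over the code tree.

Two strategies from hierarchical text classification are supported:

* **per-node** — one binary one-vs-rest classifier per trainable code,
  scoring the probability that a query belongs to that code;
* **non-terminal** — one multiclass classifier per internal node, choosing
  among its trained children plus a residual "none of the children" class
  (n+1 classes for n children).

Base learners are pluggable behind a fit/predict_proba contract; bagged
trees (random forest), boosted stumps and a softmax feed-forward network
are provided, plus a fast logistic baseline used by the synthetic
benchmarks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .corpus import (MIN_POSITIVES_DEFAULT, NodeTrainingSet,
                     oversample_minority, select_trainable_nodes)
from .hierarchy import CodeHierarchy

__all__ = [
    "BaseLearnerSpec",
    "NodeClassifier",
    "NonTerminalClassifier",
    "EnsembleModel",
    "train_per_node",
    "train_non_terminal",
    "score",
    "RESIDUAL",
    "ROOT_CLASSIFIER",
]

logger = logging.getLogger(__name__)

#: Class label of the residual "none of the children" outcome.
RESIDUAL = "__residual__"
#: Key of the virtual-root multiclass classifier over chapter-level codes.
ROOT_CLASSIFIER = "__root__"

_FAMILIES = {
    "random_forest": lambda p, s: RandomForestClassifier(
        random_state=s, **{"n_estimators": 100, **p}),
    "adaboost": lambda p, s: AdaBoostClassifier(random_state=s, **p),
    "mlp": lambda p, s: MLPClassifier(
        random_state=s,
        **{"hidden_layer_sizes": (90, 60), "solver": "adam",
           "max_iter": 300, **p}),
    "logistic": lambda p, s: LogisticRegression(
        random_state=s, **{"max_iter": 1000, **p}),
}


@dataclass
class BaseLearnerSpec:
    """Pluggable base-learner family with pinned hyperparameters.

    ``family`` is one of ``random_forest``, ``adaboost``, ``mlp`` (two
    hidden layers 90-60 with adaptive-moment optimization by default) or
    ``logistic``.  Unspecified hyperparameters stay at library defaults.
    """

    family: str = "logistic"
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def make(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown base-learner family {self.family!r}; "
                             f"choose from {sorted(_FAMILIES)}")
        return _FAMILIES[self.family](dict(self.params), self.seed)


class _ConstantClassifier:
    """Fallback when a node's training set degenerates to one class."""

    def __init__(self, classes, probs):
        self.classes_ = np.asarray(classes)
        self._probs = np.asarray(probs, dtype=float)

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        n = X.shape[0] if hasattr(X, "shape") else len(X)
        return np.tile(self._probs, (n, 1))


@dataclass
class NodeClassifier:
    """Binary one-vs-rest classifier attached to a single code node."""

    code_id: str
    estimator: object
    n_pos: int
    n_neg: int

    def score(self, X) -> np.ndarray:
        """P(code | query) in [0, 1] for each row of ``X``."""
        proba = self.estimator.predict_proba(X)
        pos_col = int(np.where(self.estimator.classes_ == 1)[0][0])
        return proba[:, pos_col]


@dataclass
class NonTerminalClassifier:
    """Multiclass classifier at an internal node over children + residual."""

    code_id: str
    classes: list[str]              # trained children codes + RESIDUAL, fixed order
    estimator: object

    def score(self, X) -> np.ndarray:
        """Row-normalized class-score matrix aligned with ``self.classes``."""
        proba = self.estimator.predict_proba(X)
        order = {c: i for i, c in enumerate(self.estimator.classes_)}
        out = np.zeros((proba.shape[0], len(self.classes)))
        for j, c in enumerate(self.classes):
            if c in order:
                out[:, j] = proba[:, order[c]]
        norm = out.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return out / norm


@dataclass
class EnsembleModel:
    """Trained classifier collection plus its hierarchy and featurizer.

    ``strategy`` is ``per-node`` or ``non-terminal``; ``classifiers`` maps
    code ids (plus :data:`ROOT_CLASSIFIER` for the non-terminal root) to
    fitted classifiers.  ``skipped`` records nodes left untrained and why.
    """

    strategy: str
    classifiers: dict
    hierarchy: CodeHierarchy
    vectorizer: object = None
    skipped: list = field(default_factory=list)

    def has(self, code_id: str) -> bool:
        return code_id in self.classifiers

    def trainable_codes(self) -> set[str]:
        return {c for c in self.classifiers if c != ROOT_CLASSIFIER}

    def featurize(self, queries: Sequence[str]):
        if self.vectorizer is None:
            raise ValueError("model has no vectorizer; pass feature matrices")
        return self.vectorizer.transform(queries)

    def score_matrix(self, X) -> dict[str, np.ndarray]:
        """Per-node positive scores for every classifier, batched over X."""
        if self.strategy != "per-node":
            raise ValueError("score_matrix applies to the per-node strategy")
        return {c: clf.score(X) for c, clf in self.classifiers.items()}


def _featurize(sets_queries, vectorizer, features):
    if vectorizer is not None:
        return vectorizer.transform(sets_queries)
    return np.asarray([features[q] for q in sets_queries])


def _stack(X):
    return sparse.vstack(X) if sparse.issparse(X[0]) else np.vstack(X)


def train_per_node(
    sets: Mapping[str, NodeTrainingSet],
    learner: BaseLearnerSpec,
    h: CodeHierarchy,
    *,
    vectorizer=None,
    features: Mapping[str, np.ndarray] | None = None,
    min_positives: int = MIN_POSITIVES_DEFAULT,
    balance: bool = False,
    smote_k: int = 5,
    negative_cap: int = 10,
    seed: int | None = None,
) -> EnsembleModel:
    """Train one binary classifier per trainable node.

    Queries are featurized through ``vectorizer`` (any object with a
    ``transform`` over text lists) or looked up in ``features``.  Nodes
    below ``min_positives`` positives are skipped and reported.  With
    ``balance`` the positives are synthetically oversampled to the negative
    count; very large negative sets are first subsampled to
    ``negative_cap`` times the positives.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    trainable = select_trainable_nodes(sets, min_positives)
    classifiers: dict[str, NodeClassifier] = {}
    skipped = []
    for code in sorted(sets):
        s = sets[code]
        if code not in trainable:
            skipped.append((code, f"{s.n_pos} positives < {min_positives}"))
            continue
        if not s.negatives:
            skipped.append((code, "no negative examples"))
            continue
        negs = list(s.negatives)
        if negative_cap and len(negs) > negative_cap * s.n_pos:
            idx = rng.choice(len(negs), negative_cap * s.n_pos, replace=False)
            negs = [negs[i] for i in sorted(idx)]
        Xp = _featurize(s.positives, vectorizer, features)
        Xn = _featurize(negs, vectorizer, features)
        X = _stack([Xp, Xn])
        y = np.concatenate([np.ones(Xp.shape[0], dtype=int),
                            -np.ones(Xn.shape[0], dtype=int)])
        if balance and Xp.shape[0] != Xn.shape[0]:
            Xd = X.toarray() if sparse.issparse(X) else X
            X, y = oversample_minority(Xd, y, k_neighbors=smote_k,
                                       seed=int(rng.integers(0, 2**31 - 1)))
        est = learner.make()
        if est.get_params().get("random_state", "absent") is None:
            est.set_params(random_state=int(rng.integers(0, 2**31 - 1)))
        est.fit(X, y)
        classifiers[code] = NodeClassifier(code, est, s.n_pos, len(negs))
    return EnsembleModel("per-node", classifiers, h, vectorizer, skipped)


def residual_examples(node_set: NodeTrainingSet,
                      child_sets: Sequence[NodeTrainingSet]) -> list[str]:
    """Positives of a node that are positive for none of its trained children."""
    covered = set()
    for cs in child_sets:
        covered.update(cs.positives)
    return [q for q in node_set.positives if q not in covered]


def train_non_terminal(
    sets: Mapping[str, NodeTrainingSet],
    h: CodeHierarchy,
    learner: BaseLearnerSpec,
    *,
    vectorizer=None,
    features: Mapping[str, np.ndarray] | None = None,
    min_positives: int = MIN_POSITIVES_DEFAULT,
    include_root: bool = True,
    seed: int | None = None,
) -> EnsembleModel:
    """Train one (children + residual) multiclass model per internal node.

    Class examples are each trained child's positives; the residual class
    holds the node's own positives not claimed by any trained child.  A
    virtual-root model over the chapter-level codes starts the top-down
    search (its residual examples are queries appearing only as negatives
    across chapter codes).  Internal nodes without trained children are
    skipped and reported.
    """
    rng = np.random.default_rng(seed)
    trainable = select_trainable_nodes(sets, min_positives)
    classifiers: dict[str, NonTerminalClassifier] = {}
    skipped = []

    def fit_multiclass(code_key, class_examples):
        classes = [c for c, ex in class_examples if ex]
        Xs, ys = [], []
        for c, ex in class_examples:
            if not ex:
                continue
            Xs.append(_featurize(ex, vectorizer, features))
            ys.extend([c] * len(ex))
        if len(classes) < 2:
            if not classes:
                return None
            cls = _ConstantClassifier(classes, [1.0])
            return NonTerminalClassifier(code_key, [c for c, _ in class_examples],
                                         cls)
        est = learner.make()
        if est.get_params().get("random_state", "absent") is None:
            est.set_params(random_state=int(rng.integers(0, 2**31 - 1)))
        est.fit(_stack(Xs), np.asarray(ys))
        return NonTerminalClassifier(code_key,
                                     [c for c, _ in class_examples], est)

    internal = [c for c in h if h.children(c)]
    for code in sorted(internal):
        kids = [k for k in h.children(code) if k in trainable and k in sets]
        if not kids:
            skipped.append((code, "no trained children"))
            continue
        node_set = sets.get(code, NodeTrainingSet(code))
        resid = residual_examples(node_set, [sets[k] for k in kids])
        class_examples = [(k, sets[k].positives) for k in kids]
        class_examples.append((RESIDUAL, resid))
        clf = fit_multiclass(code, class_examples)
        if clf is not None:
            classifiers[code] = clf

    if include_root:
        top = [c for c in h.top_level if c in trainable and c in sets]
        if top:
            pos_any = set()
            for c in top:
                pos_any.update(sets[c].positives)
            resid = []
            seen = set()
            for c in top:
                for q in sets[c].negatives:
                    if q not in pos_any and q not in seen:
                        seen.add(q)
                        resid.append(q)
            class_examples = [(c, sets[c].positives) for c in top]
            class_examples.append((RESIDUAL, resid))
            clf = fit_multiclass(ROOT_CLASSIFIER, class_examples)
            if clf is not None:
                classifiers[ROOT_CLASSIFIER] = clf
    return EnsembleModel("non-terminal", classifiers, h, vectorizer, skipped)


def per_level_micro_f1(
    model: EnsembleModel,
    val_sets: Mapping[str, NodeTrainingSet],
    *,
    threshold: float = 0.5,
) -> dict[int, dict[str, float]]:
    """Pooled per-level micro P/R/F1 of the base classifiers.

    Per-node strategy: each node's validation positives/negatives are
    scored by its binary classifier (binarized at ``threshold``) and the
    confusion counts pool over all nodes at the same level.  Non-terminal
    strategy: each internal classifier's argmax prediction over its
    validation examples is tallied against the true child class; counts
    attach to the child's level and the residual class carries no level.
    """
    h = model.hierarchy
    tallies: dict[int, dict[str, int]] = {}

    def t(level):
        return tallies.setdefault(level, {"tp": 0, "fp": 0, "fn": 0})

    if model.strategy == "per-node":
        for code, clf in model.classifiers.items():
            s = val_sets.get(code)
            if s is None or (not s.positives and not s.negatives):
                continue
            lv = h.level(code)
            if s.positives:
                p = clf.score(model.featurize(s.positives))
                t(lv)["tp"] += int(np.sum(p > threshold))
                t(lv)["fn"] += int(np.sum(p <= threshold))
            if s.negatives:
                p = clf.score(model.featurize(s.negatives))
                t(lv)["fp"] += int(np.sum(p > threshold))
    elif model.strategy == "non-terminal":
        for key, clf in model.classifiers.items():
            examples: list[tuple[str, str]] = []
            children = [c for c in clf.classes if c != RESIDUAL]
            for child in children:
                s = val_sets.get(child)
                if s is not None:
                    examples.extend((q, child) for q in s.positives)
            if not examples:
                continue
            X = model.featurize([q for q, _ in examples])
            probs = clf.score(X)
            pred = [clf.classes[i] for i in np.argmax(probs, axis=1)]
            for (q, true_c), pred_c in zip(examples, pred):
                if pred_c == true_c:
                    t(h.level(true_c))["tp"] += 1
                else:
                    t(h.level(true_c))["fn"] += 1
                    if pred_c != RESIDUAL:
                        t(h.level(pred_c))["fp"] += 1
    else:
        raise ValueError(f"unknown strategy {model.strategy!r}")

    out: dict[int, dict[str, float]] = {}
    for lv, c in sorted(tallies.items()):
        tp, fp, fn = c["tp"], c["fp"], c["fn"]
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        out[lv] = {"precision": prec, "recall": rec,
                   "f1": 0.0 if prec + rec == 0
                   else 2 * prec * rec / (prec + rec)}
    return out


def score(model: EnsembleModel, code_id: str, v):
    """Score one dense/sparse query vector at one node.

    Per-node strategy: scalar probability in [0, 1].  Non-terminal:
    normalized score vector over (children..., residual) in the
    classifier's ``classes`` order.
    """
    if not model.has(code_id):
        raise KeyError(f"no trained classifier for code {code_id!r}")
    V = v if sparse.issparse(v) else np.atleast_2d(np.asarray(v))
    clf = model.classifiers[code_id]
    out = clf.score(V)
    return float(out[0]) if model.strategy == "per-node" else out[0]
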