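"""Scikit-learn-style front end for hierarchical code assignment.

:class:`HierarchicalCodeClassifier` wires the pipeline — siblings-policy
training sets, per-node or non-terminal base classifiers, threshold
initialization/adaptation and top-down search — behind the familiar
``fit`` / ``predict`` / ``score`` contract, so it composes with sklearn
model selection and pipelines.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import classify, corpus, metrics, predict as predict_mod
from .hierarchy import CodeHierarchy, ancestors_of, true_path_closure

__all__ = ["HierarchicalCodeClassifier"]


class HierarchicalCodeClassifier(BaseEstimator, ClassifierMixin):
    """Assign hierarchical codes to short free-text queries.

    Parameters
    ----------
    hierarchy : CodeHierarchy
        The validated code tree.
    vectorizer : object
        Any transformer with ``transform(list[str]) -> matrix`` turning
        query texts into feature vectors (e.g.
        :class:`~hiercode.representation.ConceptVectorizer`, optionally
        chained with a projection or autoencoder in a sklearn Pipeline).
    strategy : {"per-node", "non-terminal"}
    learner : str
        Base-learner family (see :class:`~hiercode.classify.BaseLearnerSpec`).
    mode : {"argmax", "threshold"}
        Per-level acceptance rule of the top-down search.
    adaption : {"none", "bottom-up", "bayes"}
        Threshold post-processing: bottom-up children-mean smoothing, or
        Bayesian MAP relabeling fitted on a held-out share of the training
        records.
    min_positives : int
        Minimum positive count for a node to be trainable (default 21).

    Attributes
    ----------
    model_ : EnsembleModel
    thresholds_ : ThresholdTable
    aggregator_ : BayesianAggregator or None
    node_sets_ : mapping code -> NodeTrainingSet
    """

    def __init__(self, hierarchy: CodeHierarchy, vectorizer,
                 strategy: str = "per-node", learner: str = "logistic",
                 learner_params: dict | None = None,
                 mode: str = "argmax", adaption: str = "none",
                 min_positives: int = corpus.MIN_POSITIVES_DEFAULT,
                 balance: bool = False, default_threshold: float = 0.5,
                 threshold_init: str = "proportion",
                 validation_fraction: float = 0.4,
                 random_state: int | None = None):
        self.hierarchy = hierarchy
        self.vectorizer = vectorizer
        self.strategy = strategy
        self.learner = learner
        self.learner_params = learner_params
        self.mode = mode
        self.adaption = adaption
        self.min_positives = min_positives
        self.balance = balance
        self.default_threshold = default_threshold
        self.threshold_init = threshold_init
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------
    def fit(self, X: Sequence[str], y: Sequence[str],
            sample_label: Sequence[int] | None = None):
        """Fit from query texts and their judged codes.

        ``y[i]`` is the code judged for query ``X[i]``; ``sample_label``
        (default all ``+1``) marks each pair as a positive or an explicit
        negative log record.
        """
        if sample_label is None:
            sample_label = [1] * len(X)
        records = [corpus.QueryRecord(q, c, int(l))
                   for q, c, l in zip(X, y, sample_label)]
        return self.fit_records(records)

    def fit_records(self, records):
        """Fit from :class:`~hiercode.corpus.QueryRecord` triples."""
        h = self.hierarchy
        if hasattr(self.vectorizer, "fit"):
            try:
                self.vectorizer.fit([r.query_text for r in records])
            except TypeError:
                self.vectorizer.fit()
        self.node_sets_ = corpus.build_node_training_sets(records, h)
        spec = classify.BaseLearnerSpec(self.learner,
                                        dict(self.learner_params or {}),
                                        self.random_state)
        if self.strategy == "per-node":
            self.model_ = classify.train_per_node(
                self.node_sets_, spec, h, vectorizer=self.vectorizer,
                min_positives=self.min_positives, balance=self.balance,
                seed=self.random_state)
        elif self.strategy == "non-terminal":
            self.model_ = classify.train_non_terminal(
                self.node_sets_, h, spec, vectorizer=self.vectorizer,
                min_positives=self.min_positives, seed=self.random_state)
        else:
            raise ValueError(f"unknown strategy {self.strategy!r}")

        if self.threshold_init == "proportion":
            self.thresholds_ = predict_mod.init_thresholds(
                self.node_sets_, self.default_threshold)
        else:
            self.thresholds_ = predict_mod.ThresholdTable(
                default_t=self.default_threshold)
        self.aggregator_ = None
        if self.adaption == "bottom-up":
            self.thresholds_ = predict_mod.bottom_up_smooth(
                self.thresholds_, h)
        elif self.adaption == "bayes" and self.strategy == "per-node":
            self.aggregator_ = self._fit_aggregator(records)
        self.classes_ = np.asarray(sorted(h.nodes))
        return self

    def _fit_aggregator(self, records):
        """Estimate observation conditionals on a held-out record share."""
        rng = np.random.default_rng(self.random_state)
        queries = sorted({r.query_text for r in records if r.label == 1})
        n_val = max(1, int(len(queries) * self.validation_fraction))
        val_queries = set(rng.choice(queries, size=n_val, replace=False)) \
            if queries else set()
        gold_codes: dict[str, set[str]] = {}
        for r in records:
            if r.label == 1 and r.query_text in val_queries:
                gold_codes.setdefault(r.query_text, set()).add(r.code_id)
        X = self.model_.featurize(sorted(gold_codes))
        texts = sorted(gold_codes)
        score_mat = self.model_.score_matrix(X)
        validation = []
        for i, q in enumerate(texts):
            gold = true_path_closure(self.hierarchy, gold_codes[q])
            for code in self.model_.trainable_codes():
                yhat = int(score_mat[code][i] > self.thresholds_.get(code))
                validation.append((code, int(code in gold), yhat))
        return predict_mod.fit_bayes_aggregator(
            validation, self.hierarchy, self.node_sets_)

    # -- prediction ---------------------------------------------------------
    def predict_paths(self, X: Sequence[str]):
        """Full :class:`~hiercode.predict.PredictionResult` per query."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        V = self.model_.featurize(list(X))
        results = []
        if self.model_.strategy == "per-node":
            score_mat = self.model_.score_matrix(V)
            for i in range(V.shape[0]):
                scores = {c: float(score_mat[c][i]) for c in score_mat}
                results.append(predict_mod.hierarchical_search(
                    None, self.model_, self.thresholds_, self.mode,
                    self.aggregator_, scores=scores))
        else:
            for i in range(V.shape[0]):
                results.append(predict_mod.hierarchical_search(
                    V[i], self.model_, self.thresholds_, self.mode))
        return results

    def predict(self, X: Sequence[str]) -> np.ndarray:
        """Deepest accepted code per query ('' when nothing is accepted)."""
        return np.asarray([r.deepest or "" for r in self.predict_paths(X)],
                          dtype=object)

    def score(self, X: Sequence[str], y: Sequence[str]) -> float:
        """Mean per-query hierarchical F1 against gold codes ``y``."""
        preds = self.predict_paths(X)
        gold = [true_path_closure(self.hierarchy, [c]) for c in y]
        return metrics.evaluate(preds, gold, self.hierarchy).avg_per_query_f1
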