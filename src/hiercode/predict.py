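"""Top-down hierarchical prediction and threshold adaptation.

The search starts at the chapter-level classifiers and recurses only into
accepted nodes' children.  Acceptance is by per-level argmax (single-path
mode) or by per-node thresholds.  Deep true paths can be blocked when an
upper-level threshold is too high; two adaptations counter this:

* **bottom-up smoothing** — leaves-to-root, a parent threshold is replaced
  by the mean of its children's thresholds whenever that mean is smaller,
  so low child thresholds propagate upward and no threshold ever increases;
* **Bayesian aggregation** — the code tree is read as a Bayesian network
  over hidden binary labels ``y`` with observed binarized classifier
  outputs ``ŷ``; the MAP assignment of
  ``∏ P(ŷ_i|y_i) · ∏ P(y_i|parent(y_i))`` (max-product on the tree, with
  ``P(y_i=1 | parent=0) = 0`` enforcing the true path rule) relabels the
  decision sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classify import ROOT_CLASSIFIER, RESIDUAL, EnsembleModel
from .corpus import NodeTrainingSet
from .hierarchy import CodeHierarchy, true_path_closure

__all__ = [
    "ThresholdTable",
    "init_thresholds",
    "bottom_up_smooth",
    "PredictionResult",
    "hierarchical_search",
    "BayesianAggregator",
    "fit_bayes_aggregator",
    "bayes_map_aggregate",
]

DEFAULT_THRESHOLD = 0.5


@dataclass
class ThresholdTable:
    """Per-node decision thresholds with provenance tags.

    Provenance is ``default``, ``proportion-init`` or ``smoothed``.
    Unknown codes fall back to ``default_t`` (0.5 unless configured).
    """

    thresholds: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    default_t: float = DEFAULT_THRESHOLD

    def get(self, code_id: str) -> float:
        return self.thresholds.get(code_id, self.default_t)

    def set(self, code_id: str, t: float, tag: str) -> None:
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold for {code_id!r} outside [0,1]: {t}")
        self.thresholds[code_id] = t
        self.provenance[code_id] = tag

    def copy(self) -> "ThresholdTable":
        return ThresholdTable(dict(self.thresholds), dict(self.provenance),
                              self.default_t)

    def changed_fraction(self, other: "ThresholdTable") -> float:
        """Share of entries whose threshold differs from ``other``."""
        keys = set(self.thresholds) | set(other.thresholds)
        if not keys:
            return 0.0
        changed = sum(1 for k in keys
                      if not math.isclose(self.get(k), other.get(k)))
        return changed / len(keys)


def init_thresholds(sets: Mapping[str, NodeTrainingSet],
                    default_t: float = DEFAULT_THRESHOLD) -> ThresholdTable:
    """Initialize per-node thresholds from class proportions.

    ``t = n_pos / (n_pos + n_neg)`` per node with statistics; nodes without
    any examples keep the default (0.5).
    """
    tt = ThresholdTable(default_t=default_t)
    for code, s in sets.items():
        total = s.n_pos + s.n_neg
        if total:
            tt.set(code, s.n_pos / total, "proportion-init")
    return tt


def bottom_up_smooth(tt: ThresholdTable, h: CodeHierarchy,
                     stat: str = "mean") -> ThresholdTable:
    """Propagate low child thresholds upward, leaves-to-root.

    For each internal node (deepest first), the aggregated child threshold
    (``mean`` by default, ``min`` optionally) replaces the parent threshold
    when it is smaller.  Leaf thresholds never change and no threshold ever
    increases, so the pass is idempotent.
    """
    if stat not in ("mean", "min"):
        raise ValueError("stat must be 'mean' or 'min'")
    agg = np.mean if stat == "mean" else np.min
    out = tt.copy()
    for code in h.by_depth(deepest_first=True):
        kids = h.children(code)
        if not kids:
            continue
        child_ts = [out.get(k) for k in kids]
        candidate = float(agg(child_ts))
        if candidate < out.get(code):
            out.set(code, candidate, "smoothed")
    return out


@dataclass
class PredictionResult:
    """Outcome of one hierarchical search.

    ``accepted_per_level`` maps level -> list of ``(code, score)`` accepted
    there; ``codes`` is the ancestor-closed union of accepted codes.
    """

    accepted_per_level: dict[int, list[tuple[str, float]]]
    codes: frozenset[str]
    mode: str
    adaption: str = "none"

    @property
    def deepest(self) -> str | None:
        """Deepest accepted code (lexicographic tie-break), or None."""
        if not self.accepted_per_level:
            return None
        lv = max(self.accepted_per_level)
        return min(c for c, _ in self.accepted_per_level[lv])

    def to_dict(self) -> dict:
        return {
            "accepted": [
                {"code": c, "level": lv, "score": s}
                for lv in sorted(self.accepted_per_level)
                for c, s in self.accepted_per_level[lv]],
            "codes": sorted(self.codes),
            "mode": self.mode,
            "adaption": self.adaption,
        }


def _result(h, accepted, mode, adaption):
    per_level: dict[int, list[tuple[str, float]]] = {}
    for code, s in accepted.items():
        per_level.setdefault(h.level(code), []).append((code, s))
    for lv in per_level:
        per_level[lv].sort()
    codes = true_path_closure(h, accepted) if accepted else frozenset()
    return PredictionResult(per_level, codes, mode, adaption)


def hierarchical_search(
    v,
    model: EnsembleModel,
    tt: ThresholdTable | None = None,
    mode: str = "argmax",
    aggregator: "BayesianAggregator | None" = None,
    *,
    scores: Mapping[str, float] | None = None,
) -> PredictionResult:
    """Predict a code path for one query, top-down.

    Per-node strategy: chapter-level classifiers are evaluated first;
    ``argmax`` accepts the single best-scoring node per level (ties to the
    lexicographically smallest code) and recurses into it, ``threshold``
    accepts every node whose score strictly exceeds its threshold and
    recurses into all of them.  Non-terminal strategy: descend from the
    root multiclass model through the highest-scoring child until the
    residual class wins or a leaf is reached.

    With an ``aggregator``, all trainable classifiers are binarized at
    their thresholds and the MAP relabeling fills the decision sets.
    ``scores`` short-circuits classifier evaluation with precomputed
    per-node scores (used for batched prediction).
    """
    if not model.classifiers:
        raise ValueError("empty model")
    h = model.hierarchy

    if model.strategy == "non-terminal":
        return _search_non_terminal(v, model)

    tt = tt or ThresholdTable()
    if scores is None:
        scores = {c: model.classifiers[c].score(_as_row(v))[0]
                  for c in model.trainable_codes()}

    if aggregator is not None:
        observations = {c: int(scores[c] > tt.get(c)) for c in scores}
        positive = bayes_map_aggregate(observations, aggregator)
        accepted = {c: float(scores.get(c, 1.0)) for c in positive}
        return _result(h, accepted, mode, "bayes")

    accepted: dict[str, float] = {}
    frontier = [c for c in h.top_level if model.has(c)]
    while frontier:
        frontier_scores = {c: float(scores[c]) for c in frontier}
        if mode == "argmax":
            best = min(c for c, s in frontier_scores.items()
                       if s == max(frontier_scores.values()))
            taken = [best]
        elif mode == "threshold":
            taken = [c for c, s in frontier_scores.items() if s > tt.get(c)]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for c in taken:
            accepted[c] = frontier_scores[c]
        frontier = [k for c in taken for k in h.children(c) if model.has(k)]
    return _result(h, accepted, mode, "none")


def _as_row(v):
    from scipy import sparse

    return v if sparse.issparse(v) else np.atleast_2d(np.asarray(v))


def _search_non_terminal(v, model: EnsembleModel) -> PredictionResult:
    h = model.hierarchy
    accepted: dict[str, float] = {}
    key = ROOT_CLASSIFIER if model.has(ROOT_CLASSIFIER) else None
    V = _as_row(v)
    while key is not None:
        clf = model.classifiers[key]
        probs = clf.score(V)[0]
        best_i = int(np.argmax(probs))
        best = clf.classes[best_i]
        if best == RESIDUAL:
            break
        accepted[best] = float(probs[best_i])
        key = best if model.has(best) else None
    return _result(h, accepted, "argmax", "none")


# ---------------------------------------------------------------------------
# Bayesian aggregation
# ---------------------------------------------------------------------------

@dataclass
class BayesianAggregator:
    """Tree-structured observation model over hidden code labels.

    Per node ``i``: ``p_obs[i] = (P(ŷ=1|y=1), P(ŷ=1|y=0))`` estimated from
    validation confusion counts, and ``p_child[i] = P(y_i=1 | parent=1)``
    estimated from training-pair frequencies (for chapter-level codes this
    is the marginal prior).  ``P(y_i=1 | parent=0) = 0`` exactly, so every
    MAP assignment is closed under ancestors.
    """

    p_obs: dict[str, tuple[float, float]]
    p_child: dict[str, float]
    hierarchy: CodeHierarchy
    smoothing: float = 1.0

    def nodes(self) -> set[str]:
        return set(self.p_obs)


def fit_bayes_aggregator(
    validation: Iterable[tuple[str, int, int]],
    h: CodeHierarchy,
    sets: Mapping[str, NodeTrainingSet] | None = None,
    smoothing: float = 1.0,
) -> BayesianAggregator:
    """Estimate the aggregator from binarized validation predictions.

    ``validation`` yields ``(code_id, y, ŷ)`` triples.  Observation
    conditionals use additive (Laplace) smoothing; nodes with no validation
    coverage for a class fall back to symmetric priors.  Structural
    conditionals ``P(y=1|parent=1)`` come from the node-set positive counts
    when ``sets`` is given, else default to 0.5.
    """
    counts: dict[str, np.ndarray] = {}
    for code, y, yhat in validation:
        if code not in h:
            raise KeyError(f"validation references unknown code {code!r}")
        c = counts.setdefault(code, np.zeros((2, 2)))
        c[int(y), int(yhat)] += 1

    p_obs: dict[str, tuple[float, float]] = {}
    for code, c in counts.items():
        def rate(y):
            tot = c[y].sum()
            if tot == 0 and smoothing == 0:
                return 0.5
            return (c[y, 1] + smoothing) / (tot + 2 * smoothing)
        p_obs[code] = (rate(1), rate(0))

    p_child: dict[str, float] = {}
    for code in (set(p_obs) | (set(sets) if sets else set())):
        if sets is None:
            p_child[code] = 0.5
            continue
        n_pos = sets[code].n_pos if code in sets else 0
        parent = h.parent(code) if code in h else None
        if parent is None:
            total = sum(sets[c].n_pos for c in h.top_level if c in sets)
            p_child[code] = (n_pos + smoothing) / (total + 2 * smoothing) \
                if (total or smoothing) else 0.5
        else:
            parent_pos = sets[parent].n_pos if parent in sets else 0
            if parent_pos or smoothing:
                p_child[code] = min(1.0, (n_pos + smoothing)
                                    / (parent_pos + 2 * smoothing))
            else:
                p_child[code] = 0.5
    return BayesianAggregator(p_obs, p_child, h, smoothing)


def _log(p: float) -> float:
    return math.log(p) if p > 0.0 else -math.inf


def bayes_map_aggregate(observations: Mapping[str, int],
                        agg: BayesianAggregator) -> frozenset[str]:
    """MAP relabeling of binarized predictions over the code tree.

    Maximizes ``∏ P(ŷ_i|y_i) · ∏ P(y_i|parent)`` by max-product dynamic
    programming (upward pass of per-state subtree maxima, downward
    backtrack).  Nodes without an observation contribute no observation
    factor (they are maximized over freely).  The structural zero
    ``P(y=1|parent=0) = 0`` makes the returned positive set true-path
    closed by construction.  Ties prefer the negative label.
    """
    h = agg.hierarchy
    for code in observations:
        if code not in h:
            raise KeyError(f"observation for unknown code {code!r}")
    nodes = set(agg.p_obs) | set(observations) | set(agg.p_child)
    nodes = {c for c in nodes if c in h}

    M: dict[str, tuple[float, float]] = {}       # code -> (best | y=0, best | y=1)
    choice: dict[str, tuple[dict, dict]] = {}    # child state choices per own state

    def obs_term(code, y):
        if code not in observations:
            return 0.0
        yhat = observations[code]
        p1, p0 = agg.p_obs.get(code, (0.75, 0.25))  # symmetric fallback
        p = (p1 if y == 1 else p0)
        return _log(p if yhat == 1 else 1.0 - p)

    order = [c for c in h.by_depth(deepest_first=True) if c in nodes]
    relevant_children = {c: [k for k in h.children(c) if k in nodes]
                         for c in nodes}
    for code in order:
        kids = relevant_children[code]
        pick0, pick1 = {}, {}
        tot0 = obs_term(code, 0)
        tot1 = obs_term(code, 1)
        for k in kids:
            pc = agg.p_child.get(k, 0.5)
            m0, m1 = M[k]
            # parent = 0 forces child 0 with probability 1
            tot0 += m0
            pick0[k] = 0
            cand0 = _log(1.0 - pc) + m0
            cand1 = _log(pc) + m1
            if cand1 > cand0:
                tot1 += cand1
                pick1[k] = 1
            else:
                tot1 += cand0
                pick1[k] = 0
        M[code] = (tot0, tot1)
        choice[code] = (pick0, pick1)

    positive: set[str] = set()
    stack: list[tuple[str, int]] = []
    for code in nodes:
        if h.parent(code) is None or h.parent(code) not in nodes:
            pc = agg.p_child.get(code, 0.5)
            m0, m1 = M[code]
            root0 = _log(1.0 - pc) + m0
            root1 = _log(pc) + m1
            stack.append((code, 1 if root1 > root0 else 0))
    while stack:
        code, state = stack.pop()
        if state == 1:
            positive.add(code)
        picks = choice[code][state]
        for k, ks in picks.items():
            stack.append((k, ks))
    return frozenset(positive)
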