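"""Hierarchical and per-level evaluation of predicted code paths.

Predicted and gold label sets are compared after closure under the
ancestor operation, so a miss deep on a path still credits the correct
upper levels: hierarchical precision is ``|pred ∩ gold| / |pred|``,
hierarchical recall ``|pred ∩ gold| / |gold|``, and path distance is the
step count between two codes on the undirected code tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .hierarchy import CodeHierarchy, path_between, true_path_closure
from .predict import PredictionResult

__all__ = [
    "hierarchical_precision",
    "hierarchical_recall",
    "hierarchical_f1",
    "path_distance",
    "micro_f1_by_level",
    "MetricsReport",
    "evaluate",
]


def _closed(h: CodeHierarchy | None, codes: Iterable[str]) -> frozenset[str]:
    codes = frozenset(codes)
    if h is None:
        return codes
    return true_path_closure(h, codes)


def hierarchical_precision(pred: Iterable[str], gold: Iterable[str],
                           h: CodeHierarchy | None = None) -> float:
    """``|pred ∩ gold| / |pred|`` on ancestor-closed sets; empty pred -> 0."""
    p = _closed(h, pred)
    g = _closed(h, gold)
    if not p:
        return 0.0
    return len(p & g) / len(p)


def hierarchical_recall(pred: Iterable[str], gold: Iterable[str],
                        h: CodeHierarchy | None = None) -> float:
    """``|pred ∩ gold| / |gold|``; an empty gold set is an evaluation error."""
    p = _closed(h, pred)
    g = _closed(h, gold)
    if not g:
        raise ValueError("gold label set must be non-empty")
    return len(p & g) / len(g)


def hierarchical_f1(pred: Iterable[str], gold: Iterable[str],
                    h: CodeHierarchy | None = None) -> float:
    hp = hierarchical_precision(pred, gold, h)
    hr = hierarchical_recall(pred, gold, h)
    return 0.0 if hp + hr == 0 else 2 * hp * hr / (hp + hr)


def path_distance(pred_code: str, gold_code: str, h: CodeHierarchy) -> int:
    """Tree-path step count between a predicted and a gold code."""
    return path_between(h, pred_code, gold_code)


def micro_f1_by_level(
    predictions: Sequence[PredictionResult | Iterable[str]],
    gold: Sequence[Iterable[str]],
    h: CodeHierarchy,
) -> dict[int, dict[str, float]]:
    """Pooled per-level micro precision/recall/F1.

    For each level, true/false positives and false negatives are pooled
    over all queries restricted to codes at that level; levels with neither
    gold nor predicted codes are omitted.
    """
    if len(predictions) != len(gold):
        raise ValueError("predictions and gold must have equal length")
    tallies: dict[int, dict[str, int]] = {}
    for pred, g in zip(predictions, gold):
        p_codes = pred.codes if isinstance(pred, PredictionResult) else \
            _closed(h, pred)
        g_codes = _closed(h, g)
        for code in p_codes | g_codes:
            lv = h.level(code)
            t = tallies.setdefault(lv, {"tp": 0, "fp": 0, "fn": 0})
            if code in p_codes and code in g_codes:
                t["tp"] += 1
            elif code in p_codes:
                t["fp"] += 1
            else:
                t["fn"] += 1
    out: dict[int, dict[str, float]] = {}
    for lv, t in sorted(tallies.items()):
        tp, fp, fn = t["tp"], t["fp"], t["fn"]
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        out[lv] = {"precision": prec, "recall": rec, "f1": f1,
                   "support": tp + fn}
    return out


@dataclass
class MetricsReport:
    """Evaluation summary over a query set.

    ``macro_*`` are unweighted per-query averages; ``micro_*`` pool code
    counts over all queries.  Two F1 conventions are emitted explicitly:
    the harmonic mean of the averaged precision/recall and the average of
    per-query F1 values.
    """

    n_queries: int
    macro_precision: float
    macro_recall: float
    f1_of_averages: float
    avg_per_query_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    mean_path_distance: float | None
    per_level: dict[int, dict[str, float]] = field(default_factory=dict)
    n_empty_predictions: int = 0

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["per_level"] = {str(k): v for k, v in self.per_level.items()}
        return d


def evaluate(
    predictions: Sequence[PredictionResult | Iterable[str]],
    gold: Sequence[Iterable[str]],
    h: CodeHierarchy,
) -> MetricsReport:
    """Full hierarchical evaluation of a prediction batch.

    Empty predictions score zero precision and recall and are counted, not
    skipped.  Mean path distance is computed between the deepest predicted
    and deepest gold code of each query where both exist.
    """
    if len(predictions) != len(gold):
        raise ValueError("predictions and gold must have equal length")
    hps, hrs, f1s, dists = [], [], [], []
    tp = fp = fn = 0
    n_empty = 0
    for pred, g in zip(predictions, gold):
        p_codes = pred.codes if isinstance(pred, PredictionResult) else \
            _closed(h, pred)
        g_codes = _closed(h, g)
        if not p_codes:
            n_empty += 1
            hps.append(0.0)
            hrs.append(0.0)
            f1s.append(0.0)
            fn += len(g_codes)
            continue
        hp = len(p_codes & g_codes) / len(p_codes)
        hr = len(p_codes & g_codes) / len(g_codes)
        hps.append(hp)
        hrs.append(hr)
        f1s.append(0.0 if hp + hr == 0 else 2 * hp * hr / (hp + hr))
        tp += len(p_codes & g_codes)
        fp += len(p_codes - g_codes)
        fn += len(g_codes - p_codes)
        deep_p = max(p_codes, key=lambda c: (h.level(c), c))
        deep_g = max(g_codes, key=lambda c: (h.level(c), c))
        try:
            dists.append(path_distance(deep_p, deep_g, h))
        except Exception:
            pass  # disjoint chapter trees: distance undefined for this pair
    n = len(predictions)
    mp = sum(hps) / n if n else 0.0
    mr = sum(hrs) / n if n else 0.0
    micro_p = tp / (tp + fp) if tp + fp else 0.0
    micro_r = tp / (tp + fn) if tp + fn else 0.0
    return MetricsReport(
        n_queries=n,
        macro_precision=mp,
        macro_recall=mr,
        f1_of_averages=0.0 if mp + mr == 0 else 2 * mp * mr / (mp + mr),
        avg_per_query_f1=sum(f1s) / n if n else 0.0,
        micro_precision=micro_p,
        micro_recall=micro_r,
        micro_f1=(0.0 if micro_p + micro_r == 0
                  else 2 * micro_p * micro_r / (micro_p + micro_r)),
        mean_path_distance=(sum(dists) / len(dists)) if dists else None,
        per_level=micro_f1_by_level(predictions, gold, h),
        n_empty_predictions=n_empty,
    )
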