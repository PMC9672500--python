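"""Node-level training sets from query logs.

Query logs arrive as ``(query text, code id, label ±1)`` triples.  Per-node
training sets are derived under the *siblings policy*: positives of a code
are positives of all its ancestors (true path rule) and negatives of its
siblings, except where the query is itself positive for the sibling.  The
module also merges a mapped secondary corpus (e.g. logs from a structurally
parallel foreign catalog), selects nodes with enough positives to train,
and balances classes with synthetic minority oversampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .hierarchy import CodeHierarchy, UnknownCodeError

__all__ = [
    "QueryRecord",
    "NodeTrainingSet",
    "build_node_training_sets",
    "merge_mapped_corpus",
    "select_trainable_nodes",
    "oversample_minority",
    "read_query_log",
    "write_query_log",
]

logger = logging.getLogger(__name__)

#: Default minimum positive-example count for a node to be trainable; the
#: floor needed by the oversampler's neighborhood size in n-fold training.
MIN_POSITIVES_DEFAULT = 21


@dataclass(frozen=True)
class QueryRecord:
    """One log entry: a short free-text query judged against one code."""

    query_text: str
    code_id: str
    label: int
    source: str = "primary"

    def __post_init__(self) -> None:
        if self.label not in (+1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")
        if not self.query_text:
            raise ValueError("query_text must be non-empty")


@dataclass
class NodeTrainingSet:
    """Positive and negative query texts attached to one code node."""

    code_id: str
    positives: list[str] = field(default_factory=list)
    negatives: list[str] = field(default_factory=list)

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)


def build_node_training_sets(
    records: Sequence[QueryRecord],
    h: CodeHierarchy,
    *,
    propagate_offspring_negatives: bool = False,
) -> dict[str, NodeTrainingSet]:
    """Apply the siblings policy to raw log records.

    Three rules, in order: (1) each positive for code ``c`` becomes a
    positive for ``c`` and every ancestor of ``c``; (2) each positive for
    ``c`` becomes a negative for every sibling of ``c``; (3) exception — a
    query that is positive for a node is never used as a negative there.
    Explicit ``-1`` records are kept as negatives of their own node (and,
    with ``propagate_offspring_negatives``, of every descendant, mirroring
    the downward direction of the true path rule).

    Queries are identified by their text; duplicate contributions collapse.
    """
    for r in records:
        if r.code_id not in h:
            raise UnknownCodeError(f"unknown code {r.code_id!r} in query log")

    pos: dict[str, dict[str, None]] = {}   # code -> ordered set of queries
    neg: dict[str, dict[str, None]] = {}

    def add(table, code, query):
        table.setdefault(code, {})[query] = None

    # rule 1: upward-closed positives
    for r in records:
        if r.label == +1:
            add(pos, r.code_id, r.query_text)
            node = h.node(r.code_id)
            while node.parent_id is not None:
                add(pos, node.parent_id, r.query_text)
                node = h.node(node.parent_id)

    # rule 2: sibling negatives, generated from each explicitly labeled code
    for r in records:
        if r.label != +1:
            continue
        parent = h.parent(r.code_id)
        siblings = (h.children(parent) if parent is not None
                    else h.top_level)
        for s in siblings:
            if s != r.code_id:
                add(neg, s, r.query_text)

    # explicit negatives
    for r in records:
        if r.label == -1:
            add(neg, r.code_id, r.query_text)
            if propagate_offspring_negatives:
                stack = list(h.children(r.code_id))
                while stack:
                    c = stack.pop()
                    add(neg, c, r.query_text)
                    stack.extend(h.children(c))

    # rule 3 exception: positives shadow negatives at the same node
    sets: dict[str, NodeTrainingSet] = {}
    for code in h:
        p = pos.get(code, {})
        n = [q for q in neg.get(code, {}) if q not in p]
        if p or n:
            sets[code] = NodeTrainingSet(code, list(p), n)
    return sets


def merge_mapped_corpus(
    primary: Sequence[QueryRecord],
    secondary: Sequence[QueryRecord],
    code_map: Mapping[str, str],
) -> list[QueryRecord]:
    """Re-label a mapped secondary corpus onto primary codes and append it.

    Secondary records whose code has no mapping are dropped (the count is
    logged).  Records duplicating a primary ``(query, code)`` pair are
    collapsed, keeping the primary source tag.
    """
    out = list(primary)
    seen = {(r.query_text, r.code_id, r.label) for r in primary}
    dropped = 0
    for r in secondary:
        target = code_map.get(r.code_id)
        if target is None:
            dropped += 1
            continue
        key = (r.query_text, target, r.label)
        if key in seen:
            continue
        seen.add(key)
        out.append(QueryRecord(r.query_text, target, r.label, source="secondary"))
    if dropped:
        logger.info("merge_mapped_corpus: dropped %d unmapped secondary records",
                    dropped)
    return out


def select_trainable_nodes(
    sets: Mapping[str, NodeTrainingSet],
    min_positives: int = MIN_POSITIVES_DEFAULT,
) -> set[str]:
    """Nodes with at least ``min_positives`` positive examples.

    With ``min_positives=0`` this returns every node that has one or more
    positives (a node with zero positives cannot anchor a classifier).
    """
    if min_positives < 0:
        raise ValueError("min_positives must be >= 0")
    floor = max(min_positives, 1)
    return {c for c, s in sets.items() if s.n_pos >= floor}


def oversample_minority(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary set by synthetic minority interpolation (SMOTE).

    Each synthetic point lies on the segment between a minority point and
    one of its ``k_neighbors`` nearest minority neighbors (Euclidean);
    the majority class is left untouched and the output has equal class
    counts.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversample_minority requires both classes present")
    if len(classes) > 2:
        raise ValueError("oversample_minority is binary-only")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority count {n_min} must exceed k_neighbors={k_neighbors}")

    Xm = X[y == minority]
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
    # drop self-match in column 0; sklearn orders ties by index already
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]

    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k_neighbors, size=n_new)
    gap = rng.random(n_new)
    synthetic = Xm[base] + gap[:, None] * (Xm[neigh[base, pick]] - Xm[base])

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


# -- query-log I/O ----------------------------------------------------------

def read_query_log(path) -> list[QueryRecord]:
    """Read a query-log TSV (`query_text  code_id  label  source`)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(QueryRecord(row.query_text, str(row.code_id),
                               int(row.label),
                               getattr(row, "source", "primary") or "primary"))
    return out


def write_query_log(records: Iterable[QueryRecord], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [(r.query_text, r.code_id, r.label, r.source) for r in records],
        columns=["query_text", "code_id", "label", "source"])
    df.to_csv(path, sep="\t", index=False)
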