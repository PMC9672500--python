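"""Tree-structured procedure-code catalogs and true-path operations.

A procedure-code system such as the Swiss CHOP is a forest of up to six
levels: every code except the chapter-level ones has exactly one parent, the
is-a relation derived from the parent links is irreflexive and transitive,
and annotation follows the *true path rule* — a query labeled with a code is
implicitly labeled with every ancestor of that code.

This module provides :class:`CodeHierarchy`, the catalog parser, and the
closure/distance operations the rest of the package builds on.  A virtual
root joins the chapter-level codes for traversal purposes only; it never
appears in paths, metrics or predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CodeNode",
    "CodeHierarchy",
    "HierarchyError",
    "DuplicateCodeError",
    "UnknownCodeError",
    "MultipleParentError",
    "CycleError",
    "DisjointTreesError",
    "ValidationReport",
    "parse_catalog",
    "ancestors_of",
    "true_path_closure",
    "validate_partial_order",
    "path_between",
]

#: Sentinel used internally for the virtual root; never a real code id.
VIRTUAL_ROOT = "__root__"


class HierarchyError(ValueError):
    """Base class for catalog validation failures."""


class DuplicateCodeError(HierarchyError):
    pass


class UnknownCodeError(HierarchyError, KeyError):
    def __str__(self) -> str:  # KeyError would repr() the message
        return ValueError.__str__(self)


class MultipleParentError(HierarchyError):
    pass


class CycleError(HierarchyError):
    pass


class DisjointTreesError(HierarchyError):
    pass


@dataclass
class CodeNode:
    """One catalog entry.

    ``level`` is 1 for chapter-level codes and increases by exactly one per
    parent link.  ``children`` preserves catalog order.
    """

    code_id: str
    parent_id: str | None
    level: int
    description: str = ""
    children: list[str] = field(default_factory=list)


class CodeHierarchy:
    """A validated forest of :class:`CodeNode`.

    Parameters
    ----------
    nodes:
        Mapping ``code_id -> CodeNode``.  Parent/child links must be
        mutually consistent; pass ``validate=False`` to skip the check (used
        by :func:`validate_partial_order` to inspect broken inputs).
    """

    def __init__(self, nodes: Mapping[str, CodeNode], *, max_level: int = 6,
                 validate: bool = True) -> None:
        self.nodes: dict[str, CodeNode] = dict(nodes)
        self.max_level = max_level
        self.top_level: list[str] = [
            c for c, n in self.nodes.items() if n.parent_id is None
        ]
        if validate:
            report = validate_partial_order(self)
            if not report.ok:
                report.raise_first()

    # -- container protocol -------------------------------------------------
    def __contains__(self, code_id: str) -> bool:
        return code_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def node(self, code_id: str) -> CodeNode:
        try:
            return self.nodes[code_id]
        except KeyError:
            raise UnknownCodeError(f"unknown code {code_id!r}") from None

    def parent(self, code_id: str) -> str | None:
        return self.node(code_id).parent_id

    def children(self, code_id: str) -> list[str]:
        return list(self.node(code_id).children)

    def level(self, code_id: str) -> int:
        return self.node(code_id).level

    def is_leaf(self, code_id: str) -> bool:
        return not self.node(code_id).children

    def leaves(self) -> list[str]:
        return [c for c in self.nodes if not self.nodes[c].children]

    def codes_at_level(self, level: int) -> list[str]:
        return [c for c, n in self.nodes.items() if n.level == level]

    def levels_present(self) -> list[int]:
        return sorted({n.level for n in self.nodes.values()})

    def by_depth(self, deepest_first: bool = False) -> list[str]:
        """Codes ordered by level (stable within a level)."""
        order = sorted(self.nodes, key=lambda c: self.nodes[c].level)
        return order[::-1] if deepest_first else order


def _infer_links(df: pd.DataFrame) -> pd.DataFrame:
    """Infer parent ids and levels from dotted digit-group code strings.

    The parent of a code is the catalog entry whose digit string is the
    longest proper prefix of the code's digit string (``00.65.11`` hangs
    under ``00.65.1`` when present, else under ``00.65`` and so on); levels
    are depths in the resulting forest, so the shortest codes present form
    level 1 regardless of how many digits they carry.
    """
    digits = {str(c): str(c).replace(".", "") for c in df["code_id"]}
    by_digits = {d: c for c, d in digits.items()}
    parents = []
    for code in df["code_id"]:
        d = digits[str(code)]
        parent = ""
        for cut in range(len(d) - 1, 0, -1):
            cand = by_digits.get(d[:cut])
            if cand is not None:
                parent = cand
                break
        parents.append(parent)
    out = df.copy()
    out["parent_id"] = parents
    return out


def parse_catalog(catalog_source) -> CodeHierarchy:
    """Read a catalog table into a validated :class:`CodeHierarchy`.

    ``catalog_source`` is a TSV path/handle with a header row and columns
    ``code_id``, ``parent_id`` (empty for chapter level), optional ``level``
    and ``description`` — or an equivalent :class:`pandas.DataFrame`.  When
    the ``parent_id`` column is absent entirely, parents and levels are
    inferred from dotted digit-group code strings.

    Raises a specific :class:`HierarchyError` subclass naming the offending
    code on duplicate ids, unknown parents or cycles.
    """
    if isinstance(catalog_source, pd.DataFrame):
        df = catalog_source.copy()
    else:
        df = pd.read_csv(catalog_source, sep="\t", dtype=str, keep_default_na=False)
    if len(df) == 0:
        return CodeHierarchy({})
    if "code_id" not in df.columns:
        raise HierarchyError("catalog must have a 'code_id' column")
    df["code_id"] = df["code_id"].astype(str)
    if "parent_id" not in df.columns:
        df = _infer_links(df)
    if "description" not in df.columns:
        df["description"] = ""

    seen: set[str] = set()
    for code in df["code_id"]:
        if code in seen:
            raise DuplicateCodeError(f"duplicate code {code!r}")
        seen.add(code)

    nodes: dict[str, CodeNode] = {}
    for row in df.itertuples(index=False):
        parent = str(getattr(row, "parent_id", "") or "") or None
        if parent is not None and parent not in seen:
            raise UnknownCodeError(
                f"code {row.code_id!r} references unknown parent {parent!r}")
        nodes[row.code_id] = CodeNode(
            code_id=row.code_id, parent_id=parent, level=0,
            description=str(getattr(row, "description", "") or ""))
    for node in nodes.values():
        if node.parent_id is not None:
            nodes[node.parent_id].children.append(node.code_id)

    # depth-assign levels; detect cycles while walking
    explicit = "level" in df.columns and df["level"].astype(str).str.len().gt(0).all()
    for row in df.itertuples(index=False):
        node = nodes[row.code_id]
        if explicit:
            node.level = int(row.level)
        else:
            depth, cur = 1, node
            hops = 0
            while cur.parent_id is not None:
                cur = nodes[cur.parent_id]
                depth += 1
                hops += 1
                if hops > len(nodes):
                    raise CycleError(f"cycle involving code {row.code_id!r}")
            node.level = depth
    return CodeHierarchy(nodes)


def ancestors_of(h: CodeHierarchy, code_id: str) -> list[str]:
    """Strict ancestors of ``code_id``, chapter level first.

    Excludes ``code_id`` itself and the virtual root.
    """
    node = h.node(code_id)
    chain: list[str] = []
    hops = 0
    while node.parent_id is not None:
        chain.append(node.parent_id)
        node = h.node(node.parent_id)
        hops += 1
        if hops > len(h):
            raise CycleError(f"cycle above code {code_id!r}")
    return chain[::-1]


def true_path_closure(h: CodeHierarchy, codes: Iterable[str]) -> frozenset[str]:
    """Close a label set under the ancestor operation (true path rule).

    Idempotent and monotone: ``closure(S) ⊆ closure(T)`` whenever
    ``S ⊆ T``.
    """
    closed: set[str] = set()
    for c in codes:
        closed.add(h.node(c).code_id)
        closed.update(ancestors_of(h, c))
    return frozenset(closed)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_partial_order`.

    ``violations`` is a list of ``{rule, code_id, message}`` dicts,
    serializable with :meth:`to_json`.
    """

    violations: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_json(self) -> str:
        return json.dumps(self.violations, indent=2)

    def raise_first(self) -> None:
        v = self.violations[0]
        exc = {"cycle": CycleError, "multiple-parent": MultipleParentError,
               "unknown-parent": UnknownCodeError,
               "level": HierarchyError}.get(v["rule"], HierarchyError)
        raise exc(v["message"])


def validate_partial_order(h: CodeHierarchy) -> ValidationReport:
    """Check that parent links form a strict partial order.

    Passes iff no node is its own ancestor (anti-reflexivity of the derived
    is-a relation, whose transitive closure is then acyclic), no node claims
    two parents, all parent references resolve, and levels increase by one
    along each link.
    """
    report = ValidationReport()
    claimed_parent: dict[str, set[str]] = {}
    for code, node in h.nodes.items():
        if node.parent_id is not None and node.parent_id not in h.nodes:
            report.violations.append({
                "rule": "unknown-parent", "code_id": code,
                "message": f"code {code!r} references unknown parent "
                           f"{node.parent_id!r}"})
        for child in node.children:
            claimed_parent.setdefault(child, set()).add(code)
    for child, parents in claimed_parent.items():
        explicit = {h.nodes[child].parent_id} if child in h.nodes else set()
        if len(parents | explicit - {None}) > 1:
            report.violations.append({
                "rule": "multiple-parent", "code_id": child,
                "message": f"code {child!r} has multiple parents "
                           f"{sorted(parents)}"})
    for code, node in h.nodes.items():
        seen = {code}
        cur = node
        while cur.parent_id is not None and cur.parent_id in h.nodes:
            if cur.parent_id in seen:
                report.violations.append({
                    "rule": "cycle", "code_id": code,
                    "message": f"code {code!r} is its own ancestor via "
                               f"{cur.parent_id!r}"})
                break
            seen.add(cur.parent_id)
            cur = h.nodes[cur.parent_id]
    for code, node in h.nodes.items():
        if node.parent_id in h.nodes and node.level and h.nodes[node.parent_id].level:
            if node.level != h.nodes[node.parent_id].level + 1:
                report.violations.append({
                    "rule": "level", "code_id": code,
                    "message": f"code {code!r} at level {node.level} under "
                               f"parent at level {h.nodes[node.parent_id].level}"})
    return report


def path_between(h: CodeHierarchy, a: str, b: str) -> int:
    """Number of parent-link edges on the unique undirected tree path.

    Computed from the lowest common ancestor:
    ``level(a) + level(b) - 2 * level(lca)``.  Codes that sit in different
    chapter trees share no undirected path (the virtual root is traversal
    bookkeeping, not an edge) and raise :class:`DisjointTreesError`.
    """
    if a == b:
        h.node(a)
        return 0
    chain_a = ancestors_of(h, a) + [a]
    chain_b = ancestors_of(h, b) + [b]
    if chain_a[0] != chain_b[0]:
        raise DisjointTreesError(
            f"codes {a!r} and {b!r} are in disjoint trees")
    common = 0
    for x, y in zip(chain_a, chain_b):
        if x != y:
            break
        common += 1
    return (len(chain_a) - common) + (len(chain_b) - common)
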