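import numpy as np
import pytest

from hiercode.hierarchy import CodeHierarchy, CodeNode


def build_tree(edges, top):
    """Hierarchy from (child, parent) pairs plus top-level code list."""
    nodes = {c: CodeNode(c, None, 1) for c in top}
    for child, parent in edges:
        nodes[child] = CodeNode(child, parent, 0)
    for child, parent in edges:
        nodes[parent].children.append(child)

    def depth(c):
        d, cur = 1, nodes[c]
        while cur.parent_id is not None:
            cur = nodes[cur.parent_id]
            d += 1
        return d

    for c in nodes:
        nodes[c].level = depth(c)
    return CodeHierarchy(nodes)


def random_tree(rng, n_nodes, max_children=3):
    """Random forest of ``n_nodes`` codes named n0..n{k}; ~1-3 roots."""
    n_roots = int(rng.integers(1, min(3, n_nodes) + 1))
    top = [f"n{i}" for i in range(n_roots)]
    edges = []
    for i in range(n_roots, n_nodes):
        parent = f"n{int(rng.integers(0, i))}"
        edges.append((f"n{i}", parent))
    return build_tree(edges, top)


@pytest.fixture
def chain3():
    """A -> A.B -> A.B.C chain."""
    return build_tree([("A.B", "A"), ("A.B.C", "A.B")], ["A"])


@pytest.fixture
def two_level():
    """Two chapters, chapter A with children A.1 A.2, B with B.1."""
    return build_tree([("A.1", "A"), ("A.2", "A"), ("B.1", "B")], ["A", "B"])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
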