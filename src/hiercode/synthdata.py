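"""Synthetic code catalogs, lexicons and query corpora.

Real procedure-coding query logs are proprietary, so every stage of the
pipeline is exercised on generated data that mirrors their statistical
structure: a six-level dotted-code tree in which roughly 45% of internal
nodes have more than five children, short queries of 2-6 terms whose
tokens come from characteristic vocabularies of the nodes on the target
code's true path (plus a configurable noise fraction drawn from the global
vocabulary), and a strong negative-to-positive imbalance in the log
records.

Characteristic token sets are disjoint across nodes by construction, so a
zero-noise corpus is perfectly separable — the clean end of the benchmark
surface.  Generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import QueryRecord
from .hierarchy import CodeHierarchy, CodeNode, ancestors_of
from .representation import ConceptLexicon

__all__ = [
    "SynthConfig",
    "generate_hierarchy",
    "generate_query_corpus",
    "write_catalog",
    "simulate_to_dir",
    "default_branching",
]


def default_branching(rng: np.random.Generator) -> int:
    """Child-count draw giving ~45% of internal nodes more than 5 children."""
    if rng.random() < 0.45:
        return int(rng.integers(6, 11))
    return int(rng.integers(2, 6))


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate the catalog and log shape.

    ``branching`` may be an int (fixed fan-out) or None for the mixed
    draw of :func:`default_branching`.  ``positives_per_node`` is the mean
    of a Poisson draw (minimum 1) of positive queries per target node;
    ``negative_rate`` explicit negative records are sampled per positive
    from off-path nodes.  ``noise_rate`` is the probability that a query
    token comes from the global vocabulary instead of the true path.
    """

    depth: int = 6
    branching: int | None = None
    tokens_per_node: int = 6
    query_len: tuple[int, int] = (2, 6)
    noise_rate: float = 0.1
    positives_per_node: float = 40.0
    negative_rate: int = 8
    targets: str = "all"            # "all" | "leaves"
    synonym_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must be in [0, 1)")
        if self.query_len[0] < 1 or self.query_len[0] > self.query_len[1]:
            raise ValueError("invalid query length range")


def _format_code(digits: str) -> str:
    """Dotted digit-group formatting: '006511' -> '00.65.11'."""
    return ".".join(digits[i:i + 2] for i in range(0, len(digits), 2))


def generate_hierarchy(cfg: SynthConfig) -> CodeHierarchy:
    """Random dotted-code tree of the configured depth and fan-out."""
    rng = np.random.default_rng(cfg.seed)
    nodes: dict[str, CodeNode] = {}

    def fanout() -> int:
        return cfg.branching if cfg.branching is not None \
            else default_branching(rng)

    n_top = fanout()
    frontier: list[tuple[str, str]] = []        # (digits, code)
    for i in range(n_top):
        digits = f"{i:02d}"
        code = _format_code(digits)
        nodes[code] = CodeNode(code, None, 1, f"chapter {code}")
        frontier.append((digits, code))
    for level in range(2, cfg.depth + 1):
        nxt = []
        for digits, code in frontier:
            for j in range(fanout()):
                if j > 9:
                    break  # one appended digit per level
                cd = digits + str(j)
                ccode = _format_code(cd)
                nodes[ccode] = CodeNode(ccode, code, level,
                                        f"category {ccode}")
                nodes[code].children.append(ccode)
                nxt.append((cd, ccode))
        frontier = nxt
    return CodeHierarchy(nodes)


def _node_tokens(h: CodeHierarchy, cfg: SynthConfig) -> dict[str, list[str]]:
    """Disjoint characteristic token set per node (stable order)."""
    out = {}
    for i, code in enumerate(sorted(h.nodes)):
        out[code] = [f"w{i:05d}x{j}" for j in range(cfg.tokens_per_node)]
    return out


def _build_lexicon(tokens: dict[str, list[str]], cfg: SynthConfig,
                   rng: np.random.Generator) -> ConceptLexicon:
    t2c = {}
    sim: dict[str, list[tuple[str, float]]] = {}
    for code in sorted(tokens):
        for tok in tokens[code]:
            cid = f"c_{tok}"
            t2c[tok] = cid
            if rng.random() < cfg.synonym_fraction:
                t2c[f"syn_{tok}"] = cid
                sim[cid] = [(f"c_{tok}_rel", round(float(rng.uniform(0.3, 0.9)), 3))]
    return ConceptLexicon(t2c, sim)


def generate_query_corpus(
    h: CodeHierarchy, cfg: SynthConfig,
) -> tuple[list[QueryRecord], list[tuple[str, str]], ConceptLexicon]:
    """Query log, gold targets and lexicon for a generated hierarchy.

    Returns ``(records, gold, lexicon)`` where ``gold`` is a list of
    ``(query_text, target_code)`` pairs, one per generated query.  Each
    query's first token comes from the target node itself (so the target is
    identifiable), the rest from uniformly drawn nodes on the target's true
    path with probability ``1 - noise_rate`` and from the global vocabulary
    otherwise.  One positive record per query plus ``negative_rate``
    explicit negatives against off-path nodes.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    tokens = _node_tokens(h, cfg)
    lexicon = _build_lexicon(tokens, cfg, np.random.default_rng(cfg.seed + 2))
    vocab = [t for code in sorted(tokens) for t in tokens[code]]
    targets = sorted(h.leaves() if cfg.targets == "leaves" else h.nodes)
    all_codes = sorted(h.nodes)

    records: list[QueryRecord] = []
    gold: list[tuple[str, str]] = []
    for target in targets:
        path = ancestors_of(h, target) + [target]
        off_path = [c for c in all_codes if c not in set(path)]
        n_q = max(1, int(rng.poisson(cfg.positives_per_node)))
        for _ in range(n_q):
            length = int(rng.integers(cfg.query_len[0], cfg.query_len[1] + 1))
            toks = [tokens[target][rng.integers(len(tokens[target]))]]
            for _ in range(length - 1):
                if rng.random() < cfg.noise_rate:
                    toks.append(vocab[rng.integers(len(vocab))])
                else:
                    node = path[rng.integers(len(path))]
                    toks.append(tokens[node][rng.integers(len(tokens[node]))])
            text = " ".join(toks)
            records.append(QueryRecord(text, target, +1))
            gold.append((text, target))
            if off_path:
                for _ in range(cfg.negative_rate):
                    neg = off_path[rng.integers(len(off_path))]
                    records.append(QueryRecord(text, neg, -1))
    return records, gold, lexicon


def write_catalog(h: CodeHierarchy, path) -> None:
    rows = [(c, n.parent_id or "", n.level, n.description)
            for c, n in sorted(h.nodes.items())]
    pd.DataFrame(rows, columns=["code_id", "parent_id", "level",
                                "description"]).to_csv(path, sep="\t",
                                                       index=False)


def simulate_to_dir(cfg: SynthConfig, out_dir) -> dict:
    """Emit catalog.tsv, queries.tsv, lexicon.tsv, gold.tsv, manifest.json."""
    import json

    from .corpus import write_query_log

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = generate_hierarchy(cfg)
    records, gold, lexicon = generate_query_corpus(h, cfg)
    write_catalog(h, out / "catalog.tsv")
    write_query_log(records, out / "queries.tsv")
    lexicon.to_tsv(out / "lexicon.tsv")
    gold_rows = []
    for i, (text, code) in enumerate(gold):
        path_codes = ancestors_of(h, code) + [code]
        gold_rows.append((f"q{i:06d}", text, code, "|".join(path_codes)))
    pd.DataFrame(gold_rows, columns=["query_id", "query_text", "code_id",
                                     "true_path"]).to_csv(
        out / "gold.tsv", sep="\t", index=False)
    manifest = {"config": {**cfg.__dict__,
                           "query_len": list(cfg.query_len)},
                "n_nodes": len(h), "n_records": len(records),
                "n_queries": len(gold)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
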