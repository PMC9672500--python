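"""Query-text representations for the hierarchical classifiers.

The pipeline mirrors how short clinical search queries (2-6 terms) are
turned into classifier inputs:

1. **Bag of concepts** — tokens are mapped through a terminology lexicon to
   concept ids and enriched with similar concepts at their similarity
   weights, yielding an order-free sparse vector.
2. **Linear reduction** — an orthonormal top-variance projection (PCA with
   a deterministic sign convention) shrinks the sparse space to a tractable
   width.
3. **Stacked denoising autoencoder** — greedily pre-trained nested
   two-layer autoencoders compress the reduced vector to a dense
   representation (default 125 dimensions) fed to all base classifiers.
4. **Self-attentive encoder** — optionally, one small transformer-style
   encoder per trainable true path, pre-trained unsupervised on the pooled
   positive queries of all nodes on that path and fine-tuned on the binary
   code-matching task.

The autoencoders are plain numpy with explicit backpropagation; gradients
are covered by finite-difference checks in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = [
    "ConceptLexicon",
    "enrich_to_concepts",
    "ConceptVectorizer",
    "VarianceProjection",
    "RankError",
    "DenoisingEncoder",
    "AttentiveEncoder",
    "attention_block",
    "enumerate_true_paths",
    "fit_true_path_attentive_encoders",
    "tokenize",
]

logger = logging.getLogger(__name__)


def tokenize(text: str) -> list[str]:
    """Lowercased whitespace tokenization (no language-specific morphology)."""
    return text.lower().split()


# ---------------------------------------------------------------------------
# concept lexicon and bag-of-concepts enrichment
# ---------------------------------------------------------------------------

@dataclass
class ConceptLexicon:
    """Stand-in for a commercial terminology server.

    ``term_to_concept`` maps surface tokens to concept ids;
    ``similar`` maps a concept id to ``(similar concept id, weight)`` pairs
    with weights in ``(0, 1]``.  Self-similarity is implicit (weight 1).
    """

    term_to_concept: dict[str, str]
    similar: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, sims in self.similar.items():
            for s, w in sims:
                if not (0.0 < w <= 1.0):
                    raise ValueError(
                        f"similarity weight for {cid}->{s} must be in (0,1], "
                        f"got {w}")

    def concepts(self) -> list[str]:
        """All concept ids, sorted for a stable vector index."""
        ids = set(self.term_to_concept.values())
        for cid, sims in self.similar.items():
            ids.add(cid)
            ids.update(s for s, _ in sims)
        return sorted(ids)

    # -- TSV round trip (one file, explicit row kind) -----------------------
    @classmethod
    def from_tsv(cls, path) -> "ConceptLexicon":
        """Read a lexicon TSV with columns ``kind, key, value, weight``.

        ``kind == "term"`` rows map a term (key) to a concept id (value);
        ``kind == "similar"`` rows link a concept (key) to a similar concept
        (value) at ``weight``.
        """
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        t2c: dict[str, str] = {}
        sim: dict[str, list[tuple[str, float]]] = {}
        for row in df.itertuples(index=False):
            if row.kind == "term":
                t2c[row.key] = row.value
            elif row.kind == "similar":
                sim.setdefault(row.key, []).append((row.value, float(row.weight)))
            else:
                raise ValueError(f"unknown lexicon row kind {row.kind!r}")
        return cls(t2c, sim)

    def to_tsv(self, path) -> None:
        rows = [("term", t, c, "") for t, c in sorted(self.term_to_concept.items())]
        for cid in sorted(self.similar):
            for s, w in self.similar[cid]:
                rows.append(("similar", cid, s, repr(w)))
        pd.DataFrame(rows, columns=["kind", "key", "value", "weight"]).to_csv(
            path, sep="\t", index=False)


def enrich_to_concepts(query_text: str,
                       lexicon: ConceptLexicon) -> dict[str, float]:
    """Bag-of-concepts enrichment of one query.

    Each token that the lexicon knows contributes its concept at weight 1
    and every similar concept at its similarity weight; contributions to the
    same concept accumulate additively.  Word order plays no role; unknown
    tokens contribute nothing.
    """
    out: dict[str, float] = {}
    for tok in tokenize(query_text):
        cid = lexicon.term_to_concept.get(tok)
        if cid is None:
            continue
        out[cid] = out.get(cid, 0.0) + 1.0
        for sim_id, w in lexicon.similar.get(cid, ()):
            out[sim_id] = out.get(sim_id, 0.0) + w
    return out


class ConceptVectorizer(BaseEstimator, TransformerMixin):
    """Turn query texts into sparse concept vectors over a fixed index.

    The vector dimension is the lexicon's concept-vocabulary size; the
    index order is the sorted concept-id list, so transforms are stable
    across runs.
    """

    def __init__(self, lexicon: ConceptLexicon):
        self.lexicon = lexicon

    def fit(self, X=None, y=None):
        concepts = self.lexicon.concepts()
        self.concept_index_ = {c: i for i, c in enumerate(concepts)}
        self.n_features_ = len(concepts)
        return self

    def transform(self, X: Sequence[str]) -> sparse.csr_matrix:
        if not hasattr(self, "concept_index_"):
            self.fit()
        rows, cols, vals = [], [], []
        for i, text in enumerate(X):
            for cid, w in enrich_to_concepts(text, self.lexicon).items():
                rows.append(i)
                cols.append(self.concept_index_[cid])
                vals.append(w)
        return sparse.csr_matrix((vals, (rows, cols)),
                                 shape=(len(X), self.n_features_))


# ---------------------------------------------------------------------------
# linear top-variance projection
# ---------------------------------------------------------------------------

class RankError(ValueError):
    """Requested projection width exceeds the attainable rank."""


class VarianceProjection(BaseEstimator, TransformerMixin):
    """Orthonormal projection onto the top-variance directions.

    A thin wrapper over PCA that makes the result deterministic: each basis
    vector is flipped so its largest-magnitude component is positive.
    Degenerate inputs (rank below ``target_dim``) raise :class:`RankError`
    naming the attainable dimension.
    """

    def __init__(self, target_dim: int = 125):
        self.target_dim = target_dim

    def fit(self, X, y=None):
        X = self._densify(X)
        if self.target_dim > min(X.shape):
            raise RankError(
                f"target_dim={self.target_dim} exceeds attainable "
                f"dimension {min(X.shape)}")
        pca = PCA(n_components=self.target_dim, svd_solver="full")
        pca.fit(X)
        rank = int(np.sum(pca.explained_variance_ > 1e-12))
        if rank < self.target_dim:
            raise RankError(
                f"input rank {rank} below target_dim={self.target_dim}")
        comps = pca.components_
        flip = np.sign(comps[np.arange(len(comps)),
                             np.argmax(np.abs(comps), axis=1)])
        self.components_ = comps * flip[:, None]
        self.mean_ = pca.mean_
        self.explained_variance_ = pca.explained_variance_
        return self

    def transform(self, X):
        X = self._densify(X)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, Z):
        return np.asarray(Z) @ self.components_ + self.mean_

    @staticmethod
    def _densify(X):
        if sparse.issparse(X):
            return np.asarray(X.todense(), dtype=float)
        return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# stacked denoising autoencoder (numpy, greedy layer-wise)
# ---------------------------------------------------------------------------

class _Adam:
    """Minimal Adam optimizer over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


class DenoisingEncoder(BaseEstimator, TransformerMixin):
    """Stacked denoising autoencoder trained by greedy layer-wise pre-training.

    Each stage is a two-layer autoencoder (ReLU encoder, linear decoder,
    squared reconstruction loss) trained on the masked-out (``corruption``
    fraction zeroed) output of the previous stack; stacking the encoders
    yields the dense query representation.  The final ``layer_sizes`` entry
    is the dense dimension handed to the base classifiers (default 125).

    Attributes
    ----------
    weights_, biases_ : per-stage encoder parameters
    loss_log_ : list of per-epoch mean reconstruction losses, one per stage
    """

    def __init__(self, layer_sizes: Sequence[int] = (1000, 500, 125),
                 corruption: float = 0.1, epochs: int = 30,
                 batch_size: int = 64, lr: float = 1e-3,
                 random_state: int | None = None):
        self.layer_sizes = layer_sizes
        self.corruption = corruption
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.random_state = random_state

    def fit(self, X, y=None):
        X = VarianceProjection._densify(X)
        if X.shape[0] == 0:
            raise ValueError("cannot fit an autoencoder on an empty set")
        rng = np.random.default_rng(self.random_state)
        self.weights_, self.biases_, self.dec_weights_, self.dec_biases_ = [], [], [], []
        self.loss_log_ = []
        H = X
        for width in self.layer_sizes:
            W, b, Wd, bd, losses = self._fit_stage(H, width, rng)
            self.weights_.append(W)
            self.biases_.append(b)
            self.dec_weights_.append(Wd)
            self.dec_biases_.append(bd)
            self.loss_log_.append(losses)
            H = np.maximum(H @ W + b, 0.0)
        self.n_components_ = self.layer_sizes[-1]
        return self

    def _fit_stage(self, H, width, rng):
        n, d = H.shape
        W = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, width))
        b = np.zeros(width)
        Wd = rng.normal(0.0, np.sqrt(1.0 / width), size=(width, d))
        bd = np.zeros(d)
        opt = _Adam([W, b, Wd, bd], self.lr)
        losses = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                clean = H[idx]
                noisy = clean.copy()
                if self.corruption > 0:
                    mask = rng.random(noisy.shape) < self.corruption
                    noisy[mask] = 0.0
                Z = noisy @ W + b
                A = np.maximum(Z, 0.0)
                R = A @ Wd + bd
                diff = R - clean
                epoch_loss += float(np.sum(diff * diff))
                gR = 2.0 * diff / len(idx)
                gWd = A.T @ gR
                gbd = gR.sum(axis=0)
                gA = gR @ Wd.T
                gZ = gA * (Z > 0)
                gW = noisy.T @ gZ
                gb = gZ.sum(axis=0)
                opt.step([gW, gb, gWd, gbd])
            losses.append(epoch_loss / n)
        return W, b, Wd, bd, losses

    def transform(self, X):
        X = VarianceProjection._densify(X)
        H = X
        for W, b in zip(self.weights_, self.biases_):
            H = np.maximum(H @ W + b, 0.0)
        return H


# ---------------------------------------------------------------------------
# self-attentive encoder (one transformer block, numpy backprop)
# ---------------------------------------------------------------------------

def _softmax(S: np.ndarray) -> np.ndarray:
    S = S - S.max(axis=-1, keepdims=True)
    E = np.exp(S)
    return E / E.sum(axis=-1, keepdims=True)


def _layernorm_forward(X: np.ndarray, eps: float = 1e-6):
    mu = X.mean(axis=-1, keepdims=True)
    var = X.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    Y = (X - mu) * inv
    return Y, (X, mu, inv)


def _layernorm_backward(gY: np.ndarray, cache) -> np.ndarray:
    X, mu, inv = cache
    d = X.shape[-1]
    xhat = (X - mu) * inv
    gvar = np.sum(gY * (X - mu), axis=-1, keepdims=True) * (-0.5) * inv ** 3
    gmu = (-inv * gY.sum(axis=-1, keepdims=True)
           + gvar * (-2.0 / d) * (X - mu).sum(axis=-1, keepdims=True))
    return gY * inv + gvar * 2.0 * (X - mu) / d + gmu / d


@dataclass
class AttentiveEncoder:
    """One self-attention encoder block tied to a true path.

    Implements, per head: scaled dot-product attention
    ``softmax(QK^T / sqrt(d_k)) V`` over linear projections of the input
    sequence, a residual + layer-norm, a position-wise ReLU feed-forward of
    width ``d_f``, and a second residual + layer-norm.  Multi-head variants
    split ``d_m`` into ``n_heads`` slices and concatenate head outputs.

    Parameters live as plain arrays: ``W_q, W_k, W_v`` of shape
    ``(d_m, d_m)`` (head slices along columns), feed-forward ``W_1 (d_m,
    d_f)``, ``b_1``, ``W_2 (d_f, d_m)``, ``b_2``.
    """

    d_m: int
    d_f: int | None = None
    n_heads: int = 4
    path_id: str | None = None
    random_state: int | None = None

    def __post_init__(self):
        if self.d_f is None:
            self.d_f = 4 * self.d_m
        if self.d_m % self.n_heads:
            raise ValueError("d_m must be divisible by n_heads")
        rng = np.random.default_rng(self.random_state)
        s = np.sqrt(1.0 / self.d_m)
        self.W_q = rng.normal(0, s, (self.d_m, self.d_m))
        self.W_k = rng.normal(0, s, (self.d_m, self.d_m))
        self.W_v = rng.normal(0, s, (self.d_m, self.d_m))
        self.W_1 = rng.normal(0, s, (self.d_m, self.d_f))
        self.b_1 = np.zeros(self.d_f)
        self.W_2 = rng.normal(0, np.sqrt(1.0 / self.d_f), (self.d_f, self.d_m))
        self.b_2 = np.zeros(self.d_m)

    @property
    def d_k(self) -> int:
        return self.d_m // self.n_heads

    def params(self) -> list[np.ndarray]:
        return [self.W_q, self.W_k, self.W_v, self.W_1, self.b_1,
                self.W_2, self.b_2]

    # -- forward ------------------------------------------------------------
    def forward(self, X: np.ndarray, *, cache: bool = False):
        """Hidden sequence ``h_e`` for an ``(n, d_m)`` input sequence."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.d_m:
            raise ValueError(
                f"input must be (n, {self.d_m}), got {X.shape}")
        n = X.shape[0]
        hdim = self.d_k
        Q = X @ self.W_q
        K = X @ self.W_k
        V = X @ self.W_v
        Ah = np.empty((n, self.d_m))
        attn_caches = []
        for hslice in range(self.n_heads):
            sl = slice(hslice * hdim, (hslice + 1) * hdim)
            S = (Q[:, sl] @ K[:, sl].T) / np.sqrt(hdim)
            P = _softmax(S)
            Ah[:, sl] = P @ V[:, sl]
            attn_caches.append((P, sl))
        A1, ln1_cache = _layernorm_forward(Ah + X)          # residual + LN
        Z = A1 @ self.W_1 + self.b_1
        F = np.maximum(Z, 0.0)
        H2 = F @ self.W_2 + self.b_2
        He, ln2_cache = _layernorm_forward(H2 + A1)         # residual + LN
        if cache:
            return He, (X, Q, K, V, attn_caches, A1, ln1_cache, Z, F,
                        ln2_cache)
        return He

    def attention_weights(self, X: np.ndarray) -> np.ndarray:
        """Per-head attention matrices, shape ``(n_heads, n, n)``."""
        X = np.asarray(X, dtype=float)
        Q, K = X @ self.W_q, X @ self.W_k
        hdim = self.d_k
        out = []
        for hslice in range(self.n_heads):
            sl = slice(hslice * hdim, (hslice + 1) * hdim)
            out.append(_softmax((Q[:, sl] @ K[:, sl].T) / np.sqrt(hdim)))
        return np.stack(out)

    # -- backward -----------------------------------------------------------
    def backward(self, gHe: np.ndarray, fwd_cache) -> tuple[list[np.ndarray], np.ndarray]:
        """Gradients of all params and of the input, given dLoss/dHe."""
        X, Q, K, V, attn_caches, A1, ln1_cache, Z, F, ln2_cache = fwd_cache
        hdim = self.d_k

        gH2pA1 = _layernorm_backward(gHe, ln2_cache)
        gH2 = gH2pA1
        gA1 = gH2pA1.copy()
        gW_2 = F.T @ gH2
        gb_2 = gH2.sum(axis=0)
        gF = gH2 @ self.W_2.T
        gZ = gF * (Z > 0)
        gW_1 = A1.T @ gZ
        gb_1 = gZ.sum(axis=0)
        gA1 += gZ @ self.W_1.T

        gAhpX = _layernorm_backward(gA1, ln1_cache)
        gAh = gAhpX
        gX = gAhpX.copy()

        gQ = np.zeros_like(Q)
        gK = np.zeros_like(K)
        gV = np.zeros_like(V)
        for P, sl in attn_caches:
            gO = gAh[:, sl]
            gV[:, sl] = P.T @ gO
            gP = gO @ V[:, sl].T
            gS = P * (gP - np.sum(gP * P, axis=-1, keepdims=True))
            gS /= np.sqrt(hdim)
            gQ[:, sl] = gS @ K[:, sl]
            gK[:, sl] = gS.T @ Q[:, sl]
        gW_q = X.T @ gQ
        gW_k = X.T @ gK
        gW_v = X.T @ gV
        gX += gQ @ self.W_q.T + gK @ self.W_k.T + gV @ self.W_v.T
        return [gW_q, gW_k, gW_v, gW_1, gb_1, gW_2, gb_2], gX


def attention_block(X: np.ndarray, enc: AttentiveEncoder) -> np.ndarray:
    """Hidden sequence from one encoder block (see :class:`AttentiveEncoder`)."""
    return enc.forward(X)


# -- per-true-path training -------------------------------------------------

def enumerate_true_paths(h, trainable: Iterable[str]) -> dict[str, list[str]]:
    """Root-to-node true path for every trainable node.

    The path id is the node's own code id; the value is the full ancestor
    chain ending at the node (chapter level first).
    """
    from .hierarchy import ancestors_of

    return {c: ancestors_of(h, c) + [c] for c in sorted(trainable)}


class TruePathEncoderModel:
    """Self-attentive encoder plus heads for one true path.

    Embeds a query's concept indices, runs the attention block, mean-pools
    the hidden sequence and exposes the pooled vector as the query
    representation.  Pre-training reconstructs the uncorrupted embeddings
    from a corrupted sequence (denoising); fine-tuning optimizes a logistic
    code-matching head.
    """

    def __init__(self, enc: AttentiveEncoder, embedding: np.ndarray,
                 decoder: np.ndarray, head_w: np.ndarray, head_b: float):
        self.enc = enc
        self.embedding = embedding
        self.decoder = decoder
        self.head_w = head_w
        self.head_b = head_b

    def encode(self, token_ids: Sequence[int]) -> np.ndarray:
        X = self.embedding[list(token_ids)]
        He = self.enc.forward(X)
        return He.mean(axis=0)

    def match_probability(self, token_ids: Sequence[int]) -> float:
        z = self.encode(token_ids) @ self.head_w + self.head_b
        return float(1.0 / (1.0 + np.exp(-z)))


def fit_true_path_attentive_encoders(
    node_sets: Mapping[str, "object"],
    h,
    trainable_paths: Mapping[str, list[str]],
    *,
    vocab: Mapping[str, int],
    d_m: int = 16,
    n_heads: int = 4,
    d_f: int | None = None,
    pretrain_epochs: int = 10,
    finetune_epochs: int = 10,
    corruption: float = 0.1,
    lr: float = 1e-2,
    seed: int | None = None,
) -> dict[str, TruePathEncoderModel]:
    """Train one self-attentive encoder per trainable true path.

    The pooled training multiset of a path is the concatenation of the
    positive query lists of every node on the path, so its size is the sum
    of per-node positive counts (positives propagated upward are counted at
    each node they annotate, which is what makes deep paths trainable).
    Paths whose pooled set is empty are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, TruePathEncoderModel] = {}
    for path_id, path in trainable_paths.items():
        pooled: list[str] = []
        for code in path:
            s = node_sets.get(code)
            if s is not None:
                pooled.extend(s.positives)
        if not pooled:
            logger.warning("true path %s has no positive queries; skipped",
                           path_id)
            continue
        out[path_id] = _fit_path_encoder(
            pooled, node_sets, path, vocab, d_m, n_heads, d_f,
            pretrain_epochs, finetune_epochs, corruption, lr,
            rng.integers(0, 2**31 - 1))
    return out


def pooled_training_count(node_sets: Mapping[str, "object"],
                          path: Sequence[str]) -> int:
    """Size of the pooled per-path training multiset (sum of positives)."""
    return sum(len(node_sets[c].positives) for c in path if c in node_sets)


def _token_ids(text: str, vocab: Mapping[str, int]) -> list[int]:
    ids = [vocab[t] for t in tokenize(text) if t in vocab]
    return ids or [0]


def _fit_path_encoder(pooled, node_sets, path, vocab, d_m, n_heads, d_f,
                      pretrain_epochs, finetune_epochs, corruption, lr, seed):
    rng = np.random.default_rng(seed)
    enc = AttentiveEncoder(d_m=d_m, d_f=d_f, n_heads=n_heads,
                           path_id=path[-1], random_state=int(seed))
    E = rng.normal(0, 0.1, (len(vocab), d_m))
    D = rng.normal(0, 0.1, (d_m, d_m))     # hidden -> embedding decoder
    opt = _Adam(enc.params() + [E, D], lr)
    sequences = [_token_ids(q, vocab) for q in pooled]

    # unsupervised denoising pre-training: reconstruct clean embeddings
    for _ in range(pretrain_epochs):
        for si in rng.permutation(len(sequences)):
            ids = sequences[si]
            clean = E[ids]
            noisy = clean.copy()
            mask = rng.random(noisy.shape) < corruption
            noisy[mask] = 0.0
            He, cache = enc.forward(noisy, cache=True)
            R = He @ D
            diff = R - clean
            gHe = 2.0 * diff @ D.T / len(ids)
            gD = He.T @ (2.0 * diff) / len(ids)
            grads, gX = enc.backward(gHe, cache)
            gE = np.zeros_like(E)
            gclean = -2.0 * diff / len(ids)          # clean target term
            np.add.at(gE, ids, gX * ~mask + gclean)
            opt.step(grads + [gE, gD])

    # supervised fine-tuning: binary relevance of (query, deepest node)
    target = path[-1]
    pos = list(node_sets[target].positives) if target in node_sets else []
    neg = list(node_sets[target].negatives) if target in node_sets else []
    w = rng.normal(0, 0.1, d_m)
    b = np.zeros(1)
    if pos and neg:
        opt2 = _Adam(enc.params() + [E, w, b], lr)
        examples = [(q, 1.0) for q in pos] + [(q, 0.0) for q in neg]
        for _ in range(finetune_epochs):
            for ei in rng.permutation(len(examples)):
                q, label = examples[ei]
                ids = _token_ids(q, vocab)
                X = E[ids]
                He, cache = enc.forward(X, cache=True)
                pooled_vec = He.mean(axis=0)
                z = pooled_vec @ w + float(b[0])
                p = 1.0 / (1.0 + np.exp(-z))
                gz = p - label
                gw = gz * pooled_vec
                gb = np.array([gz])
                gHe = np.tile(gz * w / len(ids), (len(ids), 1))
                grads, gX = enc.backward(gHe, cache)
                gE = np.zeros_like(E)
                np.add.at(gE, ids, gX)
                opt2.step(grads + [gE, gw, gb])
    return TruePathEncoderModel(enc, E, D, w, float(b[0]))
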