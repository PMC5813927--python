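"""Word embeddings: skip-gram with negative sampling, and word2vec text I/O.

Embeddings are pre-trained on the full unlabeled note collection (labels are
never consulted), so that tokens occurring in similar contexts — synonyms,
abbreviations, misspellings of the same clinical term — end up with nearby
vectors. The trainer is a plain numpy SGNS implementation: deterministic
given a seed, single-threaded, batched SGD with a unigram^0.75 noise
distribution. External vectors in word2vec text format can be loaded instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .text import PAD_INDEX, Vocabulary


@dataclass
class EmbeddingTable:
    """|V| × k matrix of word vectors aligned with a :class:`Vocabulary`.

    The PAD row is identically zero so padded positions contribute nothing
    to convolutions or pooled scores.
    """

    vectors: np.ndarray  # (|V|, k) float64

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding table contains non-finite values")

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def embed(self, ids: np.ndarray) -> np.ndarray:
        return self.vectors[ids]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _init_table(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    w = (rng.random((n, k)) - 0.5) / k
    w[PAD_INDEX] = 0.0
    return w


def _collect_pairs(ids_lists: list[np.ndarray], window: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for ids in ids_lists:
        for d in range(1, window + 1):
            if len(ids) <= d:
                continue
            centers.append(ids[:-d])
            contexts.append(ids[d:])
            centers.append(ids[d:])
            contexts.append(ids[:-d])
    if not centers:
        raise ValueError("corpus too short to form any context pairs")
    return np.concatenate(centers), np.concatenate(contexts)


def train_embeddings(token_lists: Sequence[Sequence[str]], vocab: Vocabulary,
                     k: int = 100, window: int = 5, negatives: int = 5,
                     epochs: int = 5, lr: float = 0.025, seed: int = 0,
                     batch_size: int = 512,
                     subsample: float = 1e-3) -> EmbeddingTable:
    """Train SGNS embeddings on tokenized notes.

    Parameters follow the classic word2vec defaults: ``k`` vector dimension,
    symmetric context ``window``, ``negatives`` noise samples per positive
    pair, ``epochs`` full passes with per-epoch shuffling, and frequent-word
    subsampling at threshold ``subsample`` (tokens of corpus frequency f are
    kept with probability min(1, sqrt(subsample/f)); 0 disables). With
    ``epochs=0`` the seeded random initialization is returned unchanged.
    """
    if k <= 0:
        raise ValueError("embedding dimension k must be positive")
    if window <= 0:
        raise ValueError("context window must be positive")
    rng = np.random.default_rng(seed)
    n_vocab = len(vocab)
    w_in = _init_table(n_vocab, k, rng)
    if epochs == 0:
        return EmbeddingTable(vectors=w_in)
    w_out = np.zeros((n_vocab, k))

    ids_lists = [vocab.encode(toks) for toks in token_lists]
    total_tokens = sum(len(ids) for ids in ids_lists)
    # subsampling only makes sense at corpus scale; on toy corpora every
    # token is "frequent" and the discard rule would empty the stream
    if subsample > 0 and total_tokens >= 10_000:
        all_ids = np.concatenate(ids_lists)
        counts = np.bincount(all_ids, minlength=n_vocab).astype(float)
        rel = counts / counts.sum()
        keep_p = np.ones(n_vocab)
        frequent = rel > subsample
        keep_p[frequent] = np.sqrt(subsample / rel[frequent])
        ids_lists = [ids[rng.random(len(ids)) < keep_p[ids]]
                     for ids in ids_lists]
        ids_lists = [ids for ids in ids_lists if len(ids) > 1]
        if not ids_lists:
            raise ValueError("subsampling removed the entire corpus")
    centers, contexts = _collect_pairs(ids_lists, window)

    freq = np.bincount(np.concatenate(ids_lists), minlength=n_vocab).astype(float)
    freq[PAD_INDEX] = 0.0
    noise = freq ** 0.75
    noise /= noise.sum()
    noise_cdf = np.cumsum(noise)

    n_pairs = len(centers)
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            b = order[start:start + batch_size]
            c, o = centers[b], contexts[b]
            neg = np.searchsorted(noise_cdf, rng.random((len(b), negatives)))
            vc = w_in[c]                       # (B, k)
            uo = w_out[o]                      # (B, k)
            un = w_out[neg]                    # (B, neg, k)
            g_pos = _sigmoid(np.einsum("bk,bk->b", vc, uo)) - 1.0
            g_neg = _sigmoid(np.einsum("bk,bnk->bn", vc, un))
            grad_vc = g_pos[:, None] * uo + np.einsum("bn,bnk->bk", g_neg, un)
            np.add.at(w_in, c, -lr * grad_vc)
            np.add.at(w_out, o, -lr * g_pos[:, None] * vc)
            np.add.at(w_out, neg.reshape(-1),
                      -lr * (g_neg[..., None] * vc[:, None, :]).reshape(-1, k))
    w_in[PAD_INDEX] = 0.0
    if not np.all(np.isfinite(w_in)):
        raise FloatingPointError("embedding training diverged to non-finite values")
    return EmbeddingTable(vectors=w_in)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(u @ v / (nu * nv))


# ---------------------------------------------------------------------------
# word2vec text format: header "count dim", then one "token v1 ... vk" line
# per word. Values round-trip to 6 decimals.

def write_word2vec_text(table: EmbeddingTable, vocab: Vocabulary,
                        path: str | Path) -> None:
    if len(table) != len(vocab):
        raise ValueError("embedding table and vocabulary sizes differ")
    with open(path, "w") as fh:
        fh.write(f"{len(table)} {table.k}\n")
        for i, token in enumerate(vocab.index_to_token):
            vals = " ".join(f"{v:.6f}" for v in table.vectors[i])
            fh.write(f"{token} {vals}\n")


def read_word2vec_text(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Parse a word2vec text file; returns (matrix, token list)."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed header {header!r}")
        count, dim = int(header[0]), int(header[1])
        tokens: list[str] = []
        rows = np.empty((count, dim))
        for i in range(count):
            parts = fh.readline().split()
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path}: row {i} has {len(parts) - 1} values, expected {dim}")
            tokens.append(parts[0])
            rows[i] = [float(v) for v in parts[1:]]
    return rows, tokens
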