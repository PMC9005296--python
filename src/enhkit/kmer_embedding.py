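"""k-mer tokenization and word2vec-style embeddings for DNA.

A sequence of length L is split into its L - k + 1 overlapping k-mers
(stride 1, left to right), which play the role of words: a 200-bp sequence at
k = 3 becomes a 198-word sentence, and with a 200-dimensional embedding a
198 x 200 matrix. The embedding model is word2vec with both classic
architectures (CBOW: predict the center word from the averaged context;
skip-gram: predict the center word from each context word separately) and
both training objectives (hierarchical softmax over a Huffman-coded
vocabulary; negative sampling from the unigram^0.75 distribution).

The trainer is a self-contained numpy implementation using mini-batched SGD
(one batch per sentence) with a linearly decaying learning rate and dynamic
window sub-sampling as in the original word2vec: the effective window for
each center position is drawn uniformly from 1..window. Training is
single-threaded and fully deterministic for a fixed seed.

Defaults follow the configuration that wins the published parameter grid:
CBOW with hierarchical softmax, min_count = 5, window = 5, dimension 200.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import ALPHABET, DnaSequence, SequenceError, ConfigError

CBOW = "cbow"
SKIP_GRAM = "skip_gram"
HIERARCHICAL_SOFTMAX = "hierarchical_softmax"
NEGATIVE_SAMPLING = "negative_sampling"


def tokenize_kmers(seq: DnaSequence, k: int = 3) -> list[str]:
    """Overlapping k-mers of the sequence, stride 1, left to right."""
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    if len(seq) < k:
        raise SequenceError(
            f"sequence {seq.id!r}: length {len(seq)} < k={k}, cannot tokenize"
        )
    r = seq.residues
    return [r[i : i + k] for i in range(len(r) - k + 1)]


@dataclass
class KmerCorpus:
    """Per-sequence k-mer token lists ("sentences")."""

    k: int
    documents: list[list[str]]

    @classmethod
    def from_sequences(cls, sequences: Iterable[DnaSequence], k: int = 3) -> "KmerCorpus":
        return cls(k, [tokenize_kmers(s, k) for s in sequences])

    def token_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for doc in self.documents:
            for tok in doc:
                counts[tok] = counts.get(tok, 0) + 1
        return counts


@dataclass(frozen=True)
class EmbeddingConfig:
    architecture: str = CBOW
    objective: str = HIERARCHICAL_SOFTMAX
    min_count: int = 5
    window: int = 5
    dimension: int = 200
    epochs: int = 50
    learning_rate: float = 0.025
    negative: int = 5  # negatives per example (negative-sampling only)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in (CBOW, SKIP_GRAM):
            raise ConfigError(f"unknown architecture {self.architecture!r}")
        if self.objective not in (HIERARCHICAL_SOFTMAX, NEGATIVE_SAMPLING):
            raise ConfigError(f"unknown objective {self.objective!r}")
        for name in ("min_count", "window", "dimension", "epochs", "negative"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")


def _build_huffman(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Huffman codes for the vocabulary, padded to the longest code.

    Returns (points, codes, mask): for word w, points[w] are the inner-node
    indices from the root down, codes[w] the 0/1 branch taken at each, mask[w]
    flags the valid prefix. Ties in the heap break on insertion order, so the
    tree is deterministic.
    """
    v = len(counts)
    if v == 1:
        # degenerate tree: a single inner node, code length 1
        return (
            np.zeros((1, 1), dtype=np.int64),
            np.zeros((1, 1)),
            np.ones((1, 1), dtype=bool),
        )
    heap: list[tuple[int, int, int]] = [(int(c), i, i) for i, c in enumerate(counts)]
    heapq.heapify(heap)
    parent = np.zeros(2 * v - 1, dtype=np.int64)
    branch = np.zeros(2 * v - 1, dtype=np.int64)
    next_id = v
    counter = v
    while len(heap) > 1:
        c1, _, n1 = heapq.heappop(heap)
        c2, _, n2 = heapq.heappop(heap)
        parent[n1], parent[n2] = next_id, next_id
        branch[n2] = 1
        heapq.heappush(heap, (c1 + c2, counter, next_id))
        next_id += 1
        counter += 1
    root = next_id - 1
    codes_list: list[list[int]] = []
    points_list: list[list[int]] = []
    for w in range(v):
        code, point = [], []
        node = w
        while node != root:
            code.append(int(branch[node]))
            point.append(int(parent[node]) - v)  # inner nodes re-indexed from 0
            node = int(parent[node])
        codes_list.append(code[::-1])
        points_list.append(point[::-1])
    max_len = max(len(c) for c in codes_list)
    points = np.zeros((v, max_len), dtype=np.int64)
    codes = np.zeros((v, max_len))
    mask = np.zeros((v, max_len), dtype=bool)
    for w in range(v):
        ln = len(codes_list[w])
        points[w, :ln] = points_list[w]
        codes[w, :ln] = codes_list[w]
        mask[w, :ln] = True
    return points, codes, mask


@dataclass
class EmbeddingModel:
    """Trained k-mer vocabulary with d-dimensional input vectors."""

    k: int
    tokens: list[str]  # vocabulary, frequency-sorted
    vectors: np.ndarray  # (len(tokens), dimension)
    config: EmbeddingConfig

    def __post_init__(self) -> None:
        self.token_index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self.token_index

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.token_index[token]]

    def save_text(self, path: str | Path) -> None:
        """De-facto word2vec text format: header "vocab_size dim", then one
        token + vector per line."""
        lines = [f"{len(self.tokens)} {self.dimension}"]
        for tok, vec in zip(self.tokens, self.vectors):
            lines.append(tok + " " + " ".join(f"{x:.8g}" for x in vec))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load_text(cls, path: str | Path, k: int | None = None,
                  config: EmbeddingConfig | None = None) -> "EmbeddingModel":
        lines = Path(path).read_text().splitlines()
        n, dim = map(int, lines[0].split())
        tokens, rows = [], []
        for line in lines[1 : n + 1]:
            parts = line.split(" ")
            tokens.append(parts[0])
            rows.append([float(x) for x in parts[1 : dim + 1]])
        if k is None:
            k = len(tokens[0])
        if config is None:
            config = EmbeddingConfig(dimension=dim, min_count=1)
        return cls(k, tokens, np.array(rows), config)


@dataclass
class EncodedSequence:
    """Token-by-dimension matrix for one sequence; OOV rows are zero."""

    id: str
    matrix: np.ndarray  # (L - k + 1, dimension)
    mask: np.ndarray  # bool, True where the token was out of vocabulary


def _dynamic_contexts(
    n: int, window: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Context position matrix (n, 2*window) and validity mask with the
    per-center effective window drawn uniformly from 1..window."""
    offsets = np.concatenate([np.arange(-window, 0), np.arange(1, window + 1)])
    pos = np.arange(n)[:, None] + offsets[None, :]
    b = rng.integers(1, window + 1, size=n)
    valid = (pos >= 0) & (pos < n) & (np.abs(offsets)[None, :] <= b[:, None])
    return pos, valid


class _Trainer:
    def __init__(self, vocab_size: int, counts: np.ndarray, config: EmbeddingConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        d = config.dimension
        self.syn0 = (self.rng.random((vocab_size, d)) - 0.5) / d
        if config.objective == HIERARCHICAL_SOFTMAX:
            self.points, self.codes, self.path_mask = _build_huffman(counts)
            self.syn1 = np.zeros((max(vocab_size - 1, 1), d))
        else:
            self.syn1 = np.zeros((vocab_size, d))
            noise = counts.astype(float) ** 0.75
            self.noise_cdf = np.cumsum(noise / noise.sum())

    def _output_grad(self, h: np.ndarray, centers: np.ndarray, lr: float) -> np.ndarray:
        """Update output weights for a batch of hidden vectors and center
        words; return the gradient w.r.t. the hidden layer."""
        if self.cfg.objective == HIERARCHICAL_SOFTMAX:
            pts = self.points[centers]  # (B, Lmax)
            tgt = 1.0 - self.codes[centers]  # word2vec label convention
            msk = self.path_mask[centers]
        else:
            k = self.cfg.negative
            neg = np.searchsorted(
                self.noise_cdf, self.rng.random((len(centers), k)), side="right"
            )
            pts = np.concatenate([centers[:, None], neg], axis=1)
            tgt = np.zeros_like(pts, dtype=float)
            tgt[:, 0] = 1.0
            msk = np.ones_like(pts, dtype=bool)
        w = self.syn1[pts]  # (B, P, d)
        f = 1.0 / (1.0 + np.exp(-np.einsum("bd,bpd->bp", h, w)))
        g = (tgt - f) * msk * lr  # (B, P)
        dh = np.einsum("bp,bpd->bd", g, w)
        np.add.at(
            self.syn1,
            pts.ravel(),
            (g[:, :, None] * h[:, None, :]).reshape(-1, h.shape[1]),
        )
        return dh

    def train_document(self, ids: np.ndarray, lr: float) -> None:
        n = len(ids)
        if n < 2:
            return
        pos, valid = _dynamic_contexts(n, self.cfg.window, self.rng)
        if self.cfg.architecture == CBOW:
            ctx_ids = ids[np.clip(pos, 0, n - 1)]
            vecs = self.syn0[ctx_ids] * valid[:, :, None]
            n_ctx = valid.sum(axis=1)
            keep = n_ctx > 0
            h = vecs.sum(axis=1)[keep] / n_ctx[keep, None]
            dh = self._output_grad(h, ids[keep], lr)
            dctx = dh / valid[keep].sum(axis=1)[:, None]  # cbow_mean gradient
            rows, cols = np.nonzero(valid[keep])
            np.add.at(self.syn0, ctx_ids[keep][rows, cols], dctx[rows])
        else:  # skip-gram: each context word predicts the center word
            rows, cols = np.nonzero(valid)
            inputs = ids[pos[rows, cols]]
            centers = ids[rows]
            h = self.syn0[inputs]
            dh = self._output_grad(h, centers, lr)
            np.add.at(self.syn0, inputs, dh)


def train_embeddings(corpus: KmerCorpus, config: EmbeddingConfig | None = None) -> EmbeddingModel:
    """Train a word2vec model on a k-mer corpus.

    Tokens with corpus frequency below ``min_count`` are dropped from the
    vocabulary (and from sentences before windowing, as in word2vec). The
    learning rate decays linearly across epochs to 1e-4 of its initial value.
    """
    if config is None:
        config = EmbeddingConfig()
    if not corpus.documents:
        raise ConfigError("corpus is empty")
    counts_map = corpus.token_counts()
    vocab = sorted(
        (t for t, c in counts_map.items() if c >= config.min_count),
        key=lambda t: (-counts_map[t], t),
    )
    if not vocab:
        raise ConfigError(
            f"no token reaches min_count={config.min_count}; "
            "lower min_count or supply a larger corpus"
        )
    index = {t: i for i, t in enumerate(vocab)}
    counts = np.array([counts_map[t] for t in vocab])
    docs = [
        np.array([index[t] for t in doc if t in index], dtype=np.int64)
        for doc in corpus.documents
    ]
    trainer = _Trainer(len(vocab), counts, config)
    lr0, lr_min = config.learning_rate, config.learning_rate * 1e-4
    for epoch in range(config.epochs):
        lr = lr0 + (lr_min - lr0) * epoch / max(config.epochs - 1, 1)
        for ids in docs:
            trainer.train_document(ids, lr)
    return EmbeddingModel(corpus.k, vocab, trainer.syn0, config)


def encode_sequence(seq: DnaSequence, model: EmbeddingModel, k: int | None = None) -> EncodedSequence:
    """Stack the model vectors of the sequence's k-mers into a matrix.

    Out-of-vocabulary tokens produce a zero row with the mask flag set, so a
    200-bp sequence at k=3 and d=200 always yields a 198 x 200 matrix.
    """
    if k is None:
        k = model.k
    tokens = tokenize_kmers(seq, k)
    matrix = np.zeros((len(tokens), model.dimension))
    mask = np.zeros(len(tokens), dtype=bool)
    for i, tok in enumerate(tokens):
        if tok in model:
            matrix[i] = model.vector(tok)
        else:
            mask[i] = True
    return EncodedSequence(seq.id, matrix, mask)
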