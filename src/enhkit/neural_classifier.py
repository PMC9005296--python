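"""Classification heads: attention Bi-LSTM and random forest.

Two model families sit on top of the feature machinery:

* identification head — a random forest over (optionally screened and
  rank-selected) dinucleotide auto-cross covariance features, separating
  enhancers from non-enhancers;
* classification head — an attention-based bidirectional LSTM over k-mer
  embedding matrices, separating strong from weak enhancers.

The recurrent model is a self-contained numpy implementation. One LSTM step
(gates f, i, o and candidate state C~, hidden size H, input size d):

    f_t = sigma(W_f [h_{t-1}, x_t] + b_f)
    i_t = sigma(W_i [h_{t-1}, x_t] + b_i)
    C~_t = tanh(W_C [h_{t-1}, x_t] + b_C)
    C_t = f_t * C_{t-1} + i_t * C~_t
    o_t = sigma(W_o [h_{t-1}, x_t] + b_o)
    h_t = o_t * tanh(C_t)

The bidirectional encoder runs one LSTM forward and an independent LSTM
backward from zero initial states and merges per position by elementwise sum
(not concatenation): h_i = h_i(fwd) + h_i(bwd). Self-attention pooling takes
query, key and value all equal to the hidden sequence, with the query pooled
as the mean hidden state: similarities are dot products s_i = h_i . q,
weights alpha = softmax(s), context = sum_i alpha_i h_i. A single dense layer
with a sigmoid yields the positive-class score, thresholded at 0.5.

Training is full-batch-per-minibatch BPTT with the Adam optimizer and early
stopping on validation MCC; deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import dacc, feature_selection, kmer_embedding, property_screening
from .evaluation import mcc_from_labels
from .kmer_embedding import EmbeddingConfig, EmbeddingModel, EncodedSequence, KmerCorpus
from .property_index import PropertyTable
from .sequence_io import (
    NON_ENHANCER,
    STRONG_ENHANCER,
    WEAK_ENHANCER,
    ConfigError,
    DnaSequence,
    LabeledDataset,
)

ENHANCER = "enhancer"

_GATES = ("forget", "input", "candidate", "output")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class LstmParams:
    """Combined gate weights: w has shape (H + d, 4H) acting on [h_prev, x];
    b has shape (4H,). Gate order along the last axis: f, i, C~, o."""

    w: np.ndarray
    b: np.ndarray
    hidden: int

    def __post_init__(self) -> None:
        h = self.hidden
        if self.w.ndim != 2 or self.w.shape[1] != 4 * h or self.b.shape != (4 * h,):
            raise ConfigError(
                f"inconsistent LSTM shapes: w{self.w.shape}, b{self.b.shape}, H={h}"
            )

    @property
    def input_dim(self) -> int:
        return self.w.shape[0] - self.hidden

    def gate(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(W, b) slice for one named gate, for inspection."""
        if name not in _GATES:
            raise ConfigError(f"unknown gate {name!r}; expected one of {_GATES}")
        g = _GATES.index(name)
        h = self.hidden
        return self.w[:, g * h : (g + 1) * h], self.b[g * h : (g + 1) * h]

    @classmethod
    def initialize(cls, input_dim: int, hidden: int, rng: np.random.Generator) -> "LstmParams":
        scale = 1.0 / np.sqrt(input_dim + hidden)
        w = rng.uniform(-scale, scale, size=(hidden + input_dim, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[:hidden] = 1.0  # forget-gate bias 1: retain memory early in training
        return cls(w, b, hidden)


@dataclass
class LstmState:
    """c: cell state ("long-term memory"); h: hidden state ("short-term")."""

    c: np.ndarray
    h: np.ndarray


def lstm_step(x_t: np.ndarray, prev: LstmState, params: LstmParams) -> LstmState:
    """One LSTM time step; accepts a single vector or a batch (B, d)."""
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(prev.h)
    c_prev = np.atleast_2d(prev.c)
    hdim = params.hidden
    if x_t.shape[1] != params.input_dim:
        raise ConfigError(
            f"input size {x_t.shape[1]} does not match gate weights "
            f"(expected {params.input_dim})"
        )
    if h_prev.shape[1] != hdim or c_prev.shape[1] != hdim:
        raise ConfigError("previous state size does not match hidden size")
    z = np.concatenate([h_prev, x_t], axis=1) @ params.w + params.b
    f = _sigmoid(z[:, :hdim])
    i = _sigmoid(z[:, hdim : 2 * hdim])
    g = np.tanh(z[:, 2 * hdim : 3 * hdim])
    o = _sigmoid(z[:, 3 * hdim :])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    if np.asarray(prev.h).ndim == 1:
        return LstmState(c[0], h[0])
    return LstmState(c, h)


def zero_state(hidden: int, batch: int | None = None) -> LstmState:
    shape = (hidden,) if batch is None else (batch, hidden)
    return LstmState(np.zeros(shape), np.zeros(shape))


def _lstm_forward(x: np.ndarray, params: LstmParams) -> tuple[np.ndarray, dict]:
    """Run the LSTM over a batch (B, T, d); returns hidden states (B, T, H)
    and the cache needed for backpropagation through time."""
    bsz, t_len, _ = x.shape
    hdim = params.hidden
    h = np.zeros((bsz, hdim))
    c = np.zeros((bsz, hdim))
    cache = {"x": x, "f": [], "i": [], "g": [], "o": [], "c": [], "tanh_c": [], "h_prev": [], "c_prev": []}
    hs = np.empty((bsz, t_len, hdim))
    for t in range(t_len):
        z = np.concatenate([h, x[:, t]], axis=1) @ params.w + params.b
        f = _sigmoid(z[:, :hdim])
        i = _sigmoid(z[:, hdim : 2 * hdim])
        g = np.tanh(z[:, 2 * hdim : 3 * hdim])
        o = _sigmoid(z[:, 3 * hdim :])
        cache["h_prev"].append(h)
        cache["c_prev"].append(c)
        c = f * c + i * g
        tanh_c = np.tanh(c)
        h = o * tanh_c
        hs[:, t] = h
        for key, val in zip(("f", "i", "g", "o", "c", "tanh_c"), (f, i, g, o, c, tanh_c)):
            cache[key].append(val)
    return hs, cache


def _lstm_backward(
    d_hs: np.ndarray, params: LstmParams, cache: dict
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dW, db, dX) from per-step hidden-state gradients."""
    x = cache["x"]
    bsz, t_len, _ = x.shape
    hdim = params.hidden
    dw = np.zeros_like(params.w)
    db = np.zeros_like(params.b)
    dx = np.zeros_like(x)
    dh_next = np.zeros((bsz, hdim))
    dc_next = np.zeros((bsz, hdim))
    for t in range(t_len - 1, -1, -1):
        f, i, g, o = (cache[k][t] for k in ("f", "i", "g", "o"))
        tanh_c = cache["tanh_c"][t]
        dh = d_hs[:, t] + dh_next
        do = dh * tanh_c
        dc = dh * o * (1 - tanh_c**2) + dc_next
        df = dc * cache["c_prev"][t]
        di = dc * g
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [df * f * (1 - f), di * i * (1 - i), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        concat = np.concatenate([cache["h_prev"][t], x[:, t]], axis=1)
        dw += concat.T @ dz
        db += dz.sum(axis=0)
        dconcat = dz @ params.w.T
        dh_next = dconcat[:, :hdim]
        dx[:, t] = dconcat[:, hdim:]
    return dw, db, dx


def bilstm_encode(
    encoded: EncodedSequence | np.ndarray, fwd: LstmParams, bwd: LstmParams
) -> np.ndarray:
    """Bidirectional encoding of one sequence: per-position elementwise sum
    of the forward and backward hidden states, shape (T, H)."""
    x = encoded.matrix if isinstance(encoded, EncodedSequence) else np.asarray(encoded, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ConfigError("bilstm_encode requires a nonempty (T, d) input")
    xb = x[None, :, :]
    h_f, _ = _lstm_forward(xb, fwd)
    h_b, _ = _lstm_forward(xb[:, ::-1], bwd)
    return h_f[0] + h_b[0, ::-1]


@dataclass
class AttentionContext:
    """Normalized attention weights (one per time step) and the pooled
    context vector sum_i alpha_i h_i."""

    weights: np.ndarray
    context: np.ndarray


def attention_pool(h_seq: np.ndarray) -> AttentionContext:
    """Self-attention pooling with the mean hidden state as query."""
    h = np.asarray(h_seq, dtype=float)
    if h.ndim != 2 or h.shape[0] == 0:
        raise ConfigError("attention_pool requires a nonempty (T, H) input")
    q = h.mean(axis=0)
    s = h @ q
    s = s - s.max()
    alpha = np.exp(s)
    alpha /= alpha.sum()
    return AttentionContext(alpha, alpha @ h)


@dataclass(frozen=True)
class NeuralConfig:
    hidden: int = 128
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    patience: int = 8  # early-stopping patience, epochs without val MCC gain
    validation_fraction: float = 0.15
    seed: int = 0


class _Adam:
    def __init__(self, shapes: list[tuple[int, ...]], lr: float):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class AttentionBiLstm:
    """Binary attention Bi-LSTM classifier over fixed-length encodings.

    ``fit`` takes a (n, T, d) array and 0/1 targets; scores are sigmoid
    outputs for the positive class, decisions threshold at 0.5.
    """

    def __init__(self, config: NeuralConfig | None = None):
        self.config = config or NeuralConfig()
        self.fwd: LstmParams | None = None
        self.bwd: LstmParams | None = None
        self.w_out: np.ndarray | None = None
        self.b_out: float = 0.0
        self.loss_history: list[float] = []

    # -- forward/backward over a batch ------------------------------------
    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        h_f, cache_f = _lstm_forward(x, self.fwd)
        h_b_rev, cache_b = _lstm_forward(x[:, ::-1], self.bwd)
        h = h_f + h_b_rev[:, ::-1]
        t_len = h.shape[1]
        q = h.mean(axis=1)
        s = np.einsum("bth,bh->bt", h, q)
        s = s - s.max(axis=1, keepdims=True)
        alpha = np.exp(s)
        alpha /= alpha.sum(axis=1, keepdims=True)
        ctx = np.einsum("bt,bth->bh", alpha, h)
        logits = ctx @ self.w_out + self.b_out
        cache = {
            "cache_f": cache_f, "cache_b": cache_b, "h": h, "q": q,
            "alpha": alpha, "ctx": ctx, "t_len": t_len,
        }
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache: dict) -> list[np.ndarray]:
        h, q, alpha, ctx = cache["h"], cache["q"], cache["alpha"], cache["ctx"]
        t_len = cache["t_len"]
        dw_out = ctx.T @ dlogits
        db_out = dlogits.sum()
        dctx = dlogits[:, None] * self.w_out[None, :]
        dalpha = np.einsum("bh,bth->bt", dctx, h)
        dh = alpha[:, :, None] * dctx[:, None, :]
        ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        dh += ds[:, :, None] * q[:, None, :]
        dq = np.einsum("bt,bth->bh", ds, h)
        dh += dq[:, None, :] / t_len
        dw_f, db_f, _ = _lstm_backward(dh, self.fwd, cache["cache_f"])
        dw_b, db_b, _ = _lstm_backward(dh[:, ::-1], self.bwd, cache["cache_b"])
        return [dw_f, db_f, dw_b, db_b, dw_out, np.array(db_out)]

    def _loss_and_grads(
        self, x: np.ndarray, y: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        logits, cache = self._forward(x)
        p = _sigmoid(logits)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        dlogits = (p - y) / len(y)
        return loss, self._backward(dlogits, cache)

    # -- training ----------------------------------------------------------
    def fit(self, x: np.ndarray, y: np.ndarray) -> "AttentionBiLstm":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 3:
            raise ConfigError("fit expects encodings of shape (n, T, d)")
        if len(np.unique(y)) < 2:
            raise ConfigError("training set must contain both classes")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        d = x.shape[2]
        self.fwd = LstmParams.initialize(d, cfg.hidden, rng)
        self.bwd = LstmParams.initialize(d, cfg.hidden, rng)
        self.w_out = rng.uniform(-0.1, 0.1, size=cfg.hidden)
        self.b_out = 0.0

        # stratified validation split for early stopping
        n = len(y)
        n_val = max(2, int(round(cfg.validation_fraction * n)))
        order = rng.permutation(n)
        pos = [i for i in order if y[i] == 1]
        neg = [i for i in order if y[i] == 0]
        n_val_pos = max(1, int(round(n_val * len(pos) / n)))
        n_val_neg = max(1, n_val - n_val_pos)
        val_idx = np.array(pos[:n_val_pos] + neg[:n_val_neg])
        train_idx = np.array(pos[n_val_pos:] + neg[n_val_neg:])
        x_tr, y_tr = x[train_idx], y[train_idx]
        x_val, y_val = x[val_idx], y[val_idx]

        params = [self.fwd.w, self.fwd.b, self.bwd.w, self.bwd.b, self.w_out]
        adam = _Adam([p.shape for p in params] + [()], cfg.learning_rate)
        best_mcc, best_epoch = -np.inf, -1
        best_weights: list[np.ndarray] | None = None
        self.loss_history = []
        for epoch in range(cfg.epochs):
            perm = rng.permutation(len(y_tr))
            epoch_loss = 0.0
            for start in range(0, len(perm), cfg.batch_size):
                idx = perm[start : start + cfg.batch_size]
                loss, grads = self._loss_and_grads(x_tr[idx], y_tr[idx])
                epoch_loss += loss * len(idx)
                flat = [self.fwd.w, self.fwd.b, self.bwd.w, self.bwd.b, self.w_out]
                b_holder = np.array(self.b_out)
                adam.step(flat + [b_holder], grads)
                self.b_out = float(b_holder)
            self.loss_history.append(epoch_loss / len(y_tr))
            val_pred = (self.decision_scores(x_val) >= 0.5).astype(float)
            mcc = mcc_from_labels(
                [str(v) for v in y_val], [str(v) for v in val_pred], "1.0"
            )
            if mcc > best_mcc:
                best_mcc, best_epoch = mcc, epoch
                best_weights = [
                    self.fwd.w.copy(), self.fwd.b.copy(),
                    self.bwd.w.copy(), self.bwd.b.copy(),
                    self.w_out.copy(), np.array(self.b_out),
                ]
            elif epoch - best_epoch >= cfg.patience:
                break
        if best_weights is not None:
            self.fwd.w[:], self.fwd.b[:] = best_weights[0], best_weights[1]
            self.bwd.w[:], self.bwd.b[:] = best_weights[2], best_weights[3]
            self.w_out[:] = best_weights[4]
            self.b_out = float(best_weights[5])
        return self

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        """Positive-class sigmoid scores, shape (n,)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 3:
            raise ConfigError("expected encodings of shape (n, T, d)")
        out = np.empty(len(x))
        for start in range(0, len(x), 256):
            logits, _ = self._forward(x[start : start + 256])
            out[start : start + 256] = _sigmoid(logits)
        return out


# --- end-to-end pipelines --------------------------------------------------


@dataclass
class IdentifierConfig:
    """Random-forest identification head over DACC features."""

    lag: int = 5
    screen: property_screening.ScreeningConfig | None = None
    select_k: int | None = 791  # truncated to the column count when larger
    n_trees: int = 500
    seed: int = 0


class EnhancerIdentifier:
    """enhancer vs non-enhancer: screened DACC features -> random forest."""

    def __init__(self, table: PropertyTable, config: IdentifierConfig | None = None):
        self.table = table
        self.config = config or IdentifierConfig()
        self.ranking: feature_selection.FeatureRanking | None = None
        self.columns: list[str] | None = None

    @staticmethod
    def binarize(labels: Sequence[str]) -> list[str]:
        return [NON_ENHANCER if lab == NON_ENHANCER else ENHANCER for lab in labels]

    def fit(self, train: LabeledDataset) -> "EnhancerIdentifier":
        cfg = self.config
        if cfg.screen is not None:
            selected = property_screening.screen_properties(self.table, cfg.screen).selected
            self.properties = tuple(selected)
        else:
            self.properties = tuple(self.table.names)
        self.dacc_config = dacc.DaccConfig(self.properties, cfg.lag)
        matrix = dacc.dacc_matrix(train, self.dacc_config, self.table)
        y = self.binarize(train.labels)
        if len(set(y)) < 2:
            raise ConfigError("training set must contain enhancers and non-enhancers")
        if cfg.select_k is not None and matrix.shape[1] > 2:
            self.ranking = feature_selection.rank_features(matrix, y)
            k = min(cfg.select_k, matrix.shape[1])
            matrix = feature_selection.select_top(matrix, self.ranking, k)
        self.columns = list(matrix.columns)
        self.forest = RandomForestClassifier(
            n_estimators=cfg.n_trees, max_features="sqrt", random_state=cfg.seed
        )
        self.forest.fit(matrix.to_numpy(), y)
        return self

    def _features(self, sequences: Sequence[DnaSequence]) -> np.ndarray:
        ds = LabeledDataset(list(sequences), [""] * len(sequences))
        matrix = dacc.dacc_matrix(ds, self.dacc_config, self.table)
        return matrix[self.columns].to_numpy()

    def predict(self, sequences: Sequence[DnaSequence]) -> list[str]:
        return list(self.forest.predict(self._features(sequences)))

    def predict_scores(self, sequences: Sequence[DnaSequence]) -> np.ndarray:
        """Probability of the enhancer class."""
        proba = self.forest.predict_proba(self._features(sequences))
        pos = list(self.forest.classes_).index(ENHANCER)
        return proba[:, pos]


@dataclass
class ClassifierConfig:
    """Attention Bi-LSTM classification head over k-mer embeddings."""

    k: int = 3
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    neural: NeuralConfig = field(default_factory=NeuralConfig)
    train_embeddings_on: str = "train"  # "train" only (no leakage) by default


class EnhancerClassifier:
    """strong vs weak enhancer: k-mer word2vec -> attention Bi-LSTM."""

    positive_label = STRONG_ENHANCER

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self.embedding: EmbeddingModel | None = None
        self.net: AttentionBiLstm | None = None

    def _encode(self, sequences: Sequence[DnaSequence]) -> np.ndarray:
        mats = [
            kmer_embedding.encode_sequence(s, self.embedding, self.config.k).matrix
            for s in sequences
        ]
        lengths = {m.shape[0] for m in mats}
        if len(lengths) > 1:
            raise ConfigError(
                "the Bi-LSTM head requires equal-length sequences in a batch; "
                f"got token counts {sorted(lengths)}"
            )
        return np.stack(mats)

    def fit(self, train: LabeledDataset) -> "EnhancerClassifier":
        keep = [
            i for i, lab in enumerate(train.labels)
            if lab in (STRONG_ENHANCER, WEAK_ENHANCER)
        ]
        subset = train.subset(keep)
        if len(set(subset.labels)) < 2:
            raise ConfigError(
                "training set must contain both strong and weak enhancers"
            )
        corpus = KmerCorpus.from_sequences(subset.sequences, self.config.k)
        self.embedding = kmer_embedding.train_embeddings(corpus, self.config.embedding)
        x = self._encode(subset.sequences)
        y = np.array([1.0 if lab == STRONG_ENHANCER else 0.0 for lab in subset.labels])
        self.net = AttentionBiLstm(self.config.neural).fit(x, y)
        return self

    def predict_scores(self, sequences: Sequence[DnaSequence]) -> np.ndarray:
        """Probability of the strong-enhancer class."""
        return self.net.decision_scores(self._encode(sequences))

    def predict(self, sequences: Sequence[DnaSequence]) -> list[str]:
        scores = self.predict_scores(sequences)
        return [
            STRONG_ENHANCER if s >= 0.5 else WEAK_ENHANCER for s in scores
        ]


def train_classifier(
    train: LabeledDataset,
    model_config: IdentifierConfig | ClassifierConfig,
    table: PropertyTable | None = None,
):
    """Train either head from its config; returns the fitted pipeline."""
    if isinstance(model_config, IdentifierConfig):
        if table is None:
            raise ConfigError("the identification head requires a property table")
        return EnhancerIdentifier(table, model_config).fit(train)
    if isinstance(model_config, ClassifierConfig):
        return EnhancerClassifier(model_config).fit(train)
    raise ConfigError(f"unknown model config type {type(model_config).__name__}")


def predict(classifier, sequences: Sequence[DnaSequence]) -> tuple[list[str], np.ndarray]:
    """Labels and positive-class scores from a fitted pipeline."""
    return classifier.predict(sequences), classifier.predict_scores(sequences)
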