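"""Convolutional text classifier for per-phenotype note classification.

Architecture: each note is embedded token-by-token (x_i in R^k); filter banks
of widths h in {1..5} slide over the token windows, computing
c_i = relu(w · x_{i:i+h-1} + b) to form one feature map per filter; each map
is reduced by max-over-time pooling to its single strongest activation
c_hat = max(c); the pooled values z = [c_hat_1, ..., c_hat_m] from all
filters feed a sigmoid output y = sigmoid(w_out · z + b_out). One model is
trained per phenotype by minimizing the binary negative log-likelihood with
mini-batch Adam, dropout on z, and early stopping on validation F1.

Forward and backward passes are hand-written numpy. The backward pass routes
gradients only through each filter's argmax window (ties broken toward the
lowest index) and through active ReLU units, and optionally into the
embedding table when fine-tuning is enabled. Gradient correctness is
enforced by finite-difference tests rather than trusted.

Padding: notes shorter than the widest filter are right-padded with the PAD
token, whose embedding row is zero; windows consisting solely of padding are
excluded from pooling and argmax reporting.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .embeddings import EmbeddingTable, write_word2vec_text, read_word2vec_text
from .text import PAD_INDEX, Vocabulary


def _sigmoid(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _nll(logits: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary NLL from logits, computed in log space."""
    z, y = np.asarray(logits, dtype=float), np.asarray(targets, dtype=float)
    softplus = np.where(z > 0, z + np.log1p(np.exp(-np.abs(z))),
                        np.log1p(np.exp(np.minimum(z, 0))))
    return float(np.mean(softplus - y * z))


@dataclass(frozen=True)
class CNNConfig:
    widths: tuple[int, ...] = (1, 2, 3, 4, 5)
    filters_per_width: int = 100
    k: int = 100
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0
    fine_tune_embeddings: bool = True
    patience: int = 5

    def __post_init__(self) -> None:
        if not self.widths or any(h < 1 or h > 5 for h in self.widths):
            raise ValueError("widths must be a non-empty subset of {1..5}")
        if self.filters_per_width < 1:
            raise ValueError("filters_per_width must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class NoteForward:
    """Cached single-note forward pass for saliency computations."""

    y: float
    logit: float
    z: np.ndarray                      # (m,) pooled values, fixed filter order
    feature_maps: dict[int, np.ndarray]   # width -> (n_windows, m_h), post-ReLU
    pre_activations: dict[int, np.ndarray]
    argmax: dict[int, np.ndarray]      # width -> (m_h,) argmax window index
    windows: dict[int, np.ndarray]     # width -> (n_windows, h*k) inputs
    ids: np.ndarray
    n_tokens: int                      # true (unpadded) length


class ConvModel:
    """Trained per-phenotype CNN: embedding table, per-width filter banks,
    and the sigmoid output layer. Filter order (widths ascending, filter
    index within width) is part of the model and survives save/load."""

    def __init__(self, config: CNNConfig, embeddings: np.ndarray,
                 filters: dict[int, np.ndarray], biases: dict[int, np.ndarray],
                 w_out: np.ndarray, b_out: float):
        self.config = config
        self.embeddings = embeddings          # (V, k)
        self.filters = filters                # width -> (h*k, m_h)
        self.biases = biases                  # width -> (m_h,)
        self.w_out = w_out                    # (m,)
        self.b_out = b_out
        self.widths = tuple(sorted(filters))
        m = sum(f.shape[1] for f in filters.values())
        if w_out.shape != (m,):
            raise ValueError("output weight length must equal total filter count")

    # -- construction -------------------------------------------------------

    @classmethod
    def initialize(cls, config: CNNConfig, embeddings: np.ndarray) -> "ConvModel":
        rng = np.random.default_rng(config.seed)
        k = embeddings.shape[1]
        filters, biases = {}, {}
        for h in sorted(set(config.widths)):
            fan_in = h * k
            filters[h] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                    size=(fan_in, config.filters_per_width))
            biases[h] = np.zeros(config.filters_per_width)
        m = len(filters) * config.filters_per_width
        w_out = rng.normal(0.0, 0.01, size=m)
        return cls(config, embeddings.copy(), filters, biases, w_out, 0.0)

    @property
    def n_filters(self) -> int:
        return sum(f.shape[1] for f in self.filters.values())

    def filter_slices(self) -> dict[int, slice]:
        """Position of each width's pooled block inside z."""
        out, start = {}, 0
        for h in self.widths:
            m_h = self.filters[h].shape[1]
            out[h] = slice(start, start + m_h)
            start += m_h
        return out

    # -- forward -------------------------------------------------------------

    def _pad(self, ids: np.ndarray) -> np.ndarray:
        need = max(self.widths)
        if len(ids) >= need:
            return ids
        return np.concatenate([ids, np.full(need - len(ids), PAD_INDEX)])

    def forward_note(self, ids: np.ndarray) -> NoteForward:
        """Full forward pass on one note with all intermediates cached."""
        n_true = len(ids)
        ids = self._pad(np.asarray(ids, dtype=np.int64))
        X = self.embeddings[ids]              # (n, k)
        n, k = X.shape
        maps, pres, args, wins, pooled = {}, {}, {}, {}, []
        for h in self.widths:
            win = sliding_window_view(X, h, axis=0)       # (nw, k, h)
            win = win.transpose(0, 2, 1).reshape(-1, h * k)  # (nw, h*k)
            pre = win @ self.filters[h] + self.biases[h]  # (nw, m_h)
            cmap = np.maximum(pre, 0.0)
            nw = cmap.shape[0]
            # natural windows end at the true length; keep one partially
            # padded window only when the note is shorter than the filter
            valid = min(max(n_true - h + 1, 1), nw)
            masked = cmap[:valid]
            arg = masked.argmax(axis=0)
            maps[h], pres[h], args[h], wins[h] = cmap, pre, arg, win
            pooled.append(masked.max(axis=0))
        z = np.concatenate(pooled)
        logit = float(z @ self.w_out + self.b_out)
        return NoteForward(y=float(_sigmoid(logit)), logit=logit, z=z,
                           feature_maps=maps, pre_activations=pres, argmax=args,
                           windows=wins, ids=ids, n_tokens=n_true)

    def _forward_batch(self, ids: np.ndarray, lengths: np.ndarray):
        """Vectorized forward over a padded batch; returns logits + caches."""
        X = self.embeddings[ids]              # (B, n, k)
        B, n, k = X.shape
        pooled, args, caches = [], {}, {}
        for h in self.widths:
            win = sliding_window_view(X, h, axis=1)         # (B, nw, k, h)
            win = win.transpose(0, 1, 3, 2).reshape(B, -1, h * k)
            pre = win @ self.filters[h] + self.biases[h]    # (B, nw, m_h)
            cmap = np.maximum(pre, 0.0)
            nw = cmap.shape[1]
            # mask windows extending past the true length (keep one partially
            # padded window when the note is shorter than the filter)
            starts = np.arange(nw)[None, :]
            invalid = starts >= np.maximum(lengths - h + 1, 1)[:, None]
            cmap = np.where(invalid[:, :, None], -1.0, cmap)
            arg = cmap.argmax(axis=1)                       # (B, m_h)
            pooled.append(np.take_along_axis(cmap, arg[:, None, :], axis=1)[:, 0, :])
            args[h] = arg
            caches[h] = (win, pre)
        z = np.concatenate(pooled, axis=1)                  # (B, m)
        logits = z @ self.w_out + self.b_out
        return logits, z, args, caches

    def predict_proba(self, notes: Sequence[np.ndarray],
                      chunk: int = 64) -> np.ndarray:
        """Probabilities for a list of variable-length encoded notes."""
        out = np.empty(len(notes))
        order = np.argsort([len(n) for n in notes], kind="stable")
        for start in range(0, len(notes), chunk):
            sel = order[start:start + chunk]
            ids, lengths = _pad_batch([notes[i] for i in sel], max(self.widths))
            logits, _, _, _ = self._forward_batch(ids, lengths)
            out[sel] = _sigmoid(logits)
        return out

    # -- gradients -----------------------------------------------------------

    def loss_and_grads(self, ids: np.ndarray, lengths: np.ndarray,
                       targets: np.ndarray,
                       dropout_rng: np.random.Generator | None = None):
        """Mean NLL over the batch and gradients for every parameter.

        Returns (loss, grads) with grads keyed 'W{h}', 'b{h}', 'w_out',
        'b_out', and 'emb' when fine-tuning.
        """
        cfg = self.config
        B, n = ids.shape
        logits, z, args, caches = self._forward_batch(ids, lengths)
        if dropout_rng is not None and cfg.dropout_rate > 0.0:
            keep = (dropout_rng.random(z.shape) >= cfg.dropout_rate)
            z_used = z * keep / (1.0 - cfg.dropout_rate)
            logits = z_used @ self.w_out + self.b_out
        else:
            keep = None
            z_used = z
        targets = np.asarray(targets, dtype=float)
        loss = _nll(logits, targets)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")

        dlogit = (_sigmoid(logits) - targets) / B           # (B,)
        grads: dict[str, np.ndarray | float] = {
            "w_out": z_used.T @ dlogit,
            "b_out": float(dlogit.sum()),
        }
        dz = np.outer(dlogit, self.w_out)
        if keep is not None:
            dz = dz * keep / (1.0 - cfg.dropout_rate)

        demb = np.zeros_like(self.embeddings) if cfg.fine_tune_embeddings else None
        slices = self.filter_slices()
        k = self.embeddings.shape[1]
        for h in self.widths:
            win, pre = caches[h]
            m_h = pre.shape[2]
            nw = pre.shape[1]
            dpool = dz[:, slices[h]]                        # (B, m_h)
            dmap = np.zeros_like(pre)
            bi = np.arange(B)[:, None]
            fi = np.arange(m_h)[None, :]
            dmap[bi, args[h], fi] = dpool
            dmap *= (pre > 0)
            flat_win = win.reshape(B * nw, h * k)
            flat_dmap = dmap.reshape(B * nw, m_h)
            grads[f"W{h}"] = flat_win.T @ flat_dmap
            grads[f"b{h}"] = flat_dmap.sum(axis=(0))
            if demb is not None:
                dwin = (dmap @ self.filters[h].T).reshape(B, nw, h, k)
                dX = np.zeros((B, n, k))
                for o in range(h):
                    dX[:, o:o + nw, :] += dwin[:, :, o, :]
                np.add.at(demb, ids.reshape(-1), dX.reshape(-1, k))
        if demb is not None:
            demb[PAD_INDEX] = 0.0
            grads["emb"] = demb
        return loss, grads

    # -- persistence ---------------------------------------------------------

    def save(self, out_dir: str | Path, vocab: Vocabulary | None = None) -> None:
        """Checkpoint: config JSON, parameter JSON (nested lists, full float
        precision), and — when a vocabulary is supplied — embeddings in
        word2vec text format alongside the exact float64 copy in params."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2, sort_keys=True)
        params = {
            "widths": list(self.widths),
            "filters": {str(h): self.filters[h].tolist() for h in self.widths},
            "biases": {str(h): self.biases[h].tolist() for h in self.widths},
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out,
            "embeddings": self.embeddings.tolist(),
        }
        with open(out / "params.json", "w") as fh:
            json.dump(params, fh, sort_keys=True)
        if vocab is not None:
            write_word2vec_text(EmbeddingTable(vectors=self.embeddings),
                                vocab, out / "embeddings.txt")

    @classmethod
    def load(cls, in_dir: str | Path) -> "ConvModel":
        src = Path(in_dir)
        with open(src / "config.json") as fh:
            raw = json.load(fh)
        raw["widths"] = tuple(raw["widths"])
        config = CNNConfig(**raw)
        with open(src / "params.json") as fh:
            params = json.load(fh)
        filters = {int(h): np.asarray(v) for h, v in params["filters"].items()}
        biases = {int(h): np.asarray(v) for h, v in params["biases"].items()}
        return cls(config, np.asarray(params["embeddings"]), filters, biases,
                   np.asarray(params["w_out"]), float(params["b_out"]))


def _pad_batch(notes: list[np.ndarray], min_len: int
               ) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([len(x) for x in notes], dtype=np.int64)
    width = max(int(lengths.max()), min_len)
    ids = np.full((len(notes), width), PAD_INDEX, dtype=np.int64)
    for i, x in enumerate(notes):
        ids[i, :len(x)] = x
    return ids, lengths


class _Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray | float] = {}
        self.v: dict[str, np.ndarray | float] = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for key, g in grads.items():
            if key not in self.m:
                self.m[key] = np.zeros_like(g) if isinstance(g, np.ndarray) else 0.0
                self.v[key] = np.zeros_like(g) if isinstance(g, np.ndarray) else 0.0
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * (g * g if isinstance(g, np.ndarray) else g ** 2)
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            params[key] = params[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainResult:
    model: "ConvModel"
    threshold: float
    best_val_f1: float
    history: list[dict] = field(default_factory=list)


def train(train_notes: Sequence[np.ndarray], y_train: np.ndarray,
          val_notes: Sequence[np.ndarray], y_val: np.ndarray,
          config: CNNConfig, embeddings: np.ndarray) -> TrainResult:
    """Train one per-phenotype CNN with early stopping on validation F1.

    ``embeddings`` is the pre-trained table (copied into the model; updated
    in place during training when fine-tuning is on). The returned model is
    the best-validation checkpoint, and ``threshold`` is the decision
    threshold that maximized validation F1 for it.
    """
    from .evaluation import choose_threshold  # local import: avoid cycle

    y_train = np.asarray(y_train, dtype=float)
    if y_train.min() == y_train.max():
        raise ValueError("training labels contain a single class")
    model = ConvModel.initialize(config, embeddings)
    rng = np.random.default_rng(config.seed + 1)
    drop_rng = np.random.default_rng(config.seed + 2)
    adam = _Adam(config.learning_rate)

    def params_view() -> dict:
        p = {"w_out": model.w_out, "b_out": model.b_out}
        for h in model.widths:
            p[f"W{h}"] = model.filters[h]
            p[f"b{h}"] = model.biases[h]
        if config.fine_tune_embeddings:
            p["emb"] = model.embeddings
        return p

    def write_back(p: dict) -> None:
        model.w_out = p["w_out"]
        model.b_out = float(p["b_out"])
        for h in model.widths:
            model.filters[h] = p[f"W{h}"]
            model.biases[h] = p[f"b{h}"]
        if config.fine_tune_embeddings:
            model.embeddings = p["emb"]

    min_len = max(config.widths)
    best_f1, best_state, best_thr, since_best = -1.0, None, 0.5, 0
    history: list[dict] = []
    n = len(train_notes)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            ids, lengths = _pad_batch([train_notes[i] for i in sel], min_len)
            loss, grads = model.loss_and_grads(
                ids, lengths, y_train[sel], dropout_rng=drop_rng)
            p = params_view()
            adam.step(p, grads)
            write_back(p)
            epoch_loss += loss
            n_batches += 1
        val_probs = model.predict_proba(val_notes)
        thr, val_f1 = choose_threshold(val_probs, np.asarray(y_val))
        history.append({"epoch": epoch, "train_loss": epoch_loss / n_batches,
                        "val_f1": val_f1})
        # >= keeps the latest checkpoint among ties: validation F1 saturates
        # quickly on separable corpora while the margin still improves
        if val_f1 >= best_f1:
            best_f1, best_thr, since_best = val_f1, thr, 0
            best_state = (copy.deepcopy(model.filters),
                          copy.deepcopy(model.biases),
                          model.w_out.copy(), model.b_out,
                          model.embeddings.copy())
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        model.filters, model.biases, model.w_out, model.b_out, model.embeddings = (
            copy.deepcopy(best_state[0]), copy.deepcopy(best_state[1]),
            best_state[2].copy(), best_state[3], best_state[4].copy())
    return TrainResult(model=model, threshold=best_thr, best_val_f1=best_f1,
                       history=history)


def predict(model: ConvModel, notes: Sequence[np.ndarray],
            threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels (y >= threshold) and raw probabilities."""
    probs = model.predict_proba(notes)
    return (probs >= threshold).astype(int), probs


def width_ablation(train_notes, y_train, val_notes, y_val, test_notes, y_test,
                   base_config: CNNConfig, embeddings: np.ndarray,
                   width_sets: Sequence[tuple[int, ...]] = (
                       (1,), (1, 2), (1, 2, 3), (1, 2, 3, 4), (1, 2, 3, 4, 5)),
                   ) -> dict[tuple[int, ...], dict[str, float]]:
    """Train one model per width configuration and report test F1/AUC.

    The width-{1} configuration is the convolution-free pooled-projection
    baseline; deltas against it quantify what phrase windows add.
    """
    from .evaluation import confusion, metrics, roc_auc

    results: dict[tuple[int, ...], dict[str, float]] = {}
    for widths in width_sets:
        cfg = CNNConfig(**{**asdict(base_config), "widths": tuple(widths)})
        res = train(train_notes, y_train, val_notes, y_val, cfg, embeddings)
        labels, probs = predict(res.model, test_notes, res.threshold)
        p, r, f1 = metrics(confusion(labels, y_test))
        results[tuple(widths)] = {
            "precision": p, "recall": r, "f1": f1,
            "auc": roc_auc(probs, y_test),
        }
    return results
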