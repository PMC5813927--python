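"""Gradient saliency for the convolutional phenotype classifier.

Two granularities, both defined against the loss of the positive target,
L(1, y_hat) = -log y_hat:

* word saliency — the norm of the loss gradient with respect to one token's
  embedding vector, S(x_i) = ||dL/dx_i|| (L2 over the k components);
* phrase saliency — the magnitude of the loss gradient with respect to a
  pooled feature-map value, S(x_{i:i+h-1}) = |dL/dc_hat_j|, attributed to
  the argmax token window of filter j.

For this architecture the phrase saliency has a closed form: with sigmoid
output and NLL loss, dL/dlogit = y_hat - 1, so |dL/dc_hat_j| =
(1 - y_hat) · |w_out_j|. The implementation computes the gradient through
the chain rule; the closed form serves as an independent oracle in tests.

Per-note extraction keeps the best-scoring record per distinct token window;
corpus-global ranking merges per-note records, deduplicates by normalized
phrase text (keeping the maximum score), and reports the top phrases — the
machine analogue of a clinician's phrase dictionary, read out of the model.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cnn import ConvModel, NoteForward


@dataclass(frozen=True)
class SaliencyRecord:
    note_id: str
    start: int
    end: int          # half-open token window
    width: int
    phrase: str
    score: float
    filter_index: int

    def normalized_phrase(self) -> str:
        return " ".join(self.phrase.lower().split())


def _dloss_dlogit(y_hat: float, target: int) -> float:
    # d/dlogit of -[t log y + (1-t) log(1-y)] = y - t
    return y_hat - float(target)


def word_saliency(model: ConvModel, ids: np.ndarray, target: int = 1
                  ) -> np.ndarray:
    """Per-token saliency: L2 norm of dL(target, y_hat)/dx_i.

    The gradient reaches a token only through windows that are both pooled
    (argmax) and ReLU-active; tokens outside every such window score zero.
    """
    fwd = model.forward_note(np.asarray(ids, dtype=np.int64))
    n = len(fwd.ids)
    k = model.embeddings.shape[1]
    dX = np.zeros((n, k))
    dlogit = _dloss_dlogit(fwd.y, target)
    slices = model.filter_slices()
    for h in model.widths:
        w_out_h = model.w_out[slices[h]]
        arg = fwd.argmax[h]
        pre = fwd.pre_activations[h]
        dpool = dlogit * w_out_h                    # (m_h,)
        active = pre[arg, np.arange(len(arg))] > 0
        Wh = model.filters[h]                       # (h*k, m_h)
        for j in np.nonzero(active)[0]:
            i0 = int(arg[j])
            dwin = dpool[j] * Wh[:, j].reshape(h, k)
            dX[i0:i0 + h] += dwin
    scores = np.linalg.norm(dX, axis=1)
    return scores[: fwd.n_tokens]


def phrase_saliency(model: ConvModel, tokens: Sequence[str], ids: np.ndarray,
                    note_id: str = "", target: int = 1,
                    fwd: NoteForward | None = None) -> list[SaliencyRecord]:
    """One record per filter: |dL/dc_hat_j| at the filter's argmax window."""
    if fwd is None:
        fwd = model.forward_note(np.asarray(ids, dtype=np.int64))
    dlogit = _dloss_dlogit(fwd.y, target)
    records: list[SaliencyRecord] = []
    slices = model.filter_slices()
    for h in model.widths:
        base = slices[h].start
        w_out_h = model.w_out[slices[h]]
        for j, i0 in enumerate(fwd.argmax[h]):
            i0 = int(i0)
            end = min(i0 + h, len(tokens))
            records.append(SaliencyRecord(
                note_id=note_id, start=i0, end=i0 + h, width=h,
                phrase=" ".join(tokens[i0:end]),
                score=abs(dlogit * float(w_out_h[j])),
                filter_index=base + j))
    return records


def note_top_phrases(model: ConvModel, tokens: Sequence[str], ids: np.ndarray,
                     note_id: str = "", top_k: int = 5, target: int = 1
                     ) -> list[SaliencyRecord]:
    """Best-scoring record per distinct window, sorted by descending score
    (ties: lower start, then smaller width), truncated to ``top_k``."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    records = phrase_saliency(model, tokens, ids, note_id=note_id, target=target)
    best: dict[tuple[int, int], SaliencyRecord] = {}
    for rec in records:
        key = (rec.start, rec.end)
        if key not in best or rec.score > best[key].score:
            best[key] = rec
    ranked = sorted(best.values(), key=lambda r: (-r.score, r.start, r.width))
    return ranked[:top_k]


@dataclass
class GlobalPhraseRanking:
    """Corpus-level ranking of salient phrases for one phenotype model."""

    entries: list[SaliencyRecord]

    def __post_init__(self) -> None:
        scores = [e.score for e in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("global ranking scores must be non-increasing")

    def phrases(self) -> list[str]:
        return [e.phrase for e in self.entries]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tphrase\tscore\tnote_id\n")
            for rank, e in enumerate(self.entries, 1):
                fh.write(f"{rank}\t{e.phrase}\t{e.score:.6g}\t{e.note_id}\n")


def global_top_phrases(model: ConvModel,
                       notes: Sequence[tuple[str, Sequence[str], np.ndarray]],
                       top_k: int = 5, per_note_k: int | None = None,
                       target: int = 1) -> GlobalPhraseRanking:
    """Iterate over (note_id, tokens, ids) triples, pool each note's top
    records, deduplicate by normalized phrase text keeping the maximum score,
    and return the global top ``top_k``."""
    if not notes:
        raise ValueError("empty corpus")
    if per_note_k is None:
        per_note_k = top_k
    best: dict[str, SaliencyRecord] = {}
    for note_id, tokens, ids in notes:
        for rec in note_top_phrases(model, tokens, ids, note_id=note_id,
                                    top_k=per_note_k, target=target):
            key = rec.normalized_phrase()
            if key not in best or rec.score > best[key].score:
                best[key] = rec
    ranked = sorted(best.values(), key=lambda r: (-r.score, r.phrase))
    return GlobalPhraseRanking(entries=ranked[:top_k])


# ---------------------------------------------------------------------------
# Rendering

def _merge_windows(records: Sequence[SaliencyRecord]
                   ) -> list[tuple[int, int, float]]:
    """Merge overlapping windows into maximal regions, keeping the max score."""
    if not records:
        return []
    spans = sorted((r.start, r.end, r.score) for r in records)
    merged = [list(spans[0])]
    for s, e, sc in spans[1:]:
        if s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = max(merged[-1][2], sc)
        else:
            merged.append([s, e, sc])
    return [(s, e, sc) for s, e, sc in merged]


def highlight_note(tokens: Sequence[str], records: Sequence[SaliencyRecord]
                   ) -> str:
    """Plain-text rendering with salient regions wrapped in ``[[ ... |score]]``
    markers. Overlapping windows are merged into one region (max score)."""
    merged = _merge_windows(records)
    out: list[str] = []
    cursor = 0
    for s, e, sc in merged:
        out.extend(tokens[cursor:s])
        out.append("[[" + " ".join(tokens[s:min(e, len(tokens))]) + f"|{sc:.4g}]]")
        cursor = e
    out.extend(tokens[cursor:])
    return " ".join(out)


def highlight_note_html(tokens: Sequence[str],
                        records: Sequence[SaliencyRecord]) -> str:
    """HTML rendering with <mark> tags and the score in a title attribute."""
    merged = _merge_windows(records)
    out: list[str] = []
    cursor = 0
    for s, e, sc in merged:
        out.extend(html.escape(t) for t in tokens[cursor:s])
        body = html.escape(" ".join(tokens[s:min(e, len(tokens))]))
        out.append(f'<mark title="saliency {sc:.4g}">{body}</mark>')
        cursor = e
    out.extend(html.escape(t) for t in tokens[cursor:])
    return "<p>" + " ".join(out) + "</p>"


def write_saliency_report(records: Sequence[SaliencyRecord],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(r) for r in records], fh, indent=2)
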