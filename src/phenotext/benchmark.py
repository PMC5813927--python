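"""Benchmark driver: train and score every model family on one corpus.

For each phenotype the driver trains, on the patient-grouped training split:

* ``cnn`` — the convolutional classifier (pre-trained embeddings shared
  across phenotypes, trained once on all note text with labels unused);
* ``bow`` / ``ngram`` — logistic regression on unigram / 1..n-gram counts;
* ``concept-full`` — TF-IDF bag-of-concepts over the whole dictionary, with
  the best of logistic regression / naive Bayes / random forest chosen by
  validation F1;
* ``concept-filter`` — the same, restricted to concepts tagged with the
  phenotype (the clinician-filtered dictionary arm).

Thresholds are tuned on the validation split; precision, recall, F1 and AUC
are reported on the test split. Concept models are additionally run with
raw counts (TF-IDF off) to measure the weighting's AUC contribution, and
the CNN is compared against both concept arms with the chi-squared
correctness test, per phenotype and pooled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import baselines, concepts
from .cnn import CNNConfig, train as train_cnn
from .corpus import SynthCorpus
from .embeddings import train_embeddings
from .evaluation import (EvalReport, chi2_compare, choose_threshold,
                         evaluate_scores, grouped_split, roc_auc)
from .text import build_vocab

ALL_MODELS = ("cnn", "bow", "ngram", "concept-full", "concept-filter")


@dataclass
class BenchmarkSettings:
    """Desk-scale defaults: compact embeddings/CNN so a ten-phenotype corpus
    trains in minutes on one core."""

    models: tuple[str, ...] = ALL_MODELS
    seed: int = 0
    ngram_max: int = 5
    min_count: int = 2
    embed_k: int = 32
    embed_epochs: int = 2
    embed_window: int = 5
    cnn_config: CNNConfig | None = None
    tfidf_ablation: bool = True

    def resolved_cnn_config(self) -> CNNConfig:
        if self.cnn_config is not None:
            return self.cnn_config
        return CNNConfig(widths=(1, 2, 3, 4, 5), filters_per_width=16,
                         k=self.embed_k, dropout_rate=0.5, learning_rate=2e-3,
                         epochs=10, batch_size=32, seed=self.seed, patience=3)


def _concept_candidates(Xtr, ytr, Xva, yva, seed: int):
    """Fit LR, NB and RF; return (name, val_probs_fn) chosen by validation F1."""
    candidates = {}
    lr = baselines.train_logistic(Xtr, ytr)
    candidates["lr"] = lr.predict_proba
    nb = baselines.train_naive_bayes(np.abs(Xtr.toarray()), ytr)
    candidates["nb"] = lambda X, _nb=nb: _nb.predict_proba(np.abs(X.toarray()))[:, list(_nb.classes_).index(1)]
    rf = baselines.train_forest(Xtr, ytr, n_trees=100, seed=seed)
    candidates["rf"] = lambda X, _rf=rf: _rf.predict_proba(X.toarray())
    best_name, best_f1 = None, -1.0
    for name, fn in candidates.items():
        _, f1 = choose_threshold(fn(Xva), yva)
        if f1 > best_f1:
            best_name, best_f1 = name, f1
    return best_name, candidates[best_name]


def benchmark(corpus: SynthCorpus, settings: BenchmarkSettings | None = None,
              phenotypes: Sequence[str] | None = None) -> EvalReport:
    s = settings or BenchmarkSettings()
    split = grouped_split({n.note_id: n.patient_id for n in corpus.notes},
                          seed=s.seed)
    idx = {name: [i for i, n in enumerate(corpus.notes)
                  if split.assignment[n.note_id] == name]
           for name in ("train", "val", "test")}
    tokens = [n.tokens for n in corpus.notes]
    labels = corpus.labels_frame()
    ph_names = list(phenotypes) if phenotypes else corpus.phenotype_names

    vocab = build_vocab([tokens[i] for i in idx["train"]], min_count=s.min_count)
    encoded = [vocab.encode(t) for t in tokens]

    shared_emb = None
    if "cnn" in s.models:
        shared_emb = train_embeddings(
            tokens, vocab, k=s.embed_k, window=s.embed_window,
            epochs=s.embed_epochs, seed=s.seed).vectors

    ngram_X = {}
    for name, (lo, hi) in {"bow": (1, 1), "ngram": (1, s.ngram_max)}.items():
        if name in s.models:
            vec = baselines.NgramVectorizer(n_min=lo, n_max=hi).fit(
                [tokens[i] for i in idx["train"]])
            ngram_X[name] = {sp: vec.transform([tokens[i] for i in idx[sp]])
                             for sp in idx}

    bags = None
    if any(m.startswith("concept") for m in s.models):
        mentions = {n.note_id: concepts.tag_and_flag(n.tokens, corpus.concept_dictionary)
                    for n in corpus.notes}
        bags = [concepts.ConceptBag.from_mentions(n.note_id, mentions[n.note_id])
                for n in corpus.notes]

    report = EvalReport(scores={}, metadata={
        "seed": s.seed, "models": list(s.models),
        "chi2_construction": "model-by-correctness 2x2 on the shared test set",
        "undefined_metric_convention": "P/R/F1 = 0 in degenerate cases",
    })
    test_preds: dict[tuple[str, str], np.ndarray] = {}

    for ph in ph_names:
        y = {sp: labels[ph].to_numpy()[idx[sp]] for sp in idx}
        report.scores[ph] = {}
        report.thresholds[ph] = {}
        if y["train"].min() == y["train"].max() or y["test"].sum() == 0:
            report.scores[ph]["__undefined__"] = {}
            continue

        for name in ("bow", "ngram"):
            if name not in s.models:
                continue
            lm = baselines.train_logistic(ngram_X[name]["train"], y["train"])
            val_p = lm.predict_proba(ngram_X[name]["val"])
            test_p = lm.predict_proba(ngram_X[name]["test"])
            ms, thr = evaluate_scores(test_p, val_p, y["val"], y["test"])
            report.scores[ph][name] = ms
            report.thresholds[ph][name] = thr
            test_preds[(ph, name)] = (test_p >= thr).astype(int)

        for name in ("concept-full", "concept-filter"):
            if name not in s.models:
                continue
            use = bags
            if name == "concept-filter":
                use = [concepts.filter_bag(b, ph, corpus.concept_dictionary)
                       for b in bags]
            vec = concepts.BagVectorizer.fit([use[i] for i in idx["train"]])
            counts = {sp: vec.transform([use[i] for i in idx[sp]]) for sp in idx}
            weighter = concepts.TfidfWeighter.fit(counts["train"])
            X = {sp: weighter.transform(counts[sp]) for sp in idx}
            model_name, predict = _concept_candidates(
                X["train"], y["train"], X["val"], y["val"], s.seed)
            ms, thr = evaluate_scores(predict(X["test"]), predict(X["val"]),
                                      y["val"], y["test"])
            ms["selected_model"] = model_name
            report.scores[ph][name] = ms
            report.thresholds[ph][name] = thr
            test_preds[(ph, name)] = (predict(X["test"]) >= thr).astype(int)
            if s.tfidf_ablation:
                _, raw_predict = _concept_candidates(
                    counts["train"], y["train"], counts["val"], y["val"], s.seed)
                try:
                    ms["auc_raw_counts"] = roc_auc(raw_predict(counts["test"]),
                                                   y["test"])
                except ValueError:
                    ms["auc_raw_counts"] = float("nan")

        if "cnn" in s.models:
            res = train_cnn([encoded[i] for i in idx["train"]], y["train"],
                            [encoded[i] for i in idx["val"]], y["val"],
                            s.resolved_cnn_config(), shared_emb)
            test_p = res.model.predict_proba([encoded[i] for i in idx["test"]])
            val_p = res.model.predict_proba([encoded[i] for i in idx["val"]])
            ms, thr = evaluate_scores(test_p, val_p, y["val"], y["test"])
            report.scores[ph]["cnn"] = ms
            report.thresholds[ph]["cnn"] = thr
            test_preds[(ph, "cnn")] = (test_p >= thr).astype(int)

        for rival in ("concept-full", "concept-filter"):
            if (ph, "cnn") in test_preds and (ph, rival) in test_preds:
                stat, p, fallback = chi2_compare(
                    test_preds[(ph, "cnn")], test_preds[(ph, rival)], y["test"])
                report.comparisons[f"{ph}:cnn-vs-{rival}"] = {
                    "chi2": stat, "p": p, "exact_fallback": fallback}

    # pooled chi-squared across phenotypes (concatenated test vectors)
    for rival in ("concept-full", "concept-filter"):
        pairs = [(test_preds[(ph, "cnn")], test_preds[(ph, rival)],
                  labels[ph].to_numpy()[idx["test"]])
                 for ph in ph_names
                 if (ph, "cnn") in test_preds and (ph, rival) in test_preds]
        if pairs:
            pa = np.concatenate([p[0] for p in pairs])
            pb = np.concatenate([p[1] for p in pairs])
            ys = np.concatenate([p[2] for p in pairs])
            stat, p, fallback = chi2_compare(pa, pb, ys)
            report.comparisons[f"pooled:cnn-vs-{rival}"] = {
                "chi2": stat, "p": p, "exact_fallback": fallback}
    return report
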