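"""Shared fixtures: planted-signal corpora and compactly trained models.

Everything is generated programmatically and seeded; the session-scoped
fixtures exist because training even a compact convolutional model is the
dominant cost of the suite and several tests can share one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from phenotext.cnn import CNNConfig, ConvModel, TrainResult, train
from phenotext.corpus import (PhenotypeSpec, SynthConfig, SynthCorpus,
                              generate_corpus)
from phenotext.embeddings import train_embeddings
from phenotext.evaluation import grouped_split
from phenotext.text import Vocabulary, build_vocab


def single_phenotype_config(seed: int = 3, **overrides) -> SynthConfig:
    """One-phenotype corpus with 2–3 token indicators, abbreviation variants,
    misspellings and negated decoys — the standard planted-signal setup."""
    spec = PhenotypeSpec(
        name="alcohol_abuse", prevalence=0.2,
        indicator_phrases=(("alcohol", "abuse"), ("heavy", "drinking"),
                           ("etoh", "dependence")),
        synonym_groups={("alcohol", "abuse"): (("etoh", "abuse"),)})
    # trigger-free background: this desk-scale corpus backs mechanics tests
    # (descent, determinism, threshold consistency); the negation-dense
    # variant needs the full ~1,000-note corpus to be learnable and is
    # exercised by the end-to-end recovery tests
    base = dict(n_patients=400, notes_per_patient_mean=1.0, phenotypes=(spec,),
                vocab_size=800, note_length_mean=100.0, note_length_sd=25.0,
                misspelling_rate=0.1, negated_decoy_rate=0.3,
                trigger_background_rate=0.0, seed=seed)
    base.update(overrides)
    return SynthConfig(**base)


@dataclass
class CorpusSetup:
    """A corpus with its encoded notes, labels and patient-grouped split."""

    corpus: SynthCorpus
    vocab: Vocabulary
    encoded: list[np.ndarray]
    y: np.ndarray
    idx: dict[str, list[int]]
    embeddings: np.ndarray
    phenotype: str

    def split_notes(self, split: str) -> list[np.ndarray]:
        return [self.encoded[i] for i in self.idx[split]]

    def split_y(self, split: str) -> np.ndarray:
        return self.y[self.idx[split]]


def prepare(corpus: SynthCorpus, phenotype: str, embed_k: int = 24,
            embed_epochs: int = 2, split_seed: int = 0,
            subsample: float = 1e-3) -> CorpusSetup:
    tokens = [n.tokens for n in corpus.notes]
    vocab = build_vocab(tokens, min_count=1)
    emb = train_embeddings(tokens, vocab, k=embed_k, window=3,
                           epochs=embed_epochs, seed=0,
                           subsample=subsample).vectors
    split = grouped_split({n.note_id: n.patient_id for n in corpus.notes},
                          seed=split_seed)
    idx = {s: [i for i, n in enumerate(corpus.notes)
               if split.assignment[n.note_id] == s]
           for s in ("train", "val", "test")}
    return CorpusSetup(corpus=corpus, vocab=vocab,
                       encoded=[vocab.encode(t) for t in tokens],
                       y=corpus.labels_frame()[phenotype].to_numpy(),
                       idx=idx, embeddings=emb, phenotype=phenotype)


def compact_cnn_config(seed: int = 0, widths=(1, 2, 3, 4, 5), k: int = 24,
                       **overrides) -> CNNConfig:
    base = dict(widths=tuple(widths), filters_per_width=16, k=k,
                dropout_rate=0.3, learning_rate=1e-3, epochs=40,
                batch_size=16, seed=seed, patience=10)
    base.update(overrides)
    return CNNConfig(**base)


@pytest.fixture(scope="session")
def planted_setup() -> CorpusSetup:
    # subsampling off: at this corpus size the planted tokens are near the
    # frequency threshold and discarding them starves the signal
    return prepare(generate_corpus(single_phenotype_config()), "alcohol_abuse",
                   subsample=0.0)


@pytest.fixture(scope="session")
def trained_cnn(planted_setup: CorpusSetup) -> TrainResult:
    s = planted_setup
    return train(s.split_notes("train"), s.split_y("train"),
                 s.split_notes("val"), s.split_y("val"),
                 compact_cnn_config(), s.embeddings)


def random_small_model(rng: np.random.Generator, vocab_size: int = 20,
                       k: int = 4, widths=(1, 2, 3), m: int = 3) -> ConvModel:
    """A random untrained model for gradient/saliency oracle checks."""
    cfg = CNNConfig(widths=tuple(widths), filters_per_width=m, k=k,
                    dropout_rate=0.0, seed=int(rng.integers(0, 2**31)))
    emb = rng.normal(size=(vocab_size, k))
    emb[0] = 0.0
    model = ConvModel.initialize(cfg, emb)
    model.w_out = rng.normal(size=model.n_filters)
    model.b_out = float(rng.normal())
    for h in model.widths:
        model.filters[h] = rng.normal(size=model.filters[h].shape)
        model.biases[h] = rng.normal(size=model.biases[h].shape) * 0.1
    return model
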