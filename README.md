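# phenotext

Patient phenotyping from clinical narratives: does a discharge summary say
that this patient has alcohol-abuse disorder, advanced heart disease,
depression, …? Much of that evidence exists only in free text, so cohort
selection for secondary analysis of electronic health records hinges on text
classifiers that are both accurate and *explainable* to the clinicians who
must trust them.

`phenotext` implements the standard toolchain for this problem as a single
tested package:

* **Convolutional text classifier** — each note is a sequence of word
  embeddings x₁…xₙ (xᵢ ∈ ℝᵏ); filter banks of widths h ∈ {1..5} compute
  cᵢ = ReLU(w·x_{i:i+h−1} + b) over every token window; max-over-time
  pooling reduces each feature map to ĉ = max(**c**); the pooled vector
  **z** = [ĉ₁,…,ĉ_m] feeds a sigmoid output y = σ(w·**z** + b). One model
  per phenotype, trained by mini-batch Adam on the negative conditional
  log-likelihood L(θ) = −Σᵢ log p(yᵢ|xᵢ;θ) with dropout on **z** and early
  stopping on validation F1. Forward and backward passes are plain numpy,
  verified against finite differences.
* **Phrase saliency** — word saliency S(xᵢ) = ‖∂L(1,ŷ)/∂xᵢ‖ and phrase
  saliency S(x_{i:i+h−1}) = |∂L(1,ŷ)/∂ĉ| attributed to each filter's pooled
  (argmax) window. For this architecture the phrase score has the closed
  form (1−ŷ)·|w_out,j|, which the tests use as an independent oracle.
  Per-note and corpus-global salient-phrase rankings, plus text/HTML
  highlighting.
* **Concept-extraction baselines** — a dictionary tagger (greedy longest
  match) with NegEx-style negation scoping stands in for a clinical concept
  extractor; notes become bags of concepts with negated and affirmed
  mentions counted *separately*, optionally TF-IDF weighted
  (tf · ln(N/df)), classified by logistic regression, multinomial naive
  Bayes, or a random forest with gini-importance concept ranking; a
  clinician-style filtered-dictionary arm restricts features to concepts
  tagged with the phenotype.
* **n-gram baselines** — bag-of-words and 1..5-gram logistic regression,
  and the pooled word-embedding logistic regression (averaged or
  max-pooled) that demonstrates why a single shared weight vector over
  thousands of tokens degenerates to chance.
* **Evaluation harness** — 70/10/20 patient-grouped splits (all of a
  patient's notes stay in one split), exact precision/recall/F1, rank-based
  AUC (Mann–Whitney with midrank ties), Cohen's κ, a 2×2 χ² model
  comparison, and a benchmark driver producing a per-phenotype,
  per-model score table.
* **Synthetic corpus generator** — annotated discharge-summary corpora with
  the structure of real phenotyping data: ten phenotypes at 7.5%–28.6%
  prevalence, multiple notes per patient, 1–5-token indicator phrases with
  abbreviations and misspellings, negated decoy mentions in negative notes,
  negation-dense background prose, gold phrase spans, and a gold concept
  dictionary. Everything downstream is testable without restricted data.

## Worked example

```python
import numpy as np
from phenotext.corpus import PhenotypeSpec, SynthConfig, generate_corpus
from phenotext.text import build_vocab
from phenotext.embeddings import train_embeddings
from phenotext.cnn import CNNConfig, train, predict
from phenotext.evaluation import grouped_split, confusion, metrics, roc_auc
from phenotext.saliency import global_top_phrases

spec = PhenotypeSpec(
    name="alcohol_abuse", prevalence=0.2,
    indicator_phrases=(("alcohol", "abuse"), ("heavy", "drinking"),
                       ("etoh", "dependence")),
    synonym_groups={("alcohol", "abuse"): (("etoh", "abuse"),)})
cfg = SynthConfig(n_patients=500, notes_per_patient_mean=2.0,
                  phenotypes=(spec,), vocab_size=2000,
                  note_length_mean=200.0, note_length_sd=50.0,
                  misspelling_rate=0.1, negated_decoy_rate=0.3, seed=42)
corpus = generate_corpus(cfg)

tokens = [n.tokens for n in corpus.notes]
vocab = build_vocab(tokens, min_count=1)
emb = train_embeddings(tokens, vocab, k=32, window=3, epochs=2, seed=0).vectors
encoded = [vocab.encode(t) for t in tokens]
split = grouped_split({n.note_id: n.patient_id for n in corpus.notes}, seed=0)
idx = {s: [i for i, n in enumerate(corpus.notes)
           if split.assignment[n.note_id] == s]
       for s in ("train", "val", "test")}
y = corpus.labels_frame()["alcohol_abuse"].to_numpy()

ccfg = CNNConfig(widths=(1, 2, 3, 4, 5), filters_per_width=24, k=32,
                 dropout_rate=0.5, learning_rate=1e-3, epochs=40,
                 batch_size=16, seed=0, patience=8)
res = train([encoded[i] for i in idx["train"]], y[idx["train"]],
            [encoded[i] for i in idx["val"]], y[idx["val"]], ccfg, emb)
labels, probs = predict(res.model, [encoded[i] for i in idx["test"]],
                        res.threshold)
p, r, f1 = metrics(confusion(labels, y[idx["test"]]))
print(f"test P={p:.2f} R={r:.2f} F1={f1:.2f} "
      f"AUC={roc_auc(probs, y[idx['test']]):.2f}")

flagged = [(corpus.notes[i].note_id, corpus.notes[i].tokens, encoded[i])
           for j, i in enumerate(idx["test"]) if probs[j] >= 0.5]
for e in global_top_phrases(res.model, flagged, top_k=5).entries:
    print(f"{e.score:.3f}  {e.phrase}")
```

Output:

```
test P=1.00 R=1.00 F1=1.00 AUC=1.00
0.007  w00075 w00000 w00000 alcohol
0.006  w00000 alcohol
0.005  w00000 alcohol aabuse
0.005  w00000 w00075 w00000 w00000 alcohol
0.005  w00000 w00000 alcohol aabuse denies
```

The held-out F1/AUC say the model recovers the planted phenotype signal.
The top globally salient phrases — ranked over the notes the model
confidently flags — are all anchored on planted mentions amid background
filler (`w00075`-style tokens), including the *misspelled* surface `aabuse`
that the exact-match concept dictionary would miss: the interpretability
readout a clinician would review. The small absolute scores reflect a
confident model (the phrase score carries a 1−ŷ factor).

A CLI wraps the same pipelines:

```bash
phenotext synth --out corpus/ --seed 1
phenotext embed --corpus corpus/ --dim 100 --out vectors.txt --seed 1
phenotext train-cnn --corpus corpus/ --phenotype alcohol_abuse --out model/ --seed 1
phenotext interpret --corpus corpus/ --model-dir model/ --out saliency/ --seed 1
phenotext benchmark --corpus corpus/ --out report/ --seed 1
```

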