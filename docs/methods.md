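# Methods

This note documents the models implemented in `phenotext`, the assumptions
behind the synthetic corpus generator, the numerical choices that affect
results, and what the test suite does and does not establish about real
clinical data.

## The classification problem

Phenotyping assigns a binary condition label (alcohol abuse, obesity,
depression, …) to a free-text clinical note. The evidence is phrasal —
"EtOH abuse", "EF 20-30", "denies heavy drinking" — and appears with
misspellings, abbreviations, and negations, so the package implements both
of the field's standard families: concept-extraction pipelines (dictionary
tagging → negation → bag-of-concepts → shallow classifier) and a
convolutional text classifier that learns its own phrase detectors, plus a
gradient-saliency readout that turns the trained network back into a
phrase list.

## Convolutional classifier

Tokens are embedded (x_i ∈ R^k, PAD row fixed at zero), filter banks of
widths h ∈ {1..5} compute c_i = ReLU(w·x_{i:i+h−1} + b) over all windows,
max-over-time pooling keeps ĉ = max(c) per filter, and the pooled vector z
feeds a sigmoid output y = σ(w_out·z + b_out). One model is trained per
phenotype by mini-batch Adam on the mean binary negative log-likelihood
(computed in log space; non-finite loss aborts), with inverted dropout on
z and early stopping on validation F1.

Choices that matter:

* **Padding and window validity.** Notes shorter than the widest filter
  are right-padded with PAD; a filter of width h sees the natural windows
  ending within the true length, plus a single partially padded window only
  when the note is shorter than h. All-PAD windows never pool and never
  appear in argmax reports.
* **Tie-breaks.** Max-pooling resolves ties toward the lowest window
  index, making saliency attribution deterministic.
* **Early stopping** keeps the *latest* checkpoint among validation-F1
  ties: on separable corpora validation F1 saturates many epochs before the
  decision margin stops improving.
* **Decision threshold.** Chosen on the validation split by maximizing F1
  over all achievable cuts, with the returned threshold placed at the
  midpoint of the realizing score gap — an extreme tied score (e.g. 1.0 on
  a saturated validation split) transfers poorly to held-out data.
* **Gradients** are hand-written numpy and covered by central
  finite-difference tests (relative 1e-4) over every parameter tensor,
  including the embedding table when fine-tuning (the default).
* **Defaults and the desk-scale configuration.** The classic architecture
  settings are 100 filters per width and k = 100. All experiments in the
  test suite and acceptance script run a compact configuration — k = 32,
  24 filters per width, dropout 0.5, Adam lr 1e-3, batch 16, ≤ 40 epochs,
  patience 8 — because the synthetic corpora (≈1,000 notes of ≈200 tokens)
  carry a deterministic planted signal that saturates well below the full
  capacity. Learning rates above ~3e-3 were observed to collapse training
  on small corpora and are avoided.

## Saliency

Both saliency definitions target the positive label: with L(1, ŷ) =
−log ŷ,

* word saliency S(x_i) = ‖∂L/∂x_i‖₂ (L2 over the k embedding components);
* phrase saliency S(x_{i:i+h−1}) = |∂L/∂ĉ_j|, attributed to filter j's
  argmax window.

For this architecture ∂L/∂logit = ŷ − 1, so the phrase score is exactly
(1 − ŷ)·|w_out,j|; the implementation computes the gradient through the
chain rule and the tests require agreement with this closed form (relative
1e-6) and with finite differences (relative 1e-4; word saliency 1e-3).

Two consequences of the closed form shape the extraction design:

* Within one note, filters are ranked by |w_out,j| alone; the note's
  content enters through ŷ and through *which* window each filter pools.
* Across notes, the (1 − ŷ) factor ranks *less confident* notes higher.
  Over an unrestricted corpus the most confidently negative notes dominate
  the global ranking, and their argmax windows are arbitrary background.
  The global phrase ranking is therefore computed over the notes the model
  confidently flags (predicted probability ≥ 0.5) — the population a
  chart-review tool would explain. Per-note extraction keeps the
  best-scoring record per distinct window; the global ranking deduplicates
  by normalized phrase text (lowercase, collapsed whitespace), keeping the
  maximum score.

## Concept extraction

The dictionary tagger is a deliberate stand-in for a full clinical NLP
engine: greedy left-to-right longest match over pre-tokenized surface
forms, no overlap, no spelling normalization — so misspelled mentions are
missed, which is precisely the failure mode that motivates the embedding
route. Negation is NegEx-style: a pre-trigger ("no", "denies", "without",
"not", "negative for") within a 5-token window before the mention, with
"but"/"however" terminating the scope. Negated and affirmed mentions are
separate count features. TF-IDF uses the unsmoothed form
weight = tf · ln(N/df) fit on the training split (a feature present in
every training document receives exactly zero weight); the filtered arm
restricts counts to phenotype-tagged concepts *before* TF-IDF fitting.

## Baselines

Bag-of-words and n-gram (n ≤ 5) logistic regressions are trained by
deterministic full-batch gradient descent on the L2-regularized mean NLL
(weights start at zero; loss trajectory is monotone for small steps; the
n-gram vocabulary is capped at the 200k most frequent features).
Multinomial naive Bayes and the random forest (gini splits, sqrt features,
200 trees by default) are scikit-learn estimators behind the module
surface; gini importances drive global and per-document concept ranking.
The pooled-embedding logistic regression shares one weight vector across
positions and normalizes by length (or max-pools); on long notes the
planted signal is averaged away and held-out AUC sits at chance — the
expected degeneracy, reproduced by the acceptance suite on ~2,200-token
notes.

## Synthetic corpus generator

The generator emulates the *structure* of an annotated discharge-summary
corpus, not clinical language itself:

* Background prose is Zipf-distributed synthetic tokens (exponent 1.1,
  vocabulary 5,000 by default) with light section scaffolding and negation
  triggers sprinkled at 2% of tokens — real clinical text is negation-dense,
  and without this a bare trigger token would be an artifactual class
  feature.
* Ten phenotypes by default, with per-note positive prevalence matching
  the benchmark corpus this package mirrors (126–460 positives per 1,610
  notes, i.e. 7.8%–28.6%).
* Positives receive 1–3 non-negated indicator mentions (1–5 token phrases;
  abbreviation/synonym variant with probability 0.3; per-token character
  corruption — swap/drop/duplicate, edit distance ≤ 2 — at the configured
  misspelling rate). Negatives may receive one negated mention
  (trigger + phrase) with probability 0.3 by default, and never an
  affirmed one, so the label is carried exactly by the affirmed gold
  spans. An optional mode scatters the constituent unigrams of a
  multi-token indicator into negatives (1–3 sets, matching the positives'
  mention-count distribution) to build corpora where *only adjacency*
  carries the label.
* Patients receive geometric numbers of notes (mean 2), emulating
  readmission-heavy cohorts; splits are patient-grouped.
* Gold phrase spans cover the injected phrase (excluding the trigger) and
  record the negation flag; the gold concept dictionary contains one
  concept per canonical phrase with its variants as surfaces and the
  phenotype as tag, plus untagged section-phrase distractors.

What passing tests therefore show: the implementations are correct and the
methods behave as the theory predicts *when the signal is phrasal and
planted*. They do not show that these models reach any particular accuracy
on real clinical narratives, whose synonymy, discourse structure, and
label noise the generator does not attempt to model.

## Embeddings

Skip-gram with negative sampling in numpy: unigram^0.75 noise
distribution, batched SGD (batch 512, lr 0.025), per-epoch shuffling,
deterministic given a seed, word2vec text-format I/O. Frequent-word
subsampling (threshold 1e-3) is applied only when the corpus exceeds
10,000 tokens — on toy corpora every token is "frequent" and the discard
rule would empty the stream; it is also disabled in experiments whose
planted tokens are deliberately frequent. Defaults k=100, window 5,
5 negatives, 5 epochs (the classic settings of the architecture's era);
experiments use k=32 and 1–2 epochs, which suffice at planted-signal
scale. Embeddings are pre-trained on all note text with labels unused and
fine-tuned during CNN training by default.

## Evaluation

* Patient-grouped 70/10/20 split: patients shuffled by seed and assigned
  greedily to fill note-count targets; deviation from the targets is at
  most one patient's notes per boundary.
* Precision/recall/F1 are exact rational computations (P=0 when TP+FP=0,
  R=0 when TP+FN=0, F1=0 when P+R=0).
* AUC is the Mann–Whitney statistic with midrank ties — identical to
  brute-force pair enumeration, which the tests assert.
* Cohen's κ uses marginal-product expected agreement; κ=1 when both raters
  agree perfectly even with degenerate marginals.
* The χ² model comparison builds a 2×2 model-by-correctness table on the
  shared test set and evaluates the closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))
  with 1 df; when an expected cell falls below 1 the report flags the
  statistic and substitutes Fisher's exact p. This construction treats the
  two correctness vectors as independent samples — one of several
  reasonable pairings, recorded in report metadata. The benchmark reports
  the comparison per phenotype and pooled.

## Problem sizes

The acceptance script and end-to-end tests use: ~1,000 notes (500
patients, mean 2 notes) of ~200 tokens for phrase recovery; 500 single-note
patients of ~100 tokens for the width-ablation corpora (3 seeds); 240
single-note patients of ~2,200 tokens for the pooling degeneracy (3
seeds); 300 single-note patients for the negation ablation (5 seeds);
1,610 single-note patients for split-fraction checks. These sizes keep the
full suite within a few minutes on one core while leaving each effect far
from its decision boundary (e.g. width-ablation gaps of 40–70 F1 points
against a 5-point bar).

## Known limitations

* The dictionary tagger has no spelling normalization or word-sense
  disambiguation; it is a controlled stand-in, not a clinical NLP engine.
* The saliency ranking inherits the (1−ŷ)|w| structure of this
  architecture; for other output heads the closed form — and the ranking
  design built on it — would change.
* The synthetic generator's independence assumptions (token-level Zipf
  background, independent phenotypes, independent notes within a patient)
  are idealizations; patient-grouping still matters because injected
  signal is shared across a patient's notes only through the labels.
* Logistic-regression training uses a fixed step size chosen for
  determinism; very large L2 penalties require correspondingly small steps
  (lr < 2/λ) to contract.
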