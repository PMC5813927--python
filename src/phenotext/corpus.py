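"""Synthetic annotated discharge-summary corpora.

Real phenotype-annotated ICU discharge summaries are access-restricted, so
this module generates corpora that reproduce their statistical structure:
ten binary phenotypes at low-to-moderate prevalence (7.5%–28.6% positive),
multiple notes per patient ("frequent flyers"), multi-word indicator phrases
of one to five tokens with abbreviations and misspellings, and negated
mentions in negative notes that must not trigger a positive label.

Every generated corpus carries gold phrase spans and a gold concept
dictionary, so the dictionary tagger, the classifiers, and the saliency
ranking are all testable against known ground truth. Generation is fully
deterministic given a :class:`SynthConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concepts import ConceptDictionary
from .text import tokenize

Phrase = tuple[str, ...]

# Light section scaffolding so injected phrases sit in realistic context
# (diagnosis-section phrasing is where indicator phrases tend to appear).
_HEADER = ("admission", "note", "history", "of", "present", "illness")
_MID_SECTION = ("discharge", "diagnosis",)
_NEGATION_TRIGGERS = ("no", "denies", "without")


@dataclass(frozen=True)
class PhenotypeSpec:
    """One binary phenotype: its prevalence and the phrases that indicate it.

    ``indicator_phrases`` are token tuples of length 1–5; ``synonym_groups``
    maps each canonical phrase to documented variants (abbreviations,
    alternate spellings) that may be injected in its place.
    """

    name: str
    prevalence: float
    indicator_phrases: tuple[Phrase, ...]
    synonym_groups: Mapping[Phrase, tuple[Phrase, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in [0, 1): {self.prevalence}")
        if not self.indicator_phrases:
            raise ValueError(f"phenotype {self.name!r} has no indicator phrases")
        for p in self.indicator_phrases:
            if not 1 <= len(p) <= 5:
                raise ValueError(f"indicator phrase length must be 1–5: {p}")

    def variants_of(self, phrase: Phrase) -> tuple[Phrase, ...]:
        return tuple(self.synonym_groups.get(phrase, ()))

    def all_surfaces(self) -> list[Phrase]:
        out: list[Phrase] = []
        for p in self.indicator_phrases:
            out.append(p)
            out.extend(self.variants_of(p))
        return out


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults mirror the annotated-corpus structure
    this package is benchmarked against (desk-scale, ten phenotypes)."""

    n_patients: int = 800
    notes_per_patient_mean: float = 2.0
    phenotypes: tuple[PhenotypeSpec, ...] = ()
    vocab_size: int = 5000
    zipf_exponent: float = 1.1
    note_length_mean: float = 600.0
    note_length_sd: float = 150.0
    misspelling_rate: float = 0.05
    negated_decoy_rate: float = 0.3
    unigram_decoy_rate: float = 0.0
    variant_rate: float = 0.3
    # clinical text is negation-dense everywhere; sprinkling triggers into
    # background prose keeps a bare trigger token non-discriminative
    trigger_background_rate: float = 0.02
    annotator_disagreement: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, p in [("misspelling_rate", self.misspelling_rate),
                        ("negated_decoy_rate", self.negated_decoy_rate),
                        ("unigram_decoy_rate", self.unigram_decoy_rate),
                        ("trigger_background_rate", self.trigger_background_rate),
                        ("variant_rate", self.variant_rate),
                        ("annotator_disagreement", self.annotator_disagreement)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]: {p}")
        if self.notes_per_patient_mean < 1.0:
            raise ValueError("notes_per_patient_mean must be >= 1")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        names = [p.name for p in self.phenotypes]
        if len(set(names)) != len(names):
            raise ValueError("phenotype names must be unique")


@dataclass
class Note:
    note_id: str
    patient_id: str
    text: str
    tokens: list[str]
    labels: dict[str, int]


@dataclass
class SynthCorpus:
    """A generated corpus plus its ground truth.

    ``gold_spans`` maps ``(note_id, phenotype)`` to a list of
    ``(start, end, negated)`` token spans (0-based, half-open).
    """

    notes: list[Note]
    gold_spans: dict[tuple[str, str], list[tuple[int, int, bool]]]
    concept_dictionary: ConceptDictionary
    second_annotator_labels: pd.DataFrame | None = None
    config: SynthConfig | None = None

    @property
    def phenotype_names(self) -> list[str]:
        return list(self.notes[0].labels.keys()) if self.notes else []

    def labels_frame(self) -> pd.DataFrame:
        """Note-by-phenotype binary label table, indexed by note_id."""
        return pd.DataFrame(
            [n.labels for n in self.notes], index=[n.note_id for n in self.notes]
        )

    def content_hash(self) -> str:
        """SHA-256 over a canonical serialization; equal configs ⇒ equal hashes."""
        payload = {
            "notes": [
                [n.note_id, n.patient_id, n.text, sorted(n.labels.items())]
                for n in self.notes
            ],
            "spans": sorted(
                (nid, ph, sorted(spans))
                for (nid, ph), spans in self.gold_spans.items()
            ),
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


def default_phenotypes() -> tuple[PhenotypeSpec, ...]:
    """Ten phenotypes with the benchmark corpus prevalences (positives out of
    1,610 notes: 161, 275, 167, 368, 321, 196, 155, 126, 295, 460)."""

    def spec(name: str, n_pos: int, phrases: dict[Phrase, tuple[Phrase, ...]]) -> PhenotypeSpec:
        return PhenotypeSpec(
            name=name,
            prevalence=n_pos / 1610.0,
            indicator_phrases=tuple(phrases.keys()),
            synonym_groups=phrases,
        )

    return (
        spec("advanced_cancer", 161, {
            ("metastatic", "cancer"): (("mets",), ("stage", "iv", "malignancy")),
            ("pancreatic", "cancer"): (("ca", "pancreas"),),
        }),
        spec("advanced_heart_disease", 275, {
            ("severe", "cardiomyopathy"): (("cmp",),),
            ("ejection", "fraction", "less", "than", "30"): (("ef", "30"), ("lvef", "30")),
            ("heart", "transplant", "evaluation"): (("htx",),),
        }),
        spec("advanced_lung_disease", 167, {
            ("severe", "copd"): (("gold", "stage", "iv"),),
            ("pulmonary", "fibrosis"): (("ipf",),),
        }),
        spec("chronic_neurologic_dystrophies", 368, {
            ("multiple", "sclerosis"): (("ms",),),
            ("parkinsons", "disease"): (("pd",),),
            ("myasthenia", "gravis"): (("mgravis",),),
        }),
        spec("chronic_pain", 321, {
            ("chronic", "pain", "syndrome"): (("cps",),),
            ("fibromyalgia",): (("fibro",),),
        }),
        spec("alcohol_abuse", 196, {
            ("alcohol", "abuse"): (("etoh", "abuse"),),
            ("heavy", "drinking"): (("etoh",),),
        }),
        spec("substance_abuse", 155, {
            ("intravenous", "drug", "use"): (("ivdu",),),
            ("heroin", "overdose"): (("od", "heroin"),),
        }),
        spec("obesity", 126, {
            ("morbid", "obesity"): (("bmi", "42"),),
            ("gastric", "bypass"): (("gbp",),),
        }),
        spec("psychiatric_disorders", 295, {
            ("bipolar", "disorder"): (("bpad",),),
            ("schizophrenia",): (("sczo",),),
        }),
        spec("depression", 460, {
            ("major", "depressive", "disorder"): (("mdd",),),
            ("suicide", "attempt"): (("sattempt",),),
        }),
    )


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    """The standard study-structure configuration with a chosen seed."""
    kwargs = dict(phenotypes=default_phenotypes(), seed=seed)
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


def corrupt_token(token: str, rng: np.random.Generator) -> str:
    """Apply exactly one character-level corruption: swap adjacent characters,
    drop a character, or duplicate a character. Result is non-empty with
    edit distance ≤ 2 from the input. Single-character tokens can only be
    duplicated."""
    if not token:
        raise ValueError("cannot corrupt an empty token")
    if len(token) == 1:
        return token * 2
    op = rng.integers(0, 3)
    if op == 0:  # swap adjacent
        i = int(rng.integers(0, len(token) - 1))
        chars = list(token)
        chars[i], chars[i + 1] = chars[i + 1], chars[i]
        return "".join(chars)
    if op == 1:  # drop
        i = int(rng.integers(0, len(token)))
        return token[:i] + token[i + 1:]
    i = int(rng.integers(0, len(token)))  # duplicate
    return token[: i + 1] + token[i:]


def second_annotator(labels: pd.DataFrame, disagreement_rate: float,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Simulate a second annotator by independently flipping each binary label
    with probability ``disagreement_rate``."""
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ValueError("disagreement_rate must lie in [0, 1]")
    flips = rng.random(labels.shape) < disagreement_rate
    return labels.where(~flips, 1 - labels)


def build_concept_dictionary(phenotypes: Sequence[PhenotypeSpec]) -> ConceptDictionary:
    """Gold dictionary: one concept per canonical indicator phrase, with its
    variants as extra surface forms and the phenotype as its tag. A couple of
    untagged ubiquitous section concepts are included as distractors."""
    surfaces: dict[str, tuple[Phrase, ...]] = {}
    tags: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    idx = 1
    for spec in phenotypes:
        for phrase in spec.indicator_phrases:
            cid = f"C{idx:04d}"
            surfaces[cid] = (phrase,) + spec.variants_of(phrase)
            tags[cid] = frozenset({spec.name})
            names[cid] = " ".join(phrase)
            idx += 1
    for phrase in (_MID_SECTION, ("history", "of", "present", "illness")):
        cid = f"C{idx:04d}"
        surfaces[cid] = (phrase,)
        tags[cid] = frozenset()
        names[cid] = " ".join(phrase)
        idx += 1
    return ConceptDictionary(surfaces=surfaces, tags=tags, names=names)


def _sample_zipf_tokens(rng: np.random.Generator, probs: np.ndarray,
                        vocab: list[str], size: int) -> list[str]:
    idx = np.searchsorted(np.cumsum(probs), rng.random(size))
    return [vocab[i] for i in idx]


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Generate a corpus under ``config``; see the module docstring.

    Positives for a phenotype receive 1–3 non-negated indicator mentions
    (variant substitution and per-token misspelling applied at the configured
    rates); negatives may receive one negated mention (a negation trigger
    immediately before the phrase) and never a non-negated one, so the label
    is carried exactly by the non-negated gold spans.
    """
    if not config.phenotypes:
        raise ValueError("config must declare at least one phenotype")
    indicator_tokens = {
        t for spec in config.phenotypes for ph in spec.all_surfaces() for t in ph
    }
    n_background = config.vocab_size - len(indicator_tokens) - len(_HEADER) - len(_MID_SECTION)
    if n_background < 50:
        raise ValueError(
            f"vocab_size={config.vocab_size} too small to host "
            f"{len(indicator_tokens)} indicator tokens plus background text"
        )

    rng = np.random.default_rng(config.seed)
    background = [f"w{i:05d}" for i in range(n_background)]
    ranks = np.arange(1, n_background + 1, dtype=float)
    probs = ranks ** -config.zipf_exponent
    probs /= probs.sum()

    notes: list[Note] = []
    gold_spans: dict[tuple[str, str], list[tuple[int, int, bool]]] = {}
    note_idx = 0
    for p in range(config.n_patients):
        patient_id = f"pt{p:05d}"
        if config.notes_per_patient_mean <= 1.0:
            n_notes = 1
        else:
            n_notes = int(rng.geometric(1.0 / config.notes_per_patient_mean))
        for _ in range(n_notes):
            note_id = f"note{note_idx:06d}"
            note_idx += 1
            length = max(30, int(round(rng.normal(config.note_length_mean,
                                                  config.note_length_sd))))
            body = _sample_zipf_tokens(rng, probs, background, length)
            if config.trigger_background_rate > 0:
                hit = rng.random(length) < config.trigger_background_rate
                picks = rng.integers(0, len(_NEGATION_TRIGGERS), size=length)
                for t in np.nonzero(hit)[0]:
                    body[t] = _NEGATION_TRIGGERS[picks[t]]
            mid = len(body) // 2
            base = list(_HEADER) + body[:mid] + list(_MID_SECTION) + body[mid:]

            labels: dict[str, int] = {}
            injections: list[tuple[int, str, list[str], int, bool, bool]] = []
            for spec in config.phenotypes:
                positive = rng.random() < spec.prevalence
                labels[spec.name] = int(positive)
                if positive:
                    for _ in range(int(rng.integers(1, 4))):
                        injections.append(
                            _make_injection(spec, config, rng, len(base), negated=False))
                elif rng.random() < config.negated_decoy_rate:
                    injections.append(
                        _make_injection(spec, config, rng, len(base), negated=True))
                # negatives may carry the indicator tokens scattered in
                # isolation, 1-3 sets (matching the positives' mention-count
                # distribution), so only token adjacency carries the label
                if not positive and rng.random() < config.unigram_decoy_rate:
                    multi = [p for p in spec.indicator_phrases if len(p) >= 2]
                    if multi:
                        for _ in range(int(rng.integers(1, 4))):
                            phrase = multi[int(rng.integers(0, len(multi)))]
                            taken: list[int] = []
                            for tok in phrase:
                                for _ in range(20):
                                    pos = int(rng.integers(len(_HEADER),
                                                           len(base) + 1))
                                    if all(abs(pos - t) > 2 for t in taken):
                                        break
                                taken.append(pos)
                                injections.append(
                                    (pos, spec.name, [tok], 0, False, False))

            tokens, spans = _assemble(base, injections, config.phenotypes)
            for (ph_name, start, end, negated) in spans:
                gold_spans.setdefault((note_id, ph_name), []).append(
                    (start, end, negated))
            notes.append(Note(note_id=note_id, patient_id=patient_id,
                              text=" ".join(tokens), tokens=tokens, labels=labels))

    corpus = SynthCorpus(
        notes=notes,
        gold_spans=gold_spans,
        concept_dictionary=build_concept_dictionary(config.phenotypes),
        config=config,
    )
    corpus.second_annotator_labels = second_annotator(
        corpus.labels_frame(), config.annotator_disagreement, rng)
    return corpus


def _make_injection(spec: PhenotypeSpec, config: SynthConfig,
                    rng: np.random.Generator, base_len: int, negated: bool
                    ) -> tuple[int, str, list[str], int, bool, bool]:
    """Pick a phrase (canonical or variant), misspell it, choose a position.
    Returns (position, phenotype, tokens, span_offset, negated, record);
    span_offset skips the negation trigger so gold spans cover only the
    phrase."""
    canonical = spec.indicator_phrases[int(rng.integers(0, len(spec.indicator_phrases)))]
    variants = spec.variants_of(canonical)
    phrase = canonical
    if variants and rng.random() < config.variant_rate:
        phrase = variants[int(rng.integers(0, len(variants)))]
    mention = [
        corrupt_token(t, rng) if rng.random() < config.misspelling_rate else t
        for t in phrase
    ]
    offset = 0
    if negated:
        trigger = _NEGATION_TRIGGERS[int(rng.integers(0, len(_NEGATION_TRIGGERS)))]
        mention = [trigger] + mention
        offset = 1
    # keep header intact; insert anywhere after it
    pos = int(rng.integers(len(_HEADER), base_len + 1))
    return (pos, spec.name, mention, offset, negated, True)


def _assemble(base: list[str], injections: list, phenotypes) -> tuple[list[str], list]:
    """Insert mention token runs into the base note, earliest position first,
    and return the final token list plus spans in final coordinates."""
    order = sorted(range(len(injections)), key=lambda i: (injections[i][0], i))
    tokens: list[str] = []
    spans: list[tuple[str, int, int, bool]] = []
    cursor = 0
    for i in order:
        pos, ph_name, mention, offset, negated, record = injections[i]
        tokens.extend(base[cursor:pos])
        start = len(tokens) + offset
        tokens.extend(mention)
        if record:
            spans.append((ph_name, start, start + len(mention) - offset, negated))
        cursor = pos
    tokens.extend(base[cursor:])
    return tokens, spans


# ---------------------------------------------------------------------------
# Corpus I/O: JSON-lines notes, sidecar gold spans, TSV dictionary.

def write_corpus(corpus: SynthCorpus, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "notes.jsonl", "w") as fh:
        for n in corpus.notes:
            fh.write(json.dumps(
                {"note_id": n.note_id, "patient_id": n.patient_id,
                 "text": n.text, "labels": n.labels}, sort_keys=True) + "\n")
    with open(out / "gold_spans.json", "w") as fh:
        json.dump(
            {f"{nid}|{ph}": spans for (nid, ph), spans in sorted(corpus.gold_spans.items())},
            fh, sort_keys=True, indent=0)
    corpus.concept_dictionary.to_tsv(out / "dictionary.tsv")
    if corpus.second_annotator_labels is not None:
        corpus.second_annotator_labels.to_csv(out / "second_annotator_labels.csv")


def read_corpus(in_dir: str | Path) -> SynthCorpus:
    src = Path(in_dir)
    notes: list[Note] = []
    with open(src / "notes.jsonl") as fh:
        for line in fh:
            rec = json.loads(line)
            notes.append(Note(
                note_id=rec["note_id"], patient_id=rec["patient_id"],
                text=rec["text"], tokens=tokenize(rec["text"]),
                labels={k: int(v) for k, v in rec["labels"].items()}))
    gold_spans: dict[tuple[str, str], list[tuple[int, int, bool]]] = {}
    spans_path = src / "gold_spans.json"
    if spans_path.exists():
        with open(spans_path) as fh:
            for key, spans in json.load(fh).items():
                nid, ph = key.split("|", 1)
                gold_spans[(nid, ph)] = [(int(s), int(e), bool(g)) for s, e, g in spans]
    dictionary = ConceptDictionary.from_tsv(src / "dictionary.tsv")
    second = None
    second_path = src / "second_annotator_labels.csv"
    if second_path.exists():
        second = pd.read_csv(second_path, index_col=0)
    return SynthCorpus(notes=notes, gold_spans=gold_spans,
                       concept_dictionary=dictionary,
                       second_annotator_labels=second)
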