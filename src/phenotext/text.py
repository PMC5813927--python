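"""Tokenization and vocabulary construction.

Clinical narratives are noisy: inconsistent casing, punctuation glued to
measurements ("EF 20-30%."), and heavy abbreviation. The tokenizer here is
deliberately aggressive — lowercase everything and split on any run of
non-alphanumeric characters — so that "EF 20-30%." and "ef 20 30" produce
the same token stream. Numeric tokens are kept because values like ejection
fractions carry diagnostic signal.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

_TOKEN_RE = re.compile(r"[a-z0-9]+")

#: Reserved vocabulary slots.
PAD = "<pad>"
OOV = "<oov>"
PAD_INDEX = 0
OOV_INDEX = 1


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric runs.

    >>> tokenize("EF 20-30%.")
    ['ef', '20', '30']
    >>> tokenize("")
    []
    """
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Vocabulary:
    """Token-to-index mapping with reserved PAD (0) and OOV (1) slots.

    Index order over real tokens is deterministic: descending corpus
    frequency, ties broken lexicographically. Encoding never fails — tokens
    absent from the vocabulary map to the OOV index.
    """

    index_to_token: list[str]
    token_to_index: dict[str, int] = field(repr=False)
    min_count: int = 1

    def __post_init__(self) -> None:
        if self.index_to_token[PAD_INDEX] != PAD or self.index_to_token[OOV_INDEX] != OOV:
            raise ValueError("reserved slots must be PAD at 0 and OOV at 1")

    def __len__(self) -> int:
        return len(self.index_to_token)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        """Map tokens to indices; unknown tokens become OOV."""
        get = self.token_to_index.get
        return np.fromiter(
            (get(t, OOV_INDEX) for t in tokens), dtype=np.int64, count=len(tokens)
        )

    def decode(self, indices: Iterable[int]) -> list[str]:
        return [self.index_to_token[i] for i in indices]


def build_vocab(token_lists: Iterable[Sequence[str]], min_count: int = 1) -> Vocabulary:
    """Build a :class:`Vocabulary` from an iterable of token sequences.

    Tokens occurring fewer than ``min_count`` times are excluded (they encode
    to OOV). Raises ``ValueError`` when the threshold excludes every token.
    """
    counts: Counter[str] = Counter()
    for toks in token_lists:
        counts.update(toks)
    if not counts:
        raise ValueError("empty corpus: no tokens to build a vocabulary from")
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    if not kept:
        raise ValueError(f"min_count={min_count} excludes every token")
    index_to_token = [PAD, OOV] + kept
    token_to_index = {t: i for i, t in enumerate(index_to_token)}
    return Vocabulary(index_to_token=index_to_token, token_to_index=token_to_index,
                      min_count=min_count)
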