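"""Word-level tokenizer with the reserved special keywords.

Input text is already preprocessed (lowercased, whitespace-normalized), so
tokens are simply whitespace-delimited words.  The special keywords
``<BOS>``, ``<SEP>`` and ``<EOS>`` are reserved vocabulary entries; unseen
words map to ``<UNK>`` and ``<PAD>`` pads batches.

Sample-identifier words (``gsm1234``, ``gse77``) are excluded from the
vocabulary by default: each is unique to one sample, so keeping them as
tokens lets a small model key predictions on the sample id instead of the
metadata content, which hurts transfer across near-duplicate samples.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable

PAD, UNK, BOS, SEP, EOS = "<PAD>", "<UNK>", "<BOS>", "<SEP>", "<EOS>"
SPECIALS = (PAD, UNK, BOS, SEP, EOS)

#: words matching this pattern are never added to the vocabulary
DEFAULT_EXCLUDE = r"(gsm|gse)\d+"


class WordTokenizer:
    def __init__(self, vocab: list[str] | None = None, exclude_pattern: str | None = DEFAULT_EXCLUDE):
        self.exclude_pattern = exclude_pattern
        self._exclude = re.compile(exclude_pattern) if exclude_pattern else None
        words = list(vocab) if vocab else []
        rest = [w for w in words if w not in SPECIALS and not self._excluded(w)]
        self.itos: list[str] = list(SPECIALS) + rest
        self.stoi: dict[str, int] = {w: i for i, w in enumerate(self.itos)}

    def _excluded(self, word: str) -> bool:
        return bool(self._exclude and self._exclude.fullmatch(word))

    @classmethod
    def build(
        cls,
        corpus: Iterable[str],
        min_freq: int = 1,
        exclude_pattern: str | None = DEFAULT_EXCLUDE,
    ) -> "WordTokenizer":
        counts: dict[str, int] = {}
        for text in corpus:
            for w in text.split():
                counts[w] = counts.get(w, 0) + 1
        words = sorted(w for w, c in counts.items() if c >= min_freq and w not in SPECIALS)
        return cls(words, exclude_pattern=exclude_pattern)

    def __len__(self) -> int:
        return len(self.itos)

    def add_words(self, words: Iterable[str]) -> int:
        """Append unseen words to the vocabulary (online growth); returns
        the number of entries added.  Excluded (identifier-like) words are
        skipped."""
        added = 0
        for w in words:
            if w not in self.stoi and not self._excluded(w):
                self.stoi[w] = len(self.itos)
                self.itos.append(w)
                added += 1
        return added

    @property
    def pad_id(self) -> int:
        return self.stoi[PAD]

    @property
    def eos_id(self) -> int:
        return self.stoi[EOS]

    @property
    def bos_id(self) -> int:
        return self.stoi[BOS]

    def encode(self, text: str, add_special: bool = False) -> list[int]:
        unk = self.stoi[UNK]
        ids = [self.stoi.get(w, unk) for w in text.split()]
        if add_special:
            ids = [self.bos_id] + ids + [self.eos_id]
        return ids

    def decode(self, ids: Iterable[int], skip_special: bool = True) -> str:
        words = [self.itos[i] for i in ids]
        if skip_special:
            words = [w for w in words if w not in SPECIALS]
        return " ".join(words)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"itos": self.itos, "exclude_pattern": self.exclude_pattern})
        )

    @classmethod
    def load(cls, path: str | Path) -> "WordTokenizer":
        data = json.loads(Path(path).read_text())
        if isinstance(data, list):  # legacy format: bare vocabulary list
            data = {"itos": data, "exclude_pattern": DEFAULT_EXCLUDE}
        tok = cls.__new__(cls)
        tok.itos = data["itos"]
        tok.stoi = {w: i for i, w in enumerate(tok.itos)}
        tok.exclude_pattern = data.get("exclude_pattern")
        tok._exclude = re.compile(tok.exclude_pattern) if tok.exclude_pattern else None
        return tok
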