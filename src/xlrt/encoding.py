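"""Label encoding of peptide tokens and ordinal encoding of fractions.

Residue tokens are mapped to positive integers (0 is reserved for padding)
and sequences are right-padded to a fixed length.  Chromatographic fraction
numbers are represented for ordinal regression as cumulative binary
vectors: fraction ``f`` of ``n`` becomes ``f - 1`` leading ones followed by
zeros, e.g. for three fractions ``f1 = [0, 0, 0]``, ``f2 = [1, 0, 0]``,
``f3 = [1, 1, 0]``.  The network emits one sigmoid per position and the
predicted fraction is the 1-based index of the first entry below 0.5 (or
``n`` when no entry falls below the threshold, which makes the
encode/decode pair a round trip).
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np

from .io import PeptideTokens

__all__ = [
    "Alphabet",
    "build_alphabet",
    "label_encode",
    "encode_ordinal",
    "decode_ordinal",
]


class Alphabet:
    """Bijective token -> positive integer map; 0 is never assigned."""

    def __init__(self, mapping: dict[str, int]):
        if 0 in mapping.values():
            raise ValueError("integer 0 is reserved for padding")
        if len(set(mapping.values())) != len(mapping):
            raise ValueError("alphabet mapping must be bijective")
        self._map = dict(mapping)

    def __len__(self) -> int:
        return len(self._map)

    def __getitem__(self, token: str) -> int:
        try:
            return self._map[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in alphabet") from None

    def __contains__(self, token: str) -> bool:
        return token in self._map

    def __eq__(self, other) -> bool:
        return isinstance(other, Alphabet) and self._map == other._map

    @property
    def vocab_size(self) -> int:
        """Number of integers the embedding table must cover (incl. padding 0)."""
        return max(self._map.values(), default=0) + 1

    def to_dict(self) -> dict[str, int]:
        return dict(self._map)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self._map, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "Alphabet":
        with open(path) as fh:
            return cls(json.load(fh))


def build_alphabet(token_lists: Iterable[PeptideTokens | Sequence[str]]) -> Alphabet:
    """Assign integers 1..V to the sorted set of tokens in the corpus.

    Sorting makes the assignment deterministic: rebuilding on the same
    corpus (in any order) yields an identical map.
    """
    tokens: set[str] = set()
    for tl in token_lists:
        tokens.update(tl.tokens if isinstance(tl, PeptideTokens) else tl)
    if not tokens:
        raise ValueError("empty token corpus")
    return Alphabet({tok: i for i, tok in enumerate(sorted(tokens), start=1)})


def label_encode(
    tokens: PeptideTokens | Sequence[str], alphabet: Alphabet, max_len: int
) -> np.ndarray:
    """Integer-encode a token list and right-pad with zeros to ``max_len``."""
    toks = tokens.tokens if isinstance(tokens, PeptideTokens) else tuple(tokens)
    if len(toks) > max_len:
        raise ValueError(f"peptide of {len(toks)} tokens exceeds max_len={max_len}")
    out = np.zeros(max_len, dtype=np.int64)
    for i, tok in enumerate(toks):
        out[i] = alphabet[tok]
    return out


def encode_ordinal(fraction: int, n: int) -> np.ndarray:
    """Cumulative binary encoding of ``fraction`` in ``[1, n]`` (length n)."""
    if not 1 <= fraction <= n:
        raise ValueError(f"fraction {fraction} outside [1, {n}]")
    out = np.zeros(n, dtype=np.float64)
    out[: fraction - 1] = 1.0
    return out


def decode_ordinal(probs: Sequence[float], threshold: float = 0.5) -> int:
    """1-based index of the first probability below ``threshold``.

    If every entry is at or above the threshold the last fraction ``n`` is
    returned; the encoded vectors never set the final position, so this cap
    preserves the encode/decode round trip.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.size == 0:
        raise ValueError("empty probability vector")
    below = np.nonzero(probs < threshold)[0]
    return int(below[0]) + 1 if below.size else probs.size
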