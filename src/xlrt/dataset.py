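"""Bridging CSM records and the integer arrays the network consumes."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .encoding import Alphabet, build_alphabet, label_encode
from .io import CSMRecord, parse_peptide

__all__ = [
    "alphabet_from_records",
    "encode_pairs",
    "encode_peptides",
    "targets_from_records",
]


def _record_tokens(rec: CSMRecord):
    toks = [parse_peptide(rec.peptide_a, link_pos=rec.link_pos_a)]
    if rec.peptide_b:
        toks.append(parse_peptide(rec.peptide_b, link_pos=rec.link_pos_b))
    return toks


def alphabet_from_records(records: Sequence[CSMRecord]) -> Alphabet:
    corpus = []
    for rec in records:
        corpus.extend(_record_tokens(rec))
    return build_alphabet(corpus)


def encode_pairs(records: Sequence[CSMRecord], alphabet: Alphabet, max_len: int) -> np.ndarray:
    """Encode both peptides of each record -> int array (n, 2, max_len)."""
    out = np.zeros((len(records), 2, max_len), dtype=np.int64)
    for i, rec in enumerate(records):
        if not rec.peptide_b:
            raise ValueError(f"record {rec.csm_id} has no second peptide (linear?)")
        out[i, 0] = label_encode(parse_peptide(rec.peptide_a, link_pos=rec.link_pos_a), alphabet, max_len)
        out[i, 1] = label_encode(parse_peptide(rec.peptide_b, link_pos=rec.link_pos_b), alphabet, max_len)
    return out


def encode_peptides(
    peptides: Sequence[str],
    alphabet: Alphabet,
    max_len: int,
    link_positions: Sequence[int | None] | None = None,
) -> np.ndarray:
    out = np.zeros((len(peptides), max_len), dtype=np.int64)
    for i, pep in enumerate(peptides):
        link = link_positions[i] if link_positions is not None else None
        out[i] = label_encode(parse_peptide(pep, link_pos=link), alphabet, max_len)
    return out


def targets_from_records(records: Sequence[CSMRecord], tasks: Sequence[str]) -> dict:
    """Collect observed retention targets; raises if any is missing."""
    y: dict[str, list] = {t: [] for t in tasks}
    for rec in records:
        for task in tasks:
            value = {"rp": rec.rp_rt, "scx": rec.scx_fraction, "hsax": rec.hsax_fraction}[task]
            if value is None:
                raise ValueError(f"record {rec.csm_id} lacks an observed value for {task}")
            y[task].append(value)
    return {t: np.asarray(v) for t, v in y.items()}
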