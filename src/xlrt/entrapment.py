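"""Entrapment database construction.

An entrapment database adds known-irrelevant proteins to the search space
so that error rates can be measured independently of the decoy approach
(and so that overfitting of a learned rescoring model shows up as an
increased entrapment hit rate).  Candidates that share any tryptic peptide
with a target are excluded; each target is then paired with one entrapment
protein chosen by greedy nearest-neighbour matching, either on
(K/R count, sequence length) or on full amino-acid composition, so the
combined database doubles the target count without biasing the peptide
search space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pyteomics import parser as _pyt_parser
from scipy.spatial.distance import cdist

__all__ = [
    "ProteinRecord",
    "tryptic_digest",
    "homology_filter",
    "match_entrapment",
    "build_entrapment_database",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ProteinRecord:
    accession: str
    sequence: str
    is_entrapment: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def kr_count(self) -> int:
        return self.sequence.count("K") + self.sequence.count("R")

    @property
    def aa_composition(self) -> np.ndarray:
        """Residue frequency 20-vector (sums to 1 for non-empty sequences)."""
        counts = np.array([self.sequence.count(a) for a in AMINO_ACIDS], dtype=float)
        total = counts.sum()
        return counts / total if total else counts


def tryptic_digest(sequence: str, missed_cleavages: int = 1, max_len: int = 100) -> set[str]:
    """In-silico trypsin digest: cleave after K/R except before P.

    Returns the set of peptides with up to ``missed_cleavages`` missed
    sites, discarding peptides longer than ``max_len``.
    """
    if not sequence:
        return set()
    peps = _pyt_parser.cleave(sequence, "trypsin", missed_cleavages=missed_cleavages)
    return {p for p in peps if len(p) <= max_len}


def homology_filter(
    target_proteins: list[ProteinRecord],
    candidate_proteins: list[ProteinRecord],
    missed_cleavages: int = 1,
    max_len: int = 100,
    min_len: int = 7,
) -> list[ProteinRecord]:
    """Drop every candidate sharing >= 1 identical tryptic peptide with a target.

    Peptides shorter than ``min_len`` (default 7, the usual search-engine
    minimum peptide length) are ignored: one- and two-residue fragments are
    shared by essentially all proteins and carry no homology signal.
    """

    def peptides(seq: str) -> set[str]:
        return {p for p in tryptic_digest(seq, missed_cleavages, max_len) if len(p) >= min_len}

    target_peptides: set[str] = set()
    for t in target_proteins:
        target_peptides |= peptides(t.sequence)
    return [c for c in candidate_proteins if not (peptides(c.sequence) & target_peptides)]


def _feature_matrix(proteins: list[ProteinRecord], metric: str) -> np.ndarray:
    if metric == "kr_length":
        return np.array([[p.kr_count, p.length] for p in proteins], dtype=float)
    if metric == "composition":
        return np.array([p.aa_composition for p in proteins])
    raise ValueError(f"unknown metric {metric!r}")


def match_entrapment(
    targets: list[ProteinRecord],
    candidates: list[ProteinRecord],
    metric: str = "kr_length",
) -> dict[str, str]:
    """Greedy nearest-neighbour assignment of one candidate per target.

    Targets are processed in deterministic order (descending length, ties by
    accession); each receives its closest unused candidate by Euclidean
    distance on z-scored (K/R count, length) or on the composition vector.
    Returns target accession -> candidate accession.
    """
    if len(candidates) < len(targets):
        raise ValueError(
            f"candidate pool ({len(candidates)}) smaller than target set ({len(targets)})"
        )
    feats_t = _feature_matrix(targets, metric)
    feats_c = _feature_matrix(candidates, metric)
    if metric == "kr_length":
        mu = feats_c.mean(axis=0)
        sd = feats_c.std(axis=0)
        sd[sd == 0] = 1.0
        feats_t = (feats_t - mu) / sd
        feats_c = (feats_c - mu) / sd
    order = sorted(range(len(targets)), key=lambda i: (-targets[i].length, targets[i].accession))
    dist = cdist(feats_t, feats_c)
    used = np.zeros(len(candidates), dtype=bool)
    assignment: dict[str, str] = {}
    for i in order:
        row = np.where(used, np.inf, dist[i])
        j = int(np.argmin(row))
        used[j] = True
        assignment[targets[i].accession] = candidates[j].accession
    return assignment


def build_entrapment_database(
    targets: list[ProteinRecord],
    candidates: list[ProteinRecord],
    metric: str = "kr_length",
    missed_cleavages: int = 1,
    max_len: int = 100,
    min_len: int = 7,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Homology-filter candidates, match one per target, and interleave.

    The combined database lists each target followed by its entrapment
    match (flagged ``is_entrapment``), hence exactly twice the number of
    targets.
    """
    retained = homology_filter(targets, candidates, missed_cleavages, max_len, min_len)
    assignment = match_entrapment(targets, retained, metric)
    by_acc = {c.accession: c for c in retained}
    combined: list[ProteinRecord] = []
    for t in targets:
        combined.append(t)
        m = by_acc[assignment[t.accession]]
        combined.append(ProteinRecord(m.accession, m.sequence, is_entrapment=True))
    return combined, assignment
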