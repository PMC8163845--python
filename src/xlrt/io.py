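"""Reading and writing crosslink spectrum match (CSM) tables and FASTA files.

A CSM table is delimited text with one row per spectrum match: the two
peptide sequences (with inline modifications), their crosslink sites,
precursor charge, the search-engine score, target/decoy and entrapment
flags per peptide, and the observed chromatographic coordinates (SCX
fraction, hSAX fraction, reversed-phase retention time).  Column names in
the source file are mapped onto the canonical schema through a *dialect*
dictionary, so exports from different search engines can be consumed
without rewriting them.

Peptide strings use upper-case residues with optional lower-case
modification suffixes (``Mox`` = oxidized methionine, ``Ccm`` =
carbamidomethylated cysteine); the crosslinked residue is carried as a
separate 1-based position column and folded into the token sequence during
parsing.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CSMRecord",
    "PeptideTokens",
    "CSMParseError",
    "PeptideParseError",
    "DEFAULT_MOD_VOCABULARY",
    "CROSSLINK_SUFFIX",
    "parse_peptide",
    "read_csm_table",
    "write_csm_table",
    "read_fasta",
    "write_fasta",
    "assign_alpha_beta",
]

#: modification suffixes understood out of the box
DEFAULT_MOD_VOCABULARY = frozenset({"ox", "cm", "bs3", "dss"})

#: suffix appended to the token at the crosslink site
CROSSLINK_SUFFIX = "xl"


class CSMParseError(ValueError):
    """Raised when a CSM table row or column layout cannot be interpreted."""


class PeptideParseError(ValueError):
    """Raised when a peptide string does not follow the supported grammar."""


@dataclass(frozen=True)
class PeptideTokens:
    """Tokenized peptide: one token per residue, modified or crosslinked
    residues yield tokens distinct from their plain counterparts."""

    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    def to_sequence(self) -> str:
        """Reconstruct the modified-sequence string (crosslink marker dropped)."""
        out = []
        for tok in self.tokens:
            parts = tok.split("_")
            if parts[-1] == CROSSLINK_SUFFIX:
                parts = parts[:-1]
            out.append(parts[0] + "".join(parts[1:]))
        return "".join(out)


@dataclass
class CSMRecord:
    """One crosslink spectrum match."""

    csm_id: str
    peptide_a: str
    peptide_b: str = ""
    link_pos_a: int | None = None
    link_pos_b: int | None = None
    charge: int = 3
    score: float = 0.0
    is_target_a: bool = True
    is_target_b: bool = True
    is_entrapment_a: bool = False
    is_entrapment_b: bool = False
    proteins_a: tuple[str, ...] = ()
    proteins_b: tuple[str, ...] = ()
    link_class: str = "heteromeric"
    scx_fraction: int | None = None
    hsax_fraction: int | None = None
    rp_rt: float | None = None
    run_id: str = ""
    scan: int = 0

    @property
    def td_class(self) -> str:
        if self.is_target_a and self.is_target_b:
            return "TT"
        if self.is_target_a or self.is_target_b:
            return "TD"
        return "DD"

    @property
    def is_entrapment(self) -> bool:
        return self.is_entrapment_a or self.is_entrapment_b

    @property
    def is_linear(self) -> bool:
        return self.peptide_b == ""


_TOKEN_RE = re.compile(r"([A-Z])([a-z0-9]*)")


def parse_peptide(
    seq: str,
    mod_vocabulary: Iterable[str] = DEFAULT_MOD_VOCABULARY,
    link_pos: int | None = None,
) -> PeptideTokens:
    """Tokenize a modified-sequence string.

    Parameters
    ----------
    seq:
        Upper-case residues, each optionally followed by a lower-case
        modification suffix from ``mod_vocabulary`` (e.g. ``"KMoxR"``).
    link_pos:
        1-based residue index of the crosslink site; the token at that
        position receives the ``xl`` suffix so that crosslinked residues
        are encoded differently from unmodified ones.
    """
    vocab = set(mod_vocabulary)
    tokens: list[str] = []
    pos = 0
    for m in _TOKEN_RE.finditer(seq):
        if m.start() != pos:
            raise PeptideParseError(f"unexpected character at position {pos} in {seq!r}")
        residue, suffix = m.group(1), m.group(2)
        if suffix and suffix not in vocab:
            raise PeptideParseError(
                f"unknown modification suffix {suffix!r} at position {m.start()} in {seq!r}"
            )
        tokens.append(f"{residue}_{suffix}" if suffix else residue)
        pos = m.end()
    if pos != len(seq):
        raise PeptideParseError(f"unexpected character at position {pos} in {seq!r}")
    if not tokens:
        raise PeptideParseError("empty peptide string")
    if link_pos is not None:
        if not 1 <= link_pos <= len(tokens):
            raise PeptideParseError(
                f"link position {link_pos} outside peptide of length {len(tokens)}"
            )
        tokens[link_pos - 1] = f"{tokens[link_pos - 1]}_{CROSSLINK_SUFFIX}"
    return PeptideTokens(tuple(tokens))


# ---------------------------------------------------------------------------
# CSM tables
# ---------------------------------------------------------------------------

#: canonical column order used when writing
_COLUMNS = [
    "csm_id",
    "run_id",
    "scan",
    "peptide_a",
    "peptide_b",
    "link_pos_a",
    "link_pos_b",
    "charge",
    "score",
    "is_target_a",
    "is_target_b",
    "is_entrapment_a",
    "is_entrapment_b",
    "proteins_a",
    "proteins_b",
    "link_class",
    "scx_fraction",
    "hsax_fraction",
    "rp_rt",
]

_MANDATORY = {"csm_id", "peptide_a", "score", "is_target_a", "is_target_b"}

_BOOL_TRUE = {"true", "1", "t", "yes"}
_BOOL_FALSE = {"false", "0", "f", "no", ""}


def _parse_bool(raw: str, column: str) -> bool:
    low = raw.strip().lower()
    if low in _BOOL_TRUE:
        return True
    if low in _BOOL_FALSE:
        return False
    raise ValueError(f"cannot interpret {raw!r} as boolean for column {column}")


def _opt_int(raw: str) -> int | None:
    raw = raw.strip()
    return int(raw) if raw else None


def _opt_float(raw: str) -> float | None:
    raw = raw.strip()
    return float(raw) if raw else None


def read_csm_table(
    path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    n_scx: int | None = None,
    n_hsax: int | None = None,
) -> list[CSMRecord]:
    """Read a delimited CSM table into :class:`CSMRecord` objects.

    ``dialect`` maps canonical field names to the column names used in the
    file (identity mapping by default).  Rows whose mandatory fields cannot
    be parsed raise :class:`CSMParseError` naming the offending row; when
    fraction ranges are supplied, out-of-range fraction values are rejected
    the same way.
    """
    dialect = dict(dialect or {})
    with open(path, newline="") as fh:
        sample = fh.read(8192)
        fh.seek(0)
        if delimiter is None:
            delimiter = "\t" if sample.count("\t") >= sample.count(",") else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            warnings.warn(f"empty CSM table: {path}")
            return []
        colmap = {f: dialect.get(f, f) for f in _COLUMNS}
        missing = [colmap[f] for f in _MANDATORY if colmap[f] not in reader.fieldnames]
        if missing:
            raise CSMParseError(f"missing mandatory column(s) {missing} in {path}")
        present = {f: c for f, c in colmap.items() if c in reader.fieldnames}

        records: list[CSMRecord] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            try:
                records.append(_row_to_record(row, present, n_scx, n_hsax))
            except (ValueError, KeyError) as exc:
                raise CSMParseError(f"row {i} of {path}: {exc}") from exc
    if not records:
        warnings.warn(f"CSM table {path} contains no rows")
    return records


def _row_to_record(row, present, n_scx, n_hsax) -> CSMRecord:
    def get(f, default=""):
        return row.get(present[f], default) if f in present else default

    link_a = _opt_int(get("link_pos_a"))
    link_b = _opt_int(get("link_pos_b"))
    scx = _opt_int(get("scx_fraction"))
    hsax = _opt_int(get("hsax_fraction"))
    if scx is not None and n_scx is not None and not 1 <= scx <= n_scx:
        raise ValueError(f"scx_fraction {scx} outside [1, {n_scx}]")
    if hsax is not None and n_hsax is not None and not 1 <= hsax <= n_hsax:
        raise ValueError(f"hsax_fraction {hsax} outside [1, {n_hsax}]")
    pep_a = get("peptide_a").strip()
    pep_b = get("peptide_b").strip()
    if not pep_a:
        raise ValueError("empty peptide_a")
    for pep, pos, name in ((pep_a, link_a, "a"), (pep_b, link_b, "b")):
        if pep and pos is not None:
            n_res = len(_TOKEN_RE.findall(pep))
            if not 1 <= pos <= n_res:
                raise ValueError(f"link_pos_{name} {pos} outside peptide of {n_res} residues")
    rec = CSMRecord(
        csm_id=get("csm_id"),
        run_id=get("run_id"),
        scan=int(get("scan") or 0),
        peptide_a=pep_a,
        peptide_b=pep_b,
        link_pos_a=link_a,
        link_pos_b=link_b,
        charge=int(get("charge") or 3),
        score=float(get("score")),
        is_target_a=_parse_bool(get("is_target_a", "true"), "is_target_a"),
        is_target_b=_parse_bool(get("is_target_b", "true"), "is_target_b"),
        is_entrapment_a=_parse_bool(get("is_entrapment_a", "false"), "is_entrapment_a"),
        is_entrapment_b=_parse_bool(get("is_entrapment_b", "false"), "is_entrapment_b"),
        proteins_a=tuple(p for p in get("proteins_a").split(";") if p),
        proteins_b=tuple(p for p in get("proteins_b").split(";") if p),
        link_class=get("link_class") or "heteromeric",
        scx_fraction=scx,
        hsax_fraction=hsax,
        rp_rt=_opt_float(get("rp_rt")),
    )
    return rec


def write_csm_table(records: Sequence[CSMRecord], path, delimiter: str = "\t") -> None:
    """Write records in the canonical column order (lossless round trip)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.csm_id,
                    r.run_id,
                    r.scan,
                    r.peptide_a,
                    r.peptide_b,
                    "" if r.link_pos_a is None else r.link_pos_a,
                    "" if r.link_pos_b is None else r.link_pos_b,
                    r.charge,
                    repr(r.score),
                    r.is_target_a,
                    r.is_target_b,
                    r.is_entrapment_a,
                    r.is_entrapment_b,
                    ";".join(r.proteins_a),
                    ";".join(r.proteins_b),
                    r.link_class,
                    "" if r.scx_fraction is None else r.scx_fraction,
                    "" if r.hsax_fraction is None else r.hsax_fraction,
                    "" if r.rp_rt is None else repr(r.rp_rt),
                ]
            )


def assign_alpha_beta(record: CSMRecord) -> CSMRecord:
    """Canonical alpha/beta order: alpha is the longer peptide, ties broken
    lexicographically.  Deterministic and order-free; the network itself is
    order-invariant, this only fixes the single-peptide feature naming."""
    if record.is_linear:
        return record
    a, b = record.peptide_a, record.peptide_b
    if (len(b), b) > (len(a), a):
        return replace(
            record,
            peptide_a=b,
            peptide_b=a,
            link_pos_a=record.link_pos_b,
            link_pos_b=record.link_pos_a,
            is_target_a=record.is_target_b,
            is_target_b=record.is_target_a,
            is_entrapment_a=record.is_entrapment_b,
            is_entrapment_b=record.is_entrapment_a,
            proteins_a=record.proteins_b,
            proteins_b=record.proteins_a,
        )
    return record


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (header, sequence) tuples; sequences upper-cased."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rec.description!r}")
        records.append((rec.description, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    seq_records = [
        SeqRecord(Seq(seq.upper()), id=header.split()[0], description=header)
        for header, seq in records
    ]
    # SeqRecord duplicates the id inside description; write manually for a
    # lossless header round trip
    with open(path, "w") as fh:
        for rec in seq_records:
            fh.write(f">{rec.description}\n")
            s = str(rec.seq)
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
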