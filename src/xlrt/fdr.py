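"""Target-decoy and entrapment false discovery rate estimation.

CSM-level FDR uses the decoy-decoy-corrected estimator
``FDR = (TD - DD) / TT`` (clamped at zero), where TT/TD/DD count
target-target, target-decoy and decoy-decoy matches above a score
threshold.  q-values are the usual monotonized minimum FDR over all
thresholds accepting an item, ``q(t) = min_{s<=t} FDR(s)``.  Self and
heteromeric links are estimated separately — heteromeric links have a far
larger random-match space — and results roll up from CSMs to peptide
pairs, residue pairs and protein-protein interactions (PPIs), filtering at
a configurable threshold per level before the next aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CSMRecord

__all__ = [
    "csm_fdr",
    "q_values",
    "grouped_fdr",
    "unique_csm_key",
    "records_to_frame",
    "DEFAULT_LEVEL_THRESHOLDS",
]

#: roll-up thresholds used for PPI reporting: CSM/peptide/residue at 5%, PPI at 1%
DEFAULT_LEVEL_THRESHOLDS = {
    "csm": 0.05,
    "peptide_pair": 0.05,
    "residue_pair": 0.05,
    "ppi": 0.01,
}

_LEVELS = ("csm", "peptide_pair", "residue_pair", "ppi")


def csm_fdr(tt: int, td: int, dd: int) -> float:
    """Decoy-decoy-corrected FDR estimate ``max(0, (td - dd) / tt)``."""
    if tt <= 0:
        raise ValueError("FDR undefined for tt == 0")
    return max(0.0, (td - dd) / tt)


def q_values(scores: Sequence[float], td_classes: Sequence[str]) -> np.ndarray:
    """Per-item q-values from scores and TT/TD/DD classes.

    Higher score is better.  Ties are resolved conservatively: at equal
    score, decoy-containing matches are counted before targets.  The
    returned array aligns with the input order.
    """
    scores = np.asarray(scores, dtype=float)
    classes = np.asarray(td_classes)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != classes.shape:
        raise ValueError("scores and td_classes length mismatch")
    is_tt = classes == "TT"
    is_td = classes == "TD"
    is_dd = classes == "DD"
    if not (is_tt | is_td | is_dd).all():
        bad = classes[~(is_tt | is_td | is_dd)][0]
        raise ValueError(f"unknown td_class {bad!r}")
    # sort by descending score; decoys first within ties (targets enter later)
    order = np.lexsort((is_tt.astype(int), -scores))
    tt_cum = np.cumsum(is_tt[order])
    td_cum = np.cumsum(is_td[order])
    dd_cum = np.cumsum(is_dd[order])
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(tt_cum > 0, np.maximum(0.0, (td_cum - dd_cum) / tt_cum), np.inf)
    # monotonize from the worst score upwards; then equal scores share the
    # best (lowest) q among them so the result is order independent
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    out = np.empty_like(q)
    for s in np.unique(scores):
        m = scores == s
        out[m] = q[m].min()
    return out


def unique_csm_key(record: CSMRecord, context: str = "fdr") -> tuple:
    """Order-independent identity key for a CSM.

    ``context='fdr'`` includes modifications, link sites and precursor
    charge; ``context='rt_learning'`` ignores link sites and charge (the
    retention time of a peptide pair does not depend on them).
    """
    if context == "fdr":
        sides = sorted(
            [
                (record.peptide_a, record.link_pos_a or 0),
                (record.peptide_b, record.link_pos_b or 0),
            ]
        )
        return (tuple(sides[0]), tuple(sides[1]), record.charge)
    if context == "rt_learning":
        return tuple(sorted([record.peptide_a, record.peptide_b]))
    raise ValueError(f"unknown context {context!r}")


def records_to_frame(records: Iterable[CSMRecord]) -> pd.DataFrame:
    """Tabulate records with the grouping keys the FDR roll-up needs."""
    rows = []
    for r in records:
        pep_key = tuple(sorted([r.peptide_a, r.peptide_b]))
        res_key = tuple(
            sorted(
                [
                    (";".join(r.proteins_a) or r.peptide_a, r.link_pos_a or 0),
                    (";".join(r.proteins_b) or r.peptide_b, r.link_pos_b or 0),
                ]
            )
        )
        ppi_key = tuple(sorted([";".join(r.proteins_a) or r.peptide_a, ";".join(r.proteins_b) or r.peptide_b]))
        rows.append(
            {
                "csm_id": r.csm_id,
                "score": r.score,
                "td_class": r.td_class,
                "link_class": r.link_class,
                "is_entrapment": r.is_entrapment,
                "peptide_pair": pep_key,
                "residue_pair": res_key,
                "ppi": ppi_key,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FDRResult:
    """Per-level FDR tables (one DataFrame per computed level)."""

    levels: dict[str, pd.DataFrame]

    def accepted(self, level: str) -> pd.DataFrame:
        df = self.levels[level]
        return df[df["accepted"]]


def _q_per_class(df: pd.DataFrame, separate: bool) -> pd.Series:
    q = pd.Series(np.inf, index=df.index, dtype=float)
    groups = df.groupby("link_class").groups.items() if separate else [("all", df.index)]
    for _, ix in groups:
        sub = df.loc[ix]
        if (sub["td_class"] == "TT").any():
            q.loc[ix] = q_values(sub["score"].to_numpy(), sub["td_class"].to_numpy())
        # a class with no TT at all keeps q = inf (nothing acceptable)
    return q


def grouped_fdr(
    records: Iterable[CSMRecord] | pd.DataFrame,
    level: str = "csm",
    thresholds: dict | None = None,
    separate_link_classes: bool = True,
) -> FDRResult:
    """Roll-up FDR with per-level filtering.

    Levels are processed in order CSM -> peptide pair -> residue pair ->
    PPI up to ``level``.  At each aggregation the group score is the best
    member score and the group class is that of the best-scoring member;
    groups surviving the configured q-value threshold feed the next level.
    """
    if level not in _LEVELS:
        raise ValueError(f"unknown level {level!r}")
    thresholds = {**DEFAULT_LEVEL_THRESHOLDS, **(thresholds or {})}
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no records")
    out: dict[str, pd.DataFrame] = {}
    current = df.copy()
    for lev in _LEVELS:
        if lev != "csm":
            # aggregate survivors of the previous level by this level's key
            idx = current.sort_values("score", ascending=False).drop_duplicates(lev)
            current = idx.reset_index(drop=True)
        current = current.copy()
        current["q_value"] = _q_per_class(current, separate_link_classes)
        current["accepted"] = current["q_value"] <= thresholds[lev]
        out[lev] = current
        if lev == level:
            break
        current = current[current["accepted"]].reset_index(drop=True)
        if current.empty:
            raise ValueError(f"no identifications survive the {lev}-level threshold")
    return FDRResult(out)
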