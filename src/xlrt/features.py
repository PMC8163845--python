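"""Retention-time feature engineering for CSM rescoring.

For every CSM and every available chromatographic dimension three
predictions are made: for the crosslinked peptide pair (through the full
Siamese path) and for the alpha and beta peptides individually (through a
single shared branch).  From these and the observed coordinates, 13
features per dimension are derived — the raw predictions, the signed
errors (observed minus predicted), their absolute and squared variants and
alpha/beta aggregates.  With all three dimensions present, four
cross-dimension aggregates are appended for a total of 43 features
(schema v1).  Fraction-valued dimensions (SCX, hSAX) use the decoded
fraction as the prediction, so their errors are in fraction units.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import encode_pairs, encode_peptides
from .io import CSMRecord, assign_alpha_beta

__all__ = [
    "FEATURE_SCHEMA_VERSION",
    "feature_names",
    "predict_triplet",
    "build_features",
    "feature_matrix",
]

FEATURE_SCHEMA_VERSION = 1

_PER_DIM = (
    "pred_pair",
    "pred_alpha",
    "pred_beta",
    "err_pair",
    "err_alpha",
    "err_beta",
    "abs_err_pair",
    "abs_err_alpha",
    "abs_err_beta",
    "sq_err_pair",
    "sum_abs_err_ab",
    "min_abs_err_ab",
    "max_abs_err_ab",
)

_CROSS = (
    "total_abs_err_pair",
    "total_sq_err_pair",
    "total_sum_abs_err_ab",
    "err_pair_norm",
)


def feature_names(dimensions: Sequence[str], include_search_score: bool = False) -> list[str]:
    """Stable, documented feature order: 13 per dimension, plus 4
    cross-dimension aggregates when all three dimensions are present."""
    names = [f"{base}_{d}" for d in dimensions for base in _PER_DIM]
    if len(dimensions) == 3:
        names.extend(_CROSS)
    if include_search_score:
        names.append("search_score")
    return names


def predict_triplet(model, records: Sequence[CSMRecord], alphabet, dimensions) -> pd.DataFrame:
    """Pair/alpha/beta predictions per record and dimension.

    Alpha is the longer peptide (ties lexicographic).  The single-peptide
    predictions reuse the Siamese weights through one branch.
    """
    for d in dimensions:
        if d not in model._cfg["tasks"]:
            raise ValueError(f"model does not predict dimension {d!r}")
    oriented = [assign_alpha_beta(r) for r in records]
    X_pair = encode_pairs(oriented, alphabet, model.max_len)
    X_alpha = encode_peptides(
        [r.peptide_a for r in oriented], alphabet, model.max_len, [r.link_pos_a for r in oriented]
    )
    X_beta = encode_peptides(
        [r.peptide_b for r in oriented], alphabet, model.max_len, [r.link_pos_b for r in oriented]
    )
    pair = model.predict(X_pair)
    alpha = model.predict_single(X_alpha)
    beta = model.predict_single(X_beta)
    out = {"csm_id": [r.csm_id for r in records]}
    for d in dimensions:
        out[f"pred_pair_{d}"] = np.asarray(pair[d], dtype=float)
        out[f"pred_alpha_{d}"] = np.asarray(alpha[d], dtype=float)
        out[f"pred_beta_{d}"] = np.asarray(beta[d], dtype=float)
    return pd.DataFrame(out)


def _observed(record: CSMRecord, dim: str):
    return {"rp": record.rp_rt, "scx": record.scx_fraction, "hsax": record.hsax_fraction}[dim]


def build_features(
    csm: CSMRecord, triplets: Mapping[str, float], dimensions: Sequence[str]
) -> dict[str, float]:
    """13 features per dimension (+4 cross-dimension when all three)."""
    feats: dict[str, float] = {}
    for d in dimensions:
        obs = _observed(csm, d)
        if obs is None:
            raise ValueError(f"record {csm.csm_id} lacks an observed value for dimension {d!r}")
        pp = float(triplets[f"pred_pair_{d}"])
        pa = float(triplets[f"pred_alpha_{d}"])
        pb = float(triplets[f"pred_beta_{d}"])
        ep, ea, eb = obs - pp, obs - pa, obs - pb
        feats[f"pred_pair_{d}"] = pp
        feats[f"pred_alpha_{d}"] = pa
        feats[f"pred_beta_{d}"] = pb
        feats[f"err_pair_{d}"] = ep
        feats[f"err_alpha_{d}"] = ea
        feats[f"err_beta_{d}"] = eb
        feats[f"abs_err_pair_{d}"] = abs(ep)
        feats[f"abs_err_alpha_{d}"] = abs(ea)
        feats[f"abs_err_beta_{d}"] = abs(eb)
        feats[f"sq_err_pair_{d}"] = ep * ep
        feats[f"sum_abs_err_ab_{d}"] = abs(ea) + abs(eb)
        feats[f"min_abs_err_ab_{d}"] = min(abs(ea), abs(eb))
        feats[f"max_abs_err_ab_{d}"] = max(abs(ea), abs(eb))
    if len(dimensions) == 3:
        feats["total_abs_err_pair"] = sum(feats[f"abs_err_pair_{d}"] for d in dimensions)
        feats["total_sq_err_pair"] = sum(feats[f"sq_err_pair_{d}"] for d in dimensions)
        feats["total_sum_abs_err_ab"] = sum(feats[f"sum_abs_err_ab_{d}"] for d in dimensions)
        feats["err_pair_norm"] = float(
            np.sqrt(sum(feats[f"err_pair_{d}"] ** 2 for d in dimensions))
        )
    return feats


def feature_matrix(
    csms: Sequence[CSMRecord],
    triplets: pd.DataFrame,
    dimensions: Sequence[str],
    include_search_score: bool = False,
) -> pd.DataFrame:
    """One feature row per CSM, indexed by csm_id, in the schema order."""
    trip = triplets.set_index("csm_id")
    rows = []
    for csm in csms:
        feats = build_features(csm, trip.loc[csm.csm_id], dimensions)
        if include_search_score:
            feats["search_score"] = csm.score
        feats["csm_id"] = csm.csm_id
        rows.append(feats)
    cols = feature_names(dimensions, include_search_score)
    df = pd.DataFrame(rows).set_index("csm_id")
    df.attrs["schema_version"] = FEATURE_SCHEMA_VERSION
    return df[cols]
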