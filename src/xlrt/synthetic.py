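"""Ground-truth-known synthetic crosslinking data.

The generator emulates the statistical structure that retention-time-aided
rescoring relies on, without any external data:

* proteins are random sequences drawn from a fixed residue-frequency
  table; half of the pool is flagged as entrapment (irrelevant) proteins;
* peptides come from an in-silico tryptic digest; crosslinkable peptides
  contain a lysine;
* each chromatographic dimension has an additive sequence model — a
  hydrophobicity-like scale for reversed phase (RP), positive weights on
  K/R/H with an attenuated crosslinked-K contribution for strong cation
  exchange (SCX), and weights on D/E/Y/F/W for hydrophilic strong anion
  exchange (hSAX).  The retention coordinate of a crosslinked pair is the
  sum of both peptides' contributions plus Gaussian noise;
* false matches (target-decoy, decoy-decoy, random target-target including
  entrapment hits) receive retention coordinates that are *inconsistent*
  with the reported pair: either from a pair in which one peptide is
  correct and the other random, or drawn uniformly over the observed
  range.  This encodes the premise that the retention time of a crosslinked
  peptide depends on both peptides;
* SCX and hSAX fractions are obtained by quantile-binning the continuous
  coordinates (9 and 10 fractions by default); search scores are drawn
  from overlapping distributions for true and false matches.

Every latent label (true/false, mechanism, clean coordinates) is returned
in a hidden truth table that the pipeline under test never sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entrapment import AMINO_ACIDS, ProteinRecord, tryptic_digest
from .io import CSMRecord, parse_peptide

__all__ = [
    "RetentionModel",
    "SimulationConfig",
    "simulate_proteins",
    "simulate_csms",
    "simulate_dataset",
    "bin_to_fractions",
]

# roughly bacterial average residue frequencies
RESIDUE_FREQUENCIES = {
    "A": 0.089, "C": 0.011, "D": 0.054, "E": 0.058, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.060, "K": 0.048, "L": 0.100,
    "M": 0.028, "N": 0.039, "P": 0.044, "Q": 0.044, "R": 0.055,
    "S": 0.058, "T": 0.054, "V": 0.071, "W": 0.015, "Y": 0.029,
}

_RP_COEFFS = {
    "W": 8.0, "F": 7.5, "L": 7.0, "I": 6.5, "M": 4.0, "V": 4.5,
    "Y": 3.5, "C": 2.0, "A": 1.0, "T": 0.6, "P": 1.2, "E": 0.8,
    "D": 0.4, "S": 0.2, "Q": 0.0, "N": -0.2, "G": 0.0, "H": -1.3,
    "R": -2.0, "K": -2.2, "M_ox": 1.5, "K_xl": 0.5,
}

_SCX_COEFFS = {
    "K": 3.0, "R": 3.2, "H": 1.5, "K_xl": 0.8,  # crosslinked K: weaker charge
    "Q": 0.1, "N": 0.1, "S": 0.05, "T": 0.05,
}

_HSAX_COEFFS = {
    "D": 2.5, "E": 2.3, "Y": 1.3, "F": 1.1, "W": 1.0, "S": 0.1, "T": 0.1,
}


@dataclass
class RetentionModel:
    """Additive per-residue retention model for the three dimensions."""

    coefficients: dict = field(
        default_factory=lambda: {"rp": dict(_RP_COEFFS), "scx": dict(_SCX_COEFFS), "hsax": dict(_HSAX_COEFFS)}
    )
    intercepts: dict = field(default_factory=lambda: {"rp": 8.0, "scx": 0.0, "hsax": 0.0})
    length_term: dict = field(default_factory=lambda: {"rp": 0.10, "scx": 0.05, "hsax": 0.05})
    #: noise standard deviation per dimension as a fraction of the clean range
    noise_rel: dict = field(default_factory=lambda: {"rp": 0.05, "scx": 0.05, "hsax": 0.05})
    #: monotone map applied to the pair sum: "gradient" emulates elution from
    #: a (partially exponential) LC gradient, which spreads peptides roughly
    #: uniformly over a bounded elution window; "identity" and "sqrt" are
    #: simple alternatives.  Fraction-valued dimensions are binned by rank,
    #: so the transform only matters for the continuous RP dimension.
    pair_transform: str = "gradient"
    #: logistic gradient curve per dimension: rt = start + span * expit((x - loc)/scale);
    #: loc/scale are calibrated to the default peptide pool's pair-sum distribution
    gradient_params: dict = field(
        default_factory=lambda: {"rp": {"loc": 72.0, "scale": 15.0, "start": 10.0, "span": 110.0}}
    )

    def token_coeff(self, token: str, dim: str) -> float:
        table = self.coefficients[dim]
        if token in table:
            return table[token]
        if token.endswith("_xl") and token[:-3] in table:  # e.g. M_ox_xl -> M_ox
            return table[token[:-3]]
        base = token.split("_")[0]
        return table.get(base, 0.0)

    def peptide_value(self, seq: str, dim: str, link_pos: int | None = None) -> float:
        tokens = parse_peptide(seq, link_pos=link_pos).tokens
        total = sum(self.token_coeff(t, dim) for t in tokens)
        return total + self.length_term[dim] * len(tokens)

    def pair_value(self, seq_a, seq_b, dim, link_a=None, link_b=None) -> float:
        total = (
            self.intercepts[dim]
            + self.peptide_value(seq_a, dim, link_a)
            + (self.peptide_value(seq_b, dim, link_b) if seq_b else 0.0)
        )
        if self.pair_transform == "sqrt":
            return float(np.sign(total) * np.sqrt(np.abs(total)))
        if self.pair_transform == "gradient" and dim in self.gradient_params:
            g = self.gradient_params[dim]
            z = (total - g["loc"]) / g["scale"]
            return float(g["start"] + g["span"] / (1.0 + np.exp(-z)))
        return float(total)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic CSM tables."""

    n_proteins: int = 150          # target proteins; an equal entrapment pool is added
    protein_length_range: tuple = (80, 400)
    n_csms: int = 5000
    frac_true: float = 0.6         # share of CSMs that are genuine crosslinks (all TT)
    random_class_probs: tuple = (0.25, 0.5, 0.25)  # TT / TD / DD among random matches
    frac_self: float = 0.3         # self-links among true crosslinks
    n_scx: int = 9
    n_hsax: int = 10
    peptide_len_range: tuple = (6, 26)
    missed_cleavages: int = 1
    mox_prob: float = 0.15         # chance that a methionine carries oxidation
    one_correct_prob: float = 0.5  # false-match mechanism: one peptide correct
    score_true: tuple = (12.0, 3.5)   # mean, sd
    score_false: tuple = (7.0, 2.0)
    dimensions: tuple = ("rp", "scx", "hsax")


def simulate_proteins(
    config: SimulationConfig, seed: int = 0, n: int | None = None, prefix: str = "P"
) -> list[ProteinRecord]:
    """Random protein sequences from the residue-frequency table."""
    rng = np.random.default_rng(seed)
    aa = np.array(list(RESIDUE_FREQUENCIES))
    p = np.array(list(RESIDUE_FREQUENCIES.values()))
    p = p / p.sum()
    lo, hi = config.protein_length_range
    out = []
    for i in range(n if n is not None else config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aa, size=length, p=p))
        out.append(ProteinRecord(f"{prefix}{i:04d}", seq))
    return out


def bin_to_fractions(values, n_fractions: int, rule: str = "quantile", edges=None):
    """Bin continuous retention coordinates into 1-based fraction labels.

    ``rule='quantile'`` computes interior quantile edges from ``values``
    (near-equal occupancy); ``rule='fixed_edges'`` reuses previously
    computed ``edges``.  Returns ``(labels, edges)``.
    """
    values = np.asarray(values, dtype=float)
    if rule == "quantile":
        if n_fractions < 2:
            raise ValueError("need at least 2 fractions")
        if np.unique(values).size < n_fractions:
            raise ValueError("fewer distinct values than fractions")
        qs = np.linspace(0, 1, n_fractions + 1)[1:-1]
        edges = np.quantile(values, qs)
    elif rule == "fixed_edges":
        if edges is None:
            raise ValueError("fixed_edges rule requires edges")
        edges = np.asarray(edges, dtype=float)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    labels = np.searchsorted(edges, values, side="right") + 1
    return labels.astype(int), edges


def _peptide_pool(proteins, config, rng) -> list[dict]:
    lo, hi = config.peptide_len_range
    pool = []
    for prot in proteins:
        for pep in sorted(tryptic_digest(prot.sequence, config.missed_cleavages, hi)):
            if not lo <= len(pep) <= hi or "K" not in pep:
                continue
            pool.append({"seq": pep, "protein": prot.accession, "entrapment": prot.is_entrapment})
    return pool


def _decorate(seq: str, rng, config) -> tuple[str, int]:
    """Apply variable oxidation to M residues and pick a crosslink site (a K)."""
    out = []
    for ch in seq:
        if ch == "M" and rng.random() < config.mox_prob:
            out.append("Mox")
        else:
            out.append(ch)
    k_positions = [i + 1 for i, ch in enumerate(seq) if ch == "K"]
    link = int(rng.choice(k_positions)) if k_positions else int(rng.integers(1, len(seq) + 1))
    return "".join(out), link


def _pseudo_reverse(seq: str) -> str:
    """Decoy peptide: reverse all but the C-terminal residue."""
    return seq[:-1][::-1] + seq[-1] if len(seq) > 1 else seq


def simulate_csms(
    proteins: list[ProteinRecord],
    retention_model: RetentionModel,
    config: SimulationConfig,
    seed: int = 0,
) -> tuple[list[CSMRecord], pd.DataFrame]:
    """Generate a CSM table plus the hidden truth table.

    ``proteins`` must carry ``is_entrapment`` flags; true crosslinks are
    drawn from non-entrapment proteins only, random matches from the whole
    pool (and from pseudo-reversed decoy peptides).
    """
    rng = np.random.default_rng(seed)
    pool = _peptide_pool(proteins, config, rng)
    target_pool = [p for p in pool if not p["entrapment"]]
    if len(target_pool) < 10 or len(pool) < 10:
        raise ValueError("too few digestible peptides to form the requested CSMs")
    by_protein: dict[str, list] = {}
    for p in target_pool:
        by_protein.setdefault(p["protein"], []).append(p)
    multi = [v for v in by_protein.values() if len(v) >= 2]

    dims = config.dimensions
    n_true = int(round(config.frac_true * config.n_csms))
    n_rand = config.n_csms - n_true

    rows = []
    truth = []

    def clean_pair(a, la, b, lb):
        return {d: retention_model.pair_value(a, b, d, la, lb) for d in dims}

    # --- true crosslinks -------------------------------------------------
    for i in range(n_true):
        if multi and rng.random() < config.frac_self:
            prot = multi[int(rng.integers(len(multi)))]
            pa, pb = (prot[j] for j in rng.choice(len(prot), size=2, replace=False))
            link_class = "self"
        else:
            pa, pb = (target_pool[int(j)] for j in rng.choice(len(target_pool), size=2, replace=False))
            link_class = "self" if pa["protein"] == pb["protein"] else "heteromeric"
        seq_a, link_a = _decorate(pa["seq"], rng, config)
        seq_b, link_b = _decorate(pb["seq"], rng, config)
        rows.append(
            dict(
                seq_a=seq_a, seq_b=seq_b, link_a=link_a, link_b=link_b,
                prot_a=pa["protein"], prot_b=pb["protein"],
                tgt_a=True, tgt_b=True, ent_a=pa["entrapment"], ent_b=pb["entrapment"],
                link_class=link_class, is_true=True, mechanism="true",
                clean=clean_pair(seq_a, link_a, seq_b, link_b),
                score=rng.normal(*config.score_true),
            )
        )

    # --- random matches --------------------------------------------------
    class_draw = rng.choice(3, size=n_rand, p=np.asarray(config.random_class_probs))
    for i in range(n_rand):
        kind = ("TT", "TD", "DD")[class_draw[i]]
        pa, pb = (pool[int(j)] for j in rng.choice(len(pool), size=2, replace=False))
        tgt_a = tgt_b = True
        seq_a_src, seq_b_src = pa["seq"], pb["seq"]
        if kind in ("TD", "DD"):
            seq_b_src = _pseudo_reverse(pb["seq"])
            tgt_b = False
        if kind == "DD":
            seq_a_src = _pseudo_reverse(pa["seq"])
            tgt_a = False
        seq_a, link_a = _decorate(seq_a_src, rng, config)
        seq_b, link_b = _decorate(seq_b_src, rng, config)
        if rng.random() < config.one_correct_prob:
            # spectrum really comes from (peptide_a', random partner x)
            x = pool[int(rng.integers(len(pool)))]
            xs, xl = _decorate(x["seq"], rng, config)
            clean = clean_pair(seq_a, link_a, xs, xl)
            mech = "one_correct"
        else:
            clean = None  # resolved to a uniform draw once ranges are known
            mech = "random"
        rows.append(
            dict(
                seq_a=seq_a, seq_b=seq_b, link_a=link_a, link_b=link_b,
                prot_a=pa["protein"], prot_b=("decoy_" if not tgt_b else "") + pb["protein"],
                tgt_a=tgt_a, tgt_b=tgt_b,
                ent_a=pa["entrapment"] and tgt_a, ent_b=pb["entrapment"] and tgt_b,
                link_class="heteromeric" if pa["protein"] != pb["protein"] else "self",
                is_true=False, mechanism=mech, clean=clean,
                score=rng.normal(*config.score_false),
            )
        )
        if not tgt_a:
            rows[-1]["prot_a"] = "decoy_" + pa["protein"]

    # --- noise, ranges, uniform draws for fully random matches -----------
    true_clean = {d: np.array([r["clean"][d] for r in rows if r["mechanism"] == "true"]) for d in dims}
    ranges = {d: float(np.ptp(true_clean[d])) or 1.0 for d in dims}
    lo = {d: float(true_clean[d].min()) for d in dims}
    observed = {d: np.empty(len(rows)) for d in dims}
    for j, r in enumerate(rows):
        for d in dims:
            sd = retention_model.noise_rel[d] * ranges[d]
            if r["clean"] is None:
                observed[d][j] = rng.uniform(lo[d], lo[d] + ranges[d])
            else:
                observed[d][j] = r["clean"][d] + rng.normal(0.0, sd)

    fractions, edges = {}, {}
    if "scx" in dims:
        fractions["scx"], edges["scx"] = bin_to_fractions(observed["scx"], config.n_scx)
    if "hsax" in dims:
        fractions["hsax"], edges["hsax"] = bin_to_fractions(observed["hsax"], config.n_hsax)

    order = rng.permutation(len(rows))
    records, truth_rows = [], []
    for new_id, j in enumerate(order):
        r = rows[j]
        rec = CSMRecord(
            csm_id=f"csm_{new_id:06d}",
            run_id="sim",
            scan=new_id,
            peptide_a=r["seq_a"],
            peptide_b=r["seq_b"],
            link_pos_a=r["link_a"],
            link_pos_b=r["link_b"],
            charge=int(rng.integers(3, 7)),
            score=float(r["score"]),
            is_target_a=r["tgt_a"],
            is_target_b=r["tgt_b"],
            is_entrapment_a=r["ent_a"],
            is_entrapment_b=r["ent_b"],
            proteins_a=(r["prot_a"],),
            proteins_b=(r["prot_b"],),
            link_class=r["link_class"],
            scx_fraction=int(fractions["scx"][j]) if "scx" in dims else None,
            hsax_fraction=int(fractions["hsax"][j]) if "hsax" in dims else None,
            rp_rt=float(observed["rp"][j]) if "rp" in dims else None,
        )
        records.append(rec)
        trow = {
            "csm_id": rec.csm_id,
            "is_true": r["is_true"],
            "mechanism": r["mechanism"],
            "td_class": rec.td_class,
            "is_entrapment": rec.is_entrapment,
        }
        for d in dims:
            trow[f"clean_{d}"] = np.nan if r["clean"] is None else r["clean"][d]
            trow[f"observed_{d}"] = observed[d][j]
        truth_rows.append(trow)
    return records, pd.DataFrame(truth_rows)


def simulate_dataset(
    config: SimulationConfig | None = None,
    retention_model: RetentionModel | None = None,
    seed: int = 0,
):
    """Convenience wrapper: proteins (targets + entrapment pool) and CSMs.

    Returns ``(records, truth, proteins, retention_model)``.
    """
    config = config or SimulationConfig()
    retention_model = retention_model or RetentionModel()
    targets = simulate_proteins(config, seed=seed, prefix="T")
    entrap = simulate_proteins(config, seed=seed + 1, prefix="E")
    for p in entrap:
        p.is_entrapment = True
    proteins = targets + entrap
    records, truth = simulate_csms(proteins, retention_model, config, seed=seed + 2)
    return records, truth, proteins, retention_model
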