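
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlrt.fdr import csm_fdr, grouped_fdr, q_values, unique_csm_key
from xlrt.io import CSMRecord


class TestCsmFdr:
    def test_reported_proteome_counts(self):
        """(TD - DD)/TT on the 1% CSM-FDR counts of the E. coli search."""
        assert csm_fdr(11072, 87, 37) == pytest.approx(50 / 11072)

    def test_no_decoys_means_zero(self):
        assert csm_fdr(100, 0, 0) == 0.0

    def test_negative_estimate_clamped(self):
        assert csm_fdr(100, 5, 9) == 0.0

    def test_undefined_without_targets(self):
        with pytest.raises(ValueError):
            csm_fdr(0, 1, 0)

    @given(st.integers(1, 500), st.integers(0, 100), st.integers(0, 100), st.integers(2, 9))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scale_free_and_nonnegative(self, tt, td, dd, c):
        assert csm_fdr(tt, td, dd) >= 0
        assert csm_fdr(c * tt, c * td, c * dd) == pytest.approx(csm_fdr(tt, td, dd))


class TestQValues:
    def test_all_targets_no_decoys(self):
        q = q_values([5, 4, 3], ["TT", "TT", "TT"])
        assert (q == 0).all()

    def test_monotonization_of_a_dipping_fdr_sequence(self):
        """50 TTs, one TD, then 50 more TTs: the running FDR dips from
        0.02 back to ~0.01, so every item below the TD gets q ~ 0.01."""
        scores = list(range(200, 150, -1)) + [150] + list(range(149, 99, -1))
        classes = ["TT"] * 50 + ["TD"] + ["TT"] * 50
        q = q_values(scores, classes)
        assert (q[:50] == 0).all()
        assert q[50] == pytest.approx(1 / 100)
        assert np.allclose(q[51:], 1 / 100)

    def test_order_independence(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        classes = rng.choice(["TT", "TD", "DD"], size=40, p=[0.7, 0.2, 0.1])
        q = q_values(scores, classes)
        perm = rng.permutation(40)
        q2 = q_values(scores[perm], classes[perm])
        assert np.allclose(q[perm], q2)

    def test_decoys_counted_before_targets_at_ties(self):
        # TD shares the top score with a TT: conservative tie handling
        q = q_values([10, 10, 5], ["TT", "TD", "TT"])
        assert q[0] >= 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            q_values([], [])

    @given(st.lists(st.tuples(st.floats(0, 100), st.sampled_from(["TT", "TD", "DD"])), min_size=2, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_q_monotone_nonincreasing_in_score(self, items):
        # anchor with a worst-scoring target so every q is defined
        items = items + [(-1.0, "TT")]
        scores, classes = zip(*items)
        q = q_values(np.array(scores), np.array(classes))
        order = np.argsort(-np.array(scores))
        assert (np.diff(q[order]) >= -1e-12).all()


class TestUniqueCsmKey:
    A = CSMRecord(csm_id="1", peptide_a="PEPKR", peptide_b="KAR", link_pos_a=4, link_pos_b=1, charge=3)

    def test_swapped_peptide_order_equal_keys(self):
        b = CSMRecord(csm_id="2", peptide_a="KAR", peptide_b="PEPKR", link_pos_a=1, link_pos_b=4, charge=3)
        for ctx in ("fdr", "rt_learning"):
            assert unique_csm_key(self.A, ctx) == unique_csm_key(b, ctx)

    def test_charge_only_in_fdr_context(self):
        b = CSMRecord(csm_id="2", peptide_a="PEPKR", peptide_b="KAR", link_pos_a=4, link_pos_b=1, charge=4)
        assert unique_csm_key(self.A, "fdr") != unique_csm_key(b, "fdr")
        assert unique_csm_key(self.A, "rt_learning") == unique_csm_key(b, "rt_learning")

    def test_link_site_only_in_fdr_context(self):
        b = CSMRecord(csm_id="2", peptide_a="PEPKR", peptide_b="KAR", link_pos_a=5, link_pos_b=1, charge=3)
        assert unique_csm_key(self.A, "fdr") != unique_csm_key(b, "fdr")
        assert unique_csm_key(self.A, "rt_learning") == unique_csm_key(b, "rt_learning")


def _rec(i, score, tgt_a=True, tgt_b=True, link_class="heteromeric", prot_a="A", prot_b="B", pos=1):
    return CSMRecord(
        csm_id=f"c{i}",
        peptide_a=f"PEPK{'A' * (i % 3)}R",
        peptide_b="KAR",
        link_pos_a=4,
        link_pos_b=1,
        score=score,
        is_target_a=tgt_a,
        is_target_b=tgt_b,
        proteins_a=(prot_a,),
        proteins_b=(prot_b,),
        link_class=link_class,
    )


class TestGroupedFdr:
    def test_clean_ppi_has_zero_q(self):
        recs = [_rec(i, 10 - i) for i in range(3)]
        res = grouped_fdr(recs, level="ppi")
        assert (res.levels["ppi"]["q_value"] == 0).all()
        assert res.levels["ppi"].shape[0] == 1

    def test_separate_link_class_estimation(self):
        self_recs = [_rec(i, 20 - i, link_class="self", prot_a="A", prot_b="A") for i in range(5)]
        het_decoys = [
            _rec(100 + i, 19.5 - i, tgt_b=False, link_class="heteromeric") for i in range(4)
        ]
        q_self_alone = grouped_fdr(self_recs, level="csm").levels["csm"]
        q_mixed = grouped_fdr(self_recs + het_decoys, level="csm").levels["csm"]
        merged = q_mixed[q_mixed["link_class"] == "self"].sort_values("csm_id")
        assert np.allclose(
            merged["q_value"].to_numpy(),
            q_self_alone.sort_values("csm_id")["q_value"].to_numpy(),
        )

    def test_csm_level_acceptance_matches_brute_force(self):
        """Exhaustively check the q<=threshold acceptance set on a toy table."""
        scores = [10, 9.5, 9, 8, 7, 6, 5, 4]
        classes = [
            ("c0", True, True), ("c1", True, True), ("c2", True, True),
            ("c3", True, False), ("c4", True, True), ("c5", False, False),
            ("c6", True, True), ("c7", True, True),
        ]
        recs = [
            _rec(i, s, tgt_a=ta, tgt_b=tb)
            for i, (s, (cid, ta, tb)) in enumerate(zip(scores, classes))
        ]
        res = grouped_fdr(recs, level="csm", thresholds={"csm": 0.34})
        got = set(res.levels["csm"][res.levels["csm"]["accepted"]]["csm_id"])

        # brute force: for every threshold t compute (TD-DD)/TT over score>=t;
        # q(item) = min FDR over all thresholds accepting it
        def fdr_at(t):
            sub = [(s, r.td_class) for s, r in zip(scores, recs) if s >= t]
            tt = sum(1 for _, c in sub if c == "TT")
            td = sum(1 for _, c in sub if c == "TD")
            dd = sum(1 for _, c in sub if c == "DD")
            return max(0.0, (td - dd) / tt) if tt else np.inf

        expected = set()
        for i, r in enumerate(recs):
            qi = min(fdr_at(t) for t in scores if t <= scores[i])
            if r.td_class == "TT" and qi <= 0.34:
                expected.add(r.csm_id)
        lvl = res.levels["csm"]
        accepted_tt = set(lvl[lvl["accepted"] & (lvl["td_class"] == "TT")]["csm_id"])
        assert accepted_tt == expected

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            grouped_fdr([_rec(0, 1)], level="protein_group")

    def test_rollup_aggregates_by_best_member(self):
        # two CSMs on the same peptide pair: the pair keeps the best score
        a = _rec(0, 5)
        b = CSMRecord(**{**a.__dict__, "csm_id": "c1", "score": 9.0})
        res = grouped_fdr([a, b], level="peptide_pair")
        pp = res.levels["peptide_pair"]
        assert pp.shape[0] == 1 and pp.iloc[0]["score"] == 9.0
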