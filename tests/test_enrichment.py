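"""Sign-stratified Fisher enrichment: exactness, filters, verdicts."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from chromlink.enrichment import (
    ContingencyTable,
    build_contingency,
    enrichment_scan,
    fisher_one_sided,
    heat_matrix,
    results_to_frame,
)
from chromlink.synthetic import SyntheticConfig, generate_peaks_and_contacts
from helpers import contact, exact_fisher_tails, peak


class TestBuildContingency:
    def test_clean_split_by_construction(self):
        peaks = [peak("chr1", i * 1000, i * 1000 + 100, sign="+") for i in range(3)]
        peaks += [peak("chr1", i * 1000, i * 1000 + 100, sign="-") for i in range(3, 6)]
        flags = [True] * 3 + [False] * 3
        t = build_contingency(peaks, flags, "L1", "H3K27ac")
        assert (t.a, t.b, t.c, t.d) == (3, 0, 0, 3)

    def test_single_sign_gives_empty_minus_row(self):
        peaks = [peak("chr1", 0, 100, sign="+"), peak("chr1", 200, 300, sign="+")]
        t = build_contingency(peaks, [True, False], "L1", "H3K27ac")
        assert (t.c, t.d) == (0, 0) and t.is_degenerate

    def test_other_marks_and_lncrnas_excluded(self):
        peaks = [
            peak("chr1", 0, 100, lnc="L1", mark="H3K27ac", sign="+"),
            peak("chr1", 0, 100, lnc="L1", mark="H3K4me3", sign="+"),
            peak("chr1", 0, 100, lnc="L2", mark="H3K27ac", sign="-"),
        ]
        t = build_contingency(peaks, [True, True, True], "L1", "H3K27ac")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 0)

    def test_mixed_fixture_matches_hand_tally(self):
        spec = [("+", True)] * 4 + [("+", False)] * 2 + [("-", True)] * 1 + [("-", False)] * 3
        peaks = [peak("chr1", i * 1000, i * 1000 + 10, sign=s) for i, (s, _) in enumerate(spec)]
        flags = [ok for _, ok in spec]
        t = build_contingency(peaks, flags, "L1", "H3K27ac")
        assert (t.a, t.b, t.c, t.d) == (4, 2, 1, 3)

    def test_zero_peaks_degenerate_table(self):
        t = build_contingency([], [], "L1", "H3K27ac")
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0) and t.is_degenerate


class TestFisherOneSided:
    def test_clean_split_right_tail_is_one_twentieth(self):
        t = ContingencyTable(3, 0, 0, 3)
        # only the observed table in the right tail: C(3,3)C(3,0)/C(6,3) = 1/20
        assert fisher_one_sided(t, "right") == pytest.approx(0.05, abs=1e-12)

    def test_clean_split_left_tail_is_one(self):
        assert fisher_one_sided(ContingencyTable(3, 0, 0, 3), "left") == pytest.approx(1.0)

    def test_degenerate_margin_returns_one(self):
        assert fisher_one_sided(ContingencyTable(0, 0, 0, 0), "right") == 1.0
        assert fisher_one_sided(ContingencyTable(5, 3, 0, 0), "left") == 1.0

    def test_invalid_tail_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided(ContingencyTable(1, 1, 1, 1), "two")

    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    @settings(derandomize=True, max_examples=300)
    def test_matches_exact_enumeration(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        if t.is_degenerate:
            assert fisher_one_sided(t, "right") == 1.0
            return
        right, left = exact_fisher_tails(a, b, c, d)
        assert fisher_one_sided(t, "right") == pytest.approx(float(right), abs=1e-12)
        assert fisher_one_sided(t, "left") == pytest.approx(float(left), abs=1e-12)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(derandomize=True, max_examples=300)
    def test_tail_complementarity(self, a, b, c, d):
        """P(A >= a) + P(A <= a) - P(A = a) = 1 for every non-degenerate table."""
        t = ContingencyTable(a, b, c, d)
        if t.is_degenerate:
            return
        pmf = float(hypergeom.pmf(a, t.total, t.n_confirmed, t.n_plus))
        total = fisher_one_sided(t, "right") + fisher_one_sided(t, "left") - pmf
        assert total == pytest.approx(1.0, abs=1e-9)


class TestEnrichmentScan:
    def _planted(self, seed=11):
        cfg = SyntheticConfig(seed=seed, n_lncrnas=6, peaks_per_pair=60,
                              marks=("H3K27ac", "H3K4me3", "H3K27me3"),
                              background_contacts=100)
        return generate_peaks_and_contacts(cfg)

    def test_low_support_lncrna_excluded_entirely(self):
        # one lncRNA whose only mark has support 0.25 <= 0.4: never tested
        peaks = [peak("chr1", i * 1_000_000, i * 1_000_000 + 100,
                      sign="+" if i % 2 else "-") for i in range(4)]
        contacts = [contact("chr1", 0, 50)]
        results = enrichment_scan(peaks, contacts, w=0, support_threshold=0.4)
        assert results == []

    def test_symmetric_table_gives_no_verdict(self):
        # a = c and b = d: both tails >= 0.5
        peaks = [peak("chr1", i * 1_000_000, i * 1_000_000 + 100, sign=s)
                 for i, s in enumerate(["+", "+", "-", "-"])]
        contacts = [contact("chr1", 0, 50), contact("chr1", 2_000_000, 2_000_050)]
        results = enrichment_scan(peaks, contacts, w=0, support_threshold=0.4)
        (r,) = results
        assert (r.table.a, r.table.b, r.table.c, r.table.d) == (1, 1, 1, 1)
        assert r.p_right >= 0.5 and r.p_left >= 0.5
        assert r.verdict == "none"

    def test_planted_truth_recovered(self):
        peaks, contacts, truth = self._planted()
        results = enrichment_scan(peaks, contacts, w=25_000)
        verdicts = {(r.lncrna_id, r.mark): r.verdict for r in results}
        want = {"plus": "plus_enriched", "minus": "minus_enriched"}
        hits = sum(verdicts.get((l, m)) == want[d] for l, m, d in truth)
        assert hits >= 0.9 * len(truth)
        truth_set = {(l, m) for l, m, _ in truth}
        for r in results:
            if r.verdict != "none":
                assert (r.lncrna_id, r.mark) in truth_set

    def test_row_permutation_invariance(self):
        peaks, contacts, _ = self._planted(seed=12)
        base = results_to_frame(enrichment_scan(peaks, contacts))
        perm = results_to_frame(
            enrichment_scan(list(reversed(peaks)), list(reversed(contacts)))
        )
        assert base.equals(perm)

    def test_pair_gate_vs_lncrna_gate(self):
        peaks, contacts, _ = self._planted(seed=13)
        by_lnc = enrichment_scan(peaks, contacts, gate="lncrna")
        by_pair = enrichment_scan(peaks, contacts, gate="pair")
        # pair gating is at least as strict: tested pairs are a subset
        keys_pair = {(r.lncrna_id, r.mark) for r in by_pair}
        keys_lnc = {(r.lncrna_id, r.mark) for r in by_lnc}
        assert keys_pair <= keys_lnc
        assert all(r.passes_support_filter for r in by_pair)

    def test_bh_columns_present_and_no_smaller_than_raw(self):
        peaks, contacts, _ = self._planted(seed=14)
        for r in enrichment_scan(peaks, contacts):
            assert r.q_right is not None and r.q_right >= r.p_right - 1e-15
            assert r.q_left is not None and r.q_left >= r.p_left - 1e-15

    def test_heat_matrix_encodes_filtered_verdicts(self):
        peaks, contacts, truth = self._planted(seed=15)
        results = enrichment_scan(peaks, contacts)
        plus = heat_matrix(results, "plus")
        assert set(plus.values.ravel()) <= {0, 1}
        for r in results:
            expected = int(r.verdict == "plus_enriched" and r.passes_support_filter)
            assert plus.loc[r.lncrna_id, r.mark] == expected

    def test_support_fractions_match_table(self):
        peaks, contacts, _ = self._planted(seed=16)
        for r in enrichment_scan(peaks, contacts):
            t = r.table
            if t.n_plus:
                assert r.support_plus == pytest.approx(t.a / t.n_plus)
            if t.total:
                assert r.support == pytest.approx(t.n_confirmed / t.total)
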