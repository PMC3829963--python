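"""IsomiR acceptance rule: scanning, classification, multimap policies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isomirseq.matcher import (
    MatcherError,
    MatureAnnotation,
    Precursor,
    classify_isomir,
    match_tag,
    match_tag_table,
    resolve_multimap,
    scan_precursor,
)

from .conftest import MATURE22, brute_force_scan, make_hairpin

dna = st.text(alphabet="ACGT", min_size=1)


class TestScanPrecursor:
    def test_exact_substring_found_with_zero_mismatches(self):
        prec = make_hairpin(MATURE22)
        tag = MATURE22
        hits = scan_precursor(tag, prec)
        assert (5, 0) in hits

    def test_two_substitutions_rejected(self):
        prec = make_hairpin(MATURE22, flank5="", flank3="")
        tag = "TT" + MATURE22[2:]
        assert MATURE22[:2] != "TT"
        assert scan_precursor(tag, prec) == []

    def test_tag_longer_than_precursor_empty(self):
        prec = make_hairpin(MATURE22, flank5="", flank3="")
        assert scan_precursor(MATURE22 + "ACGT", prec) == []

    @settings(max_examples=200, derandomize=True)
    @given(
        seq=st.text(alphabet="ACGT", min_size=20, max_size=200),
        tag=st.text(alphabet="ACGT", min_size=15, max_size=30),
        max_mm=st.integers(min_value=0, max_value=2),
    )
    def test_equivalent_to_brute_force_oracle(self, seq, tag, max_mm):
        prec = Precursor(
            id="p", sequence=seq, chrom="c", start=0, end=len(seq), strand="+",
            matures=(MatureAnnotation("m", "5p", 0, min(20, len(seq))),),
        ) if len(seq) >= 20 else None
        if prec is None:
            return
        assert scan_precursor(tag, prec, max_mm) == brute_force_scan(tag, seq, max_mm)


class TestClassifyIsomir:
    def test_canonical_mature_has_zero_offsets(self):
        prec = make_hairpin(MATURE22, flank5="GGGG", flank3="TTTT")
        hits = classify_isomir(MATURE22, 4, 0, prec)
        assert len(hits) == 1
        h = hits[0]
        assert (h.offset5, h.offset3, h.mismatches) == (0, 0, 0)

    def test_5prime_trimmed_isomir_offsets(self):
        prec = make_hairpin(MATURE22, flank5="GGGG", flank3="TTTT")
        hits = classify_isomir(MATURE22[1:], 5, 0, prec)
        assert len(hits) == 1
        assert (hits[0].offset5, hits[0].offset3) == (1, 0)

    def test_5nt_upstream_placement_rejected(self):
        prec = make_hairpin(MATURE22, flank5="GGGGG", flank3="TTTTT")
        tag = prec.sequence[0 : len(MATURE22)]  # starts 5 nt before the mature
        assert classify_isomir(tag, 0, 0, prec) == []

    def test_4nt_offset_still_accepted(self):
        prec = make_hairpin(MATURE22, flank5="GGGG", flank3="TTTT")
        tag = prec.sequence[0 : 4 + len(MATURE22)]  # 4 nt of 5' extension
        hits = classify_isomir(tag, 0, 0, prec)
        assert len(hits) == 1 and hits[0].offset5 == -4


class TestMultimap:
    def _paralog_hits(self):
        p1 = make_hairpin(MATURE22, pid="hpA", mid="mirA")
        p2 = make_hairpin(MATURE22, flank5="CCCC", flank3="AAAA", pid="hpB", mid="mirB")
        return match_tag(MATURE22, [p1, p2])

    def test_all_policy_attributes_full_count_to_both(self):
        assigned = resolve_multimap(self._paralog_hits(), "all")
        assert {h.mature_id for h, _ in assigned} == {"mirA", "mirB"}
        assert all(w == 1.0 for _, w in assigned)

    def test_fractional_policy_halves_weight(self):
        assigned = resolve_multimap(self._paralog_hits(), "fractional")
        assert sorted(w for _, w in assigned) == [0.5, 0.5]

    def test_unique_only_discards_multimapper(self):
        assert resolve_multimap(self._paralog_hits(), "unique-only") == []

    def test_unknown_policy_raises(self):
        with pytest.raises(MatcherError):
            resolve_multimap(self._paralog_hits(), "best")

    def test_best_placement_within_precursor_prefers_fewest_mismatches(self):
        # mature repeated with one mismatch downstream in the same hairpin is
        # not annotated, so only the annotated region yields a hit
        prec = make_hairpin(MATURE22, flank5="GGGG", flank3="TTTT")
        hits = match_tag(MATURE22, [prec])
        assert len(hits) == 1 and hits[0].mismatches == 0


class TestBatchMatcher:
    def test_batch_equals_per_tag_path(self, small_precursors):
        rng = np.random.default_rng(0)
        tags = []
        for prec in small_precursors[:6]:
            m = prec.matures[0]
            seq = prec.mature_sequence(m)
            tags.append(seq)
            tags.append(seq[1:] + "A")  # shifted variant
            mutated = list(seq)
            pos = int(rng.integers(len(seq)))
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
            tags.append("".join(mutated))
        table = pd.DataFrame(
            {"sequence": tags, "count": 2, "library_id": "lib"}
        ).drop_duplicates("sequence")
        batch = match_tag_table(table, small_precursors, policy="all")
        expected = []
        for seq in table["sequence"]:
            for hit, w in resolve_multimap(match_tag(seq, small_precursors), "all"):
                expected.append((seq, hit.mature_id, hit.offset5, hit.offset3,
                                 hit.mismatches, w))
        got = [
            (r.sequence, r.mature_id, r.offset5, r.offset3, r.mismatches, r.weight)
            for r in batch.itertuples()
        ]
        assert sorted(got) == sorted(expected)

    def test_window_and_mismatch_soundness(self, small_precursors, small_cfg,
                                           small_truth):
        from isomirseq import preprocess
        from isomirseq.simdata import simulate_library

        records, _, _ = simulate_library(
            small_precursors, small_truth, "case", small_cfg
        )
        reads = preprocess.records_to_reads(records)
        tags, _ = preprocess.preprocess_library(
            reads, "case", adapter3=small_cfg.adapter3
        )
        hits = match_tag_table(tags, small_precursors)
        assert not hits.empty
        assert hits["offset5"].abs().max() <= 4
        assert hits["offset3"].abs().max() <= 4
        assert hits["mismatches"].max() <= 1
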