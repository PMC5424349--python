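"""Hit filtering, subsequence extraction, alignment construction and scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayeslca.alignment import (
    AlignedBlock,
    AlignerNotFoundError,
    FilterConfig,
    ScoringScheme,
    build_msa,
    column_pair_scores,
    extract_padded_subject,
    filter_hits,
    nw_align,
    pairwise_score,
    reverse_complement,
    search_hits,
    self_score,
)
from bayeslca.formats import FormatError, HitRow, QueryRecord, ReferenceRecord

from .conftest import random_dna
from .oracles import filter_predicate_oracle, nw_score_oracle


def make_hit(subject="r1", pident=99.0, bitscore=1000.0, qstart=1, qend=100,
             qlen=100, sstart=1, send=100, query="q1"):
    return HitRow(query, subject, pident, max(qend - qstart + 1, abs(send - sstart) + 1),
                  0, 0, qstart, qend, sstart, send, 0.0, bitscore, qlen)


class TestFilterHits:
    def test_top_percent_worked_example(self):
        hits = [make_hit(subject=f"r{i}", bitscore=s)
                for i, s in enumerate([1000, 950, 900, 899.9, 500])]
        kept = filter_hits(hits, FilterConfig(top_percent=10))
        assert [h.bitscore for h in kept] == [1000, 950, 900]

    def test_single_good_hit_retained(self):
        hits = [make_hit(pident=99.0, qstart=1, qend=100, qlen=100)]
        assert filter_hits(hits) == hits

    def test_identity_and_coverage_thresholds(self):
        low_id = make_hit(subject="a", pident=94.9)
        low_cov = make_hit(subject="b", qstart=1, qend=94, qlen=100)
        good = make_hit(subject="c")
        assert filter_hits([low_id, low_cov, good]) == [good]

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(17)
        hits = [
            make_hit(
                subject=f"r{i}",
                pident=float(rng.uniform(85, 100)),
                bitscore=float(rng.uniform(500, 1000)),
                qstart=1,
                qend=int(rng.integers(85, 101)),
            )
            for i in range(50)
        ]
        cfg = FilterConfig(min_identity=92, min_coverage=90, top_percent=25)
        expected = filter_predicate_oracle(hits, 92, 90, 25)
        assert filter_hits(hits, cfg) == expected  # unique subjects: no dedup effect

    def test_one_hit_per_subject(self):
        dup_lo = make_hit(subject="r1", bitscore=950)
        dup_hi = make_hit(subject="r1", bitscore=990)
        kept = filter_hits([dup_lo, dup_hi, make_hit(subject="r2", bitscore=1000)])
        assert {h.subject_id: h.bitscore for h in kept} == {"r1": 990, "r2": 1000}

    def test_mixed_queries_rejected(self):
        with pytest.raises(ValueError, match="single query"):
            filter_hits([make_hit(query="q1"), make_hit(query="q2")])

    @given(
        tp_low=st.floats(0, 50),
        tp_delta=st.floats(0, 50),
        scores=st.lists(st.floats(1, 1000), min_size=1, max_size=20),
    )
    @settings(derandomize=True, max_examples=50)
    def test_raising_top_percent_is_monotone(self, tp_low, tp_delta, scores):
        hits = [make_hit(subject=f"r{i}", bitscore=s) for i, s in enumerate(scores)]
        lo = filter_hits(hits, FilterConfig(top_percent=tp_low))
        hi = filter_hits(hits, FilterConfig(top_percent=tp_low + tp_delta))
        assert set(h.subject_id for h in lo) <= set(h.subject_id for h in hi)


class TestExtraction:
    REF = ReferenceRecord(id="r1", seq=random_dna(np.random.default_rng(1), 100), taxid="t")

    def test_pad_clamped_at_sequence_start(self):
        hit = make_hit(sstart=11, send=20, qend=10, qlen=10)
        assert extract_padded_subject(self.REF, hit, pad=10) == self.REF.seq[0:30]

    def test_minus_strand_is_reverse_complemented(self):
        hit = make_hit(sstart=20, send=11, qend=10, qlen=10)
        assert extract_padded_subject(self.REF, hit, pad=10) == reverse_complement(
            self.REF.seq[0:30]
        )

    def test_zero_pad_is_exact_region(self):
        hit = make_hit(sstart=11, send=20, qend=10, qlen=10)
        assert extract_padded_subject(self.REF, hit, pad=0) == self.REF.seq[10:20]

    def test_out_of_range_coordinates_rejected(self):
        hit = make_hit(sstart=50, send=149, qend=100, qlen=100)
        with pytest.raises(FormatError, match="coordinates"):
            extract_padded_subject(self.REF, hit)


class TestNeedlemanWunsch:
    def test_known_alignment_with_gap(self):
        score, qa, sa = nw_align("ACGT", "ACT")
        assert score == pytest.approx(0.5)  # 3 matches + 1 gap
        assert qa == "ACGT" and sa == "AC-T"

    def test_matches_brute_force_scores(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            a = random_dna(rng, int(rng.integers(1, 50)))
            b = random_dna(rng, int(rng.integers(1, 50)))
            score, qa, sa = nw_align(a, b)
            assert score == pytest.approx(nw_score_oracle(a, b), abs=1e-9)
            assert qa.replace("-", "") == a and sa.replace("-", "") == b

    def test_n_is_scored_as_mismatch(self):
        score, _, _ = nw_align("AN", "AN")
        assert score == pytest.approx(1.0 - 2.0)


class TestStarMsa:
    Q = QueryRecord(id="q", seq="ACGT")

    def test_identical_subject_gives_gapless_block(self):
        block = build_msa(self.Q, {"s": "ACGT"})
        assert block.column_count == 4
        assert block.query_row == "ACGT" and block.hit_rows["s"] == "ACGT"

    def test_deleted_base_gives_one_gap_column(self):
        block = build_msa(self.Q, {"s": "ACT"})
        assert block.query_row == "ACGT"
        assert block.hit_rows["s"] == "AC-T"

    def test_two_identical_subjects(self):
        block = build_msa(self.Q, {"a": "ACGT", "b": "ACGT"})
        assert block.hit_rows["a"] == block.hit_rows["b"] == block.query_row

    def test_subject_insertion_anchors_on_query(self):
        block = build_msa(self.Q, {"long": "ACGGGT", "same": "ACGT"})
        assert block.query_row.replace("-", "") == "ACGT"
        # filler columns are gaps in every row that lacks the insertion
        for row in (block.query_row, block.hit_rows["same"]):
            assert len(row) == block.column_count
        assert pairwise_score(block, "same") == pytest.approx(
            nw_score_oracle("ACGT", "ACGT")
        )

    def test_merged_scores_equal_pairwise_optimum(self):
        rng = np.random.default_rng(31)
        query = QueryRecord(id="q", seq=random_dna(rng, 40))
        subjects = {}
        for i in range(4):
            seq = list(query.seq)
            for _ in range(int(rng.integers(0, 6))):
                pos = int(rng.integers(0, len(seq)))
                op = rng.random()
                if op < 0.4:
                    seq[pos] = "ACGT"[int(rng.integers(0, 4))]
                elif op < 0.7 and len(seq) > 2:
                    del seq[pos]
                else:
                    seq.insert(pos, "ACGT"[int(rng.integers(0, 4))])
            subjects[f"s{i}"] = "".join(seq)
        block = build_msa(query, subjects)
        for sid, sseq in subjects.items():
            assert pairwise_score(block, sid) == pytest.approx(
                nw_score_oracle(query.seq, sseq), abs=1e-9
            )

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError, match="backend"):
            build_msa(self.Q, {"s": "ACGT"}, backend="magic")


class TestColumnScores:
    def _block(self, qrow, srow):
        return AlignedBlock(query_id="q", query_row=qrow, hit_rows={"s": srow})

    def test_all_match_identity(self):
        assert pairwise_score(self._block("ACGT", "ACGT"), "s") == pytest.approx(4.0)

    def test_three_matches_one_mismatch(self):
        assert pairwise_score(self._block("ACGT", "ACGA"), "s") == pytest.approx(1.0)

    def test_two_matches_one_gap(self):
        assert pairwise_score(self._block("ACG", "AC-"), "s") == pytest.approx(-0.5)

    def test_double_gap_columns_score_zero(self):
        block = AlignedBlock("q", "AC-G", {"s": "AC-G", "t": "ACTG"})
        assert pairwise_score(block, "s") == pytest.approx(3.0)
        assert pairwise_score(block, "t") == pytest.approx(3.0 - 2.5)

    def test_self_score_counts_residues(self):
        block = self._block("ACGT", "AC-T")
        assert self_score(block, "s") == pytest.approx(3.0)
        rng = np.random.default_rng(2)
        row = "".join(rng.choice(list("ACGT-"), size=30))
        block2 = self._block("A" * 30, row)
        assert self_score(block2, "s") == pytest.approx(30 - row.count("-"))

    def test_column_subsets_additive_and_order_free(self):
        rng = np.random.default_rng(3)
        qrow = "".join(rng.choice(list("ACGT-"), size=25))
        srow = "".join(rng.choice(list("ACGT-"), size=25))
        block = self._block(qrow, srow)
        cols = np.arange(25)
        left, right = cols[:12], cols[12:]
        total = pairwise_score(block, "s", columns=cols)
        assert total == pytest.approx(
            pairwise_score(block, "s", columns=left)
            + pairwise_score(block, "s", columns=right)
        )
        perm = rng.permutation(cols)
        assert pairwise_score(block, "s", columns=perm) == pytest.approx(total)

    def test_self_bounds_pairwise(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            qrow = "".join(rng.choice(list("ACGT-"), size=20))
            srow = "".join(rng.choice(list("ACGT-"), size=20))
            block = self._block(qrow, srow)
            cols = rng.integers(0, 20, size=15)
            assert self_score(block, "s", columns=cols) >= pairwise_score(
                block, "s", columns=cols
            )

    def test_unknown_subject_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            pairwise_score(self._block("AC", "AC"), "nope")


class TestExternalAligner:
    def test_missing_binary_names_fallback(self):
        with pytest.raises(AlignerNotFoundError, match="internal"):
            build_msa(QueryRecord(id="q", seq="ACGT"), {"s": "ACGT"},
                      backend="external", binary="no-such-aligner-binary")

    def test_mafft_adapter_round_trip(self):
        rng = np.random.default_rng(9)
        query = QueryRecord(id="q", seq=random_dna(rng, 60))
        subject = query.seq[:25] + query.seq[30:]  # 5 nt deletion
        block = build_msa(query, {"s": subject}, backend="external", binary="mafft")
        assert block.query_row.replace("-", "") == query.seq
        assert block.hit_rows["s"].replace("-", "") == subject


class TestInternalSearch:
    def test_identical_reference_scores_perfectly(self):
        rng = np.random.default_rng(13)
        seq = random_dna(rng, 120)
        query = QueryRecord(id="q", seq=seq)
        other = ReferenceRecord(id="far", seq=random_dna(rng, 120), taxid="t2")
        rows = search_hits(query, [ReferenceRecord(id="same", seq=seq, taxid="t1"), other])
        by_id = {r.subject_id: r for r in rows}
        assert by_id["same"].pct_identity == pytest.approx(100.0)
        assert by_id["same"].bitscore == pytest.approx(len(seq))
        assert by_id["same"].bitscore > by_id["far"].bitscore
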