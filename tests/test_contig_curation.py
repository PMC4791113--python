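"""Contig QC filters, read-stop tallies and terminal-end calling."""

import numpy as np
import pytest

from flds.contig_curation import (
    QCThresholds,
    TerminalParams,
    call_termini,
    classify_completeness,
    qc_filter,
    tally_read_stops,
)
from flds.formats_io import Alignment, CoverageVector, SequenceRecord
from flds.primers import PC2_RC
from flds.trim_map import TrimRecord


def _contig(length=1000, cid="c1"):
    return SequenceRecord(cid, "ACGT" * (length // 4) + "A" * (length % 4))


def _cov(depths, cid="c1"):
    return CoverageVector(cid, np.asarray(depths, dtype=np.int64))


class TestQcFilter:
    def test_boundary_values_pass_inclusively(self):
        # 1000 bp, min depth 3, mean exactly 10
        depths = [3] * 500 + [17] * 500
        passing, report = qc_filter([_contig(1000)], {"c1": _cov(depths)})
        assert [c.id for c in passing] == ["c1"]
        assert report[0]["passed"]

    @pytest.mark.parametrize("length,depths,reason", [
        (996, [100] * 996, "length"),                      # below 1000 bp
        (2000, [2] + [100] * 1999, "per_base"),            # one base at 2x
        (1000, [3] * 500 + [16] * 500, "average"),         # mean 9.5
    ])
    def test_single_criterion_failures(self, length, depths, reason):
        passing, report = qc_filter([_contig(length)], {"c1": _cov(depths)})
        assert passing == []
        assert reason in report[0]["failure_reasons"]

    def test_missing_coverage_vector_is_error(self):
        with pytest.raises(ValueError, match="no coverage"):
            qc_filter([_contig(1000)], {})

    def test_raising_thresholds_never_grows_passing_set(self):
        rng = np.random.default_rng(1)
        contigs, coverage = [], {}
        for i in range(20):
            length = int(rng.integers(500, 2000))
            contigs.append(SequenceRecord(f"c{i}", "A" * length))
            coverage[f"c{i}"] = _cov(rng.integers(0, 30, length), f"c{i}")
        base = QCThresholds()
        passing, _ = qc_filter(contigs, coverage, base)
        base_ids = {c.id for c in passing}
        for stricter in (
            QCThresholds(min_per_base_coverage=5),
            QCThresholds(min_average_coverage=15),
            QCThresholds(min_length=1500),
        ):
            tighter, _ = qc_filter(contigs, coverage, stricter)
            assert {c.id for c in tighter} <= base_ids


class TestTallyReadStops:
    def test_left_counts_by_start_position(self):
        alns = [Alignment(f"r{i}", "c1", 0, 300) for i in range(11)]
        alns += [Alignment(f"s{i}", "c1", 5, 300) for i in range(2)]
        tables = tally_read_stops(alns, 2000)
        assert tables.left == {0: 11, 5: 2}
        assert tables.right == {}

    def test_interior_alignments_ignored(self):
        alns = [Alignment("r1", "c1", 500, 800)]
        tables = tally_read_stops(alns, 2000)
        assert tables.left == {} and tables.right == {}

    def test_matches_brute_force_on_random_alignments(self):
        rng = np.random.default_rng(3)
        length, window = 1500, 100
        alns = []
        for i in range(500):
            s = int(rng.integers(0, length - 200))
            alns.append(Alignment(f"r{i}", "c1", s, s + 200))
        tables = tally_read_stops(alns, length, window)
        left_bf, right_bf = {}, {}
        for a in alns:
            if a.start < window:
                left_bf[a.start] = left_bf.get(a.start, 0) + 1
            if a.end > length - window:
                right_bf[a.end] = right_bf.get(a.end, 0) + 1
        assert tables.left == left_bf and tables.right == right_bf

    def test_window_clamped_to_contig_length(self):
        tables = tally_read_stops([Alignment("r", "c1", 0, 50)], 80, window=200)
        assert tables.window == 80


def _stop_scenario(support, with_primer, contig_seq=None, side="left"):
    """Build alignments + trim records for one candidate stop position."""
    contig_seq = contig_seq or ("ACGT" * 500)
    length = len(contig_seq)
    alns, recs = [], {}
    for i in range(support):
        rid = f"r{i}"
        if side == "left":
            alns.append(Alignment(rid, "c1", 0, 250, "+"))
            recs[rid] = TrimRecord(rid, removed_prefix=PC2_RC if with_primer else "")
        else:
            alns.append(Alignment(rid, "c1", length - 250, length, "-"))
            recs[rid] = TrimRecord(rid, removed_prefix=PC2_RC if with_primer else "")
    # background interior reads
    for i in range(5):
        rid = f"bg{i}"
        alns.append(Alignment(rid, "c1", 300 + i, 600 + i, "+"))
        recs[rid] = TrimRecord(rid)
    tables = tally_read_stops(alns, length)
    return tables, recs, contig_seq


class TestCallTermini:
    def test_support_eleven_with_primer_confirmed(self):
        tables, recs, seq = _stop_scenario(11, with_primer=True)
        (call,) = call_termini(tables, recs, seq)
        assert (call.side, call.position, call.support) == ("left", 0, 11)
        assert call.primer_confirmed and call.status == "confirmed"

    def test_support_ten_is_not_dominant(self):
        # "more than 10 reads" is strict
        tables, recs, seq = _stop_scenario(10, with_primer=True)
        assert call_termini(tables, recs, seq) == []

    def test_support_without_evidence_unconfirmed(self):
        tables, recs, seq = _stop_scenario(15, with_primer=False)
        (call,) = call_termini(tables, recs, seq)
        assert call.status == "unconfirmed"
        assert not call.primer_confirmed and not call.polyA

    def test_polya_tail_confirms_right_side_without_primer(self):
        seq = "ACGT" * 497 + "AAAAAAAAAAAA"  # 12-A tail
        tables, recs, _ = _stop_scenario(15, with_primer=False, contig_seq=seq,
                                         side="right")
        (call,) = call_termini(tables, recs, seq)
        assert (call.side, call.position) == ("right", len(seq) - 1)
        assert call.polyA and call.status == "confirmed"

    def test_minus_strand_read_uses_removed_suffix(self):
        seq = "ACGT" * 500
        alns = [Alignment(f"r{i}", "c1", 0, 250, "-") for i in range(12)]
        recs = {f"r{i}": TrimRecord(f"r{i}", removed_suffix=PC2_RC)
                for i in range(12)}
        tables = tally_read_stops(alns, len(seq))
        (call,) = call_termini(tables, recs, seq)
        assert call.primer_confirmed

    def test_recall_and_precision_on_simulated_community(
            self, small_community, small_mapped):
        community, _, trim_records, by_contig = small_mapped
        for contig in community.segments:
            length = len(contig.sequence)
            tables = tally_read_stops(by_contig[contig.id], length)
            calls = call_termini(tables, trim_records, contig.sequence)
            positions = {(c.side, c.position, c.status) for c in calls}
            assert positions == {("left", 0, "confirmed"),
                                 ("right", length - 1, "confirmed")}


class TestCompleteness:
    def _call(self, side, confirmed=True, pos=0):
        from flds.contig_curation import TerminalCall
        return TerminalCall("c1", side, pos, 20, primer_confirmed=confirmed,
                            polyA=False)

    def test_both_confirmed_is_full_length(self):
        status = classify_completeness(
            _contig(), [self._call("left"), self._call("right", pos=999)])
        assert status.completeness == "full-length"

    def test_one_side_is_partial(self):
        status = classify_completeness(_contig(), [self._call("left")])
        assert status.completeness == "partial"

    def test_unconfirmed_calls_do_not_count(self):
        status = classify_completeness(
            _contig(), [self._call("left", confirmed=False),
                        self._call("right", confirmed=False, pos=999)])
        assert status.completeness == "partial"

    def test_two_confirmed_same_side_is_ambiguous(self):
        with pytest.raises(ValueError, match="ambiguous"):
            classify_completeness(
                _contig(), [self._call("left", pos=0), self._call("left", pos=3)])
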