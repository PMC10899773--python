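import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chargeseq import (
    FIVEP_ADAPTER,
    THREEP_CONST,
    InsertRead,
    SampleRow,
    SampleSheet,
    TrimRejection,
    demultiplex,
    prepare_reads,
    trim_insert,
)
from chargeseq.io import revcomp

BASES = "ACGT"


def _mk_pair(trna_segment, barcode="ACACA", umi="GGTTG", read_length=150, rid="r1"):
    """Build an error-free read pair for an arbitrary tRNA segment."""
    mol = FIVEP_ADAPTER + trna_segment + umi + barcode + THREEP_CONST
    core = mol[: -len(THREEP_CONST)]
    r1 = mol[:read_length]
    r2 = revcomp(core)[:read_length]
    return ((rid, r1, "I" * len(r1)), (rid, r2, "I" * len(r2)))


def _sheet(barcodes=("ACACA",), condition="c"):
    return SampleSheet(
        [SampleRow(f"s{i}", bc, condition, i + 1) for i, bc in enumerate(barcodes)]
    )


class TestSampleSheet:
    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            _sheet(("ACACA", "ACACA"))

    def test_bad_barcode_length_rejected(self):
        with pytest.raises(ValueError, match="5 nt"):
            _sheet(("ACAC",))

    def test_tsv_roundtrip(self, tmp_path):
        sheet = _sheet(("ACACA", "CGCGC"))
        path = tmp_path / "sheet.tsv"
        sheet.to_frame().to_csv(path, sep="\t", index=False)
        back = SampleSheet.from_tsv(path)
        assert back.to_frame().equals(sheet.to_frame())


class TestDemultiplex:
    def test_exact_match_assigns(self):
        pair = _mk_pair("A" * 40, barcode="ACACA")
        res = demultiplex([pair], _sheet(("ACACA", "CGCGC")))
        assert len(res.by_sample["s0"]) == 1
        assert res.n_discarded == 0

    def test_unmatched_barcode_discarded(self):
        pair = _mk_pair("A" * 40, barcode="GGGGG")  # not in sheet
        res = demultiplex([pair], _sheet(("ACACA", "CGCGC")))
        assert res.n_discarded == 1
        assert res.n_assigned == 0

    def test_one_mismatch_decoding(self):
        sheet = _sheet(("AAAAA", "TTTTT"))
        pair = _mk_pair("A" * 40, barcode="AAATA")
        res = demultiplex([pair], sheet, max_mismatch=1)
        assert len(res.by_sample["s0"]) == 1  # Hamming-nearest is AAAAA

    def test_ambiguous_barcode_set_is_config_error(self):
        sheet = _sheet(("AAAAA", "AATTT"))  # distance 3 <= 2*max_mismatch
        with pytest.raises(ValueError, match="too close"):
            demultiplex([], sheet, max_mismatch=2)

    def test_id_mismatch_rejected(self):
        p1, p2 = _mk_pair("A" * 40)
        p2 = ("other", p2[1], p2[2])
        with pytest.raises(ValueError, match="mismatch"):
            demultiplex([(p1, p2)], _sheet())

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 4**5 - 1), max_size=60), st.integers(0, 2**31 - 1))
    def test_partition_exactness(self, codes, seed):
        """Assigned + discarded == input, on arbitrary barcode streams."""
        sheet = _sheet(("ACACA", "CGCGC", "GTGTG"))
        pairs = []
        for i, code in enumerate(codes):
            bc = "".join(BASES[(code // 4**k) % 4] for k in range(5))
            pairs.append(_mk_pair("A" * 30, barcode=bc, rid=f"r{i}"))
        res = demultiplex(pairs, sheet)
        assert res.n_assigned + res.n_discarded == len(pairs)


class TestTrim:
    def test_exact_insert_recovery(self):
        body = "ACGTTGCA" * 9 + "TCGA"  # 76 nt
        pair = _mk_pair(body + "CCA")
        res = trim_insert(pair)
        assert isinstance(res, InsertRead)
        assert res.insert_seq == body + "CCA"
        assert len(res.insert_seq) == 79
        assert not res.pair_overlap_used

    def test_adapter_dimer_rejected_short(self):
        res = trim_insert(_mk_pair(""))
        assert res == TrimRejection("r1", "short")

    def test_length_filter_boundary(self):
        at_19 = trim_insert(_mk_pair("G" * 19))
        at_20 = trim_insert(_mk_pair("G" * 20))
        assert isinstance(at_19, TrimRejection) and at_19.reason == "short"
        assert isinstance(at_20, InsertRead) and len(at_20.insert_seq) == 20

    def test_pair_overlap_path_recovers_insert(self):
        """With 100-nt reads the 3'-constant never appears in R1."""
        body = "TGCA" * 19  # 76 nt
        pair = _mk_pair(body + "CCA", read_length=100)
        assert THREEP_CONST not in pair[0][1]
        res = trim_insert(pair)
        assert isinstance(res, InsertRead)
        assert res.insert_seq == body + "CCA"
        assert res.pair_overlap_used

    def test_no_threep_constant_in_output(self):
        for seg in ["A" * 25, "C" * 40 + "CC", THREEP_CONST + "ACGTACGTACGT"]:
            res = trim_insert(_mk_pair(seg))
            if isinstance(res, InsertRead):
                assert THREEP_CONST not in res.insert_seq

    def test_tolerates_one_substitution_in_adapters(self):
        body = "GATTACAC" * 9 + "GATT"  # 76 nt
        mol = FIVEP_ADAPTER + body + "CCA" + "GGTTG" + "ACACA" + THREEP_CONST
        mutated = "T" + mol[1:60] + mol[60:]  # hit the 5'-adapter
        r1 = mutated[:150]
        core = mol[: -len(THREEP_CONST)]
        r2 = revcomp(core)[:150]
        res = trim_insert((("r", r1, "I" * len(r1)), ("r", r2, "I" * len(r2))))
        assert isinstance(res, InsertRead)
        assert res.insert_seq == body + "CCA"


class TestPrepareReads:
    def test_error_free_sample_assignment_and_recovery(self, toy_ref, clean_sim):
        design, r1, r2, truth = clean_sim
        from chargeseq import sheet_from_design

        sheet = sheet_from_design(design)
        inserts, acct = prepare_reads(zip(r1, r2), sheet)
        assert acct["n_discarded"] == 0
        truth_sample = truth.reads.set_index("read_id")["sample_id"]
        truth_entry = truth.reads.set_index("read_id")
        for sid, recs in inserts.items():
            assert len(recs) == design.samples[
                [s.sample_id for s in design.samples].index(sid)
            ].n_reads
            for rec in recs[:200]:
                assert truth_sample[rec.read_id] == sid
                row = truth_entry.loc[rec.read_id]
                entry = toy_ref.get(row["entry_id"])
                expected = entry.seq if row["charged"] else entry.seq[:-1]
                assert rec.insert_seq == expected

    def test_accounting_partition(self, noisy_run):
        _, sheet, result, _ = noisy_run
        acct = result.accounting
        assigned = sum(s["assigned"] for s in acct["per_sample"].values())
        assert assigned + acct["n_discarded"] == acct["n_input"]
        for s in acct["per_sample"].values():
            assert s["trimmed"] + sum(s["rejected"].values()) == s["assigned"]
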