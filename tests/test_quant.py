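import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chargeseq import (
    CountTable,
    call_charge,
    condition_summary,
    fraction_by_group,
    normalize,
    tabulate,
)
from chargeseq.align import AlignmentResult
from chargeseq.quant import CHARGED, INDETERMINATE, UNCHARGED, ChargeCall


def _aln(end_offset, read_id="r", entry="e1", ref_len=79, m=30):
    end = ref_len - end_offset
    return AlignmentResult(read_id, entry, end - m, end, end_offset, 0, 1)


class TestCallCharge:
    def test_flush_cca_is_charged(self):
        call = call_charge(_aln(0), "G" * 27 + "CCA")
        assert call.state == CHARGED

    def test_one_short_cc_is_uncharged(self):
        call = call_charge(_aln(1), "G" * 28 + "CC")
        assert call.state == UNCHARGED

    def test_internal_end_is_indeterminate(self):
        call = call_charge(_aln(5), "G" * 28 + "CC")
        assert call.state == INDETERMINATE

    def test_terminal_mismatch_demotes_to_indeterminate(self):
        # flush with the reference end but last base sequenced as G
        call = call_charge(_aln(0), "G" * 27 + "CCG")
        assert call.state == INDETERMINATE


class TestTabulate:
    def test_counts_and_dense_zero_rows(self):
        calls = {
            "s1": [
                ChargeCall("r1", "e1", CHARGED),
                ChargeCall("r2", "e1", CHARGED),
                ChargeCall("r3", "e1", CHARGED),
                ChargeCall("r4", "e1", UNCHARGED),
                ChargeCall("r5", "e1", INDETERMINATE),
            ],
            "s2": [],
        }
        table = tabulate(calls, ["e1", "e2"])
        assert table.charged.at["e1", "s1"] == 3
        assert table.uncharged.at["e1", "s1"] == 1  # indeterminate excluded
        assert table.charged.at["e2", "s1"] == 0
        assert table.charged.at["e1", "s2"] == 0

    def test_matches_ground_truth_exactly_when_error_free(self, clean_run):
        sheet, result, truth = clean_run
        expected = truth.counts().set_index(["entry_id", "sample_id"])
        raw = result.raw_counts
        for (entry, sid), row in expected.iterrows():
            assert raw.charged.at[entry, sid] == row["n_charged"]
            assert raw.uncharged.at[entry, sid] == row["n_uncharged"]

    def test_conservation_per_sample(self, noisy_run):
        _, sheet, result, _ = noisy_run
        for sid, acct in result.accounting["per_sample"].items():
            assert (
                acct["charged"] + acct["uncharged"] + acct["indeterminate"]
                == acct["aligned"]
            )
            classified = (
                result.raw_counts.charged[sid].sum()
                + result.raw_counts.uncharged[sid].sum()
            )
            assert classified == acct["charged"] + acct["uncharged"]


def _table(charged_rows, uncharged_rows, samples):
    entries = [f"e{i}" for i in range(len(charged_rows))]
    return CountTable(
        charged=pd.DataFrame(charged_rows, index=entries, columns=samples, dtype=float),
        uncharged=pd.DataFrame(
            uncharged_rows, index=entries, columns=samples, dtype=float
        ),
    )


class TestNormalize:
    def test_textbook_coefficients(self):
        t = _table([[60, 150, 180]], [[40, 50, 120]], ["a", "b", "c"])
        # totals 100, 200, 300 -> coefficients 2, 1, 2/3
        norm = normalize(t)
        assert norm.coefficients.tolist() == pytest.approx([2.0, 1.0, 2 / 3])
        assert norm.charged.at["e0", "a"] == 120

    def test_single_sample_unchanged(self):
        t = _table([[10]], [[5]], ["only"])
        norm = normalize(t)
        assert norm.coefficients["only"] == 1.0
        assert norm.charged.equals(t.charged)

    def test_zero_total_sample_is_error(self):
        t = _table([[10, 0]], [[5, 0]], ["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            normalize(t)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(0, 10_000), min_size=2, max_size=8),
            min_size=1,
            max_size=6,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_normalized_totals_equal_grand_mean(self, rows):
        samples = [f"s{j}" for j in range(len(rows[0]))]
        arr = np.array(rows, dtype=float)
        t = _table(arr / 2, arr - arr / 2, samples)
        totals = t.sample_totals()
        if (totals == 0).any():
            with pytest.raises(ValueError):
                normalize(t)
            return
        norm = normalize(t)
        after = norm.sample_totals()
        assert np.allclose(after, totals.mean(), rtol=1e-9)
        assert math.isclose(after.sum(), totals.sum(), rel_tol=1e-9)

    def test_fraction_invariant_under_normalization(self, clean_run, toy_ref):
        _, result, _ = clean_run
        raw_frac = fraction_by_group(result.raw_counts, toy_ref, "anticodon")
        norm_frac = fraction_by_group(result.norm_counts, toy_ref, "anticodon")
        assert np.allclose(
            raw_frac.fractions, norm_frac.fractions, rtol=1e-12, equal_nan=True
        )


class TestFractions:
    def test_simple_ratio(self, toy_ref):
        entries = toy_ref.entry_ids
        charged = pd.DataFrame(0.0, index=entries, columns=["s1"])
        uncharged = pd.DataFrame(0.0, index=entries, columns=["s1"])
        charged.loc[entries[0], "s1"] = 80
        uncharged.loc[entries[0], "s1"] = 20
        ct = fraction_by_group(
            CountTable(charged, uncharged), toy_ref, level="gene"
        )
        assert ct.fractions.loc[entries[0], "s1"] == pytest.approx(0.8)

    def test_zero_denominator_is_undefined_not_zero(self, toy_ref):
        entries = toy_ref.entry_ids
        charged = pd.DataFrame(1.0, index=entries, columns=["s1", "s2"])
        uncharged = pd.DataFrame(1.0, index=entries, columns=["s1", "s2"])
        charged.loc[entries[0]] = 0
        uncharged.loc[entries[0]] = 0
        ct = fraction_by_group(CountTable(charged, uncharged), toy_ref, "gene")
        assert math.isnan(ct.fractions.loc[entries[0], "s1"])

    def test_amino_acid_level_sums_counts_not_fractions(self):
        # two anticodon groups of one isotype with (40,10) and (10,40):
        # count-summing gives 50/100 = 0.5, not mean(0.8, 0.2) = 0.5 vs
        # a weighted table where the two disagree
        from chargeseq import TRNAGene, build_reference

        ref = build_reference(
            [
                TRNAGene("tRNA-Pro-AGG-1-1", "Pro", "AGG", "A" * 40),
                TRNAGene("tRNA-Pro-CGG-1-1", "Pro", "CGG", "C" * 40),
            ]
        )
        entries = ref.entry_ids
        charged = pd.DataFrame([[40.0], [10.0]], index=entries, columns=["s1"])
        uncharged = pd.DataFrame([[10.0], [40.0]], index=entries, columns=["s1"])
        table = CountTable(charged, uncharged)
        ct = fraction_by_group(table, ref, "amino_acid")
        assert ct.fractions.loc["Pro", "s1"] == pytest.approx(0.5)
        # unbalanced counts: count-sum weighting differs from fraction mean
        charged.iloc[0, 0] = 160.0  # (160,10) and (10,40): 170/220
        table2 = CountTable(charged, uncharged)
        ct2 = fraction_by_group(table2, ref, "amino_acid")
        assert ct2.fractions.loc["Pro", "s1"] == pytest.approx(170 / 220)
        ct2_mean = fraction_by_group(table2, ref, "amino_acid", combine="mean")
        assert ct2_mean.fractions.loc["Pro", "s1"] == pytest.approx(
            (160 / 170 + 10 / 50) / 2
        )

    def test_grouping_member_partition(self, toy_ref, clean_run):
        _, result, _ = clean_run
        gene = fraction_by_group(result.norm_counts, toy_ref, "gene")
        anti = fraction_by_group(result.norm_counts, toy_ref, "anticodon")
        assert len(gene.fractions) == 20
        assert len(anti.fractions) == 10
        assert ((anti.fractions >= 0) & (anti.fractions <= 1)).all().all()


class TestConditionSummary:
    def test_textbook_mean_sd(self):
        frac = pd.DataFrame(
            {"a1": [0.8], "a2": [0.9], "a3": [1.0]}, index=["G"]
        )
        from chargeseq.quant import ChargingTable

        ct = ChargingTable(frac, "anticodon")
        out = condition_summary(ct, {"a1": "A", "a2": "A", "a3": "A"})
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(0.9)
        assert row["sd"] == pytest.approx(0.1)
        assert row["n"] == 3

    def test_single_replicate_flagged(self):
        from chargeseq.quant import ChargingTable

        ct = ChargingTable(pd.DataFrame({"a1": [0.7]}, index=["G"]), "anticodon")
        out = condition_summary(ct, {"a1": "A"})
        assert out.iloc[0]["mean"] == pytest.approx(0.7)
        assert math.isnan(out.iloc[0]["sd"])
        assert out.iloc[0]["n"] == 1

    def test_undefined_replicates_excluded(self):
        from chargeseq.quant import ChargingTable

        frac = pd.DataFrame({"a1": [0.6], "a2": [np.nan], "b1": [np.nan]}, index=["G"])
        ct = ChargingTable(frac, "anticodon")
        with pytest.warns(UserWarning, match="no defined replicate"):
            out = condition_summary(ct, {"a1": "A", "a2": "A", "b1": "B"})
        a = out[out["condition"] == "A"].iloc[0]
        assert a["mean"] == pytest.approx(0.6) and a["n"] == 1
        b = out[out["condition"] == "B"].iloc[0]
        assert math.isnan(b["mean"]) and b["n"] == 0

    def test_replicate_mean_recovers_simulated_truth(self, toy_ref):
        # 3 replicates at truth 0.7, 50k molecules each: the condition
        # mean lands within 0.02 of truth (binomial error propagation)
        from chargeseq import SimDesign, SimSample, simulate_fastq
        from chargeseq.quant import ChargingTable

        design = SimDesign(
            samples=[
                SimSample(f"rep{i}", bc, "c", 50_000)
                for i, bc in enumerate(["ACACA", "CGCGC", "GTGTG"])
            ],
            charging={("c", "default"): 0.7},
            seed=8,
        )
        _, _, truth = simulate_fastq(design, toy_ref)
        gc = truth.group_counts(toy_ref)
        frac = gc.assign(
            f=gc["n_charged"] / (gc["n_charged"] + gc["n_uncharged"])
        ).pivot(index="group", columns="sample_id", values="f")
        ct = ChargingTable(frac, "anticodon")
        out = condition_summary(ct, {f"rep{i}": "c" for i in range(3)})
        assert (out["mean"] - 0.7).abs().max() <= 0.02
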