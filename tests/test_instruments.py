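"""Instrument selection, F-statistic, weak filter and harmonization rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate import (
    SummaryDataset,
    f_statistic,
    filter_weak,
    harmonize,
    make_truth,
    select_instruments,
    simulate_scenario,
)
from mrmediate.instruments import InstrumentSet, NoInstrumentsError
from mrmediate.synthetic_gwas import inject_ld_blocks

from conftest import make_records


def strong_dataset(n=5, seed=0):
    df = make_records(n, seed=seed)
    df["beta"] = 0.3
    df["se"] = 0.03
    df["pval"] = 1e-8
    return SummaryDataset("exp", df)


class TestFStatistic:
    def test_zero_r2_gives_zero(self):
        assert f_statistic(0.0, 1000, 5) == 0.0

    def test_closed_form_case(self):
        assert f_statistic(0.5, 102, 1) == pytest.approx(100.0)

    def test_sardinian_scale_case(self):
        # r2=1%, n=3757, k=10: (0.01*3746)/(10*0.99)
        assert f_statistic(0.01, 3757, 10) == pytest.approx(3.78383838, abs=1e-6)

    @pytest.mark.parametrize("r2, n, k", [(1.0, 100, 1), (0.5, 3, 2), (0.5, 2, 1)])
    def test_domain_errors(self, r2, n, k):
        with pytest.raises(ValueError):
            f_statistic(r2, n, k)

    @settings(max_examples=200, deadline=None)
    @given(
        r2=st.floats(0.001, 0.95),
        n=st.integers(20, 100_000),
        k=st.integers(1, 15),
        d_r2=st.floats(0.001, 0.04),
        d_n=st.integers(1, 1000),
    )
    def test_monotonicity(self, r2, n, k, d_r2, d_n):
        """F increases in r2 and n, decreases in k."""
        base = f_statistic(r2, n, k)
        assert f_statistic(min(r2 + d_r2, 0.96), n, k) >= base
        assert f_statistic(r2, n + d_n, k) >= base
        if n > k + 2:
            assert f_statistic(r2, n, k + 1) <= base or k + 2 >= n


class TestFilterWeak:
    def test_strong_set_passes_unchanged(self):
        inst = InstrumentSet("exp", ["rs1"], r2_total=0.5, n_gwas=102)  # F=100
        assert filter_weak(inst) is inst

    @pytest.mark.parametrize(
        "f_target, expect_weak", [(9.99, True), (10.0, True), (10.01, False)]
    )
    def test_boundary_is_strict(self, f_target, expect_weak):
        # choose r2 so that F == f_target exactly for n=1002, k=1
        n, k = 1002, 1
        r2 = f_target * k / (f_target * k + (n - 1 - k))
        inst = InstrumentSet("exp", ["rs1"], r2_total=r2, n_gwas=n)
        assert inst.f_stat == pytest.approx(f_target, abs=1e-9)
        if expect_weak:
            with pytest.warns(UserWarning, match="weak"):
                out = filter_weak(inst)
        else:
            out = filter_weak(inst)
        assert out.weak is expect_weak


class TestSelectInstruments:
    def test_unlinked_significant_snps_all_kept(self):
        inst = select_instruments(strong_dataset(5), p_threshold=1e-5)
        assert inst.k == 5

    def test_nothing_passes_threshold_raises(self):
        df = make_records(5)
        df["pval"] = 0.5
        with pytest.raises(NoInstrumentsError):
            select_instruments(SummaryDataset("exp", df), p_threshold=1e-5)

    def test_linked_pair_keeps_lower_p(self):
        df = make_records(2)
        df["pval"] = [1e-8, 1e-6]
        df["chrom"] = "1"
        df["pos"] = [1_000_000, 1_001_000]
        ld = pd.DataFrame(
            [[1.0, 0.5], [0.5, 1.0]], index=["rs1", "rs2"], columns=["rs1", "rs2"]
        )
        inst = select_instruments(SummaryDataset("exp", df), ld=ld)
        assert inst.snps == ["rs1"]

    def test_window_limits_pruning(self):
        """Same r2 but 20 Mb apart with a 10,000 kb window: both kept."""
        df = make_records(2)
        df["pval"] = [1e-8, 1e-6]
        df["chrom"] = "1"
        df["pos"] = [1_000_000, 21_000_001]
        ld = pd.DataFrame(
            [[1.0, 0.5], [0.5, 1.0]], index=["rs1", "rs2"], columns=["rs1", "rs2"]
        )
        inst = select_instruments(SummaryDataset("exp", df), ld=ld)
        assert inst.k == 2

    def test_blocks_scenario_matches_bruteforce_oracle(self):
        """4 blocks of 5 at r2=0.9: greedy result equals an independent
        enumeration of the greedy procedure."""
        truth = make_truth(m_snps=20, seed=17, c_direct_true=0.15, maf=(0.3, 0.5))
        out = inject_ld_blocks(simulate_scenario(truth), block_size=5, r2_within=0.9)
        exp = out.exposure_ds
        inst = select_instruments(exp, p_threshold=1e-5, ld=out.ld)
        assert inst.k == 4

        # brute-force oracle: re-run the published rule step by step
        cand = exp.records[exp.records["pval"] < 1e-5]
        cand = cand.sort_values(["pval", "chrom", "pos", "snp_id"])
        kept = []
        for row in cand.itertuples():
            ok = True
            for krow in kept:
                same_chrom = krow.chrom == row.chrom
                within = abs(krow.pos - row.pos) <= 10_000 * 1000
                r2 = float(out.ld.at[row.snp_id, krow.snp_id])
                if same_chrom and within and r2 >= 0.001:
                    ok = False
                    break
            if ok:
                kept.append(row)
        assert inst.snps == [r.snp_id for r in kept]

    def test_kept_set_is_internally_ld_free(self):
        truth = make_truth(m_snps=30, seed=19, c_direct_true=0.15, maf=(0.3, 0.5))
        out = inject_ld_blocks(simulate_scenario(truth), block_size=3, r2_within=0.8)
        inst = select_instruments(out.exposure_ds, p_threshold=1e-5, ld=out.ld)
        for a, b in itertools.combinations(inst.snps, 2):
            assert float(out.ld.at[a, b]) < 0.001

    def test_r2_total_uses_frequency_formula(self):
        ds = strong_dataset(3)
        inst = select_instruments(ds)
        rec = ds.records
        expected = (2 * rec["eaf"] * (1 - rec["eaf"]) * rec["beta"] ** 2).sum()
        assert inst.r2_total == pytest.approx(expected)

    def test_r2_fallback_without_frequency(self):
        df = strong_dataset(3).records.copy()
        df["eaf"] = np.nan
        ds = SummaryDataset("exp", df)
        inst = select_instruments(ds)
        expected = (df["beta"] ** 2 / (df["beta"] ** 2 + df["n"] * df["se"] ** 2)).sum()
        assert inst.r2_total == pytest.approx(expected)


def harmonize_pair_frames(exp_df, out_df, band=(0.42, 0.58)):
    exp = SummaryDataset("exp", exp_df)
    out = SummaryDataset("out", out_df, trait_role="outcome")
    return harmonize(exp.snp_ids, exp, out, palindromic_eaf_band=band)


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        exp_df = make_records(1)
        out_df = exp_df.copy()
        out_df["effect_allele"], out_df["other_allele"] = (
            exp_df["other_allele"],
            exp_df["effect_allele"],
        )
        out_df["beta"] = 0.1
        h = harmonize_pair_frames(exp_df, out_df)
        assert h.beta_out[0] == pytest.approx(-0.1)
        assert h.table.loc[0, "eaf_out"] == pytest.approx(1 - exp_df.loc[0, "eaf"])

    def test_palindromic_midband_dropped(self):
        exp_df = make_records(1)
        exp_df[["effect_allele", "other_allele"]] = ["A", "T"]
        exp_df["eaf"] = 0.50
        out_df = exp_df.copy()
        h = harmonize_pair_frames(exp_df, out_df)
        assert len(h) == 0
        assert h.dropped == [("rs1", "palindromic-ambiguous")]

    def test_palindromic_opposite_sides_dropped(self):
        exp_df = make_records(1)
        exp_df[["effect_allele", "other_allele"]] = ["C", "G"]
        exp_df["eaf"] = 0.2
        out_df = exp_df.copy()
        out_df["eaf"] = 0.8
        h = harmonize_pair_frames(exp_df, out_df)
        assert h.dropped == [("rs1", "palindromic-ambiguous")]

    def test_palindromic_clear_same_side_kept(self):
        exp_df = make_records(1)
        exp_df[["effect_allele", "other_allele"]] = ["A", "T"]
        exp_df["eaf"] = 0.2
        out_df = exp_df.copy()
        out_df["eaf"] = 0.25
        h = harmonize_pair_frames(exp_df, out_df)
        assert len(h) == 1

    def test_allele_mismatch_dropped(self):
        exp_df = make_records(1)
        exp_df[["effect_allele", "other_allele"]] = ["A", "G"]
        out_df = exp_df.copy()
        out_df[["effect_allele", "other_allele"]] = ["A", "C"]
        h = harmonize_pair_frames(exp_df, out_df)
        assert h.dropped == [("rs1", "allele mismatch")]

    def test_missing_in_outcome_dropped(self):
        exp_df = make_records(2)
        out_df = make_records(2).iloc[:1]
        h = harmonize_pair_frames(exp_df, out_df)
        assert ("rs2", "missing in outcome") in h.dropped
        assert len(h) >= 1

    def test_scenario_drops_match_rule_enumeration(self):
        """Full synthetic scenario: the dropped set equals a brute-force
        application of the missing/palindromic/mismatch rules."""
        truth = make_truth(m_snps=100, seed=23, c_direct_true=0.1)
        sc = simulate_scenario(truth)
        exp, out = sc.exposure_ds, sc.outcome_ds
        h = harmonize(exp.snp_ids, exp, out)

        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        expected_dropped = set()
        out_idx = out.records.set_index("snp_id")
        for row in exp.records.itertuples():
            o = out_idx.loc[row.snp_id]
            if comp[row.effect_allele] == row.other_allele:
                same_side = (row.eaf - 0.5) * (o["eaf"] - 0.5) > 0
                clear = not (0.42 < row.eaf < 0.58) and not (0.42 < o["eaf"] < 0.58)
                if not (same_side and clear):
                    expected_dropped.add(row.snp_id)
        assert {s for s, _ in h.dropped} == expected_dropped
        assert len(h) + len(h.dropped) == 100

    def test_harmonization_idempotent(self):
        """Re-harmonizing the already-aligned outcome changes nothing."""
        truth = make_truth(m_snps=50, seed=29, c_direct_true=0.1)
        sc = simulate_scenario(truth)
        exp, out = sc.exposure_ds, sc.outcome_ds
        h1 = harmonize(exp.snp_ids, exp, out)

        # rebuild an outcome dataset from the aligned table (exposure alleles)
        aligned = h1.table
        re_out = out.records[out.records["snp_id"].isin(aligned["snp_id"])].copy()
        re_out = re_out.set_index("snp_id").loc[aligned["snp_id"]].reset_index()
        re_out["effect_allele"] = aligned["effect_allele"].to_numpy()
        re_out["other_allele"] = aligned["other_allele"].to_numpy()
        re_out["beta"] = aligned["beta_out"].to_numpy()
        re_out["eaf"] = aligned["eaf_out"].to_numpy()
        out2 = SummaryDataset("out", re_out, trait_role="outcome")
        h2 = harmonize(h1.snp_ids, exp, out2)
        assert h2.dropped == []
        np.testing.assert_allclose(h2.beta_out, h1.beta_out)
        np.testing.assert_allclose(h2.beta_exp, h1.beta_exp)
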