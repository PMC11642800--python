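"""Downstream statistics: composition, motifs, calibration, deltas, m6A."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crownkit.analysis import (
    classify_tss_motif,
    composition_from_fractions,
    delta_stoichiometry,
    fold_change_stoich,
    gene_composition,
    internal_m6a_sites,
    is_drach,
    m6am_gene_index,
    naive_log2fc,
    positional_base_freq,
    promoter_context,
    scan_tata,
    spike_in_scaling,
    standards_calibration,
    stoichiometry_bins,
)


class TestComposition:
    def test_high_methylation_worked_example(self):
        s = composition_from_fractions("SRSF1", 0.540, 0.934)
        assert (round(s.pct_m6Am, 1), round(s.pct_Am, 1), round(s.pct_nonA, 1)) == (
            50.4, 3.6, 46.0,
        )

    def test_partial_methylation_worked_example(self):
        s = composition_from_fractions("JUN", 0.58, 0.75)
        assert (round(s.pct_m6Am, 1), round(s.pct_Am, 1), round(s.pct_nonA, 1)) == (
            43.5, 14.5, 42.0,
        )

    def test_no_a_starts(self):
        s = composition_from_fractions("g", 0.0, 0.0)
        assert (s.pct_m6Am, s.pct_Am, s.pct_nonA) == (0.0, 0.0, 100.0)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_percentages_sum_to_100(self, frac_a, meth):
        s = composition_from_fractions("g", frac_a, meth)
        assert s.pct_m6Am + s.pct_Am + s.pct_nonA == pytest.approx(100.0, abs=0.05)

    def test_from_table_consistent_with_fractions(self):
        tab = pd.DataFrame({
            "gene_id": "g", "chrom": "c", "pos": [1, 2, 3], "strand": "+",
            "tsn_base": ["A", "A", "G"],
            "depth": [300, 240, 460],
            "a_count": [280, 180, 0],
            "g_count": [20, 60, 450],
            "nonconversion": [280 / 300, 180 / 240, 0.0],
        })
        s = gene_composition(tab)
        assert s.frac_A == pytest.approx(540 / 1000)
        assert s.mean_methylation == pytest.approx(460 / 540)
        assert s.pct_m6Am + s.pct_Am + s.pct_nonA == pytest.approx(100.0)
        # read-weighted gene index equals pct_m6Am/100 when depth == A+G
        idx = m6am_gene_index(tab)
        assert idx == pytest.approx(s.pct_m6Am / 100, abs=1e-9)

    def test_zero_reads_undefined(self):
        tab = pd.DataFrame({"gene_id": "g", "chrom": "c", "pos": [1], "strand": "+",
                            "tsn_base": ["A"], "depth": [0], "a_count": [0],
                            "g_count": [0], "nonconversion": [np.nan]})
        with pytest.raises(ValueError):
            gene_composition(tab)


class TestGeneIndex:
    def _tab(self, bases, depths, ncs):
        return pd.DataFrame({
            "gene_id": "g", "chrom": "c", "pos": range(len(bases)), "strand": "+",
            "tsn_base": bases, "depth": depths,
            "a_count": [int(d * n) if not np.isnan(n) else 0 for d, n in zip(depths, ncs)],
            "g_count": [d - int(d * n) if not np.isnan(n) else 0 for d, n in zip(depths, ncs)],
            "nonconversion": ncs,
        })

    def test_single_fully_methylated_a_tsn(self):
        assert m6am_gene_index(self._tab(["A"], [100], [1.0])) == pytest.approx(1.0)

    def test_all_g_tsns(self):
        assert m6am_gene_index(self._tab(["G", "G"], [50, 50], [np.nan, np.nan])) == 0.0

    def test_srsf1_like_value(self):
        s = composition_from_fractions("SRSF1", 0.540, 0.934)
        assert s.m6am_gene_index == pytest.approx(0.504, abs=5e-4)

    def test_unweighted_variant(self):
        tab = self._tab(["A", "G"], [10, 1000], [1.0, np.nan])
        assert m6am_gene_index(tab, weighted=False) == pytest.approx(0.5)
        assert m6am_gene_index(tab, weighted=True) == pytest.approx(10 / 1010)


class TestBins:
    def _tab(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "chrom": "c", "pos": np.arange(n), "strand": "+",
            "stoichiometry": rng.uniform(size=n),
        })

    def test_equal_sizes(self):
        out = stoichiometry_bins(self._tab(100), 20)
        assert (out.groupby("stoich_bin").size() == 5).all()

    def test_sizes_differ_by_at_most_one(self):
        out = stoichiometry_bins(self._tab(103), 20)
        sizes = out.groupby("stoich_bin").size()
        assert sizes.max() - sizes.min() <= 1

    def test_bin_means_non_decreasing(self):
        out = stoichiometry_bins(self._tab(500, seed=3), 20)
        means = out.groupby("stoich_bin")["stoichiometry"].mean()
        assert (np.diff(means) >= 0).all()

    def test_tie_break_deterministic(self):
        tab = self._tab(40)
        tab["stoichiometry"] = 0.5
        out1 = stoichiometry_bins(tab.sample(frac=1, random_state=1), 4)
        out2 = stoichiometry_bins(tab.sample(frac=1, random_state=2), 4)
        pd.testing.assert_frame_equal(out1, out2)

    def test_too_few_sites_errors(self):
        with pytest.raises(ValueError):
            stoichiometry_bins(self._tab(10), 20)


class TestBaseFreq:
    def test_shared_promoter_gives_indicator_frequencies(self, small_ref):
        a = small_ref.truth[small_ref.truth["tsn_base"] == "A"].iloc[0]
        tab = pd.DataFrame({
            "chrom": [a.chrom] * 5, "pos": [a.tsn_pos] * 5, "strand": [a.strand] * 5,
            "stoichiometry": np.linspace(0, 1, 5), "stoich_bin": 0,
        })
        freqs, skipped = positional_base_freq(tab, small_ref.genome)
        assert skipped == 0
        vals = freqs[["A", "C", "G", "T"]].to_numpy()
        assert set(np.unique(vals)) <= {0.0, 1.0}
        assert np.allclose(vals.sum(axis=1), 1.0)

    def test_plus_one_position_is_a_for_a_tsns(self, small_ref):
        a_rows = small_ref.truth[small_ref.truth["tsn_base"] == "A"]
        tab = pd.DataFrame({
            "chrom": a_rows["chrom"].to_numpy(), "pos": a_rows["tsn_pos"].to_numpy(),
            "strand": a_rows["strand"].to_numpy(),
            "stoichiometry": a_rows["stoichiometry"].to_numpy(), "stoich_bin": 0,
        })
        freqs, _ = positional_base_freq(tab, small_ref.genome)
        plus1 = freqs[freqs["offset"] == 1]
        assert plus1["A"].iloc[0] == pytest.approx(1.0)

    def test_edge_sites_skipped_with_count(self):
        genome = {"c": "A" * 60}
        tab = pd.DataFrame({"chrom": "c", "pos": [5], "strand": "+",
                            "stoichiometry": [1.0], "stoich_bin": 0})
        _, skipped = positional_base_freq(tab, genome)
        assert skipped == 1


class TestMotifs:
    # context strings cover -4..+4 with the start nucleotide at index 4
    @pytest.mark.parametrize(
        "context,label",
        [
            ("ACGCAGCT", "SSCA+1GC"),   # S S C A G C at -3..+3
            ("ATTCAGTT", "BBCA+1BW"),   # S fails at -3, B passes
            ("AAACAAAT", "VA+1RR"),     # -3..-2 break BBCA, V A R R matches
            ("ATTTATTT", "BA+1"),       # only B at -1 + A
            ("AAAAAAAA", "VA+1RR"),     # V and R both admit A
            ("AAAAATTT", "none"),       # A at -1 breaks B, T at +2 breaks R
            ("ACGCCGCT", "none"),       # +1 not A
            ("ACGNAGCT", "none"),       # N in examined window
        ],
    )
    def test_classification(self, context, label):
        assert classify_tss_motif(context, tsn_index=4) == label

    def test_precedence_most_specific_first(self):
        # CCCAGC satisfies SSCA+1GC, BBCA+1BW and BA+1 -> most specific wins
        assert classify_tss_motif("ACCCAGCT", tsn_index=4) == "SSCA+1GC"


class TestTata:
    def _promoter(self, motif_at, motif="TATAAAAG", length=100, tsn_index=60):
        seq = ["C"] * length
        start = tsn_index + motif_at
        seq[start: start + len(motif)] = motif
        return "".join(seq), tsn_index

    def test_present_at_minus_30(self):
        prom, idx = self._promoter(-30)
        present, off = scan_tata(prom, idx)
        assert present and off == -30

    def test_w_position_mismatch_absent(self):
        prom, idx = self._promoter(-30, motif="TATACAAG")
        assert scan_tata(prom, idx) == (False, None)

    def test_boundary_straddling_absent(self):
        prom, idx = self._promoter(-25)  # 8-mer would end at -18, outside window
        assert scan_tata(prom, idx) == (False, None)

    def test_motif_ending_exactly_at_minus_19_found(self):
        prom, idx = self._promoter(-26)  # ends at -19, fully contained
        present, off = scan_tata(prom, idx)
        assert present and off == -26


class TestCalibration:
    def test_identity_fit(self):
        exp = [0, 0.25, 0.5, 0.75, 1.0]
        slope, intercept, r = standards_calibration(exp, exp)
        assert (slope, intercept, r) == pytest.approx((1.0, 0.0, 1.0))

    def test_affine_fit(self):
        exp = np.array([0, 0.25, 0.5, 0.75, 1.0])
        slope, intercept, r = standards_calibration(exp, 0.9 * exp + 0.05)
        assert (slope, intercept, r) == pytest.approx((0.9, 0.05, 1.0))

    def test_conversion_efficiency_closed_form(self):
        # observed = s + (1-s)(1-eps) -> slope eps, intercept 1-eps
        eps = 0.92
        exp = np.array([0, 0.25, 0.5, 0.75, 1.0])
        obs = exp + (1 - exp) * (1 - eps)
        slope, intercept, r = standards_calibration(exp, obs)
        assert slope == pytest.approx(eps)
        assert intercept == pytest.approx(1 - eps)
        assert r == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            standards_calibration([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            standards_calibration([0, 1], [0, 1])


def _sites(ncs, depths=None, start=0):
    n = len(ncs)
    depths = depths if depths is not None else [100] * n
    return pd.DataFrame({
        "chrom": "c", "pos": np.arange(start, start + n), "strand": "+",
        "depth": depths, "nonconversion": ncs,
    })


class TestDelta:
    def test_identical_tables_zero_deltas(self):
        tab = _sites([0.9, 0.8, 0.7])
        merged, t, p = delta_stoichiometry(tab, tab)
        assert (merged["delta"] == 0).all()
        assert np.isnan(p)

    def test_depth_threshold_in_both_conditions(self):
        a = _sites([0.9, 0.9], depths=[49, 100])
        b = _sites([0.1, 0.1], depths=[100, 100])
        merged, _, _ = delta_stoichiometry(a, b, min_reads=50)
        assert merged["pos"].tolist() == [1]

    def test_knockout_deltas_match_negative_truth(self):
        truth = np.array([0.95, 0.9, 0.85, 0.8, 0.99])
        wt = _sites(truth)
        ko = _sites(np.zeros(5))
        merged, t, p = delta_stoichiometry(wt, ko)
        assert merged["delta"].to_numpy() == pytest.approx(-truth)
        assert t < 0 and p < 0.01


class TestFoldChange:
    def test_snrna_worked_example(self):
        fc = fold_change_stoich(0.0185, 0.586)
        assert fc >= 31.6
        assert fc == pytest.approx(31.7, abs=0.05)

    @pytest.mark.parametrize("a,b,want", [(0.5, 0.5, 1.0), (0.2, 0.8, 4.0), (0.8, 0.2, 4.0)])
    def test_symmetric_ratio(self, a, b, want):
        assert fold_change_stoich(a, b) == pytest.approx(want)

    def test_zero_undefined(self):
        with pytest.raises(ValueError):
            fold_change_stoich(0.0, 0.5)


class TestInternalM6A:
    def test_thresholds_and_drach_flag(self):
        genome = {"c": "CCGGACTCC" + "CCAAACC"}
        # pos 4 is the A of GGACT (DRACH); pos 11 is an A in a non-DRACH context
        wt = pd.DataFrame({"chrom": "c", "pos": [4, 11, 4], "strand": ["+", "+", "-"],
                           "depth": [60, 60, 49], "nonconversion": [0.25, 0.19, 0.5]})
        ko = pd.DataFrame({"chrom": "c", "pos": [4, 11, 4], "strand": ["+", "+", "-"],
                           "depth": [60, 60, 60], "nonconversion": [0.30, 0.19, 0.5]})
        out = internal_m6a_sites(wt, ko, genome)
        assert out["pos"].tolist() == [4]  # 0.19/0.19 excluded; depth 49 excluded
        assert out["drach"].iloc[0]

    def test_rate_in_either_genotype_suffices(self):
        genome = {"c": "CCGGACTCC"}
        wt = _sites([0.05], depths=[100], start=4)
        ko = _sites([0.25], depths=[100], start=4)
        out = internal_m6a_sites(wt, ko, genome)
        assert len(out) == 1

    def test_is_drach_minus_strand(self):
        # forward AGTCC -> transcript sense (minus) GGACT = DRACH with A centred
        genome = {"c": "AGTCC"}
        assert is_drach(genome, "c", 2, "-")
        assert not is_drach(genome, "c", 2, "+")


class TestSpikeIn:
    def _tab(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "depth"])

    def test_perfect_spikes_threshold_zero(self):
        tabs = {"lib": self._tab([("sp1", 10, "+", 500), ("sp2", 20, "+", 300)])}
        out = spike_in_scaling(tabs, {"sp1": 10, "sp2": 20})
        assert out["fp_threshold"].iloc[0] == 0.0

    def test_off_terminus_fraction_sets_threshold(self):
        tabs = {"lib": self._tab([("sp1", 10, "+", 95), ("sp1", 33, "+", 5)])}
        out = spike_in_scaling(tabs, {"sp1": 10})
        assert out["fp_threshold"].iloc[0] == pytest.approx(0.05)

    def test_scale_factors_track_spike_totals(self):
        tabs = {
            "a": self._tab([("sp1", 10, "+", 100)]),
            "b": self._tab([("sp1", 10, "+", 200)]),
        }
        out = spike_in_scaling(tabs, {"sp1": 10}).set_index("library")
        assert out.loc["b", "scale_factor"] / out.loc["a", "scale_factor"] == pytest.approx(2.0)


def test_naive_log2fc_doubled_site():
    a = _sites([1.0], depths=[100])
    b = _sites([1.0], depths=[200])
    a2 = pd.concat([a, _sites([1.0], depths=[100], start=10)], ignore_index=True)
    b2 = pd.concat([b, _sites([1.0], depths=[100], start=10)], ignore_index=True)
    out = naive_log2fc(a2, b2).set_index("pos")
    assert out.loc[0, "log2fc"] > out.loc[10, "log2fc"]


def test_promoter_context_minus_strand(small_ref):
    minus = small_ref.truth[small_ref.truth["strand"] == "-"].iloc[0]
    ctx = promoter_context(small_ref.genome, minus.chrom, minus.tsn_pos, "-")
    assert len(ctx) == 81
    assert ctx[40] == minus.tsn_base
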