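"""Tests for call filtering, paralog screens, trimming and concatenation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phylocap.locus_screening import (
    LocusAlignment,
    alignment_score_threshold,
    concatenate,
    coverage_screen,
    filter_calls,
    mask_ambiguities,
    outgroup_delta,
    percent_variant_sites,
    screen_loci,
    standardized_quality,
    threshold_scan,
    trim_missing_columns,
    variability_stats,
)


def make_calls(qualities, variants=None, indels=None):
    n = len(qualities)
    return pd.DataFrame(
        {
            "locus_id": "L",
            "position": range(1, n + 1),
            "call": ["A"] * n,
            "quality": qualities,
            "is_variant": variants if variants is not None else [False] * n,
            "is_indel": indels if indels is not None else [False] * n,
            "depth": [30] * n,
        }
    )


class TestScanMetrics:
    @pytest.mark.parametrize(
        "constant,length,expected",
        [(20, 1, 20.0), (320, 250, 364.17), (420, 100, 456.84)],
    )
    def test_score_threshold_formula(self, constant, length, expected):
        assert alignment_score_threshold(constant, length) == pytest.approx(expected, abs=0.01)

    def test_score_threshold_rejects_bad_length(self):
        with pytest.raises(ValueError):
            alignment_score_threshold(20, 0)

    def test_percent_variant_sites(self):
        assert percent_variant_sites(make_calls([40] * 100)) == 0.0
        calls = make_calls([40] * 200, variants=[True] * 5 + [False] * 195)
        assert percent_variant_sites(calls) == pytest.approx(2.5)
        with pytest.raises(ValueError):
            percent_variant_sites(make_calls([]))

    def test_standardized_quality(self):
        calls = make_calls([40, 40, 20, 20, 20], variants=[True, True, False, False, False])
        assert standardized_quality(calls) == pytest.approx(2.0)
        same = make_calls([33] * 6, variants=[True, False] * 3)
        assert standardized_quality(same) == pytest.approx(1.0)

    def test_standardized_quality_undefined_flagged(self):
        with pytest.warns(UserWarning):
            assert math.isnan(standardized_quality(make_calls([40, 40])))

    def test_threshold_scan_flat_and_errors(self):
        calls = make_calls([40] * 50, variants=[True] * 5 + [False] * 45)
        scan = threshold_scan({20.0: calls, 60.0: calls.copy(), 100.0: calls.copy()})
        assert np.allclose(scan["d_pct_variant"].dropna(), 0.0)
        assert np.allclose(scan["d_std_quality"].dropna(), 0.0)
        with pytest.raises(ValueError):
            threshold_scan({20.0: calls})

    def test_threshold_scan_detects_vanishing_contamination(self):
        """Spurious variant calls disappearing above c* spike the scan metrics there."""
        from phylocap.synthetic_data import simulate_capture_dataset

        ds = simulate_capture_dataset(n_loci=2, seed=5)
        scan = threshold_scan(ds.call_tables).set_index("constant")
        drops = scan["d_pct_variant"]
        crit = 300.0  # generator's critical constant: first clean table is c=300
        assert drops.idxmin() == pytest.approx(crit)
        # standardized quality jumps up at the same constant and plateaus after
        assert scan["d_std_quality"].idxmax() == pytest.approx(crit)
        after = scan.loc[scan.index > crit, "d_std_quality"].abs()
        assert (after < 0.05).all()


class TestFilterCalls:
    def test_quality_boundary_strict(self):
        calls = make_calls([35.9, 36.0, 36.1])
        out = filter_calls(calls)
        assert list(out["quality"]) == [36.0, 36.1]

    def test_indels_dropped_regardless_of_quality(self):
        calls = make_calls([60.0, 60.0], indels=[True, False])
        out = filter_calls(calls)
        assert len(out) == 1 and not out["is_indel"].any()
        assert out.attrs["retention"]["dropped_indel"] == 1

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning):
            out = filter_calls(make_calls([10.0, 20.0]))
        assert len(out) == 0

    def test_idempotence(self):
        calls = make_calls([10, 36, 40, 50], indels=[False, False, True, False])
        once = filter_calls(calls)
        twice = filter_calls(once)
        pd.testing.assert_frame_equal(once, twice)


class TestMaskAmbiguities:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", "ACGT"), ("ARYT", "ANNT"), ("acgt", "ACGT"), ("A-N", "A-N")],
    )
    def test_examples(self, seq, expected):
        assert mask_ambiguities(seq) == expected

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError):
            mask_ambiguities("AXGT")

    @given(st.text(alphabet="ACGTNRYSWKMBDHVacgt-", max_size=50))
    def test_idempotent_and_length_preserving(self, seq):
        masked = mask_ambiguities(seq)
        assert len(masked) == len(seq)
        assert mask_ambiguities(masked) == masked
        assert set(masked) <= set("ACGTN-")


class TestCoverageScreen:
    def test_uniform_matrix_excludes_nothing(self):
        cov = pd.DataFrame(30.0, index=list("abcd"), columns=["l1", "l2", "l3"])
        excluded, report = coverage_screen(cov)
        assert excluded == set()
        assert not report["coverage_excluded"].any()

    def test_exceeding_a_third_of_accessions_excludes(self):
        # locus l5 at depth 200: accessions a,b have across-locus mean
        # (4*10 + 200)/5 = 48, and 200 > 3*48, so 2 of 4 accessions (> 1/3)
        base = {f"l{i}": [10.0] * 4 for i in range(1, 5)}
        cov = pd.DataFrame({**base, "l5": [200.0, 200.0, 10.0, 10.0]}, index=list("abcd"))
        excluded, report = coverage_screen(cov)
        assert excluded == {"l5"}
        assert report.loc["l5", "n_elevated"] == 2

    def test_boundary_exactly_one_third_is_kept(self):
        # 1 of 3 accessions elevated: fraction == 1/3, rule is strictly greater
        base = {f"l{i}": [10.0] * 3 for i in range(1, 5)}
        cov = pd.DataFrame({**base, "l5": [200.0, 10.0, 10.0]}, index=list("abc"))
        excluded, _ = coverage_screen(cov)
        assert excluded == set()

    def test_planted_high_coverage_loci_recovered(self):
        """Strong conserved-window pileups are flagged at >= 80% recall."""
        from phylocap.synthetic_data import DepthModel, simulate_capture_dataset

        ds = simulate_capture_dataset(
            n_loci=100,
            paralog_fraction=0.15,
            depth_model=DepthModel(conserved_multiplier=10.0),
            seed=21,
        )
        excluded, _ = coverage_screen(ds.coverage)
        truth = ds.truth.per_locus
        planted = set(truth.loc[truth.is_paralog, "locus_id"])
        orthologs = set(truth.loc[~truth.is_paralog, "locus_id"])
        assert len(excluded & planted) / len(planted) >= 0.8
        assert len(excluded & orthologs) / len(orthologs) <= 0.2

    def test_missing_cells_do_not_count(self):
        # only accession a has data at l5, elevated (200 > 3*48): 1/1 > 1/3
        base = {f"l{i}": [10.0] * 3 for i in range(1, 5)}
        cov = pd.DataFrame({**base, "l5": [200.0, np.nan, np.nan]}, index=list("abc"))
        excluded, report = coverage_screen(cov)
        assert excluded == {"l5"}
        assert report.loc["l5", "n_accessions_with_data"] == 1


class TestVariabilityStats:
    def test_toy_counts(self, toy_alignment):
        prop_var, prop_pi = variability_stats(toy_alignment)
        assert prop_var == pytest.approx(2 / 3)
        assert prop_pi == pytest.approx(1 / 3)

    def test_identical_sequences(self):
        aln = LocusAlignment("x", {"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        assert variability_stats(aln) == (0.0, 0.0)

    def test_planted_counts_exact(self):
        from phylocap.synthetic_data import planted_alignment

        aln, truth = planted_alignment("p", n_seqs=8, length=400, n_variable=60,
                                       n_informative=25, seed=3)
        prop_var, prop_pi = variability_stats(aln)
        assert prop_var == pytest.approx(truth["prop_variable"])
        assert prop_pi == pytest.approx(truth["prop_parsimony_informative"])

    def test_missing_data_treated_as_absent(self):
        aln = LocusAlignment("x", {"a": "AN-", "b": "ANA", "c": "TNA"})
        # col1 variable (A,A,T); col2 all missing; col3 two As (one gap)
        prop_var, prop_pi = variability_stats(aln)
        assert prop_var == pytest.approx(1 / 2)  # denominator: 2 assessable columns
        assert prop_pi == 0.0

    def test_requires_two_sequences(self):
        aln = LocusAlignment("x", {"a": "ACGT", "b": "ACGT"})
        with pytest.raises(ValueError):
            variability_stats(aln, exclude={"b"})


class TestOutgroupDelta:
    def test_outgroup_identical_to_ingroup_gives_zero_delta(self):
        aln = LocusAlignment(
            "x",
            {"i1": "AAAA", "i2": "AATA", "og": "AATA"},
            outgroup="og",
        )
        delta, excluded = outgroup_delta(aln)
        assert delta == pytest.approx(0.0)
        assert excluded

    def test_relative_rule_application(self):
        # 5/8 columns variable with the outgroup, 2/8 without: delta 60% -> kept
        aln = LocusAlignment(
            "x",
            {
                "i1": "AAAACCCC",
                "i2": "ATAACCCC",
                "i3": "ATTACCCC",
                "og": "ATTTCCGG",
            },
            outgroup="og",
        )
        delta, excluded = outgroup_delta(aln)
        assert delta == pytest.approx(100.0 * (0.625 - 0.25) / 0.625)
        assert not excluded

    def test_absolute_mode(self):
        aln = LocusAlignment(
            "x",
            {"i1": "AAAACCCC", "i2": "ATAACCCC", "i3": "ATTACCCC", "og": "ATTTCCGG"},
            outgroup="og",
        )
        delta, _ = outgroup_delta(aln, mode="absolute")
        assert delta == pytest.approx(100.0 * (0.625 - 0.25))

    def test_no_variation_excluded(self):
        aln = LocusAlignment("x", {"i1": "AAAA", "i2": "AAAA", "og": "AAAA"}, outgroup="og")
        delta, excluded = outgroup_delta(aln)
        assert excluded

    def test_missing_outgroup_rejected(self):
        aln = LocusAlignment("x", {"i1": "AAAA", "i2": "AAAA"})
        with pytest.raises(ValueError):
            outgroup_delta(aln, "og")
        aln2 = LocusAlignment("x", {"i1": "AAAA", "og": "NNNN"}, outgroup="og")
        with pytest.raises(ValueError):
            outgroup_delta(aln2)


class TestTrimAndConcat:
    def test_trim_boundary_half_present_kept(self):
        seqs = {f"s{i}": "AN" for i in range(12)} | {f"t{i}": "AA" for i in range(12)}
        # col2: 12 of 24 present = exactly half -> kept
        aln = LocusAlignment("x", seqs)
        trimmed = trim_missing_columns(aln)
        assert trimmed.length == 2

    def test_trim_more_than_half_missing_removed(self):
        seqs = {f"s{i}": "AN" for i in range(13)} | {f"t{i}": "AA" for i in range(11)}
        # col2: 11 of 24 present < half -> removed
        aln = LocusAlignment("x", seqs)
        trimmed = trim_missing_columns(aln)
        assert trimmed.length == 1

    def test_trim_all_present_unchanged_and_idempotent(self):
        aln = LocusAlignment("x", {"a": "ACGT", "b": "ACGT", "c": "AC-T"})
        once = trim_missing_columns(aln)
        assert trim_missing_columns(once).sequences == once.sequences

    def test_concatenate_lengths_partitions_and_missing_fill(self):
        l1 = LocusAlignment("g1", {"a": "A" * 100, "b": "C" * 100})
        l2 = LocusAlignment("g2", {"a": "G" * 50})
        supermatrix, parts = concatenate([l1, l2])
        assert supermatrix.length == 150
        assert parts.to_dict(orient="records") == [
            {"locus_id": "g1", "start": 1, "end": 100},
            {"locus_id": "g2", "start": 101, "end": 150},
        ]
        assert supermatrix.sequences["b"][100:] == "N" * 50

    def test_concatenate_placeholder_for_absent_locus(self):
        l1 = LocusAlignment("g1", {"a": "ACGT", "b": "ACGT"})
        supermatrix, parts = concatenate([l1, ("g2", None)])
        assert supermatrix.length == 4 + 260
        assert supermatrix.sequences["a"][4:] == "N" * 260

    def test_concatenate_conservation_property(self):
        """Every non-placeholder character survives; partitions tile exactly."""
        rng = np.random.default_rng(0)
        loci = []
        for j in range(6):
            length = int(rng.integers(5, 30))
            accs = rng.choice(list("abcde"), size=rng.integers(2, 5), replace=False)
            seqs = {
                acc: "".join(rng.choice(list("ACGT"), size=length)) for acc in accs
            }
            loci.append(LocusAlignment(f"g{j}", seqs))
        supermatrix, parts = concatenate(loci, accessions=list("abcde"))
        assert parts["start"].iloc[0] == 1
        assert (parts["start"].values[1:] == parts["end"].values[:-1] + 1).all()
        assert parts["end"].iloc[-1] == supermatrix.length
        for aln, row in zip(loci, parts.itertuples()):
            for acc, seq in aln.sequences.items():
                assert supermatrix.sequences[acc][row.start - 1 : row.end] == seq

    def test_supermatrix_stats_match_planted_truth(self):
        from phylocap.synthetic_data import planted_alignment

        loci, total_var, total_pi, total_len = [], 0, 0, 0
        for j, (nv, npi) in enumerate([(10, 4), (0, 0), (25, 12)]):
            aln, truth = planted_alignment(f"g{j}", 6, 200, nv, npi, seed=j)
            loci.append(aln)
            total_var += nv
            total_pi += npi
            total_len += truth["length"]
        supermatrix, _ = concatenate(loci)
        prop_var, prop_pi = variability_stats(supermatrix)
        assert prop_var == pytest.approx(total_var / total_len)
        assert prop_pi == pytest.approx(total_pi / total_len)


class TestScreenLoci:
    def test_combined_screen_on_planted_paralogs(self):
        from phylocap.synthetic_data import simulate_capture_dataset

        ds = simulate_capture_dataset(n_loci=80, seed=13)
        report = screen_loci(ds.alignments, coverage=ds.coverage, outgroup="OUTGROUP")
        merged = report.join(ds.truth.per_locus.set_index("locus_id"))
        paralogs = merged[merged.is_paralog]
        orthologs = merged[~merged.is_paralog]
        assert (~paralogs.passed).mean() >= 0.8
        assert orthologs.passed.mean() >= 0.8

    def test_report_is_deterministic(self):
        from phylocap.synthetic_data import simulate_capture_dataset

        ds = simulate_capture_dataset(n_loci=20, seed=2)
        r1 = screen_loci(ds.alignments, coverage=ds.coverage, outgroup="OUTGROUP")
        r2 = screen_loci(ds.alignments, coverage=ds.coverage, outgroup="OUTGROUP")
        pd.testing.assert_frame_equal(r1, r2)
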