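import itertools

import numpy as np
import pytest

from leucidelim import (
    SeqEntry,
    SequenceSet,
    band_length_attribution,
    collapse_haplotypes,
    count_variable_sites,
    diagnostic_differences,
    p_distance_matrix,
    pairwise_identity,
    pcoa,
    similarity_summary,
)
from leucidelim.popgen import DistanceMatrix, UndefinedIdentityError, substitution_class


def _aln(seqs, taxa=None, marker="cytb"):
    taxa = taxa or ["t"] * len(seqs)
    return SequenceSet(
        marker, [SeqEntry(f"s{i}", taxa[i], s) for i, s in enumerate(seqs)]
    )


class TestVariableSites:
    def test_identical_sequences_have_none(self):
        r = count_variable_sites(_aln(["ACGTACGTAC"] * 3))
        assert r == {"variable": 0, "length": 10, "pct": 0.0}

    def test_planted_columns_counted_by_enumeration_oracle(self):
        seqs = ["ACGTACGTAC", "AGGTACGCAC", "ACGTACGCAC"]  # columns 1 and 7 differ
        oracle = sum(
            1
            for col in zip(*seqs)
            if len(set(col) & set("ACGT")) >= 2
        )
        r = count_variable_sites(_aln(seqs))
        assert r["variable"] == oracle == 2

    def test_n_only_variation_not_counted(self):
        r = count_variable_sites(_aln(["ACGT", "ACGN"]))
        assert r["variable"] == 0

    def test_gap_with_single_base_not_variable(self):
        r = count_variable_sites(_aln(["A-GT", "AAGT"]))
        assert r["variable"] == 0

    def test_two_bases_variable_regardless_of_gaps(self):
        r = count_variable_sites(_aln(["A-GT", "ACGT", "GCGT"]))
        assert r["variable"] == 1

    def test_invariant_to_sequence_order(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(5)]
        base = count_variable_sites(_aln(seqs))
        for perm in itertools.islice(itertools.permutations(seqs), 10):
            assert count_variable_sites(_aln(list(perm))) == base

    def test_unaligned_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            count_variable_sites(_aln(["ACGT", "ACGTA"]))


class TestHaplotypes:
    def test_copies_collapse_to_one(self):
        h = collapse_haplotypes(_aln(["ACGT"] * 4))
        assert h.n_haplotypes == 1
        assert h.haplotypes[0].multiplicity == 4

    def test_single_site_difference_separates(self):
        h = collapse_haplotypes(_aln(["ACGT", "ACGA"]))
        assert h.n_haplotypes == 2

    def test_planted_haplotype_count_recovered(self, templates):
        from leucidelim import simulate_sequences

        aln = simulate_sequences(templates, "rag1", [4, 4, 4, 4], seed=1, within_scale=0.0)
        # no within-species variation: exactly one haplotype per species
        assert collapse_haplotypes(aln).n_haplotypes == 4


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGTACGTAC", "ACGTACGTAC") == 100.0

    def test_one_mismatch_in_ten(self):
        assert pairwise_identity("ACGTACGTAC", "ACGTACGTAA") == pytest.approx(90.0)

    def test_gap_positions_excluded(self):
        assert pairwise_identity("AC-T", "ACTT") == 100.0

    def test_empty_overlap_rejected(self):
        with pytest.raises(UndefinedIdentityError):
            pairwise_identity("--AA", "GG--")

    def test_global_align_mode_recovers_identity_across_indel(self):
        a = "ACGTACGTACGTACGT"
        b = "ACGTACGTCGTACGT"  # one base deleted
        assert pairwise_identity(a, b, mode="global_align") == pytest.approx(100.0)

    def test_similarity_summary_reports_all_three_statistics(self):
        aln = _aln(["ACGT", "ACGA", "TTTT"], taxa=["x", "x", "y"])
        s = similarity_summary(aln)
        assert set(s["within"]["x"]) == {"mean", "min", "max"}
        assert "x|y" in s["between"]


class TestPDistance:
    def test_identical_pair_zero(self):
        dm = p_distance_matrix(_aln(["ACGT", "ACGT"]))
        assert dm.values[0, 1] == 0

    def test_three_in_ten(self):
        dm = p_distance_matrix(_aln(["ACGTACGTAC", "TCGAACGTAA"]))
        assert dm.values[0, 1] == pytest.approx(0.3)

    def test_matches_naive_loop_oracle(self, rng):
        seqs = ["".join(rng.choice(list("ACGTN-"), 40)) for _ in range(5)]
        dm = p_distance_matrix(_aln(seqs))
        for i in range(5):
            for j in range(5):
                diffs = comp = 0
                for x, y in zip(seqs[i], seqs[j]):
                    if x in "ACGT" and y in "ACGT":
                        comp += 1
                        diffs += x != y
                assert dm.values[i, j] == pytest.approx(diffs / comp, abs=1e-12)

    def test_two_marker_average(self):
        a1 = _aln(["ACGT", "AAAA"])
        a2 = _aln(["ACGT", "ACGA"], marker="rag1")
        dm = p_distance_matrix([a1, a2])
        assert dm.values[0, 1] == pytest.approx((0.75 + 0.25) / 2)
        assert "mean of 2 markers" in dm.metric_tag

    def test_roster_mismatch_rejected(self):
        a1 = _aln(["ACGT", "AAAA"])
        a2 = SequenceSet("rag1", [SeqEntry("other", "t", "ACGT"), SeqEntry("s1", "t", "ACGA")])
        with pytest.raises(ValueError, match="roster"):
            p_distance_matrix([a1, a2])

    def test_jc_correction_larger_than_p(self):
        dm_p = p_distance_matrix(_aln(["ACGTACGTAC", "TCGAACGTAA"]))
        dm_jc = p_distance_matrix(_aln(["ACGTACGTAC", "TCGAACGTAA"]), metric="jc")
        assert dm_jc.values[0, 1] > dm_p.values[0, 1]


class TestDiagnosticDifferences:
    def test_group_against_itself_empty(self):
        aln = _aln(["ACGT", "ACGA"], taxa=["x", "x"], marker="cyfunp")
        d = diagnostic_differences(aln, "x", "x")
        assert d.substitutions == [] and d.indels == []

    def test_fixed_difference_reported_shared_polymorphism_not(self):
        # column 0: fixed A/G difference; column 3: polymorphic within x
        aln = _aln(["ACGT", "ACGA", "GCGT", "GCGT"], taxa=["x", "x", "y", "y"])
        d = diagnostic_differences(aln, "x", "y")
        assert len(d.substitutions) == 1
        pos, a, b, cls = d.substitutions[0]
        assert (pos, a, b, cls) == (0, "A", "G", "transition")

    def test_transition_transversion_classification(self):
        assert substitution_class("A", "G") == "transition"
        assert substitution_class("C", "T") == "transition"
        assert substitution_class("A", "C") == "transversion"
        assert substitution_class("G", "T") == "transversion"

    def test_symmetric_under_group_swap(self):
        aln = _aln(
            ["ACGT--XT".replace("X", "A"), "ACGT--AT", "GCGTCCAT", "GCGTCCAT"],
            taxa=["x", "x", "y", "y"],
        )
        d1 = diagnostic_differences(aln, "x", "y")
        d2 = diagnostic_differences(aln, "y", "x")
        assert [(p, b, a, c) for p, a, b, c in d1.substitutions] == d2.substitutions
        assert [(s, l, "x") for s, l, g in d2.indels] == d1.indels

    def test_maximal_indel_block(self):
        aln = _aln(["AC---TGA", "AC---TGA", "ACGTCTGA", "ACGTCTGA"], taxa=["x", "x", "y", "y"])
        d = diagnostic_differences(aln, "x", "y")
        assert d.indels == [(2, 3, "x")]

    def test_absent_group_label_rejected(self):
        aln = _aln(["ACGT", "ACGT"], taxa=["x", "x"])
        with pytest.raises(ValueError, match="absent"):
            diagnostic_differences(aln, "x", "z")


class TestBandAttribution:
    @pytest.mark.parametrize(
        "length,expected",
        [(310, "T. muticellus"), (440, "R. rubilio"), (410, "Squalius"), (350, "unassigned")],
    )
    def test_default_key(self, length, expected):
        assert band_length_attribution(length) == expected

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            band_length_attribution(300, key={"a": (290, 320), "b": (310, 330)})


def _dm(values, ids=None):
    values = np.asarray(values, float)
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return DistanceMatrix(ids=ids, values=values, metric_tag="test")


class TestPcoa:
    def test_recovers_planar_configuration(self, rng):
        pts = rng.normal(size=(4, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(axis=2))
        res = pcoa(_dm(d))
        assert res.coordinates.shape[1] == 2
        rec = np.sqrt(((res.coordinates[:, None] - res.coordinates[None]) ** 2).sum(axis=2))
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_eigenvalues_match_characteristic_polynomial_oracle(self):
        """3x3 case: eigenvalues = roots of det(B - lambda I) found independently."""
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.4], [0.5, 0.4, 0.0]])
        res = pcoa(_dm(d))
        n = 3
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        # characteristic polynomial coefficients from trace identities
        t1 = np.trace(b)
        t2 = 0.5 * (t1**2 - np.trace(b @ b))
        t3 = np.linalg.det(b)
        roots = sorted(np.roots([1.0, -t1, t2, -t3]).real, reverse=True)
        np.testing.assert_allclose(res.eigenvalues, roots, atol=1e-8)

    def test_eigenvalue_sum_equals_centered_trace(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.5], [2.0, 1.5, 0.0]])
        res = pcoa(_dm(d))
        n = 3
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-9)

    def test_axis_sign_convention(self, rng):
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(axis=2))
        res = pcoa(_dm(d))
        for j in range(res.coordinates.shape[1]):
            col = res.coordinates[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    @pytest.mark.parametrize("correction", ["lingoes", "cailliez"])
    def test_corrections_remove_negative_eigenvalues(self, correction):
        # a non-Euclidean dissimilarity (violates the triangle inequality badly)
        d = np.array(
            [[0.0, 1.0, 1.0, 9.0], [1.0, 0.0, 1.0, 1.0], [1.0, 1.0, 0.0, 1.0], [9.0, 1.0, 1.0, 0.0]]
        )
        raw = pcoa(_dm(d))
        assert raw.negative_eigenvalue_sum < 0
        fixed = pcoa(_dm(d), correction=correction)
        assert fixed.correction == correction
        assert fixed.negative_eigenvalue_sum == pytest.approx(0.0, abs=1e-6)

    def test_correction_noop_when_euclidean(self, rng, caplog):
        pts = rng.normal(size=(4, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(axis=2))
        res = pcoa(_dm(d), correction="lingoes")
        assert res.correction == "none"

    def test_matches_skbio_ordination(self, rng):
        """Cross-check coordinates against an independent implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as skbio_pcoa

        pts = rng.normal(size=(6, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(axis=2))
        ours = pcoa(_dm(d))
        theirs = skbio_pcoa(skbio.DistanceMatrix(d))
        m = ours.coordinates.shape[1]
        for j in range(m):
            a = ours.coordinates[:, j]
            b = theirs.samples.values[:, j]
            s = np.sign(a @ b)
            np.testing.assert_allclose(a, s * b, atol=1e-8)


class TestSeparationMonotoneInDivergence:
    def test_pcoa_axis1_separation_grows_with_divergence(self, templates):
        """Star-topology sequences: more divergence, more axis-1 separation."""
        from dataclasses import replace
        from leucidelim import simulate_sequences

        seps = []
        for div in (0.01, 0.05, 0.12):
            vals = []
            for seed in range(20):
                pair = [
                    replace(templates[0], clade=None, clade_divergence={}, divergence={"cytb": div}),
                    replace(templates[2], divergence={"cytb": div}),
                ]
                aln = simulate_sequences(pair, "cytb", [5, 5], seed=seed)
                res = pcoa(p_distance_matrix(aln), n_axes=2)
                ax1 = res.coordinates[:, 0]
                vals.append(abs(ax1[:5].mean() - ax1[5:].mean()))
            seps.append(np.mean(vals))
        assert seps[0] < seps[1] < seps[2]
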