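"""Filter-stack rules, heteroplasmy genotyping, substitution spectra and
homopolymer length heteroplasmy."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mitodlp import genotyping as gt
from mitodlp.simulate import SimulationConfig, inject_strand_artifact, simulate_dataset
from tests.conftest import TOY_EXPECTED_PASS, make_variant_cells


class TestStrandSupport:
    @pytest.mark.parametrize(
        "fwd,rev,expected",
        [(2, 2, True), (3, 1, False), (0, 10, False), (1, 1, False), (100, 2, True)],
    )
    def test_rule(self, fwd, rev, expected):
        assert gt.strand_support_filter(fwd, rev) is expected

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            gt.strand_support_filter(-1, 5)


class TestStrandConcordance:
    def test_identical_nonconstant_vectors_pass(self):
        df = make_variant_cells(10, "A", "G", [1, 5, 9], [10] * 3, [1, 5, 9], [10] * 3)
        ok, r, _ = gt.strand_concordance_filter(df)
        assert ok and r == pytest.approx(1.0)

    def test_perfect_anticorrelation_fails(self):
        df = make_variant_cells(10, "A", "G", [1, 5, 9], [10] * 3, [9, 5, 1], [10] * 3)
        ok, r, reason = gt.strand_concordance_filter(df)
        assert not ok and r == pytest.approx(-1.0) and reason == "low_strand_correlation"

    def test_hand_evaluated_pearson_on_four_points(self):
        # fwd (0.2,0.4,0.6,0.8) vs rev (0.25,0.35,0.65,0.75):
        # r = 0.18 / sqrt(0.2 * 0.17)
        df = make_variant_cells(10, "A", "G", [4, 8, 12, 16], [20] * 4, [5, 7, 13, 15], [20] * 4)
        ok, r, _ = gt.strand_concordance_filter(df)
        assert ok and r == pytest.approx(0.18 / np.sqrt(0.2 * 0.17))

    def test_boundary_is_inclusive(self):
        df = make_variant_cells(10, "A", "G", [4, 8, 12, 16], [20] * 4, [5, 7, 13, 15], [20] * 4)
        r_exact = 0.18 / np.sqrt(0.2 * 0.17)
        ok, _, _ = gt.strand_concordance_filter(df, min_r=r_exact)
        assert ok

    def test_zero_informative_cells_fails_with_reason(self):
        df = make_variant_cells(10, "A", "G", [0, 0, 0], [0, 0, 0], [0, 0, 0], [10, 10, 10])
        ok, r, reason = gt.strand_concordance_filter(df)
        assert not ok and np.isnan(r) and reason == "too_few_informative_cells"

    def test_zero_variance_fails_with_reason(self):
        df = make_variant_cells(10, "A", "G", [5, 5, 5], [10] * 3, [1, 5, 9], [10] * 3)
        ok, r, reason = gt.strand_concordance_filter(df)
        assert not ok and reason == "zero_variance"


class TestBlacklist:
    @pytest.mark.parametrize(
        "pos,passes",
        [(514, False), (526, True), (3105, False), (513, False), (525, False),
         (3109, False), (3110, True), (512, True), (1, True), (16569, True)],
    )
    def test_rule(self, pos, passes):
        assert gt.blacklist_filter(pos) is passes

    @pytest.mark.parametrize("pos", [0, -3, 16570])
    def test_out_of_range_raises(self, pos):
        with pytest.raises(gt.CoordinateError):
            gt.blacklist_filter(pos)


def test_filter_stack_on_toy_table(toy_filter_table):
    records = gt.apply_filter_stack(toy_filter_table)
    assert len(records) == 12
    passed = {r.position for r in records if r.is_pass}
    assert passed == TOY_EXPECTED_PASS
    by_pos = {r.position: r for r in records}
    assert "strand_support" not in by_pos[101].filters_passed
    assert by_pos[101].filters_passed >= {"strand_concordance", "blacklist"}
    assert by_pos[200].filters_passed == {"strand_support", "blacklist"}
    assert by_pos[513].filters_passed == {"strand_support", "strand_concordance"}


def test_filter_stack_order_invariance(toy_filter_table):
    """The three filters are independent predicates, so any application order
    gives the same PASS set; verified by recomputing set intersections in
    every order."""
    records = gt.apply_filter_stack(toy_filter_table)
    sets = {
        name: {r.position for r in records if name in r.filters_passed}
        for name in gt.FILTER_NAMES
    }
    reference_pass = None
    for order in itertools.permutations(gt.FILTER_NAMES):
        surviving = {r.position for r in records}
        for name in order:
            surviving &= sets[name]
        if reference_pass is None:
            reference_pass = surviving
        assert surviving == reference_pass
    assert reference_pass == TOY_EXPECTED_PASS


def test_planted_variants_pass_filters_on_clean_simulation():
    cfg = SimulationConfig(
        n_libraries=1, cells_per_library=150, n_clones=2, n_variants=10,
        mean_site_coverage=60, seed=7,
    )
    _, counts, truth = simulate_dataset(cfg)
    records = gt.apply_filter_stack(counts)
    expected = []
    H = truth.clone_heteroplasmy
    # variants whose expected pooled alternate reads per strand are >= 4
    for j, pos in enumerate(truth.variants["position"]):
        exp_alt_per_strand = 0.5 * H[:, j].mean() * 60 * 150
        if exp_alt_per_strand >= 4:
            expected.append(pos)
    passed = {r.position for r in records if r.is_pass}
    frac = len(passed & set(expected)) / len(expected)
    assert frac >= 0.95


def test_strand_artifact_always_rejected(two_clone_dataset):
    _, counts, truth = two_clone_dataset
    pos = int(truth.variants["position"].iloc[0])
    bad = inject_strand_artifact(counts, pos)
    records = gt.apply_filter_stack(bad)
    rec = next(r for r in records if r.position == pos)
    assert "strand_support" not in rec.filters_passed


class TestGenotypeCells:
    def test_pooled_strand_heteroplasmy(self):
        df = make_variant_cells(10, "A", "G", [3], [5], [1], [5])
        het, depth = gt.genotype_cells(df)
        assert het.loc["c0", 10] == pytest.approx(0.4)
        assert depth.loc["c0", 10] == 10

    def test_zero_depth_is_missing(self):
        df = make_variant_cells(10, "A", "G", [0, 5], [0, 10], [0, 0], [0, 0])
        het, depth = gt.genotype_cells(df)
        assert np.isnan(het.loc["c0", 10]) and depth.loc["c0", 10] == 0
        assert het.loc["c1", 10] == pytest.approx(0.5)

    def test_matrix_entries_in_unit_interval(self, two_clone_dataset):
        _, counts, _ = two_clone_dataset
        het, depth = gt.genotype_cells(counts)
        defined = het.to_numpy()[depth.to_numpy() > 0]
        assert np.isfinite(defined).all()
        assert ((defined >= 0) & (defined <= 1)).all()


class TestHomoplasmy:
    def test_extremes(self):
        het = pd.DataFrame({"v1": [1.0, 1.0, 1.0], "v2": [0.3, 0.3, 0.3]})
        labels = gt.classify_homoplasmy(het)
        assert labels["v1"] == "homoplasmic" and labels["v2"] == "heteroplasmic"

    def test_median_above_threshold(self):
        het = pd.DataFrame({"v": [0.96, 0.97, 0.95]})
        assert gt.classify_homoplasmy(het)["v"] == "homoplasmic"

    def test_all_missing_raises(self):
        het = pd.DataFrame({"v": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            gt.classify_homoplasmy(het)


class TestTrinucleotideSpectrum:
    def test_toy_circular_reference(self):
        # one C>T at position 3 of circular AACGT; context ACG occurs once
        variants = pd.DataFrame({"position": [3], "ref": ["C"], "alt": ["T"]})
        spec, skipped = gt.trinucleotide_spectrum(variants, "AACGT")
        assert skipped == 0
        row = spec[(spec["strand"] == "L") & (spec["context"] == "ACG")].iloc[0]
        assert row["substitution"] == "C>T"
        assert row["count"] == 1 and row["context_freq"] == 1 and row["rate"] == 1.0

    def test_no_variants_gives_empty_spectrum(self):
        spec, _ = gt.trinucleotide_spectrum(pd.DataFrame(columns=["position", "ref", "alt"]), "AACGT")
        assert len(spec) == 0

    def test_palindromic_reference_strand_symmetry(self):
        # ACGT is its own reverse complement; a variant plus its mirrored
        # complement makes the L and H spectra identical
        variants = pd.DataFrame({"position": [2, 3], "ref": ["C", "G"], "alt": ["T", "A"]})
        spec, _ = gt.trinucleotide_spectrum(variants, "ACGT")
        l = spec[spec["strand"] == "L"].set_index(["context", "substitution"])["rate"]
        h = spec[spec["strand"] == "H"].set_index(["context", "substitution"])["rate"]
        pd.testing.assert_series_equal(l.sort_index(), h.sort_index(), check_names=False)

    def test_denormalization_recovers_substitution_totals(self, two_clone_dataset):
        _, _, truth = two_clone_dataset
        spec, _ = gt.trinucleotide_spectrum(truth.variants, truth.reference)
        for strand in ("L", "H"):
            sub = spec[spec["strand"] == strand]
            assert (sub["rate"] * sub["context_freq"]).sum() == pytest.approx(len(truth.variants))

    def test_indels_skipped_with_count(self):
        variants = pd.DataFrame({"position": [2, 3], "ref": ["C", "G"], "alt": ["CT", "A"]})
        _, skipped = gt.trinucleotide_spectrum(variants, "AACGT")
        assert skipped == 1


class TestLengthHeteroplasmy:
    def make(self, per_cell):
        rows = []
        for cell, alleles in per_cell.items():
            for a, n in alleles.items():
                rows.append({"cell_id": cell, "allele": a, "count": n})
        return pd.DataFrame(rows)

    def test_reference_majority(self):
        out = gt.length_heteroplasmy(self.make({"c0": {"A": 8, "AC": 2}}), ref_allele="A")
        assert out.iloc[0]["ref_heteroplasmy"] == pytest.approx(0.8)
        assert out.iloc[0]["major_allele"] == "A"

    def test_insertion_majority(self):
        out = gt.length_heteroplasmy(self.make({"c0": {"A": 0, "AC": 10}}), ref_allele="A")
        assert out.iloc[0]["ref_heteroplasmy"] == 0.0
        assert out.iloc[0]["major_allele"] == "AC"

    def test_three_allele_proportions(self):
        out = gt.length_heteroplasmy(self.make({"c0": {"A": 5, "AC": 3, "ACC": 2}}), ref_allele="A")
        assert out.iloc[0]["ref_heteroplasmy"] == pytest.approx(0.5)
        assert out.iloc[0]["major_allele"] == "A"

    def test_coverage_exclusion_and_empty_reason(self):
        out = gt.length_heteroplasmy(self.make({"c0": {"A": 4, "AC": 5}}), ref_allele="A")
        assert len(out) == 0 and out.attrs["reason"] == "all_cells_below_min_total"
        out2 = gt.length_heteroplasmy(
            self.make({"c0": {"A": 4, "AC": 5}, "c1": {"A": 9, "AC": 1}}), ref_allele="A"
        )
        assert list(out2["cell_id"]) == ["c1"]


def test_vcf_round_trip_filters(tmp_path, toy_filter_table):
    records = gt.apply_filter_stack(toy_filter_table)
    path = tmp_path / "variants.vcf"
    gt.write_vcf(records, path)
    lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == 12
    by_pos = {int(l.split("\t")[1]): l.split("\t")[6] for l in lines}
    for pos in TOY_EXPECTED_PASS:
        assert by_pos[pos] == "PASS"
    assert "blacklist" in by_pos[513]
    assert "strand_support" in by_pos[101]
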