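"""Recombination frequency, distance, genotype inference, interval refinement."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsamap.recomb import (
    HET,
    HOM_MUT,
    UNKNOWN,
    MarkerGenotypeTable,
    RecombinationEstimate,
    SpeciesParams,
    distance_estimate,
    genomes_screened,
    infer_missing_genotypes,
    locus_position_estimate,
    pairing_probability,
    read_genotype_table,
    recombination_frequency,
    refine_interval,
    write_genotype_table,
)
from bsamap.snp_index import MappedInterval


def table(chrom, positions, rows):
    animals = [f"a{i}" for i in range(len(rows))]
    return MarkerGenotypeTable(chrom, list(positions), animals, dict(zip(animals, [list(r) for r in rows])))


def mutant_cross_table(n_het_a_only, n_het_both, n_hom, positions=(2_500_000, 10_710_000)):
    """The two-marker genotype layout of a typical refinement experiment."""
    rows = (
        [[HET, HOM_MUT]] * n_het_a_only
        + [[HET, HET]] * n_het_both
        + [[HOM_MUT, HOM_MUT]] * n_hom
    )
    return table("chr1", positions, rows)


class TestRecombinationFrequency:
    def test_twelve_of_thirtyfive(self):
        t = mutant_cross_table(11, 1, 23)
        est = recombination_frequency(t, 0)
        assert (est.recombinants, est.genotyped) == (12, 35)
        assert est.rf == pytest.approx(12 / 35)

    def test_one_of_thirtyfive(self):
        t = mutant_cross_table(11, 1, 23)
        est = recombination_frequency(t, 1)
        assert est.rf == pytest.approx(1 / 35)

    def test_fully_linked(self):
        t = mutant_cross_table(0, 0, 35)
        assert recombination_frequency(t, 0).rf == 0.0

    def test_unknowns_not_genotyped(self):
        t = table("chr1", [100, 200], [[HET, UNKNOWN], [UNKNOWN, UNKNOWN]])
        est = recombination_frequency(t, 0)
        assert (est.recombinants, est.genotyped) == (1, 1)
        with pytest.raises(ValueError):
            recombination_frequency(t, 1)


class TestDistanceEstimate:
    @pytest.mark.parametrize(
        "recomb,total,expected_mb,expected_rounded",
        [(12, 35, 25.371428, 25), (1, 35, 2.114285, 2), (0, 35, 0.0, 0)],
    )
    def test_zebrafish_map_density(self, recomb, total, expected_mb, expected_rounded):
        est = RecombinationEstimate("chr1", 1, recomb, total)
        d = distance_estimate(est, SpeciesParams(0.74))
        assert d == pytest.approx(expected_mb, abs=1e-4)
        assert round(d) == expected_rounded

    def test_linear_in_recombinants(self):
        sp = SpeciesParams()
        d = [distance_estimate(RecombinationEstimate("c", 1, r, 40), sp) for r in range(41)]
        diffs = {round(b - a, 9) for a, b in zip(d, d[1:])}
        assert len(diffs) == 1  # constant increments: linear and monotone


class TestInferMissing:
    def test_concordant_flanks_inferred(self):
        t = table("chr1", [100, 200, 300], [[HOM_MUT, UNKNOWN, HOM_MUT]])
        out = infer_missing_genotypes(t)
        assert out.genotypes["a0"] == [HOM_MUT, HOM_MUT, HOM_MUT]
        assert ("a0", 1) in out.inferred

    def test_discordant_flanks_unchanged(self):
        t = table("chr1", [100, 200, 300], [[HOM_MUT, UNKNOWN, HET]])
        assert infer_missing_genotypes(t).genotypes["a0"][1] == UNKNOWN

    def test_edge_unknown_unchanged(self):
        t = table("chr1", [100, 200, 300], [[UNKNOWN, HOM_MUT, HOM_MUT]])
        assert infer_missing_genotypes(t).genotypes["a0"][0] == UNKNOWN

    def test_nearest_known_skips_adjacent_unknowns(self):
        t = table("chr1", [100, 200, 300, 400], [[HET, UNKNOWN, UNKNOWN, HET]])
        out = infer_missing_genotypes(t)
        assert out.genotypes["a0"] == [HET, HET, HET, HET]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([HOM_MUT, HET, UNKNOWN]), min_size=1, max_size=12))
    def test_never_alters_known_genotypes(self, row):
        t = table("chr1", [100 * (i + 1) for i in range(len(row))], [row])
        out = infer_missing_genotypes(t)
        for before, after in zip(row, out.genotypes["a0"]):
            if before != UNKNOWN:
                assert after == before


ARCHES_IV = MappedInterval("chr1", 2_460_000, 13_870_000, 12_000_000, 1.0)


class TestRefineInterval:
    def test_two_marker_worked_example(self):
        # 11 animals recombinant at the outer marker only, one at both,
        # 23 fully linked: everything left of the inner marker is excluded.
        t = mutant_cross_table(11, 1, 23)
        res = refine_interval(ARCHES_IV, t)
        assert res.interval.left == 10_710_000
        assert res.interval.right == 13_870_000
        assert res.interval.size == pytest.approx(3_160_000)
        assert res.conflicts == []

    def test_five_marker_worked_example(self):
        # markers at 19.03, 26.12, 28.09, 29.09, 31.61 Mb inside [12.53, 42.96]:
        # right-end het runs through the 26.12 marker and a left-end run at
        # 19.03 leave ~7 Mb between them.
        positions = [19_034_592, 26_124_850, 28_090_051, 29_087_847, 31_609_203]
        rows = (
            [[HOM_MUT, HET, HET, HET, HET]] * 3  # right-end run through D
            + [[HOM_MUT, HOM_MUT, HOM_MUT, HET, HET]] * 2
            + [[HET, HOM_MUT, HOM_MUT, HOM_MUT, HOM_MUT]] * 2  # left-end run at E
            + [[HOM_MUT] * 5] * 30
        )
        iv = MappedInterval("chr7", 12_530_000, 42_960_000, 25_000_000, 1.0)
        res = refine_interval(iv, table("chr7", positions, rows))
        assert res.interval.left == 19_034_592
        assert res.interval.right == 26_124_850
        assert res.interval.size / 1e6 == pytest.approx(7.09, abs=0.01)

    def test_all_homozygous_leaves_interval_unchanged(self):
        t = mutant_cross_table(0, 0, 10)
        res = refine_interval(ARCHES_IV, t)
        assert (res.interval.left, res.interval.right) == (ARCHES_IV.left, ARCHES_IV.right)

    def test_refined_is_subset_and_idempotent(self):
        t = mutant_cross_table(5, 0, 10)
        res1 = refine_interval(ARCHES_IV, t)
        assert ARCHES_IV.left <= res1.interval.left <= res1.interval.right <= ARCHES_IV.right
        res2 = refine_interval(res1.interval, t)
        assert (res2.interval.left, res2.interval.right) == (res1.interval.left, res1.interval.right)

    def test_interior_het_flagged_conflicting(self):
        rows = [[HOM_MUT, HET, HOM_MUT], [HOM_MUT, HOM_MUT, HOM_MUT]]
        t = table("chr1", [3_000_000, 5_000_000, 9_000_000], rows)
        res = refine_interval(ARCHES_IV, t)
        assert res.conflicts == ["a0"]
        assert (res.interval.left, res.interval.right) == (ARCHES_IV.left, ARCHES_IV.right)

    def test_emptying_refinement_errors(self):
        rows = [[HET, HOM_MUT], [HOM_MUT, HET]]
        t = table("chr1", [2_500_000, 13_000_000], rows)
        squeezed = MappedInterval("chr1", 2_460_000, 13_100_000, 12_900_000, 1.0)
        res = refine_interval(squeezed, t)
        assert (res.interval.left, res.interval.right) == (2_500_000, 13_000_000)
        rows_bad = [[HET, HET, HOM_MUT], [HOM_MUT, HET, HET]]
        t_bad = table("chr1", [2_500_000, 9_000_000, 13_000_000], rows_bad)
        with pytest.raises(ValueError, match="empties"):
            refine_interval(squeezed, t_bad)

    def test_wrong_chromosome_rejected(self):
        with pytest.raises(ValueError):
            refine_interval(ARCHES_IV, table("chr9", [3_000_000], [[HET]]))


class TestLocusPosition:
    def test_signs_chosen_toward_interval(self):
        iv = MappedInterval("chr1", 12_000_000, 18_000_000, 15_000_000, 1.0)
        ests = [
            RecombinationEstimate("chr1", 10_000_000, 0, 1, distance_mb=5.0),
            RecombinationEstimate("chr1", 30_000_000, 0, 1, distance_mb=15.0),
        ]
        mean, sd, flags = locus_position_estimate(ests, iv)
        assert mean == pytest.approx(15_000_000)
        assert sd == pytest.approx(0.0)
        assert flags == [False, False]

    def test_single_marker_sd_zero(self):
        iv = MappedInterval("chr1", 12_000_000, 18_000_000, 15_000_000, 1.0)
        ests = [RecombinationEstimate("chr1", 10_000_000, 0, 1, distance_mb=4.0)]
        mean, sd, _ = locus_position_estimate(ests, iv)
        assert (mean, sd) == (14_000_000, 0.0)

    def test_out_of_interval_candidate_flagged(self):
        iv = MappedInterval("chr1", 12_000_000, 13_000_000, 12_500_000, 1.0)
        ests = [RecombinationEstimate("chr1", 20_000_000, 0, 1, distance_mb=2.0)]
        mean, _, flags = locus_position_estimate(ests, iv)
        assert flags == [True]
        assert mean == pytest.approx(18_000_000)  # nearest-to-interval candidate


class TestScreenDesign:
    def test_six_crosses(self):
        assert pairing_probability(6) == pytest.approx(1 - 0.75**6)
        assert pairing_probability(6) == pytest.approx(0.82, abs=0.005)

    def test_degenerate_cases(self):
        assert pairing_probability(0) == 0.0
        assert pairing_probability(1, carrier_fraction=1.0) == 1.0

    def test_genomes_screened_additive(self):
        one = genomes_screened([6])
        assert one == pytest.approx(0.822, abs=0.001)
        assert genomes_screened([6, 6]) == pytest.approx(2 * one)
        assert genomes_screened([]) == 0.0


class TestTableIO:
    def test_roundtrip(self, tmp_path):
        t = mutant_cross_table(2, 1, 3)
        t.genotypes["a0"][1] = UNKNOWN
        path = tmp_path / "genos.tsv"
        write_genotype_table(t, path)
        back = read_genotype_table(path)
        assert back.chrom == t.chrom
        assert back.positions == t.positions
        assert back.genotypes == t.genotypes

    def test_mixed_chromosomes_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("animal\tchr1:100\tchr2:200\na0\tM\tH\n")
        with pytest.raises(ValueError):
            read_genotype_table(path)
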