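"""Library construction, spectrum fates, efficiency and dilution metrics."""

import pytest

from saavbench.annotation import PSMRecord, annotate_psm
from saavbench.chem import DEFAULT_TABLE, delta_mass
from saavbench.digestion import CleavageRule
from saavbench.errors import InputError
from saavbench.evaluation import (
    AMBIGUOUS_FILTERED,
    COGNATE_ASSIGNMENT,
    CORRECT,
    FATE_CATEGORIES,
    INCORRECT_MODIFIED,
    NO_IDENTIFICATION,
    OTHER_INCORRECT,
    ZERO_INTENSITY_FILTERED,
    build_library,
    categorize_fates,
    compute_efficiency,
    dilution_metrics,
    fate_fractions,
    library_from_frame,
    library_to_frame,
    score_deltas,
)
from saavbench.saav import find_saav_pairs

RULE = CleavageRule(min_length=1, max_length=1000, max_missed_cleavages=1)
PAIRS = find_saav_pairs(
    ["PEPTIDEK", "AAAGGGK", "TESTK"], ["PEPSIDEK", "AAACGGK", "TESTR"], RULE
)


def psm(spectrum, peptide, offset=0.0, position=None, intensity=1e6, prob=0.99,
        sample="D01", source="two_genome"):
    return PSMRecord(
        spectrum_id=spectrum,
        assigned_peptide=peptide,
        observed_offset=offset,
        precursor_intensity=intensity,
        peptide_neutral_mass=DEFAULT_TABLE.peptide_mass(peptide),
        posterior_probability=prob,
        offset_position=position,
        sample_label=sample,
        source_search=source,
    )


def toy_library():
    two_genome = [
        psm("s1", "PEPSIDEK", prob=0.99),
        psm("s2", "PEPSIDEK", prob=0.95, sample="D02", intensity=4e6),
        psm("s3", "AAACGGK", prob=0.97),
        psm("s4", "TESTR", prob=0.96),
        psm("s5", "PEPTIDEK"),  # cognate only: not a library member
    ]
    return build_library(two_genome, PAIRS)


class TestBuildLibrary:
    def test_only_variant_spectra_enter(self):
        library = toy_library()
        assert [e.spectrum_id for e in library] == ["s1", "s2", "s3", "s4"]

    def test_entry_carries_substitution_context(self):
        entry = next(e for e in toy_library() if e.spectrum_id == "s1")
        sub = entry.truth_pair.substitution
        assert (sub.from_class, sub.to_class) == ("T", "S")
        assert entry.position == 4
        assert entry.position_from_c == 5
        assert entry.truth_pair.reference_sequence == "PEPTIDEK"

    def test_spectrum_conflict_resolved_by_probability(self, caplog):
        two = [psm("s1", "PEPSIDEK", prob=0.80), psm("s1", "TESTR", prob=0.99)]
        library = build_library(two, PAIRS)
        assert len(library) == 1
        assert library[0].truth_sequence == "TESTR"

    def test_library_round_trips_through_frame(self):
        library = toy_library()
        rebuilt = library_from_frame(library_to_frame(library))
        assert [e.truth_sequence for e in rebuilt] == [
            e.truth_sequence for e in library
        ]
        assert [e.truth_pair.scissor_class for e in rebuilt] == [
            e.truth_pair.scissor_class for e in library
        ]


class TestCategorizeFates:
    def fates_for(self, one_genome_psms, library=None):
        library = library if library is not None else toy_library()
        anns = [annotate_psm(p) for p in one_genome_psms]
        return categorize_fates(library, anns), library

    def test_correct_identification(self):
        fates, _ = self.fates_for(
            [psm("s1", "PEPTIDEK", offset=delta_mass("T", "S"), position=4)]
        )
        assert fates[0].category == CORRECT

    def test_absent_spectrum_is_no_identification(self):
        fates, _ = self.fates_for([])
        assert {f.category for f in fates} == {NO_IDENTIFICATION}

    def test_cognate_assignment(self):
        fates, _ = self.fates_for([psm("s1", "PEPTIDEK", offset=0.0)])
        assert fates[0].category == COGNATE_ASSIGNMENT

    def test_wrong_modified_sequence(self):
        # uniquely localized substitution that is not the truth
        fates, _ = self.fates_for(
            [psm("s1", "PEPTIDEK", offset=delta_mass("P", "W"), position=1)]
        )
        assert fates[0].category == INCORRECT_MODIFIED

    def test_zero_intensity_beats_other_categories(self):
        fates, _ = self.fates_for(
            [psm("s1", "PEPTIDEK", offset=delta_mass("T", "S"), position=4,
                 intensity=0.0)]
        )
        assert fates[0].category == ZERO_INTENSITY_FILTERED

    def test_ambiguous_offset_filtered(self):
        # deamidation-sized shift on the N-containing cognate is ambiguous
        fates, _ = self.fates_for(
            [psm("s3", "AAAGGGK", offset=delta_mass("G", "A"))]
        )
        assert fates[2].category == AMBIGUOUS_FILTERED

    def test_unrelated_unmodified_assignment(self):
        fates, _ = self.fates_for([psm("s1", "AAAGGGK", offset=0.0)])
        assert fates[0].category == OTHER_INCORRECT

    def test_duplicate_spectrum_rejected_with_id(self):
        anns = [
            annotate_psm(psm("s1", "PEPTIDEK")),
            annotate_psm(psm("s1", "TESTK")),
        ]
        with pytest.raises(InputError, match="s1"):
            categorize_fates(toy_library(), anns)

    def test_fates_partition_library(self):
        fates, library = self.fates_for(
            [
                psm("s1", "PEPTIDEK", offset=delta_mass("T", "S"), position=4),
                psm("s3", "AAAGGGK", offset=0.0),
            ]
        )
        assert len(fates) == len(library)
        fractions = fate_fractions(fates)
        assert sum(fractions.values()) == pytest.approx(1.0)
        assert set(fractions) == set(FATE_CATEGORIES)


class TestComputeEfficiency:
    def test_spectrum_and_peptide_levels(self):
        library = toy_library()
        # correct only for the two PEPSIDEK spectra
        one = [
            psm("s1", "PEPTIDEK", offset=delta_mass("T", "S"), position=4),
            psm("s2", "PEPTIDEK", offset=delta_mass("T", "S"), position=4),
        ]
        fates = categorize_fates(library, [annotate_psm(p) for p in one])
        report = compute_efficiency(fates, library)
        assert report.spectrum_level_efficiency == pytest.approx(2 / 4)
        assert report.peptide_level_efficiency == pytest.approx(1 / 3)
        cell = report.by_type[("T", "S")]
        assert (cell.n_library, cell.n_correct) == (2, 2)
        assert cell.efficiency == pytest.approx(1.0)

    def test_all_correct_gives_full_efficiency(self):
        library = toy_library()
        one = [
            psm("s1", "PEPTIDEK", offset=delta_mass("T", "S"), position=4),
            psm("s2", "PEPTIDEK", offset=delta_mass("T", "S"), position=4),
            psm("s3", "AAAGGGK", offset=delta_mass("G", "C"), position=4),
            psm("s4", "TESTK", offset=delta_mass("K", "R"), position=5),
        ]
        fates = categorize_fates(library, [annotate_psm(p) for p in one])
        report = compute_efficiency(fates, library)
        assert report.spectrum_level_efficiency == 1.0
        assert report.peptide_level_efficiency == 1.0
        assert all(
            c.efficiency == 1.0 for c in report.by_type.values()
        )
        assert report.zero_identified_types == 0

    def test_matrix_counts_sum_to_library_size(self):
        library = toy_library()
        fates = categorize_fates(library, [])
        report = compute_efficiency(fates, library)
        assert sum(c.n_library for c in report.by_type.values()) == len(library)
        assert sum(c.n_library for c in report.by_length_position.values()) == len(
            library
        )
        assert sum(c.n_library for c in report.by_scissor.values()) == len(library)
        assert 0.0 <= report.spectrum_level_efficiency <= 1.0
        assert 0.0 <= report.peptide_level_efficiency <= 1.0

    def test_empty_library_rejected(self):
        with pytest.raises(InputError):
            compute_efficiency([], [])


class TestScoreDeltas:
    def test_differences_and_summary(self):
        library = toy_library()
        one = [
            psm("s1", "PEPTIDEK", offset=delta_mass("T", "S"), position=4,
                prob=0.99),
            psm("s2", "PEPTIDEK", offset=delta_mass("T", "S"), position=4,
                prob=0.91),
        ]
        fates = categorize_fates(library, [annotate_psm(p) for p in one])
        summary = score_deltas(library, fates)
        assert len(summary.deltas) == 2  # one per correct spectrum
        assert sorted(round(d, 6) for d in summary.deltas) == [-0.04, 0.0]
        assert summary.fraction_zero == pytest.approx(0.5)
        assert summary.fraction_negative == pytest.approx(0.5)


class TestDilutionMetrics:
    def entry(self, spectrum, seq, intensity, sample):
        library = toy_library()
        base = next(e for e in library if e.truth_sequence == seq)
        return type(base)(
            spectrum_id=spectrum,
            truth_sequence=seq,
            truth_pair=base.truth_pair,
            intensity=intensity,
            retention_time=50.0,
            ion_mobility=None,
            library_probability=0.99,
            sample_label=sample,
        )

    def test_dynamic_range_is_log10_ratio(self):
        entries = [
            self.entry("a", "PEPSIDEK", 1e6, "D03"),
            self.entry("b", "PEPSIDEK", 4e6, "D02"),
            self.entry("c", "PEPSIDEK", 1e8, "D01"),
        ]
        metrics = dilution_metrics(entries)
        pep = metrics.per_peptide["PEPSIDEK"]
        assert pep.dynamic_range == pytest.approx(2.0)
        assert pep.min_intensity == 1e6
        assert pep.last_sample == "D03"

    def test_single_detection_has_zero_range(self):
        metrics = dilution_metrics([self.entry("a", "TESTR", 5e6, "D01")])
        assert metrics.per_peptide["TESTR"].dynamic_range == 0.0

    def test_peptides_are_independent(self):
        entries = [
            self.entry("a", "PEPSIDEK", 1e6, "D01"),
            self.entry("b", "TESTR", 1e9, "D04"),
        ]
        metrics = dilution_metrics(entries)
        assert metrics.per_peptide["PEPSIDEK"].dynamic_range == 0.0
        assert metrics.per_peptide["TESTR"].last_sample == "D04"

    def test_zero_intensity_entries_excluded(self):
        entries = [
            self.entry("a", "PEPSIDEK", 0.0, "D01"),
            self.entry("b", "PEPSIDEK", 1e6, "D02"),
        ]
        metrics = dilution_metrics(entries)
        assert metrics.per_peptide["PEPSIDEK"].min_intensity == 1e6
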