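"""The planted-truth simulator: determinism, recovery, dilution behavior."""

import numpy as np
import pytest

from saavbench.annotation import annotate_psm
from saavbench.digestion import digest
from saavbench.errors import ConfigError
from saavbench.evaluation import (
    CORRECT,
    build_library,
    categorize_fates,
    compute_efficiency,
    dilution_metrics,
)
from saavbench.saav import apply_exclusions, hamming1_position
from saavbench.simulation import (
    DEFAULT_FATE_PROBABILITIES,
    SimulationConfig,
    generate_reference_proteome,
    mutate_proteome,
    simulate,
)

SMALL = dict(n_proteins=25, protein_length=(120, 240))


def records_from_frame(frame):
    from saavbench.annotation import DEFAULT_COLUMN_MAP, PSMRecord

    col = DEFAULT_COLUMN_MAP
    out = []
    for _, row in frame.iterrows():
        pos = row[col["offset_position"]]
        out.append(
            PSMRecord(
                spectrum_id=str(row[col["spectrum_id"]]),
                assigned_peptide=str(row[col["assigned_peptide"]]),
                observed_offset=float(row[col["observed_offset"]]),
                precursor_intensity=float(row[col["precursor_intensity"]]),
                peptide_neutral_mass=float(row[col["peptide_neutral_mass"]]),
                posterior_probability=float(row[col["posterior_probability"]]),
                offset_position=int(pos) if str(pos) not in ("", "nan") else None,
                sample_label=str(row[col["sample_label"]]),
                source_search=str(row[col["source_search"]]),
            )
        )
    return out


def run_pipeline(result, config):
    two = records_from_frame(result.two_genome)
    one = records_from_frame(result.one_genome)
    library = build_library(two, result.pairs)
    annotations = [annotate_psm(p, config.ptms, config.tolerances) for p in one]
    fates = categorize_fates(library, annotations)
    return library, annotations, fates


class TestMutateProteome:
    def test_zero_rate_is_identity(self, rng):
        config = SimulationConfig(substitution_rate=0.0, **SMALL)
        proteins = generate_reference_proteome(config, rng)
        variant, events = mutate_proteome(proteins, config, rng)
        assert variant == proteins
        assert events == []

    def test_event_count_binomially_consistent(self):
        config = SimulationConfig(
            n_proteins=100, protein_length=(300, 300), substitution_rate=0.01
        )
        rng = np.random.default_rng(11)
        proteins = generate_reference_proteome(config, rng)
        _, events = mutate_proteome(proteins, config, rng)
        n = 100 * 300
        expected = n * config.substitution_rate
        sd = (n * 0.01 * 0.99) ** 0.5
        assert abs(len(events) - expected) < 4 * sd

    def test_no_il_swaps_planted(self):
        config = SimulationConfig(substitution_rate=0.05, **SMALL)
        rng = np.random.default_rng(5)
        proteins = generate_reference_proteome(config, rng)
        _, events = mutate_proteome(proteins, config, rng)
        assert events, "expected some events at 5% rate"
        assert not any(
            e.from_residue in "IL" and e.to_residue in "IL" for e in events
        )

    def test_scissor_bias_enriches_kr_events(self):
        rng = np.random.default_rng(7)
        config = SimulationConfig(substitution_rate=0.02, scissor_bias=1.0, **SMALL)
        proteins = generate_reference_proteome(config, rng)
        _, events = mutate_proteome(proteins, config, rng)
        assert all(
            e.from_residue in "KR" or e.to_residue in "KR" for e in events
        )


class TestDeterminism:
    def test_fixed_seed_reproduces_tables(self):
        config = SimulationConfig(random_seed=42, **SMALL)
        a, b = simulate(config), simulate(config)
        assert a.two_genome.equals(b.two_genome)
        assert a.one_genome.equals(b.one_genome)
        assert a.truth.equals(b.truth)
        assert a.reference_proteins == b.reference_proteins

    def test_different_seeds_differ(self):
        a = simulate(SimulationConfig(random_seed=1, **SMALL))
        b = simulate(SimulationConfig(random_seed=2, **SMALL))
        assert not a.two_genome.equals(b.two_genome)


class TestPlantedEventRecovery:
    @pytest.mark.parametrize("seed", [9, 23, 57])
    def test_pairs_equal_event_derived_oracle(self, seed):
        """The pair list equals an independent, coordinate-based
        re-derivation from the planted event list: nothing invented,
        nothing lost."""
        config = SimulationConfig(random_seed=seed, **SMALL)
        result = simulate(config)
        expected = _pairs_from_events(
            dict(result.reference_proteins),
            dict(result.variant_proteins),
            result.events,
            config.rule,
        )
        found = {
            (p.variant_sequence, p.reference_sequence, p.position)
            for p in result.pairs
        }
        # completeness: every event the oracle deems recoverable is found
        assert expected <= found
        # soundness: found pairs are genuine Hamming-1 pairs surviving the
        # exclusions (extras beyond the oracle are cross-protein sequence
        # coincidences, which are legitimate pairs)
        for var, ref, pos in found:
            assert hamming1_position(ref, var) == pos
            assert apply_exclusions(ref, var, pos)[0]

    def test_truth_table_consistent_with_emitted_psms(self):
        result = simulate(SimulationConfig(random_seed=9, **SMALL))
        two = result.two_genome.set_index("Spectrum")
        for _, row in result.truth.iterrows():
            assert two.loc[row["Spectrum"], "Peptide"] == row["truth_sequence"]
            assert two.loc[row["Spectrum"], "Sample"] == row["Sample"]


def _pairs_from_events(ref_proteins, var_proteins, events, rule):
    """Independent oracle: walk every variant-digest peptide, keep those hit
    by exactly one planted event whose reference-side window is itself a
    digestible reference peptide and which survives the exclusion rules."""
    positions_by_protein = {}
    for e in events:
        positions_by_protein.setdefault(e.protein_id, set()).add(e.position)
    ref_peptide_seqs = {
        p.sequence
        for pid, seq in ref_proteins.items()
        for p in digest(seq, rule, protein_id=pid)
    }
    expected = set()
    for protein_id, var_seq in var_proteins.items():
        hits = positions_by_protein.get(protein_id, set())
        if not hits:
            continue
        ref_seq = ref_proteins[protein_id]
        for pep in digest(var_seq, rule, protein_id=protein_id):
            inside = [p for p in hits if pep.start <= p <= pep.end]
            if len(inside) != 1:
                continue
            ref_pep = ref_seq[pep.start - 1 : pep.end]
            if ref_pep not in ref_peptide_seqs:
                continue
            local = inside[0] - pep.start + 1
            keep, _ = apply_exclusions(ref_pep, pep.sequence, local)
            if keep:
                expected.add((pep.sequence, ref_pep, local))
    return expected


class TestFateRoundTrip:
    def test_all_correct_scenario_gives_full_efficiency(self):
        # perfect-information limit: exact planted offsets, no PTM space to
        # collide with, so every spectrum can realize a correct outcome
        from saavbench.chem import Tolerances

        config = SimulationConfig(
            random_seed=13,
            fate_probabilities={CORRECT: 1.0},
            ptms=(),
            tolerances=Tolerances(offset_match_ppm=1.0),
            **SMALL,
        )
        result = simulate(config)
        library, _, fates = run_pipeline(result, config)
        report = compute_efficiency(fates, library)
        assert report.spectrum_level_efficiency == 1.0
        assert report.peptide_level_efficiency == 1.0

    def test_planted_fates_reproduced_exactly(self):
        """Perfect-information limit: pipeline categories equal the plant."""
        config = SimulationConfig(random_seed=21, **SMALL)
        result = simulate(config)
        library, _, fates = run_pipeline(result, config)
        truth_fate = dict(zip(result.truth["Spectrum"], result.truth["fate"]))
        assert len(fates) == len(truth_fate)
        for fate in fates:
            assert fate.category == truth_fate[fate.spectrum_id]

    def test_invalid_fate_vector_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(fate_probabilities={CORRECT: 0.5})
        with pytest.raises(ConfigError):
            SimulationConfig(fate_probabilities={"bogus": 1.0})


class TestDilutionSeries:
    def test_median_intensity_halves_per_level(self):
        config = SimulationConfig(
            random_seed=3,
            detection_limit=0.0,  # no truncation: test the pure model
            dilution_levels=5,
            replicates=4,
            **SMALL,
        )
        result = simulate(config)
        medians = result.two_genome.groupby("Sample")["Intensity"].median()
        for a, b in zip(medians.index[:-1], medians.index[1:]):
            assert medians[a] / medians[b] == pytest.approx(2.0, rel=0.35)

    def test_dynamic_range_observable_from_library(self):
        config = SimulationConfig(random_seed=3, detection_limit=0.0, **SMALL)
        result = simulate(config)
        library, _, _ = run_pipeline(result, config)
        metrics = dilution_metrics(library)
        ranges = [m.dynamic_range for m in metrics.per_peptide.values()]
        assert all(r >= 0 for r in ranges)
        # 2-fold x 6 levels spans ~1.5 decades for peptides seen throughout
        assert np.median(ranges) > 1.0

    def test_spectra_target_reached_exactly(self):
        config = SimulationConfig(random_seed=5, n_spectra_target=2000, **SMALL)
        result = simulate(config)
        assert len(result.two_genome) == 2000
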