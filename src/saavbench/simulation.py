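"""Synthetic proteome pairs and paired search tables with planted truth.

The generator emulates the two-organism benchmark design end-to-end but at
the level the real pipeline consumes — PSM tables, never spectra:

1. a reference proteome is generated (or loaded), and a variant proteome is
   derived from it by planting point substitutions at a configured rate;
2. both proteomes are digested and the detectable SAAV peptide pairs found;
3. every SAAV peptide yields spectra across a 2-fold dilution series with
   log-normal intensities (the *two-genome* table, i.e. ground truth);
4. each spectrum's outcome in the discovery search (the *one-genome* table)
   is drawn from configured fate probabilities.

Fate category totals follow a multinomial draw from the configured vector.
Assignment of categories to individual spectra respects constructability:
a spectrum whose substitution is mass-degenerate with another candidate at
its own site (for example N→D versus deamidation) cannot be realized as a
``correct`` one-genome identification, so such spectra receive their fates
from the remaining categories.  This keeps the pipeline's recovered
category fractions equal to the planted draw — the perfect-information
round trip the generator is specified to provide.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import (
    AMBIGUOUS,
    DEFAULT_COLUMN_MAP,
    ONE_GENOME,
    PTM_ONLY,
    TWO_GENOME,
    UNIQUE_SUBSTITUTION,
    PSMRecord,
    SubstitutionAnnotation,
    annotate_psm,
)
from .chem import (
    CANONICAL_RESIDUES,
    DEFAULT_PTMS,
    DEFAULT_TABLE,
    PTMDefinition,
    ResidueMassTable,
    Tolerances,
)
from .digestion import CleavageRule, digest, digest_proteome
from .errors import ConfigError
from .evaluation import (
    AMBIGUOUS_FILTERED,
    COGNATE_ASSIGNMENT,
    CORRECT,
    FATE_CATEGORIES,
    INCORRECT_MODIFIED,
    NO_IDENTIFICATION,
    OTHER_INCORRECT,
    ZERO_INTENSITY_FILTERED,
)
from .saav import SAAVPair, find_saav_pairs, select_truth_pairs

logger = logging.getLogger(__name__)

#: Fate mix of the benchmark study conditions (fractions of library spectra).
DEFAULT_FATE_PROBABILITIES: Dict[str, float] = {
    CORRECT: 0.383,
    NO_IDENTIFICATION: 0.340,
    COGNATE_ASSIGNMENT: 0.149,
    INCORRECT_MODIFIED: 0.057,
    AMBIGUOUS_FILTERED: 0.022,
    ZERO_INTENSITY_FILTERED: 0.024,
    OTHER_INCORRECT: 0.025,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults model a small bacterial-scale experiment: ~100 proteins,
    a per-residue substitution rate of 0.5% between the two proteomes,
    a six-step 2-fold dilution series in technical duplicate, log-normal
    precursor intensities spanning several decades, and the benchmark fate
    mix for the discovery search.
    """

    n_proteins: int = 100
    protein_length: Tuple[int, int] = (180, 420)
    substitution_rate: float = 0.005
    residue_frequencies: Optional[Dict[str, float]] = None
    allow_il_substitutions: bool = False
    scissor_bias: float = 0.0  # fraction of events forced to involve K/R
    dilution_levels: int = 6
    dilution_fold: float = 2.0
    replicates: int = 2
    intensity_log_mean: float = 17.2  # ln scale; exp(17.2) ~ 3e7
    intensity_log_sigma: float = 1.2
    intensity_jitter: float = 0.3
    detection_limit: float = 1e5
    fate_probabilities: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FATE_PROBABILITIES)
    )
    score_equal_fraction: float = 0.4
    score_drop_scale: float = 0.05
    n_spectra_target: Optional[int] = None
    rule: CleavageRule = field(default_factory=CleavageRule)
    tolerances: Tolerances = field(default_factory=Tolerances)
    ptms: Tuple[PTMDefinition, ...] = DEFAULT_PTMS
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ConfigError("substitution_rate must lie in [0, 1]")
        total = sum(self.fate_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"fate probabilities sum to {total}, expected 1")
        unknown = set(self.fate_probabilities) - set(FATE_CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown fate categories: {sorted(unknown)}")


PRESETS: Dict[str, SimulationConfig] = {
    "baseline": SimulationConfig(),
    "scissor_enriched": SimulationConfig(scissor_bias=0.6, substitution_rate=0.008),
}


@dataclass(frozen=True)
class SubstitutionEvent:
    protein_id: str
    position: int  # 1-based in the protein
    from_residue: str
    to_residue: str


def generate_reference_proteome(
    config: SimulationConfig, rng: np.random.Generator
) -> List[Tuple[str, str]]:
    """Random proteins with configurable residue frequencies."""
    residues = list(CANONICAL_RESIDUES)
    if config.residue_frequencies:
        probs = np.array([config.residue_frequencies.get(r, 0.0) for r in residues])
        probs = probs / probs.sum()
    else:
        probs = np.full(len(residues), 1.0 / len(residues))
    lo, hi = config.protein_length
    proteins = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(residues, size=length, p=probs))
        proteins.append((f"prot{i + 1:04d}", seq))
    return proteins


def mutate_proteome(
    proteins: Sequence[Tuple[str, str]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Tuple[List[Tuple[str, str]], List[SubstitutionEvent]]:
    """Plant point substitutions at the configured per-residue rate.

    I<->L swaps are never planted unless explicitly allowed (they are
    invisible to mass spectrometry).  With ``scissor_bias`` > 0, that
    fraction of events is forced to involve lysine/arginine, enriching
    cut-site gains and losses.  Peptide segments hit by more than one event
    leave the single-substitution space; they are allowed but flagged.
    """
    variant: List[Tuple[str, str]] = []
    events: List[SubstitutionEvent] = []
    for protein_id, seq in proteins:
        chars = list(seq)
        hit_mask = rng.random(len(chars)) < config.substitution_rate
        for idx in np.flatnonzero(hit_mask):
            orig = chars[idx]
            choices = [
                c
                for c in CANONICAL_RESIDUES
                if c != orig
                and (config.allow_il_substitutions or not (orig in "IL" and c in "IL"))
            ]
            if config.scissor_bias and rng.random() < config.scissor_bias:
                if orig not in "KR":
                    choices = ["K", "R"]
            target = str(rng.choice(choices))
            chars[idx] = target
            events.append(SubstitutionEvent(protein_id, int(idx) + 1, orig, target))
        variant.append((protein_id, "".join(chars)))
    _flag_multihit_segments(proteins, events, config.rule)
    return variant, events


def _flag_multihit_segments(
    proteins: Sequence[Tuple[str, str]],
    events: Sequence[SubstitutionEvent],
    rule: CleavageRule,
) -> None:
    by_protein: Dict[str, List[int]] = {}
    for ev in events:
        by_protein.setdefault(ev.protein_id, []).append(ev.position)
    n_multi = 0
    for protein_id, seq in proteins:
        positions = by_protein.get(protein_id)
        if not positions or len(positions) < 2:
            continue
        segments = [
            (p.start, p.end)
            for p in digest(
                seq,
                replace(rule, min_length=1, max_length=10**9, max_missed_cleavages=0),
                protein_id=protein_id,
            )
        ]
        for s, e in segments:
            if sum(1 for pos in positions if s <= pos <= e) > 1:
                n_multi += 1
    if n_multi:
        logger.warning(
            "%d peptide segment(s) received more than one substitution and "
            "leave the single-variant space",
            n_multi,
        )


@dataclass
class SimulationResult:
    """Everything the simulator produced, in memory."""

    reference_proteins: List[Tuple[str, str]]
    variant_proteins: List[Tuple[str, str]]
    events: List[SubstitutionEvent]
    pairs: List[SAAVPair]
    two_genome: pd.DataFrame
    one_genome: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> None:
        from .io import write_fasta, write_tsv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reference_proteins, out / "reference.fasta")
        write_fasta(self.variant_proteins, out / "variant.fasta")
        write_tsv(self.two_genome, out / "two_genome.tsv")
        write_tsv(self.one_genome, out / "one_genome.tsv")
        write_tsv(self.truth, out / "truth.tsv")


def simulate(config: SimulationConfig = SimulationConfig()) -> SimulationResult:
    """Generate proteomes, plant substitutions and emit both search tables."""
    rng = np.random.default_rng(config.random_seed)
    reference = generate_reference_proteome(config, rng)
    variant, events = mutate_proteome(reference, config, rng)
    return simulate_searches(reference, variant, config, rng, events=events)


# ---------------------------------------------------------------------------
# fate planning: rows guaranteed to realize a category through the pipeline


def _annotate_hypothetical(
    sequence: str,
    offset: float,
    position: Optional[int],
    config: SimulationConfig,
    table: ResidueMassTable,
) -> SubstitutionAnnotation:
    psm = PSMRecord(
        spectrum_id="hypothetical",
        assigned_peptide=sequence,
        observed_offset=offset,
        precursor_intensity=1.0,
        peptide_neutral_mass=table.peptide_mass(sequence),
        posterior_probability=1.0,
        offset_position=position,
    )
    return annotate_psm(psm, config.ptms, config.tolerances, table)


def _plan_correct(
    pair: SAAVPair, config: SimulationConfig, table: ResidueMassTable
) -> Optional[Tuple[float, Optional[int]]]:
    offset = pair.substitution.delta_mass
    ann = _annotate_hypothetical(
        pair.reference_sequence, offset, pair.position, config, table
    )
    if ann.status == UNIQUE_SUBSTITUTION:
        return offset, pair.position
    return None


def _plan_ambiguous(
    pair: SAAVPair, config: SimulationConfig, table: ResidueMassTable
) -> Optional[Tuple[float, Optional[int]]]:
    seq = pair.reference_sequence
    tried: set = set()
    # un-localized offsets first: any shift explicable at two or more sites
    for res in seq:
        cls = table.class_of(res)
        for to in table.classes:
            if to == cls:
                continue
            offset = round(table.masses[to] - table.masses[cls], 6)
            if offset in tried:
                continue
            tried.add(offset)
            ann = _annotate_hypothetical(seq, offset, None, config, table)
            if ann.status == AMBIGUOUS:
                return offset, None
    # localized substitution/PTM conflicts (e.g. deamidation-class)
    for pos, res in enumerate(seq, 1):
        cls = table.class_of(res)
        for ptm in config.ptms:
            if not ptm.applies_to({cls}):
                continue
            ann = _annotate_hypothetical(seq, ptm.delta_mass, pos, config, table)
            if ann.status == AMBIGUOUS:
                return ptm.delta_mass, pos
    return None


def _plan_incorrect_modified(
    pair: SAAVPair, config: SimulationConfig, table: ResidueMassTable
) -> Optional[Tuple[float, Optional[int]]]:
    seq = pair.reference_sequence
    truth_class = table.class_sequence(pair.variant_sequence)
    # a localized PTM-only explanation reads as a wrong modified sequence
    for pos, res in enumerate(seq, 1):
        cls = table.class_of(res)
        for ptm in config.ptms:
            if not ptm.applies_to({cls}):
                continue
            ann = _annotate_hypothetical(seq, ptm.delta_mass, pos, config, table)
            if ann.status == PTM_ONLY:
                return ptm.delta_mass, pos
    # otherwise a uniquely-localized substitution other than the truth
    for pos, res in enumerate(seq, 1):
        cls = table.class_of(res)
        for to in table.classes:
            if to == cls:
                continue
            offset = table.masses[to] - table.masses[cls]
            ann = _annotate_hypothetical(seq, offset, pos, config, table)
            if (
                ann.status == UNIQUE_SUBSTITUTION
                and table.class_sequence(ann.variant_sequence) != truth_class
            ):
                return offset, pos
    return None


_RESTRICTED_PLANNERS = {
    CORRECT: _plan_correct,
    AMBIGUOUS_FILTERED: _plan_ambiguous,
    INCORRECT_MODIFIED: _plan_incorrect_modified,
}


def _allocate_fates(
    peptide_of_spectrum: Sequence[str],
    plans: Mapping[str, Dict[str, Optional[Tuple[float, Optional[int]]]]],
    probabilities: Mapping[str, float],
    rng: np.random.Generator,
) -> List[str]:
    """Assign one fate per spectrum, honoring per-peptide constructability.

    Category totals come from a single multinomial draw.  Restricted
    categories (correct / ambiguous / incorrect-modified) are filled from
    spectra whose peptide supports them; any unfillable remainder falls to
    ``other_incorrect`` with a warning.
    """
    n = len(peptide_of_spectrum)
    order = list(FATE_CATEGORIES)
    counts = dict(
        zip(order, rng.multinomial(n, [probabilities.get(c, 0.0) for c in order]))
    )
    assignment: List[Optional[str]] = [None] * n
    indices = rng.permutation(n)

    for category in (AMBIGUOUS_FILTERED, INCORRECT_MODIFIED, CORRECT):
        need = counts[category]
        for i in indices:
            if need == 0:
                break
            if assignment[i] is None and plans[peptide_of_spectrum[i]][category]:
                assignment[i] = category
                need -= 1
        if need:
            logger.warning(
                "%d %s spectrum/spectra not constructable; reassigned to %s",
                need,
                category,
                OTHER_INCORRECT,
            )
            counts[OTHER_INCORRECT] += need

    remaining = [i for i in indices if assignment[i] is None]
    cursor = 0
    for category in (
        NO_IDENTIFICATION,
        COGNATE_ASSIGNMENT,
        ZERO_INTENSITY_FILTERED,
        OTHER_INCORRECT,
    ):
        take = min(counts[category], len(remaining) - cursor)
        for i in remaining[cursor : cursor + take]:
            assignment[i] = category
        cursor += take
    for i in remaining[cursor:]:  # rounding slack from unfilled categories
        assignment[i] = OTHER_INCORRECT
    return [a if a is not None else OTHER_INCORRECT for a in assignment]


def simulate_searches(
    reference_proteins: Sequence[Tuple[str, str]],
    variant_proteins: Sequence[Tuple[str, str]],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    events: Optional[List[SubstitutionEvent]] = None,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> SimulationResult:
    """Emit paired two-genome/one-genome PSM tables with planted truth."""
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    ref_digest = digest_proteome(reference_proteins, config.rule)
    var_digest = digest_proteome(variant_proteins, config.rule)
    pairs = find_saav_pairs(ref_digest, var_digest, config.rule, table)
    truth_pairs = select_truth_pairs(pairs)
    library_peptides = sorted(truth_pairs)
    if not library_peptides:
        raise ConfigError("no detectable SAAV peptides; raise the substitution rate")

    library_class_seqs = {table.class_sequence(p) for p in library_peptides}
    decoys = [
        s for s in ref_digest.sequences
        if table.class_sequence(s) not in library_class_seqs
    ]

    # --- spectra slots across the dilution series -------------------------
    base_ln = {
        pep: rng.normal(config.intensity_log_mean, config.intensity_log_sigma)
        for pep in library_peptides
    }
    pep_rt = {pep: rng.uniform(10.0, 100.0) for pep in library_peptides}
    pep_im = {pep: rng.uniform(0.7, 1.5) for pep in library_peptides}

    def slot_round(rep: int) -> List[Tuple[str, int, float]]:
        slots = []
        for pep in library_peptides:
            for level in range(config.dilution_levels):
                ln_i = (
                    base_ln[pep]
                    - level * math.log(config.dilution_fold)
                    + rng.normal(0.0, config.intensity_jitter)
                )
                intensity = math.exp(ln_i)
                if intensity >= config.detection_limit:
                    slots.append((pep, level, intensity))
        return slots

    slots: List[Tuple[str, int, float]] = []
    rep = 0
    target = config.n_spectra_target
    while rep < config.replicates or (target is not None and len(slots) < target):
        slots.extend(slot_round(rep))
        rep += 1
        if target is not None and rep > 10000:
            raise ConfigError("cannot reach n_spectra_target; check detection limit")
    if target is not None:
        if len(slots) < target:
            raise ConfigError("cannot reach n_spectra_target; too few peptides")
        keep = rng.permutation(len(slots))[:target]
        slots = [slots[i] for i in sorted(keep)]

    # --- fate planning -----------------------------------------------------
    plans: Dict[str, Dict[str, Optional[Tuple[float, Optional[int]]]]] = {}
    for pep in library_peptides:
        pair = truth_pairs[pep]
        plans[pep] = {
            cat: planner(pair, config, table)
            for cat, planner in _RESTRICTED_PLANNERS.items()
        }
    fates = _allocate_fates([s[0] for s in slots], plans, config.fate_probabilities, rng)

    # --- emit tables ---------------------------------------------------------
    col = DEFAULT_COLUMN_MAP
    two_rows, one_rows, truth_rows = [], [], []
    for i, ((pep, level, intensity), fate) in enumerate(zip(slots, fates)):
        pair = truth_pairs[pep]
        spectrum = f"scan{i + 1:06d}"
        sample = f"D{level + 1:02d}"
        lib_prob = min(1.0, max(0.5, 1.0 - rng.exponential(0.02)))
        rt = pep_rt[pep] + rng.normal(0.0, 0.2)
        im = pep_im[pep] + rng.normal(0.0, 0.01)
        two_rows.append(
            {
                col["spectrum_id"]: spectrum,
                col["assigned_peptide"]: pep,
                col["observed_offset"]: 0.0,
                col["offset_position"]: "",
                col["precursor_intensity"]: intensity,
                col["peptide_neutral_mass"]: table.peptide_mass(pep),
                col["retention_time"]: rt,
                col["ion_mobility"]: im,
                col["posterior_probability"]: lib_prob,
                col["sample_label"]: sample,
                col["source_search"]: TWO_GENOME,
            }
        )
        truth_rows.append(
            {
                "Spectrum": spectrum,
                "Sample": sample,
                "fate": fate,
                "truth_sequence": pep,
                "reference_sequence": pair.reference_sequence,
                "position": pair.position,
                "from_class": pair.substitution.from_class,
                "to_class": pair.substitution.to_class,
                "scissor_class": pair.scissor_class,
                "intensity": intensity,
                "library_probability": lib_prob,
            }
        )
        row = _one_genome_row(
            fate, pair, plans[pep], spectrum, sample, intensity, lib_prob,
            rt, im, decoys, config, rng, table, col,
        )
        if row is not None:
            one_rows.append(row)

    return SimulationResult(
        reference_proteins=list(reference_proteins),
        variant_proteins=list(variant_proteins),
        events=events or [],
        pairs=pairs,
        two_genome=pd.DataFrame(two_rows),
        one_genome=pd.DataFrame(one_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def _one_genome_row(
    fate: str,
    pair: SAAVPair,
    plan: Mapping[str, Optional[Tuple[float, Optional[int]]]],
    spectrum: str,
    sample: str,
    intensity: float,
    lib_prob: float,
    rt: float,
    im: float,
    decoys: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
    table: ResidueMassTable,
    col: Mapping[str, str],
) -> Optional[dict]:
    if fate == NO_IDENTIFICATION:
        return None
    peptide = pair.reference_sequence
    offset, position = 0.0, None
    one_intensity = intensity * math.exp(rng.normal(0.0, 0.05))
    if fate == CORRECT:
        offset, position = plan[CORRECT]
    elif fate == ZERO_INTENSITY_FILTERED:
        offset, position = pair.substitution.delta_mass, pair.position
        one_intensity = 0.0
    elif fate == AMBIGUOUS_FILTERED:
        offset, position = plan[AMBIGUOUS_FILTERED]
    elif fate == INCORRECT_MODIFIED:
        offset, position = plan[INCORRECT_MODIFIED]
    elif fate == OTHER_INCORRECT:
        cognate = table.class_sequence(pair.reference_sequence)
        peptide = pair.reference_sequence  # degenerate toy-proteome fallback
        for _ in range(20):  # rejection-sample a non-cognate decoy
            if not decoys:
                break
            candidate = decoys[int(rng.integers(len(decoys)))]
            if table.class_sequence(candidate) != cognate:
                peptide = candidate
                break
    # cognate_assignment keeps the reference sequence at offset zero
    if rng.random() < config.score_equal_fraction:
        prob = lib_prob
    else:
        prob = max(0.5, lib_prob - rng.exponential(config.score_drop_scale))
    return {
        col["spectrum_id"]: spectrum,
        col["assigned_peptide"]: peptide,
        col["observed_offset"]: offset,
        col["offset_position"]: "" if position is None else position,
        col["precursor_intensity"]: one_intensity,
        col["peptide_neutral_mass"]: table.peptide_mass(peptide),
        col["retention_time"]: rt + rng.normal(0.0, 0.2),
        col["ion_mobility"]: im + rng.normal(0.0, 0.01),
        col["posterior_probability"]: prob,
        col["sample_label"]: sample,
        col["source_search"]: ONE_GENOME,
    }
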