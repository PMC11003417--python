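"""Ground-truth library construction and spectrum-fate bookkeeping.

The evaluation design is a paired search of the same spectra: a *two-genome*
search (both proteomes in the database) defines, for every spectrum matching
a variant peptide with a known single-substitution cognate, the ground-truth
sequence; a *one-genome* search (reference proteome only, open/mass-offset
mode) is then scored spectrum-by-spectrum against that truth.  Every library
spectrum receives exactly one fate, so fate counts always partition the
library and efficiency numbers are directly comparable across categories.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import (
    AMBIGUOUS,
    PTM_ONLY,
    UNIQUE_SUBSTITUTION,
    UNMODIFIED,
    PSMRecord,
    SubstitutionAnnotation,
)
from .chem import DEFAULT_TABLE, ResidueMassTable
from .errors import InputError
from .saav import SAAVPair, select_truth_pairs

logger = logging.getLogger(__name__)

# Fate categories of a library spectrum in the one-genome search
CORRECT = "correct"
NO_IDENTIFICATION = "no_identification"
COGNATE_ASSIGNMENT = "cognate_assignment"
INCORRECT_MODIFIED = "incorrect_modified"
AMBIGUOUS_FILTERED = "ambiguous_filtered"
ZERO_INTENSITY_FILTERED = "zero_intensity_filtered"
OTHER_INCORRECT = "other_incorrect"

FATE_CATEGORIES = (
    CORRECT,
    NO_IDENTIFICATION,
    COGNATE_ASSIGNMENT,
    INCORRECT_MODIFIED,
    AMBIGUOUS_FILTERED,
    ZERO_INTENSITY_FILTERED,
    OTHER_INCORRECT,
)


@dataclass(frozen=True)
class LibraryEntry:
    """One ground-truth spectrum: its true variant sequence and context."""

    spectrum_id: str
    truth_sequence: str
    truth_pair: SAAVPair
    intensity: float
    retention_time: float
    ion_mobility: Optional[float]
    library_probability: float
    sample_label: str

    @property
    def peptide_length(self) -> int:
        return len(self.truth_sequence)

    @property
    def position(self) -> int:
        return self.truth_pair.position

    @property
    def position_from_c(self) -> int:
        return self.truth_pair.position_from_c


@dataclass(frozen=True)
class FateRecord:
    spectrum_id: str
    category: str
    one_genome_probability: Optional[float] = None


def build_library(
    two_genome_psms: Iterable[PSMRecord],
    saav_pairs: Sequence[SAAVPair],
    table: ResidueMassTable = DEFAULT_TABLE,
) -> List[LibraryEntry]:
    """Ground-truth library: two-genome spectra assigned a SAAV variant.

    A spectrum enters the library when its assigned sequence is the variant
    member of a SAAV pair (I/L collapsed for the comparison).  When several
    PSMs claim one spectrum, the highest-probability one wins and the
    conflict is logged.
    """
    truth_by_variant = {
        table.class_sequence(v): p for v, p in select_truth_pairs(saav_pairs).items()
    }
    best: Dict[str, PSMRecord] = {}
    conflicts = 0
    for psm in two_genome_psms:
        key = table.class_sequence(psm.assigned_peptide)
        if key not in truth_by_variant:
            continue
        prev = best.get(psm.spectrum_id)
        if prev is not None:
            conflicts += 1
            if psm.posterior_probability <= prev.posterior_probability:
                continue
        best[psm.spectrum_id] = psm
    if conflicts:
        logger.warning("%d spectrum/spectra assigned to multiple variants", conflicts)
    entries = []
    for psm in best.values():
        pair = truth_by_variant[table.class_sequence(psm.assigned_peptide)]
        entries.append(
            LibraryEntry(
                spectrum_id=psm.spectrum_id,
                truth_sequence=psm.assigned_peptide,
                truth_pair=pair,
                intensity=psm.precursor_intensity,
                retention_time=psm.retention_time,
                ion_mobility=psm.ion_mobility,
                library_probability=psm.posterior_probability,
                sample_label=psm.sample_label,
            )
        )
    entries.sort(key=lambda e: e.spectrum_id)
    return entries


def categorize_fates(
    library: Sequence[LibraryEntry],
    one_genome_annotations: Iterable[SubstitutionAnnotation],
    table: ResidueMassTable = DEFAULT_TABLE,
) -> List[FateRecord]:
    """Final fate of every library spectrum in the one-genome search.

    A spectrum absent from the one-genome results failed identification
    outright; otherwise its annotation decides: the implied variant equal to
    truth is ``correct``; zero precursor intensity or an ambiguous offset
    means it would be filtered; the unmodified cognate sequence is the
    classic decoy of substitution detection; any other modified assignment
    is ``incorrect_modified``; everything else is ``other_incorrect``.
    """
    by_spectrum: Dict[str, SubstitutionAnnotation] = {}
    for ann in one_genome_annotations:
        sid = ann.psm.spectrum_id
        if sid in by_spectrum:
            raise InputError(f"duplicate spectrum id in one-genome results: {sid}")
        by_spectrum[sid] = ann

    fates: List[FateRecord] = []
    for entry in library:
        ann = by_spectrum.get(entry.spectrum_id)
        if ann is None:
            fates.append(FateRecord(entry.spectrum_id, NO_IDENTIFICATION))
            continue
        prob = ann.psm.posterior_probability
        truth = table.class_sequence(entry.truth_sequence)
        cognate = table.class_sequence(entry.truth_pair.reference_sequence)
        if ann.psm.precursor_intensity == 0:
            category = ZERO_INTENSITY_FILTERED
        elif ann.status == AMBIGUOUS:
            category = AMBIGUOUS_FILTERED
        elif ann.status == UNIQUE_SUBSTITUTION:
            implied = table.class_sequence(ann.variant_sequence)
            category = CORRECT if implied == truth else INCORRECT_MODIFIED
        elif ann.status == PTM_ONLY:
            category = INCORRECT_MODIFIED
        elif ann.status == UNMODIFIED:
            assigned = table.class_sequence(ann.psm.assigned_peptide)
            category = COGNATE_ASSIGNMENT if assigned == cognate else OTHER_INCORRECT
        else:
            category = OTHER_INCORRECT
        fates.append(FateRecord(entry.spectrum_id, category, prob))
    return fates


@dataclass(frozen=True)
class CellStats:
    """Library and correct counts for one stratification cell."""

    n_library: int
    n_correct: int

    @property
    def efficiency(self) -> Optional[float]:
        return self.n_correct / self.n_library if self.n_library else None


@dataclass
class EfficiencyReport:
    """Spectrum- and peptide-level efficiency plus stratified matrices.

    Cells with no library spectra are simply absent (never reported as 0%).
    """

    spectrum_level_efficiency: float
    peptide_level_efficiency: float
    by_type: Dict[Tuple[str, str], CellStats]
    by_length_position: Dict[Tuple[int, int], CellStats]
    by_scissor: Dict[str, CellStats]
    zero_identified_types: int
    n_spectra: int
    n_peptides: int


def compute_efficiency(
    fates: Sequence[FateRecord],
    library: Sequence[LibraryEntry],
    table: ResidueMassTable = DEFAULT_TABLE,
) -> EfficiencyReport:
    """Aggregate fates into efficiency statistics.

    Spectrum-level efficiency is the fraction of library spectra with a
    correct fate; peptide-level efficiency the fraction of unique truth
    sequences with at least one correct spectrum.  Matrices stratify by
    substitution type, by (peptide length, substitution position), and by
    scissor class.
    """
    if not library:
        raise InputError("cannot compute efficiency of an empty library")
    if len(fates) != len(library):
        raise InputError("fates and library must align one-to-one")
    fate_by_id = {f.spectrum_id: f.category for f in fates}

    n_correct = 0
    by_type: Dict[Tuple[str, str], List[int]] = {}
    by_lp: Dict[Tuple[int, int], List[int]] = {}
    by_sc: Dict[str, List[int]] = {}
    peptides_total: Dict[str, int] = {}
    for entry in library:
        correct = fate_by_id[entry.spectrum_id] == CORRECT
        n_correct += correct
        sub = entry.truth_pair.substitution
        for bucket, key in (
            (by_type, (sub.from_class, sub.to_class)),
            (by_lp, (entry.peptide_length, entry.position)),
            (by_sc, entry.truth_pair.scissor_class),
        ):
            cell = bucket.setdefault(key, [0, 0])
            cell[0] += 1
            cell[1] += correct
        seq = table.class_sequence(entry.truth_sequence)
        peptides_total[seq] = max(peptides_total.get(seq, 0), int(correct))

    type_cells = {k: CellStats(v[0], v[1]) for k, v in by_type.items()}
    return EfficiencyReport(
        spectrum_level_efficiency=n_correct / len(library),
        peptide_level_efficiency=sum(peptides_total.values()) / len(peptides_total),
        by_type=type_cells,
        by_length_position={k: CellStats(*v) for k, v in by_lp.items()},
        by_scissor={k: CellStats(*v) for k, v in by_sc.items()},
        zero_identified_types=sum(1 for c in type_cells.values() if c.n_correct == 0),
        n_spectra=len(library),
        n_peptides=len(peptides_total),
    )


@dataclass(frozen=True)
class ScoreDeltaSummary:
    """Per-spectrum posterior-probability differences for correct spectra.

    ``deltas`` holds one-genome minus library probability; mass at zero and
    the negative tail summarize how the discovery search penalizes the same
    spectral evidence.
    """

    deltas: np.ndarray
    fraction_zero: float
    fraction_negative: float


def score_deltas(
    library: Sequence[LibraryEntry],
    fates: Sequence[FateRecord],
    zero_tol: float = 1e-9,
) -> ScoreDeltaSummary:
    """Probability difference (one-genome minus library) per correct spectrum."""
    lib_prob = {e.spectrum_id: e.library_probability for e in library}
    deltas = np.array(
        [
            f.one_genome_probability - lib_prob[f.spectrum_id]
            for f in fates
            if f.category == CORRECT and f.one_genome_probability is not None
        ]
    )
    n = len(deltas)
    return ScoreDeltaSummary(
        deltas=deltas,
        fraction_zero=float(np.sum(np.abs(deltas) <= zero_tol)) / n if n else 0.0,
        fraction_negative=float(np.sum(deltas < -zero_tol)) / n if n else 0.0,
    )


@dataclass(frozen=True)
class PeptideDilution:
    dynamic_range: float  # log10(max/min) over samples where detected
    min_intensity: float
    max_intensity: float
    last_sample: str  # final (most dilute) sample with a detection


@dataclass
class DilutionMetrics:
    per_peptide: Dict[str, PeptideDilution]
    per_sample: Dict[str, np.ndarray]  # intensity distributions


def dilution_metrics(
    library: Sequence[LibraryEntry],
    sample_order: Optional[Sequence[str]] = None,
) -> DilutionMetrics:
    """Per-peptide dynamic range and detection floor across a dilution series.

    ``sample_order`` lists sample labels from most to least concentrated;
    when omitted, labels sort lexicographically (the simulator emits
    zero-padded labels so this is the dilution order).  Spectra with zero
    recorded intensity are excluded.
    """
    groups: Dict[str, List[LibraryEntry]] = {}
    samples: Dict[str, List[float]] = {}
    for e in library:
        if e.intensity <= 0:
            continue
        groups.setdefault(e.truth_sequence, []).append(e)
        samples.setdefault(e.sample_label, []).append(e.intensity)
    if sample_order is None:
        sample_order = sorted(samples)
    rank = {s: i for i, s in enumerate(sample_order)}

    per_peptide = {}
    for seq, entries in groups.items():
        intensities = [e.intensity for e in entries]
        lo, hi = min(intensities), max(intensities)
        last = max(entries, key=lambda e: rank.get(e.sample_label, -1)).sample_label
        per_peptide[seq] = PeptideDilution(
            dynamic_range=math.log10(hi / lo),
            min_intensity=lo,
            max_intensity=hi,
            last_sample=last,
        )
    return DilutionMetrics(
        per_peptide=per_peptide,
        per_sample={s: np.array(v) for s, v in samples.items()},
    )


def library_to_frame(library: Sequence[LibraryEntry]) -> "pd.DataFrame":
    """Tabular view of a library (inverse of :func:`library_from_frame`)."""
    import pandas as pd

    rows = []
    for e in library:
        rows.append(
            {
                "Spectrum": e.spectrum_id,
                "truth_sequence": e.truth_sequence,
                "reference_sequence": e.truth_pair.reference_sequence,
                "position": e.position,
                "from_class": e.truth_pair.substitution.from_class,
                "to_class": e.truth_pair.substitution.to_class,
                "scissor_class": e.truth_pair.scissor_class,
                "intensity": e.intensity,
                "retention_time": e.retention_time,
                "ion_mobility": e.ion_mobility if e.ion_mobility is not None else "",
                "library_probability": e.library_probability,
                "sample": e.sample_label,
            }
        )
    return pd.DataFrame(rows)


def library_from_frame(
    frame: "pd.DataFrame", table: ResidueMassTable = DEFAULT_TABLE
) -> List[LibraryEntry]:
    """Rebuild library entries from a library TSV written by the CLI."""
    from .chem import SubstitutionType
    from .digestion import Peptide

    entries = []
    for _, row in frame.iterrows():
        variant = str(row["truth_sequence"])
        reference = str(row["reference_sequence"])
        position = int(row["position"])
        sub = SubstitutionType(
            str(row["from_class"]),
            str(row["to_class"]),
            table.masses[str(row["to_class"])] - table.masses[str(row["from_class"])],
        )
        pair = SAAVPair(
            variant=Peptide(variant, "?", 1, len(variant), 0),
            reference=Peptide(reference, "?", 1, len(reference), 0),
            position=position,
            substitution=sub,
            scissor_class=str(row["scissor_class"]),
        )
        im = row.get("ion_mobility", "")
        entries.append(
            LibraryEntry(
                spectrum_id=str(row["Spectrum"]),
                truth_sequence=variant,
                truth_pair=pair,
                intensity=float(row["intensity"]),
                retention_time=float(row["retention_time"]),
                ion_mobility=float(im) if str(im) not in ("", "nan") else None,
                library_probability=float(row["library_probability"]),
                sample_label=str(row["sample"]),
            )
        )
    return entries


def fate_fractions(fates: Sequence[FateRecord]) -> Dict[str, float]:
    """Fraction of library spectra per fate category (sums to 1)."""
    counts = {c: 0 for c in FATE_CATEGORIES}
    for f in fates:
        counts[f.category] += 1
    n = len(fates)
    return {c: counts[c] / n for c in FATE_CATEGORIES} if n else counts


def report_to_dict(report: EfficiencyReport) -> dict:
    """JSON-serializable view of an efficiency report (schema v1)."""
    return {
        "schema_version": 1,
        "n_spectra": report.n_spectra,
        "n_peptides": report.n_peptides,
        "spectrum_level_efficiency": report.spectrum_level_efficiency,
        "peptide_level_efficiency": report.peptide_level_efficiency,
        "zero_identified_types": report.zero_identified_types,
        "by_type": [
            {
                "from": k[0],
                "to": k[1],
                "n_library": v.n_library,
                "n_correct": v.n_correct,
                "efficiency": v.efficiency,
            }
            for k, v in sorted(report.by_type.items())
        ],
        "by_length_position": [
            {
                "length": k[0],
                "position": k[1],
                "n_library": v.n_library,
                "n_correct": v.n_correct,
                "efficiency": v.efficiency,
            }
            for k, v in sorted(report.by_length_position.items())
        ],
        "by_scissor": {
            k: {
                "n_library": v.n_library,
                "n_correct": v.n_correct,
                "efficiency": v.efficiency,
            }
            for k, v in sorted(report.by_scissor.items())
        },
    }
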