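"""Annotation of open-search mass offsets as amino acid substitutions.

Upstream search engines report, for each peptide-spectrum match (PSM), the
assigned peptide and the unexplained precursor mass offset.  This module
turns those offsets into substitution hypotheses: every substitution whose
origin residue is present (or at the localized position, when the engine
localized the offset) and every configured PTM whose shift matches within a
ppm tolerance of the peptide neutral mass.  A PSM is only usable as a
substitution identification when exactly one hypothesis survives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .chem import (
    DEFAULT_PTMS,
    DEFAULT_TABLE,
    PTMDefinition,
    ResidueMassTable,
    SubstitutionType,
    Tolerances,
)
from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)

# Annotation statuses
UNMODIFIED = "unmodified"
UNIQUE_SUBSTITUTION = "unique_substitution"
AMBIGUOUS = "ambiguous"
PTM_ONLY = "ptm_only"
UNMATCHED = "unmatched"  # nonzero offset with no candidate at all

# Filter drop reasons
DROP_ZERO_INTENSITY = "zero_intensity"
DROP_AMBIGUOUS = "ambiguous"
DROP_NON_AAS = "non_AAS"
DROP_OFF_TARGET = "off_target"

TWO_GENOME = "two_genome"
ONE_GENOME = "one_genome"


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match row from an upstream search."""

    spectrum_id: str
    assigned_peptide: str
    observed_offset: float
    precursor_intensity: float
    peptide_neutral_mass: float
    posterior_probability: float
    offset_position: Optional[int] = None  # 1-based, None when not localized
    retention_time: float = math.nan
    ion_mobility: Optional[float] = None
    sample_label: str = ""
    source_search: str = ONE_GENOME

    def __post_init__(self) -> None:
        if not self.assigned_peptide:
            raise InputError("PSM has an empty peptide sequence")
        if not 0.0 <= self.posterior_probability <= 1.0:
            raise InputError("posterior probability must lie in [0, 1]")
        if self.precursor_intensity < 0:
            raise InputError("precursor intensity must be >= 0")


@dataclass(frozen=True)
class SubstitutionCandidate:
    """A substitution hypothesis placed at a specific peptide position."""

    substitution: SubstitutionType
    position: int  # 1-based


@dataclass(frozen=True)
class SubstitutionAnnotation:
    """A PSM with its candidate mass-offset explanations and a status."""

    psm: PSMRecord
    substitution_candidates: Tuple[SubstitutionCandidate, ...]
    ptm_candidates: Tuple[PTMDefinition, ...]
    status: str
    variant_sequence: Optional[str] = None  # implied sequence when unique


#: Column names of the shipped tab-separated PSM dialect (FragPipe-like).
DEFAULT_COLUMN_MAP: Dict[str, str] = {
    "spectrum_id": "Spectrum",
    "assigned_peptide": "Peptide",
    "observed_offset": "Delta Mass",
    "offset_position": "Offset Position",
    "precursor_intensity": "Intensity",
    "peptide_neutral_mass": "Calculated Peptide Mass",
    "retention_time": "Retention",
    "ion_mobility": "Ion Mobility",
    "posterior_probability": "PeptideProphet Probability",
    "sample_label": "Sample",
    "source_search": "Source",
}

_MANDATORY_FIELDS = (
    "spectrum_id",
    "assigned_peptide",
    "observed_offset",
    "precursor_intensity",
    "peptide_neutral_mass",
    "posterior_probability",
)


def parse_psm_table(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
) -> List[PSMRecord]:
    """Read a tab-separated PSM table into records.

    ``column_map`` maps record fields to column names (defaults to the
    shipped dialect).  Rows whose mandatory fields fail to parse are
    rejected with a logged count; a missing mandatory column raises a
    :class:`ConfigError` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"PSM table not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for fieldname in _MANDATORY_FIELDS:
        if cmap[fieldname] not in df.columns:
            raise ConfigError(
                f"{path}: mandatory column {cmap[fieldname]!r} (field "
                f"{fieldname!r}) is missing"
            )
    records: List[PSMRecord] = []
    rejected = 0
    for _, row in df.iterrows():
        try:
            records.append(_row_to_record(row, cmap))
        except (InputError, ValueError):
            rejected += 1
    if rejected:
        logger.warning("%s: rejected %d unparseable row(s)", path, rejected)
    if not records:
        logger.warning("%s: no PSM records parsed", path)
    return records


def _row_to_record(row: pd.Series, cmap: Mapping[str, str]) -> PSMRecord:
    def opt(fieldname: str, default: str = "") -> str:
        col = cmap[fieldname]
        return str(row[col]).strip() if col in row.index else default

    pos_raw = opt("offset_position")
    im_raw = opt("ion_mobility")
    rt_raw = opt("retention_time")
    return PSMRecord(
        spectrum_id=str(row[cmap["spectrum_id"]]),
        assigned_peptide=str(row[cmap["assigned_peptide"]]).strip(),
        observed_offset=float(row[cmap["observed_offset"]]),
        precursor_intensity=float(row[cmap["precursor_intensity"]]),
        peptide_neutral_mass=float(row[cmap["peptide_neutral_mass"]]),
        posterior_probability=float(row[cmap["posterior_probability"]]),
        offset_position=int(float(pos_raw)) if pos_raw else None,
        retention_time=float(rt_raw) if rt_raw else math.nan,
        ion_mobility=float(im_raw) if im_raw else None,
        sample_label=opt("sample_label"),
        source_search=opt("source_search", ONE_GENOME) or ONE_GENOME,
    )


def annotate_psm(
    psm: PSMRecord,
    ptm_list: Sequence[PTMDefinition] = DEFAULT_PTMS,
    tolerances: Tolerances = Tolerances(),
    table: ResidueMassTable = DEFAULT_TABLE,
) -> SubstitutionAnnotation:
    """Assign candidate substitutions/PTMs to a PSM's mass offset.

    An offset within the ppm window of zero is ``unmodified``.  Otherwise
    candidates are generated at the localized residue when the search engine
    provided a position, or across every residue of the peptide when it did
    not.  Exactly one substitution candidate and no competing PTM gives
    ``unique_substitution``; several substitution placements or a
    substitution/PTM mass conflict is ``ambiguous``; PTM-only matches are
    ``ptm_only``.
    """
    window = tolerances.offset_window_da(psm.peptide_neutral_mass)
    if abs(psm.observed_offset) <= window:
        return SubstitutionAnnotation(psm, (), (), UNMODIFIED)

    seq = psm.assigned_peptide
    if psm.offset_position is not None:
        if not 1 <= psm.offset_position <= len(seq):
            raise InputError(
                f"offset position {psm.offset_position} outside peptide "
                f"{seq!r} ({psm.spectrum_id})"
            )
        positions = [psm.offset_position]
    else:
        positions = list(range(1, len(seq) + 1))

    subs: List[SubstitutionCandidate] = []
    ptms: List[PTMDefinition] = []
    seen_ptms: Set[str] = set()
    for pos in positions:
        res_class = table.class_of(seq[pos - 1])
        for sub in _subs_from(res_class, table):
            if abs(sub.delta_mass - psm.observed_offset) <= window:
                subs.append(SubstitutionCandidate(sub, pos))
        for ptm in ptm_list:
            if ptm.name in seen_ptms:
                continue
            if ptm.applies_to({res_class}) and abs(ptm.delta_mass - psm.observed_offset) <= window:
                ptms.append(ptm)
                seen_ptms.add(ptm.name)

    if len(subs) == 1 and not ptms:
        cand = subs[0]
        variant = (
            seq[: cand.position - 1]
            + table.representative(cand.substitution.to_class)
            + seq[cand.position :]
        )
        return SubstitutionAnnotation(
            psm, tuple(subs), (), UNIQUE_SUBSTITUTION, variant_sequence=variant
        )
    if subs:
        return SubstitutionAnnotation(psm, tuple(subs), tuple(ptms), AMBIGUOUS)
    if ptms:
        return SubstitutionAnnotation(psm, (), tuple(ptms), PTM_ONLY)
    return SubstitutionAnnotation(psm, (), (), UNMATCHED)


def _subs_from(res_class: str, table: ResidueMassTable) -> List[SubstitutionType]:
    return [
        SubstitutionType(res_class, to, table.masses[to] - table.masses[res_class])
        for to in table.classes
        if to != res_class
    ]


def render_annotation(
    annotation: SubstitutionAnnotation, table: ResidueMassTable = DEFAULT_TABLE
) -> str:
    """Human-readable candidate list, e.g. ``"G → A or S → T"``."""
    if annotation.status == UNMODIFIED:
        return "unmodified"
    parts = [c.substitution.label(table) for c in annotation.substitution_candidates]
    parts += [p.name for p in annotation.ptm_candidates]
    return " or ".join(parts) if parts else "unannotated"


@dataclass
class FilterReport:
    """Tally of retained vs removed annotations, by drop reason."""

    input_count: int = 0
    retained: int = 0
    removed: Dict[str, int] = field(
        default_factory=lambda: {
            DROP_ZERO_INTENSITY: 0,
            DROP_AMBIGUOUS: 0,
            DROP_NON_AAS: 0,
            DROP_OFF_TARGET: 0,
        }
    )

    def check_conservation(self) -> bool:
        return self.retained + sum(self.removed.values()) == self.input_count


def filter_to_targets(
    annotations: Iterable[SubstitutionAnnotation],
    target_sequences: Iterable[str],
    table: ResidueMassTable = DEFAULT_TABLE,
) -> Tuple[List[SubstitutionAnnotation], FilterReport]:
    """Keep unique substitution annotations whose variant is a SAAV target.

    Drop order: unquantified (zero-intensity) PSMs, then ambiguous
    annotations, then non-substitution records (unmodified / PTM-only /
    unmatched), then unique substitutions whose implied variant sequence is
    not in the target list.  Target comparison collapses I/L.
    """
    targets = {table.class_sequence(t) for t in target_sequences}
    if not targets:
        logger.warning("empty SAAV target list: every annotation will be dropped")
    report = FilterReport()
    retained: List[SubstitutionAnnotation] = []
    for ann in annotations:
        report.input_count += 1
        if ann.psm.precursor_intensity == 0:
            report.removed[DROP_ZERO_INTENSITY] += 1
        elif ann.status == AMBIGUOUS:
            report.removed[DROP_AMBIGUOUS] += 1
        elif ann.status != UNIQUE_SUBSTITUTION:
            report.removed[DROP_NON_AAS] += 1
        elif table.class_sequence(ann.variant_sequence) not in targets:
            report.removed[DROP_OFF_TARGET] += 1
        else:
            report.retained += 1
            retained.append(ann)
    return retained, report


def annotations_to_frame(
    annotations: Sequence[SubstitutionAnnotation],
    table: ResidueMassTable = DEFAULT_TABLE,
) -> pd.DataFrame:
    """Tabular view of annotations (for TSV export)."""
    rows = []
    for ann in annotations:
        rows.append(
            {
                "Spectrum": ann.psm.spectrum_id,
                "Peptide": ann.psm.assigned_peptide,
                "Delta Mass": ann.psm.observed_offset,
                "status": ann.status,
                "candidate_list": render_annotation(ann, table),
                "variant_sequence": ann.variant_sequence or "",
            }
        )
    return pd.DataFrame(rows)
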