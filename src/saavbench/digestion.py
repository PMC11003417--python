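"""In-silico protease digestion with missed cleavages.

The default rule is trypsin: cut after K or R, suppressed when the next
residue is proline.  Position and missed-cleavage provenance is retained on
every peptide because downstream scissor-substitution logic depends on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

from .errors import InputError
from .chem import CANONICAL_RESIDUES

logger = logging.getLogger(__name__)

TERMINUS = "-"


@dataclass(frozen=True)
class CleavageRule:
    """Protease cleavage specificity plus peptide acceptance bounds."""

    cut_after: frozenset = frozenset("KR")
    suppress_if_next: frozenset = frozenset("P")
    min_length: int = 5
    max_length: int = 50
    max_missed_cleavages: int = 1

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise InputError("min_length must be >= 1")
        if self.max_length < self.min_length:
            raise InputError("max_length must be >= min_length")
        if self.max_missed_cleavages < 0:
            raise InputError("max_missed_cleavages must be >= 0")

    def is_cutsite(self, sequence: str, position: int) -> bool:
        """True if the residue at 1-based ``position`` is a cleavage site.

        A site at the final residue counts (the protease cut that produced
        the peptide); an internal site followed by a suppressing residue
        (proline for trypsin) does not.
        """
        res = sequence[position - 1]
        if res not in self.cut_after:
            return False
        if position < len(sequence) and sequence[position] in self.suppress_if_next:
            return False
        return True


@dataclass(frozen=True)
class Peptide:
    """A digested peptide with positional provenance in its parent protein."""

    sequence: str
    protein_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    missed_cleavages: int
    prev_residue: str = TERMINUS
    next_residue: str = TERMINUS

    def __len__(self) -> int:
        return len(self.sequence)


def _cut_points(sequence: str, rule: CleavageRule) -> List[int]:
    """0-based indices i such that the bond after sequence[i] is cleaved."""
    pts = []
    for i in range(len(sequence) - 1):
        if sequence[i] in rule.cut_after and sequence[i + 1] not in rule.suppress_if_next:
            pts.append(i)
    return pts


def digest(sequence: str, rule: CleavageRule = CleavageRule(), protein_id: str = "protein") -> List[Peptide]:
    """All fully and partially cleaved peptides of a protein sequence.

    Peptides are returned in deterministic order (by start, then end) and
    filtered to the rule's length bounds.  Peptides containing non-canonical
    residues (B, Z, X, U, ...) are skipped with a logged warning.
    """
    if not sequence:
        raise InputError("cannot digest an empty sequence")
    cuts = _cut_points(sequence, rule)
    bounds = [0] + [c + 1 for c in cuts] + [len(sequence)]
    segments: List[Tuple[int, int]] = [
        (bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
    ]
    peptides: List[Peptide] = []
    skipped = 0
    for i in range(len(segments)):
        for k in range(rule.max_missed_cleavages + 1):
            if i + k >= len(segments):
                break
            s, e = segments[i][0], segments[i + k][1]
            pep = sequence[s:e]
            if not (rule.min_length <= len(pep) <= rule.max_length):
                continue
            if any(c not in CANONICAL_RESIDUES for c in pep):
                skipped += 1
                continue
            peptides.append(
                Peptide(
                    sequence=pep,
                    protein_id=protein_id,
                    start=s + 1,
                    end=e,
                    missed_cleavages=k,
                    prev_residue=sequence[s - 1] if s > 0 else TERMINUS,
                    next_residue=sequence[e] if e < len(sequence) else TERMINUS,
                )
            )
    if skipped:
        logger.warning(
            "%s: skipped %d peptide(s) containing non-canonical residues",
            protein_id,
            skipped,
        )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


@dataclass
class ProteomeDigest:
    """De-duplicated peptide index over a digested proteome.

    ``occurrences`` maps each distinct peptide sequence to every (protein,
    position) occurrence; helper accessors expose the representative
    occurrence with the fewest missed cleavages.
    """

    occurrences: Dict[str, List[Peptide]] = field(default_factory=dict)

    def add(self, peptide: Peptide) -> None:
        self.occurrences.setdefault(peptide.sequence, []).append(peptide)

    @property
    def sequences(self) -> List[str]:
        return sorted(self.occurrences)

    def representative(self, sequence: str) -> Peptide:
        """The occurrence with fewest missed cleavages (then first position)."""
        return min(
            self.occurrences[sequence],
            key=lambda p: (p.missed_cleavages, p.protein_id, p.start),
        )

    def min_missed(self, sequence: str) -> int:
        return min(p.missed_cleavages for p in self.occurrences[sequence])

    def __len__(self) -> int:
        return len(self.occurrences)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self.occurrences


def digest_proteome(
    proteins: Iterable[Tuple[str, str]] | str | Path,
    rule: CleavageRule = CleavageRule(),
    clip_nterm_met: bool = False,
) -> ProteomeDigest:
    """Digest a whole proteome into a de-duplicated peptide index.

    ``proteins`` is either a FASTA path or an iterable of ``(id, sequence)``
    records.  With ``clip_nterm_met`` the initiator methionine is removed
    before digestion (off by default).
    """
    if isinstance(proteins, (str, Path)):
        from .io import read_fasta

        proteins = read_fasta(proteins)
    index = ProteomeDigest()
    n = 0
    for protein_id, sequence in proteins:
        n += 1
        if clip_nterm_met and sequence.startswith("M"):
            sequence = sequence[1:]
        if not sequence:
            continue
        for pep in digest(sequence, rule, protein_id=protein_id):
            index.add(pep)
    if n == 0:
        raise InputError("no protein records to digest")
    return index
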