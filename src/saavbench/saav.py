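"""Single amino acid variant (SAAV) peptide pairing between two proteomes.

A SAAV pair is a peptide from the variant proteome that differs from a
reference-proteome peptide at exactly one residue.  Two mass-degenerate
situations are excluded up front, mirroring how such target lists are built
in practice:

* I <-> L differences (indistinguishable by mass anywhere in the peptide);
* differences at the C-terminal residue, unless the swap is K <-> R — any
  other C-terminal replacement would have removed the protease cleavage
  site that defined the peptide, so the "pair" could not both exist as
  tryptic peptides.

Scissor substitutions — those that create or destroy an internal protease
cleavage site — are classified on each pair, because they are exactly the
cases where the physical peptide and the in-silico expectation diverge.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .chem import DEFAULT_TABLE, ResidueMassTable, SubstitutionType
from .digestion import CleavageRule, Peptide, ProteomeDigest

logger = logging.getLogger(__name__)

SCISSOR_NONE = "none"
SCISSOR_GAIN = "gain_cutsite"
SCISSOR_LOSS = "loss_cutsite"

DROP_IL = "isoleucine_leucine"
DROP_CTERM = "c_terminal_non_KR"


@dataclass(frozen=True)
class SAAVPair:
    """A variant/reference peptide pair differing at exactly one position."""

    variant: Peptide
    reference: Peptide
    position: int  # 1-based index of the differing residue
    substitution: SubstitutionType  # reference -> variant
    scissor_class: str

    @property
    def position_from_c(self) -> int:
        return len(self.variant.sequence) - self.position + 1

    @property
    def variant_sequence(self) -> str:
        return self.variant.sequence

    @property
    def reference_sequence(self) -> str:
        return self.reference.sequence


def hamming1_position(a: str, b: str) -> Optional[int]:
    """1-based position of the single difference, or None if not Hamming-1."""
    if len(a) != len(b):
        return None
    pos = 0
    for i, (x, y) in enumerate(zip(a, b), 1):
        if x != y:
            if pos:
                return None
            pos = i
    return pos or None


def apply_exclusions(
    reference_seq: str, variant_seq: str, position: int
) -> Tuple[bool, Optional[str]]:
    """Decide whether a candidate Hamming-1 pair enters the SAAV space.

    Returns ``(keep, reason)``; ``reason`` names the exclusion when dropped.
    """
    ref_res = reference_seq[position - 1]
    var_res = variant_seq[position - 1]
    if {ref_res, var_res} == {"I", "L"}:
        return False, DROP_IL
    if position == len(reference_seq) and not {ref_res, var_res} <= {"K", "R"}:
        return False, DROP_CTERM
    return True, None


def classify_scissor(
    reference_seq: str,
    variant_seq: str,
    position: int,
    rule: CleavageRule = CleavageRule(),
) -> str:
    """Scissor class of a substitution (reference -> variant).

    ``loss_cutsite``: the reference residue at the differing internal
    position is a protease cut site and the variant residue is not — the
    physical variant peptide corresponds to an in-silico missed-cleavage
    peptide.  ``gain_cutsite``: the variant introduces an internal cut site
    the reference lacks — the physical peptide is shorter than the in-silico
    expectation.  A C-terminal K <-> R swap keeps the cleavage site and is
    classified ``none``.
    """
    if position == len(reference_seq):
        return SCISSOR_NONE
    ref_cut = rule.is_cutsite(reference_seq, position)
    var_cut = rule.is_cutsite(variant_seq, position)
    if ref_cut and not var_cut:
        return SCISSOR_LOSS
    if var_cut and not ref_cut:
        return SCISSOR_GAIN
    return SCISSOR_NONE


def _masked_keys(seq: str) -> Iterable[Tuple[int, str]]:
    for i in range(len(seq)):
        yield i + 1, seq[:i] + "\x00" + seq[i + 1 :]


def find_saav_pairs(
    peptides_reference: ProteomeDigest | Iterable[str],
    peptides_variant: ProteomeDigest | Iterable[str],
    rule: CleavageRule = CleavageRule(),
    table: ResidueMassTable = DEFAULT_TABLE,
) -> List[SAAVPair]:
    """All variant/reference peptide pairs at Hamming distance exactly one.

    Uses a masked-peptide hash join: every length-n peptide emits n keys with
    one position wildcarded, so candidate pairs are found without an
    all-pairs scan.  Each surviving pair is classified for scissor
    substitutions.  Output order is deterministic (variant, then reference
    sequence).
    """
    ref_index = _as_digest(peptides_reference)
    var_index = _as_digest(peptides_variant)
    if not len(ref_index) or not len(var_index):
        logger.warning("empty peptide set; no SAAV pairs to find")
        return []

    ref_by_key: Dict[Tuple[int, str], List[str]] = defaultdict(list)
    for seq in ref_index.sequences:
        for key in _masked_keys(seq):
            ref_by_key[key].append(seq)

    pairs: List[SAAVPair] = []
    for var_seq in var_index.sequences:
        for pos, key in _masked_keys(var_seq):
            for ref_seq in ref_by_key.get((pos, key), ()):
                if ref_seq[pos - 1] == var_seq[pos - 1]:
                    continue  # identical peptides: distance 0, not a variant
                keep, _ = apply_exclusions(ref_seq, var_seq, pos)
                if not keep:
                    continue
                sub = SubstitutionType(
                    table.class_of(ref_seq[pos - 1]),
                    table.class_of(var_seq[pos - 1]),
                    table.mass_of(var_seq[pos - 1]) - table.mass_of(ref_seq[pos - 1]),
                )
                pairs.append(
                    SAAVPair(
                        variant=var_index.representative(var_seq),
                        reference=ref_index.representative(ref_seq),
                        position=pos,
                        substitution=sub,
                        scissor_class=classify_scissor(ref_seq, var_seq, pos, rule),
                    )
                )
    pairs.sort(key=lambda p: (p.variant_sequence, p.reference_sequence))
    return pairs


def _as_digest(peptides: ProteomeDigest | Iterable[str]) -> ProteomeDigest:
    if isinstance(peptides, ProteomeDigest):
        return peptides
    index = ProteomeDigest()
    for seq in peptides:
        index.add(
            Peptide(
                sequence=seq,
                protein_id="?",
                start=1,
                end=len(seq),
                missed_cleavages=0,
            )
        )
    return index


def select_truth_pairs(pairs: Sequence[SAAVPair]) -> Dict[str, SAAVPair]:
    """One truth pair per variant sequence.

    A variant peptide may pair with several reference peptides; for
    ground-truth assignment the pair whose reference has the fewest missed
    cleavages wins (tie-break: lexicographically smallest reference
    sequence).
    """
    chosen: Dict[str, SAAVPair] = {}
    for pair in pairs:
        cur = chosen.get(pair.variant_sequence)
        key = (pair.reference.missed_cleavages, pair.reference_sequence)
        if cur is None or key < (cur.reference.missed_cleavages, cur.reference_sequence):
            chosen[pair.variant_sequence] = pair
    return chosen


@dataclass(frozen=True)
class HammingDistanceSummary:
    """Per-peptide minimum cross-proteome difference, bucketed {0,1,2,>2}."""

    counts: Dict[str, int]
    n: int

    @property
    def fractions(self) -> Dict[str, float]:
        return {k: v / self.n for k, v in self.counts.items()}


BUCKETS = ("0", "1", "2", ">2")


def hamming_summary(
    peptides_query: ProteomeDigest | Iterable[str],
    peptides_other: ProteomeDigest | Iterable[str],
) -> HammingDistanceSummary:
    """Bucket each query peptide by its minimum difference to the other set.

    Peptides with no same-length partner fall in the ``>2`` bucket.  Exact
    matches use a set lookup, distance-1 a wildcard hash, and distance-2 a
    bounded scan over same-length peptides.
    """
    query = list(_as_digest(peptides_query).sequences)
    other = _as_digest(peptides_other).sequences
    if not query or not other:
        raise ValueError("hamming_summary requires two nonempty peptide sets")
    other_set: Set[str] = set(other)
    other_keys: Set[Tuple[int, str]] = set()
    by_length: Dict[int, List[str]] = defaultdict(list)
    for seq in other:
        by_length[len(seq)].append(seq)
        for key in _masked_keys(seq):
            other_keys.add(key)

    counts = {b: 0 for b in BUCKETS}
    for seq in query:
        if seq in other_set:
            counts["0"] += 1
            continue
        if any(key in other_keys for key in _masked_keys(seq)):
            counts["1"] += 1
            continue
        if _has_distance2_partner(seq, by_length.get(len(seq), ())):
            counts["2"] += 1
        else:
            counts[">2"] += 1
    return HammingDistanceSummary(counts=counts, n=len(query))


def _has_distance2_partner(seq: str, candidates: Iterable[str]) -> bool:
    for cand in candidates:
        diff = 0
        for x, y in zip(seq, cand):
            if x != y:
                diff += 1
                if diff > 2:
                    break
        if diff == 2:
            return True
    return False
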