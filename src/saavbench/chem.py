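"""Residue mass model and the amino acid substitution mass space.

Bottom-up proteomics observes peptides through their mass, so two residues
with the same monoisotopic mass (isoleucine and leucine) are a single
observable class.  Collapsing I/L leaves 19 mass-distinct residue classes and
``19 x 18 = 342`` ordered substitution types, each with a characteristic
precursor mass shift (``mass(to) - mass(from)``).

Two practical defaults deserve a note:

* Cysteine is carried as its S-carbamidomethyl derivative (+57.02146 Da),
  because shotgun workflows alkylate cysteines before digestion.  The mass
  shift observable for any substitution involving Cys therefore includes the
  gain or loss of the carbamidomethyl group.  Pass
  ``ResidueMassTable.default(cys_carbamidomethyl=False)`` for free cysteine.
* The default PTM list is a small, documented stand-in for the common
  artifacts an open search reports; it is fully swappable (see
  :data:`DEFAULT_PTMS` and :func:`load_ptm_table`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import ConfigError, InputError, InvalidSubstitutionError

# Monoisotopic residue (residue-in-chain) masses, Da.  I and L share a mass
# and are merged into the class symbol "J" in the default table below.
MONOISOTOPIC_RESIDUE_MASS: Dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "I": 113.084064,
    "L": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

CARBAMIDOMETHYL_MASS = 57.021464
WATER_MASS = 18.010565

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Class symbol used for the merged isoleucine/leucine class.
IL_CLASS = "J"


@dataclass(frozen=True)
class Tolerances:
    """Mass tolerances used throughout the pipeline.

    ``isobaric_window`` is an absolute window (Da) for comparing substitution
    mass shifts with each other; ``offset_match_ppm`` scales with the peptide
    neutral mass when matching an observed precursor mass offset to candidate
    modifications.
    """

    isobaric_window: float = 0.02
    offset_match_ppm: float = 25.0

    def __post_init__(self) -> None:
        if self.isobaric_window <= 0 or self.offset_match_ppm <= 0:
            raise ConfigError("tolerances must be strictly positive")

    def offset_window_da(self, peptide_mass: float) -> float:
        """Absolute matching window (Da) for a peptide of the given mass."""
        return self.offset_match_ppm * peptide_mass * 1e-6


@dataclass(frozen=True)
class ResidueMassTable:
    """Mass-distinct residue classes and their monoisotopic masses.

    ``masses`` maps a one-letter class symbol to its residue mass; ``members``
    maps each class to the canonical residues it absorbs (only the I/L class
    has more than one member in the default table).
    """

    masses: Mapping[str, float]
    members: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.masses) < 2:
            raise InputError("a residue mass table needs at least two classes")
        vals = list(self.masses.values())
        if any(v <= 0 for v in vals):
            raise InputError("residue masses must be strictly positive")
        if len(set(vals)) != len(vals):
            raise InputError("residue classes must have pairwise distinct masses")
        if not self.members:
            object.__setattr__(self, "members", {c: c for c in self.masses})
        reverse: Dict[str, str] = {}
        for sym, mem in self.members.items():
            reverse[sym] = sym
            for residue in mem:
                reverse[residue] = sym
        object.__setattr__(self, "_reverse", reverse)

    @classmethod
    def default(cls, cys_carbamidomethyl: bool = True) -> "ResidueMassTable":
        """The 19-class table with I/L merged (class symbol ``J``)."""
        masses = {}
        members = {}
        for aa, m in MONOISOTOPIC_RESIDUE_MASS.items():
            cls_sym = IL_CLASS if aa in "IL" else aa
            if aa == "C" and cys_carbamidomethyl:
                m = m + CARBAMIDOMETHYL_MASS
            masses[cls_sym] = m
            members[cls_sym] = members.get(cls_sym, "") + aa
        return cls(masses=masses, members=members)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueMassTable":
        """Load a table from a 2/3-column TSV: symbol, mass[, members]."""
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"residue mass table not found: {path}")
        masses: Dict[str, float] = {}
        members: Dict[str, str] = {}
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected at least 2 columns")
            sym = parts[0]
            try:
                masses[sym] = float(parts[1])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: bad mass {parts[1]!r}") from exc
            members[sym] = parts[2] if len(parts) > 2 else sym
        return cls(masses=masses, members=members)

    @property
    def classes(self) -> List[str]:
        return sorted(self.masses)

    def class_of(self, residue: str) -> str:
        """Map a canonical residue letter to its class symbol."""
        try:
            return self._reverse[residue]  # type: ignore[attr-defined]
        except KeyError:
            raise InputError(f"unknown residue symbol: {residue!r}") from None

    def mass_of(self, symbol: str) -> float:
        sym = symbol if symbol in self.masses else self.class_of(symbol)
        return self.masses[sym]

    def display(self, symbol: str) -> str:
        """Human-readable label for a class (``J`` renders as ``I/L``)."""
        mem = self.members.get(symbol, symbol)
        return "/".join(mem) if len(mem) > 1 else mem

    def representative(self, symbol: str) -> str:
        """A canonical residue letter standing in for the class."""
        return min(self.members.get(symbol, symbol))

    def class_sequence(self, sequence: str) -> str:
        """Rewrite a residue string in class symbols (collapses I/L)."""
        return "".join(self.class_of(c) for c in sequence)

    def peptide_mass(self, sequence: str) -> float:
        """Monoisotopic neutral mass of a peptide (residues + water)."""
        return sum(self.mass_of(c) for c in sequence) + WATER_MASS


DEFAULT_TABLE = ResidueMassTable.default()


@dataclass(frozen=True, order=True)
class SubstitutionType:
    """An ordered substitution between two residue classes."""

    from_class: str
    to_class: str
    delta_mass: float = field(compare=False)

    def label(self, table: ResidueMassTable = DEFAULT_TABLE) -> str:
        return f"{table.display(self.from_class)} → {table.display(self.to_class)}"

    def reverse(self) -> "SubstitutionType":
        return SubstitutionType(self.to_class, self.from_class, -self.delta_mass)


@dataclass(frozen=True)
class PTMDefinition:
    """A named modification with a mass shift and residue specificity.

    ``residues`` is a frozenset of class symbols, or ``None`` for
    position-independent ("any residue") modifications.
    """

    name: str
    delta_mass: float
    residues: Optional[FrozenSet[str]] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise InputError("PTM name must be nonempty")
        if self.delta_mass != self.delta_mass or abs(self.delta_mass) == float("inf"):
            raise InputError("PTM delta mass must be finite")

    def applies_to(self, residue_classes: Iterable[str]) -> bool:
        if self.residues is None:
            return True
        return bool(self.residues & set(residue_classes))


#: Documented default modification list (a stand-in for the larger set an
#: open search reports; swap via :func:`load_ptm_table`).
DEFAULT_PTMS: Tuple[PTMDefinition, ...] = (
    PTMDefinition("oxidation", 15.994915, frozenset("M")),
    PTMDefinition("dehydration", -18.010565, frozenset("ST")),
    PTMDefinition("deamidation", 0.984016, frozenset("NQ")),
    PTMDefinition("methylation", 14.015650, frozenset("KR")),
    PTMDefinition("carbamidomethylation", 57.021464, frozenset("HKDE")),
    PTMDefinition("pyro-glutamate", -17.026549, frozenset("Q")),
)


def load_ptm_table(path: str | Path) -> List[PTMDefinition]:
    """Load PTMs from a 3-column TSV: name, delta_mass, residues (or 'any')."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"PTM table not found: {path}")
    ptms = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise InputError(f"{path}:{lineno}: expected 3 columns")
        residues = None if parts[2].lower() == "any" else frozenset(parts[2])
        ptms.append(PTMDefinition(parts[0], float(parts[1]), residues))
    return ptms


def delta_mass(
    from_class: str, to_class: str, table: ResidueMassTable = DEFAULT_TABLE
) -> float:
    """Precursor mass shift (Da) of substituting ``from_class`` by ``to_class``.

    Full floating precision is returned; round to 3 decimals for display.
    """
    f = table.class_of(from_class) if from_class not in table.masses else from_class
    t = table.class_of(to_class) if to_class not in table.masses else to_class
    if f == t:
        raise InvalidSubstitutionError(
            f"{from_class!r} and {to_class!r} are the same residue class"
        )
    return table.masses[t] - table.masses[f]


def enumerate_substitution_types(
    table: ResidueMassTable = DEFAULT_TABLE,
) -> List[SubstitutionType]:
    """All ordered pairs of distinct residue classes (342 on the default table)."""
    return [
        SubstitutionType(a, b, table.masses[b] - table.masses[a])
        for a in table.classes
        for b in table.classes
        if a != b
    ]


def isobaric_neighbors(
    sub: SubstitutionType,
    table: ResidueMassTable = DEFAULT_TABLE,
    window: float = 0.02,
    types: Optional[Sequence[SubstitutionType]] = None,
) -> FrozenSet[SubstitutionType]:
    """All other substitution types whose shift lies within ``±window`` Da."""
    if window <= 0:
        raise ConfigError("isobaric window must be positive")
    if types is None:
        types = enumerate_substitution_types(table)
    return frozenset(
        t
        for t in types
        if (t.from_class, t.to_class) != (sub.from_class, sub.to_class)
        and abs(t.delta_mass - sub.delta_mass) <= window
    )


def isobaric_map(
    table: ResidueMassTable = DEFAULT_TABLE, window: float = 0.02
) -> Dict[SubstitutionType, FrozenSet[SubstitutionType]]:
    """Neighbor sets for every substitution type (per-type window, not clusters)."""
    types = enumerate_substitution_types(table)
    return {t: isobaric_neighbors(t, table, window, types) for t in types}


def double_substitution_deltas(
    table: ResidueMassTable = DEFAULT_TABLE,
) -> Dict[Tuple[SubstitutionType, SubstitutionType], float]:
    """Summed mass shifts of every unordered pair of substitution types.

    Pairs of a type with itself are included (two identical substitutions in
    one peptide are chemically possible).
    """
    types = enumerate_substitution_types(table)
    return {
        (a, b): a.delta_mass + b.delta_mass
        for a, b in itertools.combinations_with_replacement(sorted(types), 2)
    }


def substitution_search_space(
    peptide_length: int, table: ResidueMassTable = DEFAULT_TABLE
) -> int:
    """Number of mass-distinct single-substitution permutations of a peptide.

    Each of the ``peptide_length`` positions can change to any of the other
    ``n_classes - 1`` residue classes.
    """
    if peptide_length < 1:
        raise InputError("peptide length must be >= 1")
    return peptide_length * (len(table.classes) - 1)


def match_offset_to_candidates(
    observed_offset: float,
    peptide_mass: float,
    residues_present: Iterable[str],
    ptm_list: Sequence[PTMDefinition] = DEFAULT_PTMS,
    tolerances: Tolerances = Tolerances(),
    table: ResidueMassTable = DEFAULT_TABLE,
) -> List[SubstitutionType | PTMDefinition]:
    """Candidate explanations for an observed precursor mass offset.

    Returns every substitution type whose origin residue occurs in
    ``residues_present`` and every PTM applicable to those residues, whose
    mass shift lies within ``offset_match_ppm`` of the peptide neutral mass
    around ``observed_offset``.
    """
    if peptide_mass <= 0:
        raise InputError("peptide mass must be positive")
    residues = {table.class_of(r) if r not in table.masses else r for r in residues_present}
    if not residues:
        raise InputError("residues_present must be nonempty")
    window = tolerances.offset_window_da(peptide_mass)
    out: List[SubstitutionType | PTMDefinition] = []
    for sub in enumerate_substitution_types(table):
        if sub.from_class in residues and abs(sub.delta_mass - observed_offset) <= window:
            out.append(sub)
    for ptm in ptm_list:
        if ptm.applies_to(residues) and abs(ptm.delta_mass - observed_offset) <= window:
            out.append(ptm)
    return out
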