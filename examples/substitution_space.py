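"""Explore the amino acid substitution mass space.

Builds the default 19-class residue mass table (I/L merged, Cys
carbamidomethylated), enumerates all ordered substitution types, and shows
why mass alone cannot always identify a substitution: many shifts are
isobaric with other substitutions or with common modifications.
"""

from saavbench import (
    DEFAULT_TABLE,
    delta_mass,
    enumerate_substitution_types,
    isobaric_map,
    match_offset_to_candidates,
    substitution_search_space,
)

types = enumerate_substitution_types()
print(f"ordered substitution types over 19 mass-distinct classes: {len(types)}")
print(f"single-substitution permutations of a 14-residue peptide: "
      f"{substitution_search_space(14)}")

shift = delta_mass("G", "A")
print(f"\nG → A precursor mass shift: {shift:+.3f} Da")

degeneracy = isobaric_map(window=0.02)
n_isobaric = sum(1 for nb in degeneracy.values() if nb)
print(f"types isobaric with another type at ±0.02 Da: {n_isobaric} of {len(types)}")

g_a = next(t for t in types if (t.from_class, t.to_class) == ("G", "A"))
partners = ", ".join(sorted(n.label(DEFAULT_TABLE) for n in degeneracy[g_a]))
print(f"shifts indistinguishable from G → A: {partners}")

print("\ncandidates for a +14.016 Da offset on a peptide containing G, S and K:")
for cand in match_offset_to_candidates(14.016, 1000.0, {"G", "S", "K"}):
    name = cand.label(DEFAULT_TABLE) if hasattr(cand, "label") else cand.name
    print(f"  {name}")
print("-> without fragment-ion localization this offset is ambiguous; the"
      "\n   annotation module drops such PSMs rather than guessing.")
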