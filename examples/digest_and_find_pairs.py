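"""Digest two small proteomes and find their SAAV peptide pairs.

Two toy proteins differ at two positions: one neutral substitution and one
that destroys a tryptic cleavage site (a "scissor" substitution).  The
scissor variant peptide only pairs with a missed-cleavage peptide of the
reference — exactly the situation that penalizes these substitutions in
real discovery searches.
"""

from saavbench import CleavageRule, digest_proteome, find_saav_pairs

rule = CleavageRule(min_length=4, max_length=50, max_missed_cleavages=1)

reference = [("refA", "MSTELKDVIGGRAAAKGGGRTESTK")]
#                  T->S neutral   ^K->T scissor (loses the cut site)
variant = [("varA", "MSSELKDVIGGRAAATGGGRTESTK")]

ref_digest = digest_proteome(reference, rule)
var_digest = digest_proteome(variant, rule)
print(f"reference peptides: {ref_digest.sequences}")
print(f"variant peptides:   {var_digest.sequences}")

pairs = find_saav_pairs(ref_digest, var_digest, rule)
print(f"\n{len(pairs)} SAAV pair(s):")
for p in pairs:
    sub = p.substitution
    print(
        f"  {p.reference_sequence} -> {p.variant_sequence}"
        f"  {sub.from_class}→{sub.to_class} at position {p.position}"
        f" ({sub.delta_mass:+.3f} Da), scissor: {p.scissor_class}"
    )
print("\nA loss_cutsite pair means the physical variant peptide matches an"
      "\nin-silico missed-cleavage peptide of the reference proteome.")
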