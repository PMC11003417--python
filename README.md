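# saavbench

Ground-truth evaluation of amino acid substitution (AAS) detection in
shotgun proteomics.

Amino acid substitutions — from mistranslation, mutation or polymorphism —
appear in mass spectra as peptides one residue away from the genome-encoded
database. Discovery searches (open / mass-offset searches) can find them, but
with biases that are invisible without ground truth: you cannot count the
spectra a search *failed* to identify unless you already know what they were.
`saavbench` implements the two-proteome benchmark design that provides this
ground truth, for bioinformaticians evaluating or tuning AAS discovery
pipelines:

1. **SAAV target space.** Two related proteomes are digested in silico and
   every peptide pair at Hamming distance one (a *single amino acid variant*,
   SAAV) is enumerated, after excluding mass-ambiguous cases (I↔L anywhere;
   non-K/R swaps at the peptide C terminus).
2. **Ground-truth library.** A *two-genome* search of mixed-lysate spectra —
   both proteomes in the database — assigns each spectrum a confident
   sequence. Spectra matching SAAV variant peptides become library entries
   with known truth: sequence, substitution type, position, intensity.
3. **Fate tracing.** The same spectra searched with only one proteome (the
   *one-genome* mass-offset search) are compared spectrum-by-spectrum against
   the library. Every library spectrum receives exactly one fate: `correct`,
   `no_identification`, `cognate_assignment` (the unmodified genomic twin),
   `incorrect_modified`, `ambiguous_filtered`, `zero_intensity_filtered`, or
   `other_incorrect`.
4. **Efficiency statistics.** Identification efficiency (correct / total) is
   reported at spectrum and peptide level and stratified by substitution type
   (a 19×19 matrix over mass-distinct residue classes), by peptide length ×
   substitution position, and by *scissor* class — substitutions that gain or
   lose a protease cleavage site and therefore clash with how search engines
   predict peptides.

The substitution mass space itself is modeled explicitly: with isoleucine
and leucine merged (equal mass) there are 19 residue classes and
19 × 18 = 342 ordered substitution types, each with shift
Δm = m(to) − m(from). At ±0.02 Da, 190 of the 342 types are isobaric with at
least one other type (e.g. G→A, S→T, D→E, N→Q and V→I/L all sit at
+14.016 Da), and every single-substitution shift is shadowed by sums of two
substitutions — which is why confident AAS calls need localized fragment
evidence, not precursor mass alone. Cysteine is carried as its
S-carbamidomethyl derivative by default, matching standard alkylation
chemistry; the table is swappable (`ResidueMassTable`).

A planted-truth simulator (`saavbench.simulation`) generates reference /
variant proteome pairs and paired two-genome / one-genome PSM tables at the
level the pipeline consumes, so the entire workflow is testable without any
external data.

## Worked example

```bash
python examples/end_to_end_benchmark.py
```

```
proteins: 100, planted events: 168, SAAV pairs: 334

library: 3955 spectra, 331 peptides
spectrum-level efficiency: 38.8%
peptide-level efficiency:  92.1%

fate fractions (recovered vs planted):
  correct                   38.8%    38.8%
  no_identification         33.8%    33.8%
  cognate_assignment        15.3%    15.3%
  incorrect_modified         5.6%     5.6%
  ambiguous_filtered         2.0%     2.0%
  zero_intensity_filtered    2.4%     2.4%
  other_incorrect            2.1%     2.1%

efficiency by scissor class:
  gain_cutsite     46/227  (20.3%)
  loss_cutsite     61/132  (46.2%)
  none           1426/3596 (39.7%)
```

The simulator planted a fate for every one of the 3955 library spectra; the
pipeline (annotation → target filtering → fate categorization) recovered the
planted fractions exactly, and the scissor stratification shows the expected
penalty for substitutions that alter the tryptic cleavage pattern. The other
examples (`examples/substitution_space.py`,
`examples/digest_and_find_pairs.py`) walk the mass space and the pairing
logic on desk-scale inputs.

The same steps are available as a file-to-file CLI:

```bash
saavbench simulate --seed 4 --out sim/
saavbench find-saav --fasta-a sim/reference.fasta --fasta-b sim/variant.fasta -o pairs.tsv
saavbench build-library --psm sim/two_genome.tsv --pairs pairs.tsv -o library.tsv
saavbench evaluate --library library.tsv --one-genome sim/one_genome.tsv -o report.json
saavbench isobaric-map -o isobaric.tsv
```

Real searches plug in the same way: point `annotate` / `build-library` at
tab-separated PSM tables (a FragPipe-psm.tsv-like dialect; the column map is
configurable) and `find-saav` at the two organisms' FASTA proteomes.

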