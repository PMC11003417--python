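# Methods

## The benchmark model

`saavbench` treats AAS detection as a paired-search experiment over one set
of spectra. The *two-genome* search, with both proteomes in the database, is
taken as ground truth: any spectrum it confidently assigns to a peptide that
is a single amino acid variant (SAAV) of the other proteome becomes a
library entry whose true sequence, substitution type, position and cognate
are known. The *one-genome* search — reference proteome only, precursor mass
offsets allowed — is the system under evaluation. Because both searches are
keyed by spectrum id, every library spectrum can be assigned exactly one
fate, and fate counts partition the library by construction.

The package never touches spectra. Both searches enter as tab-separated PSM
tables (spectrum id, assigned peptide, precursor mass offset, optional
offset localization, precursor intensity, calculated peptide mass, posterior
probability, sample label). Upstream scoring and FDR control are consumed,
not re-estimated.

## Residue classes and the substitution space

Isoleucine and leucine have identical residue mass, so the mass-observable
alphabet has 19 classes; the merged class is carried under the symbol `J`
and rendered as `I/L`. The ordered substitution space is all 19 × 18 = 342
(from, to) pairs with shift Δm = m(to) − m(from).

Default masses are standard monoisotopic residue-in-chain values, embedded
to six decimals and cross-checked against `pyteomics.mass.std_aa_mass` in a
test. **Cysteine defaults to its S-carbamidomethyl derivative**
(103.009185 + 57.021464 Da): shotgun workflows alkylate cysteines before
digestion, so the mass shift physically observable for any substitution
involving Cys includes the gain or loss of the carbamidomethyl group. This
choice is load-bearing for the degeneracy census: with CAM-Cys, 190 of the
342 types have another type within ±0.02 Da (free Cys would give 196). Pass
`ResidueMassTable.default(cys_carbamidomethyl=False)`, or a TSV via
`ResidueMassTable.from_tsv`, to change the chemistry.

Isobaric grouping is deliberately *per type* — a window centered on each
type's own shift — not transitive clustering; the relation is symmetric and
the reported "group of five" at +14.016 Da (G→A, S→T, D→E, N→Q, V→I/L) is a
type plus its neighbors.

## Offset annotation

An observed offset is matched against all 342 substitution shifts and a
configurable PTM list within `ppm × peptide neutral mass` (default 25 ppm,
computed on the neutral mass, not m/z). When the upstream engine localized
the offset, candidates are restricted to that residue; otherwise every
residue of the peptide generates candidates, one per position. A PSM is a
usable substitution call only when exactly one candidate survives:
several substitution placements, or a substitution/PTM mass collision, make
it `ambiguous` and it is dropped rather than guessed. Offsets within the
ppm window of zero are `unmodified`; there is no separate deadband.

The shipped PTM list is a documented six-entry stand-in for the larger set
an open search would consider: oxidation (M, +15.994915), dehydration (S/T,
−18.010565), deamidation (N/Q, +0.984016), methylation (K/R, +14.015650),
carbamidomethyl artifacts (H/K/D/E, +57.021464) and pyro-glutamate (Q,
−17.026549). It is swappable per run (TSV or API). Note the intrinsic
degeneracies it encodes: N→D and Q→E are *exactly* deamidation, so those
substitutions can never be uniquely called from precursor mass — a real
property of the chemistry, not an artifact.

Filtering order for target lists is: zero-intensity (unquantified), then
ambiguous, then non-substitution records, then unique substitutions whose
implied variant is not in the SAAV target list. The filter report always
conserves records (retained + removed = input), and target comparison
collapses I/L.

## SAAV pairing and scissor substitutions

Pair finding uses a masked-peptide hash join (each length-n peptide emits n
single-wildcard keys), which is equivalent to the all-pairs Hamming-1 scan —
an equivalence the test suite asserts against a brute-force oracle on random
proteomes. Exclusions mirror how such target lists must be built: I↔L
differences are invisible to mass, and a difference at the C-terminal
residue is kept only for the K↔R swap (any other replacement would have
removed the cleavage site that defined the peptide).

A substitution at an internal position is a *scissor* substitution when
exactly one of the two residues is a protease cut site there (proline
suppression respected): reference-side cut site lost → `loss_cutsite`
(the physical variant peptide equals an in-silico missed-cleavage peptide);
variant-side cut site gained → `gain_cutsite` (the physical peptide is
shorter than anything the engine predicts). Classification is
direction-sensitive and swaps gain↔loss when the proteome roles are
reversed. Context changes *adjacent* to the substitution (e.g. a new proline
suppressing the neighboring site) are not classed as scissor.

When one variant peptide pairs with several reference peptides, all pairs
are kept; for ground-truth assignment the pair whose reference has the
fewest missed cleavages wins, with the lexicographically smaller reference
sequence as tie-break.

## Fates and efficiency

Per library spectrum, in order: absent from the one-genome table →
`no_identification`; zero precursor intensity → `zero_intensity_filtered`;
ambiguous annotation → `ambiguous_filtered`; unique substitution whose
implied variant equals the truth (I/L collapsed) → `correct`, otherwise
`incorrect_modified`; PTM-only → `incorrect_modified`; unmodified cognate →
`cognate_assignment`; anything else → `other_incorrect`. The explicit
catch-all guarantees exact conservation.

Spectrum-level efficiency is correct/total; peptide-level efficiency is the
fraction of unique truth sequences with at least one correct spectrum,
pooled over all samples. Stratified matrices (by type, by length × position,
by scissor class) report cells only where library spectra exist — an empty
cell is absent, never 0%. Score deltas (one-genome minus library posterior
probability, correct spectra only) and dilution metrics (per-peptide
log₁₀ max/min intensity, detection floor, last sample of detection) complete
the report.

## The simulator

The generator emulates the study conditions at PSM-table level: ~100 random
proteins of 180–420 residues (uniform residue frequencies by default), point
substitutions planted at 0.5% per residue (never I↔L; a `scissor_bias`
option forces a fraction of events to involve K/R), tryptic digestion with
one missed cleavage and 5–50 residue bounds, a six-step 2-fold dilution
series in technical duplicate, log-normal peptide base intensities
(ln-scale mean 17.2 ≈ 3×10⁷, σ 1.2) with per-spectrum jitter and a 10⁵
detection floor, and posterior probabilities near 1 with an exponential
lower tail. The default fate vector is the benchmark mix (38.3% correct,
34.0% no identification, 14.9% cognate, 5.7% incorrectly modified, 2.2%
ambiguous, 2.4% unquantified, 2.5% other). Presets: `baseline` and
`scissor_enriched`.

Fate totals come from one multinomial draw; assignment to spectra respects
constructability. A spectrum whose substitution is mass-degenerate at its
own site (N→D vs deamidation; X→Q vs X→K on heavy peptides at 25 ppm)
cannot realize a `correct` outcome, so such spectra draw from the remaining
categories; rows for each fate are constructed so the pipeline's
categorization provably reproduces the plant (the test suite asserts the
round trip is exact). Degenerate scenarios such as `{correct: 1.0}` are run
in the perfect-information limit (empty PTM list, tight ppm), where every
spectrum is constructible.

All randomness flows from one `numpy` generator seeded by
`SimulationConfig.random_seed`; outputs are byte-identical across runs.

## What the simulator does and does not show

Planted fates are drawn independently per spectrum, conditioned only on
constructability. Real spectra of the same peptide succeed or fail together
(shared fragmentation chemistry), which drives peptide-level efficiency far
below the independent-fates prediction: synthetic runs show ~92% peptide
level at ~38% spectrum level, whereas correlated real data sit much closer
together. Passing tests therefore validate the bookkeeping — pairing,
annotation, conservation, stratification — not the biology of which
substitutions are hard. The simulator also fabricates no fragment spectra,
no chromatography and no ion-mobility physics: retention time and 1/K0 are
decorative covariates, and score distributions are a two-parameter sketch
(fraction unchanged, exponential drop) of the qualitative pattern that
discovery searches score the same evidence lower.

## Numerical and scale choices

Test and example problem sizes (25–100 proteins, ≤10⁴ spectra, 100 oracle
trials with two 1000-peptide sides) were chosen so the whole suite runs in
seconds while every code path is exercised; all scale linearly if raised.
Annotation ties at different residues are dropped as ambiguous rather than
broken arbitrarily. Floating-point display rounds shifts to 3 decimals;
comparisons always use full precision. Known limitations: no multi-residue
variants (distance-2 peptides are counted in the Hamming summary but not
paired), no semi-specific digestion, no FDR re-estimation, and PSM tables
are trusted as delivered by the upstream pipeline.
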