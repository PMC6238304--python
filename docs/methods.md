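# Methods

## The allele model

A star allele is modelled as a name, a set of associated substitutions
(`all_variants`), the subset that defines the assignment
(`key_variants`), a set of structural events, and a function class. The
bundled table covers the six alleles a four-SNP + structural-flag panel
can type:

| allele | variants | structural | function | activity |
|---|---|---|---|---|
| \*1 | — | — | normal | 1.0 |
| \*2 | C2850T, G4180C | — | normal | 1.0 |
| \*4 | C100T, G1846A, G4180C | — | none | 0.0 |
| \*5 | — | whole-gene deletion | none | 0.0 |
| \*10 | C100T, G4180C | — | decreased | 0.5 |
| \*36 | C100T, G4180C | exon-9 conversion | decreased | 0.5 |

Validation enforces signature uniqueness: no two alleles may share both
the same variant set and the same structural set. \*10 and \*36 are
SNP-identical and distinguished only by the conversion; \*4 is \*10's
SNPs plus the splice-defect variant.

Two further substitutions seen by exon sequencing in the source cohort,
C1039T and G1661C, are catalogued as variants but deliberately assigned
to no allele and excluded from the informative loci: the definition
table does not map them, and inventing allele content would change
calls. Their printed frequencies are numerically consistent with riding
on \*4+\*10+\*36 and \*2+\*4+\*10+\*36 respectively, but that reading is
not assumed.

Activity values follow the standard additive activity-score convention
(normal 1.0, decreased 0.5, none 0.0, configurable per table); the
summary reports a cohort mean activity score but no phenotype cutoffs.

Coordinates are gene-local and 1-based on the conventional genomic
reference for this gene; no genome-build liftover is attempted.

## Diplotype calling

Calling is exhaustive enumeration over unordered allele pairs, filtered
by three constraints:

1. **Genotype match.** A pair survives only if its predicted apparent
   genotype equals every observed (non-missing) informative locus.
   Prediction follows alt-allele dose, with hemizygote masking for
   deletion carriers (single surviving copy appears homozygous) and
   all-missing for the double deletion.
2. **Deletion band.** Present → only hemizygous pairs (a, \*5) are
   candidates; absent → \*5 is excluded. A heterozygous genotype call
   together with a deletion band is physically impossible and yields
   status `inconsistent` with a diagnostic note rather than an
   exception. The fully missing deletion-band sample is the defined
   homozygous-deletion case, called (\*5, \*5) with a note.
3. **Exon-9 conversion dose.** Sanger sequencing of exon 9 distinguishes
   a heterozygous conversion (mixed traces over the converted tract)
   from a homozygous one (clean converted sequence), so the evidence is
   modelled as {absent, present, homozygous, untested} and must equal
   the pair's conversion-allele dose, with hemizygote masking applying
   here too (a (\*36, \*5) sample reads homozygous). This dose-aware
   observation is what makes (\*10, \*36) and (\*36, \*36) separable;
   under a presence-only flag they would be mutually ambiguous by
   pigeonhole. When exon 9 is untested, conversion alleles are not
   proposed at all — otherwise nearly every \*10 call would be
   ambiguous against \*36 — and calls collapse to the SNP-identical
   counterpart; `allow_untested_exon9_ambiguity=True` restores the
   ambiguous behaviour for sensitivity analyses.

The duplication band never filters candidates: the assay cannot resolve
which allele is duplicated or the copy number, so the flag is carried as
a note (`duplication_present_copy_number_unresolved`) and every sample
contributes exactly two allele slots downstream. Copy-number-aware
calls such as \*1xN are out of scope.

Ranking multiplies per-allele prior weights (uniform by default, ×2 for
heterozygous pairs), breaking ties in ascending star-number order for
determinism. When a call is unique the ranking is irrelevant by
construction, which the tests assert as a prior-invariance property.

## Cohort statistics

* Allele counts sum to 2n; the deletion allele occupies a slot.
* Derived SNP frequencies are sums of carrying-allele frequencies over
  the same 2n denominator. This convention reproduces the published
  cohort's C100T = 60/140 ≈ 0.43 and G4180C = 106/140 ≈ 0.76. For
  C2850T it gives 46/140 ≈ 0.33; the source abstract prints 0.32 for
  that marker, a value not reproducible under any single consistent
  denominator, and this package reports the count-implied 0.33.
* Function burden is the allele-frequency mass per function class;
  `reduced_function_fraction` defaults to {decreased, none}, the
  intermediate-metabolizer burden.
* Non-unique calls are excluded from summaries with a logged count,
  never imputed.
* The Hardy–Weinberg exact test conditions on observed allele counts,
  enumerates all heterozygote counts of matching parity, and sums the
  probabilities of configurations no more probable than the observed
  one (two-sided). Computation is in log-space for numerical range; an
  exact rational-arithmetic enumeration oracle backs it in the tests
  for 2n ≤ 20.

### Cross-population comparison

The bundled panel transcribes published per-study marker frequencies.
Following the survey convention, columns named after a defining variant
or structural event hold the corresponding *allele* frequency (C100T →
\*10, G1846A → \*4, C2850T → \*2, deletion → \*5, exon-9 conversion →
\*36), while plain columns (C1039T, G1661C, G4180C) hold substitution
frequencies; the target cohort's values are mapped the same way before
differencing. Divergence is the mean absolute frequency difference over
the requested markers a study determined (undetermined markers are
excluded row-wise); the default marker set is the four columns most
studies typed (C100T, G1846A, C2850T, deletion). No formal
differentiation statistic (F_ST, homogeneity chi-square) is computed —
the table answers "which published populations look closest", not "is
the difference significant".

## Assay QC

* `gc_percent` rounds half-up to one decimal, matching print precision.
  The bundled 36-oligo panel reproduces printed lengths exactly; the 28
  primers match printed GC within ±0.1, and the 8 allele-specific
  probes are printed at integer precision and match after integer
  rounding.
* `melting_temperature` uses SantaLucia nearest-neighbor parameters
  under PCR-buffer conditions: 50 mM monovalent salt, 1.5 mM Mg²⁺,
  0.6 mM dNTPs, 50 nM primer, Owczarzy divalent correction. Under these
  defaults all 28 primers fall within ±2.7 °C of their printed values;
  because the reference computation conditions are unstated, tests
  assert only a ±5 °C band, and probe Tms are not checked at all
  (dual-labelled probe chemistry shifts them outside any plain-DNA NN
  model). All parameters are keyword-configurable.
* `pairwise_identity` is global alignment (match +1, mismatch −1, gap
  open −2, gap extend −1) with identity = matches / alignment columns,
  gap columns included in the denominator — a conservative reading of
  "sequence similarity". `classify_amplicon` accepts a query as the
  functional gene only when identity to the gene reference strictly
  exceeds the threshold (default 95%) *and* strictly beats every
  pseudogene reference; symmetric for pseudogene; otherwise
  indeterminate.
* The bundled intron-2 references are synthetic 1,101-base stand-ins
  (the length of the real intron-2 amplicon) at ~93% mutual identity,
  in the realistic >90% homology band and below the 95% acceptance
  threshold; they are generated sequences, clearly labelled, keeping
  the repository download-free. Classifier behaviour on real pseudogene
  homology structure (which is locally clustered, not uniform) is not
  exercised.

## Synthetic data

`simulate_population` draws each sample's two alleles i.i.d. from a
star-allele frequency simplex (Hardy–Weinberg equilibrium) by
inverse-CDF lookup on a seeded PCG64 generator, then renders assay
records with the same masking rules the caller assumes. Defaults are the
published cohort's estimates (\*1 0.214, \*2 0.329, \*4 0.021, \*5
0.029, \*10 0.400, \*36 0.007), n = 70, no no-calls, no duplications.
Optional per-locus no-calls and duplication flags are Bernoulli.
Cohorts are byte-for-byte reproducible from the seed.

`reconstruct_karen_cohort` expands the published 11 diplotype counts
(3, 8, 3, 2, 10, 1, 7, 1, 23, 1, 11; total 70) into deterministic
records, rendering exon-9 evidence (one `present` carrier) and deletion
bands (4 carriers). Duplication flags are false for all 70: the source
does not identify the two duplication carriers, and the flag enters no
frequency computation. A guard rejects count sets not summing to 70.

Because the simulator and the caller share the rendering model, the
round-trip tests demonstrate internal consistency of the calling rules,
not robustness to real-world assay artefacts (allele dropout,
cross-reactivity, clustering errors); the no-call mechanism is uniform
per locus, unlike real missingness which concentrates in specific
assays.

## Problem sizes and numerical choices

The default test suite and the acceptance script use the 70-sample
reconstruction, 1,000 randomized samples for oracle equivalence, a
5,000-sample simulation for parameter recovery (±0.02 band), and 100
alignment replicates at 1,101 bases; the whole suite runs in a few
seconds on one CPU. Exact-test p-values are compared to the oracle at
1e-9; frequency identities at 1e-12. Presentation rounding (two decimals
for allele/SNP frequencies, three for diplotype frequencies) happens
only at serialization; all internal arithmetic is full precision.

## Known limitations

* The allele universe is the six-allele panel, not the full nomenclature
  catalog (>100 alleles); profiles outside the universe surface as
  `inconsistent`, never as novel-allele calls.
* No phasing from population linkage disequilibrium; ambiguity is
  reported, not resolved statistically (priors only rank, and only when
  survivors are already plural).
* Copy number is observed but never quantified; allele-specific
  duplication assignment is explicitly out of scope.
* Frequencies carry no confidence intervals, mirroring the descriptive
  style of the surveys the panel fixture transcribes.
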