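# Methods

## Scope and data model

The pipeline consumes a multi-sample VCF (one case plus a control
panel), a reference FASTA, single-transcript gene models from GFF3, a
6-column PED pedigree, a candidate-gene list, and optional marker and
primer tables. Coordinates are 1-based with closed intervals throughout;
genotypes are unphased diploid autosomal calls (haploid and >2-allele
calls are rejected; phase separators are accepted and ignored).
Multi-allelic sites are split on read into one record per alternate
allele, with any *other* alternate allele recoded as reference — the
private filter is defined per allele, and a control carrying a different
allele at the same site does not contradict absence of the allele under
test.

## Variant normalization and the 3′ rule

Every variant is reduced to the parsimonious, left-aligned VCF form (one
anchor base for indels) and, independently, shifted to the most 3′
equivalent placement. Both placements are retained because they are both
meaningful: short-read pipelines and genome browsers display the
left-aligned form, while nomenclature follows the 3′ rule, and for an
indel inside a repeat tract the two disagree by the length of the tract.
An insertion is flagged as a duplication when, after 3′ shifting, the
inserted string equals the reference sequence immediately 5′ of the
insertion point. Normalization is validated against a brute-force oracle
that enumerates every placement reproducing the identical mutant
sequence; idempotence and edit preservation are property-tested.

## Consequence calling

For a variant overlapping a CDS, the edit is projected into transcript
coordinates (strand-aware), 3′-shifted again along the CDS string, and
applied; wild-type and mutant CDS are translated and compared. CDS
membership of an indel is decided at its 3′-most placement in transcript
orientation (the HGVS convention; on the minus strand this is the
left-aligned genomic placement). Categories follow the translation
comparison: synonymous, missense, stop_gained, stop_lost, start_lost,
inframe insertion/deletion, frameshift. Conventions chosen where the
comparison is ambiguous:

- indels touching the start codon are `start_lost` regardless of frame
  (the translation-comparison oracle is undefined there);
- an inframe indel whose new codons include a premature stop is
  `stop_gained`;
- frameshifted sequence is translated only to the end of the annotated
  CDS — no 3′ UTR read-through is modeled. If no stop appears, the
  protein change is reported `fs*?` and no truncation fraction is given;
- frameshift protein names count the new stop *including* the stop
  codon, with the first changed residue named: three novel residues then
  a stop is `fs*4`. (The alternative convention that excludes the stop
  would print `fs*3` for the same molecule; this package uses the
  stop-inclusive form exclusively.)
- variants spanning a CDS/intron boundary raise an unsupported-variant
  error and are reported in a failure list, never dropped silently;
  variants within 2 bp of a CDS boundary carry a `near_splice` flag but
  are categorized by CDS overlap only — splice-site prediction is out of
  scope.

The truncation fraction of a premature stop is
`1 − len(mutant protein)/len(wild-type protein)`, stop codons excluded
from both lengths.

Consequence calls are cross-checked on thousands of random planted CDS
variants per strand against an independent oracle that rebuilds the
whole mutant chromosome, shifts the annotation intervals, re-extracts
and translates the CDS.

## Filter cascade

Row 1 counts the case-carried variants (case 0/1 or 1/1), split by the
case genotype into the het/hom columns; sites where the case is 0/0 or
./. never enter the cascade. A configurable `row1="all"` reading
additionally counts case hom-ref calls in the homozygous column; the
default is the case-carried reading. Row 2 applies the private filter
(all controls 0/0 or ./.; missing control genotypes explicitly do not
contradict privacy, missing case genotypes exclude the variant). Row 3
intersects with protein-changing consequences (missense, frameshift,
stop gain/loss, start loss, inframe indel). Row 4 intersects with the
candidate-gene panel by exact case-insensitive symbol match; a variant
overlapping several genes is kept if any overlapping gene is a
candidate.

## Cosegregation

Under the fully penetrant autosomal-recessive model, perfection requires
(a) every genotyped affected 1/1, (b) no genotyped unaffected 1/1,
(c) every genotyped obligate carrier — a parent of an affected — 0/1,
and (d) no Mendelian-impossible parent–offspring transmission.
Individuals of unknown affection are exempt from (a)/(b) but checked for
(d); ungenotyped parents are skipped, not imputed. No cosegregation
LOD or probability is computed — the claim is perfect/not-perfect — but
the number of informative meioses (genotyped parent–child transmissions)
is reported descriptively. The Mendelian check is validated against an
exhaustive enumeration of all 27 trio genotype combinations.

## ACMG-lite engine

Three criteria are computed from data: PVS1 (category ∈ {frameshift,
stop_gained, start_lost, stop_lost} in a gene flagged as having a known
loss-of-function disease mechanism; very strong), PM2 (zero alternate
alleles across a control panel of at least `min_controls` = 50 genomes;
missing genotypes are not observations; moderate), PP1 (perfect
cosegregation with ≥2 genotyped affected; supporting). Strengths are
overridable by configuration only. The combiner implements the full
consensus pathogenic and likely-pathogenic rule lists; one rule was
added beyond the original list — two or more very-strong items classify
as pathogenic — because without it the label is not monotone in added
evidence (e.g. {VS,VS,M} would score below {VS,M}), and monotonicity is
an invariant of this engine. Benign-evidence criteria are not
implemented; the classification therefore assumes absence of benign
evidence.

## Synthetic cohort

The generator emulates the study design: one chromosome (~73 kb) with 20
candidate and 30 background genes, a 31-cat pedigree (1 sire, 3 dams, 3
litters of 9, 4 affected kittens), 77 WGS controls, and a 16-locus
microsatellite panel. Candidate gene 1 (plus strand, 1211-aa protein) is
engineered so a C duplicated at the 3′ end of a poly-C run (default
length 6, ending at c.698) changes Ser235→Gln and terminates after two
further novel residues (`c.698dup`, `p.(Ser235Glnfs*4)`, truncation
0.804). Candidate gene 2 (minus strand, 1365-aa protein) carries the
decoy context CGA→CAA at codon 795 (`c.2384G>A`, `p.(Arg795Gln)`). The
causal VCF record is emitted left-aligned at the run start to force the
annotator's 3′ shift. The study-family template assigns causal genotypes
deterministically — parents het, offspring 4 hom-alt (the affected), 16
het, 7 hom-ref — and decoy genotypes such that the case is het and four
unaffected littermates are hom-alt, so the decoy survives the control
filter but fails cosegregation.

Background variation is biallelic SNVs at positions drawn without
replacement, with control allele frequencies from Beta(4, 8) (mean
0.33). The background deliberately models *shared* panel polymorphism:
the private-variant class is represented by the planted variants. At
genome scale, case-private background exists in bulk but essentially
never lands in candidate-gene CDS (candidate CDS is ~0.1% of a 2.4 Gb
genome); in the mini genome candidate CDS is ~30% of the sequence, so a
rare-skewed frequency distribution would fabricate private
protein-changing candidate-gene hits that the full-scale analysis would
not see. With the common-allele default, the planted duplication is
recovered as the sole homozygous endpoint in 50/50 seeds. Control and
family genotypes are Hardy–Weinberg draws and Mendelian gene drops
respectively; 2% genotype missingness applies to controls everywhere and
to family members at background sites, never to the case and never to
family genotypes at the planted sites (those stand in for the complete
Sanger genotyping of the family). All randomness flows through one
seeded generator with a fixed draw order; identical config and seed give
byte-identical output files.

What a green test does not establish: the generator has no linkage
disequilibrium, no demography or relatedness among controls, no
sequencing error, no indel background, no multi-transcript genes and no
marker mutation, so the pipeline's behavior on those real-data features
is untested here.

## Confirmation

In-silico PCR uses exact full-length primer matching on both
orientations, reporting every pairing within `max_product`; amplicon
length counts both primers. Mismatch tolerance is a deliberate non-goal
(the emulated assay used a unique product under standard conditions).
The pipeline auto-designs a flanking pair sized to a 169 bp wild-type
product, so the variant-applied haplotype yields 170 bp — the wild-type/
mutant size relationship used for genotyping. Parentage exclusion
excludes a single candidate parent at a locus when offspring and
candidate share no allele, and a parent pair when no assignment of one
offspring allele to each parent is consistent; missing loci are skipped
and not counted. Microsatellite mutation is not modeled, so a zero
exclusion threshold is appropriate; with real markers a one-step
mutation allowance would be needed.

## Orchestration

`run-all` executes simulate → annotate → filter → coseg → classify →
confirm with stage-scoped logging and distinct exit codes per failing
stage. The summary JSON contains the cascade table, HGVS strings,
segregation verdicts for every final-row survivor, ACMG evidence and
classification, amplicon lengths, parentage verdicts and MD5 checksums
of every artifact; it contains no timestamps, so runs are byte-identical
under a fixed seed. Configuration is a flat YAML file; command-line
flags override it.
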