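# felvar

Rare-disease variant prioritization for small pedigrees, built around the
workflow that identifies a recessive causal allele in a single sequenced
case: a feline family segregating the dermatosparaxis type of
Ehlers–Danlos syndrome (dEDS), in which loss of the procollagen
N-proteinase ADAMTS2 leaves skin collagen uncleaved and fragile. The
package re-implements that analysis as a tested, reusable pipeline and
ships a synthetic cohort generator so every stage runs end to end with no
external data.

## What it computes

**Hard-filter cascade.** With one affected case *c* and a control panel
*K* (77 genomes by default), a variant *v* is *private* iff

```
GT_c(v) ∈ {0/1, 1/1}   and   GT_k(v) ∈ {0/0, ./.} for all k ∈ K
```

The cascade tabulates, split by the case genotype (het / hom columns):
all case-carried variants → private variants → protein-changing private
variants → protein-changing private variants in functional candidate
genes (a 20-gene panel by default).

**Consequence annotation with the HGVS 3′ rule.** Variants are reduced to
a parsimonious left-aligned VCF form (what aligners and IGV show) and
additionally shifted to their most 3′ equivalent placement in transcript
orientation. For an insertion inside a repeat tract these differ: a 1-bp
duplication in a CDS poly-C run left-aligns to the run start but is named
at the run's 3′ end (e.g. `c.698dup`). Consequences are called by editing
the coding sequence and translating: a frameshift's protein name
`p.(Ser235Glnfs*4)` counts the first changed residue (Ser235→Gln) and the
new stop, stop included. The ORF truncation fraction is
`1 − len(mutant)/len(wild-type)` over stop-excluded protein lengths.

**Cosegregation (autosomal recessive, fully penetrant).** Perfect iff all
genotyped affected are 1/1, no genotyped unaffected is 1/1, every
genotyped obligate carrier (parent of an affected) is 0/1, and no
parent–offspring transmission is Mendelian-impossible.

**ACMG-lite classification.** PVS1 (null variant in a LOF-mechanism
gene, very strong), PM2 (allele absent from ≥50 controls, moderate) and
PP1 (perfect cosegregation with ≥2 affected, supporting) are computed
from the pipeline's own outputs and combined with the consensus
pathogenic / likely-pathogenic combining rules.

**Confirmation support.** Exact-match in-silico PCR predicts genotyping
amplicon sizes on the reference and on the variant-applied haplotype;
microsatellite parentage exclusion tests candidate parents by allele
sharing across a 16-locus panel.

## Worked example

```bash
felvar run-all --outdir run --seed 1
```

simulates the default cohort (one case + 77 controls + a 31-cat family
with 4 affected kittens, a causal homozygous 1-bp duplication planted in
the poly-C run of candidate gene 1 and a decoy heterozygous missense in
candidate gene 2), then annotates, filters, checks segregation,
classifies and confirms. It prints `classification: pathogenic` and
writes `run/summary.json` containing, for seed 1:

| Filtering step | Het | Hom |
|---|---|---|
| All variants in the sequenced case | 792 | 253 |
| Private variants | 1 | 1 |
| Protein-changing private variants | 1 | 1 |
| Protein-changing private variants in functional candidate genes | 1 | 1 |

The homozygous survivor is annotated `c.698dup` /
`p.(Ser235Glnfs*4)` with ORF truncation 0.804: the duplication is
reported at the 3′ end of the poly-C run even though the VCF record is
left-aligned at its start. Its family genotypes tabulate 4 affected
hom-alt / 20 het / 7 hom-ref across the 31 cats with a perfect
cosegregation verdict, so PVS1 + PM2 + PP1 all trigger and combine to
*pathogenic*. The decoy missense survives the cascade too (the het cell)
but fails cosegregation with 4 unaffected homozygotes. In-silico PCR on
an auto-designed flanking primer pair yields a 169 bp wild-type and a
170 bp mutant product, and the sire's paternity is compatible at all 16
marker loci for each affected kitten.

Every stage is also exposed as a subcommand (`simulate`, `annotate`,
`filter`, `coseg`, `classify`, `pcr`, `parentage`) over the files the
simulator writes.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic cohort from the given seed and
recomputes, from scratch: the homozygous count of the final cascade row,
and the number of triggered ACMG evidence criteria for the causal
variant (verifying that they combine to the pathogenic label). Results
are written as JSON keyed by target id.

## Layout

- `src/felvar/` — `io` (FASTA/VCF/GFF3/PED/TSV), `simulate`, `annotate`,
  `filtering`, `segregation`, `acmg`, `confirm`, `pipeline`, `cli`
- `tests/` — unit and property tests, including brute-force oracles for
  normalization, consequence calling, the private filter and Mendelian
  checks
- `docs/methods.md` — model assumptions, parameter defaults, and known
  limitations
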