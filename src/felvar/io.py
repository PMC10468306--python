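"""Readers and writers for every external format the pipeline touches.

Parsing of the standard formats is delegated to pysam (VCF), gffutils
(GFF3) and Biopython (FASTA); serialization is plain deterministic text so
that identical in-memory data always produces byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

from .errors import FormatError, ValidationError
from .models import (
    Affection,
    GeneModel,
    GenotypeCall,
    Individual,
    Pedigree,
    ReferenceGenome,
    Sex,
    VariantRecord,
)

# ---------------------------------------------------------------- FASTA


def read_fasta(path) -> ReferenceGenome:
    """Load a FASTA file into a :class:`ReferenceGenome` (uppercased)."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate FASTA header {record.id!r}")
        sequences[record.id] = str(record.seq)
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    try:
        return ReferenceGenome(sequences)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fasta(path, genome: ReferenceGenome, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------------------ VCF


def _recode_gt(
    alleles: tuple, alt_index: int, n_alts: int, context: str
) -> GenotypeCall:
    """Recode a raw GT tuple against one alternate allele.

    Any *other* alternate allele counts as reference: for the privacy
    filter a control carrying a different allele at the site does not
    contradict absence of this one.
    """
    if all(a is None for a in alleles):
        return GenotypeCall.MISSING
    if len(alleles) != 2:
        raise FormatError(f"{context}: only diploid genotype calls are supported")
    if any(a is None for a in alleles):
        # pysam yields None for out-of-range allele indices and half-calls
        raise FormatError(
            f"{context}: GT allele index out of range or partially missing call"
        )
    for a in alleles:
        if not 0 <= a <= n_alts:
            raise FormatError(f"{context}: GT allele index {a} out of range")
    coded = [1 if a == alt_index else 0 for a in alleles]
    return GenotypeCall.from_alleles(coded[0], coded[1])


def read_vcf(path) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF v4.2, splitting multi-allelic sites per alternate allele.

    Returns records in file order (split records stay adjacent, in ALT
    order) together with the ordered sample list.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse VCF: {exc}") from exc
    samples = list(vcf.header.samples)
    records: list[VariantRecord] = []
    for rec in vcf:
        context = f"{path}:{rec.chrom}:{rec.pos}"
        if "GT" not in rec.format:
            raise FormatError(f"{context}: record has no GT field")
        alts = rec.alts or ()
        raw = {s: rec.samples[s].get("GT", (None, None)) for s in samples}
        for alt_index, alt in enumerate(alts, start=1):
            if alt is None or set(alt) - set("ACGTN"):
                raise FormatError(f"{context}: unsupported ALT allele {alt!r}")
            genotypes = {
                s: _recode_gt(raw[s], alt_index, len(alts), context) for s in samples
            }
            records.append(
                VariantRecord(rec.chrom, rec.pos, rec.ref.upper(), alt.upper(), genotypes)
            )
    vcf.close()
    return records, samples


def write_vcf(
    path,
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    contigs: Optional[Mapping[str, int]] = None,
) -> None:
    """Serialize biallelic records as a minimal GT-only VCF v4.2."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(samples)
    lines.append("\t".join(header))
    for v in records:
        row = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", ".", ".", "GT"]
        row.extend(v.genotypes.get(s, GenotypeCall.MISSING).value for s in samples)
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ PED

_PED_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}
_PED_AFF = {"1": Affection.UNAFFECTED, "2": Affection.AFFECTED}


def read_ped(path) -> Pedigree:
    """Read a 6-column PED file (fam, id, sire, dam, sex, phenotype)."""
    path = Path(path)
    individuals = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
        _fam, iid, sire, dam, sex, pheno = fields[:6]
        individuals.append(
            Individual(
                id=iid,
                sire=None if sire == "0" else sire,
                dam=None if dam == "0" else dam,
                sex=_PED_SEX.get(sex, Sex.UNKNOWN),
                affection=_PED_AFF.get(pheno, Affection.UNKNOWN),
            )
        )
    return Pedigree(individuals)


def write_ped(path, pedigree: Pedigree, family_id: str = "FAM1") -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_code = {Affection.UNAFFECTED: "1", Affection.AFFECTED: "2", Affection.UNKNOWN: "0"}
    lines = []
    for ind in pedigree:
        lines.append(
            "\t".join(
                [
                    family_id,
                    ind.id,
                    ind.sire or "0",
                    ind.dam or "0",
                    sex_code[ind.sex],
                    aff_code[ind.affection],
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------- GFF3


def read_gff3(path, genome: Optional[ReferenceGenome] = None) -> list[GeneModel]:
    """Read gene models (one transcript each) from GFF3.

    CDS intervals are returned in transcript (5'->3') order.  When a
    genome is supplied, soft coding checks (start/stop codon, internal
    stops) emit warnings without failing.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="error", keep_order=True
        )
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse GFF3: {exc}") from exc
    models = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        intervals = [(c.start, c.end) for c in cds]
        if mrna.strand == "-":
            intervals = intervals[::-1]
        gene_name = mrna.attributes.get("gene", [None])[0]
        if gene_name is None:
            parents = list(db.parents(mrna, featuretype="gene"))
            gene_name = (
                parents[0].attributes.get("Name", [parents[0].id])[0]
                if parents
                else mrna.id
            )
        model = GeneModel(
            gene=gene_name,
            transcript=mrna.id,
            chrom=mrna.seqid,
            strand=mrna.strand,
            cds_intervals=intervals,
        )
        if genome is not None:
            model.validate_coding(genome)
        models.append(model)
    return models


def write_gff3(path, models: Sequence[GeneModel]) -> None:
    lines = ["##gff-version 3"]
    for m in models:
        start, end = m.span
        gid, tid = f"gene:{m.gene}", m.transcript
        lines.append(
            f"{m.chrom}\tfelvar\tgene\t{start}\t{end}\t.\t{m.strand}\t.\t"
            f"ID={gid};Name={m.gene}"
        )
        lines.append(
            f"{m.chrom}\tfelvar\tmRNA\t{start}\t{end}\t.\t{m.strand}\t.\t"
            f"ID={tid};Parent={gid};gene={m.gene}"
        )
        # phase: number of bases to skip to reach the next codon start
        phase, n = {}, 0
        for s, e in m.cds_intervals:
            phase[(s, e)] = (3 - n % 3) % 3
            n += e - s + 1
        for i, (s, e) in enumerate(sorted(m.cds_intervals), start=1):
            lines.append(
                f"{m.chrom}\tfelvar\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase[(s, e)]}\t"
                f"ID=cds:{tid}.{i};Parent={tid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------- small TSV/text


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; '#' starts a comment."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    return symbols


def write_gene_list(path, symbols: Sequence[str]) -> None:
    Path(path).write_text("\n".join(symbols) + "\n")


def read_tsv_table(path, schema: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a TSV with a header row, optionally enforcing required columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
    return df


MarkerGenotypes = dict[str, dict[str, Optional[tuple[int, int]]]]


def read_markers(path) -> MarkerGenotypes:
    """Read a wide microsatellite table: 'sample' column + one column per locus.

    Genotypes are 'a/b' integer allele pairs; '.' marks a missing locus.
    """
    df = read_tsv_table(path, schema=["sample"])
    loci = [c for c in df.columns if c != "sample"]
    table: MarkerGenotypes = {}
    for _, row in df.iterrows():
        genos: dict[str, Optional[tuple[int, int]]] = {}
        for locus in loci:
            cell = row[locus]
            if pd.isna(cell) or cell in (".", "./."):
                genos[locus] = None
            else:
                try:
                    a, b = (int(x) for x in str(cell).split("/"))
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: bad marker genotype {cell!r} for {row['sample']}"
                    ) from exc
                genos[locus] = (a, b)
        table[str(row["sample"])] = genos
    return table


def write_markers(path, table: MarkerGenotypes) -> None:
    samples = list(table)
    loci = list(next(iter(table.values()))) if table else []
    lines = ["\t".join(["sample"] + loci)]
    for s in samples:
        cells = [s]
        for locus in loci:
            g = table[s][locus]
            cells.append("." if g is None else f"{g[0]}/{g[1]}")
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def write_json_report(path, payload: dict) -> None:
    """Deterministic JSON serialization (sorted keys, fixed separators)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
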