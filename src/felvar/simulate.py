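"""Synthetic study stand-in: mini genome, gene models, pedigree, cohort VCF.

The generator emulates the design of the original investigation: one
affected kitten sequenced against a 77-genome control panel, a 20-gene
functional candidate panel, and an extended family of 31 cats (one sire,
three dams, three litters, four affected kittens).  Two variants are
planted in candidate genes:

* the causal allele — a homozygous 1-bp duplication inside a CDS poly-C
  homopolymer of candidate gene 1, engineered so that its 3'-shifted HGVS
  name is c.698dup / p.(Ser235Glnfs*4) on a 1211-aa wild-type protein;
  the VCF record is emitted left-aligned (anchor base before the run),
  the representation short-read pipelines produce, to force downstream
  3'-shifting;
* a decoy heterozygous missense in candidate gene 2 (minus strand),
  engineered as c.2384G>A / p.(Arg795Gln); it is private to the case with
  respect to the controls but fails cosegregation in the family, where
  four unaffected cats are homozygous for it.

Background variation is biallelic SNVs with control allele frequencies
drawn from a Beta distribution.  All randomness flows through a single
seeded generator; the draw order is fixed (documented in
:func:`plant_variants`) so identical config + seed gives byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import GenerationError, SizingError, ValidationError
from .io import (
    write_fasta,
    write_gene_list,
    write_gff3,
    write_json_report,
    write_markers,
    write_ped,
    write_vcf,
)
from .models import (
    Affection,
    GeneModel,
    GenotypeCall,
    Individual,
    Pedigree,
    ReferenceGenome,
    Sex,
    VariantRecord,
    reverse_complement,
)

CHROM = "chrA1"

_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world; defaults mirror the emulated study."""

    seed: int = 1
    n_controls: int = 77  # WGS control panel size
    n_genotyping_controls: int = 48  # unrelated cats in the Sanger panel
    n_candidate_genes: int = 20
    n_background_genes: int = 30
    n_background_variants: int = 2000
    # background variants model *shared* panel polymorphism (the planted
    # variants model the private class); a common-allele Beta keeps the
    # mini genome's 30%-candidate-CDS scale from fabricating private
    # protein-changing candidate-gene hits that a 2.4 Gb genome would not
    control_allele_freq_beta: tuple[float, float] = (4.0, 8.0)
    missing_genotype_rate: float = 0.02
    homopolymer_length: int = 6
    pedigree_template: str = "study_family"
    litter_sizes: tuple[int, ...] = (9, 9, 9)
    max_chrom_length: int = 500_000

    def __post_init__(self):
        if not 0.0 <= self.missing_genotype_rate <= 1.0:
            raise ValidationError("missing_genotype_rate must be in [0, 1]")
        if self.homopolymer_length < 4:
            raise ValidationError("homopolymer_length must be >= 4")
        if self.homopolymer_length > 100:
            raise ValidationError("homopolymer_length must be <= 100")
        for name in (
            "n_controls",
            "n_genotyping_controls",
            "n_candidate_genes",
            "n_background_genes",
            "n_background_variants",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_candidate_genes < 2:
            raise ValidationError("need >= 2 candidate genes to plant both variants")
        if self.pedigree_template not in ("study_family", "custom"):
            raise ValidationError(
                f"unknown pedigree_template {self.pedigree_template!r}"
            )
        a, b = self.control_allele_freq_beta
        if a <= 0 or b <= 0:
            raise ValidationError("Beta parameters must be positive")


@dataclass
class PlantedTruth:
    """Ground truth of the planted scenario, for oracle-style checks."""

    causal: dict
    decoy: dict
    causal_genotypes: dict[str, str]
    case_id: str
    control_ids: list[str]

    def as_dict(self) -> dict:
        return {
            "causal": self.causal,
            "decoy": self.decoy,
            "causal_genotypes": self.causal_genotypes,
            "case_id": self.case_id,
            "control_ids": self.control_ids,
        }


# ----------------------------------------------------------- CDS builders

# Engineered context downstream of the poly-C run (CDS positions 699-714).
# With the run ending at c.698, duplicating one C gives: codons 233/234
# unchanged (CCN->CCC Pro, GGC->GGG Gly), codon 235 Ser(AGC)->Gln(CAG),
# two further novel residues, then a new stop at mutant codon 238 -> fs*4.
_CAUSAL_DOWNSTREAM = "GGGCAGCTTACATAAA"  # c.699..714
_CAUSAL_RUN_END = 698
_CAUSAL_PROTEIN_AA = 1211  # true feline ADAMTS2 length; truncation ~0.80

_DECOY_PROTEIN_AA = 1365  # COL1A2-scale protein
_DECOY_CODON = 795  # CGA (Arg) -> c.2384G>A -> CAA (Gln)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random stop-free codons + TAA (n_codons includes start & stop)."""
    body = rng.choice(_NON_STOP_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def _engineer_causal_cds(rng: np.random.Generator, run_length: int) -> str:
    cds = list(_random_cds(rng, _CAUSAL_PROTEIN_AA + 1))
    run_start = _CAUSAL_RUN_END - run_length + 1  # 1-based
    pre = run_start - 1  # base immediately 5' of the run; must not be C
    for i in range(run_start, _CAUSAL_RUN_END + 1):
        cds[i - 1] = "C"
    for i, base in enumerate(_CAUSAL_DOWNSTREAM):
        cds[_CAUSAL_RUN_END + i] = base
    placed = False
    for candidate in "AGT":
        cds[pre - 1] = candidate
        codon_start = 3 * ((pre - 1) // 3)
        codon = "".join(cds[codon_start : codon_start + 3])
        if codon not in ("TAA", "TAG", "TGA"):
            placed = True
            break
    if not placed:  # pragma: no cover - at least one of A/G/T always works
        raise GenerationError("could not place homopolymer boundary base")
    return "".join(cds)


def _engineer_decoy_cds(rng: np.random.Generator) -> str:
    cds = list(_random_cds(rng, _DECOY_PROTEIN_AA + 1))
    start = 3 * (_DECOY_CODON - 1)
    cds[start : start + 3] = "CGA"
    return "".join(cds)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _split_lengths(total: int, n_parts: int, rng: np.random.Generator) -> list[int]:
    """Split a CDS length into n exon lengths, each >= 30 bases."""
    if n_parts == 1 or total < 60 * n_parts:
        return [total]
    cuts = sorted(rng.choice(np.arange(30, total - 30), size=n_parts - 1, replace=False))
    cuts = [0] + list(cuts) + [total]
    lengths = [b - a for a, b in zip(cuts, cuts[1:])]
    if min(lengths) < 30:
        return [total]
    return lengths


def simulate_reference(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[ReferenceGenome, list[GeneModel], list[str]]:
    """One chromosome carrying candidate + background genes.

    Candidate gene 1 (plus strand) holds the engineered homopolymer; gene 2
    (minus strand) the decoy missense context.  Remaining genes are random
    stop-free open reading frames split into 1-4 exons on random strands.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    candidate_names = [f"CAND{i:02d}" for i in range(1, config.n_candidate_genes + 1)]
    background_names = [f"BG{i:02d}" for i in range(1, config.n_background_genes + 1)]

    chunks: list[str] = []
    cursor = 0  # length so far
    models: list[GeneModel] = []

    def emit(seq: str) -> tuple[int, int]:
        nonlocal cursor
        chunks.append(seq)
        start = cursor + 1
        cursor += len(seq)
        return start, cursor

    for idx, name in enumerate(candidate_names + background_names):
        emit(_random_dna(rng, int(rng.integers(200, 500))))  # intergenic gap
        if name == "CAND01":
            cds = _engineer_causal_cds(rng, config.homopolymer_length)
            strand = "+"
            exon_lengths = [900, 900, 900, len(cds) - 2700]
        elif name == "CAND02":
            cds = _engineer_decoy_cds(rng)
            strand = "-"
            exon_lengths = [1000, 1000, 1000, len(cds) - 3000]
        else:
            n_codons = int(rng.integers(120, 400))
            cds = _random_cds(rng, n_codons)
            strand = "+" if rng.random() < 0.5 else "-"
            exon_lengths = _split_lengths(len(cds), int(rng.integers(1, 5)), rng)

        exons = []
        off = 0
        for L in exon_lengths:
            exons.append(cds[off : off + L])
            off += L
        genomic_exons = exons if strand == "+" else [reverse_complement(e) for e in exons[::-1]]
        intervals = []
        for i, piece in enumerate(genomic_exons):
            if i:
                emit(_random_dna(rng, int(rng.integers(80, 200))))  # intron
            intervals.append(emit(piece))
        if strand == "-":
            intervals = intervals[::-1]
        models.append(
            GeneModel(
                gene=name,
                transcript=f"{name}.t1",
                chrom=CHROM,
                strand=strand,
                cds_intervals=intervals,
            )
        )
    emit(_random_dna(rng, 300))
    if cursor > config.max_chrom_length:
        raise SizingError(
            f"simulated chromosome ({cursor} bp) exceeds max_chrom_length "
            f"({config.max_chrom_length} bp): fewer/smaller genes required"
        )
    genome = ReferenceGenome({CHROM: "".join(chunks)})
    return genome, models, candidate_names


# --------------------------------------------------------------- pedigree

_HOM, _HET, _REF = GenotypeCall.HOM_ALT, GenotypeCall.HET, GenotypeCall.HOM_REF

# Study-family template: 1 sire x 3 dams, 3 litters of 9, 31 cats total,
# 4 affected.  Causal genotypes reproduce the published tabulation
# (4 hom-alt affected / 20 het / 7 hom-ref); the decoy column leaves four
# unaffected littermates homozygous for the decoy allele.
_STUDY_FAMILY: list[tuple[str, Optional[str], Optional[str], Sex, GenotypeCall, GenotypeCall]] = [
    # id, sire, dam, sex, causal gt, decoy gt
    ("SIRE", None, None, Sex.MALE, _HET, _HET),
    ("DAM1", None, None, Sex.FEMALE, _HET, _HET),
    ("DAM2", None, None, Sex.FEMALE, _HET, _REF),
    ("DAM3", None, None, Sex.FEMALE, _HET, _REF),
    ("L1K1", "SIRE", "DAM1", Sex.MALE, _HOM, _HET),  # the sequenced case
    ("L1K2", "SIRE", "DAM1", Sex.FEMALE, _HOM, _HET),
    ("L1K3", "SIRE", "DAM1", Sex.MALE, _HET, _HOM),
    ("L1K4", "SIRE", "DAM1", Sex.FEMALE, _HET, _HOM),
    ("L1K5", "SIRE", "DAM1", Sex.MALE, _HET, _HOM),
    ("L1K6", "SIRE", "DAM1", Sex.FEMALE, _HET, _HOM),
    ("L1K7", "SIRE", "DAM1", Sex.MALE, _HET, _REF),
    ("L1K8", "SIRE", "DAM1", Sex.FEMALE, _REF, _HET),
    ("L1K9", "SIRE", "DAM1", Sex.MALE, _REF, _REF),
    ("L2K1", "SIRE", "DAM2", Sex.FEMALE, _HOM, _HET),
    ("L2K2", "SIRE", "DAM2", Sex.MALE, _HET, _REF),
    ("L2K3", "SIRE", "DAM2", Sex.FEMALE, _HET, _HET),
    ("L2K4", "SIRE", "DAM2", Sex.MALE, _HET, _REF),
    ("L2K5", "SIRE", "DAM2", Sex.FEMALE, _HET, _HET),
    ("L2K6", "SIRE", "DAM2", Sex.MALE, _HET, _REF),
    ("L2K7", "SIRE", "DAM2", Sex.FEMALE, _REF, _HET),
    ("L2K8", "SIRE", "DAM2", Sex.MALE, _REF, _REF),
    ("L2K9", "SIRE", "DAM2", Sex.FEMALE, _REF, _HET),
    ("L3K1", "SIRE", "DAM3", Sex.MALE, _HOM, _HET),
    ("L3K2", "SIRE", "DAM3", Sex.FEMALE, _HET, _REF),
    ("L3K3", "SIRE", "DAM3", Sex.MALE, _HET, _HET),
    ("L3K4", "SIRE", "DAM3", Sex.FEMALE, _HET, _REF),
    ("L3K5", "SIRE", "DAM3", Sex.MALE, _HET, _HET),
    ("L3K6", "SIRE", "DAM3", Sex.FEMALE, _HET, _REF),
    ("L3K7", "SIRE", "DAM3", Sex.MALE, _HET, _HET),
    ("L3K8", "SIRE", "DAM3", Sex.FEMALE, _REF, _REF),
    ("L3K9", "SIRE", "DAM3", Sex.MALE, _REF, _HET),
]

CASE_ID = "L1K1"


def simulate_pedigree(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[Pedigree, dict[str, GenotypeCall], dict[str, GenotypeCall]]:
    """Pedigree plus per-individual causal and decoy genotype assignments.

    The ``study_family`` template is fully deterministic; ``custom`` keeps
    the 1-sire/3-dam structure with configurable litter sizes and assigns
    genotypes by Mendelian gene drop from carrier-by-construction parents.
    """
    if config.pedigree_template == "study_family":
        individuals, causal, decoy = [], {}, {}
        for iid, sire, dam, sex, c_gt, d_gt in _STUDY_FAMILY:
            affection = (
                Affection.AFFECTED if c_gt is _HOM else Affection.UNAFFECTED
            )
            individuals.append(Individual(iid, sire, dam, sex, affection))
            causal[iid] = c_gt
            decoy[iid] = d_gt
        return Pedigree(individuals), causal, decoy

    if rng is None:
        rng = np.random.default_rng(config.seed)
    individuals, causal, decoy = [], {}, {}
    founders = [("SIRE", Sex.MALE)] + [
        (f"DAM{i}", Sex.FEMALE) for i in range(1, len(config.litter_sizes) + 1)
    ]
    founder_alleles: dict[str, tuple[int, int]] = {}
    for iid, sex in founders:
        founder_alleles[iid] = (0, 1)  # obligate carriers by construction
        individuals.append(Individual(iid, None, None, sex, Affection.UNAFFECTED))
        causal[iid] = _HET
        decoy[iid] = _REF
    alleles = dict(founder_alleles)
    for li, size in enumerate(config.litter_sizes, start=1):
        dam = f"DAM{li}"
        for ki in range(1, size + 1):
            iid = f"L{li}K{ki}"
            a = alleles["SIRE"][rng.integers(0, 2)]
            b = alleles[dam][rng.integers(0, 2)]
            alleles[iid] = (a, b)
            gt = GenotypeCall.from_alleles(a, b)
            causal[iid] = gt
            decoy[iid] = _REF
            affection = (
                Affection.AFFECTED if gt is _HOM else Affection.UNAFFECTED
            )
            sex = Sex.MALE if ki % 2 else Sex.FEMALE
            individuals.append(Individual(iid, "SIRE", dam, sex, affection))
    return Pedigree(individuals), causal, decoy


# ---------------------------------------------------------------- variants


def _find_run(cds: str, run_length: int) -> int:
    """1-based CDS start of the first C-homopolymer of exactly run_length."""
    target = "C" * run_length
    i = cds.find(target)
    while i >= 0:
        left_ok = i == 0 or cds[i - 1] != "C"
        right_ok = i + run_length >= len(cds) or cds[i + run_length] != "C"
        if left_ok and right_ok:
            return i + 1
        i = cds.find(target, i + 1)
    raise GenerationError(f"no C-homopolymer of length {run_length} in causal CDS")


def plant_variants(
    config: SimulationConfig,
    genome: ReferenceGenome,
    genes: Sequence[GeneModel],
    pedigree: Pedigree,
    causal_genotypes: dict[str, GenotypeCall],
    decoy_genotypes: dict[str, GenotypeCall],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[VariantRecord], list[str], PlantedTruth]:
    """Cohort variant set: two planted variants + Beta-frequency background.

    Draw order (fixed for reproducibility): 1) background positions,
    2) alternate bases, 3) Beta allele frequencies, 4) control genotypes,
    5) family founder alleles, 6) Mendelian drop per offspring in pedigree
    order, 7) control missingness at the planted sites, 8) missingness
    mask over background genotypes.  The case sample is never masked, and
    family genotypes at the two planted sites are never masked (they stand
    in for the complete Sanger genotyping of the family).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    causal_gene, decoy_gene = genes[0], genes[1]
    chrom_seq = genome[CHROM]
    family_ids = pedigree.ids()
    control_ids = [f"CTRL{i:03d}" for i in range(1, config.n_controls + 1)]
    samples = family_ids + control_ids
    case_id = CASE_ID if CASE_ID in pedigree else pedigree.affected()[0].id

    # --- causal 1-bp duplication, emitted left-aligned with anchor base
    cds = causal_gene.cds_sequence(genome)
    run_start_c = _find_run(cds, config.homopolymer_length)
    g_run_start = causal_gene.cds_to_genomic(run_start_c)
    anchor = g_run_start - 1
    anchor_base = chrom_seq[anchor - 1]
    causal_record = VariantRecord(
        CHROM, anchor, anchor_base, anchor_base + "C", {}
    )

    # --- decoy missense (minus-strand gene): c.2384G>A -> genomic C>T
    g_decoy = decoy_gene.cds_to_genomic(3 * (_DECOY_CODON - 1) + 2)
    decoy_ref = chrom_seq[g_decoy - 1]
    decoy_alt = {"C": "T", "G": "A", "A": "G", "T": "C"}[decoy_ref]
    decoy_record = VariantRecord(CHROM, g_decoy, decoy_ref, decoy_alt, {})

    # --- background biallelic SNVs
    n_bg = config.n_background_variants
    forbidden = {anchor, g_decoy}
    candidates = np.setdiff1d(
        np.arange(1, len(chrom_seq) + 1), np.array(sorted(forbidden))
    )
    positions = np.sort(rng.choice(candidates, size=n_bg, replace=False))
    ref_bases = np.array([chrom_seq[p - 1] for p in positions])
    alt_choice = rng.integers(0, 3, size=n_bg)
    others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    alt_bases = np.array(
        [others[r][c] for r, c in zip(ref_bases, alt_choice)]
    )

    a, b = config.control_allele_freq_beta
    freqs = rng.beta(a, b, size=n_bg)
    control_gt = rng.binomial(2, freqs[:, None], size=(n_bg, len(control_ids)))

    founder_ids = [i.id for i in pedigree.founders()]
    fam_alleles: dict[str, np.ndarray] = {}
    for fid in founder_ids:
        fam_alleles[fid] = rng.binomial(1, freqs[:, None], size=(n_bg, 2))
    for child, sire, dam in pedigree.trios():
        pick_s = rng.integers(0, 2, size=n_bg)
        pick_d = rng.integers(0, 2, size=n_bg)
        fam_alleles[child] = np.stack(
            [
                fam_alleles[sire][np.arange(n_bg), pick_s],
                fam_alleles[dam][np.arange(n_bg), pick_d],
            ],
            axis=1,
        )
    fam_gt = {iid: fam_alleles[iid].sum(axis=1) for iid in family_ids}

    # --- missingness
    planted_control_missing = (
        rng.random((2, len(control_ids))) < config.missing_genotype_rate
    )
    maskable = [s for s in samples if s != case_id]
    bg_missing = rng.random((n_bg, len(maskable))) < config.missing_genotype_rate
    bg_missing_lookup = {s: bg_missing[:, j] for j, s in enumerate(maskable)}

    def planted_genotypes(
        family_assignment: dict[str, GenotypeCall], planted_row: int
    ) -> dict[str, GenotypeCall]:
        gts = {iid: family_assignment[iid] for iid in family_ids}
        for j, cid in enumerate(control_ids):
            gts[cid] = (
                GenotypeCall.MISSING
                if planted_control_missing[planted_row, j]
                else GenotypeCall.HOM_REF
            )
        return gts

    causal_record = causal_record.with_genotypes(
        planted_genotypes(causal_genotypes, 0)
    )
    decoy_record = decoy_record.with_genotypes(planted_genotypes(decoy_genotypes, 1))

    records = [causal_record, decoy_record]
    code = {0: GenotypeCall.HOM_REF, 1: GenotypeCall.HET, 2: GenotypeCall.HOM_ALT}
    for k in range(n_bg):
        gts: dict[str, GenotypeCall] = {}
        for iid in family_ids:
            gt = code[int(fam_gt[iid][k])]
            if iid != case_id and bg_missing_lookup[iid][k]:
                gt = GenotypeCall.MISSING
            gts[iid] = gt
        for j, cid in enumerate(control_ids):
            gt = code[int(control_gt[k, j])]
            if bg_missing_lookup[cid][k]:
                gt = GenotypeCall.MISSING
            gts[cid] = gt
        records.append(
            VariantRecord(CHROM, int(positions[k]), str(ref_bases[k]), str(alt_bases[k]), gts)
        )
    records.sort(key=lambda v: (v.pos, v.ref, v.alt))

    truth = PlantedTruth(
        causal={
            "chrom": CHROM,
            "pos": causal_record.pos,
            "ref": causal_record.ref,
            "alt": causal_record.alt,
            "gene": causal_gene.gene,
            "hgvs_genomic_pos": causal_gene.cds_to_genomic(_CAUSAL_RUN_END),
            "hgvs_c": f"c.{_CAUSAL_RUN_END}dup",
        },
        decoy={
            "chrom": CHROM,
            "pos": decoy_record.pos,
            "ref": decoy_record.ref,
            "alt": decoy_record.alt,
            "gene": decoy_gene.gene,
            "hgvs_c": f"c.{3 * (_DECOY_CODON - 1) + 2}G>A",
        },
        causal_genotypes={iid: causal_genotypes[iid].value for iid in family_ids},
        case_id=case_id,
        control_ids=control_ids,
    )
    return records, samples, truth


# ----------------------------------------------------------------- markers


def simulate_markers(
    pedigree: Pedigree,
    n_loci: int = 16,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    extra_unrelated: Sequence[str] = (),
) -> dict[str, dict[str, Optional[tuple[int, int]]]]:
    """Multi-allelic microsatellite genotypes for the pedigree.

    Each locus has 4-10 alleles (integer fragment lengths); founders draw
    from Dirichlet-distributed locus allele frequencies and non-founders
    inherit one allele from each parent.  ``extra_unrelated`` individuals
    are drawn from the founder frequencies, for exclusion experiments.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    loci = [f"MS{i:02d}" for i in range(1, n_loci + 1)]
    table: dict[str, dict[str, Optional[tuple[int, int]]]] = {
        iid: {} for iid in pedigree.ids()
    }
    for extra in extra_unrelated:
        table[extra] = {}
    for locus in loci:
        n_alleles = int(rng.integers(4, 11))
        alleles = 100 + 2 * np.arange(n_alleles)
        freqs = rng.dirichlet(np.ones(n_alleles))
        genos: dict[str, tuple[int, int]] = {}
        for founder in pedigree.founders():
            pair = rng.choice(alleles, size=2, p=freqs)
            genos[founder.id] = (int(pair[0]), int(pair[1]))
        for child, sire, dam in pedigree.trios():
            a = genos[sire][int(rng.integers(0, 2))]
            b = genos[dam][int(rng.integers(0, 2))]
            genos[child] = (a, b)
        for extra in extra_unrelated:
            pair = rng.choice(alleles, size=2, p=freqs)
            genos[extra] = (int(pair[0]), int(pair[1]))
        for iid, pair in genos.items():
            table[iid][locus] = (min(pair), max(pair))
    return table


# ------------------------------------------------------------ full bundle


@dataclass
class CohortBundle:
    config: SimulationConfig
    genome: ReferenceGenome
    genes: list[GeneModel]
    candidate_genes: list[str]
    pedigree: Pedigree
    variants: list[VariantRecord]
    samples: list[str]
    truth: PlantedTruth
    markers: dict = field(default_factory=dict)

    @property
    def case_id(self) -> str:
        return self.truth.case_id

    @property
    def control_ids(self) -> list[str]:
        return self.truth.control_ids


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Run all generator stages with one seeded generator threaded through."""
    rng = np.random.default_rng(config.seed)
    genome, genes, candidates = simulate_reference(config, rng)
    pedigree, causal_gt, decoy_gt = simulate_pedigree(config, rng)
    variants, samples, truth = plant_variants(
        config, genome, genes, pedigree, causal_gt, decoy_gt, rng
    )
    markers = simulate_markers(pedigree, n_loci=16, rng=rng)
    return CohortBundle(
        config, genome, genes, candidates, pedigree, variants, samples, truth, markers
    )


def write_cohort(bundle: CohortBundle, outdir) -> dict[str, Path]:
    """Write every artifact of the bundle; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gff3": outdir / "genes.gff3",
        "vcf": outdir / "cohort.vcf",
        "ped": outdir / "family.ped",
        "markers": outdir / "markers.tsv",
        "candidates": outdir / "candidate_genes.txt",
        "truth": outdir / "truth.json",
    }
    write_fasta(paths["fasta"], bundle.genome)
    write_gff3(paths["gff3"], bundle.genes)
    write_vcf(
        paths["vcf"],
        bundle.variants,
        bundle.samples,
        contigs={CHROM: len(bundle.genome[CHROM])},
    )
    write_ped(paths["ped"], bundle.pedigree)
    write_markers(paths["markers"], bundle.markers)
    write_gene_list(paths["candidates"], bundle.candidate_genes)
    write_json_report(paths["truth"], bundle.truth.as_dict())
    return paths
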