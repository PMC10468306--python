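"""Coding-consequence annotation with HGVS-style 3'-shifting.

A minimal re-implementation of the consequence-prediction step of a
standard short-variant pipeline: variants are first reduced to a
parsimonious, left-aligned VCF form (the representation aligners and IGV
display), then additionally placed at their most 3' equivalent position —
the HGVS convention.  The two placements differ exactly when an indel sits
inside a repeat tract, e.g. a 1-bp duplication in a homopolymer run.

Consequences are called by editing the coding sequence in transcript
coordinates and translating: the mutant protein is compared with the
wild type, which keeps the category definitions honest for edge cases
(a "missense" SNV that creates a stop is stop_gained, a synonymous indel
cannot occur, ...).  Frameshifted sequence is translated only to the end
of the annotated CDS; no 3'UTR read-through is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.SeqUtils import seq3

from .errors import ContractError, UnsupportedVariantError
from .models import (
    GeneModel,
    ReferenceGenome,
    VariantRecord,
    reverse_complement,
    translate_cds,
)

PROTEIN_CHANGING = frozenset(
    {
        "missense",
        "frameshift",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "inframe_insertion",
        "inframe_deletion",
    }
)


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


# ----------------------------------------------------------- normalization


@dataclass(frozen=True)
class NormalizedVariant:
    """A variant in both canonical placements.

    ``vcf_form`` is parsimonious and left-aligned (one anchor base for
    indels); ``hgvs_genomic_pos`` is the position of the same edit after
    shifting as far 3' (rightward on the plus strand) as the sequence
    allows.  For a duplication it is the position of the last duplicated
    base, for a deletion the first deleted base, for an insertion the base
    preceding the insertion point, and for a substitution simply its
    position.
    """

    vcf_form: VariantRecord
    hgvs_genomic_pos: int
    is_duplication: bool

    @property
    def kind(self) -> str:
        r, a = self.vcf_form.ref, self.vcf_form.alt
        if len(r) == 1 and len(a) == 1:
            return "snv"
        if len(r) == 1 and len(a) > 1 and a[0] == r:
            return "ins"
        if len(a) == 1 and len(r) > 1 and r[0] == a:
            return "del"
        return "mnv"


def _trim(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Remove shared flanking sequence down to the VCF parsimonious form."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize(variant: VariantRecord, genome: ReferenceGenome) -> NormalizedVariant:
    """Reduce to parsimonious left-aligned form and compute the 3' placement."""
    variant.check_reference(genome)
    seq = genome[variant.chrom]
    pos, ref, alt = _trim(variant.pos, variant.ref, variant.alt)

    if len(ref) == len(alt) or (len(ref) > 1 and len(alt) > 1):
        # substitution / MNV: both placements coincide
        vcf = VariantRecord(variant.chrom, pos, ref, alt, variant.genotypes)
        return NormalizedVariant(vcf, pos, False)

    if len(alt) > len(ref):  # insertion
        if ref[0] != alt[0]:
            # no anchor: re-anchor on the preceding base
            if pos > 1:
                anchor = seq[pos - 2]
                pos, ref, alt = pos - 1, anchor + ref, anchor + alt
                pos, ref, alt = _trim(pos, ref, alt)
        ins = alt[len(ref) :]
        anchor_pos = pos + len(ref) - 1  # base after which ins sits
        # left-align
        p, s = anchor_pos, ins
        while p >= 1 and seq[p - 1] == s[-1]:
            s = s[-1] + s[:-1]
            p -= 1
        left_pos, left_ins = p, s
        # 3'-shift
        p, s = anchor_pos, ins
        while p < len(seq) and seq[p] == s[0]:
            s = s[1:] + s[0]
            p += 1
        right_pos, right_ins = p, s
        L = len(right_ins)
        is_dup = right_pos - L >= 0 and seq[right_pos - L : right_pos] == right_ins
        if left_pos >= 1:
            vcf = VariantRecord(
                variant.chrom,
                left_pos,
                seq[left_pos - 1],
                seq[left_pos - 1] + left_ins,
                variant.genotypes,
            )
        else:  # insertion before the first base: no anchor available 5'
            vcf = VariantRecord(
                variant.chrom, 1, seq[0], left_ins + seq[0], variant.genotypes
            )
        return NormalizedVariant(vcf, right_pos, is_dup)

    # deletion
    if ref[0] != alt[0] and pos > 1:
        anchor = seq[pos - 2]
        pos, ref, alt = pos - 1, anchor + ref, anchor + alt
        pos, ref, alt = _trim(pos, ref, alt)
    deleted = ref[len(alt) :]
    start = pos + len(alt)  # first deleted base (1-based)
    end = start + len(deleted) - 1
    # left-align
    s, e = start, end
    while s > 1 and seq[s - 2] == seq[e - 1]:
        s, e = s - 1, e - 1
    left_start = s
    # 3'-shift
    s, e = start, end
    while e < len(seq) and seq[e] == seq[s - 1]:
        s, e = s + 1, e + 1
    right_start = s
    if left_start > 1:
        anchor = seq[left_start - 2]
        vcf = VariantRecord(
            variant.chrom,
            left_start - 1,
            anchor + seq[left_start - 1 : left_start - 1 + len(deleted)],
            anchor,
            variant.genotypes,
        )
    else:
        after = seq[len(deleted)]
        vcf = VariantRecord(
            variant.chrom, 1, seq[: len(deleted)] + after, after, variant.genotypes
        )
    return NormalizedVariant(vcf, right_start, False)


def apply_variant_to_sequence(seq: str, variant: VariantRecord) -> str:
    """Return the chromosome string with the variant applied."""
    start = variant.pos - 1
    if seq[start : start + len(variant.ref)] != variant.ref:
        raise ContractError(
            f"REF {variant.ref!r} does not match sequence at {variant.pos}"
        )
    return seq[:start] + variant.alt + seq[start + len(variant.ref) :]


# ------------------------------------------------------------ consequences


@dataclass
class Consequence:
    """Predicted coding effect of one variant on one transcript."""

    gene: Optional[str]
    transcript: Optional[str]
    category: str
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    truncated_fraction: Optional[float] = None
    near_splice: bool = False
    wt_protein_length: Optional[int] = None
    mutant_protein_length: Optional[int] = None

    @property
    def protein_changing(self) -> bool:
        return self.category in PROTEIN_CHANGING


@dataclass(frozen=True)
class _CdsEdit:
    """An edit expressed on the CDS string (1-based transcript coordinates)."""

    kind: str  # snv | ins | del
    # snv: position + new base; ins: insertion after `pos` of `seq`;
    # del: closed range [pos, end]
    pos: int
    end: int = 0
    seq: str = ""


def _shift3_cds(cds: str, edit: _CdsEdit) -> _CdsEdit:
    """Shift an indel edit to its most 3' equivalent CDS placement."""
    if edit.kind == "ins":
        p, s = edit.pos, edit.seq
        while p < len(cds) and cds[p] == s[0]:
            s = s[1:] + s[0]
            p += 1
        return _CdsEdit("ins", p, seq=s)
    if edit.kind == "del":
        s, e = edit.pos, edit.end
        while e < len(cds) and cds[e] == cds[s - 1]:
            s, e = s + 1, e + 1
        return _CdsEdit("del", s, e)
    return edit


def _apply_cds_edit(cds: str, edit: _CdsEdit) -> str:
    if edit.kind == "snv":
        return cds[: edit.pos - 1] + edit.seq + cds[edit.pos :]
    if edit.kind == "ins":
        return cds[: edit.pos] + edit.seq + cds[edit.pos :]
    return cds[: edit.pos - 1] + cds[edit.end :]


def _hgvs_c(cds: str, edit: _CdsEdit) -> str:
    if edit.kind == "snv":
        return f"c.{edit.pos}{cds[edit.pos - 1]}>{edit.seq}"
    if edit.kind == "del":
        if edit.pos == edit.end:
            return f"c.{edit.pos}del"
        return f"c.{edit.pos}_{edit.end}del"
    L = len(edit.seq)
    if edit.pos - L >= 0 and cds[edit.pos - L : edit.pos] == edit.seq:
        if L == 1:
            return f"c.{edit.pos}dup"
        return f"c.{edit.pos - L + 1}_{edit.pos}dup"
    return f"c.{edit.pos}_{edit.pos + 1}ins{edit.seq}"


def _hgvs_p(wt: str, mut: str, frameshift: bool, mut_has_stop: bool = True) -> str:
    """Protein-level HGVS from the two translated proteins (stops excluded)."""
    if wt == mut:
        return "p.(=)"
    i = 0
    while i < len(wt) and i < len(mut) and wt[i] == mut[i]:
        i += 1
    if i == 0 and (not mut or mut[0] != "M"):
        return "p.(Met1?)"
    if frameshift:
        if i >= len(wt):  # new reading runs past the wild-type stop
            return f"p.(*{len(wt) + 1}{_aa3(mut[i])}ext*?)"
        if not mut_has_stop:
            new = _aa3(mut[i]) if i < len(mut) else "?"
            return f"p.({_aa3(wt[i])}{i + 1}{new}fs*?)"
        if i >= len(mut):  # stop lands on the first changed codon
            return f"p.({_aa3(wt[i])}{i + 1}*)"
        stop_offset = len(mut) - i + 1
        return f"p.({_aa3(wt[i])}{i + 1}{_aa3(mut[i])}fs*{stop_offset})"
    if i >= len(wt):  # stop codon replaced: extension
        return f"p.(*{len(wt) + 1}{_aa3(mut[i])}ext*?)"
    if i >= len(mut):  # premature stop, upstream identical
        return f"p.({_aa3(wt[i])}{i + 1}*)"
    if len(wt) == len(mut):
        j_wt, j_mut = len(wt), len(mut)
        while j_wt > i and j_mut > i and wt[j_wt - 1] == mut[j_mut - 1]:
            j_wt, j_mut = j_wt - 1, j_mut - 1
        if j_wt == i + 1:
            return f"p.({_aa3(wt[i])}{i + 1}{_aa3(mut[i])})"
        return (
            f"p.({_aa3(wt[i])}{i + 1}_{_aa3(wt[j_wt - 1])}{j_wt}"
            f"delins{''.join(_aa3(a) for a in mut[i:j_mut])})"
        )
    # inframe indel at protein level
    j_wt, j_mut = len(wt), len(mut)
    while j_wt > i and j_mut > i and wt[j_wt - 1] == mut[j_mut - 1]:
        j_wt, j_mut = j_wt - 1, j_mut - 1
    if len(mut) > len(wt) and j_wt == i:
        return f"p.({_aa3(wt[i - 1])}{i}_{_aa3(wt[i])}{i + 1}ins" + "".join(
            _aa3(a) for a in mut[i:j_mut]
        ) + ")"
    if len(mut) < len(wt) and j_mut == i:
        if j_wt == i + 1:
            return f"p.({_aa3(wt[i])}{i + 1}del)"
        return f"p.({_aa3(wt[i])}{i + 1}_{_aa3(wt[j_wt - 1])}{j_wt}del)"
    return (
        f"p.({_aa3(wt[i])}{i + 1}_{_aa3(wt[j_wt - 1])}{j_wt}"
        f"delins{''.join(_aa3(a) for a in mut[i:j_mut])})"
    )


def categorize(
    wt_prot: str, mut_prot: str, edit_kind: str, net_length_change: int, start_hit: bool
) -> str:
    """Category from the translated proteins plus the edit's frame effect."""
    if start_hit or not mut_prot or mut_prot[0] != "M":
        return "start_lost"
    if edit_kind != "snv" and net_length_change % 3 != 0:
        return "frameshift"
    if wt_prot == mut_prot:
        return "synonymous"
    if edit_kind == "snv":
        if len(mut_prot) < len(wt_prot) and mut_prot == wt_prot[: len(mut_prot)]:
            return "stop_gained"
        if len(mut_prot) > len(wt_prot):
            return "stop_lost"
        return "missense"
    if len(mut_prot) < len(wt_prot) - abs(net_length_change) // 3:
        # inframe indel whose new codons include a premature stop
        return "stop_gained"
    return "inframe_insertion" if net_length_change > 0 else "inframe_deletion"


class Annotator:
    """Caches wild-type CDS/protein per transcript and a gene index."""

    def __init__(self, genome: ReferenceGenome, genes: Sequence[GeneModel]):
        self.genome = genome
        self.genes = list(genes)
        self._cds_cache: dict[str, str] = {}
        self._prot_cache: dict[str, str] = {}
        self._spans = sorted(
            ((g.span[0], g.span[1], g) for g in self.genes),
            key=lambda t: (t[2].chrom, t[0]),
        )

    def wt_cds(self, gene: GeneModel) -> str:
        if gene.transcript not in self._cds_cache:
            self._cds_cache[gene.transcript] = gene.cds_sequence(self.genome)
        return self._cds_cache[gene.transcript]

    def wt_protein(self, gene: GeneModel) -> str:
        if gene.transcript not in self._prot_cache:
            self._prot_cache[gene.transcript] = translate_cds(self.wt_cds(gene))
        return self._prot_cache[gene.transcript]

    def gene_at(self, chrom: str, start: int, end: int) -> Optional[GeneModel]:
        """First gene (genomic order) whose CDS span overlaps [start, end]."""
        for s, e, g in self._spans:
            if g.chrom == chrom and s <= end and start <= e:
                return g
        return None


def call_consequence(
    norm: NormalizedVariant,
    gene: Optional[GeneModel],
    genome: ReferenceGenome,
    annotator: Optional[Annotator] = None,
) -> Consequence:
    """Classify one normalized variant against one gene model.

    The variant is placed at its most 3' position *in transcript
    orientation* (HGVS rule) before deciding CDS overlap, then edited into
    the CDS string, 3'-shifted again in CDS coordinates, and translated.
    """
    v = norm.vcf_form
    if gene is None:
        return Consequence(None, None, "intergenic")
    seq = genome[v.chrom]
    wt_cds = annotator.wt_cds(gene) if annotator else gene.cds_sequence(genome)
    wt_prot = annotator.wt_protein(gene) if annotator else translate_cds(wt_cds)

    kind = norm.kind
    near = False

    def near_splice(*positions: int) -> bool:
        bounds = [b for s, e in gene.cds_intervals for b in (s, e)]
        return any(abs(p - b) <= 2 for p in positions for b in bounds)

    if kind in ("snv", "mnv"):
        start, end = v.pos, v.end
        c_start = gene.genomic_to_cds(start)
        c_end = gene.genomic_to_cds(end)
        near = near_splice(start, end)
        if c_start is None and c_end is None:
            lo, hi = gene.span
            cat = "intronic" if lo <= start and end <= hi else "intergenic"
            return Consequence(gene.gene, gene.transcript, cat, near_splice=near)
        if c_start is None or c_end is None or kind == "mnv" and abs(c_end - c_start) != end - start:
            raise UnsupportedVariantError(
                f"{v.chrom}:{v.pos} {v.ref}>{v.alt} spans a CDS boundary"
            )
        if kind == "mnv":
            raise UnsupportedVariantError(
                f"{v.chrom}:{v.pos} multi-nucleotide substitution not supported"
            )
        if gene.strand == "+":
            edit = _CdsEdit("snv", c_start, seq=v.alt)
        else:
            edit = _CdsEdit("snv", c_start, seq=reverse_complement(v.alt))
        net = 0
    elif kind == "ins":
        ins = v.alt[1:]
        # transcript-orientation 3'-most genomic placement
        if gene.strand == "+":
            p, s = norm.hgvs_genomic_pos, _rotated_ins(seq, v, norm)
            left, right = p, p + 1  # flanking genomic bases
        else:
            p = v.pos  # left-aligned = 3'-most on the minus strand
            s = v.alt[1:]
            left, right = p, p + 1
        c_left, c_right = gene.genomic_to_cds(left), gene.genomic_to_cds(right)
        near = near_splice(left, right)
        if c_left is None and c_right is None:
            lo, hi = gene.span
            cat = "intronic" if lo <= left and right <= hi else "intergenic"
            return Consequence(gene.gene, gene.transcript, cat, near_splice=near)
        if c_left is None or c_right is None or abs(c_left - c_right) != 1:
            raise UnsupportedVariantError(
                f"{v.chrom}:{v.pos} insertion at a CDS boundary"
            )
        if gene.strand == "+":
            edit = _CdsEdit("ins", c_left, seq=s)
        else:
            edit = _CdsEdit("ins", c_right, seq=reverse_complement(s))
        net = len(ins)
    elif kind == "del":
        deleted = v.ref[1:]
        if gene.strand == "+":
            g_start = norm.hgvs_genomic_pos
        else:
            g_start = v.pos + 1  # left-aligned deletion start
        g_end = g_start + len(deleted) - 1
        c_a, c_b = gene.genomic_to_cds(g_start), gene.genomic_to_cds(g_end)
        near = near_splice(g_start, g_end)
        if c_a is None and c_b is None:
            lo, hi = gene.span
            cat = "intronic" if lo <= g_start and g_end <= hi else "intergenic"
            return Consequence(gene.gene, gene.transcript, cat, near_splice=near)
        if c_a is None or c_b is None or abs(c_a - c_b) != g_end - g_start:
            raise UnsupportedVariantError(
                f"{v.chrom}:{v.pos} deletion spans a CDS boundary"
            )
        edit = _CdsEdit("del", min(c_a, c_b), max(c_a, c_b))
        net = -len(deleted)
    else:  # pragma: no cover - kinds are exhaustive
        raise UnsupportedVariantError(f"unsupported variant kind {kind}")

    edit = _shift3_cds(wt_cds, edit)
    mut_cds = _apply_cds_edit(wt_cds, edit)
    mut_prot = translate_cds(mut_cds)

    start_hit = (
        (edit.kind == "snv" and edit.pos <= 3)
        or (edit.kind == "ins" and edit.pos < 3)
        or (edit.kind == "del" and edit.pos <= 3)
    )
    category = categorize(wt_prot, mut_prot, edit.kind, net, start_hit)
    hgvs_c = _hgvs_c(wt_cds, edit)
    frameshift = category == "frameshift"
    mut_has_stop = _has_stop(mut_cds)
    hgvs_p = _hgvs_p(wt_prot, mut_prot, frameshift, mut_has_stop)
    if category == "start_lost":
        hgvs_p = "p.(Met1?)"

    truncated = None
    if category in ("frameshift", "stop_gained") and mut_has_stop:
        if len(mut_prot) < len(wt_prot):
            truncated = 1.0 - len(mut_prot) / len(wt_prot)
    return Consequence(
        gene=gene.gene,
        transcript=gene.transcript,
        category=category,
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
        truncated_fraction=truncated,
        near_splice=near,
        wt_protein_length=len(wt_prot),
        mutant_protein_length=len(mut_prot),
    )


def translate_full(cds: str) -> str:
    from Bio.Seq import Seq

    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate())


def _has_stop(cds: str) -> bool:
    return "*" in translate_full(cds)


def _rotated_ins(seq: str, v: VariantRecord, norm: NormalizedVariant) -> str:
    """Inserted sequence after rotating to the 3'-most genomic placement."""
    ins = v.alt[1:]
    p, s = v.pos, ins
    while p < len(seq) and seq[p] == s[0]:
        s = s[1:] + s[0]
        p += 1
    return s


def truncation_fraction(consequence: Consequence) -> float:
    """Fraction of the wild-type open reading frame removed by a premature stop."""
    if consequence.category not in ("frameshift", "stop_gained"):
        raise ContractError(
            f"truncation fraction undefined for category {consequence.category!r}"
        )
    if consequence.truncated_fraction is None:
        raise ContractError("no premature stop: truncation fraction undefined")
    return consequence.truncated_fraction


def annotate_variants(
    variants: Sequence[VariantRecord],
    genome: ReferenceGenome,
    genes: Sequence[GeneModel],
) -> tuple[dict[tuple, "Consequence"], dict[tuple, NormalizedVariant], list[tuple]]:
    """Annotate a cohort; returns (consequences, normalized forms, failures).

    Variants the annotator cannot classify (CDS-boundary-spanning) are
    reported in ``failures`` with the error message, never dropped
    silently.
    """
    annotator = Annotator(genome, genes)
    consequences: dict[tuple, Consequence] = {}
    normalized: dict[tuple, NormalizedVariant] = {}
    failures: list[tuple] = []
    for v in variants:
        norm = normalize(v, genome)
        nv = norm.vcf_form
        gene = annotator.gene_at(nv.chrom, nv.pos, max(nv.end, norm.hgvs_genomic_pos))
        try:
            cons = call_consequence(norm, gene, genome, annotator)
        except UnsupportedVariantError as exc:
            failures.append((v.key, str(exc)))
            cons = Consequence(
                gene.gene if gene else None,
                gene.transcript if gene else None,
                "unsupported",
            )
        consequences[v.key] = cons
        normalized[v.key] = norm
    return consequences, normalized, failures
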