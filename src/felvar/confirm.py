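"""Wet-lab confirmation support.

In-silico PCR predicts genotyping amplicon sizes (the published assay
yields a 169 bp wild-type / 170 bp mutant product around the causal
duplication), and microsatellite parentage exclusion tests candidate
parents by Mendelian allele sharing across a marker panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

from .annotate import apply_variant_to_sequence
from .errors import ValidationError
from .models import DNA_ALPHABET, ReferenceGenome, VariantRecord, reverse_complement


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    max_product: int = 5000

    def __post_init__(self):
        for primer in (self.forward, self.reverse):
            if not primer or set(primer) - (DNA_ALPHABET - {"N"}):
                raise ValidationError(f"{self.name}: primers must be non-empty ACGT")


@dataclass(frozen=True)
class Amplicon:
    chrom: str
    start: int  # 1-based, 5' end of the leftmost primer
    end: int  # 1-based, 3' end of the rightmost primer
    length: int
    allele_context: str  # "reference" or "variant-applied"

    def __post_init__(self):
        assert self.length == self.end - self.start + 1


def _find_all(haystack: str, needle: str) -> list[int]:
    """0-based start offsets of every (possibly overlapping) exact match."""
    hits, i = [], haystack.find(needle)
    while i >= 0:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def insilico_pcr(
    template: Union[ReferenceGenome, Mapping[str, str]],
    primers: PrimerPair,
    allele_context: str = "reference",
) -> list[Amplicon]:
    """Exact-match amplicon prediction on every sequence of the template.

    A product forms when one primer matches the plus strand and the other
    primer's reverse complement matches downstream of it (both
    orientations of the pair are searched); the length counts both
    primers.  No mismatches or ambiguity codes are tolerated.
    """
    sequences = (
        template.sequences if isinstance(template, ReferenceGenome) else template
    )
    amplicons = []
    seen = set()
    pairs = [
        (primers.forward, primers.reverse),
        (primers.reverse, primers.forward),
    ]
    for chrom, seq in sequences.items():
        for left, right in pairs:
            right_rc = reverse_complement(right)
            for i in _find_all(seq, left):
                for j in _find_all(seq, right_rc):
                    end = j + len(right_rc)  # 0-based exclusive
                    if end <= i + len(left):
                        continue
                    length = end - i
                    if length > primers.max_product:
                        continue
                    key = (chrom, i, end)
                    if key in seen:
                        continue
                    seen.add(key)
                    amplicons.append(
                        Amplicon(chrom, i + 1, end, length, allele_context)
                    )
    amplicons.sort(key=lambda a: (a.chrom, a.start, a.end))
    return amplicons


def apply_variant(genome: ReferenceGenome, variant: VariantRecord) -> dict[str, str]:
    """Variant-applied haplotype: the edited chromosome plus the others."""
    variant.check_reference(genome)
    sequences = dict(genome.sequences)
    sequences[variant.chrom] = apply_variant_to_sequence(
        sequences[variant.chrom], variant
    )
    return sequences


# ---------------------------------------------------------------- parentage

Genotype = Optional[tuple[int, int]]


@dataclass
class ParentageResult:
    offspring_id: str
    candidate_parents: list[str]
    excluded_loci: list[str] = field(default_factory=list)
    loci_tested: int = 0

    @property
    def compatible(self) -> bool:
        return not self.excluded_loci

    def as_dict(self) -> dict:
        return {
            "offspring": self.offspring_id,
            "candidate_parents": self.candidate_parents,
            "excluded_loci": self.excluded_loci,
            "loci_tested": self.loci_tested,
            "compatible": self.compatible,
        }


def _shares_allele(offspring: tuple[int, int], parent: tuple[int, int]) -> bool:
    return bool(set(offspring) & set(parent))


def _trio_compatible(
    offspring: tuple[int, int], p1: tuple[int, int], p2: tuple[int, int]
) -> bool:
    """One offspring allele from each parent, in either assignment."""
    a, b = offspring
    return (a in p1 and b in p2) or (b in p1 and a in p2)


def parentage_exclusion(
    offspring_id: str,
    offspring: Mapping[str, Genotype],
    sire: Mapping[str, Genotype],
    dam: Optional[Mapping[str, Genotype]] = None,
    sire_id: str = "sire",
    dam_id: str = "dam",
) -> ParentageResult:
    """Exclusion test of one candidate parent (or a parent pair).

    Single candidate: a locus excludes when offspring and candidate share
    no allele.  With both parents, a locus additionally excludes when no
    assignment of one offspring allele to each parent is consistent.
    Loci missing in any tested individual are skipped and not counted.
    """
    shared = [loc for loc in offspring if loc in sire and (dam is None or loc in dam)]
    if not shared:
        raise ValidationError("no shared marker loci between offspring and candidates")
    result = ParentageResult(
        offspring_id, [sire_id] if dam is None else [sire_id, dam_id]
    )
    for loc in shared:
        o, s = offspring[loc], sire[loc]
        d = None if dam is None else dam[loc]
        if o is None or s is None or (dam is not None and d is None):
            continue
        result.loci_tested += 1
        if dam is None:
            if not _shares_allele(o, s):
                result.excluded_loci.append(loc)
        else:
            if not _trio_compatible(o, s, d):
                result.excluded_loci.append(loc)
    return result
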