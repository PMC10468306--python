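"""Core in-memory data model.

Coordinates are 1-based and intervals are closed on both ends throughout
(VCF/GFF3 convention).  Genotypes are unphased diploid autosomal calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Optional, Sequence

from Bio.Seq import Seq

from .errors import ReferenceMismatchError, ValidationError

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a coding sequence, stopping at the first stop codon.

    The returned protein excludes the stop.  A trailing partial codon
    (frameshifted sequence) is ignored.
    """
    trimmed = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(trimmed).translate())
    stop = prot.find("*")
    return prot if stop < 0 else prot[:stop]


class GenotypeCall(Enum):
    """Unphased diploid genotype at a biallelic site."""

    HOM_REF = "0/0"
    HET = "0/1"
    HOM_ALT = "1/1"
    MISSING = "./."

    @classmethod
    def from_alleles(cls, a: Optional[int], b: Optional[int]) -> "GenotypeCall":
        if a is None or b is None:
            return cls.MISSING
        n = (1 if a else 0) + (1 if b else 0)
        return (cls.HOM_REF, cls.HET, cls.HOM_ALT)[n]

    @property
    def alt_count(self) -> Optional[int]:
        """Number of alternate alleles carried, or None if missing."""
        return {self.HOM_REF: 0, self.HET: 1, self.HOM_ALT: 2, self.MISSING: None}[self]

    @property
    def carries_alt(self) -> bool:
        return self in (GenotypeCall.HET, GenotypeCall.HOM_ALT)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ReferenceGenome:
    """Uppercase DNA sequences keyed by unique sequence name."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if not name:
                raise ValidationError("empty sequence name")
            if name in self.sequences:
                raise ValidationError(f"duplicate sequence name {name!r}")
            seq = seq.upper()
            bad = set(seq) - DNA_ALPHABET
            if bad:
                offset = next(i for i, c in enumerate(seq) if c in bad)
                raise ValidationError(
                    f"sequence {name!r}: invalid base {seq[offset]!r} at offset {offset}"
                )
            self.sequences[name] = seq

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def names(self) -> list[str]:
        return list(self.sequences)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Inclusive 1-based slice."""
        return self.sequences[chrom][start - 1 : end]


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic sequence variant plus per-sample genotype calls."""

    chrom: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alt: str
    genotypes: Mapping[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError("REF and ALT must be non-empty")
        if self.ref == self.alt:
            raise ValidationError("REF and ALT must differ")
        for allele in (self.ref, self.alt):
            if set(allele) - DNA_ALPHABET:
                raise ValidationError(f"non-DNA allele {allele!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """1-based position of the last REF base."""
        return self.pos + len(self.ref) - 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    def check_reference(self, genome: ReferenceGenome) -> None:
        observed = genome.fetch(self.chrom, self.pos, self.end)
        if observed != self.ref:
            raise ReferenceMismatchError(
                f"{self.chrom}:{self.pos} REF {self.ref!r} != reference {observed!r}"
            )

    def with_genotypes(self, genotypes: Mapping[str, GenotypeCall]) -> "VariantRecord":
        return VariantRecord(self.chrom, self.pos, self.ref, self.alt, dict(genotypes))


@dataclass
class GeneModel:
    """A single-transcript protein-coding gene model.

    ``cds_intervals`` are 1-based closed genomic intervals listed in
    transcript (5'->3') order: ascending genomic start on the plus strand,
    descending on the minus strand.
    """

    gene: str
    transcript: str
    chrom: str
    strand: str
    cds_intervals: Sequence[tuple[int, int]]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_intervals:
            raise ValidationError(f"{self.gene}: no CDS intervals")
        for s, e in self.cds_intervals:
            if s > e or s < 1:
                raise ValidationError(f"{self.gene}: bad interval ({s}, {e})")
        genomic = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValidationError(f"{self.gene}: overlapping CDS intervals")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.cds_intervals) != expected:
            raise ValidationError(
                f"{self.gene}: CDS intervals not in transcript (5'->3') order"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent (min start, max end) over all CDS intervals."""
        starts, ends = zip(*self.cds_intervals)
        return min(starts), max(ends)

    def cds_sequence(self, genome: ReferenceGenome) -> str:
        parts = []
        for s, e in sorted(self.cds_intervals):
            parts.append(genome.fetch(self.chrom, s, e))
        seq = "".join(parts)
        return seq if self.strand == "+" else reverse_complement(seq)

    def protein(self, genome: ReferenceGenome) -> str:
        return translate_cds(self.cds_sequence(genome))

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """Map a genomic position to a 1-based CDS coordinate, or None."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                if self.strand == "+":
                    return offset + (pos - s) + 1
                return offset + (e - pos) + 1
            offset += e - s + 1
        return None

    def cds_to_genomic(self, c: int) -> int:
        if not 1 <= c <= self.cds_length:
            raise ValueError(f"CDS coordinate {c} out of range for {self.gene}")
        offset = 0
        for s, e in self.cds_intervals:
            length = e - s + 1
            if c <= offset + length:
                within = c - offset - 1
                return s + within if self.strand == "+" else e - within
            offset += length
        raise AssertionError("unreachable")

    def containing_interval(self, pos: int) -> Optional[tuple[int, int]]:
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                return (s, e)
        return None

    def validate_coding(self, genome: ReferenceGenome) -> list[str]:
        """Soft checks on the encoded protein; returns warning strings."""
        problems = []
        cds = self.cds_sequence(genome)
        if len(cds) % 3:
            problems.append(f"{self.gene}: CDS length {len(cds)} not divisible by 3")
        if not cds.startswith("ATG"):
            problems.append(f"{self.gene}: CDS does not start with ATG")
        trimmed = cds[: len(cds) - len(cds) % 3]
        prot = str(Seq(trimmed).translate())
        if not prot.endswith("*"):
            problems.append(f"{self.gene}: CDS does not end with a stop codon")
        if "*" in prot[:-1]:
            problems.append(f"{self.gene}: internal stop codon")
        for msg in problems:
            warnings.warn(msg, stacklevel=2)
        return problems


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Individual:
    id: str
    sire: Optional[str]
    dam: Optional[str]
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN


class Pedigree:
    """A validated pedigree: unique ids, resolvable parents, acyclic."""

    def __init__(self, individuals: Sequence[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self._by_id: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise ValidationError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        for ind in self.individuals:
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in self._by_id:
                    raise ValidationError(
                        f"individual {ind.id!r}: unresolved parent id {parent!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0=visiting, 1=done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise ValidationError(f"pedigree cycle involving {iid!r}")
            state[iid] = 0
            ind = self._by_id[iid]
            for parent in (ind.sire, ind.dam):
                if parent is not None:
                    visit(parent, stack + [iid])
            state[iid] = 1

        for ind in self.individuals:
            visit(ind.id, [])

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def get(self, iid: str) -> Individual:
        return self._by_id[iid]

    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.sire is None and i.dam is None]

    def affected(self) -> list[Individual]:
        return [i for i in self.individuals if i.affection is Affection.AFFECTED]

    def obligate_carriers(self) -> list[str]:
        """Parents of affected individuals (fully penetrant recessive model)."""
        carriers: list[str] = []
        for ind in self.affected():
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in carriers:
                    carriers.append(parent)
        return carriers

    def trios(self) -> list[tuple[str, Optional[str], Optional[str]]]:
        """(child, sire, dam) for every non-founder."""
        return [
            (i.id, i.sire, i.dam)
            for i in self.individuals
            if i.sire is not None or i.dam is not None
        ]
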