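"""Pedigree cosegregation under a fully penetrant autosomal-recessive model.

Perfect cosegregation requires: every genotyped affected individual
homozygous for the alternate allele, no genotyped unaffected individual
homozygous for it, every genotyped obligate carrier (parent of an
affected) heterozygous, and no parent-offspring Mendelian inconsistency
at the site.  Individuals of unknown affection are exempt from the first
two rules but still checked for Mendelian consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import ValidationError
from .models import Affection, GenotypeCall, Pedigree


@dataclass
class GenotypeClassCounts:
    hom_alt_affected: int = 0
    hom_alt_unaffected: int = 0
    het: int = 0
    hom_ref: int = 0
    missing: int = 0

    @property
    def total(self) -> int:
        return (
            self.hom_alt_affected
            + self.hom_alt_unaffected
            + self.het
            + self.hom_ref
            + self.missing
        )


@dataclass
class SegregationResult:
    counts: GenotypeClassCounts
    perfect: bool
    violations: list[tuple[str, str]] = field(default_factory=list)
    obligate_carriers_checked: list[str] = field(default_factory=list)
    informative_meioses: int = 0
    model: str = "autosomal_recessive"

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "counts": {
                "hom_alt_affected": self.counts.hom_alt_affected,
                "hom_alt_unaffected": self.counts.hom_alt_unaffected,
                "het": self.counts.het,
                "hom_ref": self.counts.hom_ref,
                "missing": self.counts.missing,
            },
            "perfect": self.perfect,
            "violations": [list(v) for v in self.violations],
            "obligate_carriers_checked": self.obligate_carriers_checked,
            "informative_meioses": self.informative_meioses,
        }


def tabulate(
    genotypes: Mapping[str, GenotypeCall], pedigree: Pedigree
) -> GenotypeClassCounts:
    """Genotype-class counts split by affection status for hom-alt calls."""
    counts = GenotypeClassCounts()
    for iid, gt in genotypes.items():
        if iid not in pedigree:
            raise ValidationError(f"genotype for unknown individual {iid!r}")
        ind = pedigree.get(iid)
        if gt is GenotypeCall.MISSING:
            counts.missing += 1
        elif gt is GenotypeCall.HOM_ALT:
            if ind.affection is Affection.AFFECTED:
                counts.hom_alt_affected += 1
            else:
                counts.hom_alt_unaffected += 1
        elif gt is GenotypeCall.HET:
            counts.het += 1
        else:
            counts.hom_ref += 1
    return counts


def mendelian_errors(
    child: GenotypeCall,
    sire: Optional[GenotypeCall],
    dam: Optional[GenotypeCall],
) -> bool:
    """True if the trio (or duo) genotypes are Mendelian-inconsistent.

    Missing genotypes (or absent parents) never violate.  A biallelic
    child genotype is consistent when one of its alleles can come from
    each available parent (a single available parent only constrains one
    allele).
    """
    missing = GenotypeCall.MISSING
    if child is missing:
        return False

    def alleles(gt: Optional[GenotypeCall]) -> Optional[set[tuple[int, int]]]:
        if gt is None or gt is missing:
            return None
        return {
            GenotypeCall.HOM_REF: {(0, 0)},
            GenotypeCall.HET: {(0, 1), (1, 0)},
            GenotypeCall.HOM_ALT: {(1, 1)},
        }[gt]

    child_pairs = alleles(child)
    sire_pairs = alleles(sire)
    dam_pairs = alleles(dam)
    for ca, cb in child_pairs:
        from_sire_ok = sire_pairs is None or any(ca in p for p in sire_pairs)
        from_dam_ok = dam_pairs is None or any(cb in p for p in dam_pairs)
        if from_sire_ok and from_dam_ok:
            return False
    return True


def cosegregation_check(
    genotypes: Mapping[str, GenotypeCall],
    pedigree: Pedigree,
    model: str = "autosomal_recessive",
) -> SegregationResult:
    if model != "autosomal_recessive":
        raise ValidationError(f"unsupported inheritance model {model!r}")
    counts = tabulate(genotypes, pedigree)
    violations: list[tuple[str, str]] = []

    def gt(iid: Optional[str]) -> Optional[GenotypeCall]:
        if iid is None:
            return None
        return genotypes.get(iid, GenotypeCall.MISSING)

    for ind in pedigree:
        g = gt(ind.id)
        if g is GenotypeCall.MISSING or g is None:
            continue
        if ind.affection is Affection.AFFECTED and g is not GenotypeCall.HOM_ALT:
            violations.append((ind.id, "affected_not_hom_alt"))
        if ind.affection is Affection.UNAFFECTED and g is GenotypeCall.HOM_ALT:
            violations.append((ind.id, "unaffected_hom_alt"))

    carriers = pedigree.obligate_carriers()
    checked = []
    for iid in carriers:
        g = gt(iid)
        if g is None or g is GenotypeCall.MISSING:
            continue  # ungenotyped parents are skipped, not imputed
        checked.append(iid)
        if g is not GenotypeCall.HET:
            violations.append((iid, "obligate_carrier_not_het"))

    meioses = 0
    for child, sire, dam in pedigree.trios():
        if mendelian_errors(gt(child), gt(sire), gt(dam)):
            violations.append((child, "mendelian_inconsistency"))
        if gt(child) is not GenotypeCall.MISSING:
            for parent in (sire, dam):
                pg = gt(parent)
                if pg is not None and pg is not GenotypeCall.MISSING:
                    meioses += 1

    # deduplicate while keeping order
    seen = set()
    unique = []
    for v in violations:
        if v not in seen:
            seen.add(v)
            unique.append(v)
    return SegregationResult(
        counts=counts,
        perfect=not unique,
        violations=unique,
        obligate_carriers_checked=checked,
        informative_meioses=meioses,
    )
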