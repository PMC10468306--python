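"""ACMG/AMP-lite rule engine.

Three criteria are computed from pipeline outputs — PVS1 (null variant in
a gene where loss of function is a known disease mechanism), PM2 (allele
absent from a sufficiently large control panel) and PP1 (cosegregation
with disease in multiple affected family members) — and combined with the
full pathogenic / likely-pathogenic combining rules of the consensus
framework.  Benign-evidence criteria are not implemented; absence of
benign evidence is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .annotate import Consequence
from .errors import ConfigurationError
from .models import GenotypeCall, VariantRecord
from .segregation import SegregationResult

NULL_VARIANT_CATEGORIES = frozenset(
    {"frameshift", "stop_gained", "start_lost", "stop_lost"}
)

DEFAULT_STRENGTHS = {"PVS1": "very_strong", "PM2": "moderate", "PP1": "supporting"}
STRENGTHS = ("very_strong", "strong", "moderate", "supporting")
LABELS = ("pathogenic", "likely_pathogenic", "uncertain_significance")


@dataclass(frozen=True)
class Evidence:
    criterion: str
    strength: str
    triggered: bool
    rationale: str


@dataclass(frozen=True)
class Classification:
    label: str
    fired_rule: str


def _strength(criterion: str, overrides: Optional[Mapping[str, str]]) -> str:
    s = (overrides or {}).get(criterion, DEFAULT_STRENGTHS[criterion])
    if s not in STRENGTHS:
        raise ConfigurationError(f"unknown evidence strength {s!r}")
    return s


def evaluate_pvs1(
    consequence: Consequence,
    gene_lof_mechanism: bool,
    strength_overrides: Optional[Mapping[str, str]] = None,
) -> Evidence:
    """Null variant (frameshift/stop/start) in a gene with a known LOF mechanism."""
    is_null = consequence.category in NULL_VARIANT_CATEGORIES
    triggered = is_null and gene_lof_mechanism
    if triggered:
        rationale = (
            f"{consequence.category} in {consequence.gene}, a gene where loss of "
            "function is a known mechanism of disease"
        )
    elif not is_null:
        rationale = f"not a null variant (category {consequence.category})"
    else:
        rationale = f"{consequence.gene} not flagged as a LOF-mechanism gene"
    return Evidence("PVS1", _strength("PVS1", strength_overrides), triggered, rationale)


def evaluate_pm2(
    variant: VariantRecord,
    control_ids: Sequence[str],
    min_controls: int = 50,
    strength_overrides: Optional[Mapping[str, str]] = None,
) -> Evidence:
    """Alternate allele absent from a control panel of sufficient size.

    Missing genotypes are not observations: they neither count alleles nor
    contribute to the panel-size requirement being unmet.
    """
    strength = _strength("PM2", strength_overrides)
    if not control_ids:
        return Evidence("PM2", strength, False, "empty control panel: no evidence")
    alt_alleles = 0
    for cid in control_ids:
        gt = variant.genotypes.get(cid, GenotypeCall.MISSING)
        if gt.alt_count is not None:
            alt_alleles += gt.alt_count
    if alt_alleles > 0:
        return Evidence(
            "PM2", strength, False, f"{alt_alleles} alternate allele(s) in controls"
        )
    if len(control_ids) < min_controls:
        return Evidence(
            "PM2",
            strength,
            False,
            f"absent, but panel of {len(control_ids)} < required {min_controls}",
        )
    return Evidence(
        "PM2", strength, True, f"absent from all {len(control_ids)} control genomes"
    )


def evaluate_pp1(
    segregation: SegregationResult,
    strength_overrides: Optional[Mapping[str, str]] = None,
) -> Evidence:
    """Perfect cosegregation with >= 2 genotyped affected family members."""
    n_affected = segregation.counts.hom_alt_affected
    triggered = segregation.perfect and n_affected >= 2
    if triggered:
        rationale = (
            f"perfect cosegregation with disease in {n_affected} affected members "
            f"({segregation.informative_meioses} informative meioses)"
        )
    elif not segregation.perfect:
        rationale = f"cosegregation not perfect ({len(segregation.violations)} violations)"
    else:
        rationale = f"only {n_affected} genotyped affected (need >= 2)"
    return Evidence("PP1", _strength("PP1", strength_overrides), triggered, rationale)


def combine(evidence: Sequence[Evidence]) -> Classification:
    """Combine triggered evidence with the consensus pathogenicity rules."""
    for ev in evidence:
        if ev.strength not in STRENGTHS:
            raise ConfigurationError(f"unknown strength {ev.strength!r}")
        if not ev.criterion:
            raise ConfigurationError("evidence without a criterion name")
    vs = sum(1 for e in evidence if e.triggered and e.strength == "very_strong")
    st = sum(1 for e in evidence if e.triggered and e.strength == "strong")
    mo = sum(1 for e in evidence if e.triggered and e.strength == "moderate")
    su = sum(1 for e in evidence if e.triggered and e.strength == "supporting")

    # not part of the original combining list, but required for the label
    # to be monotone in added evidence
    if vs >= 2:
        return Classification("pathogenic", "P0: >=2 very_strong")
    if vs >= 1:
        if st >= 1:
            return Classification("pathogenic", "P1a: 1 very_strong + >=1 strong")
        if mo >= 2:
            return Classification("pathogenic", "P1b: 1 very_strong + >=2 moderate")
        if mo == 1 and su == 1:
            return Classification(
                "pathogenic", "P1c: 1 very_strong + 1 moderate + 1 supporting"
            )
        if su >= 2:
            return Classification("pathogenic", "P1d: 1 very_strong + >=2 supporting")
    if st >= 2:
        return Classification("pathogenic", "P2: >=2 strong")
    if st == 1:
        if mo >= 3:
            return Classification("pathogenic", "P3a: 1 strong + >=3 moderate")
        if mo == 2 and su >= 2:
            return Classification(
                "pathogenic", "P3b: 1 strong + 2 moderate + >=2 supporting"
            )
        if mo == 1 and su >= 4:
            return Classification(
                "pathogenic", "P3c: 1 strong + 1 moderate + >=4 supporting"
            )
    if vs >= 1 and mo >= 1:
        return Classification("likely_pathogenic", "LP1: 1 very_strong + 1 moderate")
    if st == 1 and 1 <= mo <= 2:
        return Classification("likely_pathogenic", "LP2: 1 strong + 1-2 moderate")
    if st == 1 and su >= 2:
        return Classification("likely_pathogenic", "LP3: 1 strong + >=2 supporting")
    if mo >= 3:
        return Classification("likely_pathogenic", "LP4: >=3 moderate")
    if mo == 2 and su >= 2:
        return Classification("likely_pathogenic", "LP5: 2 moderate + >=2 supporting")
    if mo == 1 and su >= 4:
        return Classification("likely_pathogenic", "LP6: 1 moderate + >=4 supporting")
    return Classification("uncertain_significance", "none")
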