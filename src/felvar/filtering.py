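"""Hard-filter cascade: case-carried -> private -> protein-changing -> candidate genes.

The cascade mirrors the published four-row filtering table.  A variant is
*private* when the case carries it (het or hom-alt) and every control is
hom-ref or missing.  The het/hom partition of every row is determined
solely by the case sample's genotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotate import Consequence
from .errors import ConfigurationError
from .models import GenotypeCall, VariantRecord

ROW_LABELS = (
    "All variants in the sequenced case",
    "Private variants",
    "Protein-changing private variants",
    "Protein-changing private variants in functional candidate genes",
)


@dataclass
class FilterCascade:
    """Ordered rows of (label, het count, hom count) plus surviving variants."""

    rows: list[tuple[str, int, int]]
    surviving: list[tuple[list[VariantRecord], list[VariantRecord]]]

    @property
    def final_counts(self) -> tuple[int, int]:
        return self.rows[-1][1], self.rows[-1][2]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["Filtering step", "Heterozygous", "Homozygous"]
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _check_samples(
    variants: Sequence[VariantRecord], case_id: str, control_ids: Sequence[str]
) -> None:
    if not variants:
        return
    known = set(variants[0].genotypes)
    unknown = [s for s in [case_id, *control_ids] if s not in known]
    if unknown:
        raise ConfigurationError(f"unknown sample id(s): {unknown}")
    if case_id in control_ids:
        raise ConfigurationError(f"case {case_id!r} also listed as control")


def private_filter(
    variants: Sequence[VariantRecord], case_id: str, control_ids: Sequence[str]
) -> list[VariantRecord]:
    """Variants carried by the case and absent (hom-ref/missing) in all controls."""
    _check_samples(variants, case_id, control_ids)
    kept = []
    for v in variants:
        case = v.genotypes[case_id]
        if not case.carries_alt:
            continue
        if all(
            v.genotypes[c] in (GenotypeCall.HOM_REF, GenotypeCall.MISSING)
            for c in control_ids
        ):
            kept.append(v)
    return kept


def _partition(
    variants: Sequence[VariantRecord], case_id: str
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    het = [v for v in variants if v.genotypes[case_id] is GenotypeCall.HET]
    hom = [v for v in variants if v.genotypes[case_id] is GenotypeCall.HOM_ALT]
    return het, hom


def cascade(
    variants: Sequence[VariantRecord],
    consequences: Mapping[tuple, Consequence],
    candidate_genes: Sequence[str],
    case_id: str,
    control_ids: Sequence[str],
    row1: str = "case-carried",
) -> FilterCascade:
    """Four-step cascade with per-row het/hom counts and surviving variants.

    ``row1`` controls whether the first row counts only case-carried
    variants (default, the published reading) or all input records
    (``"all"``; sites the case does not carry still never pass row 2).
    """
    _check_samples(variants, case_id, control_ids)
    if row1 not in ("case-carried", "all"):
        raise ConfigurationError(f"row1 must be 'case-carried' or 'all', got {row1!r}")

    if not candidate_genes:
        logging.getLogger("felvar").warning(
            "empty candidate-gene list: final cascade row will be 0/0"
        )
    carried = [v for v in variants if v.genotypes[case_id].carries_alt]
    row2 = private_filter(carried, case_id, control_ids)
    row3 = [v for v in row2 if consequences[v.key].protein_changing]
    panel = {g.upper() for g in candidate_genes}
    row4 = [
        v
        for v in row3
        if consequences[v.key].gene is not None
        and consequences[v.key].gene.upper() in panel
    ]

    rows, surviving = [], []
    for i, (label, kept) in enumerate(zip(ROW_LABELS, (carried, row2, row3, row4))):
        het, hom = _partition(kept, case_id)
        if i == 0 and row1 == "all":
            # reading in which row 1 counts every genotyped call of the
            # case: hom-ref sites join the homozygous column
            hom = hom + [
                v for v in variants if v.genotypes[case_id] is GenotypeCall.HOM_REF
            ]
        rows.append((label, len(het), len(hom)))
        surviving.append((het, hom))
    return FilterCascade(rows, surviving)
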