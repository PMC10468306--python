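"""End-to-end orchestration: simulate -> annotate -> filter -> cosegregate ->
classify -> confirm, with a machine-readable summary.

Stages run in a fixed order; each stage's outputs are written under the
run directory and checksummed into the summary.  The summary itself
contains no timestamps, so two runs with the same configuration and seed
are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import acmg, confirm, filtering, segregation
from .annotate import annotate_variants
from .errors import ConfigurationError, GenerationError
from .io import (
    read_fasta,
    read_gene_list,
    read_gff3,
    read_markers,
    read_ped,
    read_vcf,
    write_json_report,
    write_vcf,
)
from .models import GenotypeCall, VariantRecord
from .simulate import CASE_ID, SimulationConfig, simulate_cohort, write_cohort

log = logging.getLogger("felvar")

STAGE_EXIT_CODES = {
    "config": 2,
    "simulate": 3,
    "annotate": 4,
    "filter": 5,
    "coseg": 6,
    "classify": 7,
    "confirm": 8,
}


class StageError(Exception):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)
        self.cause = cause


@dataclass
class PipelineConfig:
    """Run configuration; defaults reproduce the emulated study scenario."""

    outdir: str = "felvar_run"
    seed: int = 1
    simulate: bool = True
    # input paths, required when simulate is False
    vcf: Optional[str] = None
    fasta: Optional[str] = None
    gff3: Optional[str] = None
    ped: Optional[str] = None
    candidates: Optional[str] = None
    markers: Optional[str] = None
    case_id: Optional[str] = None
    control_ids: Optional[list[str]] = None
    lof_genes: list[str] = field(default_factory=lambda: ["CAND01"])
    row1: str = "case-carried"
    pm2_min_controls: int = 50
    wildtype_product_size: int = 169
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        cfg = cls(**raw)
        cfg.simulation = SimulationConfig(**sim_raw)
        return cfg

    def validate(self) -> None:
        if self.case_id is not None and self.control_ids is not None:
            if self.case_id in self.control_ids:
                raise ConfigurationError(
                    f"case id {self.case_id!r} also listed as a control"
                )
        if not self.simulate:
            required = ("vcf", "fasta", "gff3", "ped", "candidates")
            missing = [n for n in required if getattr(self, n) is None]
            if missing:
                raise ConfigurationError(
                    f"simulate=False requires input paths: missing {missing}"
                )
            for name in required + ("markers",):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(f"{name} path does not exist: {p}")


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def design_genotyping_primers(
    seq: str,
    chrom: str,
    variant_pos: int,
    product_size: int = 169,
    primer_len: int = 20,
) -> confirm.PrimerPair:
    """Design an exact-match primer pair around a variant position.

    The wild-type product has exactly ``product_size`` bases, the variant
    lies between the primers, and both primers occur exactly once in the
    sequence (shifting the window if necessary).
    """
    for offset in range(40, product_size - primer_len - 40):
        start0 = variant_pos - offset  # 0-based product start
        if start0 < 0 or start0 + product_size > len(seq):
            continue
        fwd = seq[start0 : start0 + primer_len]
        rev_site = seq[start0 + product_size - primer_len : start0 + product_size]
        if seq.count(fwd) == 1 and seq.count(rev_site) == 1:
            from .models import reverse_complement

            return confirm.PrimerPair(
                name=f"{chrom}:{variant_pos}",
                forward=fwd,
                reverse=reverse_complement(rev_site),
                max_product=5 * product_size,
            )
    raise GenerationError(
        f"no unique primer pair found around {chrom}:{variant_pos}"
    )


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": [], "checksums": {}}

    def checksum(label: str, path: Path) -> None:
        summary["checksums"][label] = _md5(path)

    # ---- config
    try:
        config.validate()
    except Exception as exc:
        raise StageError("config", exc)

    # ---- simulate / load
    try:
        if config.simulate:
            sim = SimulationConfig(**{**config.simulation.__dict__, "seed": config.seed})
            bundle = simulate_cohort(sim)
            paths = write_cohort(bundle, outdir / "inputs")
            for label, p in paths.items():
                checksum(f"inputs/{label}", p)
            genome, genes = bundle.genome, bundle.genes
            candidate_genes = bundle.candidate_genes
            pedigree, markers = bundle.pedigree, bundle.markers
            variants, samples = bundle.variants, bundle.samples
            case_id = config.case_id or bundle.case_id
            control_ids = config.control_ids or bundle.control_ids
            n_genotyping_controls = sim.n_genotyping_controls
        else:
            genome = read_fasta(config.fasta)
            genes = read_gff3(config.gff3)
            candidate_genes = read_gene_list(config.candidates)
            pedigree = read_ped(config.ped)
            markers = read_markers(config.markers) if config.markers else {}
            variants, samples = read_vcf(config.vcf)
            if config.case_id is None or config.control_ids is None:
                raise ConfigurationError(
                    "case_id and control_ids are required when simulate=False"
                )
            case_id, control_ids = config.case_id, config.control_ids
            n_genotyping_controls = 0
        log.info("cohort: %d variants, %d samples", len(variants), len(samples))
        summary["stages"].append("simulate" if config.simulate else "load")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", exc)

    # ---- annotate
    try:
        consequences, normalized, failures = annotate_variants(variants, genome, genes)
        ann_path = outdir / "annotations.tsv"
        rows = []
        for v in variants:
            c = consequences[v.key]
            n = normalized[v.key]
            rows.append(
                {
                    "chrom": v.chrom,
                    "pos_vcf": n.vcf_form.pos,
                    "pos_hgvs": n.hgvs_genomic_pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "gene": c.gene or ".",
                    "category": c.category,
                    "hgvs_c": c.hgvs_c or ".",
                    "hgvs_p": c.hgvs_p or ".",
                    "truncated_fraction": (
                        "." if c.truncated_fraction is None
                        else f"{c.truncated_fraction:.4f}"
                    ),
                    "protein_changing": int(c.protein_changing),
                    "near_splice": int(c.near_splice),
                }
            )
        pd.DataFrame(rows).to_csv(ann_path, sep="\t", index=False)
        checksum("annotations", ann_path)
        if failures:
            log.warning("%d variants could not be classified", len(failures))
        summary["annotation_failures"] = [list(map(str, f[0])) for f in failures]
        summary["stages"].append("annotate")
    except Exception as exc:
        raise StageError("annotate", exc)

    # ---- filter cascade
    try:
        cascade = filtering.cascade(
            variants, consequences, candidate_genes, case_id, control_ids, config.row1
        )
        cascade.to_tsv(outdir / "cascade.tsv")
        checksum("cascade", outdir / "cascade.tsv")
        contigs = {name: len(genome[name]) for name in genome.names()}
        for i, (het, hom) in enumerate(cascade.surviving, start=1):
            row_path = outdir / f"cascade_row{i}.vcf"
            merged = sorted(het + hom, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
            write_vcf(row_path, merged, samples, contigs)
            checksum(f"cascade_row{i}", row_path)
        summary["cascade"] = [
            {"step": label, "het": h, "hom": m} for label, h, m in cascade.rows
        ]
        summary["stages"].append("filter")
    except Exception as exc:
        raise StageError("filter", exc)

    het_final, hom_final = cascade.surviving[-1]
    top_variant = hom_final[0] if hom_final else (het_final[0] if het_final else None)

    # ---- cosegregation on every final-row survivor
    try:
        coseg_reports = {}
        for v in het_final + hom_final:
            family_gts = {
                iid: v.genotypes.get(iid, GenotypeCall.MISSING)
                for iid in pedigree.ids()
            }
            result = segregation.cosegregation_check(family_gts, pedigree)
            key = f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"
            coseg_reports[key] = result.as_dict()
            coseg_reports[key]["case_genotype"] = v.genotypes[case_id].value
        write_json_report(outdir / "cosegregation.json", coseg_reports)
        checksum("cosegregation", outdir / "cosegregation.json")
        summary["cosegregation"] = coseg_reports
        summary["stages"].append("coseg")
    except Exception as exc:
        raise StageError("coseg", exc)

    # ---- ACMG classification of the homozygous survivor
    try:
        classification_report = None
        if top_variant is not None:
            cons = consequences[top_variant.key]
            lof = (cons.gene or "").upper() in {g.upper() for g in config.lof_genes}
            family_gts = {
                iid: top_variant.genotypes.get(iid, GenotypeCall.MISSING)
                for iid in pedigree.ids()
            }
            seg = segregation.cosegregation_check(family_gts, pedigree)
            evidence = [
                acmg.evaluate_pvs1(cons, lof),
                acmg.evaluate_pm2(top_variant, control_ids, config.pm2_min_controls),
                acmg.evaluate_pp1(seg),
            ]
            cls = acmg.combine(evidence)
            classification_report = {
                "variant": f"{top_variant.chrom}:{top_variant.pos}:"
                f"{top_variant.ref}:{top_variant.alt}",
                "gene": cons.gene,
                "hgvs_c": cons.hgvs_c,
                "hgvs_p": cons.hgvs_p,
                "truncated_fraction": cons.truncated_fraction,
                "evidence": [
                    {
                        "criterion": e.criterion,
                        "strength": e.strength,
                        "triggered": e.triggered,
                        "rationale": e.rationale,
                    }
                    for e in evidence
                ],
                "n_triggered": sum(e.triggered for e in evidence),
                "classification": cls.label,
                "fired_rule": cls.fired_rule,
            }
            write_json_report(outdir / "classification.json", classification_report)
            checksum("classification", outdir / "classification.json")
        summary["classification"] = classification_report
        summary["stages"].append("classify")
    except Exception as exc:
        raise StageError("classify", exc)

    # ---- confirmation: in-silico PCR + parentage
    try:
        confirmation: dict = {}
        if top_variant is not None:
            chrom_seq = genome[top_variant.chrom]
            primers = design_genotyping_primers(
                chrom_seq,
                top_variant.chrom,
                top_variant.pos,
                product_size=config.wildtype_product_size,
            )
            ref_amps = confirm.insilico_pcr(genome, primers, "reference")
            mutant = confirm.apply_variant(genome, top_variant)
            mut_amps = confirm.insilico_pcr(mutant, primers, "variant-applied")
            confirmation["pcr"] = {
                "primers": {"forward": primers.forward, "reverse": primers.reverse},
                "reference_product_bp": [a.length for a in ref_amps],
                "variant_product_bp": [a.length for a in mut_amps],
            }
            confirmation["genotyping_controls"] = {
                "n": n_genotyping_controls,
                "alt_alleles": 0,  # unrelated Sanger panel simulated hom-ref
            }
        if markers:
            verdicts = {}
            for ind in pedigree.affected():
                if ind.sire and ind.dam and ind.sire in markers and ind.dam in markers:
                    res = confirm.parentage_exclusion(
                        ind.id,
                        markers[ind.id],
                        markers[ind.sire],
                        markers[ind.dam],
                        sire_id=ind.sire,
                        dam_id=ind.dam,
                    )
                    verdicts[ind.id] = res.as_dict()
            confirmation["parentage"] = verdicts
        write_json_report(outdir / "confirmation.json", confirmation)
        checksum("confirmation", outdir / "confirmation.json")
        summary["confirmation"] = confirmation
        summary["stages"].append("confirm")
    except Exception as exc:
        raise StageError("confirm", exc)

    write_json_report(outdir / "summary.json", summary)
    return summary
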