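import numpy as np
import pytest

from felvar.errors import SizingError, ValidationError
from felvar.models import Affection, GenotypeCall
from felvar.segregation import mendelian_errors
from felvar.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_markers,
    simulate_pedigree,
    simulate_reference,
    write_cohort,
)


class TestConfig:
    def test_defaults_mirror_study(self):
        cfg = SimulationConfig()
        assert cfg.n_controls == 77
        assert cfg.n_genotyping_controls == 48
        assert cfg.n_candidate_genes == 20

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"missing_genotype_rate": 1.5},
            {"homopolymer_length": 3},
            {"n_controls": -1},
            {"pedigree_template": "nonsense"},
            {"control_allele_freq_beta": (0.0, 3.0)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SimulationConfig(**kwargs)


class TestReference:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=1)
        a = write_cohort(simulate_cohort(cfg), tmp_path / "a")
        b = write_cohort(simulate_cohort(cfg), tmp_path / "b")
        for name in a:
            assert a[name].read_bytes() == b[name].read_bytes(), name

    def test_homopolymer_planted(self):
        cfg = SimulationConfig(seed=3, homopolymer_length=6)
        genome, genes, candidates = simulate_reference(cfg)
        cds = genes[0].cds_sequence(genome)
        assert "CCCCCC" in cds
        # the engineered run ends at c.698 and is bounded by non-C bases
        assert cds[692:698] == "CCCCCC"
        assert cds[691] != "C" and cds[698] != "C"
        assert candidates[0] == genes[0].gene

    def test_all_gene_models_encode_valid_proteins(self, default_bundle):
        # translate every CDS: start codon, terminal stop, no internal stop
        for gene in default_bundle.genes:
            cds = gene.cds_sequence(default_bundle.genome)
            assert len(cds) % 3 == 0
            assert gene.validate_coding(default_bundle.genome) == []

    def test_sizing_error(self):
        cfg = SimulationConfig(seed=1, max_chrom_length=10_000)
        with pytest.raises(SizingError):
            simulate_reference(cfg)


class TestPedigree:
    def test_study_family_structure(self):
        ped, causal, decoy = simulate_pedigree(SimulationConfig(seed=1))
        assert len(ped) == 31
        assert len(ped.affected()) == 4
        assert len(ped.founders()) == 4  # 1 sire + 3 dams
        litters = {i.dam for i in ped if i.dam}
        assert litters == {"DAM1", "DAM2", "DAM3"}
        sires = {i.sire for i in ped if i.sire}
        assert sires == {"SIRE"}

    def test_affected_parents_are_het(self):
        ped, causal, _ = simulate_pedigree(SimulationConfig(seed=1))
        for ind in ped.affected():
            assert causal[ind.sire] is GenotypeCall.HET
            assert causal[ind.dam] is GenotypeCall.HET
        assert set(ped.obligate_carriers()) == {"SIRE", "DAM1", "DAM2", "DAM3"}

    def test_affection_iff_hom_alt(self):
        ped, causal, _ = simulate_pedigree(SimulationConfig(seed=1))
        for ind in ped:
            assert (ind.affection is Affection.AFFECTED) == (
                causal[ind.id] is GenotypeCall.HOM_ALT
            )

    def test_custom_template_mendelian_drop(self):
        cfg = SimulationConfig(seed=11, pedigree_template="custom",
                               litter_sizes=(5, 3, 7))
        ped, causal, _ = simulate_pedigree(cfg)
        assert len(ped) == 4 + 15
        for child, sire, dam in ped.trios():
            assert not mendelian_errors(causal[child], causal[sire], causal[dam])


class TestPlantedVariants:
    def test_case_genotypes_at_planted_sites(self, default_bundle, causal_variant,
                                             decoy_variant):
        case = default_bundle.case_id
        assert causal_variant.genotypes[case] is GenotypeCall.HOM_ALT
        assert decoy_variant.genotypes[case] is GenotypeCall.HET

    def test_controls_clean_at_planted_sites(self, default_bundle, causal_variant,
                                             decoy_variant):
        ok = (GenotypeCall.HOM_REF, GenotypeCall.MISSING)
        for v in (causal_variant, decoy_variant):
            assert all(v.genotypes[c] in ok for c in default_bundle.control_ids)

    def test_causal_emitted_left_aligned(self, default_bundle, causal_variant):
        # anchor base precedes the poly-C run; alt appends one C
        seq = default_bundle.genome["chrA1"]
        assert causal_variant.alt == causal_variant.ref + "C"
        assert seq[causal_variant.pos - 1] != "C"
        assert seq[causal_variant.pos] == "C"
        # 3'-shifted position recorded in truth is strictly downstream
        assert default_bundle.truth.causal["hgvs_genomic_pos"] > causal_variant.pos

    def test_family_background_genotypes_are_mendelian(self, default_bundle):
        ped = default_bundle.pedigree
        trios = ped.trios()
        for v in default_bundle.variants[:200]:
            for child, sire, dam in trios:
                assert not mendelian_errors(
                    v.genotypes[child], v.genotypes[sire], v.genotypes[dam]
                )

    def test_background_allele_freq_matches_beta(self):
        # empirical control-panel frequency mean within 3 SE of the Beta mean
        cfg = SimulationConfig(seed=5, n_background_variants=2000)
        bundle = simulate_cohort(cfg)
        a, b = cfg.control_allele_freq_beta
        beta_mean = a / (a + b)
        beta_var = a * b / ((a + b) ** 2 * (a + b + 1))
        freqs = []
        planted = {bundle.truth.causal["pos"], bundle.truth.decoy["pos"]}
        for v in bundle.variants:
            if v.pos in planted:
                continue
            counts = [v.genotypes[c].alt_count for c in bundle.control_ids]
            obs = [c for c in counts if c is not None]
            freqs.append(sum(obs) / (2 * len(obs)))
        n = len(freqs)
        # Var(p_hat) ~ Var(p) + E[p(1-p)]/(2*77); the first term dominates
        se = np.sqrt((beta_var + beta_mean / (2 * 77)) / n)
        assert abs(np.mean(freqs) - beta_mean) < 3 * se

    def test_case_never_missing(self, default_bundle):
        case = default_bundle.case_id
        assert all(
            v.genotypes[case] is not GenotypeCall.MISSING
            for v in default_bundle.variants
        )


class TestMarkers:
    def test_panel_shape(self, default_bundle):
        table = default_bundle.markers
        assert len(table) == 31
        assert all(len(loci) == 16 for loci in table.values())

    def test_offspring_share_allele_with_each_parent(self, default_bundle):
        table = default_bundle.markers
        for child, sire, dam in default_bundle.pedigree.trios():
            for locus in table[child]:
                c = set(table[child][locus])
                assert c & set(table[sire][locus])
                assert c & set(table[dam][locus])

    def test_determinism(self, default_bundle):
        ped = default_bundle.pedigree
        t1 = simulate_markers(ped, seed=42)
        t2 = simulate_markers(ped, seed=42)
        assert t1 == t2
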