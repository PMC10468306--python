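import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from felvar.annotate import (
    Annotator,
    apply_variant_to_sequence,
    call_consequence,
    normalize,
    translate_full,
    truncation_fraction,
)
from felvar.errors import ContractError, ReferenceMismatchError
from felvar.models import GeneModel, ReferenceGenome, VariantRecord

from _oracles import (
    enumerate_deletion_placements,
    enumerate_insertion_placements,
    oracle_consequence,
    oracle_hgvs_p,
)


def _genome(seq: str) -> ReferenceGenome:
    return ReferenceGenome({"c": seq})


class TestNormalize:
    def test_insertion_in_homopolymer_shifts_3prime(self):
        # inserting C after pos 2 of TACCCCGA duplicates the run; the
        # rightmost equivalent placement is after the last C (pos 6)
        g = _genome("TACCCCGA")
        norm = normalize(VariantRecord("c", 2, "A", "AC", {}), g)
        mutant = apply_variant_to_sequence(g["c"], norm.vcf_form)
        placements = enumerate_insertion_placements(g["c"], mutant)
        assert norm.hgvs_genomic_pos == max(placements) == 6
        assert norm.is_duplication
        assert norm.vcf_form.pos == 2  # already left-aligned

    def test_snv_is_fixed_point(self):
        g = _genome("TACCCCGA")
        norm = normalize(VariantRecord("c", 4, "C", "G", {}), g)
        assert norm.hgvs_genomic_pos == 4
        assert norm.vcf_form.key == ("c", 4, "C", "G")
        assert not norm.is_duplication

    def test_deletion_in_homopolymer(self):
        g = _genome("TACCCCGA")
        norm = normalize(VariantRecord("c", 2, "AC", "A", {}), g)
        mutant = apply_variant_to_sequence(g["c"], norm.vcf_form)
        placements = enumerate_deletion_placements(g["c"], mutant)
        # rightmost equivalent deleted base is the last C of the run
        assert norm.hgvs_genomic_pos - 1 == max(placements) == 5
        # both placements describe the same edited sequence
        right_form = g["c"][:5] + g["c"][6:]
        assert mutant == right_form

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ReferenceMismatchError):
            normalize(VariantRecord("c", 1, "G", "T", {}), _genome("TACG"))

    def test_oracle_1000_random_indels(self):
        # repeat-rich random genomes force nontrivial shifts both ways
        rng = np.random.default_rng(2024)
        n_checked = 0
        while n_checked < 1000:
            seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.5, 0.2, 0.1], size=60))
            g = _genome(seq)
            pos = int(rng.integers(2, 50))
            if rng.random() < 0.5:  # insertion, 1-3 bp
                ins = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 4)))
                v = VariantRecord("c", pos, seq[pos - 1], seq[pos - 1] + ins, {})
            else:  # deletion, 1-3 bp
                length = int(rng.integers(1, 4))
                if pos + length > len(seq):
                    continue
                v = VariantRecord(
                    "c", pos, seq[pos - 1 : pos + length], seq[pos - 1], {}
                )
            norm = normalize(v, g)
            mutant_in = apply_variant_to_sequence(seq, v)
            mutant_norm = apply_variant_to_sequence(seq, norm.vcf_form)
            assert mutant_norm == mutant_in  # normalization preserves the edit
            if len(v.alt) > len(v.ref):
                placements = enumerate_insertion_placements(seq, mutant_in)
                assert norm.hgvs_genomic_pos == max(placements)
                if min(placements) > 0:
                    assert (
                        norm.vcf_form.pos + len(norm.vcf_form.ref) - 1
                        == min(placements)
                    )
                L = len(v.alt) - len(v.ref)
                p = norm.hgvs_genomic_pos
                expected_dup = p >= L and seq[p - L : p] == mutant_in[p : p + L]
                assert norm.is_duplication == expected_dup
            else:
                placements = enumerate_deletion_placements(seq, mutant_in)
                assert norm.hgvs_genomic_pos - 1 == max(placements)
            # idempotence
            again = normalize(norm.vcf_form, g)
            assert again.vcf_form.key == norm.vcf_form.key
            assert again.hgvs_genomic_pos == norm.hgvs_genomic_pos
            n_checked += 1


@settings(max_examples=300, derandomize=True)
@given(
    seq=st.text(alphabet="AC", min_size=12, max_size=40),
    pos=st.integers(min_value=2, max_value=10),
    ins=st.text(alphabet="ACGT", min_size=1, max_size=3),
    deletion=st.booleans(),
    length=st.integers(min_value=1, max_value=3),
)
def test_normalize_sequence_equivalence_property(seq, pos, ins, deletion, length):
    """Any indel representation normalizes to an edit-preserving, idempotent
    form whose left and 3'-shifted placements describe the same sequence."""
    g = ReferenceGenome({"c": seq})
    if deletion:
        if pos + length > len(seq):
            return
        v = VariantRecord("c", pos, seq[pos - 1 : pos + length], seq[pos - 1], {})
    else:
        v = VariantRecord("c", pos, seq[pos - 1], seq[pos - 1] + ins, {})
    norm = normalize(v, g)
    assert apply_variant_to_sequence(seq, norm.vcf_form) == apply_variant_to_sequence(
        seq, v
    )
    again = normalize(norm.vcf_form, g)
    assert again.vcf_form.key == norm.vcf_form.key
    assert again.hgvs_genomic_pos == norm.hgvs_genomic_pos


class TestPaperScaleConsequences:
    """The engineered genes reproduce the published annotation strings."""

    def test_causal_duplication(self, default_bundle, causal_variant):
        b = default_bundle
        ann = Annotator(b.genome, b.genes)
        norm = normalize(causal_variant, b.genome)
        cons = call_consequence(norm, b.genes[0], b.genome, ann)
        assert cons.category == "frameshift"
        assert cons.hgvs_c == "c.698dup"
        assert cons.hgvs_p == "p.(Ser235Glnfs*4)"
        assert cons.protein_changing
        assert norm.is_duplication

    def test_causal_truncates_about_80_percent(self, default_bundle, causal_variant):
        b = default_bundle
        norm = normalize(causal_variant, b.genome)
        cons = call_consequence(norm, b.genes[0], b.genome)
        assert cons.wt_protein_length == 1211
        assert truncation_fraction(cons) == pytest.approx(1 - 237 / 1211)
        assert truncation_fraction(cons) == pytest.approx(0.8, abs=0.02)

    def test_decoy_missense(self, default_bundle, decoy_variant):
        b = default_bundle
        norm = normalize(decoy_variant, b.genome)
        cons = call_consequence(norm, b.genes[1], b.genome)
        assert cons.category == "missense"
        assert cons.hgvs_c == "c.2384G>A"
        assert cons.hgvs_p == "p.(Arg795Gln)"

    def test_synonymous_third_position(self, default_bundle):
        # find a codon whose third-position change preserves the residue
        b = default_bundle
        gene = b.genes[0]
        cds = gene.cds_sequence(b.genome)
        from Bio.Seq import Seq

        for codon_i in range(5, 200):
            codon = cds[3 * codon_i : 3 * codon_i + 3]
            for new in "ACGT":
                if new == codon[2]:
                    continue
                if str(Seq(codon).translate()) == str(Seq(codon[:2] + new).translate()):
                    c_pos = 3 * codon_i + 3
                    g_pos = gene.cds_to_genomic(c_pos)
                    ref = b.genome.fetch("chrA1", g_pos, g_pos)
                    alt = new if gene.strand == "+" else new  # gene 0 is plus strand
                    v = VariantRecord("chrA1", g_pos, ref, alt, {})
                    cons = call_consequence(normalize(v, b.genome), gene, b.genome)
                    assert cons.category == "synonymous"
                    assert not cons.protein_changing
                    return
        pytest.fail("no synonymous site found in the first 200 codons")


class TestTruncationFraction:
    def _tiny_gene(self):
        # 10-codon gene: stop introduced at codon 3 leaves 2 residues -> 0.8
        cds = "ATG" + "TGG" * 8 + "TAA"  # Met + 8 Trp + stop
        genome = ReferenceGenome({"c": "AAAA" + cds + "TTTT"})
        gene = GeneModel("T", "T.t1", "c", "+", [(5, 4 + len(cds))])
        return genome, gene

    def test_premature_stop_arithmetic(self):
        genome, gene = self._tiny_gene()
        # TGG -> TGA at codon 3 (c.9 G>A)
        g_pos = gene.cds_to_genomic(9)
        v = VariantRecord("c", g_pos, "G", "A", {})
        cons = call_consequence(normalize(v, genome), gene, genome)
        assert cons.category == "stop_gained"
        assert truncation_fraction(cons) == pytest.approx(1 - 2 / 9)

    def test_stop_at_final_codon_truncates_little(self):
        genome, gene = self._tiny_gene()
        g_pos = gene.cds_to_genomic(27)  # codon 9, last before the stop
        v = VariantRecord("c", g_pos, "G", "A", {})
        cons = call_consequence(normalize(v, genome), gene, genome)
        assert cons.category == "stop_gained"
        assert truncation_fraction(cons) == pytest.approx(1 / 9)

    def test_contract_error_on_non_truncating(self, default_bundle, decoy_variant):
        b = default_bundle
        cons = call_consequence(
            normalize(decoy_variant, b.genome), b.genes[1], b.genome
        )
        with pytest.raises(ContractError):
            truncation_fraction(cons)


def _plant_random_cds_variant(rng, gene, genome_seq):
    """Random SNV/ins/del strictly inside one CDS interval (safe margins)."""
    intervals = [iv for iv in gene.cds_intervals if iv[1] - iv[0] > 30]
    s, e = intervals[rng.integers(0, len(intervals))]
    pos = int(rng.integers(s + 12, e - 12))
    kind = ["snv", "ins", "del"][rng.integers(0, 3)]
    ref1 = genome_seq[pos - 1]
    if kind == "snv":
        alt = rng.choice([b for b in "ACGT" if b != ref1])
        return VariantRecord("chrA1", pos, ref1, str(alt), {})
    if kind == "ins":
        ins = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 4)))
        return VariantRecord("chrA1", pos, ref1, ref1 + ins, {})
    length = int(rng.integers(1, 4))
    return VariantRecord(
        "chrA1", pos, genome_seq[pos - 1 : pos + length], ref1, {}
    )


@pytest.mark.parametrize("strand_gene_index", [0, 1], ids=["plus", "minus"])
def test_consequence_oracle_1000_variants_per_strand(small_bundle, strand_gene_index):
    """Category/hgvs_p agree with a genome-rebuild + translate oracle."""
    b = small_bundle
    gene = b.genes[strand_gene_index]
    assert gene.strand == "+-"[strand_gene_index]
    seq = b.genome["chrA1"]
    ann = Annotator(b.genome, b.genes)
    rng = np.random.default_rng(99 + strand_gene_index)
    checked = 0
    while checked < 1000:
        v = _plant_random_cds_variant(rng, gene, seq)
        norm = normalize(v, b.genome)
        nv = norm.vcf_form
        # skip edits whose equivalent placements approach an exon boundary:
        # their annotation is representation-dependent by convention
        span = abs(norm.hgvs_genomic_pos - nv.pos) + len(nv.ref) + 4
        if not any(
            s + span <= nv.pos and norm.hgvs_genomic_pos + span <= e
            for s, e in gene.cds_intervals
            if s <= nv.pos <= e
        ):
            continue
        expected = oracle_consequence(seq, gene, nv.pos, nv.ref, nv.alt)
        if expected is None:
            continue
        cons = call_consequence(norm, gene, b.genome, ann)
        assert cons.category == expected["category"], (v.key, cons.hgvs_c)
        want_p = oracle_hgvs_p(
            expected["wt_prot"], expected["mut_prot"], expected["category"]
        )
        if want_p is not None and "*?" not in (cons.hgvs_p or ""):
            assert cons.hgvs_p == want_p, (v.key, cons.category, cons.hgvs_c)
        checked += 1


def test_strand_symmetry(small_bundle):
    """Mirroring the genome and gene model leaves hgvs_c/hgvs_p unchanged."""
    from felvar.models import reverse_complement

    b = small_bundle
    seq = b.genome["chrA1"]
    n = len(seq)
    mirrored_genome = ReferenceGenome({"chrA1": reverse_complement(seq)})
    rng = np.random.default_rng(7)
    for gene in b.genes[:2]:
        flipped = GeneModel(
            gene.gene,
            gene.transcript,
            "chrA1",
            "-" if gene.strand == "+" else "+",
            [(n - e + 1, n - s + 1) for s, e in gene.cds_intervals],
        )
        assert flipped.cds_sequence(mirrored_genome) == gene.cds_sequence(b.genome)
        checked = 0
        while checked < 50:
            v = _plant_random_cds_variant(rng, gene, seq)
            norm = normalize(v, b.genome)
            mirrored_v = VariantRecord(
                "chrA1",
                n - (v.pos + len(v.ref) - 1) + 1,
                reverse_complement(v.ref),
                reverse_complement(v.alt),
                {},
            )
            m_norm = normalize(mirrored_v, mirrored_genome)
            try:
                cons = call_consequence(norm, gene, b.genome)
                m_cons = call_consequence(m_norm, flipped, mirrored_genome)
            except Exception:
                continue
            assert (cons.category, cons.hgvs_c, cons.hgvs_p) == (
                m_cons.category, m_cons.hgvs_c, m_cons.hgvs_p,
            )
            checked += 1
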