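"""Codon genotype reconstruction, translation, amino-acid variant calling
and major-allele polarization."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix, small_config
from hybridload.codons import (
    build_codon_genotypes,
    call_amino_acid_variants,
    polarize_and_patch,
    translate_codon_genotypes,
)
from hybridload.datatypes import CodingRegion
from hybridload.genetics import translate_codon
from hybridload.synthetic import simulate_dataset
from oracles import bio_translate

REGION = {"gene_000": CodingRegion("gene_000", "ACGAAATTTGGG")}


def _codon_pair(table, entry, individual):
    ids = table.ids[entry, individual]
    if ids[0] < 0:
        return None
    return tuple(sorted(table.alleles[entry][a] for a in ids))


class TestBuildCodonGenotypes:
    def test_het_snp_substitutes_into_reference_codon(self):
        # reference codon ACG, SNP at offset 1, C/T het -> {ACG, ATG}
        m = make_matrix([[1]], pos=[2], ref="C", alt="T")
        table = build_codon_genotypes(m, REGION)
        assert table.alleles[0] == ["ACG", "ATG"]
        assert _codon_pair(table, 0, 0) == ("ACG", "ATG")

    def test_hom_ref_individual_keeps_reference_pair(self):
        m = make_matrix([[0]], pos=[2], ref="C", alt="T")
        table = build_codon_genotypes(m, REGION)
        assert _codon_pair(table, 0, 0) == ("ACG", "ACG")

    def test_missing_constituent_makes_codon_missing(self):
        m = make_matrix([[1], [-1]], pos=[4, 6], ref=["A", "A"], alt=["C", "G"])
        table = build_codon_genotypes(m, REGION)
        assert _codon_pair(table, 0, 0) is None

    def test_two_het_snps_use_ref_together_phasing(self):
        # ref codon AAA with het alts at offsets 0 and 2; of the two possible
        # phasings {AAA,CAG} and {CAA,AAG}, the convention keeps refs together
        region = {"gene_000": CodingRegion("gene_000", "AAATTTGGG")}
        m = make_matrix([[1], [1]], pos=[1, 3], ref=["A", "A"], alt=["C", "G"])
        table = build_codon_genotypes(m, region)
        assert _codon_pair(table, 0, 0) == ("AAA", "CAG")
        assert bool(table.entries["phased_by_convention"].iloc[0])
        enumerated = [("AAA", "CAG"), ("AAG", "CAA")]
        assert _codon_pair(table, 0, 0) in enumerated

    def test_mixed_hom_and_het_snps_in_one_codon(self):
        region = {"gene_000": CodingRegion("gene_000", "AAATTTGGG")}
        m = make_matrix([[2], [1]], pos=[1, 3], ref=["A", "A"], alt=["C", "G"])
        table = build_codon_genotypes(m, region)
        assert _codon_pair(table, 0, 0) == ("CAA", "CAG")
        assert not bool(table.entries["phased_by_convention"].iloc[0])

    def test_indel_allele_rejected(self):
        m = make_matrix([[1]], pos=[2], ref="C", alt="TT")
        with pytest.raises(ValueError, match="indels"):
            build_codon_genotypes(m, REGION)

    def test_reference_mismatch_rejected(self):
        m = make_matrix([[1]], pos=[2], ref="G", alt="T")
        with pytest.raises(ValueError, match="does not match"):
            build_codon_genotypes(m, REGION)


def test_translation_of_all_observed_codons_matches_standard_code(small_dataset):
    table = build_codon_genotypes(small_dataset.genotype_matrix, small_dataset.coding_regions)
    for alleles, aas in zip(table.alleles, translate_codon_genotypes(table)):
        for codon, aa in zip(alleles, aas):
            assert aa == bio_translate(codon)


class TestVariantCalling:
    def _table(self, gt_row, cds="ACGAAA", ref="C", alt="T", pos=2):
        region = {"gene_000": CodingRegion("gene_000", cds)}
        m = make_matrix([gt_row], pos=[pos], ref=ref, alt=alt)
        return build_codon_genotypes(m, region)

    def test_minor_allele_frequency_from_counts(self):
        # 300 individuals: 280 hom Thr + 20 het -> 580 Thr, 20 Met of 600
        gt = [0] * 280 + [1] * 20
        aa = call_amino_acid_variants(self._table(gt), min_alleles=500)
        row = aa.variants.iloc[0]
        assert (row.major_aa, row.minor_aa) == ("T", "M")
        assert row.minor_count == 20
        assert row.alleles_genotyped == 600
        assert row.minor_freq == pytest.approx(20 / 600)
        assert row.var_class == "nonsynonymous"

    def test_tied_major_alleles_removed(self):
        gt = [0] * 130 + [2] * 130  # 260 Thr vs 260 Met
        aa = call_amino_acid_variants(self._table(gt), min_alleles=500)
        assert len(aa.variants) == 0
        assert list(aa.removals["reason"]) == ["removed_tie"]

    def test_low_call_positions_removed(self):
        gt = [0] * 200 + [1] * 49 + [-1]  # 498 alleles genotyped
        aa = call_amino_acid_variants(self._table(gt), min_alleles=500)
        assert list(aa.removals["reason"]) == ["removed_low_call"]

    def test_stop_involving_positions_removed(self):
        # TAC -> TAA creates a stop allele
        gt = [0] * 260 + [1] * 40
        aa = call_amino_acid_variants(
            self._table(gt, cds="TACAAA", ref="C", alt="A", pos=3), min_alleles=500
        )
        assert list(aa.removals["reason"]) == ["removed_stop"]

    def test_synonymous_codon_variant_recorded(self):
        # TTT -> TTC, both Phe
        gt = [0] * 280 + [1] * 20
        aa = call_amino_acid_variants(
            self._table(gt, cds="TTTAAA", ref="T", alt="C", pos=3), min_alleles=500
        )
        row = aa.variants.iloc[0]
        assert row.var_class == "synonymous"
        assert (row.major_codon, row.minor_codon) == ("TTT", "TTC")
        assert row.minor_count == 20

    def test_multiallelic_position_emits_each_minor(self):
        # two SNPs in one codon producing three amino acids
        region = {"gene_000": CodingRegion("gene_000", "AAATTT")}
        gt = np.zeros((2, 300), dtype=np.int8)
        gt[0, :30] = 1  # AAA->CAA (K->Q)
        gt[1, 30:50] = 1  # AAA->AAG... offset2: K unchanged? use nonsyn: pos3 A->C (AAC, N)
        m = make_matrix(gt, pos=[1, 3], ref=["A", "A"], alt=["C", "C"])
        table = build_codon_genotypes(m, region)
        aa = call_amino_acid_variants(table, min_alleles=500)
        assert set(aa.variants["minor_aa"]) == {"Q", "N"}
        assert (aa.variants["major_aa"] == "K").all()
        assert (aa.variants["minor_freq"] <= 0.5).all()

    def test_allele_count_conservation_and_dosage_consistency(self, small_dataset):
        table = build_codon_genotypes(
            small_dataset.genotype_matrix, small_dataset.coding_regions
        )
        aa = call_amino_acid_variants(table, min_alleles=30)
        v = aa.variants
        assert ((v["minor_freq"] > 0) & (v["minor_freq"] <= 0.5)).all()
        assert (v["alleles_genotyped"] >= 30).all()
        for k in range(len(v)):
            dos = aa.dosages[k]
            called = dos >= 0
            # summing the dosage over individuals recovers the minor count
            assert dos[called].sum() == v["minor_count"].iloc[k]
            assert 2 * called.sum() == v["alleles_genotyped"].iloc[k]


class TestPolarizeAndPatch:
    def test_reference_minor_allele_is_replaced(self):
        # reference ACG (Thr) but major allele is Met (ATG)
        gt = [2] * 290 + [1] * 10
        region = {"gene_000": CodingRegion("gene_000", "ACGAAA")}
        m = make_matrix([gt], pos=[2], ref="C", alt="T")
        table = build_codon_genotypes(m, region)
        aa = call_amino_acid_variants(table, min_alleles=500)
        patch = polarize_and_patch(region, aa)
        assert patch.proteins["gene_000"][0] == "M"
        assert patch.n_reference_minor == 1
        assert aa.variants.iloc[0]["minor_aa"] == "T"

    def test_reference_equal_major_keeps_sequence(self):
        gt = [0] * 290 + [1] * 10
        region = {"gene_000": CodingRegion("gene_000", "ACGAAA")}
        m = make_matrix([gt], pos=[2], ref="C", alt="T")
        table = build_codon_genotypes(m, region)
        aa = call_amino_acid_variants(table, min_alleles=500)
        patch = polarize_and_patch(region, aa)
        assert patch.proteins["gene_000"] == region["gene_000"].protein
        assert patch.n_reference_minor == 0

    def test_patched_residues_match_recounted_majors(self, small_dataset):
        table = build_codon_genotypes(
            small_dataset.genotype_matrix, small_dataset.coding_regions
        )
        aa = call_amino_acid_variants(table, min_alleles=30)
        patch = polarize_and_patch(small_dataset.coding_regions, aa)
        aa_per_entry = translate_codon_genotypes(table)
        lookup = {
            (table.entries["gene"].iloc[e], table.entries["codon_index"].iloc[e] + 1): e
            for e in range(table.n_codons)
        }
        for rec in aa.variants.itertuples(index=False):
            e = lookup[(rec.gene, rec.protein_pos)]
            ids = table.ids[e]
            called = ids[:, 0] >= 0
            aas = [aa_per_entry[e][a] for a in ids[called].ravel()]
            values, counts = np.unique(aas, return_counts=True)
            recounted_major = values[np.argmax(counts)]
            assert patch.proteins[rec.gene][rec.protein_pos - 1] == recounted_major

    def test_out_of_range_position_errors(self):
        region = {"gene_000": CodingRegion("gene_000", "ACGAAA")}
        gt = [1] * 100 + [0] * 200
        m = make_matrix([gt], pos=[2], ref="C", alt="T")
        table = build_codon_genotypes(m, region)
        aa = call_amino_acid_variants(table, min_alleles=100)
        aa.variants.loc[0, "protein_pos"] = 99
        with pytest.raises(ValueError, match="outside protein"):
            polarize_and_patch(region, aa)


def test_called_classes_agree_with_simulator_truth():
    """At complete data, every called variant's synonymous/nonsynonymous
    class matches the simulator's truth for its codon."""
    ds = simulate_dataset(small_config(missing_rate=0.0))
    table = build_codon_genotypes(ds.genotype_matrix, ds.coding_regions)
    aa = call_amino_acid_variants(table, min_alleles=1)
    truth = ds.true_variant_classes
    truth_by_codon = {
        (r.gene, r.codon_index + 1): r.category for r in truth.itertuples(index=False)
    }
    checked = 0
    for rec in aa.variants.itertuples(index=False):
        cat = truth_by_codon.get((rec.gene, rec.protein_pos))
        if cat is None:
            continue
        if rec.var_class == "synonymous":
            assert cat == "synonymous"
        else:
            assert cat in ("neutral_nonsyn", "deleterious_nonsyn")
        checked += 1
    assert checked > 100
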