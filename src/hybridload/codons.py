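"""Codon genotypes from SNP calls, translation, amino-acid variant calling,
and major/minor polarization with reference patching.

Genotypes are unphased; when a codon contains two or more heterozygous
SNPs the two codon haplotypes cannot be resolved and the "ref-together"
convention is applied: reference alleles on one haplotype, alternates on
the other.  Affected codons are flagged.  A codon with any missing
constituent genotype is missing for that individual, and "alleles
genotyped" at a position means two per fully genotyped individual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CodingRegion, GenotypeMatrix
from .genetics import BASES, translate_codon

# gt dosage -> (hap1 allele id, hap2 allele id) for a single-SNP codon
_PAIR_OF_GT = np.array([[-1, -1], [0, 0], [0, 1], [1, 1]], dtype=np.int8)


@dataclass
class CodonGenotypeTable:
    """Per polymorphic codon: its observed codon alleles and, per
    individual, the pair of codon-allele ids (-1,-1 when missing)."""

    individuals: list[str]
    entries: pd.DataFrame  # gene, codon_index, n_alleles, multi_snp, phased_by_convention
    alleles: list[list[str]]
    ids: np.ndarray  # (n_codons, n_individuals, 2) int8
    regions: dict[str, CodingRegion]

    @property
    def n_codons(self) -> int:
        return len(self.entries)


@dataclass
class AminoAcidVariantTable:
    """Called amino-acid variants plus per-individual minor-allele dosages.

    ``variants`` has one row per minor allele (a multi-allelic position
    contributes several rows); ``dosages[v, i]`` counts copies of variant
    v's minor allele in individual i (-1 when the position is missing).
    ``positions``/``position_called`` cover the retained nonsynonymous
    (amino-acid polymorphic) positions used as per-individual denominators.
    """

    individuals: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    removals: pd.DataFrame
    positions: pd.DataFrame
    position_called: np.ndarray


def build_codon_genotypes(
    matrix: GenotypeMatrix, regions: dict[str, CodingRegion]
) -> CodonGenotypeTable:
    """Reconstruct the two codon strings per individual at every codon
    containing one or more SNPs."""
    sites = matrix.sites
    for col in ("ref", "alt"):
        bad = ~sites[col].astype(str).isin(list(BASES))
        if bad.any():
            offender = sites.loc[bad, col].iloc[0]
            raise ValueError(
                f"SNP allele {offender!r} is not a single nucleotide (indels unsupported)"
            )

    codon_idx = np.empty(len(sites), dtype=int)
    offsets = np.empty(len(sites), dtype=int)
    for i, row in enumerate(sites.itertuples(index=False)):
        region = regions[row.gene]
        c, off = region.codon_of(int(row.pos))
        if region.cds[int(row.pos) - 1] != row.ref:
            raise ValueError(
                f"{row.gene}:{row.pos} reference allele {row.ref!r} does not "
                f"match the CDS base {region.cds[int(row.pos) - 1]!r}"
            )
        codon_idx[i], offsets[i] = c, off

    order = np.lexsort((codon_idx, sites["gene"].to_numpy()))
    n_ind = matrix.n_individuals
    entry_rows, alleles_out, ids_out = [], [], []

    i = 0
    while i < len(order):
        j = i + 1
        g = sites["gene"].iloc[order[i]]
        c = codon_idx[order[i]]
        while j < len(order) and sites["gene"].iloc[order[j]] == g and codon_idx[order[j]] == c:
            j += 1
        group = order[i:j]
        i = j
        region = regions[g]
        ref_codon = region.ref_codon(c)
        if len(group) == 1:
            row = group[0]
            off = offsets[row]
            alt_codon = ref_codon[:off] + sites["alt"].iloc[row] + ref_codon[off + 1 :]
            ids = _PAIR_OF_GT[matrix.gt[row] + 1]
            alleles = [ref_codon, alt_codon]
            multi = phased = False
        else:
            gts = matrix.gt[group]  # (k, n_ind)
            missing = (gts < 0).any(axis=0)
            hap1 = np.tile(np.array(list(ref_codon)), (n_ind, 1))
            hap2 = hap1.copy()
            for s_row, s_idx in enumerate(group):
                off = offsets[s_idx]
                alt = sites["alt"].iloc[s_idx]
                hap2[gts[s_row] >= 1, off] = alt  # het: alt on hap2 (ref-together)
                hap1[gts[s_row] == 2, off] = alt
            allele_map: dict[str, int] = {ref_codon: 0}
            alleles = [ref_codon]
            ids = np.full((n_ind, 2), -1, dtype=np.int8)
            for ind in range(n_ind):
                if missing[ind]:
                    continue
                for h, hap in enumerate((hap1, hap2)):
                    codon = "".join(hap[ind])
                    if codon not in allele_map:
                        allele_map[codon] = len(alleles)
                        alleles.append(codon)
                    ids[ind, h] = allele_map[codon]
            multi = True
            phased = bool((((gts == 1).sum(axis=0) >= 2) & ~missing).any())
        entry_rows.append(
            {
                "gene": g,
                "codon_index": int(c),
                "n_alleles": len(alleles),
                "multi_snp": multi,
                "phased_by_convention": phased,
            }
        )
        alleles_out.append(alleles)
        ids_out.append(ids)

    entries = pd.DataFrame(
        entry_rows,
        columns=["gene", "codon_index", "n_alleles", "multi_snp", "phased_by_convention"],
    )
    ids_arr = (
        np.stack(ids_out) if ids_out else np.empty((0, n_ind, 2), dtype=np.int8)
    )
    return CodonGenotypeTable(
        individuals=list(matrix.individuals),
        entries=entries,
        alleles=alleles_out,
        ids=ids_arr,
        regions=regions,
    )


def translate_codon_genotypes(table: CodonGenotypeTable) -> list[list[str]]:
    """Translate each entry's codon alleles; returns one amino-acid list per
    entry, aligned with ``table.alleles`` (stop codons become '*')."""
    return [[translate_codon(c) for c in alleles] for alleles in table.alleles]


def call_amino_acid_variants(
    table: CodonGenotypeTable, min_alleles: int = 500
) -> AminoAcidVariantTable:
    """Call amino-acid variants per protein position with the hard filters.

    Removal reasons: ``removed_low_call`` (< ``min_alleles`` alleles
    genotyped), ``removed_stop`` (any observed allele translates to a
    stop), ``removed_tie`` (top two allele counts equal, i.e. more than one
    major allele).  Positions where the observed codon alleles all encode
    one amino acid are emitted as synonymous variants with codon-level
    major/minor; every non-major amino acid at a retained position becomes
    its own variant row.
    """
    aa_per_entry = translate_codon_genotypes(table)
    n_ind = len(table.individuals)
    variant_rows, removal_rows, dosage_rows = [], [], []
    position_rows, position_called = [], []

    for e in range(table.n_codons):
        gene = table.entries["gene"].iloc[e]
        ppos = int(table.entries["codon_index"].iloc[e]) + 1
        ids = table.ids[e]
        called = ids[:, 0] >= 0
        n_called = int(called.sum())
        alleles_genotyped = 2 * n_called
        if alleles_genotyped == 0:
            continue
        flat = ids[called].ravel()
        cnt = np.bincount(flat, minlength=len(table.alleles[e]))
        observed = np.flatnonzero(cnt)
        if alleles_genotyped < min_alleles:
            removal_rows.append((gene, ppos, "removed_low_call"))
            continue
        aa_list = aa_per_entry[e]
        if any(aa_list[k] == "*" for k in observed):
            removal_rows.append((gene, ppos, "removed_stop"))
            continue
        if len(observed) < 2:
            continue  # monomorphic after missing-data removal

        observed_aas = sorted({aa_list[k] for k in observed})
        if len(observed_aas) == 1:
            # synonymous: polarize at the codon level
            c_sorted = np.sort(cnt[observed])[::-1]
            if c_sorted[0] == c_sorted[1]:
                removal_rows.append((gene, ppos, "removed_tie"))
                continue
            major_k = observed[np.argmax(cnt[observed])]
            for k in observed:
                if k == major_k:
                    continue
                dos = (ids == k).sum(axis=1).astype(np.int8)
                dos[~called] = -1
                variant_rows.append(
                    {
                        "gene": gene,
                        "protein_pos": ppos,
                        "major_aa": aa_list[major_k],
                        "minor_aa": aa_list[k],
                        "major_codon": table.alleles[e][major_k],
                        "minor_codon": table.alleles[e][k],
                        "minor_count": int(cnt[k]),
                        "alleles_genotyped": alleles_genotyped,
                        "minor_freq": cnt[k] / alleles_genotyped,
                        "var_class": "synonymous",
                    }
                )
                dosage_rows.append(dos)
            continue

        aa_index = {aa: i for i, aa in enumerate(observed_aas)}
        aa_of_allele = np.array([aa_index.get(a, -1) for a in aa_list])
        aa_cnt = np.zeros(len(observed_aas), dtype=int)
        for k in observed:
            aa_cnt[aa_of_allele[k]] += cnt[k]
        order = np.sort(aa_cnt)[::-1]
        if order[0] == order[1]:
            removal_rows.append((gene, ppos, "removed_tie"))
            continue
        major_i = int(np.argmax(aa_cnt))
        aa_ids = np.where(ids >= 0, aa_of_allele[np.maximum(ids, 0)], -1)
        for m, aa in enumerate(observed_aas):
            if m == major_i or aa_cnt[m] == 0:
                continue
            dos = (aa_ids == m).sum(axis=1).astype(np.int8)
            dos[~called] = -1
            variant_rows.append(
                {
                    "gene": gene,
                    "protein_pos": ppos,
                    "major_aa": observed_aas[major_i],
                    "minor_aa": aa,
                    "major_codon": "",
                    "minor_codon": "",
                    "minor_count": int(aa_cnt[m]),
                    "alleles_genotyped": alleles_genotyped,
                    "minor_freq": aa_cnt[m] / alleles_genotyped,
                    "var_class": "nonsynonymous",
                }
            )
            dosage_rows.append(dos)
        position_rows.append({"gene": gene, "protein_pos": ppos})
        position_called.append(called)

    variants = pd.DataFrame(
        variant_rows,
        columns=[
            "gene",
            "protein_pos",
            "major_aa",
            "minor_aa",
            "major_codon",
            "minor_codon",
            "minor_count",
            "alleles_genotyped",
            "minor_freq",
            "var_class",
        ],
    )
    removals = pd.DataFrame(removal_rows, columns=["gene", "protein_pos", "reason"])
    positions = pd.DataFrame(position_rows, columns=["gene", "protein_pos"])
    dosages = (
        np.stack(dosage_rows) if dosage_rows else np.empty((0, n_ind), dtype=np.int8)
    )
    called_arr = (
        np.stack(position_called) if position_called else np.empty((0, n_ind), dtype=bool)
    )
    return AminoAcidVariantTable(
        individuals=list(table.individuals),
        variants=variants,
        dosages=dosages,
        removals=removals,
        positions=positions,
        position_called=called_arr,
    )


@dataclass
class PatchResult:
    proteins: dict[str, str]
    n_reference_minor: int  # retained positions where reference != major
    table: pd.DataFrame  # gene, protein_pos, ref_aa, major_aa


def polarize_and_patch(
    regions: dict[str, CodingRegion], aa_table: AminoAcidVariantTable
) -> PatchResult:
    """Replace the reference residue with the sample major allele at every
    retained polymorphic amino-acid position."""
    proteins = {g: list(r.protein) for g, r in regions.items()}
    rows = []
    seen = set()
    for rec in aa_table.variants.itertuples(index=False):
        key = (rec.gene, rec.protein_pos)
        if key in seen:
            continue
        seen.add(key)
        prot = proteins[rec.gene]
        if not 1 <= rec.protein_pos <= len(prot):
            raise ValueError(
                f"{rec.gene}: position {rec.protein_pos} outside protein length {len(prot)}"
            )
        ref_aa = prot[rec.protein_pos - 1]
        prot[rec.protein_pos - 1] = rec.major_aa
        rows.append(
            {
                "gene": rec.gene,
                "protein_pos": rec.protein_pos,
                "ref_aa": ref_aa,
                "major_aa": rec.major_aa,
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "protein_pos", "ref_aa", "major_aa"])
    n_diff = int((table["ref_aa"] != table["major_aa"]).sum()) if len(table) else 0
    return PatchResult(
        proteins={g: "".join(p) for g, p in proteins.items()},
        n_reference_minor=n_diff,
        table=table,
    )
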