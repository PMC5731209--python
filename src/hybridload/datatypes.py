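"""Core in-memory containers: diploid genotype matrix and coding regions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import translate_cds

#: columns required in :attr:`GenotypeMatrix.sites`
SITE_COLUMNS = (
    "gene",
    "pos",
    "ref",
    "alt",
    "qual",
    "mq",
    "fs",
    "haplotype_score",
    "mq_rank_sum",
    "read_pos_rank_sum",
)

MISSING = -1  # genotype / annotation sentinel in integer arrays


@dataclass
class GenotypeMatrix:
    """Diploid unphased genotypes (sites x individuals) with QC annotations.

    ``gt`` holds the alternate-allele dosage (0, 1, 2) with ``-1`` for a
    missing call.  ``dp``/``gq`` are per-genotype depth and quality;
    ``ad_ref``/``ad_alt`` are per-genotype allele depths.  Site positions are
    1-based within the coding sequence of ``gene``.
    """

    individuals: list[str]
    sites: pd.DataFrame
    gt: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray

    def __post_init__(self) -> None:
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"sites table lacks columns: {missing_cols}")
        n_sites, n_ind = self.gt.shape
        if len(self.sites) != n_sites:
            raise ValueError("sites table / genotype array length mismatch")
        if len(self.individuals) != n_ind:
            raise ValueError("individuals / genotype array width mismatch")
        dup = self.sites.duplicated(subset=["gene", "pos"])
        if dup.any():
            raise ValueError("duplicate site coordinates within a gene")
        if not np.isin(self.gt, (-1, 0, 1, 2)).all():
            raise ValueError("genotypes must be dosage 0/1/2 or -1 (missing)")

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.gt.shape[1]

    def subset_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            sites=self.sites.iloc[index].reset_index(drop=True),
            gt=self.gt[index],
            dp=self.dp[index],
            gq=self.gq[index],
            ad_ref=self.ad_ref[index],
            ad_alt=self.ad_alt[index],
        )

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in index],
            sites=self.sites.copy(),
            gt=self.gt[:, index],
            dp=self.dp[:, index],
            gq=self.gq[:, index],
            ad_ref=self.ad_ref[:, index],
            ad_alt=self.ad_alt[:, index],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            individuals=list(self.individuals),
            sites=self.sites.copy(),
            gt=self.gt.copy(),
            dp=self.dp.copy(),
            gq=self.gq.copy(),
            ad_ref=self.ad_ref.copy(),
            ad_alt=self.ad_alt.copy(),
        )

    def site_lookup(self) -> dict[tuple[str, int], int]:
        """Map (gene, pos) -> row index."""
        return {
            (g, int(p)): i
            for i, (g, p) in enumerate(zip(self.sites["gene"], self.sites["pos"]))
        }


@dataclass(frozen=True)
class CodingRegion:
    """One gene's reference CDS in coding orientation, frame 0.

    SNP positions are 1-based within the CDS; codon indices are 0-based.
    """

    gene_id: str
    cds: str

    def __post_init__(self) -> None:
        if len(self.cds) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        protein = translate_cds(self.cds)
        if "*" in protein[:-1]:
            raise ValueError(f"{self.gene_id}: internal stop codon in CDS")

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    @property
    def protein(self) -> str:
        return translate_cds(self.cds)

    def codon_of(self, pos: int) -> tuple[int, int]:
        """Return (codon_index 0-based, offset 0..2) for a 1-based CDS position."""
        if not 1 <= pos <= len(self.cds):
            raise ValueError(f"{self.gene_id}: position {pos} outside CDS")
        return (pos - 1) // 3, (pos - 1) % 3

    def ref_codon(self, codon_index: int) -> str:
        return self.cds[3 * codon_index : 3 * codon_index + 3]
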