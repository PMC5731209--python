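"""Reading and writing the standard interchange formats.

VCF is written as plain text (one biallelic SNP per record, FORMAT
GT:DP:GQ:AD) and read back through cyvcf2; FASTA goes through Biopython.
Site positions are 1-based within each gene's CDS and the CHROM column
carries the gene identifier.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import CodingRegion, GenotypeMatrix

_INFO_FIELDS = (
    ("mq", "MQ"),
    ("fs", "FS"),
    ("haplotype_score", "HaplotypeScore"),
    ("mq_rank_sum", "MQRankSum"),
    ("read_pos_rank_sum", "ReadPosRankSum"),
)

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand phred-scaled p-value">
##INFO=<ID=HaplotypeScore,Number=1,Type=Float,Description="Haplotype score">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
"""

_GT_STRING = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.individuals)
            + "\n"
        )
        for i, site in enumerate(matrix.sites.itertuples(index=False)):
            info = ";".join(
                f"{tag}={getattr(site, col):.4g}"
                for col, tag in _INFO_FIELDS
                if np.isfinite(getattr(site, col))
            )
            cells = [
                f"{_GT_STRING[int(g)]}:{d}:{q}:{ar},{aa}"
                for g, d, q, ar, aa in zip(
                    matrix.gt[i], matrix.dp[i], matrix.gq[i], matrix.ad_ref[i], matrix.ad_alt[i]
                )
            ]
            fh.write(
                f"{site.gene}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t"
                f"{site.qual:.4g}\t.\t{info or '.'}\tGT:DP:GQ:AD\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path), gts012=True)
    individuals = list(vcf.samples)
    rows, gt, dp, gq, ad_ref, ad_alt = [], [], [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"{v.CHROM}:{v.POS}: only biallelic SNP records supported")
        rows.append(
            {
                "gene": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0],
                "qual": v.QUAL if v.QUAL is not None else np.nan,
                "mq": _info(v, "MQ"),
                "fs": _info(v, "FS"),
                "haplotype_score": _info(v, "HaplotypeScore"),
                "mq_rank_sum": _info(v, "MQRankSum"),
                "read_pos_rank_sum": _info(v, "ReadPosRankSum"),
            }
        )
        g = v.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g[g == 3] = -1
        gt.append(g)
        dp.append(_format_col(v, "DP"))
        gq.append(_format_col(v, "GQ"))
        ad = v.format("AD")
        if ad is None:
            ad = np.zeros((len(individuals), 2), dtype=np.int32)
        ad = np.where(ad < 0, 0, ad)
        ad_ref.append(ad[:, 0])
        ad_alt.append(ad[:, 1])
    sites = pd.DataFrame(rows)
    return GenotypeMatrix(
        individuals=individuals,
        sites=sites,
        gt=np.asarray(gt, dtype=np.int8),
        dp=np.asarray(dp, dtype=np.int16),
        gq=np.asarray(gq, dtype=np.int16),
        ad_ref=np.asarray(ad_ref, dtype=np.int16),
        ad_alt=np.asarray(ad_alt, dtype=np.int16),
    )


def _info(v, tag):
    val = v.INFO.get(tag)
    return float(val) if val is not None else np.nan


def _format_col(v, tag):
    arr = v.format(tag)
    if arr is None:
        return np.zeros(len(v.gt_types), dtype=np.int16)
    arr = arr.reshape(len(v.gt_types), -1)[:, 0]
    return np.where(arr < 0, 0, arr)


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, dict) else records
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in items),
        os.fspath(path),
        "fasta",
    )


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(os.fspath(path), "fasta")]


def write_regions_table(regions: dict[str, CodingRegion], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": list(regions),
            "length": [len(r.cds) for r in regions.values()],
            "frame": 0,
            "start": 1,
            "end": [len(r.cds) for r in regions.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_regions(cds_fasta, table_path=None) -> dict[str, CodingRegion]:
    regions = {name: CodingRegion(name, seq) for name, seq in read_fasta(cds_fasta)}
    if table_path is not None:
        table = pd.read_csv(table_path, sep="\t")
        for rec in table.itertuples(index=False):
            if rec.gene_id in regions and len(regions[rec.gene_id].cds) != rec.length:
                raise ValueError(f"{rec.gene_id}: region table length mismatch")
    return regions


def write_dataset(dataset, outdir) -> None:
    """Write a synthetic dataset to a directory of standard text formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(dataset.genotype_matrix, out / "genotypes.vcf")
    write_fasta({g: r.cds for g, r in dataset.coding_regions.items()}, out / "reference_cds.fasta")
    write_regions_table(dataset.coding_regions, out / "regions.tsv")
    hom_dir = out / "homologs"
    hom_dir.mkdir(exist_ok=True)
    for gene, family in dataset.homolog_families.items():
        write_fasta(family, hom_dir / f"{gene}.fasta")
    meta = pd.DataFrame(
        {
            "individual": dataset.genotype_matrix.individuals,
            "ancestry_q": dataset.true_ancestry,
            "third_species_q": dataset.third_species_q,
            "biomass": dataset.phenotypes,
            "selfed": dataset.selfed.astype(int),
        }
    )
    meta.to_csv(out / "individuals.tsv", sep="\t", index=False, float_format="%.10g")
    dataset.true_variant_classes.to_csv(
        out / "variant_truth.tsv", sep="\t", index=False, float_format="%.10g"
    )
    dataset.diagnostic_panel.to_csv(
        out / "diagnostic_panel.tsv", sep="\t", index=False, float_format="%.10g"
    )
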