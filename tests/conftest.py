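import numpy as np
import pandas as pd
import pytest

from hybridload.datatypes import GenotypeMatrix
from hybridload.synthetic import SimulationConfig, simulate_dataset


def small_config(**overrides) -> SimulationConfig:
    """A fast simulator configuration for unit tests."""
    base = dict(
        n_individuals_per_group=20,
        n_genes=12,
        codons_per_gene=30,
        snps_per_gene=12,
        n_diagnostic_per_gene=3,
        n_homologs_per_gene=6,
        n_selfed=2,
        seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


def make_matrix(
    gt,
    genes=None,
    pos=None,
    ref="A",
    alt="G",
    qual=100.0,
    mq=55.0,
    fs=1.0,
    haplotype_score=2.0,
    mq_rank_sum=0.0,
    read_pos_rank_sum=0.0,
    dp=30,
    gq=90,
    ad_alt=None,
) -> GenotypeMatrix:
    """Build a toy GenotypeMatrix from a dosage array (sites x individuals).

    Scalar annotation arguments are broadcast across sites; ``ad_alt``
    defaults to a balanced split of depth for heterozygotes.
    """
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_ind = gt.shape

    def _col(v, dtype=float):
        return np.full(n_sites, v, dtype=dtype) if np.isscalar(v) else np.asarray(v, dtype=dtype)

    sites = pd.DataFrame(
        {
            "gene": _col(genes, object) if genes is not None else ["gene_000"] * n_sites,
            "pos": pos if pos is not None else np.arange(1, n_sites + 1),
            "ref": _col(ref, object),
            "alt": _col(alt, object),
            "qual": _col(qual),
            "mq": _col(mq),
            "fs": _col(fs),
            "haplotype_score": _col(haplotype_score),
            "mq_rank_sum": _col(mq_rank_sum),
            "read_pos_rank_sum": _col(read_pos_rank_sum),
        }
    )
    dp_arr = np.full(gt.shape, dp, dtype=np.int16) if np.isscalar(dp) else np.asarray(dp, dtype=np.int16)
    gq_arr = np.full(gt.shape, gq, dtype=np.int16) if np.isscalar(gq) else np.asarray(gq, dtype=np.int16)
    if ad_alt is None:
        ad_alt_arr = np.where(gt == 1, dp_arr // 2, np.where(gt == 2, dp_arr, 0)).astype(np.int16)
    else:
        ad_alt_arr = np.asarray(ad_alt, dtype=np.int16)
    ad_ref_arr = (dp_arr - ad_alt_arr).astype(np.int16)
    ad_ref_arr[gt == -1] = 0
    ad_alt_arr = ad_alt_arr.copy()
    ad_alt_arr[gt == -1] = 0
    return GenotypeMatrix(
        individuals=[f"ind_{i:04d}" for i in range(n_ind)],
        sites=sites,
        gt=gt,
        dp=dp_arr,
        gq=gq_arr,
        ad_ref=ad_ref_arr,
        ad_alt=ad_alt_arr,
    )
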