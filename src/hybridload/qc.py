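"""Post-calling quality control: genotype masks, hard site filters,
inbreeding and ancestry screens, and individual removal.

Thresholds follow widely used GATK-style hard filters; the supervised
ancestry estimator replaces unsupervised clustering by counting
species-associated alleles at a diagnostic panel with (near-)fixed
frequency differences between the parental reference groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .genetics import translate_codon

SITE_REASONS = (
    "qual",
    "map_quality",
    "fisher_strand",
    "haplotype_score",
    "mq_rank_sum",
    "read_pos_rank_sum",
    "allele_balance",
    "call_rate",
    "heterozygosity",
)

INDIVIDUAL_FLAGS = ("low_callrate", "inbred_outlier", "third_species")


@dataclass(frozen=True)
class SiteFilterConfig:
    min_qual: float = 20.0
    min_mq: float = 40.0
    max_fs: float = 40.0
    max_haplotype_score: float = 13.0
    min_mq_rank_sum: float = -12.5
    min_read_pos_rank_sum: float = -8.0  # strict: retained iff RPRS > this
    max_allele_balance: float = 2.3
    min_genotype_gq: float = 20.0  # strict: retained iff GQ > this
    min_genotype_depth: float = 5.0  # strict: retained iff DP > this
    min_fraction_genotyped: float = 0.10
    max_heterozygosity: float = 0.7

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class IndividualQCConfig:
    callrate_percentile: float = 1.0
    inbreeding_cutoff: float = 0.35
    third_species_cutoff: float = 0.12


def apply_genotype_masks(
    matrix: GenotypeMatrix, config: SiteFilterConfig | None = None
) -> GenotypeMatrix:
    """Set genotypes with GQ <= threshold or DP <= threshold to missing.

    The comparisons are strict (a call survives only with GQ strictly above
    20 *and* depth strictly above 5 at the defaults).
    """
    config = config or SiteFilterConfig()
    for name in ("gq", "dp"):
        if getattr(matrix, name) is None:
            raise ValueError(f"genotype annotation {name.upper()} is missing")
    out = matrix.copy()
    bad = (out.gq <= config.min_genotype_gq) | (out.dp <= config.min_genotype_depth)
    out.gt[bad] = -1
    return out


def _allele_balance(matrix: GenotypeMatrix) -> np.ndarray:
    """Mean over heterozygotes of max(AD)/min(AD); NaN where no hets.

    Heterozygous genotypes with a zero allele depth are given an infinite
    ratio (maximally unbalanced).
    """
    het = matrix.gt == 1
    hi = np.maximum(matrix.ad_ref, matrix.ad_alt).astype(float)
    lo = np.minimum(matrix.ad_ref, matrix.ad_alt).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / lo, np.inf)
    n_het = het.sum(axis=1)
    total = np.where(het, ratio, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(n_het > 0, total / np.maximum(n_het, 1), np.nan)


def filter_sites(
    matrix: GenotypeMatrix, config: SiteFilterConfig | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the hard site filters; return (retained index, reasons table).

    Missing rank-sum annotations count as passing (they are emitted only
    when computable); sites with no heterozygotes skip the allele-balance
    test.  The reasons table has one boolean column per reason plus a
    ``retained`` column.
    """
    config = config or SiteFilterConfig()
    s = matrix.sites
    n_ind = matrix.n_individuals
    genotyped = (matrix.gt >= 0).sum(axis=1)
    het_count = (matrix.gt == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(genotyped > 0, het_count / np.maximum(genotyped, 1), 0.0)
    balance = _allele_balance(matrix)

    def _fail_low(values, cutoff):
        v = np.asarray(values, dtype=float)
        return np.where(np.isnan(v), False, v < cutoff)

    def _fail_high(values, cutoff):
        v = np.asarray(values, dtype=float)
        return np.where(np.isnan(v), False, v > cutoff)

    reasons = pd.DataFrame(
        {
            "qual": _fail_low(s["qual"], config.min_qual),
            "map_quality": _fail_low(s["mq"], config.min_mq),
            "fisher_strand": _fail_high(s["fs"], config.max_fs),
            "haplotype_score": _fail_high(s["haplotype_score"], config.max_haplotype_score),
            "mq_rank_sum": _fail_low(s["mq_rank_sum"], config.min_mq_rank_sum),
            "read_pos_rank_sum": np.where(
                np.isnan(s["read_pos_rank_sum"].astype(float)),
                False,
                s["read_pos_rank_sum"].astype(float) <= config.min_read_pos_rank_sum,
            ),
            "allele_balance": _fail_high(balance, config.max_allele_balance),
            "call_rate": genotyped / n_ind < config.min_fraction_genotyped,
            "heterozygosity": het_frac > config.max_heterozygosity,
        }
    )
    reasons["retained"] = ~reasons[list(SITE_REASONS)].any(axis=1)
    retained = np.flatnonzero(reasons["retained"].to_numpy())
    return retained, reasons


def classify_sites_synonymous(matrix: GenotypeMatrix, regions) -> np.ndarray:
    """Boolean per site: does the alt allele preserve the amino acid?"""
    syn = np.zeros(matrix.n_sites, dtype=bool)
    for i, row in enumerate(matrix.sites.itertuples(index=False)):
        region = regions[row.gene]
        c, off = region.codon_of(int(row.pos))
        ref_codon = region.ref_codon(c)
        alt_codon = ref_codon[:off] + row.alt + ref_codon[off + 1 :]
        syn[i] = translate_codon(alt_codon) == translate_codon(ref_codon)
    return syn


def estimate_inbreeding(
    matrix: GenotypeMatrix, site_subset: np.ndarray | None = None
) -> np.ndarray:
    """Method-of-moments inbreeding coefficient per individual.

    F = 1 - (observed het count) / (sum over genotyped sites of 2p(1-p)),
    with p the sample allele frequency; monomorphic sites are excluded.
    Individuals with no usable site get NaN.
    """
    sub = matrix if site_subset is None else matrix.subset_sites(site_subset)
    gt = sub.gt
    called = gt >= 0
    an = 2 * called.sum(axis=1)
    ac = np.where(called, gt, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(an > 0, ac / np.maximum(an, 1), 0.0)
    usable = (p > 0) & (p < 1)
    exp_het = 2 * p * (1 - p)
    obs = ((gt == 1) & usable[:, None]).sum(axis=0).astype(float)
    denom = (called * (usable * exp_het)[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 1.0 - obs / denom
    f[denom == 0] = np.nan
    return f


def estimate_ancestry(matrix: GenotypeMatrix, diagnostic_panel: pd.DataFrame) -> np.ndarray:
    """Supervised ancestry proportion from a diagnostic-allele panel.

    ``diagnostic_panel`` carries (gene, pos, freq_E, freq_W); the
    E-associated allele at each site is whichever allele is the more
    frequent in the E reference group.  q is the fraction of an
    individual's non-missing panel alleles that are E-associated; NaN when
    no panel site is genotyped.
    """
    lookup = matrix.site_lookup()
    rows, e_is_alt = [], []
    for rec in diagnostic_panel.itertuples(index=False):
        key = (rec.gene, int(rec.pos))
        if key in lookup:
            rows.append(lookup[key])
            e_is_alt.append(rec.freq_E > rec.freq_W)
    if not rows:
        raise ValueError("no diagnostic panel sites present in the matrix")
    gt = matrix.gt[np.asarray(rows)]
    called = gt >= 0
    dos = np.where(called, gt, 0)
    e_dos = np.where(np.asarray(e_is_alt)[:, None], dos, np.where(called, 2 - dos, 0))
    n_alleles = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = e_dos.sum(axis=0) / n_alleles
    q = np.asarray(q, dtype=float)
    q[n_alleles == 0] = np.nan
    return q


def select_diagnostic_panel(
    matrix: GenotypeMatrix,
    e_individuals: np.ndarray,
    w_individuals: np.ndarray,
    min_freq_diff: float = 0.8,
    min_maf: float = 0.01,
    max_missing: float = 0.30,
    one_per_gene: bool = True,
) -> pd.DataFrame:
    """Pick ancestry-informative sites from reference parental groups.

    Filters: overall minor-allele frequency > ``min_maf``, missingness
    < ``max_missing``, |freq_E - freq_W| >= ``min_freq_diff``; linkage
    pruning approximated by keeping at most one site per gene.
    """

    def _freq(idx):
        g = matrix.gt[:, idx]
        called = g >= 0
        an = 2 * called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, np.where(called, g, 0).sum(axis=1) / np.maximum(an, 1), np.nan)

    f_e, f_w = _freq(np.asarray(e_individuals)), _freq(np.asarray(w_individuals))
    called = matrix.gt >= 0
    an = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(an > 0, np.where(called, matrix.gt, 0).sum(axis=1) / np.maximum(an, 1), 0.0)
    maf = np.minimum(p, 1 - p)
    miss = 1.0 - called.mean(axis=1)
    ok = (
        (maf > min_maf)
        & (miss < max_missing)
        & ~np.isnan(f_e)
        & ~np.isnan(f_w)
        & (np.abs(f_e - f_w) >= min_freq_diff)
    )
    panel = matrix.sites.loc[ok, ["gene", "pos"]].copy()
    panel["freq_E"] = f_e[ok]
    panel["freq_W"] = f_w[ok]
    if one_per_gene:
        panel = panel.groupby("gene", as_index=False).first()
    return panel.reset_index(drop=True)


def filter_individuals(
    matrix: GenotypeMatrix,
    inbreeding_f: np.ndarray,
    ancestry_q: np.ndarray,
    third_species_q: np.ndarray | None = None,
    config: IndividualQCConfig | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Flag individuals for removal; return (QC report, retained index).

    Flags: call rate below the chosen percentile of the per-individual
    callrate distribution; inbreeding F above the cutoff; third-species
    ancestry above the cutoff.
    """
    config = config or IndividualQCConfig()
    n_genotyped = (matrix.gt >= 0).sum(axis=0)
    cut = np.percentile(n_genotyped, config.callrate_percentile)
    low_call = n_genotyped < cut
    f = np.asarray(inbreeding_f, dtype=float)
    inbred = np.where(np.isnan(f), True, f > config.inbreeding_cutoff)
    if third_species_q is None:
        third_species_q = np.zeros(matrix.n_individuals)
    third = np.asarray(third_species_q) > config.third_species_cutoff
    flags = [
        ";".join(
            name
            for name, hit in (
                ("low_callrate", low_call[i]),
                ("inbred_outlier", inbred[i]),
                ("third_species", third[i]),
            )
            if hit
        )
        for i in range(matrix.n_individuals)
    ]
    report = pd.DataFrame(
        {
            "individual": matrix.individuals,
            "n_sites_genotyped": n_genotyped,
            "inbreeding_F": f,
            "ancestry_q": np.asarray(ancestry_q, dtype=float),
            "third_species_q": np.asarray(third_species_q, dtype=float),
            "removal_flags": flags,
        }
    )
    retained = np.flatnonzero(~(low_call | inbred | third))
    return report, retained
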