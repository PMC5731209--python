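"""End-to-end analysis: simulate (or load) genotypes, QC, codon genotypes,
delta-score classification, load metrics and diversity in one call.

The paper-scale variant filter of 500 alleles genotyped presumes several
hundred diploids; at simulation scale the same *fraction* of the maximum
allele count is used instead (0.46, i.e. 500 of 2x539), unless an absolute
``min_alleles`` is given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import diversity, load, qc
from .codons import build_codon_genotypes, call_amino_acid_variants, polarize_and_patch
from .provean import ScoringParams, score_variants, threshold_sweep
from .synthetic import SimulationConfig, SyntheticDataset, simulate_dataset

MIN_ALLELES_FRACTION = 500 / (2 * 539)


@dataclass(frozen=True)
class AnalysisConfig:
    site_filter: qc.SiteFilterConfig = field(default_factory=qc.SiteFilterConfig)
    individual_qc: qc.IndividualQCConfig = field(default_factory=qc.IndividualQCConfig)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    group_thresholds: load.GroupThresholds = field(default_factory=load.GroupThresholds)
    min_alleles: int | None = None  # None -> MIN_ALLELES_FRACTION of 2N
    sfs_bins: int = 50
    diversity_min_bp: float = 100.0
    diversity_min_individuals: int = 20
    run_diversity: bool = True
    run_sweep: bool = True


@dataclass
class AnalysisResult:
    dataset: SyntheticDataset
    qc_report: pd.DataFrame
    retained_sites: np.ndarray
    site_reasons: pd.DataFrame
    matrix: "object"  # post-QC GenotypeMatrix
    ancestry_q: np.ndarray
    variants: pd.DataFrame  # scored variant table
    aa_table: "object"
    patch: "object"
    profiles: pd.DataFrame
    regressions: pd.DataFrame
    group_comparison: dict
    sfs: pd.DataFrame
    freq_tests: dict
    freq_tests_no_singletons: dict
    sweep: pd.DataFrame | None
    uneven_count: int
    group_freqs: pd.DataFrame
    diversity_table: pd.DataFrame | None
    diversity_tests: dict | None
    phenotype: dict
    min_alleles_used: int


def effective_min_alleles(n_individuals: int, min_alleles: int | None) -> int:
    if min_alleles is not None:
        return min_alleles
    return math.ceil(MIN_ALLELES_FRACTION * 2 * n_individuals)


def run_full_analysis(
    sim_config: SimulationConfig | None = None,
    analysis: AnalysisConfig | None = None,
    dataset: SyntheticDataset | None = None,
    seed: int | None = None,
) -> AnalysisResult:
    analysis = analysis or AnalysisConfig()
    if dataset is None:
        sim_config = sim_config or SimulationConfig()
        if seed is not None:
            sim_config = replace(sim_config, seed=seed)
        dataset = simulate_dataset(sim_config)

    # --- site-level QC ---
    masked = qc.apply_genotype_masks(dataset.genotype_matrix, analysis.site_filter)
    retained_sites, site_reasons = qc.filter_sites(masked, analysis.site_filter)
    matrix = masked.subset_sites(retained_sites)

    # --- individual-level QC ---
    syn_flags = qc.classify_sites_synonymous(matrix, dataset.coding_regions)
    panel_keys = {
        (g, int(p))
        for g, p in zip(dataset.diagnostic_panel["gene"], dataset.diagnostic_panel["pos"])
    }
    in_panel = np.array(
        [(g, int(p)) in panel_keys for g, p in zip(matrix.sites["gene"], matrix.sites["pos"])]
    )
    f = qc.estimate_inbreeding(matrix, np.flatnonzero(syn_flags & ~in_panel))
    q_hat = qc.estimate_ancestry(matrix, dataset.diagnostic_panel)
    report, retained_ind = qc.filter_individuals(
        matrix, f, q_hat, dataset.third_species_q, analysis.individual_qc
    )
    inbred_flagged = report["removal_flags"].str.contains("inbred_outlier").to_numpy()
    matrix = matrix.subset_individuals(retained_ind)
    q_kept = q_hat[retained_ind]

    # --- codon genotypes and amino-acid variants ---
    codon_table = build_codon_genotypes(matrix, dataset.coding_regions)
    min_alleles = effective_min_alleles(matrix.n_individuals, analysis.min_alleles)
    aa_table = call_amino_acid_variants(codon_table, min_alleles=min_alleles)
    patch = polarize_and_patch(dataset.coding_regions, aa_table)

    # --- delta scoring ---
    variants = score_variants(
        aa_table.variants, patch.proteins, dataset.homolog_families, analysis.scoring
    )

    # --- load metrics ---
    profiles = load.individual_load_profiles(aa_table, variants, q_kept)
    regressions = load.regress_load_on_ancestry(profiles)
    groups = load.assign_groups(q_kept, analysis.group_thresholds)
    group_comparison = load.binned_group_comparison(profiles, groups)
    sfs = load.folded_sfs(variants, n_bins=analysis.sfs_bins)
    freq_tests = load.compare_frequency_distributions(variants)
    freq_tests_ns = load.compare_frequency_distributions(load.drop_singletons(variants))
    sweep = threshold_sweep(variants) if analysis.run_sweep else None
    group_freqs = load.group_minor_allele_frequencies(aa_table, groups)
    uneven_count, _ = load.uneven_sampling_check(variants, group_freqs)

    # --- phenotype association (phenotypes follow the retained individuals) ---
    phen = dataset.phenotypes[retained_ind]
    phenotype = load.phenotype_association(profiles, phen, inbred_flagged=None)
    # the inbred-vs-others biomass comparison uses the pre-removal sample
    phenotype["inbred_biomass_ttest"] = load.inbred_biomass_test(
        dataset.phenotypes, inbred_flagged
    )

    # --- diversity ---
    diversity_table = diversity_tests = None
    if analysis.run_diversity:
        haps = diversity.build_haplotype_sequences(codon_table, dataset.coding_regions)
        by_group: dict[str, dict[str, list[str]]] = {}
        for gname in ("pure_W", "intermediate", "pure_E"):
            idx = np.flatnonzero(groups == gname)
            if idx.size == 0:
                continue
            hap_idx = np.concatenate([[2 * i, 2 * i + 1] for i in idx])
            by_group[gname] = {g: [seqs[h] for h in hap_idx] for g, seqs in haps.items()}
        if len(by_group) >= 2:
            diversity_table = diversity.group_region_diversity(
                by_group,
                min_bp=analysis.diversity_min_bp,
                min_individuals=analysis.diversity_min_individuals,
            )
            if len(diversity_table):
                diversity_tests = diversity.group_diversity_comparison(diversity_table)

    return AnalysisResult(
        dataset=dataset,
        qc_report=report,
        retained_sites=retained_sites,
        site_reasons=site_reasons,
        matrix=matrix,
        ancestry_q=q_kept,
        variants=variants,
        aa_table=aa_table,
        patch=patch,
        profiles=profiles,
        regressions=regressions,
        group_comparison=group_comparison,
        sfs=sfs,
        freq_tests=freq_tests,
        freq_tests_no_singletons=freq_tests_ns,
        sweep=sweep,
        uneven_count=uneven_count,
        group_freqs=group_freqs,
        diversity_table=diversity_table,
        diversity_tests=diversity_tests,
        phenotype=phenotype,
        min_alleles_used=min_alleles,
    )


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_results(result: AnalysisResult, outdir) -> None:
    """Write the main result tables as deterministic TSV files plus a JSON
    statistics report."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", index=False, float_format="%.10g")
    result.qc_report.to_csv(out / "qc_individuals.tsv", **fmt)
    result.site_reasons.to_csv(out / "qc_sites.tsv", **fmt)
    result.variants.to_csv(out / "variants_scored.tsv", **fmt)
    result.profiles.to_csv(out / "load_profiles.tsv", **fmt)
    result.regressions.to_csv(out / "load_regressions.tsv", **fmt)
    result.sfs.to_csv(out / "folded_sfs.tsv", **fmt)
    if result.sweep is not None:
        result.sweep.to_csv(out / "threshold_sweep.tsv", **fmt)
    if result.diversity_table is not None:
        result.diversity_table.to_csv(out / "region_diversity.tsv", **fmt)
    report = {
        "min_alleles_used": result.min_alleles_used,
        "n_variants": len(result.variants),
        "frequency_tests": result.freq_tests,
        "frequency_tests_no_singletons": result.freq_tests_no_singletons,
        "group_comparison": result.group_comparison,
        "uneven_sampling_count": result.uneven_count,
        "phenotype": result.phenotype,
        "diversity_tests": result.diversity_tests,
    }
    (out / "statistics.json").write_text(
        json.dumps(_json_safe(report), indent=2, sort_keys=True) + "\n"
    )
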