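"""Population and per-individual mutation-load statistics.

"Polymorphic loci" throughout refers to retained polymorphic amino-acid
positions; per-individual proportions use only the positions genotyped in
that individual.  Species groups are binned on the Engelmann-ancestry
proportion q: pure E (q >= 0.90), pure W (q <= 0.10), intermediate hybrids
(0.40 <= q <= 0.60).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codons import AminoAcidVariantTable

LOAD_METRICS = (
    "prop_minor_nondel",
    "prop_minor_del",
    "prop_het_del",
    "prop_hom_del",
    "prop_hom_nondel",
    "ratio_del_nondel",
    "ratio_hom",
)


@dataclass(frozen=True)
class GroupThresholds:
    pure_e_min: float = 0.90
    pure_w_max: float = 0.10
    intermediate: tuple[float, float] = (0.40, 0.60)


@dataclass(frozen=True)
class LethalEquivalents:
    R: float
    B: float
    two_B: float


def lethal_equivalents(R: float) -> LethalEquivalents:
    """Lethal equivalents from the selfed/outcrossed survival ratio R.

    2B = -4 ln R, with B the average number of lethal equivalents per
    gamete and 2B the per-zygote number.
    """
    if not 0 < R <= 1:
        raise ValueError(f"R={R} must be in (0, 1]")
    two_b = -4.0 * np.log(R)
    return LethalEquivalents(R=R, B=two_b / 2.0, two_B=two_b)


def assign_groups(q: np.ndarray, thresholds: GroupThresholds | None = None) -> np.ndarray:
    """Bin individuals into pure_E / pure_W / intermediate / unbinned by q."""
    thresholds = thresholds or GroupThresholds()
    q = np.asarray(q, dtype=float)
    lo, hi = thresholds.intermediate
    out = np.full(q.shape, "unbinned", dtype=object)
    out[q >= thresholds.pure_e_min] = "pure_E"
    out[q <= thresholds.pure_w_max] = "pure_W"
    out[(q >= lo) & (q <= hi)] = "intermediate"
    out[np.isnan(q)] = "unbinned"
    return out


def folded_sfs(
    variants: pd.DataFrame, n_bins: int = 50, max_freq: float = 0.5
) -> pd.DataFrame:
    """Folded site frequency spectrum per variant class.

    Returns a table with one row per frequency bin and one count column
    per class present in ``variants['var_class']``.
    """
    edges = np.linspace(0.0, max_freq, n_bins + 1)
    out = pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
        }
    )
    for cls in sorted(variants["var_class"].unique()):
        f = variants.loc[variants["var_class"] == cls, "minor_freq"].to_numpy()
        counts, _ = np.histogram(f, bins=edges)
        # frequencies exactly at max_freq fall in the last bin via histogram's
        # closed right edge; values at 0 are excluded by construction (f > 0)
        out[cls] = counts
    return out


def compare_frequency_distributions(variants: pd.DataFrame) -> dict:
    """Two-sided rank-sum tests: deleterious vs synonymous, deleterious vs
    non-deleterious.  Empty classes produce a skipped-contrast notice."""
    freq = {
        cls: variants.loc[variants["var_class"] == cls, "minor_freq"].to_numpy()
        for cls in ("synonymous", "nonsyn_non_deleterious", "nonsyn_deleterious")
    }
    results = {}
    for name, other in (
        ("deleterious_vs_synonymous", "synonymous"),
        ("deleterious_vs_non_deleterious", "nonsyn_non_deleterious"),
    ):
        a, b = freq["nonsyn_deleterious"], freq[other]
        if len(a) < 2 or len(b) < 2:
            results[name] = {"skipped": f"empty class in contrast {name}"}
            continue
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        results[name] = {
            "u": float(u),
            "p_value": float(p),
            "mean_diff": float(a.mean() - b.mean()),
            "n": (len(a), len(b)),
        }
    return results


def drop_singletons(variants: pd.DataFrame) -> pd.DataFrame:
    """Remove variants whose minor allele was observed exactly once."""
    return variants[variants["minor_count"] != 1].reset_index(drop=True)


def individual_load_profiles(
    aa_table: AminoAcidVariantTable,
    scored_variants: pd.DataFrame,
    ancestry_q: np.ndarray,
) -> pd.DataFrame:
    """Per-individual load profile over retained nonsynonymous positions.

    prop_minor_X = (het_X + 2*hom_X) / (2 * n positions genotyped);
    prop_het_X and prop_hom_X are per-locus proportions.  A multi-allelic
    position counts once per minor allele carried.  Ratio metrics are NaN
    when their denominator is zero.  Individuals with zero genotyped
    positions get NaN metrics and ``undefined=True``.
    """
    if len(scored_variants) != len(aa_table.dosages):
        raise ValueError("scored variant table does not align with dosage matrix")
    classes = scored_variants["var_class"].to_numpy()
    is_del = classes == "nonsyn_deleterious"
    is_nondel = classes == "nonsyn_non_deleterious"
    dos = aa_table.dosages
    called = dos >= 0
    d = np.where(called, dos, 0)

    n_pos = aa_table.position_called.sum(axis=0).astype(float)  # per individual

    def _per_class(mask):
        alleles = d[mask].sum(axis=0)
        het = ((dos[mask] == 1) & called[mask]).sum(axis=0)
        hom = (dos[mask] == 2).sum(axis=0)
        return alleles, het, hom

    del_alleles, del_het, del_hom = _per_class(is_del)
    non_alleles, non_het, non_hom = _per_class(is_nondel)

    with np.errstate(invalid="ignore", divide="ignore"):
        prop_minor_del = del_alleles / (2 * n_pos)
        prop_minor_nondel = non_alleles / (2 * n_pos)
        prop_het_del = del_het / n_pos
        prop_hom_del = del_hom / n_pos
        prop_hom_nondel = non_hom / n_pos
        ratio_del_nondel = np.where(prop_minor_nondel > 0, prop_minor_del / prop_minor_nondel, np.nan)
        ratio_hom = np.where(prop_hom_nondel > 0, prop_hom_del / prop_hom_nondel, np.nan)

    profiles = pd.DataFrame(
        {
            "individual": aa_table.individuals,
            "q": np.asarray(ancestry_q, dtype=float),
            "n_polymorphic_genotyped": n_pos.astype(int),
            "prop_minor_nondel": prop_minor_nondel,
            "prop_minor_del": prop_minor_del,
            "prop_het_del": prop_het_del,
            "prop_hom_del": prop_hom_del,
            "prop_hom_nondel": prop_hom_nondel,
            "ratio_del_nondel": ratio_del_nondel,
            "ratio_hom": ratio_hom,
        }
    )
    undefined = n_pos == 0
    profiles["undefined"] = undefined
    metric_cols = list(LOAD_METRICS)
    profiles.loc[undefined, metric_cols] = np.nan
    return profiles


def _ols(y: np.ndarray, X: np.ndarray):
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(X, has_constant="add"), missing="drop").fit()
    return model


def regress_load_on_ancestry(profiles: pd.DataFrame) -> pd.DataFrame:
    """Linear fits on q for allele-proportion metrics, quadratic (q + q^2)
    for homozygosity metrics; one row per (metric, model)."""
    q = profiles["q"].to_numpy(dtype=float)
    if np.nanstd(q) == 0 or len(profiles) < 3:
        raise ValueError("need >= 3 individuals with variance in ancestry")
    plans = [
        ("prop_minor_nondel", "linear"),
        ("prop_minor_del", "linear"),
        ("ratio_del_nondel", "linear"),
        ("prop_hom_nondel", "quadratic"),
        ("prop_hom_del", "quadratic"),
        ("ratio_hom", "quadratic"),
    ]
    rows = []
    for metric, kind in plans:
        y = profiles[metric].to_numpy(dtype=float)
        X = q[:, None] if kind == "linear" else np.column_stack([q, q**2])
        ok = ~np.isnan(y)
        model = _ols(y[ok], X[ok])
        coefs = model.params
        rows.append(
            {
                "metric": metric,
                "model": kind,
                "r2": float(model.rsquared),
                "F": float(model.fvalue),
                "p_value": float(model.f_pvalue),
                "intercept": float(coefs[0]),
                "beta_q": float(coefs[1]),
                "beta_q2": float(coefs[2]) if kind == "quadratic" else np.nan,
            }
        )
    return pd.DataFrame(rows)


def binned_group_comparison(
    profiles: pd.DataFrame,
    groups: np.ndarray | None = None,
    thresholds: GroupThresholds | None = None,
    metrics=LOAD_METRICS,
) -> dict:
    """Group means, one-way ANOVA and Tukey honest-significant-difference
    contrasts for each load metric across the binned species groups."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if groups is None:
        groups = assign_groups(profiles["q"].to_numpy(), thresholds)
    groups = np.asarray(groups, dtype=object)
    use = np.isin(groups, ("pure_E", "pure_W", "intermediate"))
    labels = sorted(set(groups[use]))
    empty = sorted({"pure_E", "pure_W", "intermediate"} - set(labels))
    if empty:
        raise ValueError(f"empty species groups: {empty}")
    results: dict = {"groups": labels}
    for metric in metrics:
        y = profiles[metric].to_numpy(dtype=float)
        ok = use & ~np.isnan(y)
        samples = [y[ok & (groups == g)] for g in labels]
        if any(len(s) < 2 for s in samples):
            raise ValueError(f"fewer than two usable individuals in a group for {metric}")
        fstat, pval = stats.f_oneway(*samples)
        tukey = pairwise_tukeyhsd(y[ok], groups[ok].astype(str))
        tukey_df = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        results[metric] = {
            "means": {g: float(s.mean()) for g, s in zip(labels, samples)},
            "anova_F": float(fstat),
            "anova_p": float(pval),
            "tukey": tukey_df,
        }
    return results


def group_minor_allele_frequencies(
    aa_table: AminoAcidVariantTable, groups: np.ndarray
) -> pd.DataFrame:
    """Per-variant minor-allele frequency within each binned species group."""
    out = {}
    for g, col in (("pure_E", "freq_E"), ("pure_W", "freq_W"), ("intermediate", "freq_mid")):
        idx = np.flatnonzero(np.asarray(groups, dtype=object) == g)
        dos = aa_table.dosages[:, idx]
        called = dos >= 0
        an = 2 * called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(an > 0, np.where(called, dos, 0).sum(axis=1) / np.maximum(an, 1), np.nan)
        out[col] = f
    return pd.DataFrame(out)


def uneven_sampling_check(
    variants: pd.DataFrame, group_freqs: pd.DataFrame
) -> tuple[int, np.ndarray]:
    """Count major alleles at higher relative frequency in the W group than
    in the E group whose two group frequencies sum to less than one.

    Such alleles would have been the tested (minor) allele under even
    sampling; a small count means uneven sampling had little effect.
    """
    maj_w = 1.0 - group_freqs["freq_W"].to_numpy()
    maj_e = 1.0 - group_freqs["freq_E"].to_numpy()
    nonsyn = variants["var_class"].str.startswith("nonsyn").to_numpy()
    suspect = nonsyn & (maj_w > maj_e) & (maj_w + maj_e < 1.0)
    suspect &= ~np.isnan(maj_w) & ~np.isnan(maj_e)
    return int(suspect.sum()), suspect


def phenotype_association(
    profiles: pd.DataFrame,
    phenotypes: np.ndarray,
    inbred_flagged: np.ndarray | None = None,
) -> dict:
    """Quadratic biomass-on-ancestry fit, load effects on its residuals, and
    the inbred-vs-others biomass comparison.

    Returns the quadratic fit (r2, F, p), linear fits of the residuals on
    prop_minor_del and prop_hom_del, and a Welch t-test of biomass for
    inbred-flagged vs other individuals (None when no individual is
    flagged).
    """
    y = np.asarray(phenotypes, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 individuals")
    q = profiles["q"].to_numpy(dtype=float)
    quad = _ols(y, np.column_stack([q, q**2]))
    resid = y - quad.fittedvalues
    out = {
        "quadratic_ancestry": {
            "r2": float(quad.rsquared),
            "F": float(quad.fvalue),
            "p_value": float(quad.f_pvalue),
        }
    }
    for metric in ("prop_minor_del", "prop_hom_del"):
        x = profiles[metric].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        fit = _ols(resid[ok], x[ok, None])
        out[f"residuals_on_{metric}"] = {
            "slope": float(fit.params[1]),
            "F": float(fit.fvalue),
            "p_value": float(fit.f_pvalue),
            "r2": float(fit.rsquared),
        }
    out["inbred_biomass_ttest"] = inbred_biomass_test(y, inbred_flagged)
    return out


def inbred_biomass_test(phenotypes: np.ndarray, inbred_flagged) -> dict | None:
    """Welch t-test of biomass for inbred-flagged vs other individuals."""
    if inbred_flagged is None or not np.asarray(inbred_flagged).any():
        return None
    y = np.asarray(phenotypes, dtype=float)
    flagged = np.asarray(inbred_flagged, dtype=bool)
    t, p = stats.ttest_ind(y[~flagged], y[flagged], equal_var=False)
    return {
        "t": float(t),
        "p_value": float(p),
        "mean_inbred": float(y[flagged].mean()),
        "mean_other": float(y[~flagged].mean()),
        "n_inbred": int(flagged.sum()),
    }
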