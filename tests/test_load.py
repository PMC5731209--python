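"""Load statistics: SFS, frequency contrasts, per-individual profiles,
regressions, group contrasts, lethal equivalents, phenotype association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridload import load
from hybridload.codons import AminoAcidVariantTable


def make_aa_table(dosages, classes, freqs=None, individuals=None):
    """Assemble an AminoAcidVariantTable from a dosage matrix and classes,
    one variant per position."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_var, n_ind = dosages.shape
    individuals = individuals or [f"ind_{i:04d}" for i in range(n_ind)]
    called = dosages >= 0
    minor_count = np.where(called, dosages, 0).sum(axis=1)
    alleles = 2 * called.sum(axis=1)
    variants = pd.DataFrame(
        {
            "gene": "gene_000",
            "protein_pos": np.arange(1, n_var + 1),
            "major_aa": "A",
            "minor_aa": "V",
            "major_codon": "",
            "minor_codon": "",
            "minor_count": minor_count,
            "alleles_genotyped": alleles,
            "minor_freq": freqs if freqs is not None else minor_count / alleles,
            "var_class": classes,
        }
    )
    nonsyn = variants["var_class"].str.startswith("nonsyn").to_numpy()
    return AminoAcidVariantTable(
        individuals=individuals,
        variants=variants,
        dosages=dosages,
        removals=pd.DataFrame(columns=["gene", "protein_pos", "reason"]),
        positions=variants.loc[nonsyn, ["gene", "protein_pos"]].reset_index(drop=True),
        position_called=called[nonsyn],
    )


class TestLethalEquivalents:
    def test_no_inbreeding_depression_gives_zero(self):
        assert load.lethal_equivalents(1.0).two_B == 0.0

    def test_closed_form_at_exp_minus_one(self):
        le = load.lethal_equivalents(np.exp(-1.0))
        assert le.two_B == pytest.approx(4.0)
        assert le.B == pytest.approx(2.0)

    def test_white_spruce_magnitude(self):
        # R ~= 0.043 corresponds to ~12.6 lethal equivalents per zygote
        assert load.lethal_equivalents(0.043).two_B == pytest.approx(12.59, abs=0.01)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.2])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            load.lethal_equivalents(bad)


class TestGroups:
    def test_threshold_assignment(self):
        q = np.array([0.95, 0.50, 0.75, 0.05, 0.40, 0.60, 0.39, 0.90, 0.10])
        got = load.assign_groups(q)
        assert list(got) == [
            "pure_E",
            "intermediate",
            "unbinned",
            "pure_W",
            "intermediate",
            "intermediate",
            "unbinned",
            "pure_E",
            "pure_W",
        ]


class TestFoldedSfs:
    def test_single_variant_lands_in_first_bin(self):
        v = pd.DataFrame({"minor_freq": [0.005], "var_class": ["synonymous"]})
        sfs = load.folded_sfs(v, n_bins=50)
        assert sfs["synonymous"].iloc[0] == 1
        assert sfs["synonymous"].sum() == 1

    def test_empty_table_gives_all_zero(self):
        v = pd.DataFrame({"minor_freq": [], "var_class": []})
        sfs = load.folded_sfs(v)
        assert len(sfs) == 50 and sfs.shape[1] == 2

    def test_counts_match_direct_tally(self):
        rng = np.random.default_rng(0)
        v = pd.DataFrame(
            {
                "minor_freq": rng.uniform(0.001, 0.5, 400),
                "var_class": rng.choice(
                    ["synonymous", "nonsyn_deleterious", "nonsyn_non_deleterious"], 400
                ),
            }
        )
        sfs = load.folded_sfs(v, n_bins=10)
        for cls in v["var_class"].unique():
            f = v.loc[v["var_class"] == cls, "minor_freq"]
            assert sfs[cls].sum() == len(f)
            first_bin = ((f > 0) & (f <= 0.05) | (f < 0.05)).sum()
            assert sfs[cls].iloc[0] == (f < 0.05).sum()


class TestFrequencyContrasts:
    def test_identical_distributions_not_significant(self):
        f = np.linspace(0.01, 0.3, 50)
        v = pd.DataFrame(
            {
                "minor_freq": np.concatenate([f, f, f]),
                "var_class": ["synonymous"] * 50
                + ["nonsyn_non_deleterious"] * 50
                + ["nonsyn_deleterious"] * 50,
                "minor_count": 2,
            }
        )
        res = load.compare_frequency_distributions(v)
        assert res["deleterious_vs_synonymous"]["p_value"] > 0.9
        assert res["deleterious_vs_non_deleterious"]["mean_diff"] == pytest.approx(0.0)

    def test_empty_class_reports_skip(self):
        v = pd.DataFrame(
            {
                "minor_freq": [0.1, 0.2],
                "var_class": ["synonymous", "synonymous"],
                "minor_count": 2,
            }
        )
        res = load.compare_frequency_distributions(v)
        assert "skipped" in res["deleterious_vs_synonymous"]

    def test_drop_singletons_keeps_doubletons(self):
        v = pd.DataFrame(
            {
                "minor_count": [1, 2, 1, 5],
                "minor_freq": [0.01, 0.02, 0.01, 0.05],
                "var_class": ["synonymous"] * 4,
            }
        )
        out = load.drop_singletons(v)
        assert list(out["minor_count"]) == [2, 5]


class TestProfiles:
    def test_worked_example_proportions(self):
        # 100 positions; individual 0 het-deleterious at 2, nothing else
        dosages = np.zeros((100, 3), dtype=np.int8)
        dosages[0, 0] = 1
        dosages[1, 0] = 1
        classes = ["nonsyn_deleterious"] * 100
        table = make_aa_table(dosages, classes)
        profiles = load.individual_load_profiles(
            table, table.variants, np.array([0.5, 0.5, 0.5])
        )
        row = profiles.iloc[0]
        assert row.prop_het_del == pytest.approx(0.02)
        assert row.prop_minor_del == pytest.approx(0.01)
        assert row.prop_hom_del == 0.0
        # an individual with no minor alleles has all-zero load
        assert profiles.iloc[1][["prop_minor_del", "prop_minor_nondel"]].sum() == 0

    def test_state_conservation_per_individual(self):
        rng = np.random.default_rng(4)
        dosages = rng.choice([-1, 0, 1, 2], size=(60, 10), p=[0.1, 0.6, 0.2, 0.1])
        classes = ["nonsyn_deleterious" if i % 3 == 0 else "nonsyn_non_deleterious" for i in range(60)]
        table = make_aa_table(dosages, classes)
        profiles = load.individual_load_profiles(table, table.variants, np.full(10, 0.5))
        hom_major = ((dosages == 0)).sum(axis=0)
        het = (dosages == 1).sum(axis=0)
        hom_minor = (dosages == 2).sum(axis=0)
        missing = (dosages == -1).sum(axis=0)
        np.testing.assert_array_equal(hom_major + het + hom_minor + missing, 60)
        np.testing.assert_array_equal(
            profiles["n_polymorphic_genotyped"], 60 - missing
        )

    def test_minor_allele_tallies_match_variant_counts(self):
        rng = np.random.default_rng(9)
        dosages = rng.choice([-1, 0, 1, 2], size=(30, 20), p=[0.05, 0.75, 0.15, 0.05])
        classes = ["nonsyn_non_deleterious"] * 30
        table = make_aa_table(dosages, classes)
        per_variant = np.where(dosages >= 0, dosages, 0).sum(axis=1)
        np.testing.assert_array_equal(per_variant, table.variants["minor_count"])

    def test_duplicating_variants_leaves_proportions_unchanged(self):
        rng = np.random.default_rng(2)
        dosages = rng.choice([0, 1, 2], size=(40, 8), p=[0.7, 0.2, 0.1])
        classes = ["nonsyn_deleterious" if i < 10 else "nonsyn_non_deleterious" for i in range(40)]
        t1 = make_aa_table(dosages, classes)
        t2 = make_aa_table(np.vstack([dosages, dosages]), classes + classes)
        p1 = load.individual_load_profiles(t1, t1.variants, np.full(8, 0.5))
        p2 = load.individual_load_profiles(t2, t2.variants, np.full(8, 0.5))
        for m in load.LOAD_METRICS:
            np.testing.assert_allclose(p1[m], p2[m], equal_nan=True)

    def test_zero_genotyped_individual_flagged(self):
        dosages = np.full((5, 2), -1, dtype=np.int8)
        dosages[:, 1] = 1
        table = make_aa_table(dosages, ["nonsyn_deleterious"] * 5)
        profiles = load.individual_load_profiles(table, table.variants, np.array([0.5, 0.5]))
        assert bool(profiles["undefined"].iloc[0])
        assert np.isnan(profiles["prop_minor_del"].iloc[0])


class TestRegressions:
    def _profiles(self, q, metric_values):
        df = pd.DataFrame({"q": q})
        for m in load.LOAD_METRICS:
            df[m] = metric_values
        return df

    def test_exact_linear_metric_has_unit_r2(self):
        q = np.linspace(0, 1, 30)
        profiles = self._profiles(q, 0.01 + 0.05 * q)
        res = load.regress_load_on_ancestry(profiles)
        row = res[res["metric"] == "prop_minor_nondel"].iloc[0]
        assert row.r2 == pytest.approx(1.0)
        assert row.beta_q == pytest.approx(0.05)

    def test_constant_metric_has_zero_slope(self):
        q = np.linspace(0, 1, 30)
        profiles = self._profiles(q, np.full(30, 0.02))
        res = load.regress_load_on_ancestry(profiles)
        assert res[res["metric"] == "prop_minor_del"].iloc[0].beta_q == pytest.approx(0.0, abs=1e-12)

    def test_requires_ancestry_variance(self):
        profiles = self._profiles(np.full(10, 0.5), np.full(10, 0.1))
        with pytest.raises(ValueError):
            load.regress_load_on_ancestry(profiles)


class TestGroupComparison:
    def test_null_groups_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            q = np.repeat([0.0, 0.5, 1.0], 25)
            profiles = pd.DataFrame({"q": q})
            for m in load.LOAD_METRICS:
                profiles[m] = rng.normal(0.05, 0.01, 75)
            res = load.binned_group_comparison(profiles, metrics=("prop_minor_del",))
            hits += res["prop_minor_del"]["anova_p"] < 0.05
        assert hits <= 1

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        q = np.repeat([0.0, 0.5, 1.0], 30)
        profiles = pd.DataFrame({"q": q})
        for m in load.LOAD_METRICS:
            profiles[m] = rng.normal(0.05, 0.005, 90) + 0.02 * (q == 0.5)
        res = load.binned_group_comparison(profiles, metrics=("prop_hom_del",))
        assert res["prop_hom_del"]["anova_p"] < 1e-6
        means = res["prop_hom_del"]["means"]
        assert means["intermediate"] > means["pure_E"]

    def test_empty_group_is_an_error(self):
        profiles = pd.DataFrame({"q": np.repeat([0.0, 1.0], 10)})
        for m in load.LOAD_METRICS:
            profiles[m] = 0.05
        with pytest.raises(ValueError, match="intermediate"):
            load.binned_group_comparison(profiles)


class TestUnevenSampling:
    def test_counting_rule(self):
        variants = pd.DataFrame({"var_class": ["nonsyn_non_deleterious"] * 3})
        gf = pd.DataFrame(
            {
                # minor-allele frequencies per group; major = 1 - minor
                "freq_W": [0.4, 0.2, 0.3],
                "freq_E": [0.7, 0.1, 0.75],
                "freq_mid": [0.5, 0.15, 0.5],
            }
        )
        # majors: W (0.6,0.8,0.7); E (0.3,0.9,0.25); sums (0.9,1.7,0.95)
        count, mask = load.uneven_sampling_check(variants, gf)
        assert count == 2
        assert list(mask) == [True, False, True]


class TestPhenotypeAssociation:
    def test_noiseless_quadratic_fully_explained(self):
        q = np.linspace(0, 1, 40)
        y = 3 + 2 * q - 1.5 * q**2
        profiles = pd.DataFrame(
            {"q": q, "prop_minor_del": np.linspace(0, 0.01, 40), "prop_hom_del": 0.001}
        )
        res = load.phenotype_association(profiles, y)
        assert res["quadratic_ancestry"]["r2"] == pytest.approx(1.0)
        assert abs(res["residuals_on_prop_minor_del"]["slope"]) < 1e-8

    def test_null_load_effect_rarely_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            q = np.repeat([0.0, 0.5, 1.0], 20)
            y = 10 + q - q**2 + rng.normal(0, 1, 60)
            profiles = pd.DataFrame(
                {
                    "q": q,
                    "prop_minor_del": rng.uniform(0, 0.01, 60),
                    "prop_hom_del": rng.uniform(0, 0.001, 60),
                }
            )
            res = load.phenotype_association(profiles, y)
            hits += res["residuals_on_prop_hom_del"]["p_value"] < 0.05
        assert hits <= 1

    def test_strong_homozygous_penalty_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            q = np.repeat([0.0, 0.5, 1.0], 20)
            hom = rng.uniform(0, 0.01, 60)
            y = 10 + q - q**2 - 300 * hom + rng.normal(0, 0.3, 60)
            profiles = pd.DataFrame(
                {"q": q, "prop_minor_del": rng.uniform(0, 0.01, 60), "prop_hom_del": hom}
            )
            res = load.phenotype_association(profiles, y)
            ok = (
                res["residuals_on_prop_hom_del"]["slope"] < 0
                and res["residuals_on_prop_hom_del"]["p_value"] < 0.05
            )
            hits += ok
        assert hits >= 9

    def test_inbred_comparison_reported(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([rng.normal(10, 1, 50), rng.normal(6, 1, 5)])
        flags = np.array([False] * 50 + [True] * 5)
        res = load.inbred_biomass_test(y, flags)
        assert res["t"] > 2 and res["p_value"] < 0.05
        assert load.inbred_biomass_test(y, np.zeros(55, bool)) is None
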