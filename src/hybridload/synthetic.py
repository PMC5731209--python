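"""Seedable synthetic datasets for the hybrid mutation-load analysis.

The generator emulates the statistical structure the downstream analysis
assumes: two parental species with unequal diversity (species E segregates
more, and more rare, alleles than species W), an ancestry gradient of
hybrids, deleterious nonsynonymous alleles that are rarer than neutral ones
and largely species-private, partial recessivity of deleterious effects on
a biomass phenotype, per-genotype missingness, and homolog protein families
whose conserved positions carry the deleterious variants' signal.

Hybrid genotypes are drawn per site from the ancestry-weighted allele
frequency ``q*p_E + (1-q)*p_W`` under Hardy-Weinberg within the individual;
no linkage structure is simulated (no linkage-based statistic is computed
downstream).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CodingRegion, GenotypeMatrix
from .genetics import (
    AMINO_ACIDS,
    SENSE_CODONS,
    codon_neighbors,
    translate_cds,
    translate_codon,
)

VARIANT_CATEGORIES = ("synonymous", "neutral_nonsyn", "deleterious_nonsyn")

# All (reference codon, offset, alt base) triples whose single-base change is
# synonymous (resp. nonsynonymous) and does not create or destroy a stop.
_SYN_TRIPLES: list[tuple[str, int, str]] = []
_NONSYN_TRIPLES: list[tuple[str, int, str]] = []
for _codon in SENSE_CODONS:
    _aa = translate_codon(_codon)
    for _off, _base, _mut in codon_neighbors(_codon):
        _maa = translate_codon(_mut)
        if _maa == "*":
            continue
        if _maa == _aa:
            _SYN_TRIPLES.append((_codon, _off, _base))
        else:
            _NONSYN_TRIPLES.append((_codon, _off, _base))


@dataclass(frozen=True)
class SpeciesSpectrum:
    """Minor-allele-frequency spectrum of one parental species.

    ``scale`` is the rate parameter (mean before truncation) of a truncated
    exponential on (0, 0.5]; a smaller scale concentrates mass near zero
    (more rare alleles).  ``seg_prob`` is the probability that a variant
    segregates in this species at all.
    """

    scale: float
    seg_prob: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("spectrum scale must be positive")
        if not 0 <= self.seg_prob <= 1:
            raise ValueError("seg_prob must be in [0, 1]")


@dataclass(frozen=True)
class PhenotypeEffects:
    """Coefficients of the biomass model.

    biomass = intercept + linear*q + quadratic*q**2
              - sum_v s_v * (h*het_v + hom_v) + Normal(0, noise_sd)

    with selection coefficients ``s_v ~ Exponential(selection_scale)`` per
    deleterious variant and ``h`` the dominance coefficient.  Defaults keep
    the load penalty weak (a few percent of variance at most), mirroring a
    fitness proxy only loosely coupled to load.
    """

    intercept: float = 10.0
    linear: float = 2.0
    quadratic: float = -2.0
    selection_scale: float = 0.03
    inbreeding_depression: float = 2.5
    noise_sd: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals_per_group: int = 60
    n_genes: int = 80
    codons_per_gene: int = 60
    ancestry_grid: tuple[float, ...] = (0.0, 0.5, 1.0)
    species_allele_freq_shape: dict = field(
        default_factory=lambda: {
            "E": SpeciesSpectrum(scale=0.06, seg_prob=0.90),
            "W": SpeciesSpectrum(scale=0.08, seg_prob=0.60),
        }
    )
    snps_per_gene: int = 30
    n_diagnostic_per_gene: int = 5
    diagnostic_freq: float = 0.99  # E-allele frequency in species E at panel sites
    frac_nonsynonymous: float = 0.567
    frac_deleterious_of_nonsyn: float = 0.25
    deleterious_freq_downweight: float = 0.25
    # a minority of deleterious alleles drift to moderate frequency within
    # one species (finite local populations; drift vs selection)
    drift_fraction: float = 0.3
    drift_freq_range: tuple[float, float] = (0.05, 0.20)
    private_fraction: float = 0.85
    private_e_weight: float = 0.6
    # conserved-position nonsynonymous variants that are not labelled
    # deleterious are still under weak constraint: their frequencies are
    # multiplied by this factor
    conserved_constraint_factor: float = 0.4
    conserved_fraction: float = 0.4
    conserved_deleterious_bias: float = 0.9
    # segregating neutral nonsynonymous variants avoid conserved codons with
    # this probability (purifying selection has already removed the others)
    conserved_neutral_avoidance: float = 0.95
    dominance_coefficient: float = 0.1
    missing_rate: float = 0.08
    n_homologs_per_gene: int = 15
    homolog_divergence: float = 0.85
    n_selfed: int = 4
    selfing_f: float = 0.5
    effects: PhenotypeEffects = field(default_factory=PhenotypeEffects)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_nonsynonymous",
            "frac_deleterious_of_nonsyn",
            "private_fraction",
            "private_e_weight",
            "conserved_fraction",
            "conserved_deleterious_bias",
            "conserved_neutral_avoidance",
            "dominance_coefficient",
            "missing_rate",
            "homolog_divergence",
            "diagnostic_freq",
            "selfing_f",
            "drift_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        for name in (
            "n_individuals_per_group",
            "n_genes",
            "codons_per_gene",
            "n_homologs_per_gene",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.snps_per_gene < 0 or self.n_diagnostic_per_gene < 0:
            raise ValueError("SNP counts must be non-negative")
        if self.snps_per_gene + self.n_diagnostic_per_gene > self.codons_per_gene:
            raise ValueError("more SNPs than codons per gene")
        if not all(0.0 <= q <= 1.0 for q in self.ancestry_grid):
            raise ValueError("ancestry grid values must be in [0, 1]")
        if not 0 < self.deleterious_freq_downweight <= 1:
            raise ValueError("deleterious_freq_downweight must be in (0, 1]")
        if not 0 < self.conserved_constraint_factor <= 1:
            raise ValueError("conserved_constraint_factor must be in (0, 1]")
        lo, hi = self.drift_freq_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("drift_freq_range must satisfy 0 < low <= high <= 0.5")
        n_del = (
            self.snps_per_gene
            * self.n_genes
            * self.frac_nonsynonymous
            * self.frac_deleterious_of_nonsyn
        )
        if n_del < 1:
            raise ValueError(
                "configuration leaves zero deleterious variants "
                "(frac_nonsynonymous x frac_deleterious_of_nonsyn too small)"
            )
        if set(self.species_allele_freq_shape) != {"E", "W"}:
            raise ValueError("species_allele_freq_shape must have keys 'E' and 'W'")

    @property
    def n_individuals(self) -> int:
        return self.n_individuals_per_group * len(self.ancestry_grid)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genotype_matrix: GenotypeMatrix
    coding_regions: dict[str, CodingRegion]
    homolog_families: dict[str, list[tuple[str, str]]]
    true_ancestry: np.ndarray
    third_species_q: np.ndarray
    true_genotypes: np.ndarray  # pre-missingness dosages
    true_variant_classes: pd.DataFrame
    diagnostic_panel: pd.DataFrame
    phenotypes: np.ndarray
    selfed: np.ndarray  # boolean per individual

    def digest(self) -> str:
        """SHA-256 digest of the dataset contents (determinism checks)."""
        h = hashlib.sha256()
        m = self.genotype_matrix
        for arr in (m.gt, m.dp, m.gq, m.ad_ref, m.ad_alt, self.true_genotypes):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(",".join(m.individuals).encode())
        h.update(m.sites.to_csv(index=False).encode())
        for gid in sorted(self.coding_regions):
            h.update(self.coding_regions[gid].cds.encode())
            for name, seq in self.homolog_families[gid]:
                h.update(name.encode())
                h.update(seq.encode())
        h.update(self.true_ancestry.tobytes())
        h.update(self.phenotypes.tobytes())
        h.update(self.true_variant_classes.to_csv(index=False).encode())
        return h.hexdigest()


def truncated_exponential_mean(scale: float, upper: float = 0.5) -> float:
    """Closed-form mean of an exponential truncated to (0, upper]."""
    z = 1.0 - np.exp(-upper / scale)
    return scale - upper * np.exp(-upper / scale) / z


def _draw_truncated_exponential(rng, scale: float, size=None, upper: float = 0.5):
    u = rng.random(size)
    x = -scale * np.log1p(-u * (1.0 - np.exp(-upper / scale)))
    return np.clip(x, np.nextafter(0, 1), upper)


def draw_species_frequencies(
    category: str,
    species: str,
    rng: np.random.Generator,
    config: SimulationConfig,
    size=None,
):
    """Draw minor-allele frequencies in (0, 0.5] for one variant category.

    Deleterious draws are multiplied by ``deleterious_freq_downweight`` and
    truncated back to (0, 0.5].
    """
    if category not in VARIANT_CATEGORIES:
        raise ValueError(f"unknown variant category: {category!r}")
    try:
        spectrum = config.species_allele_freq_shape[species]
    except KeyError:
        raise ValueError(f"unknown species label: {species!r}") from None
    x = _draw_truncated_exponential(rng, spectrum.scale, size=size)
    if category == "deleterious_nonsyn":
        x = np.clip(x * config.deleterious_freq_downweight, np.nextafter(0, 1), 0.5)
    return x


def generate_homolog_family(
    reference_protein: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    conserved_mask: np.ndarray | None = None,
    gene_id: str = "gene",
) -> list[tuple[str, str]]:
    """Simulate a homologous protein family for one reference protein.

    Positions flagged conserved are identical to the reference in every
    homolog; all other positions are substituted independently with
    probability ``homolog_divergence``.
    """
    if len(reference_protein) < 1:
        raise ValueError("reference protein must be non-empty")
    n = len(reference_protein)
    if conserved_mask is None:
        conserved_mask = rng.random(n) < config.conserved_fraction
    conserved_mask = np.asarray(conserved_mask, dtype=bool)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    ref = np.array(list(reference_protein))
    family = []
    for k in range(config.n_homologs_per_gene):
        seq = ref.copy()
        sub = (rng.random(n) < config.homolog_divergence) & ~conserved_mask
        for i in np.where(sub)[0]:
            choices = [c.decode() for c in aa if c.decode() != ref[i]]
            seq[i] = choices[rng.integers(len(choices))]
        family.append((f"{gene_id}_hom{k:02d}", "".join(seq)))
    return family


def _assign_categories(config: SimulationConfig) -> list[str]:
    """Deterministic per-gene category counts for the regular SNPs."""
    n = config.snps_per_gene
    n_syn = round(n * (1.0 - config.frac_nonsynonymous))
    n_del = round(n * config.frac_nonsynonymous * config.frac_deleterious_of_nonsyn)
    n_neut = n - n_syn - n_del
    return (
        ["synonymous"] * n_syn
        + ["neutral_nonsyn"] * n_neut
        + ["deleterious_nonsyn"] * n_del
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    rng = np.random.default_rng(config.seed)
    n_per = config.n_individuals_per_group
    q = np.repeat(np.asarray(config.ancestry_grid, dtype=float), n_per)
    n_ind = q.size
    individuals = [f"ind_{i:04d}" for i in range(n_ind)]
    third_q = np.zeros(n_ind)
    selfed = np.zeros(n_ind, dtype=bool)
    if config.n_selfed:
        selfed[rng.choice(n_ind, size=min(config.n_selfed, n_ind), replace=False)] = True

    regions: dict[str, CodingRegion] = {}
    families: dict[str, list[tuple[str, str]]] = {}
    site_rows = []
    truth_rows = []
    base_categories = _assign_categories(config)

    for g in range(config.n_genes):
        gene_id = f"gene_{g:03d}"
        nc = config.codons_per_gene
        conserved = rng.random(nc) < config.conserved_fraction
        categories = list(base_categories)
        rng.shuffle(categories)
        categories = ["diagnostic"] * config.n_diagnostic_per_gene + categories

        # allocate codons: deleterious variants prefer conserved codons
        available = list(rng.permutation(nc))
        chosen: list[int] = []
        for cat in categories:
            idx = None
            if cat == "deleterious_nonsyn" and rng.random() < config.conserved_deleterious_bias:
                want_conserved = True
            elif cat == "neutral_nonsyn" and rng.random() < config.conserved_neutral_avoidance:
                want_conserved = False
            else:
                want_conserved = None
            if want_conserved is not None:
                for j, c in enumerate(available):
                    if conserved[c] == want_conserved:
                        idx = j
                        break
            if idx is None:
                idx = 0
            chosen.append(available.pop(idx))

        codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=nc)]
        for cat, c in zip(categories, chosen):
            pool = _SYN_TRIPLES if cat in ("diagnostic", "synonymous") else _NONSYN_TRIPLES
            ref_codon, off, alt = pool[rng.integers(len(pool))]
            codons[c] = ref_codon
            pos = 3 * c + off + 1
            base_cat = "synonymous" if cat == "diagnostic" else cat
            if cat == "diagnostic":
                p_e, p_w = config.diagnostic_freq, 1.0 - config.diagnostic_freq
                private_to = ""
            else:
                p_e, p_w, private_to = _draw_variant_frequencies(
                    base_cat, rng, config, conserved=bool(conserved[c])
                )
            truth_rows.append(
                {
                    "gene": gene_id,
                    "pos": pos,
                    "codon_index": c,
                    "offset": off,
                    "ref": ref_codon[off],
                    "alt": alt,
                    "category": base_cat,
                    "diagnostic": cat == "diagnostic",
                    "conserved": bool(conserved[c]),
                    "freq_E": p_e,
                    "freq_W": p_w,
                    "private_to": private_to,
                    "s": 0.0,
                }
            )
        cds = "".join(codons)
        # guard against an accidental internal stop at unassigned codons
        protein = translate_cds(cds)
        if "*" in protein:
            fixed = codons[:]
            for i, a in enumerate(protein):
                if a == "*":
                    fixed[i] = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
            cds = "".join(fixed)
            protein = translate_cds(cds)
        regions[gene_id] = CodingRegion(gene_id, cds)
        families[gene_id] = generate_homolog_family(
            protein, config, rng, conserved_mask=conserved, gene_id=gene_id
        )

    truth = pd.DataFrame(truth_rows)
    truth["s"] = np.where(
        truth["category"] == "deleterious_nonsyn",
        rng.exponential(config.effects.selection_scale, size=len(truth)),
        0.0,
    )
    n_sites = len(truth)

    # genotypes under Hardy-Weinberg within the ancestry-mixed frequency
    p_e = truth["freq_E"].to_numpy()[:, None]
    p_w = truth["freq_W"].to_numpy()[:, None]
    p_ind = q[None, :] * p_e + (1.0 - q[None, :]) * p_w
    gt_true = rng.binomial(2, p_ind).astype(np.int8)
    for i in np.where(selfed)[0]:
        autoz = rng.random(n_sites) < config.selfing_f
        allele = rng.random(n_sites) < p_ind[:, i]
        gt_true[autoz, i] = (2 * allele[autoz]).astype(np.int8)

    phenotypes = simulate_phenotypes(
        gt_true,
        q,
        truth,
        config.effects,
        config.dominance_coefficient,
        rng,
        inbreeding=config.selfing_f * selfed,
    )

    gt = gt_true.copy()
    miss = rng.random(gt.shape) < config.missing_rate
    gt[miss] = -1

    # per-site quality annotations: drawn from passing ranges
    sites = pd.DataFrame(
        {
            "gene": truth["gene"],
            "pos": truth["pos"],
            "ref": truth["ref"],
            "alt": truth["alt"],
            "qual": rng.uniform(50, 900, n_sites).round(2),
            "mq": rng.uniform(50, 60, n_sites).round(2),
            "fs": np.minimum(rng.exponential(2.0, n_sites), 35.0).round(3),
            "haplotype_score": rng.uniform(0, 5, n_sites).round(3),
            "mq_rank_sum": np.clip(rng.normal(0, 2, n_sites), -8, 8).round(3),
            "read_pos_rank_sum": np.clip(rng.normal(0, 2, n_sites), -6, 8).round(3),
        }
    )

    dp = (rng.poisson(25, gt.shape) + 6).astype(np.int16)
    gq = rng.integers(60, 100, gt.shape, dtype=np.int16)
    ad_alt = np.zeros(gt.shape, dtype=np.int16)
    het = gt == 1
    ad_alt[het] = rng.binomial(dp[het], 0.5)
    hom = gt == 2
    ad_alt[hom] = dp[hom]
    ad_ref = (dp - ad_alt).astype(np.int16)
    ad_ref[gt == -1] = 0
    ad_alt[gt == -1] = 0
    dp = dp.copy()
    dp[gt == -1] = 0
    gq[gt == -1] = 0

    matrix = GenotypeMatrix(
        individuals=individuals,
        sites=sites,
        gt=gt,
        dp=dp,
        gq=gq,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
    )

    panel = truth.loc[truth["diagnostic"], ["gene", "pos", "freq_E", "freq_W"]]
    panel = panel.reset_index(drop=True)

    return SyntheticDataset(
        config=config,
        genotype_matrix=matrix,
        coding_regions=regions,
        homolog_families=families,
        true_ancestry=q,
        third_species_q=third_q,
        true_genotypes=gt_true,
        true_variant_classes=truth,
        diagnostic_panel=panel,
        phenotypes=phenotypes,
        selfed=selfed,
    )


def _draw_variant_frequencies(category, rng, config, conserved=False):
    """Per-species alt-allele frequencies for one non-diagnostic variant.

    Deleterious draws come from the downweighted spectrum, except that a
    ``drift_fraction`` minority has drifted to a moderate frequency drawn
    uniformly from ``drift_freq_range``.  Nonsynonymous variants at
    conserved positions that are *not* labelled deleterious are still
    weakly constrained (frequencies scaled by
    ``conserved_constraint_factor``).
    """
    spectra = config.species_allele_freq_shape

    def _draw(species):
        if category == "deleterious_nonsyn" and rng.random() < config.drift_fraction:
            return float(rng.uniform(*config.drift_freq_range))
        p = float(draw_species_frequencies(category, species, rng, config))
        if category == "neutral_nonsyn" and conserved:
            p *= config.conserved_constraint_factor
        return p

    if category == "deleterious_nonsyn" and rng.random() < config.private_fraction:
        species = "E" if rng.random() < config.private_e_weight else "W"
        p = _draw(species)
        return (p, 0.0, species) if species == "E" else (0.0, p, species)
    while True:
        seg_e = rng.random() < spectra["E"].seg_prob
        seg_w = rng.random() < spectra["W"].seg_prob
        if seg_e or seg_w:
            break
    p_e = _draw("E") if seg_e else 0.0
    p_w = _draw("W") if seg_w else 0.0
    return p_e, p_w, ""


def simulate_phenotypes(
    genotypes: np.ndarray,
    ancestry: np.ndarray,
    variant_classes: pd.DataFrame,
    effects: PhenotypeEffects,
    dominance: float,
    rng: np.random.Generator,
    inbreeding: np.ndarray | None = None,
) -> np.ndarray:
    """Biomass = quadratic(q) - per-individual load penalty + noise.

    The penalty sums ``s_v * (h*het + hom)`` over true deleterious variants,
    so with ``h=0`` heterozygous deleterious genotypes contribute nothing
    (full recessivity).  ``inbreeding`` (per-individual F, e.g. 0.5 for a
    selfed individual) adds a genome-wide inbreeding-depression penalty
    ``inbreeding_depression * F`` representing load outside the assayed
    exome.
    """
    q = np.asarray(ancestry, dtype=float)
    base = effects.intercept + effects.linear * q + effects.quadratic * q**2
    is_del = (variant_classes["category"] == "deleterious_nonsyn").to_numpy()
    s = variant_classes["s"].to_numpy()[is_del][:, None]
    g = genotypes[is_del]
    penalty = (s * (dominance * (g == 1) + (g == 2))).sum(axis=0)
    if inbreeding is not None:
        penalty = penalty + effects.inbreeding_depression * np.asarray(inbreeding, dtype=float)
    noise = rng.normal(0.0, effects.noise_sd, size=q.size) if effects.noise_sd else 0.0
    return base - penalty + noise
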