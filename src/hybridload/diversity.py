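"""Synonymous and nonsynonymous pairwise nucleotide diversity per coding
region, with Nei-Gojobori-style site and difference counting.

Counting conventions: a codon position's synonymous site fraction is the
proportion of its single-nucleotide changes that preserve the amino acid,
with changes to stop codons dropped from both numerator and denominator;
pairwise differences between codons average the synonymous/nonsynonymous
classification of each step over all mutational pathways that avoid stop
codons.  No multiple-hit correction is applied (within-species
polymorphism, far from saturation).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .codons import CodonGenotypeTable
from .datatypes import CodingRegion
from .genetics import STOP_CODONS, translate_codon


@dataclass(frozen=True)
class RegionDiversity:
    gene_id: str
    group: str
    n_sequences: int
    n_pairs: int
    syn_sites: float  # mean per-pair synonymous site count
    nonsyn_sites: float
    pi_s: float
    pi_n: float


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) fractional site counts for a sense codon;
    the two always sum to exactly 3."""
    aa = translate_codon(codon)
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site counts")
    syn = 0.0
    for off in range(3):
        n_syn = 0
        n_considered = 0
        for base in "ACGT":
            if base == codon[off]:
                continue
            mut = codon[:off] + base + codon[off + 1 :]
            if mut in STOP_CODONS:
                continue
            n_considered += 1
            if translate_codon(mut) == aa:
                n_syn += 1
        if n_considered:
            syn += n_syn / n_considered
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def pairwise_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense
    codons, averaged over all stop-free mutational pathways.

    The two counts sum to the number of differing positions.  In the
    (degenerate) case where every pathway passes through a stop codon, all
    pathways are used.
    """
    for c in (codon_a, codon_b):
        if translate_codon(c) == "*":
            raise ValueError(f"stop codon {c} in pairwise comparison")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0

    def _walk(order, allow_stops):
        syn = nonsyn = 0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if translate_codon(current) == translate_codon(nxt):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        return syn, nonsyn

    paths = [r for order in permutations(diff_pos) if (r := _walk(order, False))]
    if not paths:
        paths = [_walk(order, True) for order in permutations(diff_pos)]
    syn = float(np.mean([p[0] for p in paths]))
    return syn, float(k) - syn


def build_haplotype_sequences(
    table: CodonGenotypeTable, regions: dict[str, CodingRegion]
) -> dict[str, list[str]]:
    """Two pseudo-haplotype CDS strings per individual and gene.

    Monomorphic codons come from the reference; polymorphic codons with a
    missing genotype become 'NNN'.  Haplotypes are ordered
    [ind0_hap1, ind0_hap2, ind1_hap1, ...] under the same ref-together
    phase convention used for codon genotypes.
    """
    n_ind = len(table.individuals)
    out: dict[str, list[str]] = {}
    by_gene = table.entries.groupby("gene").indices
    for gene, region in regions.items():
        ref_codons = [region.ref_codon(c) for c in range(region.n_codons)]
        haps = [[list(ref_codons), list(ref_codons)] for _ in range(n_ind)]
        for e in by_gene.get(gene, []):
            c = int(table.entries["codon_index"].iloc[e])
            alleles = table.alleles[e]
            ids = table.ids[e]
            for ind in range(n_ind):
                for h in range(2):
                    a = ids[ind, h]
                    haps[ind][h][c] = "NNN" if a < 0 else alleles[a]
        out[gene] = ["".join(haps[i][h]) for i in range(n_ind) for h in range(2)]
    return out


def _encode(seqs: list[str]) -> tuple[np.ndarray, int]:
    """Byte-encode aligned CDS strings -> (n_hap, length) uint8 array."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    (L,) = lengths
    if L % 3:
        raise ValueError("alignment length not divisible by 3")
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), L)
    return arr, L // 3


def region_pi(sequences: list[str], gene_id: str = "", group: str = "") -> RegionDiversity:
    """Average pairwise diversity per synonymous / nonsynonymous site.

    For each unordered sequence pair, differences and site counts use only
    the codons complete (no N) in both members; site counts are averaged
    over the two compared sequences, and the reported pi is the mean over
    pairs of (differences / sites).  Raises when no pair shares any
    complete codon.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    arr, n_codons = _encode(sequences)
    n_hap = arr.shape[0]
    has_n = (arr == ord("N")).reshape(n_hap, n_codons, 3).any(axis=2)

    # per codon: map distinct complete codons to small allele ids
    ids = np.full((n_hap, n_codons), -1, dtype=np.int16)
    codon_alleles: list[list[str]] = []
    view = arr.reshape(n_hap, n_codons, 3)
    for c in range(n_codons):
        col = view[:, c, :]
        complete = ~has_n[:, c]
        mapping: dict[bytes, int] = {}
        alleles: list[str] = []
        for h in np.flatnonzero(complete):
            key = col[h].tobytes()
            if key not in mapping:
                mapping[key] = len(alleles)
                alleles.append(key.decode())
            ids[h, c] = mapping[key]
        codon_alleles.append(alleles)

    kmax = max((len(a) for a in codon_alleles), default=1)
    t_syn = np.zeros((n_codons, kmax, kmax))
    t_non = np.zeros((n_codons, kmax, kmax))
    s_syn = np.zeros((n_codons, kmax))
    s_non = np.zeros((n_codons, kmax))
    for c, alleles in enumerate(codon_alleles):
        for a, ca in enumerate(alleles):
            s_syn[c, a], s_non[c, a] = codon_site_counts(ca)
            for b, cb in enumerate(alleles):
                if b < a:
                    continue
                ds, dn = pairwise_differences(ca, cb)
                t_syn[c, a, b] = t_syn[c, b, a] = ds
                t_non[c, a, b] = t_non[c, b, a] = dn

    cidx = np.arange(n_codons)
    safe = np.maximum(ids, 0)
    ratios_s, ratios_n, sites_s, sites_n = [], [], [], []
    n_pairs = 0
    for i in range(n_hap - 1):
        js = slice(i + 1, n_hap)
        shared = (ids[i] >= 0) & (ids[js] >= 0)  # (nj, n_codons)
        ai = safe[i]
        aj = safe[js]
        ds = np.where(shared, t_syn[cidx, ai, aj], 0.0).sum(axis=1)
        dn = np.where(shared, t_non[cidx, ai, aj], 0.0).sum(axis=1)
        ss = np.where(shared, 0.5 * (s_syn[cidx, ai] + s_syn[cidx, aj]), 0.0).sum(axis=1)
        sn = np.where(shared, 0.5 * (s_non[cidx, ai] + s_non[cidx, aj]), 0.0).sum(axis=1)
        usable = (ss + sn) > 0
        n_pairs += int(usable.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios_s.append(np.where(ss > 0, ds / np.maximum(ss, 1e-300), 0.0)[usable])
            ratios_n.append(np.where(sn > 0, dn / np.maximum(sn, 1e-300), 0.0)[usable])
        sites_s.append(ss[usable])
        sites_n.append(sn[usable])
    if n_pairs == 0:
        raise ValueError(f"{gene_id}: no sequence pair shares a complete codon")
    return RegionDiversity(
        gene_id=gene_id,
        group=group,
        n_sequences=n_hap,
        n_pairs=n_pairs,
        syn_sites=float(np.concatenate(sites_s).mean()),
        nonsyn_sites=float(np.concatenate(sites_n).mean()),
        pi_s=float(np.concatenate(ratios_s).mean()),
        pi_n=float(np.concatenate(ratios_n).mean()),
    )


def filter_regions(
    sequences_by_gene: dict[str, list[str]],
    min_bp: float = 100.0,
    min_individuals: int = 20,
) -> list[str]:
    """Regions usable for one group: variable, and with more than ``min_bp``
    positions of complete (non-N, both haplotypes) data in at least
    ``min_individuals`` individuals."""
    usable = []
    for gene, seqs in sequences_by_gene.items():
        arr, _ = _encode(seqs)
        n_ind = arr.shape[0] // 2
        pair_ok = (arr[0::2] != ord("N")) & (arr[1::2] != ord("N"))
        complete_bp = pair_ok.sum(axis=1)
        enough = (complete_bp > min_bp).sum() >= min_individuals
        lo = np.where(arr == ord("N"), 255, arr).min(axis=0)
        hi = np.where(arr == ord("N"), 0, arr).max(axis=0)
        variable = bool(((hi > 0) & (lo < 255) & (lo != hi)).any())
        if enough and variable:
            usable.append(gene)
    return usable


def group_region_diversity(
    sequences_by_gene: dict[str, dict[str, list[str]]],
    min_bp: float = 100.0,
    min_individuals: int = 20,
) -> pd.DataFrame:
    """Per-region diversity for each group, restricted to regions passing
    the completeness filter in *every* group.

    ``sequences_by_gene`` maps group -> gene -> haplotype sequences.
    """
    groups = list(sequences_by_gene)
    usable = None
    for g in groups:
        ok = set(filter_regions(sequences_by_gene[g], min_bp, min_individuals))
        usable = ok if usable is None else usable & ok
    rows = []
    for gene in sorted(usable or ()):
        for g in groups:
            rd = region_pi(sequences_by_gene[g][gene], gene_id=gene, group=g)
            rows.append(rd.__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "group",
            "n_sequences",
            "n_pairs",
            "syn_sites",
            "nonsyn_sites",
            "pi_s",
            "pi_n",
        ],
    )


def nemenyi_posthoc(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Nemenyi all-pairs rank test (Tukey-type, studentized range)."""
    labels = list(samples)
    values = np.concatenate([np.asarray(samples[g], dtype=float) for g in labels])
    sizes = [len(samples[g]) for g in labels]
    ranks = stats.rankdata(values)
    n_total = len(values)
    k = len(labels)
    mean_ranks = {}
    start = 0
    for g, n in zip(labels, sizes):
        mean_ranks[g] = ranks[start : start + n].mean()
        start += n
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = labels[i], labels[j]
            se = np.sqrt(n_total * (n_total + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = abs(mean_ranks[gi] - mean_ranks[gj]) / se
            p = stats.studentized_range.sf(q * np.sqrt(2.0), k, np.inf)
            rows.append({"group_a": gi, "group_b": gj, "q": float(q), "p_value": float(p)})
    return pd.DataFrame(rows)


def group_diversity_comparison(region_diversities: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Kruskal-Wallis omnibus per statistic (pi_s, pi_n) across groups, with
    Nemenyi pairwise post-hoc tests when the omnibus is significant."""
    out = {}
    groups = sorted(region_diversities["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for stat_name in ("pi_s", "pi_n"):
        samples = {
            g: region_diversities.loc[region_diversities["group"] == g, stat_name].to_numpy()
            for g in groups
        }
        if any(len(v) < 2 for v in samples.values()):
            raise ValueError("need at least two regions per group")
        h, p = stats.kruskal(*samples.values())
        entry = {
            "kruskal_h": float(h),
            "p_value": float(p),
            "group_means": {g: float(np.mean(v)) for g, v in samples.items()},
            "posthoc": None,
        }
        if p < alpha:
            entry["posthoc"] = nemenyi_posthoc(samples)
        out[stat_name] = entry
    return out
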