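"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: local alignment by
exhaustive enumeration over monotone matchings, codon arithmetic via
Biopython translation of enumerated neighbors, and diversity via a naive
per-pair double loop.
"""

from itertools import permutations

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

STOPS = {"TAA", "TAG", "TGA"}


def bio_translate(codon: str) -> str:
    return str(Seq(codon).translate())


def brute_force_local_score(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Maximal local alignment score by exhaustive enumeration of all
    monotone matchings of residue pairs (gap blocks between consecutive
    matched pairs charged open + length*extend; end gaps free)."""
    m, n = len(a), len(b)
    S = _BLOSUM62
    best = 0.0

    def gap(d: int) -> float:
        return gap_open + gap_extend * d if d > 0 else 0.0

    def rec(pi: int, pj: int, score: float) -> None:
        nonlocal best
        if score > best:
            best = score
        for i2 in range(pi + 1, m):
            for j2 in range(pj + 1, n):
                rec(i2, j2, score + S[a[i2], b[j2]] - gap(i2 - pi - 1) - gap(j2 - pj - 1))

    for i in range(m):
        for j in range(n):
            rec(i, j, float(S[a[i], b[j]]))
    return best


def enumerate_codon_site_counts(codon: str) -> tuple[float, float]:
    """Per-position synonymous fraction over the 9 single-base neighbors,
    stop changes excluded from numerator and denominator."""
    aa = bio_translate(codon)
    syn = 0.0
    for off in range(3):
        considered = 0
        syn_here = 0
        for base in "ACGT":
            if base == codon[off]:
                continue
            mut = codon[:off] + base + codon[off + 1 :]
            if mut in STOPS:
                continue
            considered += 1
            if bio_translate(mut) == aa:
                syn_here += 1
        if considered:
            syn += syn_here / considered
    return syn, 3.0 - syn


def enumerate_pairwise_differences(ca: str, cb: str) -> tuple[float, float]:
    """Average syn/nonsyn step classification over stop-free pathways."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow):
        cur, syn, non = ca, 0, 0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOPS and not allow:
                return None
            if bio_translate(cur) == bio_translate(nxt):
                syn += 1
            else:
                non += 1
            cur = nxt
        return syn, non

    paths = [r for order in permutations(diff) if (r := walk(order, False))]
    if not paths:
        paths = [walk(order, True) for order in permutations(diff)]
    syn = sum(p[0] for p in paths) / len(paths)
    return syn, len(diff) - syn


def naive_region_pi(sequences: list[str]) -> tuple[float, float]:
    """(pi_s, pi_n): per-pair ratios averaged over pairs, pairwise-complete
    codon deletion, site counts averaged over the compared sequences."""
    n = len(sequences)
    nc = len(sequences[0]) // 3
    ratios_s, ratios_n = [], []
    for i in range(n):
        for j in range(i + 1, n):
            ds = dn = ss = sn = 0.0
            for c in range(nc):
                ca = sequences[i][3 * c : 3 * c + 3]
                cb = sequences[j][3 * c : 3 * c + 3]
                if "N" in ca or "N" in cb:
                    continue
                s1, n1 = enumerate_codon_site_counts(ca)
                s2, n2 = enumerate_codon_site_counts(cb)
                ss += 0.5 * (s1 + s2)
                sn += 0.5 * (n1 + n2)
                d_s, d_n = enumerate_pairwise_differences(ca, cb)
                ds += d_s
                dn += d_n
            if ss + sn > 0:
                ratios_s.append(ds / ss if ss > 0 else 0.0)
                ratios_n.append(dn / sn if sn > 0 else 0.0)
    return (
        sum(ratios_s) / len(ratios_s),
        sum(ratios_n) / len(ratios_n),
    )
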