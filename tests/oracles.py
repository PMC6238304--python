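"""Independent re-implementations used only as test oracles.

These deliberately avoid the package's own code paths: the pair
enumeration is written as plain nested loops with its own genotype
arithmetic, and the Hardy-Weinberg oracle enumerates every arrangement of
alleles into ordered mating slots with exact rational arithmetic.
"""

from __future__ import annotations

import re
from fractions import Fraction
from functools import lru_cache
from itertools import combinations
from math import comb


def _star_num(name: str) -> tuple[int, str]:
    m = re.match(r"^\*(\d+)", name)
    return (int(m.group(1)) if m else 1 << 30, name)


def naive_consistent_pairs(sample, table):
    """Brute-force enumeration over the allele universe, written from scratch."""
    loci = list(table.informative_loci)
    obs = {l: sample.genotypes.get(l, "missing") for l in loci}
    del_names = [
        n for n in table.alleles if "whole_gene_deletion" in table.alleles[n].structural
    ]
    names = sorted(table.alleles, key=_star_num)

    if sample.deletion_band and all(v == "missing" for v in obs.values()) and del_names:
        d = del_names[0]
        return [(d, d)]

    def conv(n):
        return "exon9_conversion" in table.alleles[n].structural

    def carries(n, locus):
        return locus in table.alleles[n].all_variants

    def expected(a, b, locus):
        a_del, b_del = a in del_names, b in del_names
        if a_del and b_del:
            return "missing"
        if a_del or b_del:
            survivor = b if a_del else a
            return "alt_alt" if carries(survivor, locus) else "ref_ref"
        k = carries(a, locus) + carries(b, locus)
        return ["ref_ref", "ref_alt", "alt_alt"][k]

    def expected_exon9(a, b):
        a_del, b_del = a in del_names, b in del_names
        if a_del and b_del:
            return "untested"
        if a_del or b_del:
            return "homozygous" if conv(b if a_del else a) else "absent"
        return ["absent", "present", "homozygous"][conv(a) + conv(b)]

    out = []
    for i, a in enumerate(names):
        for b in names[i:]:
            n_del = (a in del_names) + (b in del_names)
            if sample.deletion_band and n_del != 1:
                continue
            if not sample.deletion_band and n_del > 0:
                continue
            if sample.exon9_conversion == "untested":
                if conv(a) or conv(b):
                    continue
            elif expected_exon9(a, b) != sample.exon9_conversion:
                continue
            if all(
                obs[l] == "missing" or expected(a, b, l) == obs[l] for l in loci
            ):
                out.append(tuple(sorted((a, b), key=_star_num)))
    return sorted(set(out), key=lambda p: (_star_num(p[0]), _star_num(p[1])))


@lru_cache(maxsize=None)
def _het_distribution(n: int, n_ref: int) -> dict[int, Fraction]:
    """Exact distribution of the heterozygote count when n_ref reference and
    2n - n_ref alternate alleles are arranged uniformly into n ordered pairs."""
    total = comb(2 * n, n_ref)
    counts: dict[int, int] = {}
    for ref_positions in combinations(range(2 * n), n_ref):
        rp = set(ref_positions)
        het = sum((2 * i in rp) != (2 * i + 1 in rp) for i in range(n))
        counts[het] = counts.get(het, 0) + 1
    return {h: Fraction(c, total) for h, c in counts.items()}


def hwe_exact_oracle(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact two-sided HWE p-value by full enumeration (feasible for 2n <= 20)."""
    n = n_ref_hom + n_het + n_alt_hom
    n_ref = 2 * n_ref_hom + n_het
    dist = _het_distribution(n, n_ref)
    p_obs = dist[n_het]
    return float(sum(p for p in dist.values() if p <= p_obs))
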