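"""Independent brute-force oracles used to check closed-form statistics.

Everything here is deliberately written by direct enumeration over
genotype space (loops, no shared code with the package implementation)
so it can serve as an independent cross-check on tiny inputs.
"""

from __future__ import annotations

import math

import numpy as np


def genotype_space(k: int):
    return [(i, j) for i in range(k) for j in range(i, k)]


def hwe_prob(g, p):
    i, j = g
    return p[i] ** 2 if i == j else 2 * p[i] * p[j]


def pic_enum(p) -> float:
    s2 = sum(x * x for x in p)
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2 * p[i] ** 2 * p[j] ** 2
    return 1.0 - s2 - cross


def pid_enum(p) -> float:
    """P(two random HWE individuals share a genotype), by enumeration."""
    return sum(hwe_prob(g, p) ** 2 for g in genotype_space(len(p)))


def pid_sibs_enum(p) -> float:
    """P(two full sibs share a genotype): enumerate parental genotype
    pairs under HWE and Mendelian segregation of the offspring."""
    total = 0.0
    genos = genotype_space(len(p))
    for gm in genos:
        for gf in genos:
            w = hwe_prob(gm, p) * hwe_prob(gf, p)
            dist: dict = {}
            for am in gm:
                for af in gf:
                    g = tuple(sorted((am, af)))
                    dist[g] = dist.get(g, 0.0) + 0.25
            total += w * sum(v * v for v in dist.values())
    return total


def unbiased_he_enum(p, n) -> float:
    return (2 * n / (2 * n - 1)) * (1.0 - sum(x * x for x in p))


def nei_da_enum(x: dict, y: dict) -> float:
    loci = [l for l in x if l in y]
    acc = 0.0
    for l in loci:
        for a, fx in x[l].items():
            acc += math.sqrt(fx * y[l].get(a, 0.0))
    return 1.0 - acc / len(loci)


def hl_enum(calls: dict, ref: dict) -> float:
    num = den = 0.0
    for loc, call in calls.items():
        if call is None or loc not in ref:
            continue
        e = 1.0 - sum(f * f for f in ref[loc].values())
        den += e
        if call[0] == call[1]:
            num += e
    return num / den


def ir_enum(calls: dict, ref: dict) -> float:
    hom = n = 0
    fsum = 0.0
    for loc, call in calls.items():
        if call is None or loc not in ref:
            continue
        n += 1
        hom += call[0] == call[1]
        fsum += ref[loc].get(call[0], 0.0) + ref[loc].get(call[1], 0.0)
    return (2 * hom - fsum) / (2 * n - fsum)


def hudson_fst(per_pop_freqs, n1: int, n2: int) -> float:
    """Multilocus Hudson-style F_ST estimator (ratio of sums) from
    per-population sample allele-frequency vectors."""
    num = den = 0.0
    for p1, p2 in per_pop_freqs:
        p1 = np.asarray(p1)
        p2 = np.asarray(p2)
        num += (
            np.sum((p1 - p2) ** 2)
            - np.sum(p1 * (1 - p1)) / (2 * n1 - 1)
            - np.sum(p2 * (1 - p2)) / (2 * n2 - 1)
        )
        den += np.sum(p1 * (1 - p2) + p2 * (1 - p1))
    return float(num / den)


def realized_fst(truth, n_per_pop: int) -> float:
    sizes = np.asarray(truth.allele_sizes)
    pairs = []
    for l in range(len(truth.loci)):
        fr = []
        for pop in ("China", "Russia"):
            idx = truth.individuals.index[truth.individuals.population == pop]
            g = truth.genotypes[np.asarray(idx)][:, l, :]
            c = np.array([(g == s).sum() for s in sizes], float)
            fr.append(c / c.sum())
        pairs.append(fr)
    return hudson_fst(pairs, n_per_pop, n_per_pop)
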