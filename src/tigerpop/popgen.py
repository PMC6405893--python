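"""Per-locus diversity statistics and data-quality tests.

Observed and (small-sample unbiased) expected heterozygosity,
polymorphism information content (PIC), the probability-of-identity
family P_ID / unbiased P_ID / P_ID(sibs) with cumulative multilocus
curves, Monte-Carlo exact Hardy-Weinberg and linkage-disequilibrium
tests, a null-allele screen (Brookfield estimator + homozygote-excess
resampling), and Holm sequential-Bonferroni correction.

All Monte-Carlo p-values use the (1 + hits) / (N + 1) convention, which
never returns zero and is a valid test.
"""

from __future__ import annotations

import decimal
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

Call = tuple[int, int]


# ---------------------------------------------------------------------------
# allele frequency container


@dataclass
class PopAlleleFreqs:
    """Per-population, per-locus allele counts with derived frequencies.

    ``counts[pop][locus]`` maps allele -> number of copies among typed
    individuals; ``n[pop][locus]`` is the number of typed individuals and
    ``n_het[pop][locus]`` the number of heterozygous ones.
    """

    counts: dict[str, dict[str, Counter]] = field(default_factory=dict)
    n: dict[str, dict[str, int]] = field(default_factory=dict)
    n_het: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        return list(self.counts)

    def loci(self, population: str) -> list[str]:
        return list(self.counts[population])

    def frequencies(self, population: str, locus: str) -> dict[int, float]:
        c = self.counts[population][locus]
        total = sum(c.values())
        return {a: k / total for a, k in c.items()}

    def freq_vector(self, population: str, locus: str) -> np.ndarray:
        return np.array(list(self.frequencies(population, locus).values()))

    def pooled(self) -> "PopAlleleFreqs":
        """Collapse all populations into a single pool named 'pooled'."""
        counts: dict[str, Counter] = {}
        n: dict[str, int] = {}
        n_het: dict[str, int] = {}
        for pop in self.counts:
            for loc, c in self.counts[pop].items():
                counts.setdefault(loc, Counter()).update(c)
                n[loc] = n.get(loc, 0) + self.n[pop][loc]
                n_het[loc] = n_het.get(loc, 0) + self.n_het[pop][loc]
        return PopAlleleFreqs(
            counts={"pooled": counts}, n={"pooled": n}, n_het={"pooled": n_het}
        )


def allele_frequencies(
    individuals: Iterable, by_population: bool = True
) -> PopAlleleFreqs:
    """Tabulate allele counts from individuals' consensus genotypes.

    Accepts objects with ``population_label`` and ``genotype`` attributes
    (see :class:`tigerpop.genotyping.Individual`) or ``(population,
    calls)`` pairs.  Missing genotypes reduce only that locus's typed
    count.  Loci with zero typed individuals in a population are
    excluded.
    """
    out = PopAlleleFreqs()
    for ind in individuals:
        if hasattr(ind, "genotype"):
            pop = ind.population_label if by_population else "pooled"
            calls = ind.genotype
        else:
            pop, calls = ind
            if not by_population:
                pop = "pooled"
        pop = str(pop)
        cc = out.counts.setdefault(pop, {})
        nn = out.n.setdefault(pop, {})
        hh = out.n_het.setdefault(pop, {})
        for loc, call in calls.items():
            if call is None:
                continue
            cc.setdefault(loc, Counter()).update(call)
            nn[loc] = nn.get(loc, 0) + 1
            hh[loc] = hh.get(loc, 0) + (1 if call[0] != call[1] else 0)
    return out


# ---------------------------------------------------------------------------
# closed-form per-locus statistics


def heterozygosity(freqs: PopAlleleFreqs, population: str, locus: str) -> tuple[float, float]:
    """(H_O, H_E) at one locus.

    H_O is the fraction of typed individuals that are heterozygous; H_E
    is Nei's small-sample unbiased estimator
    ``(2n / (2n - 1)) * (1 - sum p_i^2)``.
    """
    n = freqs.n[population][locus]
    if n < 2:
        raise ValueError(f"H_E undefined for n={n} at {locus}")
    h_o = freqs.n_het[population][locus] / n
    p = freqs.freq_vector(population, locus)
    h_e = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p**2)))
    return h_o, h_e


def pic(p: Sequence[float]) -> float:
    """Polymorphism information content:
    ``1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``."""
    p = np.asarray(p, dtype=float)
    s2 = float(np.sum(p**2))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    cross = s2**2 - float(np.sum(p**4))
    return 1.0 - s2 - cross


def pid_biased(p: Sequence[float]) -> float:
    """Probability that two random (unrelated, HWE) individuals share a
    genotype: ``2 (sum p_i^2)^2 - sum p_i^4``."""
    p = np.asarray(p, dtype=float)
    a2 = float(np.sum(p**2))
    a4 = float(np.sum(p**4))
    return 2.0 * a2**2 - a4


def pid_unbiased(p: Sequence[float], n: int) -> float:
    """Small-sample unbiased P_ID estimator from sample allele
    proportions ``p`` out of ``n`` typed individuals (requires n >= 4).

    The correction polynomial is a function of the number of sampled
    allele copies, m = 2n (a diploid individual contributes two copies);
    with m in that role the estimator's expectation matches the
    true-frequency P_ID.
    """
    if n < 4:
        raise ValueError(f"unbiased P_ID requires n >= 4 typed individuals, got {n}")
    p = np.asarray(p, dtype=float)
    a2 = float(np.sum(p**2))
    a3 = float(np.sum(p**3))
    a4 = float(np.sum(p**4))
    m = 2 * n
    num = (
        m**3 * (2 * a2**2 - a4)
        - 2 * m**2 * (a3 + 2 * a2)
        + m * (9 * a2 + 2)
        - 6
    )
    return num / ((m - 1) * (m - 2) * (m - 3))


def pid_sibs(p: Sequence[float]) -> float:
    """P_ID for full siblings:
    ``0.25 + 0.5 a2 + 0.5 a2^2 - 0.25 a4``."""
    p = np.asarray(p, dtype=float)
    a2 = float(np.sum(p**2))
    a4 = float(np.sum(p**4))
    return 0.25 + 0.5 * a2 + 0.5 * a2**2 - 0.25 * a4


def locus_stats(freqs: PopAlleleFreqs, population: str) -> pd.DataFrame:
    """Per-locus summary table: n, H_O, H_E, PIC and the P_ID family."""
    rows = []
    for loc in freqs.loci(population):
        n = freqs.n[population][loc]
        p = freqs.freq_vector(population, loc)
        if n < 2:
            h_o, h_e = np.nan, np.nan  # undefined, flagged
        else:
            h_o, h_e = heterozygosity(freqs, population, loc)
        rows.append(
            {
                "locus": loc,
                "n": n,
                "H_O": h_o,
                "H_E": h_e,
                "PIC": pic(p),
                "PID_biased": pid_biased(p),
                "PID_unbiased": pid_unbiased(p, n) if n >= 4 else np.nan,
                "PID_sibs": pid_sibs(p),
            }
        )
    return pd.DataFrame(rows)


def cumulative_pid(
    freqs: PopAlleleFreqs, population: str, order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Cumulative multilocus P_ID curve.

    Loci are multiplied most-informative-first (ascending per-locus
    unbiased P_ID) unless an explicit ``order`` is given.  Returns one
    row per added locus with cumulative unbiased P_ID and P_ID(sibs).
    """
    stats = locus_stats(freqs, population).set_index("locus")
    if order is None:
        usable = stats.dropna(subset=["PID_unbiased"])
        order = list(usable.sort_values("PID_unbiased").index)
    cum_u, cum_s = 1.0, 1.0
    rows = []
    for loc in order:
        cum_u *= stats.loc[loc, "PID_unbiased"]
        cum_s *= stats.loc[loc, "PID_sibs"]
        rows.append(
            {"locus": loc, "cum_PID_unbiased": cum_u, "cum_PID_sibs": cum_s}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte-Carlo exact tests


def _genotype_array_logprob(genotypes: Sequence[Call]) -> float:
    """Log conditional probability of a genotype array given its allele
    counts (Levene's distribution): log[ n! 2^h prod_a c_a! / ((2n)!
    prod_g g_count!) ]."""
    n = len(genotypes)
    allele_counts = Counter()
    geno_counts = Counter()
    h = 0
    for g in genotypes:
        allele_counts.update(g)
        geno_counts[g] += 1
        if g[0] != g[1]:
            h += 1
    logp = gammaln(n + 1) + h * np.log(2.0)
    logp += sum(gammaln(c + 1) for c in allele_counts.values())
    logp -= gammaln(2 * n + 1)
    logp -= sum(gammaln(c + 1) for c in geno_counts.values())
    return float(logp)


def hwe_exact_test(
    genotypes: Sequence[Call],
    n_mc: int = 10000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo exact Hardy-Weinberg test for one locus.

    The observed genotype array's conditional probability given the
    allele counts is compared against arrays obtained by shuffling the
    observed allele pool into random pairs;
    ``p = (1 + #{simulated logP <= observed}) / (n_mc + 1)``.
    A monomorphic locus is untestable and returns p = 1.
    """
    genotypes = [tuple(sorted(g)) for g in genotypes if g is not None]
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    pool = np.array([a for g in genotypes for a in g])
    if len(genotypes) < 3 or np.unique(pool).size < 2:
        return 1.0
    rng = np.random.default_rng(seed)
    # the allele-count and n! terms are invariant under pool shuffling,
    # so tables compare on  h*log2 - sum_g log(g_count!)  alone
    obs = _table_logprob_kernel(pool.reshape(-1, 2))
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        if _table_logprob_kernel(pool.reshape(-1, 2)) <= obs + 1e-12:
            hits += 1
    return (1 + hits) / (n_mc + 1)


def _table_logprob_kernel(pairs: np.ndarray) -> float:
    """Shuffle-variant part of the Levene log-probability for a genotype
    array given as an (n, 2) allele matrix."""
    a = pairs.min(axis=1)
    b = pairs.max(axis=1)
    h = int(np.sum(a != b))
    codes = a * 100000 + b
    _, counts = np.unique(codes, return_counts=True)
    return h * float(np.log(2.0)) - float(np.sum(gammaln(counts + 1)))


def _g_statistic_codes(xa: np.ndarray, xb: np.ndarray, na: int, nb: int) -> float:
    tab = np.bincount(xa * nb + xb, minlength=na * nb).reshape(na, nb).astype(float)
    total = tab.sum()
    exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
    mask = tab > 0
    return 2.0 * float(np.sum(tab[mask] * np.log(tab[mask] / exp[mask])))


def ld_permutation_test(
    genotypes_a: Sequence[Call],
    genotypes_b: Sequence[Call],
    n_perm: int = 10000,
    seed: int | None = None,
) -> float:
    """Permutation test of linkage disequilibrium between two loci.

    The log-likelihood-ratio G statistic on the two-locus genotype
    contingency table is compared against its null distribution obtained
    by permuting one locus's genotypes across individuals (pairs with a
    missing call at either locus are dropped).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pairs = [
        (tuple(sorted(a)), tuple(sorted(b)))
        for a, b in zip(genotypes_a, genotypes_b)
        if a is not None and b is not None
    ]
    xa = [p[0] for p in pairs]
    xb = [p[1] for p in pairs]
    if len(set(xa)) < 2 or len(set(xb)) < 2:
        raise ValueError("LD test requires both loci polymorphic")
    rng = np.random.default_rng(seed)
    ca, ia = np.unique(np.array([str(g) for g in xa]), return_inverse=True)
    cb, ib = np.unique(np.array([str(g) for g in xb]), return_inverse=True)
    na, nb = len(ca), len(cb)
    obs = _g_statistic_codes(ia, ib, na, nb)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(ib)
        if _g_statistic_codes(ia, ib, na, nb) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def null_allele_check(
    genotypes: Sequence[Call],
    n_mc: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Simplified null-allele screen for one locus.

    Returns ``(brookfield_r, excess_hom_p, flagged)`` where
    ``r = (H_E - H_O) / (1 + H_E)`` is Brookfield's null-allele frequency
    estimator and ``excess_hom_p`` is a Monte-Carlo p-value for
    homozygote excess (total homozygote count against genotype arrays
    resampled under HWE from the observed allele pool).  A locus is
    flagged only when r > 0 and the excess is significant at ``alpha``.
    """
    genotypes = [tuple(sorted(g)) for g in genotypes if g is not None]
    n = len(genotypes)
    pool = np.array([a for g in genotypes for a in g])
    p = np.unique(pool, return_counts=True)[1] / (2 * n)
    h_e = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p**2)))
    h_o = sum(1 for g in genotypes if g[0] != g[1]) / n
    r = (h_e - h_o) / (1.0 + h_e)
    rng = np.random.default_rng(seed)
    obs_hom = sum(1 for g in genotypes if g[0] == g[1])
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        sim_hom = int(np.sum(pool[0::2] == pool[1::2]))
        if sim_hom >= obs_hom:
            hits += 1
    excess_p = (1 + hits) / (n_mc + 1)
    return r, excess_p, (r > 0 and excess_p < alpha)


def sequential_bonferroni(
    p_values: Sequence[float], alpha: float = 0.05
) -> np.ndarray:
    """Holm step-down multiple-testing correction.

    Returns a boolean rejection decision per input p-value (original
    order): sorted ascending, reject while ``p_(i) <= alpha / (m - i +
    1)``, stopping at the first failure.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject


# ---------------------------------------------------------------------------
# published reference diversity table (worked example)


def load_reference_locus_table() -> pd.DataFrame:
    """Published per-locus diversity values (H_E, H_O, PIC) for the two
    study populations (9 Russian and 15 Chinese tigers at 8 loci)."""
    with resources.files("tigerpop").joinpath("data/locus_diversity.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _round_printed(value: float, ndigits: int = 2) -> float:
    """Round half-up at the table's printed precision (plain float
    rounding is half-even and disagrees on e.g. 0.485)."""
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(str(round(value, 10)))
    return float(d.quantize(q, rounding=decimal.ROUND_HALF_UP))


def summarize_reference_table(df: pd.DataFrame) -> dict[str, float]:
    """Column means and H_O extremes of the published diversity table,
    rounded to the printed precision (2 decimals)."""
    out = {}
    for col in df.columns:
        if col == "locus":
            continue
        out[f"mean_{col}"] = _round_printed(float(df[col].mean()))
    out["max_H_O_Russia"] = float(df["H_O_Russia"].max())
    out["min_H_O_China"] = float(df["H_O_China"].min())
    return out
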