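"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: exact rational
arithmetic for the Hardy-Weinberg conditional distribution, exhaustive
label permutation for the rank-sum test, and a plain per-individual loop
for polygenic scoring.
"""

from fractions import Fraction
from itertools import combinations
from math import factorial

import numpy as np


def hwe_enumeration_p(n_hom_effect: int, n_het: int, n_hom_other: int) -> float:
    """Exact two-sided HWE p by enumerating heterozygote counts (rationals).

    Given allele counts, P(genotype config) = n! / (nAA! nAa! naa!) * 2^nAa
    * nA! * na! / (2n)! under random union of gametes; the p-value sums the
    probabilities of configurations no more probable than the observed one.
    """
    n = n_hom_effect + n_het + n_hom_other
    n_eff = 2 * n_hom_effect + n_het
    n_oth = 2 * n - n_eff
    if n_eff == 0 or n_oth == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        haa = (n_eff - h) // 2
        hoo = n - haa - h
        return (
            Fraction(factorial(n), factorial(haa) * factorial(h) * factorial(hoo))
            * Fraction(2) ** h
            * Fraction(factorial(n_eff) * factorial(n_oth), factorial(2 * n))
        )

    hs = range(n_eff % 2, min(n_eff, n_oth) + 1, 2)
    probs = {h: prob(h) for h in hs}
    obs = probs[n_het]
    return float(min(Fraction(1), sum(p for p in probs.values() if p <= obs)))


def mannwhitney_permutation_p(group1, group0) -> tuple[float, float]:
    """(U of group1, two-sided p) by exhaustive enumeration of group labels.

    Two-sided p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))) over all
    equally likely assignments of the pooled values to groups.
    """
    g1 = np.asarray(group1, dtype=float)
    g0 = np.asarray(group0, dtype=float)
    pooled = np.concatenate([g1, g0])
    n1 = len(g1)

    def u_stat(sample1, sample0):
        return sum((a > b) + 0.5 * (a == b) for a in sample1 for b in sample0)

    u_obs = u_stat(g1, g0)
    us = []
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        us.append(u_stat(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return float(u_obs), float(min(1.0, 2.0 * min(p_le, p_ge)))


def score_bruteforce(panel, weights, missing_policy: str) -> np.ndarray:
    """Per-individual, per-variant scoring loop mirroring the stated rules."""
    n = panel.n_individuals
    scores = np.zeros(n)
    for entry in weights.entries:
        if entry.variant_id not in panel.variant_ids:
            continue
        j = panel.index_of(entry.variant_id)
        v = panel.variants[j]
        col = panel.dosages[:, j]
        observed = [x for x in col if not np.isnan(x)]
        mean_raw = np.mean(observed) if observed else 0.0
        for i in range(n):
            x = col[i]
            if np.isnan(x):
                if missing_policy == "skip":
                    continue
                x = mean_raw
            if entry.scoring_allele == v.non_effect_allele:
                x = 2.0 - x
            scores[i] += entry.weight * x
    return scores
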