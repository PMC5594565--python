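"""Independent brute-force oracles: explicit pair/class enumeration.

Deliberately naive (nested loops, tuple dictionaries) so they share no code
path with the package implementations they check.
"""
import itertools

import numpy as np


def brute_homozygosity(alleles):
    """Sum p_k^2 over distinct values in a list of hashable alleles."""
    n = len(alleles)
    counts = {}
    for a in alleles:
        counts[a] = counts.get(a, 0) + 1
    return sum((c / n) ** 2 for c in counts.values())


def brute_pi(matrix):
    """Mean over all unordered pairs of the city-block row distance."""
    n = len(matrix)
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += sum(abs(int(x) - int(y)) for x, y in zip(matrix[i], matrix[j]))
    return total / (n * (n - 1) / 2)


def brute_diversity(matrix, site_loci=None, n_loci=None):
    """(F_locus list, F_hap, pi) by explicit enumeration.

    For an SMM matrix pass nothing extra; for an ISM matrix pass the locus
    of origin of each column and the locus count.
    """
    matrix = [list(map(int, row)) for row in np.asarray(matrix)]
    if site_loci is None:
        L = len(matrix[0])
        groups = [[i] for i in range(L)]
    else:
        L = n_loci
        groups = [[c for c, l in enumerate(site_loci) if l == i] for i in range(L)]
    F_locus = []
    for cols in groups:
        alleles = [tuple(row[c] for c in cols) for row in matrix]
        F_locus.append(brute_homozygosity(alleles))
    F_hap = brute_homozygosity([tuple(row) for row in matrix])
    return F_locus, F_hap, brute_pi(matrix)


def brute_triple(pair):
    """(P, MSH, DH) of a paired replicate by explicit enumeration."""
    Fi_i, F_i, pi_i = brute_diversity(
        pair.ism, site_loci=list(pair.site_locus), n_loci=pair.model.L
    )
    Fi_s, F_s, pi_s = brute_diversity(pair.smm)
    P = 1 - F_i / F_s
    MSH = 1 - sum(a / b for a, b in zip(Fi_i, Fi_s)) / pair.model.L
    DH = 0.0 if pi_i == 0 else (pi_i - pi_s) / pi_i
    return P, MSH, DH


def brute_summaries(matrix, ddof=0):
    """(V, H, a) by explicit enumeration."""
    matrix = [list(map(int, row)) for row in np.asarray(matrix)]
    n, L = len(matrix), len(matrix[0])
    V = 0.0
    H = 0.0
    for i in range(L):
        col = [row[i] for row in matrix]
        mean = sum(col) / n
        V += sum((x - mean) ** 2 for x in col) / (n - ddof)
        H += 1 - brute_homozygosity(col)
    a = len({tuple(row) for row in matrix})
    return V / L, H / L, a


def brute_mismatch_histogram(matrix):
    """Pairwise city-block distance histogram by explicit enumeration."""
    n = len(matrix)
    dists = []
    for i, j in itertools.combinations(range(n), 2):
        dists.append(
            sum(abs(int(x) - int(y)) for x, y in zip(matrix[i], matrix[j]))
        )
    out = [0] * (max(dists) + 1 if dists else 1)
    for d in dists:
        out[d] += 1
    return out
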