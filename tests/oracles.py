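"""Independent, naively-coded reference implementations used as oracles.

Everything here is deliberately written with plain Python loops and no
shared code with the package, so agreement between the two routes is
evidence of correctness rather than tautology.
"""

from __future__ import annotations

import math
from math import comb, erf, sqrt


def phi(x: float) -> float:
    """Standard normal CDF via erf."""
    return 0.5 * (1.0 + erf(x / sqrt(2.0)))


def naive_kernel_cdf(matrix):
    """Double-loop kernel CDF: z_ij = mean_k Phi((x_ij - x_ik)/ (s_i/4))."""
    p = len(matrix)
    n = len(matrix[0])
    z = [[0.5] * n for _ in range(p)]
    for i in range(p):
        row = matrix[i]
        mean = sum(row) / n
        var = sum((v - mean) ** 2 for v in row) / (n - 1)
        if var == 0:
            continue
        h = sqrt(var) / 4.0
        for j in range(n):
            z[i][j] = sum(phi((row[j] - row[k]) / h) for k in range(n)) / n
    return z


def naive_ranks(z_column):
    """Rank of each gene (1 = largest z), ties by input row order."""
    p = len(z_column)
    order = sorted(range(p), key=lambda i: (-z_column[i], i))
    ranks = [0] * p
    for pos, gene in enumerate(order):
        ranks[gene] = pos + 1
    return ranks


def naive_walk(ranks, members, tau):
    """Literal accumulation of the two walk sums; returns (es_pos, es_neg)."""
    p = len(ranks)
    member_set = set(members)
    m = len(member_set)
    order = sorted(range(p), key=lambda i: ranks[i])
    denom = sum((abs(p / 2.0 - ranks[i]) ** tau) for i in member_set)
    running_in = 0.0
    running_out = 0.0
    best_pos, best_neg = 0.0, 0.0
    for gene in order:
        if gene in member_set:
            if denom > 0:
                running_in += abs(p / 2.0 - ranks[gene]) ** tau / denom
            else:
                running_in += 1.0 / m
        else:
            running_out += 1.0 / (p - m)
        nu = running_in - running_out
        best_pos = max(best_pos, nu)
        best_neg = min(best_neg, nu)
    return best_pos, best_neg


def naive_gsva(matrix, modules, tau, convention):
    """Full single-sample scoring path, all loops.

    ``matrix`` is a list of gene rows; ``modules`` maps name -> list of row
    indices.  Returns {module: [score per sample]}.
    """
    z = naive_kernel_cdf(matrix)
    n = len(matrix[0])
    out = {}
    for name, members in modules.items():
        scores = []
        for j in range(n):
            col = [z[i][j] for i in range(len(matrix))]
            ranks = naive_ranks(col)
            es_pos, es_neg = naive_walk(ranks, members, tau)
            if convention == "signed_sum":
                scores.append(es_pos + es_neg)
            else:
                # magnitude ties resolve to the positive extremum
                scores.append(es_pos if es_pos >= -es_neg - 1e-12 else es_neg)
        out[name] = scores
    return out


def naive_bh(pvals):
    """Step-up minimisation written out directly: q_(i) = min_{k>=i} p_(k) m/k."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for pos_i, gene_i in enumerate(order):
        best = min(
            pvals[order[pos_k]] * m / (pos_k + 1)
            for pos_k in range(pos_i, m)
        )
        q[gene_i] = min(best, 1.0)
    return q


def naive_pooled_t(group1, group2):
    """Classical two-sample pooled-variance t statistic."""
    n1, n2 = len(group1), len(group2)
    m1 = sum(group1) / n1
    m2 = sum(group2) / n2
    ss = sum((v - m1) ** 2 for v in group1) + sum((v - m2) ** 2 for v in group2)
    s2 = ss / (n1 + n2 - 2)
    return (m2 - m1) / sqrt(s2 * (1 / n1 + 1 / n2))


def naive_chi2(table):
    """Sum (O - E)^2 / E over a 2x2 table given as ((a, b), (c, d))."""
    (a, b), (c, d) = table
    total = a + b + c + d
    stat = 0.0
    for i, row_sum in enumerate((a + b, c + d)):
        for j, col_sum in enumerate((a + c, b + d)):
            observed = table[i][j]
            expected = row_sum * col_sum / total
            stat += (observed - expected) ** 2 / expected
    return stat


def naive_hypergeom_upper(k, N, K, n):
    """P(X >= k) by explicit summation of hypergeometric point masses."""
    lo = max(k, 0)
    hi = min(n, K)
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(lo, hi + 1)) / total


def naive_concordance(mouse_pathways, human_z, z_cut, min_tissues):
    """Recount the >=k-of-m classification from scratch.

    ``mouse_pathways``: list of pathway names (mouse-significant decreased).
    ``human_z``: {tissue: {pathway: Z}}.
    Returns (n_concordant, fraction or None).
    """
    n_conc = 0
    for pw in mouse_pathways:
        count = 0
        for tissue in human_z:
            z = human_z[tissue].get(pw)
            if z is not None and not math.isnan(z) and z > z_cut:
                count += 1
        if count >= min_tissues:
            n_conc += 1
    if not mouse_pathways:
        return 0, None
    return n_conc, n_conc / len(mouse_pathways)
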