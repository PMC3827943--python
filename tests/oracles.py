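"""Independent brute-force oracles used to cross-check the vectorized code.

Everything here is written as literal nested loops over the defining
formulas, with compensated summation, and shares no code with the package
internals it checks.
"""

import math

import numpy as np


def oracle_stats(sub):
    """Means, residues, MSR and per-mode scores of a 3D block, by loops."""
    g, c, t = sub.shape
    gene_means = [math.fsum(sub[i, j, k] for j in range(c) for k in range(t))
                  / (c * t) for i in range(g)]
    sample_means = [math.fsum(sub[i, j, k] for i in range(g) for k in range(t))
                    / (g * t) for j in range(c)]
    time_means = [math.fsum(sub[i, j, k] for i in range(g) for j in range(c))
                  / (g * c) for k in range(t)]
    grand = math.fsum(sub[i, j, k] for i in range(g) for j in range(c)
                      for k in range(t)) / (g * c * t)
    residues = np.empty_like(sub)
    for i in range(g):
        for j in range(c):
            for k in range(t):
                residues[i, j, k] = (sub[i, j, k] - gene_means[i]
                                     - sample_means[j] - time_means[k]
                                     + 2 * grand)
    msr = math.fsum(residues[i, j, k] ** 2 for i in range(g)
                    for j in range(c) for k in range(t)) / (g * c * t)
    mu_gene = [math.fsum(residues[i, j, k] ** 2 for j in range(c)
                         for k in range(t)) / (c * t) for i in range(g)]
    mu_sample = [math.fsum(residues[i, j, k] ** 2 for i in range(g)
                           for k in range(t)) / (g * t) for j in range(c)]
    mu_time = [math.fsum(residues[i, j, k] ** 2 for i in range(g)
                         for j in range(c)) / (g * c) for k in range(t)]
    return {
        "gene_means": np.array(gene_means),
        "sample_means": np.array(sample_means),
        "time_means": np.array(time_means),
        "grand_mean": grand,
        "residues": residues,
        "msr": msr,
        "mu_gene": np.array(mu_gene),
        "mu_sample": np.array(mu_sample),
        "mu_time": np.array(mu_time),
    }


def power_iteration_top_vector(Z, iters=5000, tol=1e-14, seed=7):
    """Dominant eigenvector of Z^T Z by plain power iteration."""
    rng = np.random.default_rng(seed)
    A = Z.T @ Z
    v = rng.normal(size=A.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(iters):
        w = A @ v
        nw = np.linalg.norm(w)
        if nw == 0:
            return v
        w /= nw
        if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
            v = w
            break
        v = w
    return v


def hypergeom_upper_tail(overlap, universe, set_size, cluster_size):
    """P[X >= overlap] for X hypergeometric, by exact binomial arithmetic."""
    total = math.comb(universe, cluster_size)
    acc = 0
    hi = min(set_size, cluster_size)
    for x in range(overlap, hi + 1):
        acc += math.comb(set_size, x) * math.comb(universe - set_size,
                                                  cluster_size - x)
    return acc / total
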