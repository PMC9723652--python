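"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and scipy's
closed forms where they are the thing under test): the collapsed
posterior is enumerated state by state, the hypergeometric tail is a
direct pmf summation over binomial coefficients, and topic matching is
an exhaustive scan over all permutations.
"""
import itertools
from math import comb, lgamma

import numpy as np


def exact_collapsed_posterior(token_cell, token_gene, n_cells, n_genes, k_topics,
                              alpha, beta):
    """Enumerate P(z) for every assignment state of a tiny corpus.

    P(z) is proportional to
    prod_d prod_k Gamma(n_dk + alpha) / Gamma(alpha)
    * prod_k [ Gamma(G beta) / Gamma(n_k + G beta)
               * prod_w Gamma(n_kw + beta) / Gamma(beta) ].
    Returns a dict mapping assignment tuples to normalized probabilities.
    """
    n_tokens = len(token_cell)
    log_weights = {}
    for state in itertools.product(range(k_topics), repeat=n_tokens):
        n_dk = np.zeros((n_cells, k_topics))
        n_kw = np.zeros((k_topics, n_genes))
        n_k = np.zeros(k_topics)
        for t, topic in enumerate(state):
            n_dk[token_cell[t], topic] += 1
            n_kw[topic, token_gene[t]] += 1
            n_k[topic] += 1
        logw = 0.0
        for d in range(n_cells):
            for j in range(k_topics):
                logw += lgamma(n_dk[d, j] + alpha) - lgamma(alpha)
        for j in range(k_topics):
            logw += lgamma(n_genes * beta) - lgamma(n_k[j] + n_genes * beta)
            for w in range(n_genes):
                logw += lgamma(n_kw[j, w] + beta) - lgamma(beta)
        log_weights[state] = logw
    peak = max(log_weights.values())
    weights = {s: np.exp(w - peak) for s, w in log_weights.items()}
    total = sum(weights.values())
    return {s: w / total for s, w in weights.items()}


def hypergeom_upper_tail(overlap, set_a, set_b, universe):
    """P(X >= overlap) by direct pmf summation over binomial coefficients."""
    denominator = comb(universe, set_b)
    total = 0
    for x in range(overlap, min(set_a, set_b) + 1):
        total += comb(set_a, x) * comb(universe - set_a, set_b - x)
    return total / denominator


def best_permutation_cosine(phi_recovered, phi_true):
    """Exhaustive best one-to-one matching by total cosine similarity (K <= 6)."""
    a = phi_recovered / np.linalg.norm(phi_recovered, axis=1, keepdims=True)
    b = phi_true / np.linalg.norm(phi_true, axis=1, keepdims=True)
    similarity = a @ b.T
    k = similarity.shape[0]
    best_total, best_perm = -np.inf, None
    for perm in itertools.permutations(range(k)):
        total = sum(similarity[i, perm[i]] for i in range(k))
        if total > best_total:
            best_total, best_perm = total, perm
    return np.array(best_perm), best_total
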