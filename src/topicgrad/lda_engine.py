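"""Latent Dirichlet allocation by collapsed Gibbs sampling.

Each cell is a document and every unit of the integer input matrix is a
token carrying a gene identity. With symmetric Dirichlet priors
(concentration ``alpha`` on the per-cell topic mixture theta, ``beta``
on the per-topic gene distribution phi), theta and phi integrate out
analytically and the sampler updates only the per-token topic labels z.
The full conditional for token i (cell d, gene w) is

    P(z_i = k | z_-i) ∝ (n_dk + alpha) * (n_kw + beta) / (n_k + G*beta)

with all counts excluding token i. Point estimates are the posterior
means given the final (or averaged) count state:

    theta_dk = (n_dk + alpha) / (n_d + K*alpha)
    phi_kw   = (n_kw + beta)  / (n_k + G*beta)

The inner sweep is numba-compiled; all randomness is drawn from numba's
own generator, seeded once per fit, so identical seed + input gives
bit-identical results.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .exceptions import ValidationError
from .preprocess import LdaInput


@dataclass
class TopicModel:
    """A fitted topic model.

    ``theta`` is cells x K row-stochastic, ``phi`` K x genes
    row-stochastic. ``counts_ck``/``counts_kg`` hold the sampler's final
    token-count state (None for models re-read from disk).
    ``alpha_mode`` records whether ``alpha`` was used as-is ("fixed") or
    divided by K ("scaled"), the alternative convention.
    """

    k: int
    alpha: float
    beta: float
    theta: np.ndarray
    phi: np.ndarray
    vocabulary: np.ndarray
    cell_barcodes: np.ndarray
    seed: int
    iterations: int
    burn_in: int
    alpha_mode: str = "fixed"
    counts_ck: np.ndarray | None = None
    counts_kg: np.ndarray | None = None
    assignments: np.ndarray | None = None
    assignment_trace: np.ndarray | None = None

    @property
    def effective_alpha(self) -> float:
        return self.alpha / self.k if self.alpha_mode == "scaled" else self.alpha


@njit(cache=True)
def _seed_rng(seed):  # pragma: no cover - trivial jitted shim
    np.random.seed(seed)


@njit(cache=True)
def _init_assignments(n_tokens, k):
    z = np.empty(n_tokens, dtype=np.int32)
    for t in range(n_tokens):
        z[t] = np.random.randint(0, k)
    return z


@njit(cache=True)
def _sweep(token_cell, token_gene, z, n_dk, n_kw, n_k, alpha, beta, cum):
    k_topics = n_kw.shape[0]
    g_beta = beta * n_kw.shape[1]
    for t in range(z.size):
        d = token_cell[t]
        w = token_gene[t]
        old = z[t]
        n_dk[d, old] -= 1
        n_kw[old, w] -= 1
        n_k[old] -= 1
        total = 0.0
        for j in range(k_topics):
            total += (n_dk[d, j] + alpha) * (n_kw[j, w] + beta) / (n_k[j] + g_beta)
            cum[j] = total
        u = np.random.random() * total
        new = 0
        while cum[new] < u:
            new += 1
        z[t] = new
        n_dk[d, new] += 1
        n_kw[new, w] += 1
        n_k[new] += 1


def _tokenize(matrix: np.ndarray):
    """Expand the genes x cells integer matrix into per-token cell/gene ids,
    visiting cells, then genes, then multiplicity (fixed order for
    reproducibility)."""
    cmat = matrix.T  # cells x genes, row-major scan = cell then gene
    rows, cols = np.nonzero(cmat)
    mult = cmat[rows, cols]
    token_cell = np.repeat(rows, mult).astype(np.int32)
    token_gene = np.repeat(cols, mult).astype(np.int32)
    return token_cell, token_gene


def fit_lda(
    lda_input: LdaInput,
    k: int,
    alpha: float = 50.0,
    beta: float = 0.1,
    iterations: int = 500,
    burn_in: int = 250,
    seed: int = 0,
    alpha_mode: str = "fixed",
    average_every: int = 0,
    collect_states: bool = False,
) -> TopicModel:
    """Fit a K-topic model to an :class:`LdaInput` by collapsed Gibbs sampling.

    Parameters
    ----------
    alpha, beta
        Symmetric Dirichlet concentrations (defaults 50 and 0.1).
    alpha_mode
        "fixed" uses ``alpha`` as given; "scaled" uses ``alpha / k``, the
        alternative convention common in the topic-modeling literature.
    iterations, burn_in
        Total Gibbs sweeps and how many to discard before estimation.
    average_every
        0 estimates theta/phi from the final sweep's counts; a positive
        value m additionally averages the counts of every m-th
        post-burn-in sweep, lowering estimator variance.
    collect_states
        Record the full assignment vector after every post-burn-in sweep
        (for posterior diagnostics on tiny corpora).
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValidationError("k must be an integer >= 1")
    if iterations <= burn_in or burn_in < 0:
        raise ValidationError("need iterations > burn_in >= 0")
    if alpha <= 0 or beta <= 0:
        raise ValidationError("alpha and beta must be positive")
    if alpha_mode not in ("fixed", "scaled"):
        raise ValidationError("alpha_mode must be 'fixed' or 'scaled'")
    if lda_input.total_tokens == 0:
        raise ValidationError("input has zero total tokens")

    k = int(k)
    eff_alpha = alpha / k if alpha_mode == "scaled" else alpha
    n_cells = lda_input.n_cells
    n_genes = lda_input.n_genes
    token_cell, token_gene = _tokenize(lda_input.matrix)
    n_tokens = token_cell.size

    _seed_rng(int(seed) % (2**32))
    z = _init_assignments(n_tokens, k)

    n_dk = np.zeros((n_cells, k), dtype=np.int32)
    n_kw = np.zeros((k, n_genes), dtype=np.int32)
    np.add.at(n_dk, (token_cell, z), 1)
    np.add.at(n_kw, (z, token_gene), 1)
    n_k = n_kw.sum(axis=1).astype(np.int64)
    cum = np.empty(k, dtype=np.float64)

    acc_dk = np.zeros((n_cells, k), dtype=np.float64)
    acc_kw = np.zeros((k, n_genes), dtype=np.float64)
    n_avg = 0
    trace = [] if collect_states else None

    for sweep in range(iterations):
        _sweep(token_cell, token_gene, z, n_dk, n_kw, n_k, eff_alpha, beta, cum)
        if sweep >= burn_in:
            if collect_states:
                trace.append(z.copy())
            if average_every and (sweep - burn_in) % average_every == 0:
                acc_dk += n_dk
                acc_kw += n_kw
                n_avg += 1

    if average_every and n_avg > 0:
        est_dk = acc_dk / n_avg
        est_kw = acc_kw / n_avg
    else:
        est_dk = n_dk.astype(np.float64)
        est_kw = n_kw.astype(np.float64)

    n_d = est_dk.sum(axis=1, keepdims=True)
    theta = (est_dk + eff_alpha) / (n_d + k * eff_alpha)
    n_k_est = est_kw.sum(axis=1, keepdims=True)
    phi = (est_kw + beta) / (n_k_est + n_genes * beta)

    return TopicModel(
        k=k,
        alpha=float(alpha),
        beta=float(beta),
        alpha_mode=alpha_mode,
        theta=theta,
        phi=phi,
        vocabulary=lda_input.gene_names.copy(),
        cell_barcodes=lda_input.cell_barcodes.copy(),
        seed=int(seed),
        iterations=int(iterations),
        burn_in=int(burn_in),
        counts_ck=n_dk,
        counts_kg=n_kw,
        assignments=z,
        assignment_trace=np.array(trace, dtype=np.int32) if trace else None,
    )


def log_likelihood(model: TopicModel, lda_input: LdaInput) -> float:
    """Token log-likelihood sum_d sum_tokens ln sum_k theta_dk phi_kw.

    Cells with zero tokens contribute nothing; the result is <= 0.
    """
    if model.phi.shape[1] != lda_input.n_genes or not np.array_equal(
        np.asarray(model.vocabulary, dtype=object), lda_input.gene_names
    ):
        raise ValidationError("model vocabulary does not match input vocabulary")
    if model.theta.shape[0] != lda_input.n_cells:
        raise ValidationError("model cell dimension does not match input")
    mixture = model.theta @ model.phi  # cells x genes
    cmat = lda_input.matrix.T
    mask = cmat > 0
    return float(np.sum(cmat[mask] * np.log(mixture[mask])))
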