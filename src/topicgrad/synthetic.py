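"""Dirichlet-multinomial corpora with planted topics and response gradients.

The generator mirrors the topic model's own generative story: per-topic
gene distributions phi_k ~ Dirichlet_G(beta_gen), per-cell topic
mixtures theta_d ~ Dirichlet_K(alpha_gen), and per cell ``depth`` tokens
drawn topic-then-gene. Pure Dirichlet draws do not guarantee that
topics are identifiable, so each phi row is blended with a disjoint
anchor block: ``anchor_strength`` of its mass is concentrated on a
dedicated block of G // K genes, making top-gene recovery a testable
property. The gradient variant emulates a hormone-response time course:
ordered groups of cells whose mixture weight on designated effect
topics ramps up across groups.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .exceptions import ValidationError
from .matrix_io import CountMatrix


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated corpus."""

    theta_true: np.ndarray
    phi_true: np.ndarray
    anchor_genes: list
    group_labels: np.ndarray | None
    seed: int
    depth: int


def _make_phi(rng, n_genes, n_topics, beta_gen, anchor_strength):
    """Dirichlet phi rows blended with disjoint anchor blocks.

    Each row is a Dirichlet_G(beta_gen) draw blended with
    ``anchor_strength`` of mass Dirichlet-spread (concentration 10, so
    anchors rank stably instead of tying) over the topic's block of
    G // K genes. The row's values are then rearranged so that the
    block carries its largest probabilities: a heavy tail of the base
    Dirichlet could otherwise outrank a weak anchor, and the recorded
    anchors must be each row's top genes by construction.
    """
    phi = rng.dirichlet(np.full(n_genes, beta_gen), size=n_topics)
    block = n_genes // n_topics
    anchors = []
    if anchor_strength > 0 and block >= 1:
        for k in range(n_topics):
            rows = np.arange(k * block, (k + 1) * block)
            profile = np.zeros(n_genes)
            profile[rows] = rng.dirichlet(np.full(block, 10.0))
            blended = (1 - anchor_strength) * phi[k] + anchor_strength * profile
            ranked = np.sort(blended)[::-1]
            out = np.empty(n_genes)
            out[rows] = rng.permutation(ranked[:block])
            mask = np.ones(n_genes, dtype=bool)
            mask[rows] = False
            out[mask] = rng.permutation(ranked[block:])
            phi[k] = out
            anchors.append(rows)
    else:
        anchors = [np.empty(0, dtype=int) for _ in range(n_topics)]
    return phi, anchors


def _draw_counts(rng, theta, phi, depths):
    """Token-equivalent sampling: per cell, multinomial over topics then genes."""
    n_cells = theta.shape[0]
    n_genes = phi.shape[1]
    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    for d in range(n_cells):
        per_topic = rng.multinomial(depths[d], theta[d])
        for k, m in enumerate(per_topic):
            if m > 0:
                counts[:, d] += rng.multinomial(m, phi[k])
    return counts


def _names(prefix, n):
    width = max(4, len(str(n)))
    return np.array([f"{prefix}{i:0{width}d}" for i in range(1, n + 1)], dtype=object)


def generate_lda_corpus(
    n_cells: int = 500,
    n_genes: int = 200,
    n_topics: int = 5,
    alpha_gen: float = 0.5,
    beta_gen: float = 0.1,
    depth: int = 500,
    anchor_strength: float = 0.5,
    seed: int = 0,
    depth_model: str = "fixed",
    depth_dispersion: float = 10.0,
    phi: np.ndarray | None = None,
):
    """Draw a planted-topic corpus; returns (CountMatrix, SyntheticTruth).

    ``phi`` may be supplied to reuse the planted topics of an earlier
    corpus (e.g. to build a transfer target drawn from the same
    topics); anchors are then re-derived as each row's top G//K genes.
    ``depth_model`` is "fixed" (every cell gets exactly ``depth``
    tokens) or "nb" (negative-binomial depths with mean ``depth`` and
    shape ``depth_dispersion``, floored at 1).
    """
    if min(n_cells, n_genes, n_topics) < 1:
        raise ValidationError("all sizes must be >= 1")
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    if not 0 <= anchor_strength < 1:
        raise ValidationError("anchor_strength must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if phi is None:
        phi, anchors = _make_phi(rng, n_genes, n_topics, beta_gen, anchor_strength)
    else:
        phi = np.asarray(phi, dtype=np.float64)
        if phi.shape != (n_topics, n_genes):
            raise ValidationError("supplied phi has the wrong shape")
        block = n_genes // n_topics
        anchors = [np.argsort(-phi[k])[:block] for k in range(n_topics)]
    theta = rng.dirichlet(np.full(n_topics, alpha_gen), size=n_cells)
    if depth_model == "fixed":
        depths = np.full(n_cells, int(depth))
    elif depth_model == "nb":
        p = depth_dispersion / (depth_dispersion + depth)
        depths = np.maximum(rng.negative_binomial(depth_dispersion, p, n_cells), 1)
    else:
        raise ValidationError("depth_model must be 'fixed' or 'nb'")
    counts = _draw_counts(rng, theta, phi, depths)
    gene_names = _names("G", n_genes)
    matrix = CountMatrix(counts, gene_names, _names("C", n_cells))
    truth = SyntheticTruth(
        theta_true=theta,
        phi_true=phi,
        anchor_genes=[list(gene_names[a]) for a in anchors],
        group_labels=None,
        seed=int(seed),
        depth=int(depth),
    )
    return matrix, truth


def generate_response_gradient(
    n_per_group: int = 100,
    groups=("0h", "3h", "24h", "48h"),
    effect_topics=(0,),
    effect_ramp=(0.0, 0.1, 0.25, 0.4),
    n_genes: int = 150,
    n_topics: int = 5,
    alpha_gen: float = 0.5,
    beta_gen: float = 0.1,
    depth: int = 300,
    anchor_strength: float = 0.5,
    seed: int = 0,
):
    """Labeled corpus whose effect-topic weight ramps across ordered groups.

    For a cell in group g with base mixture u ~ Dirichlet_K(alpha_gen)
    and ramp value r_g, theta = (1 - r_g * E) * u plus r_g added to each
    of the E effect topics, so the expected effect-topic weight
    increases by (r_g - r_g') * (1 - E/K) between groups g and g' while
    the other topics renormalize. A ramp of all zeros makes the groups
    exchangeable. Default group labels mimic a treatment time course.
    """
    groups = list(groups)
    effect_topics = [int(t) for t in effect_topics]
    effect_ramp = [float(r) for r in effect_ramp]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if len(effect_ramp) != len(groups):
        raise ValidationError("effect_ramp must have one value per group")
    n_effect = len(effect_topics)
    if any(not 0 <= t < n_topics for t in effect_topics):
        raise ValidationError("effect topic index out of range")
    if any(r < 0 or r * n_effect >= 1 for r in effect_ramp):
        raise ValidationError("ramp values must satisfy 0 <= r and r * E < 1")
    rng = np.random.default_rng(seed)
    phi, anchors = _make_phi(rng, n_genes, n_topics, beta_gen, anchor_strength)
    n_cells = n_per_group * len(groups)
    theta = np.empty((n_cells, n_topics))
    labels = np.empty(n_cells, dtype=object)
    row = 0
    for g, label in enumerate(groups):
        r = effect_ramp[g]
        base = rng.dirichlet(np.full(n_topics, alpha_gen), size=n_per_group)
        block = (1 - r * n_effect) * base
        block[:, effect_topics] += r
        theta[row:row + n_per_group] = block
        labels[row:row + n_per_group] = label
        row += n_per_group
    counts = _draw_counts(rng, theta, phi, np.full(n_cells, int(depth)))
    gene_names = _names("G", n_genes)
    matrix = CountMatrix(counts, gene_names, _names("C", n_cells), labels)
    truth = SyntheticTruth(
        theta_true=theta,
        phi_true=phi,
        anchor_genes=[list(gene_names[a]) for a in anchors],
        group_labels=labels,
        seed=int(seed),
        depth=int(depth),
    )
    return matrix, truth


def match_topics(phi_recovered: np.ndarray, phi_true: np.ndarray):
    """Optimal one-to-one topic matching by total cosine similarity.

    Returns ``(permutation, similarities)`` where ``permutation[i]`` is
    the true-topic index assigned to recovered topic i and
    ``similarities[i]`` their cosine similarity.
    """
    phi_recovered = np.asarray(phi_recovered, dtype=np.float64)
    phi_true = np.asarray(phi_true, dtype=np.float64)
    if phi_recovered.shape != phi_true.shape or phi_recovered.ndim != 2:
        raise ValidationError("phi matrices must have identical 2-D shapes")
    a = phi_recovered / np.linalg.norm(phi_recovered, axis=1, keepdims=True)
    b = phi_true / np.linalg.norm(phi_true, axis=1, keepdims=True)
    similarity = a @ b.T
    rows, cols = linear_sum_assignment(similarity, maximize=True)
    permutation = np.empty(phi_true.shape[0], dtype=int)
    permutation[rows] = cols
    return permutation, similarity[rows, cols][np.argsort(rows)]
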