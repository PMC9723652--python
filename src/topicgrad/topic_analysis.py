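"""Topic signatures, cell scores, transfer, overlap, and the delta-Z statistic.

A fitted model's topics are summarized by their top genes (default 50,
ranked by phi). Signatures support three downstream uses:

* per-cell topic scores (raw theta or per-topic Z-normalized theta);
* transfer onto an independent dataset via binned-control module scores
  (mean normalized expression of signature genes minus that of
  expression-matched control genes);
* cross-model comparison via top-gene overlap counts.

Treatment response over a labeled time course is quantified by the
delta-control Z-score: topic scores are Z-scored across all cells and
the median Z of the control group is subtracted, so control cells sit
at median zero and treated groups shift by their response.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .lda_engine import TopicModel
from .matrix_io import CountMatrix


@dataclass
class GeneSignature:
    """Ordered top genes of one topic (descending phi, ties lexicographic)."""

    topic_id: int
    genes: list
    source_model_id: str = ""


@dataclass
class CellScoreTable:
    """Cells x topics score table.

    ``score_kind`` is one of "theta" (raw mixture weights), "z_theta"
    (per-topic Z-normalized theta), or "signature" (transferred module
    scores).
    """

    scores: pd.DataFrame
    score_kind: str
    group_labels: np.ndarray | None = None


def _rank_genes(phi_row: np.ndarray, vocabulary: np.ndarray) -> np.ndarray:
    names = np.array([str(g) for g in vocabulary])
    order = np.lexsort((names, -phi_row))
    return np.asarray(vocabulary, dtype=object)[order]


def top_genes(model: TopicModel, topic: int, n: int = 50) -> GeneSignature:
    """Top-``n`` genes of 1-based ``topic``, ordered by descending phi."""
    if not 1 <= topic <= model.k:
        raise ValidationError(f"topic {topic} out of range 1..{model.k}")
    if n < 1:
        raise ValidationError("n must be >= 1")
    ranked = _rank_genes(model.phi[topic - 1], model.vocabulary)
    return GeneSignature(topic_id=int(topic), genes=list(ranked[:n]))


def normalize_cell_scores(model: TopicModel) -> CellScoreTable:
    """Per-topic Z-score of theta across cells (sample standard deviation,
    the convention of R's ``scale``).

    Constant topics yield all-zero columns with a warning rather than NaN.
    """
    theta = model.theta
    if theta.shape[0] <= 1:
        raise ValidationError("z-normalization needs more than one cell")
    mean = theta.mean(axis=0)
    std = theta.std(axis=0, ddof=1)
    z = np.zeros_like(theta)
    nonconstant = std > 0
    z[:, nonconstant] = (theta[:, nonconstant] - mean[nonconstant]) / std[nonconstant]
    if not nonconstant.all():
        warnings.warn(
            f"{(~nonconstant).sum()} topic(s) have constant theta; "
            "their z-scores are set to zero",
            UserWarning,
            stacklevel=2,
        )
    frame = pd.DataFrame(
        z,
        index=model.cell_barcodes,
        columns=[f"Topic_{k}" for k in range(1, model.k + 1)],
    )
    return CellScoreTable(scores=frame, score_kind="z_theta")


def _normalized_expression(counts: CountMatrix) -> np.ndarray:
    """log1p counts after scaling each cell's library size to the median depth."""
    depth = counts.counts.sum(axis=0).astype(np.float64)
    target = np.median(depth[depth > 0]) if np.any(depth > 0) else 1.0
    safe_depth = np.where(depth > 0, depth, 1.0)
    scaled = counts.counts / safe_depth[None, :] * target
    return np.log1p(scaled)


def signature_score(
    counts: CountMatrix,
    signature,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control module score of a gene signature, one value per cell.

    Genes are binned (``n_bins`` equal-frequency bins) by their average
    normalized expression; for every signature gene, ``n_ctrl`` control
    genes are sampled with replacement from its bin. The score is the
    mean normalized expression of the signature genes minus the mean
    over the sampled control pool, so a flat expression matrix scores 0.
    Absent signature genes are dropped with a warning.
    """
    signature = [str(g).strip() for g in signature]
    index = {str(g): i for i, g in enumerate(counts.gene_names)}
    present = [g for g in signature if g in index]
    missing = [g for g in signature if g not in index]
    if not present:
        raise ValidationError("no signature gene present in the count matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) absent from the matrix "
            f"(first: {missing[0]})",
            UserWarning,
            stacklevel=2,
        )
    expr = _normalized_expression(counts)
    gene_mean = expr.mean(axis=1)
    try:
        bins = pd.qcut(gene_mean, q=min(n_bins, len(gene_mean)),
                       labels=False, duplicates="drop")
    except ValueError:
        bins = np.zeros(len(gene_mean))
    bins = np.asarray(bins, dtype=float)
    bins[np.isnan(bins)] = 0.0  # degenerate (near-constant) averages: one bin
    bins = bins.astype(int)
    rng = np.random.default_rng(seed)
    members: dict[int, np.ndarray] = {
        b: np.nonzero(bins == b)[0] for b in np.unique(bins)
    }
    sig_rows = np.array([index[g] for g in present])
    ctrl_rows = []
    for row in sig_rows:
        pool = members[bins[row]]
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_rows = np.concatenate(ctrl_rows)
    return expr[sig_rows].mean(axis=0) - expr[ctrl_rows].mean(axis=0)


def transfer_topics(
    source: TopicModel,
    target: CountMatrix,
    n: int = 50,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> CellScoreTable:
    """Score a source model's topic signatures on an independent dataset.

    Each topic's top-``n`` genes are module-scored on the target counts;
    topics sharing no genes with the target are dropped with a warning.
    """
    target_genes = {str(g) for g in target.gene_names}
    columns = {}
    for topic in range(1, source.k + 1):
        signature = top_genes(source, topic, n=min(n, len(source.vocabulary)))
        overlap = [g for g in signature.genes if str(g) in target_genes]
        if not overlap:
            warnings.warn(
                f"topic {topic} shares no genes with the target; column dropped",
                UserWarning,
                stacklevel=2,
            )
            continue
        child_seed = (int(seed) * 131 + topic) % (2**31)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            columns[f"Topic_{topic}"] = signature_score(
                target, signature.genes, n_bins=n_bins, n_ctrl=n_ctrl,
                seed=child_seed,
            )
    frame = pd.DataFrame(columns, index=target.cell_barcodes)
    return CellScoreTable(
        scores=frame, score_kind="signature", group_labels=target.cell_groups,
    )


def topic_overlap(model_a: TopicModel, model_b: TopicModel, n: int = 50) -> np.ndarray:
    """K_a x K_b matrix of top-``n`` gene overlap counts between two models."""
    n_a = min(n, len(model_a.vocabulary))
    n_b = min(n, len(model_b.vocabulary))
    sets_a = [set(top_genes(model_a, t, n=n_a).genes) for t in range(1, model_a.k + 1)]
    sets_b = [set(top_genes(model_b, t, n=n_b).genes) for t in range(1, model_b.k + 1)]
    out = np.zeros((model_a.k, model_b.k), dtype=np.int64)
    for i, sa in enumerate(sets_a):
        for j, sb in enumerate(sets_b):
            out[i, j] = len(sa & sb)
    return out


def delta_control_zscore(scores, groups, control_label) -> np.ndarray:
    """Z-score ``scores`` across all cells, minus the control group's median Z.

    Invariant to affine transformation of the input scores; the control
    group's deltas have median exactly zero by construction.
    """
    scores = np.asarray(scores, dtype=np.float64)
    groups = np.asarray(groups, dtype=object)
    if scores.ndim != 1 or scores.shape != groups.shape:
        raise ValidationError("scores and groups must be 1-D and equal length")
    control_mask = groups == control_label
    if not control_mask.any():
        raise ValidationError(f"control label {control_label!r} not present")
    std = scores.std(ddof=1) if scores.size > 1 else 0.0
    if std == 0:
        raise ValidationError("scores have zero variance")
    z = (scores - scores.mean()) / std
    return z - np.median(z[control_mask])
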