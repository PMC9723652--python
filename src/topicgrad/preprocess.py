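"""Variable-gene selection and the CLR-to-pseudo-count transform.

The topic model treats each cell as a bag-of-words document, but raw
UMI counts would let a handful of highly expressed genes dominate every
topic. The pipeline therefore (i) restricts to the most variable genes,
(ii) applies a centered log-ratio (CLR) transform per cell — making the
values ratio-based and invariant to sequencing depth — and (iii) scales
and rounds the result back to non-negative integer pseudo-counts that a
collapsed Gibbs sampler can treat as word frequencies.

CLR(x)_i = ln((x_i + c) / g(x + c)), with g the geometric mean over all
G components and c a pseudo count (default 1) guarding zeros. Values
below the geometric mean are negative and are clamped to zero before
scaling: LDA word frequencies cannot be negative, and genes expressed
below a cell's average carry no positive evidence for any topic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import ValidationError
from .matrix_io import CountMatrix


@dataclass
class LdaInput:
    """Genes x cells non-negative integer matrix fed to the sampler.

    ``flagged_cells`` lists barcodes whose entire row became zero after
    CLR/clamp/round (e.g. perfectly flat cells); they are retained but
    skipped by the sampler.
    """

    matrix: np.ndarray
    gene_names: np.ndarray
    cell_barcodes: np.ndarray
    scale_factor: float = 10.0
    pseudo_count: float = 1.0
    flagged_cells: list = field(default_factory=list)

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix)
        if matrix.ndim != 2:
            raise ValidationError("LdaInput matrix must be 2-D")
        if not np.issubdtype(matrix.dtype, np.integer):
            if np.any(matrix != np.floor(matrix)):
                raise ValidationError("LdaInput matrix must be integer")
            matrix = matrix.astype(np.int64)
        if np.any(matrix < 0):
            raise ValidationError("LdaInput matrix must be non-negative")
        self.matrix = matrix.astype(np.int64, copy=False)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if len(self.gene_names) != matrix.shape[0]:
            raise ValidationError("gene_names length mismatch")
        if len(self.cell_barcodes) != matrix.shape[1]:
            raise ValidationError("cell_barcodes length mismatch")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    @property
    def total_tokens(self) -> int:
        return int(self.matrix.sum())


def select_variable_genes(counts: CountMatrix, n_features: int = 5000) -> list:
    """Rank genes by variance-stabilized dispersion and return the top names.

    Implements a vst-style selector: per-gene counts are standardized
    against a smooth mean-variance trend (lowess of log10 variance on
    log10 mean), clipped at sqrt(N), and genes are ranked by the variance
    of the clipped standardized values. Ties break lexicographically, so
    the result is deterministic. Returns min(n_features, n_genes) names.
    """
    if n_features <= 0:
        raise ValidationError("n_features must be positive")
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValidationError("count matrix is empty")
    x = counts.counts.astype(np.float64)
    n = counts.n_cells
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1) if n > 1 else np.zeros_like(mean)

    expected_var = np.zeros_like(var)
    fit_mask = (var > 0) & (mean > 0)
    if fit_mask.sum() >= 2:
        log_mean = np.log10(mean[fit_mask])
        log_var = np.log10(var[fit_mask])
        if np.ptp(log_mean) < 0.1:
            # degenerate mean spread (< a tenth of a decade): a local
            # regression would chase individual variances; use a flat trend
            fitted = np.full(fit_mask.sum(), np.median(log_var))
        else:
            fitted = lowess(log_var, log_mean, frac=0.3, return_sorted=False)
        expected_var[fit_mask] = 10.0 ** fitted
    elif fit_mask.any():
        expected_var[fit_mask] = var[fit_mask]

    score = np.zeros(counts.n_genes)
    clip = np.sqrt(n)
    nonzero = expected_var > 0
    if nonzero.any():
        sd = np.sqrt(expected_var[nonzero])
        z = (x[nonzero] - mean[nonzero, None]) / sd[:, None]
        np.clip(z, -clip, clip, out=z)
        score[nonzero] = z.var(axis=1, ddof=1) if n > 1 else 0.0

    order = sorted(range(counts.n_genes),
                   key=lambda i: (-score[i], str(counts.gene_names[i])))
    k = min(n_features, counts.n_genes)
    return [counts.gene_names[i] for i in order[:k]]


def clr_transform(x, pseudo_count: float = 1.0) -> np.ndarray:
    """Centered log-ratio of a non-negative vector after adding a pseudo count.

    Returns ln((x_i + c) / g(x + c)) per component, g the geometric mean of
    the shifted vector over all components; the output sums to zero.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 1:
        raise ValidationError("clr_transform expects a 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValidationError("clr_transform input must be finite")
    if np.any(x < 0):
        raise ValidationError("clr_transform input must be non-negative")
    shifted = x + pseudo_count
    if np.any(shifted <= 0):
        raise ValidationError("pseudo_count must make all components positive")
    logs = np.log(shifted)
    return logs - logs.mean()


def prepare_lda_input(
    counts: CountMatrix,
    genes,
    scale_factor: float = 10.0,
    pseudo_count: float = 1.0,
) -> LdaInput:
    """CLR-transform, clamp, scale and round counts into sampler input.

    Per cell: subset to ``genes``, CLR with ``pseudo_count``, clamp
    negatives to zero, multiply by ``scale_factor`` and round half away
    from zero. Cells whose whole row becomes zero are flagged (with a
    warning) but retained.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("gene list is empty")
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    if pseudo_count <= 0:
        raise ValidationError("pseudo_count must be positive")
    subset = counts.subset_genes(genes)
    shifted = subset.counts.astype(np.float64) + pseudo_count
    logs = np.log(shifted)
    clr = logs - logs.mean(axis=0, keepdims=True)  # per-cell centering
    clr[clr < 0] = 0.0
    # round half away from zero (values are non-negative after the clamp)
    matrix = np.floor(clr * scale_factor + 0.5).astype(np.int64)
    flagged = [
        str(subset.cell_barcodes[j])
        for j in np.nonzero(matrix.sum(axis=0) == 0)[0]
    ]
    if flagged:
        warnings.warn(
            f"{len(flagged)} cell(s) have all-zero rows after the CLR "
            f"transform and are flagged (first: {flagged[0]})",
            UserWarning,
            stacklevel=2,
        )
    return LdaInput(
        matrix=matrix,
        gene_names=subset.gene_names,
        cell_barcodes=subset.cell_barcodes,
        scale_factor=float(scale_factor),
        pseudo_count=float(pseudo_count),
        flagged_cells=flagged,
    )
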