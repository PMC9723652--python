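"""Perplexity, rate-of-perplexity-change (RPC), and elbow selection of K.

The number of topics is chosen heuristically: one model is fitted per
candidate K, each is scored by perplexity on the input it was trained on
(exp of the negative per-token mean log-likelihood; lower is better),
and the absolute perplexity change per unit K (RPC) is plotted against
K. The selected K is the onset of the RPC plateau — the first point at
which RPC stops decreasing — with a fallback to the K after the largest
relative RPC drop when RPC decreases throughout the sweep.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .lda_engine import TopicModel, fit_lda, log_likelihood
from .preprocess import LdaInput


@dataclass
class ModelSweep:
    """Result of a topic-number sweep."""

    k_values: list
    perplexities: list
    rpc_values: list
    selected_k: int
    seed: int
    models: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        """Elbow-plot-ready table: K, perplexity, RPC (NaN for the first K)."""
        rpc_column = [np.nan] + list(self.rpc_values)
        return pd.DataFrame(
            {"k": self.k_values, "perplexity": self.perplexities, "rpc": rpc_column}
        )


def perplexity(model: TopicModel, lda_input: LdaInput) -> float:
    """exp(-L/T) with L the token log-likelihood and T the token total.

    Equals the vocabulary size for a uniform-phi model and approaches 1
    for a model that predicts every token with certainty.
    """
    total = lda_input.total_tokens
    if total == 0:
        raise ValidationError("perplexity undefined for zero total tokens")
    return float(np.exp(-log_likelihood(model, lda_input) / total))


def rpc(k_values, perplexities) -> np.ndarray:
    """Absolute perplexity change per unit K for each adjacent K pair."""
    k_values = np.asarray(k_values, dtype=float)
    perplexities = np.asarray(perplexities, dtype=float)
    if k_values.shape != perplexities.shape or k_values.size < 2:
        raise ValidationError("need equal-length k and perplexity arrays, >= 2")
    if np.any(np.diff(k_values) <= 0):
        raise ValidationError("k_values must be strictly increasing")
    return np.abs(np.diff(perplexities)) / np.diff(k_values)


def select_elbow(k_values, rpc_values) -> int:
    """Pick the K where the RPC curve collapses onto its low plateau.

    With rpc_j the RPC of the K pair (k_j, k_{j+1}), the relative drop
    between adjacent pairs is (rpc_j - rpc_{j+1}) / rpc_j; the selected
    K is the pairs' shared endpoint k_{j+1} at the largest relative drop
    (the last such j when several drops tie, i.e. the end of a uniform
    decay). A never-decreasing RPC curve is degenerate: the first K
    pair's right endpoint is returned with a warning. Deterministic.

    A literal "first adjacent pair where RPC stops decreasing" onset
    rule is not used: RPC typically rises before a genuine elbow (the
    perplexity drop accelerates as K approaches the data's topic count)
    and bounces at float precision on the plateau, so an exact
    comparison fires both too early and too late on sampled
    perplexities. The largest-relative-drop form of the plateau
    criterion is insensitive to both.
    """
    k_values = list(k_values)
    rpc_values = np.asarray(rpc_values, dtype=float)
    if len(k_values) < 3:
        raise ValidationError("elbow selection needs at least 3 k values")
    if rpc_values.size != len(k_values) - 1:
        raise ValidationError("rpc length must be len(k_values) - 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        drops = np.where(
            rpc_values[:-1] > 0,
            (rpc_values[:-1] - rpc_values[1:]) / rpc_values[:-1],
            0.0,
        )
    best = drops.max()
    if best <= 0:
        warnings.warn(
            "RPC never decreases; no plateau exists, returning the first "
            "K pair's right endpoint",
            UserWarning,
            stacklevel=2,
        )
        return int(k_values[1])
    j = int(np.nonzero(drops == best)[0][-1])
    return int(k_values[j + 1])


def sweep_topics(
    lda_input: LdaInput,
    k_values,
    alpha: float = 50.0,
    beta: float = 0.1,
    iterations: int = 200,
    burn_in: int = 100,
    seed: int = 0,
    alpha_mode: str = "fixed",
    average_every: int = 10,
    keep_models: bool = False,
) -> ModelSweep:
    """Fit one model per K and locate the perplexity elbow.

    Each K gets a deterministic seed offset from ``seed``, so the sweep
    is reproducible as a whole. Defaults are a screening configuration:
    fewer sweeps than a final fit, with theta/phi averaged over every
    10th post-burn-in sweep to stabilize the perplexity estimate that
    the RPC differences depend on.
    """
    k_values = [int(k) for k in k_values]
    if len(k_values) < 2 or any(b <= a for a, b in zip(k_values, k_values[1:])):
        raise ValidationError("k_values must be strictly increasing with length >= 2")
    perplexities = []
    models = {} if keep_models else None
    for index, k in enumerate(k_values):
        child_seed = (int(seed) + 100003 * index) % (2**31)
        model = fit_lda(
            lda_input,
            k,
            alpha=alpha,
            beta=beta,
            iterations=iterations,
            burn_in=burn_in,
            seed=child_seed,
            alpha_mode=alpha_mode,
            average_every=average_every,
        )
        perplexities.append(perplexity(model, lda_input))
        if keep_models:
            models[k] = model
    rpc_values = rpc(k_values, perplexities)
    if len(k_values) >= 3:
        selected = select_elbow(k_values, rpc_values)
    else:
        selected = int(k_values[int(np.argmin(perplexities))])
    return ModelSweep(
        k_values=k_values,
        perplexities=perplexities,
        rpc_values=list(rpc_values),
        selected_k=selected,
        seed=int(seed),
        models=models,
    )
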