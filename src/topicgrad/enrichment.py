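"""Hypergeometric over-representation of topic signatures in gene sets.

Each topic's top genes are tested for overlap against every annotated
gene set (e.g. factor-associated target genes derived from ChIP data)
within a defined gene universe. The p-value is the inclusive upper tail
P(X >= overlap) of the hypergeometric distribution; each topic is
assigned a top factor by ascending raw p-value (the standard
over-representation reading of "most significant overlap"), with
Benjamini-Hochberg adjusted p-values reported alongside.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .lda_engine import TopicModel
from .matrix_io import GeneSetCollection
from .topic_analysis import top_genes


@dataclass
class EnrichmentTable:
    """All (topic, set) tests plus each topic's best-ranked factor."""

    table: pd.DataFrame
    top_factors: dict


def hypergeom_pvalue(
    overlap: int, set_a_size: int, set_b_size: int, universe_size: int
) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, set_a, draws=set_b).

    ``set_a_size`` plays the role of successes in the universe and
    ``set_b_size`` the number of draws; the test is symmetric in the two.
    Overlap 0 gives exactly 1.
    """
    overlap = int(overlap)
    set_a_size = int(set_a_size)
    set_b_size = int(set_b_size)
    universe_size = int(universe_size)
    if universe_size < 1:
        raise ValidationError("universe_size must be >= 1")
    if not (0 <= set_a_size <= universe_size and 0 <= set_b_size <= universe_size):
        raise ValidationError("set sizes must lie in [0, universe_size]")
    if not 0 <= overlap <= min(set_a_size, set_b_size):
        raise ValidationError("overlap must lie in [0, min(set sizes)]")
    if overlap == 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, universe_size, set_a_size, set_b_size))


def enrich_topics(
    model: TopicModel,
    sets: GeneSetCollection,
    n: int = 50,
    universe: str = "dataset",
) -> EnrichmentTable:
    """Test every (topic, gene set) pair for signature overlap.

    ``universe="dataset"`` uses the model vocabulary as the gene
    universe; ``"intersection"`` restricts it further to genes that
    appear in at least one annotated set, so sets and signatures are
    both clipped to genes observable on both sides. Ranking within a
    topic uses the raw p-value (ties: larger overlap, then set name);
    BH adjustment is applied across the whole table.
    """
    if len(sets) == 0:
        raise ValidationError("gene-set collection is empty")
    vocabulary = [str(g) for g in model.vocabulary]
    if universe == "dataset":
        universe_genes = set(vocabulary)
    elif universe == "intersection":
        annotated = set()
        for members in sets.sets.values():
            annotated.update(str(g).strip() for g in members)
        universe_genes = set(vocabulary) & annotated
    else:
        raise ValidationError("universe must be 'dataset' or 'intersection'")
    if not universe_genes:
        raise ValidationError("gene universe is empty")

    clipped_sets = {
        name: {str(g).strip() for g in members} & universe_genes
        for name, members in sets.sets.items()
    }
    rows = []
    n_eff = min(n, len(vocabulary))
    for topic in range(1, model.k + 1):
        signature = set(top_genes(model, topic, n=n_eff).genes) & universe_genes
        for name in sorted(clipped_sets):
            members = clipped_sets[name]
            overlap = len(signature & members)
            p = hypergeom_pvalue(
                overlap, len(signature), len(members), len(universe_genes)
            )
            rows.append(
                {
                    "topic_id": topic,
                    "set_name": name,
                    "overlap": overlap,
                    "signature_size": len(signature),
                    "set_size_in_universe": len(members),
                    "universe_size": len(universe_genes),
                    "p_value": p,
                }
            )
    table = pd.DataFrame(rows)
    table["adjusted_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
    top_factors = {}
    for topic, block in table.groupby("topic_id"):
        ranked = block.sort_values(
            by=["p_value", "overlap", "set_name"], ascending=[True, False, True]
        )
        top_factors[int(topic)] = str(ranked.iloc[0]["set_name"])
    return EnrichmentTable(table=table, top_factors=top_factors)
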