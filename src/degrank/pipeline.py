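"""End-to-end per-cluster scoring: four analyses plus rank integration.

This is the glue the command line, the analysis drivers and the acceptance
checks share: given cluster profiles (already keyed by human gene IDs), a
risk gene set, a postmortem DEG set and a heritability source, compute the
four P values per cluster and direction, then the rank-sum prioritization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster_enrichment import (
    ClusterProfile,
    RegressionFit,
    fit_expected_degs,
    heritability_slot,
    hypergeometric_overlap,
    residual_pvalue,
    select_top_degs,
)
from .io_formats import AnalysisConfig, GeneSet
from .rank_integration import ClusterScoreCard, rank_clusters

__all__ = ["DirectionScores", "score_direction", "score_clusters"]

_DIRECTION_INDEX = {"all": 0, "up": 1, "down": 2}


@dataclass
class DirectionScores:
    """Scoring outcome for one DEG direction."""

    direction: str
    fit: RegressionFit
    p_table: pd.DataFrame  # one row per cluster, one column per analysis
    cards: list[ClusterScoreCard]
    metadata: dict


def score_direction(
    profiles: Sequence[ClusterProfile],
    exome_set: GeneSet,
    postmortem_set: GeneSet | None,
    config: AnalysisConfig,
    direction: str = "all",
    heritability_table: Mapping[str, float] | None = None,
    heritability_scores: Mapping[str, float] | None = None,
) -> DirectionScores:
    """Compute the four per-cluster P values and integrate them.

    The heritability slot uses ``heritability_table`` (label -> P, keys
    ``<cluster_label>.<direction>``) when given, else the permutation stub
    over ``heritability_scores``; with neither, the analysis is dropped for
    all clusters and the rank sum runs over the remaining three.
    """
    fit = fit_expected_degs(profiles, direction=direction)
    residuals = residual_pvalue(fit.observed, fit.expected, fit.cluster_labels)

    per_cluster: dict[str, dict[str, float | None]] = {}
    for i, prof in enumerate(profiles):
        degs = prof.deg_genes(direction)
        universe = prof.background_genes
        p_exome = hypergeometric_overlap(degs, exome_set, universe).p_value
        p_post = (
            hypergeometric_overlap(degs, postmortem_set, universe).p_value
            if postmortem_set is not None
            else None
        )
        if heritability_table is not None:
            p_her: float | None = heritability_slot(
                [],
                source=heritability_table,
                label=f"{prof.cluster_label}.{direction}",
            )
        elif heritability_scores is not None and degs:
            table = prof.deg_table(direction)
            gene_list = select_top_degs(table, min(config.top_n_degs, len(table)))
            rng = np.random.default_rng(
                [config.seed, 401, _DIRECTION_INDEX[direction], i]
            )
            p_her = heritability_slot(
                gene_list,
                scores=heritability_scores,
                universe=sorted(universe),
                mc_reps=config.mc_reps,
                rng=rng,
            )
        else:
            p_her = None
        per_cluster[prof.cluster_label] = {
            "residual": residuals[i].p_one_tailed,
            "exome_overlap": p_exome,
            "heritability": p_her,
            "postmortem_overlap": p_post,
        }

    cards, metadata = rank_clusters(per_cluster, direction=direction)
    metadata["regression"] = {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "pearson_r": fit.pearson_r,
    }
    p_table = pd.DataFrame.from_dict(per_cluster, orient="index").rename_axis(
        "cluster_label"
    )
    return DirectionScores(direction, fit, p_table, cards, metadata)


def score_clusters(
    profiles: Sequence[ClusterProfile],
    exome_set: GeneSet,
    postmortem_set: GeneSet | None,
    config: AnalysisConfig,
    directions: Sequence[str] = ("all", "up", "down"),
    heritability_table: Mapping[str, float] | None = None,
    heritability_scores: Mapping[str, float] | None = None,
) -> dict[str, DirectionScores]:
    """Run :func:`score_direction` for each requested DEG direction."""
    return {
        d: score_direction(
            profiles,
            exome_set,
            postmortem_set,
            config,
            direction=d,
            heritability_table=heritability_table,
            heritability_scores=heritability_scores,
        )
        for d in directions
    }
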