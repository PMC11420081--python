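"""Rank-sum integration of the four per-cluster P values.

Each analysis ranks the clusters by ascending P (average ranks on exact
ties); a cluster's total score is the sum of its four ranks, and smaller
totals mean stronger disease-associated transcriptomic alteration.  Clusters
with equal totals are ordered by the Fisher combined probability of their
four P values, then by label for a fully deterministic output.  Spearman's
rho between the up- and down-DEG rankings measures direction concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import isfinite
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import IntegrityError, ParameterError

__all__ = [
    "ANALYSES",
    "ClusterScoreCard",
    "fisher_combine",
    "rank_clusters",
    "rank_concordance",
]

#: canonical analysis order (also the scorecard column order)
ANALYSES = ("residual", "exome_overlap", "heritability", "postmortem_overlap")


@dataclass
class ClusterScoreCard:
    """One cluster's P values, per-analysis ranks and final position."""

    cluster_label: str
    direction: str
    p_values: dict[str, float]  # analysis -> P (only contributing analyses)
    ranks: dict[str, float]  # analysis -> rank within that analysis
    rank_sum: float
    fisher_combined_p: float
    final_rank: int

    def as_row(self) -> dict:
        row: dict = {
            "cluster_label": self.cluster_label,
            "direction": self.direction,
        }
        for a in ANALYSES:
            row[f"p_{a}"] = self.p_values.get(a, float("nan"))
        for a in ANALYSES:
            row[f"rank_{a}"] = self.ranks.get(a, float("nan"))
        row["rank_sum"] = self.rank_sum
        row["fisher_combined_p"] = self.fisher_combined_p
        row["final_rank"] = self.final_rank
        return row


def fisher_combine(p_values: Sequence[float]) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2m df under H0."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ParameterError("no P values to combine")
    if np.any(p <= 0.0) or np.any(p > 1.0) or not np.all(np.isfinite(p)):
        raise ParameterError(
            "P values must lie in (0, 1]; zero P values are not admissible "
            "(use add-one permutation P values)"
        )
    # summing in sorted order makes the statistic invariant to the input
    # permutation at floating-point precision (exact ties stay exact)
    x = -2.0 * np.sort(np.log(p)).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def rank_clusters(
    per_cluster: Mapping[str, Mapping[str, float | None]],
    direction: str = "all",
) -> tuple[list[ClusterScoreCard], dict]:
    """Integrate per-analysis P values into the final cluster ranking.

    ``per_cluster`` maps cluster label -> {analysis name -> P value}.  An
    analysis missing (``None``/NaN) for any cluster is dropped for *all*
    clusters -- mixing 3- and 4-analysis totals would make rank sums
    incomparable -- and the drop is recorded in the returned metadata.
    Returns the cards in final order (rank 1 first) plus metadata.
    """
    labels = list(per_cluster)
    if len(labels) != len(set(labels)):
        raise IntegrityError("duplicate cluster labels")
    if not labels:
        raise ParameterError("no clusters to rank")

    contributing = []
    dropped = []
    for analysis in ANALYSES:
        vals = [per_cluster[lab].get(analysis) for lab in labels]
        ok = all(v is not None and isfinite(float(v)) for v in vals)
        (contributing if ok else dropped).append(analysis)
    if not contributing:
        raise ParameterError("no analysis has a complete P-value column")

    pmat = np.array(
        [[float(per_cluster[lab][a]) for a in contributing] for lab in labels]
    )
    if np.any(pmat <= 0) or np.any(pmat > 1):
        raise ParameterError("P values must lie in (0, 1]")
    # ascending average ranks within each analysis
    rmat = np.column_stack(
        [stats.rankdata(pmat[:, j], method="average") for j in range(pmat.shape[1])]
    )
    rank_sums = rmat.sum(axis=1)
    combined = np.array([fisher_combine(pmat[i]) for i in range(len(labels))])

    order = sorted(
        range(len(labels)), key=lambda i: (rank_sums[i], combined[i], labels[i])
    )
    cards = []
    for pos, i in enumerate(order, start=1):
        cards.append(
            ClusterScoreCard(
                cluster_label=labels[i],
                direction=direction,
                p_values={a: float(pmat[i, j]) for j, a in enumerate(contributing)},
                ranks={a: float(rmat[i, j]) for j, a in enumerate(contributing)},
                rank_sum=float(rank_sums[i]),
                fisher_combined_p=float(combined[i]),
                final_rank=pos,
            )
        )
    metadata = {
        "direction": direction,
        "analyses_used": list(contributing),
        "analyses_dropped": dropped,
        "n_clusters": len(labels),
    }
    return cards, metadata


def _spearman_exact_p(rho_obs: float, ranks_a: np.ndarray, ranks_b: np.ndarray) -> float:
    """Two-sided exact permutation P for Spearman's rho (small K only)."""
    n = len(ranks_a)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        rho = float(np.corrcoef(ranks_a, ranks_b[list(perm)])[0, 1])
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def rank_concordance(
    cards_a: Sequence[ClusterScoreCard],
    cards_b: Sequence[ClusterScoreCard],
    exact: bool | None = None,
) -> tuple[float, float]:
    """Spearman's rho between two final rankings of the same cluster set.

    Default P value is the asymptotic t approximation; ``exact=True``
    (available for K <= 8) enumerates all permutations instead.
    """
    ranks_a = {c.cluster_label: c.final_rank for c in cards_a}
    ranks_b = {c.cluster_label: c.final_rank for c in cards_b}
    if set(ranks_a) != set(ranks_b):
        raise IntegrityError("cluster sets differ between the two rankings")
    labels = sorted(ranks_a)
    va = np.array([ranks_a[lab] for lab in labels], dtype=float)
    vb = np.array([ranks_b[lab] for lab in labels], dtype=float)
    res = stats.spearmanr(va, vb)
    rho = float(res.statistic)
    if exact:
        if len(labels) > 8:
            raise ParameterError("exact permutation P limited to K <= 8")
        return rho, _spearman_exact_p(rho, va, vb)
    return rho, float(res.pvalue)
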