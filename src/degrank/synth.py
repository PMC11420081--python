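"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate the two data shapes the analyses consume, carrying
ground truth for parameter-recovery tests:

* per-cluster DEG tables whose DEG counts scale linearly with cluster cell
  counts (plus Gaussian noise), with risk-gene enrichment planted at a
  chosen odds ratio in chosen clusters; and
* paired mutant/treatment fold-change tables with a planted sign-reversal
  probability and a damping slope.

Everything is simulated at the summary-statistic level (fold changes and
P values), not the read-count level: the downstream statistics consume
summaries only, and differential-expression engines are out of scope.  All
generators are pure functions of their parameter objects; the same truth
object always yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster_enrichment import ClusterProfile
from .io_formats import DEGTable, GeneSet, ParameterError
from .ortholog import OrthologTable

__all__ = [
    "ClusterSimTruth",
    "ReversalSimTruth",
    "simulate_gene_universe",
    "simulate_cluster_profiles",
    "simulate_reversal_pair",
]


@dataclass(frozen=True)
class ClusterSimTruth:
    """Ground truth for a simulated cell-cluster experiment.

    Per-cluster DEG counts are round(intercept + slope * cells + N(0, sd)),
    truncated at zero; DEG genes are drawn from the universe with risk-set
    members weighted by that cluster's planted odds ratio (1 = null).

    The default noise SD (18) is about sqrt(2 E) at the default expected
    count of ~160: the dispersion a 2xK observed/expected contingency-table
    residual implicitly assumes (both rows treated as sampled), so the
    count-excess P values are calibrated under the null generator.
    """

    cell_counts: tuple[int, ...]
    planted_or: tuple[float, ...]
    n_genes: int = 2000
    risk_set_size: int = 200
    deg_rate_slope: float = 0.15
    deg_rate_intercept: float = 10.0
    noise_sd: float = 18.0
    deg_p_threshold: float = 0.05
    seed: int = 0
    #: optional per-cluster additive DEG-count excess above the linear trend
    #: (a planted disease-associated cluster produces extra DEGs on top of
    #: its size-expected count); None means no excess anywhere
    deg_excess: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.cell_counts) != len(self.planted_or):
            raise ParameterError("cell_counts and planted_or length mismatch")
        if self.deg_excess is not None and len(self.deg_excess) != len(
            self.cell_counts
        ):
            raise ParameterError("deg_excess and cell_counts length mismatch")
        if any(c <= 0 for c in self.cell_counts):
            raise ParameterError("cell counts must be positive")
        if any(r < 1 for r in self.planted_or):
            raise ParameterError("planted odds ratios must be >= 1")
        if self.risk_set_size >= self.n_genes:
            raise ParameterError("risk_set_size must be < n_genes")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def n_clusters(self) -> int:
        return len(self.cell_counts)

    @property
    def expected_deg_counts(self) -> tuple[float, ...]:
        excess = self.deg_excess or (0.0,) * len(self.cell_counts)
        return tuple(
            self.deg_rate_intercept + self.deg_rate_slope * c + e
            for c, e in zip(self.cell_counts, excess)
        )

    @property
    def is_planted(self) -> tuple[bool, ...]:
        return tuple(r > 1 for r in self.planted_or)


@dataclass(frozen=True)
class ReversalSimTruth:
    """Ground truth for a paired mutant/treatment fold-change simulation.

    Each DEG's treatment fold change is ``s * damping * mutant_fc + noise``
    with ``s = -1`` (reversal) with probability ``reversal_prob``, else +1.
    A ``below_floor_fraction`` of genes receives a mean expression at half
    the conventional baseMean floor of 20, to exercise the low-expression
    filter.
    """

    n_deg_up: int = 210
    n_deg_down: int = 217
    reversal_prob: float = 0.9
    damping: float = 0.8
    noise_sd: float = 0.05
    below_floor_fraction: float = 0.0
    mean_expr_floor: float = 20.0
    deg_p_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.reversal_prob <= 1.0:
            raise ParameterError("reversal_prob must lie in [0, 1]")
        if self.damping < 0 or self.noise_sd < 0:
            raise ParameterError("damping and noise_sd must be >= 0")
        if not 0.0 <= self.below_floor_fraction < 1.0:
            raise ParameterError("below_floor_fraction must lie in [0, 1)")
        if self.n_deg_up < 0 or self.n_deg_down < 0 or self.n_deg_up + self.n_deg_down == 0:
            raise ParameterError("need at least one DEG")


def _mouse_symbol(i: int) -> str:
    return f"Simgene{i:05d}"


def _human_id(i: int) -> str:
    return f"ENSG{i:011d}"


def simulate_gene_universe(
    n_genes: int,
    risk_set_size: int,
    seed: int,
    ambiguous_fraction: float = 0.1,
) -> tuple[list[str], GeneSet, OrthologTable]:
    """A synthetic gene universe with a planted ortholog correspondence.

    Returns (human gene-id universe, risk gene set, ortholog table).  A
    ``ambiguous_fraction`` of mouse symbols receives an extra decoy human
    candidate (a pseudogene-style symbol with a distinct ID) so the table is
    many-to-many; the capitalization rule resolves every entry back to the
    planted one-to-one map.
    """
    if risk_set_size >= n_genes:
        raise ParameterError("risk_set_size must be < n_genes")
    if not 0.0 <= ambiguous_fraction <= 1.0:
        raise ParameterError("ambiguous_fraction must lie in [0, 1]")
    rng = np.random.default_rng([seed, 101])
    mouse = [_mouse_symbol(i) for i in range(n_genes)]
    human_ids = [_human_id(i) for i in range(n_genes)]
    rows = {
        "mouse_symbol": list(mouse),
        "human_symbol": [m.upper() for m in mouse],
        "human_gene_id": list(human_ids),
    }
    n_amb = int(round(ambiguous_fraction * n_genes))
    if n_amb:
        decoys = rng.choice(n_genes, size=n_amb, replace=False)
        for i in decoys:
            rows["mouse_symbol"].append(mouse[i])
            rows["human_symbol"].append(mouse[i].upper() + "P1")
            rows["human_gene_id"].append(_human_id(n_genes + int(i)))
    ortho = OrthologTable(pd.DataFrame(rows))
    risk = rng.choice(n_genes, size=risk_set_size, replace=False)
    risk_set = GeneSet(
        "risk_set",
        "synthetic planted risk-gene set",
        frozenset(human_ids[int(i)] for i in risk),
    )
    return human_ids, risk_set, ortho


def _deg_frame(
    idx: np.ndarray,
    human_ids: Sequence[str],
    log2fc: np.ndarray,
    mean_expr: np.ndarray,
    p_value: np.ndarray,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [human_ids[int(i)] for i in idx],
            "symbol": [_mouse_symbol(int(i)) for i in idx],
            "log2fc": log2fc,
            "mean_expr": mean_expr,
            "p_value": p_value,
            "p_adj": np.nan,
        }
    )


def simulate_cluster_profiles(
    truth: ClusterSimTruth,
    universe: Sequence[str] | None = None,
    risk_set: GeneSet | None = None,
) -> list[ClusterProfile]:
    """Per-cluster DEG tables with planted linear size scaling and enrichment.

    When ``universe``/``risk_set`` are omitted they are regenerated from the
    truth object's own parameters and seed, so a truth object alone fully
    determines the output.  DEG P values are Uniform(0, threshold) -- the
    downstream statistics use only thresholding and top-N order -- and
    up/down direction is a fair coin.
    """
    if universe is None or risk_set is None:
        universe, risk_set, _ = simulate_gene_universe(
            truth.n_genes, truth.risk_set_size, truth.seed
        )
    universe = list(universe)
    n = len(universe)
    risk_mask = np.array([g in risk_set.members for g in universe])
    background = set(universe)
    profiles: list[ClusterProfile] = []
    for c, (cells, odds, mean_count) in enumerate(
        zip(truth.cell_counts, truth.planted_or, truth.expected_deg_counts)
    ):
        rng = np.random.default_rng([truth.seed, 211, c])
        n_deg = int(round(mean_count + rng.normal(0.0, truth.noise_sd)))
        n_deg = max(0, min(n_deg, n))
        if np.isinf(odds):
            pool = np.flatnonzero(risk_mask)
            if len(pool) < n_deg:
                raise ParameterError(
                    "infinite odds ratio needs risk_set_size >= DEG count"
                )
            idx = rng.choice(pool, size=n_deg, replace=False)
        else:
            w = np.where(risk_mask, odds, 1.0)
            idx = rng.choice(n, size=n_deg, replace=False, p=w / w.sum())
        idx = np.sort(idx)
        log2fc = rng.choice([-1.0, 1.0], size=n_deg) * (
            0.1 + np.abs(rng.normal(0.0, 0.5, size=n_deg))
        )
        mean_expr = np.exp(rng.normal(4.5, 0.8, size=n_deg))
        p_value = rng.uniform(0.0, truth.deg_p_threshold, size=n_deg)
        frame = _deg_frame(idx, universe, log2fc, mean_expr, p_value)
        label = f"cluster{c:02d}"
        table = DEGTable(label, frame)
        up, down = table.split_directions(1.0)  # all rows are sub-threshold
        profiles.append(
            ClusterProfile(
                cluster_label=label,
                cell_count=int(cells),
                deg_up=up,
                deg_down=down,
                background_genes=background,
            )
        )
    return profiles


def simulate_reversal_pair(truth: ReversalSimTruth) -> tuple[DEGTable, DEGTable]:
    """(mutant-vs-wildtype DEG table, treatment-effect fold-change table).

    The two tables share gene ids and mean expressions; the mutant table's
    rows are all sub-threshold DEGs with the requested direction split, and
    the effect table carries the planted reversals.
    """
    rng = np.random.default_rng([truth.seed, 307])
    n = truth.n_deg_up + truth.n_deg_down
    signs = np.concatenate(
        [np.ones(truth.n_deg_up), -np.ones(truth.n_deg_down)]
    )
    magnitude = 0.3 + np.abs(rng.normal(0.0, 0.4, size=n))
    mutant_fc = signs * magnitude
    p_value = rng.uniform(0.0, truth.deg_p_threshold, size=n)

    mean_expr = truth.mean_expr_floor + np.exp(rng.normal(4.0, 0.8, size=n))
    n_low = int(round(truth.below_floor_fraction * n))
    if n_low:
        low_idx = rng.choice(n, size=n_low, replace=False)
        mean_expr[low_idx] = truth.mean_expr_floor / 2.0

    reversed_flag = rng.random(n) < truth.reversal_prob
    effect_fc = (
        np.where(reversed_flag, -1.0, 1.0) * truth.damping * mutant_fc
        + rng.normal(0.0, truth.noise_sd, size=n)
    )

    idx = np.arange(n)
    human_ids = [_human_id(i) for i in range(n)]
    mutant = DEGTable(
        "mutant_vs_wt",
        _deg_frame(idx, human_ids, mutant_fc, mean_expr, p_value),
    )
    effect = DEGTable(
        "treatment_effect",
        _deg_frame(idx, human_ids, effect_fc, mean_expr, rng.uniform(0, 1, size=n)),
    )
    return mutant, effect
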