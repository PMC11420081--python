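"""Per-cluster association statistics for the rank-sum prioritization.

Four analyses score each cell cluster's differentially expressed genes:

1. *DEG excess*: deviation of the observed DEG count from the count
   expected under an ordinary least-squares regression of DEG count on
   cluster cell count, scored as an adjusted standardized residual of the
   2xK observed/expected contingency table, converted to an upper one-tailed
   normal P value.
2. *Risk-gene overlap*: inclusive upper-tail hypergeometric overlap between
   the cluster's DEGs and a risk gene set, within the detected-and-mapped
   background universe.
3. *Heritability slot*: either externally computed per-gene-list SNP
   heritability enrichment P values (e.g. stratified LD-score regression
   output) passed through by label, or a built-in permutation stub scoring a
   gene list against per-gene scores.
4. *Postmortem-DEG overlap*: hypergeometric overlap with a disease
   postmortem-brain DEG set, as in 2.

The module also provides the Monte-Carlo Fisher exact test used for the
genotype x cluster cell-composition comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io_formats import (
    DEGTable,
    GeneSet,
    IntegrityError,
    ParameterError,
)

log = logging.getLogger("degrank")

__all__ = [
    "ClusterProfile",
    "EnrichmentResult",
    "ResidualResult",
    "RegressionFit",
    "hypergeometric_overlap",
    "fit_expected_degs",
    "residual_pvalue",
    "select_top_degs",
    "heritability_slot",
    "read_heritability_table",
    "composition_test",
]


@dataclass
class ClusterProfile:
    """A cell cluster's size and its direction-split DEG tables."""

    cluster_label: str
    cell_count: int
    deg_up: DEGTable
    deg_down: DEGTable
    background_genes: set[str]

    def __post_init__(self) -> None:
        if self.cell_count <= 0:
            raise ParameterError(f"{self.cluster_label}: cell_count must be > 0")
        up, down = self.deg_up.gene_ids, self.deg_down.gene_ids
        if up & down:
            raise IntegrityError(
                f"{self.cluster_label}: genes in both directions: "
                f"{sorted(up & down)[:5]}"
            )
        if not (up | down) <= self.background_genes:
            raise IntegrityError(
                f"{self.cluster_label}: DEG ids outside background universe"
            )

    def deg_genes(self, direction: str = "all") -> set[str]:
        if direction == "up":
            return self.deg_up.gene_ids
        if direction == "down":
            return self.deg_down.gene_ids
        if direction == "all":
            return self.deg_up.gene_ids | self.deg_down.gene_ids
        raise ParameterError(f"unknown direction {direction!r}")

    def deg_table(self, direction: str = "all") -> DEGTable:
        if direction == "up":
            return self.deg_up
        if direction == "down":
            return self.deg_down
        if direction == "all":
            merged = pd.concat(
                [self.deg_up.data, self.deg_down.data], ignore_index=True
            )
            return DEGTable(f"{self.cluster_label}.all", merged)
        raise ParameterError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overlap outcome: k of n_draw DEGs hit a K_set-gene set."""

    k: int
    n_draw: int
    K_set: int
    N: int
    p_value: float


@dataclass(frozen=True)
class ResidualResult:
    """Observed vs expected DEG count for one cluster."""

    cluster_label: str
    observed: int
    expected: float
    std_residual: float
    p_one_tailed: float


@dataclass(frozen=True)
class RegressionFit:
    """OLS of DEG count on cell count across clusters."""

    slope: float
    intercept: float
    pearson_r: float
    expected: tuple[float, ...]
    observed: tuple[int, ...]
    cluster_labels: tuple[str, ...]


def hypergeometric_overlap(
    deg_genes: Iterable[str], gene_set: GeneSet, universe: Iterable[str]
) -> EnrichmentResult:
    """Inclusive upper-tail hypergeometric P for a DEG/gene-set overlap.

    The gene set is intersected with the background universe before testing;
    ``p = P(X >= k)`` where ``X ~ Hypergeometric(N, K_set, n_draw)``.
    """
    universe = set(universe)
    if not universe:
        raise ParameterError("empty background universe")
    deg_genes = set(deg_genes)
    if not deg_genes <= universe:
        raise IntegrityError("DEG genes are not a subset of the universe")
    set_in_universe = set(gene_set.members) & universe
    k = len(deg_genes & set_in_universe)
    N, K, n = len(universe), len(set_in_universe), len(deg_genes)
    # survival function at k-1 gives the inclusive tail P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(k=k, n_draw=n, K_set=K, N=N, p_value=min(max(p, 0.0), 1.0))


def fit_expected_degs(
    profiles: Sequence[ClusterProfile],
    direction: str = "all",
    p_threshold: float | None = None,
    expected_floor: float = 0.5,
) -> RegressionFit:
    """OLS regression of per-cluster DEG count on cell count.

    DEG counts scale roughly linearly with the number of cells per cluster
    (more cells, more power), so the expected count for each cluster is the
    regression prediction, floored at ``expected_floor`` to keep the
    downstream contingency table positive.
    """
    if len(profiles) < 3:
        raise ParameterError("need >= 3 clusters to fit the DEG-count regression")
    cells = np.array([p.cell_count for p in profiles], dtype=float)
    if np.all(cells == cells[0]):
        raise ParameterError("all cell counts identical: regression is singular")
    counts = np.array([len(p.deg_genes(direction)) for p in profiles], dtype=float)
    res = stats.linregress(cells, counts)
    expected = np.maximum(res.intercept + res.slope * cells, expected_floor)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        expected=tuple(float(e) for e in expected),
        observed=tuple(int(c) for c in counts),
        cluster_labels=tuple(p.cluster_label for p in profiles),
    )


def residual_pvalue(
    observed: Sequence[int],
    expected: Sequence[float],
    cluster_labels: Sequence[str] | None = None,
) -> list[ResidualResult]:
    """Adjusted standardized residuals of the 2xK observed/expected table.

    Row 1 holds the observed DEG counts, row 2 the (rounded) expected
    counts; for each cluster column the adjusted standardized residual of
    the observed cell under the independence model,

        r_c = (O_c - E_hat_c) / sqrt(E_hat_c (1 - rowprop_1)(1 - colprop_c)),

    is converted to an upper one-tailed standard-normal P value.  A cluster
    producing more DEGs than its size predicts gets a positive residual and
    a small P.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise ParameterError("observed and expected must be equal-length vectors")
    if np.any(exp <= 0):
        raise ParameterError("expected counts must all be > 0")
    labels = (
        list(cluster_labels)
        if cluster_labels is not None
        else [f"c{i}" for i in range(len(obs))]
    )
    if len(labels) != len(obs):
        raise ParameterError("cluster_labels length mismatch")

    row2 = np.rint(exp)
    table = np.vstack([obs, row2])
    total = table.sum()
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    if np.any(col_sums <= 0) or np.any(row_sums <= 0):
        raise ParameterError("degenerate contingency table margin")
    fitted = np.outer(row_sums, col_sums) / total
    rowprop = row_sums / total
    colprop = col_sums / total
    denom = np.sqrt(fitted[0] * (1.0 - rowprop[0]) * (1.0 - colprop))
    resid = (table[0] - fitted[0]) / denom
    pvals = stats.norm.sf(resid)
    return [
        ResidualResult(
            cluster_label=labels[c],
            observed=int(obs[c]),
            expected=float(exp[c]),
            std_residual=float(resid[c]),
            p_one_tailed=float(pvals[c]),
        )
        for c in range(len(obs))
    ]


def select_top_degs(deg: DEGTable, n: int) -> list[str]:
    """The n gene ids with the smallest unadjusted P values.

    Ties are broken by larger absolute log2 fold change, then gene id; a
    table shorter than n is returned whole with a warning.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    d = deg.data.assign(_absfc=lambda f: f["log2fc"].abs())
    d = d.sort_values(
        ["p_value", "_absfc", "gene_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    if len(d) < n:
        log.warning(
            "%s: only %d rows for top-%d selection", deg.comparison_label, len(d), n
        )
    return d["gene_id"].head(n).tolist()


def read_heritability_table(path: str | Path) -> dict[str, float]:
    """Read externally computed per-gene-list heritability-enrichment P values.

    Two-column TSV: analysis label, P value (as printed by e.g. a stratified
    LD-score regression wrapper).
    """
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.shape[1] < 2:
        raise ParameterError(f"{path}: need two columns (label, p_value)")
    labels = frame.iloc[:, 0].astype(str)
    pvals = pd.to_numeric(frame.iloc[:, 1])
    return dict(zip(labels, pvals.astype(float)))


def heritability_slot(
    gene_list: Sequence[str],
    source: Mapping[str, float] | Mapping[str, object] | None = None,
    *,
    label: str | None = None,
    scores: Mapping[str, float] | None = None,
    universe: Sequence[str] | None = None,
    mc_reps: int = 999,
    rng: np.random.Generator | None = None,
) -> float:
    """One heritability-enrichment P value for a gene list.

    Two sources are supported.  With ``source`` (a label -> P mapping, e.g.
    from :func:`read_heritability_table`) and ``label``, the externally
    computed value is passed through.  Otherwise the built-in stub scores
    the list: the statistic is the summed per-gene score of the list, its
    null the same-size uniform random gene lists from the universe, and the
    P value uses the add-one rule (k+1)/(R+1) so it is never zero.
    """
    if source is not None:
        if label is None:
            raise ParameterError("external heritability source requires a label")
        if label not in source:
            raise KeyError(f"heritability table has no entry for {label!r}")
        return float(source[label])  # type: ignore[arg-type]
    if scores is None or universe is None:
        raise ParameterError("stub mode requires per-gene scores and a universe")
    if rng is None:
        raise ParameterError("stub mode requires an explicit rng")
    gene_list = list(gene_list)
    m = len(gene_list)
    if m == 0:
        raise ParameterError("empty gene list")
    universe = list(universe)
    if m > len(universe):
        raise ParameterError("gene list larger than universe")
    score_vec = np.array([scores[g] for g in universe], dtype=float)
    observed = float(sum(scores[g] for g in gene_list))
    # uniform m-subsets via random keys; argpartition keeps it O(R * N)
    keys = rng.random((mc_reps, len(universe)))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    null_sums = score_vec[idx].sum(axis=1)
    k = int(np.sum(null_sums >= observed - 1e-12))
    return (k + 1) / (mc_reps + 1)


def _log_table_prob(table: np.ndarray, row_sums: np.ndarray, col_sums: np.ndarray) -> float:
    """Log probability of an r x c table under the fixed-margins null."""
    total = row_sums.sum()
    return float(
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(total + 1)
        - gammaln(table + 1).sum()
    )


def _enumerate_two_row_tables(row_sums: np.ndarray, col_sums: np.ndarray):
    """Yield all 2 x K tables with the given margins."""
    r1 = int(row_sums[0])
    K = len(col_sums)

    def rec(j: int, remaining: int, prefix: list[int]):
        if j == K - 1:
            last = remaining
            if 0 <= last <= col_sums[-1]:
                yield prefix + [last]
            return
        tail_cap = int(col_sums[j + 1 :].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(int(col_sums[j]), remaining)
        for a in range(lo, hi + 1):
            yield from rec(j + 1, remaining - a, prefix + [a])

    for top in rec(0, r1, []):
        top_arr = np.array(top, dtype=float)
        yield np.vstack([top_arr, col_sums - top_arr])


def composition_test(
    counts: Sequence[Sequence[int]] | np.ndarray,
    mc_reps: int = 2000,
    seed: int | np.random.Generator | None = 0,
    method: str = "monte-carlo",
) -> float:
    """Fisher exact test of an r x c contingency table, Monte-Carlo flavored.

    Used for the genotype x cell-cluster composition comparison, where the
    table is far too large for full enumeration.  The P value is the
    probability mass of tables (with the observed margins) no more probable
    than the observed one, estimated from ``mc_reps`` Patefield draws with
    the add-one rule; ``method="exact"`` enumerates all tables instead
    (2 x K tables only, for small fixtures).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ParameterError("counts must be a 2-D table")
    if np.any(table < 0) or not np.allclose(table, np.rint(table)):
        raise ParameterError("counts must be nonnegative integers")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    if np.any(row_sums <= 0) or np.any(col_sums <= 0):
        raise ParameterError("degenerate table: zero row or column margin")

    logp_obs = _log_table_prob(table, row_sums, col_sums)
    # match observed-probability comparisons with a relative tolerance, as
    # exact ties in floating point are the common case here
    tol = 1e-7

    if method == "exact":
        if table.shape[0] != 2:
            raise ParameterError("exact enumeration implemented for 2 x K tables")
        total = 0.0
        for cand in _enumerate_two_row_tables(row_sums, col_sums):
            lp = _log_table_prob(cand, row_sums, col_sums)
            if lp <= logp_obs + tol:
                total += float(np.exp(lp))
        return min(total, 1.0)

    if method != "monte-carlo":
        raise ParameterError(f"unknown method {method!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = stats.random_table(row_sums.astype(int), col_sums.astype(int))
    draws = dist.rvs(mc_reps, method="patefield", random_state=rng)
    lp = (
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(row_sums.sum() + 1)
        - gammaln(draws + 1).sum(axis=(1, 2))
    )
    k = int(np.sum(lp <= logp_obs + tol))
    return (k + 1) / (mc_reps + 1)
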