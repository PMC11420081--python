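"""Drug-reversal statistics for paired differential-expression comparisons.

Given the DEGs of an untreated mutant-vs-wildtype comparison and the fold
changes induced by a treatment in the mutant, a DEG counts as *reversed*
when the treatment moves its expression in the opposite direction
(upregulated DEG decreased, downregulated DEG increased) -- i.e. toward the
wildtype state.  The module provides the exact two-sided binomial test of
the reversal counts against a 0.5 direction probability, Pearson
correlations of fold-change vectors, and Steiger's test comparing two
dependent correlations that share one variable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnalysisConfig, DEGTable, ParameterError

log = logging.getLogger("degrank")

__all__ = [
    "ReversalCounts",
    "ReversalSummary",
    "classify_reversal",
    "binomial_direction_test",
    "fc_correlation",
    "steiger_dependent_test",
    "reversal_report",
]


@dataclass(frozen=True)
class ReversalCounts:
    """Direction-concordance counts for up- and down-regulated DEGs."""

    n_up: int
    k_up_reversed: int
    n_down: int
    k_down_reversed: int
    missing_genes: tuple[str, ...]


@dataclass(frozen=True)
class ReversalSummary:
    """Full reversal analysis: counts, binomial P values and correlations."""

    n_up: int
    k_up_reversed: int
    frac_up: float
    p_binom_up: float
    n_down: int
    k_down_reversed: int
    frac_down: float
    p_binom_down: float
    r_effect: float
    p_r_effect: float
    n_effect: int
    r_untreated: float
    r_treated: float
    r_between: float
    n_pair: int
    steiger_z: float
    steiger_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def classify_reversal(
    mutant_degs: DEGTable,
    effect_fc: Mapping[str, float] | pd.Series,
    p_threshold: float = 0.05,
) -> ReversalCounts:
    """Count DEGs whose treatment fold change opposes their mutant change.

    ``mutant_degs`` is the mutant-vs-wildtype table (its rows with
    P < ``p_threshold`` are the DEGs, split by fold-change sign);
    ``effect_fc`` maps gene id -> treatment log2 fold change.  An up-DEG is
    reversed iff its effect fold change is < 0, a down-DEG iff > 0; an
    effect fold change of exactly 0 counts as not reversed.  DEGs absent
    from the effect table are excluded and reported.
    """
    effect = pd.Series(effect_fc, dtype=float)
    up, down = mutant_degs.split_directions(p_threshold)
    missing: list[str] = []

    def count(table: DEGTable, reversed_sign: int) -> tuple[int, int]:
        ids = table.data["gene_id"]
        present = ids[ids.isin(effect.index)]
        missing.extend(ids[~ids.isin(effect.index)])
        eff = effect[present].to_numpy(float)
        k = int(np.sum(np.sign(eff) == reversed_sign))
        return len(present), k

    n_up, k_up = count(up, -1)
    n_down, k_down = count(down, +1)
    if n_up + n_down == 0:
        raise ParameterError("no DEGs shared with the effect fold-change table")
    if missing:
        log.warning("classify_reversal: %d DEGs absent from effect table", len(missing))
    return ReversalCounts(n_up, k_up, n_down, k_down, tuple(sorted(missing)))


def binomial_direction_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial P value (point-probability definition).

    Sums the probabilities of all outcomes whose point probability does not
    exceed that of ``k`` under Binomial(n, p0); for p0 = 0.5 this equals the
    doubled smaller tail capped at 1.  Extreme tails are evaluated by the
    exact distribution functions, which stay accurate far below 1e-40.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not 0 <= k <= n:
        raise ParameterError("k must lie in [0, n]")
    return float(stats.binomtest(k, n, p0).pvalue)


def fc_correlation(
    fc_a: Mapping[str, float] | pd.Series, fc_b: Mapping[str, float] | pd.Series
) -> tuple[float, float, int]:
    """Pearson correlation of two fold-change vectors on their shared genes.

    Returns (r, two-sided P, number of shared genes).  Vectors are aligned
    on gene ids; fewer than 3 shared genes or a constant vector is an error.
    """
    a = pd.Series(fc_a, dtype=float)
    b = pd.Series(fc_b, dtype=float)
    shared = a.index.intersection(b.index)
    n = len(shared)
    if n < 3:
        raise ParameterError(f"only {n} shared genes; need >= 3")
    x = a[shared].to_numpy(float)
    y = b[shared].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("constant fold-change vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def steiger_dependent_test(
    r_jk: float, r_jh: float, r_kh: float, n: int
) -> tuple[float, float]:
    """Steiger's test for two overlapping dependent correlations.

    Compares r_jk and r_jh (sharing variable j) measured on the same n
    observations, given the correlation r_kh between the non-shared
    variables.  Both correlations are Fisher z-transformed; their asymptotic
    covariance uses the pooled correlation r_bar = (r_jk + r_jh)/2:

        psi_bar = r_kh (1 - 2 r_bar^2) - r_bar^2 (1 - 2 r_bar^2 - r_kh^2)/2
        s_bar   = psi_bar / (1 - r_bar^2)^2
        z       = (z_jk - z_jh) sqrt((n - 3) / (2 - 2 s_bar))

    with a two-sided standard-normal P value.
    """
    if n < 4:
        raise ParameterError("n must be >= 4")
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 < r < 1.0:
            raise ParameterError(f"{name} must lie strictly inside (-1, 1)")
    z_jk = math.atanh(r_jk)
    z_jh = math.atanh(r_jh)
    r_bar = (r_jk + r_jh) / 2.0
    psi_bar = r_kh * (1.0 - 2.0 * r_bar**2) - 0.5 * r_bar**2 * (
        1.0 - 2.0 * r_bar**2 - r_kh**2
    )
    s_bar = psi_bar / (1.0 - r_bar**2) ** 2
    z = (z_jk - z_jh) * math.sqrt((n - 3.0) / (2.0 - 2.0 * s_bar))
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, min(p, 1.0)


def reversal_report(
    mutant_degs: DEGTable,
    effect_fc: DEGTable,
    treated_vs_wt_fc: DEGTable | None,
    reference_degs: DEGTable | None,
    config: AnalysisConfig = AnalysisConfig(),
) -> ReversalSummary:
    """Assemble the full reversal analysis from four comparisons.

    mutant_degs
        Untreated mutant vs wildtype comparison; its sub-threshold rows are
        the DEGs classified for reversal.
    effect_fc
        Treated mutant vs untreated mutant (the treatment-effect analysis).
    treated_vs_wt_fc
        Treated mutant vs untreated wildtype.
    reference_degs
        An independent earlier mutant-vs-wildtype comparison whose DEG fold
        changes are correlated against the untreated comparison
        (r_untreated) and against the treated-vs-wildtype comparison
        (r_treated); Steiger's test then compares the two, with the
        empirical correlation between the two target vectors as r_kh and
        the shared gene count as n.  With either table absent the
        correlation-pair comparison is skipped (NaN fields).

    Genes with mean expression at or below ``config.mean_expr_floor`` are
    excluded from every table before any statistic is computed.
    """
    floor = config.mean_expr_floor
    mutant = mutant_degs.filter_expressed(floor)
    effect = effect_fc.filter_expressed(floor)

    counts = classify_reversal(
        mutant, effect.log2fc_series(), config.deg_p_threshold
    )
    p_up = binomial_direction_test(counts.k_up_reversed, counts.n_up)
    p_down = binomial_direction_test(counts.k_down_reversed, counts.n_down)

    r_effect, p_r_effect, n_effect = fc_correlation(
        mutant.log2fc_series(), effect.log2fc_series()
    )

    nan = float("nan")
    r_untreated = r_treated = r_between = z = p_steiger = nan
    n_pair = 0
    if treated_vs_wt_fc is not None and reference_degs is not None:
        treated = treated_vs_wt_fc.filter_expressed(floor)
        reference = reference_degs.filter_expressed(floor)
        ref_deg_fc = reference.significant(config.deg_p_threshold).log2fc_series()
        untreated_fc = mutant.log2fc_series()
        treated_fc = treated.log2fc_series()
        shared = ref_deg_fc.index.intersection(untreated_fc.index).intersection(
            treated_fc.index
        )
        r_untreated, _, _ = fc_correlation(ref_deg_fc[shared], untreated_fc[shared])
        r_treated, _, _ = fc_correlation(ref_deg_fc[shared], treated_fc[shared])
        r_between, _, n_pair = fc_correlation(
            untreated_fc[shared], treated_fc[shared]
        )
        z, p_steiger = steiger_dependent_test(
            r_untreated, r_treated, r_between, n_pair
        )

    return ReversalSummary(
        n_up=counts.n_up,
        k_up_reversed=counts.k_up_reversed,
        frac_up=counts.k_up_reversed / counts.n_up if counts.n_up else float("nan"),
        p_binom_up=p_up,
        n_down=counts.n_down,
        k_down_reversed=counts.k_down_reversed,
        frac_down=(
            counts.k_down_reversed / counts.n_down if counts.n_down else float("nan")
        ),
        p_binom_down=p_down,
        r_effect=r_effect,
        p_r_effect=p_r_effect,
        n_effect=n_effect,
        r_untreated=r_untreated,
        r_treated=r_treated,
        r_between=r_between,
        n_pair=n_pair,
        steiger_z=z,
        steiger_p=p_steiger,
    )
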