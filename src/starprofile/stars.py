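"""Gene-reliability scoring: Poisson counting error, depth stars, Q-test stars.

Read counting is a Poisson process, so an observed count N carries a relative
statistical error

    E[%] = 100 * k / sqrt(N)

where k sets the confidence interval (k=1 -> 68.3%, k=2 -> 95.5%,
k=3 -> 99.7%). Requiring E <= 25% at k=1 gives the count cutoff N = 16: genes
whose summed counts over the seven early stages fall below it are filtered.

Two star scores are then assigned per surviving gene:

* depth stars (tau-sigma): confidence of the whole seven-stage temporal
  dynamic, limited by its weakest stage — tau = floor(sqrt(min_i N_i) / 4),
  so seven counts of 16 earn exactly one star;
* Q-test stars: a Dixon r10 outlier test on the seven normalized expression
  values; a point deviating at 90/95/99% confidence earns 1/2/3 stars.

Genes totalling at least 2 stars are the candidates admitted to clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    DIXON_CRITICAL_N7,
    EARLY_STAGES,
    ConfigError,
    ConsistencyError,
    ParameterError,
)
from .profiling import CountMatrix, normalize_per_million

_CONF_TO_STARS = {0: 0, 90: 1, 95: 2, 99: 3}


@dataclass
class ConfidenceParams:
    """Poisson-error filter settings; N_cutoff = ceil((100 k / E_target)^2)."""

    k: float = 1.0
    E_target: float = 25.0

    def __post_init__(self):
        if self.k <= 0 or self.E_target <= 0:
            raise ParameterError("k and E_target must be positive")

    @property
    def N_cutoff(self) -> int:
        return cutoff_count(self.E_target, self.k)


@dataclass
class QTestResult:
    q_low: float
    q_high: float
    confidence: int  # 0 (none), 90, 95 or 99

    @property
    def q_max(self) -> float:
        return max(self.q_low, self.q_high)

    @property
    def stars(self) -> int:
        return _CONF_TO_STARS[self.confidence]


def relative_error(N: float, k: float = 1.0) -> float:
    """Relative Poisson counting error in percent: E = 100*k/sqrt(N)."""
    if N <= 0:
        raise ParameterError("N must be positive")
    if k <= 0:
        raise ParameterError("k must be positive")
    return 100.0 * k / math.sqrt(N)


def cutoff_count(E_target: float, k: float = 1.0) -> int:
    """Smallest integer count whose relative error is at most ``E_target`` percent."""
    if E_target <= 0 or k <= 0:
        raise ParameterError("E_target and k must be positive")
    # epsilon guard: keep ceil from bumping an exactly-attained cutoff up one
    # on floating-point roundoff (e.g. E derived from relative_error(N))
    return math.ceil((100.0 * k / E_target) ** 2 * (1 - 1e-12))


def filter_by_total(
    cm: CountMatrix,
    stage_subset: tuple[str, ...] = EARLY_STAGES,
    cutoff: int = 16,
    op: str = "ge",
) -> CountMatrix:
    """Drop genes whose summed raw counts over ``stage_subset`` miss the cutoff.

    The adult tissue library is excluded by default: reliability concerns the
    developmental time course. ``op`` is 'ge' (sum >= cutoff, default) or 'gt'.
    """
    unknown = [s for s in stage_subset if s not in cm.counts.columns]
    if unknown:
        raise ConfigError(f"unknown stage labels: {unknown}")
    totals = cm.counts[list(stage_subset)].sum(axis=1)
    if op == "ge":
        keep = totals >= cutoff
    elif op == "gt":
        keep = totals > cutoff
    else:
        raise ParameterError("op must be 'ge' or 'gt'")
    return CountMatrix(cm.counts[keep], cm.library_totals)


def tau_sigma_stars(counts_7, aggregator: str = "min") -> int:
    """Depth-confidence stars of a seven-stage count vector.

    Default reading: the weakest stage limits the confidence of the whole
    temporal dynamic, tau = floor(sqrt(min_i N_i)/4); seven counts of 16 give
    exactly 1 star. ``aggregator='mean'`` substitutes the mean count.
    """
    arr = np.asarray(counts_7, dtype=float)
    if arr.shape != (7,):
        raise ParameterError(f"expected 7 stage counts, got shape {arr.shape}")
    if (arr < 0).any():
        raise ParameterError("counts must be non-negative")
    if aggregator == "min":
        n = arr.min()
    elif aggregator == "mean":
        n = arr.mean()
    else:
        raise ParameterError("aggregator must be 'min' or 'mean'")
    return int(math.sqrt(n) / 4.0)


def dixon_q(values_7, critical=None) -> QTestResult:
    """Dixon r10 Q-test over seven values.

    Sorted ascending x(1..7): q_low = (x2-x1)/(x7-x1) tests the low extreme,
    q_high = (x7-x6)/(x7-x1) the high extreme; max(q_low, q_high) is compared
    to the n=7 critical values (defaults 0.507/0.568/0.680 for 90/95/99%).
    A zero range makes the statistic undefined: confidence 'none'.
    """
    arr = np.asarray(values_7, dtype=float)
    if arr.shape != (7,):
        raise ParameterError(f"expected 7 values, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ParameterError("non-finite value in Q-test input")
    crit = dict(critical or DIXON_CRITICAL_N7)
    x = np.sort(arr)
    rng = x[-1] - x[0]
    if rng == 0:
        return QTestResult(q_low=0.0, q_high=0.0, confidence=0)
    q_low = (x[1] - x[0]) / rng
    q_high = (x[-1] - x[-2]) / rng
    q_max = max(q_low, q_high)
    confidence = 0
    for level in sorted(crit):
        if q_max > crit[level]:
            confidence = level
    return QTestResult(q_low=float(q_low), q_high=float(q_high), confidence=confidence)


def assign_stars(
    expression_row,
    counts_row,
    min_total: int = 2,
    critical=None,
    q_on: str = "expression",
    tau_aggregator: str = "min",
) -> dict:
    """Score one gene: depth stars from raw counts, Q stars from expression.

    Both rows must be aligned over the same seven stages. ``q_on`` selects
    what the Q-test sees: normalized 'expression' (default — the test is on
    the expression data points) or raw 'counts'.
    """
    e = np.asarray(expression_row, dtype=float)
    c = np.asarray(counts_row, dtype=float)
    if e.shape != c.shape or e.shape != (7,):
        raise ConsistencyError(
            f"expression and counts must both cover 7 aligned stages, got {e.shape} and {c.shape}"
        )
    tau = tau_sigma_stars(c, aggregator=tau_aggregator)
    q = dixon_q(e if q_on == "expression" else c, critical=critical)
    total = tau + q.stars
    return {
        "tau_sigma_stars": tau,
        "q_stars": q.stars,
        "q_low": q.q_low,
        "q_high": q.q_high,
        "q_max": q.q_max,
        "q_confidence": q.confidence,
        "total_stars": total,
        "candidate": total >= min_total,
    }


def star_table(
    cm: CountMatrix,
    stage_subset: tuple[str, ...] = EARLY_STAGES,
    params: ConfidenceParams | None = None,
    min_total: int = 2,
    critical=None,
    q_on: str = "expression",
    tau_aggregator: str = "min",
    filter_op: str = "ge",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full reliability pipeline on a count matrix.

    Filters genes by summed early-stage counts, normalizes to per-million
    expression, scores depth and Q-test stars per gene, and flags candidates.
    Returns ``(stars, candidate_expression)``: the per-gene star table and the
    normalized expression rows (over ``stage_subset``) of the candidates.
    """
    params = params or ConfidenceParams()
    filtered = filter_by_total(cm, stage_subset, params.N_cutoff, op=filter_op)
    expr = normalize_per_million(filtered)[list(stage_subset)]
    counts = filtered.counts[list(stage_subset)]
    rows = {
        gene: assign_stars(
            expr.loc[gene], counts.loc[gene],
            min_total=min_total, critical=critical,
            q_on=q_on, tau_aggregator=tau_aggregator,
        )
        for gene in filtered.counts.index
    }
    stars = pd.DataFrame.from_dict(rows, orient="index")
    stars.index.name = "gene_id"
    candidates = expr[stars["candidate"]] if len(stars) else expr
    return stars, candidates
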