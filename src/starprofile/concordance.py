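"""Cross-platform validation of sequencing-derived temporal dynamics against qPCR.

qPCR series are expressed as fold-changes with the lowest stage set to 1.
The sequencing-side series is first normalized to the internal control genes
(ICGs, default YB1 and OAZ1 — stably expressed reference genes) and rescaled
the same way, then the two seven-stage series are compared by Pearson
correlation: r > 0.75 is a strong correlation, r > 0.6 acceptable, anything
else weak. Because r is invariant under positive affine rescaling, the
scale-matching step affects plots only, never the classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DEFAULT_ICGS, ParameterError


@dataclass
class ConcordanceResult:
    gene_id: str
    r: float
    category: str  # strong / acceptable / weak / incomparable


def qpcr_relative(raw_levels) -> np.ndarray:
    """Scale a positive qPCR series so its minimum is exactly 1."""
    arr = np.asarray(raw_levels, dtype=float)
    if (arr <= 0).any():
        raise ParameterError("qPCR levels must be positive")
    return arr / arr.min()


def normalize_454_to_icg(gene_expression, icg_expressions) -> np.ndarray:
    """ICG-normalize a sequencing expression series and min-scale it to 1.

    ``icg_expressions`` is one series or a list of series aligned to the same
    stages; multiple ICGs combine by their per-stage geometric mean (the
    standard rule for reference-gene panels). Any non-positive ICG value
    makes that stage's normalization undefined and raises, naming the stage.
    """
    gene = np.asarray(gene_expression, dtype=float)
    icgs = np.atleast_2d(np.asarray(icg_expressions, dtype=float))
    if icgs.shape[1] != gene.shape[0]:
        raise ParameterError("ICG series length does not match the gene series")
    bad = np.nonzero((icgs <= 0).any(axis=0))[0]
    if len(bad):
        stages = _stage_names(gene_expression, bad)
        raise ParameterError(f"non-positive ICG expression at stage(s): {stages}")
    divisor = np.exp(np.log(icgs).mean(axis=0))
    scaled = gene / divisor
    return scaled / scaled.min() if scaled.min() > 0 else scaled


def _stage_names(series, positions) -> list:
    if isinstance(series, pd.Series):
        return [series.index[i] for i in positions]
    return list(positions)


def pearson_and_classify(
    series_a,
    series_b,
    strong: float = 0.75,
    acceptable: float = 0.6,
    log_scale: bool = False,
    gene_id: str = "",
) -> ConcordanceResult:
    """Pearson r between two aligned series with the strong/acceptable/weak call.

    Constant input makes r undefined; the result is 'incomparable' with NaN.
    ``log_scale`` compares log-transformed series (both must be positive).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ParameterError("series must be 1-D, aligned, and of length >= 3")
    if log_scale:
        if (a <= 0).any() or (b <= 0).any():
            raise ParameterError("log-scale comparison requires positive series")
        a, b = np.log(a), np.log(b)
    if a.std() == 0 or b.std() == 0:
        return ConcordanceResult(gene_id, float("nan"), "incomparable")
    r = float(stats.pearsonr(a, b).statistic)
    if r > strong:
        category = "strong"
    elif r > acceptable:
        category = "acceptable"
    else:
        category = "weak"
    return ConcordanceResult(gene_id, r, category)


def concordance_summary(
    results: list[ConcordanceResult],
    strong: float = 0.75,
    acceptable: float = 0.6,
) -> dict:
    """Counts and fractions of comparable genes above each reliability threshold."""
    if not results:
        raise ParameterError("no concordance results to summarize")
    comparable = [res for res in results if np.isfinite(res.r)]
    n = len(comparable)
    n_strong = sum(res.r > strong for res in comparable)
    n_acceptable = sum(res.r > acceptable for res in comparable)
    return {
        "n": n,
        "n_strong": n_strong,
        "n_acceptable": n_acceptable,
        "frac_strong": n_strong / n if n else float("nan"),
        "frac_acceptable": n_acceptable / n if n else float("nan"),
    }


def validate_against_qpcr(
    expression: pd.DataFrame,
    qpcr: pd.DataFrame,
    icgs: tuple[str, ...] = DEFAULT_ICGS,
    strong: float = 0.75,
    acceptable: float = 0.6,
    log_scale: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Compare every shared non-ICG gene's sequencing series to its qPCR series.

    Both frames are genes x stages over the same stage columns; the
    sequencing side must include rows for the ICGs. Returns the per-gene
    table (r, category) and the summary block.
    """
    stages = [s for s in expression.columns if s in qpcr.columns]
    if len(stages) < 3:
        raise ParameterError("need at least 3 shared stages")
    missing = [g for g in icgs if g not in expression.index]
    if missing:
        raise ParameterError(f"ICG rows missing from expression matrix: {missing}")
    icg_rows = expression.loc[list(icgs), stages].to_numpy(float)
    results = []
    for gene in qpcr.index:
        if gene in icgs or gene not in expression.index:
            continue
        seq_series = normalize_454_to_icg(expression.loc[gene, stages], icg_rows)
        q_series = qpcr_relative(qpcr.loc[gene, stages])
        results.append(
            pearson_and_classify(
                seq_series, q_series, strong, acceptable, log_scale, gene_id=gene
            )
        )
    table = pd.DataFrame(
        [(res.gene_id, res.r, res.category) for res in results],
        columns=["gene_id", "r", "category"],
    ).set_index("gene_id")
    return table, concordance_summary(results, strong, acceptable)
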