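"""Transcription-effort statistics and expression-concentration summaries.

The transcription effort of a gene (or gene group) in a sample is the
percentage of that sample's total transcription it accounts for: for a
per-million-normalised matrix, ``100 * value / 10^6``.  Ordering genes from
most to least expressed and accumulating effort yields a concentration
curve that, for heavy-tailed transcriptomes, is well described by
``effort ≈ a·ln(rank) + b``; the fit's coefficient of determination and the
minimal number of top genes needed to reach an effort threshold summarise
how concentrated transcription is.

Efforts are kept at full precision internally; reports round efforts to two
decimals and catalog fractions to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _sps

from .expression_io import PER_MILLION, PER_MILLION_TOTAL, ExpressionMatrix

#: absolute tolerance on "sums to 100" conservation checks
CONSERVATION_ATOL = 1e-6


class InsufficientDataError(ValueError):
    """A partial matrix does not carry enough mass to answer the query."""


def _require_per_million(m: ExpressionMatrix) -> None:
    if m.unit != PER_MILLION:
        raise ValueError(
            "effort statistics need a per_million matrix; call normalize_per_million first"
        )


def _sample_values(m: ExpressionMatrix, sample_id: str) -> np.ndarray:
    return m.sample(sample_id).to_numpy(dtype=float)


def _descending_order(values: np.ndarray, gene_ids: Sequence[str]) -> np.ndarray:
    """Indices sorting by descending value, ties broken by ascending gene ID."""
    ids = np.asarray(gene_ids, dtype=str)
    return np.lexsort((ids, -values))


# ---------------------------------------------------------------------------
# per-gene effort


def gene_effort(
    m: ExpressionMatrix,
    gene_id: str,
    sample_id: str,
    total: float = PER_MILLION_TOTAL,
) -> float:
    """Percentage of a sample's total transcription carried by one gene.

    ``total`` is the sample's true per-million total (10^6 for a full
    matrix); it must be supplied explicitly in spirit for partial matrices,
    where the default remains correct only because the unit is per-million.
    """
    _require_per_million(m)
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * m.value(gene_id, sample_id) / total


def group_effort(
    m: ExpressionMatrix,
    gene_ids: Sequence[str],
    sample_id: str,
    total: float = PER_MILLION_TOTAL,
) -> float:
    """Summed effort of a group of genes (missing genes contribute nothing)."""
    _require_per_million(m)
    col = m.sample(sample_id)
    present = [g for g in gene_ids if g in col.index]
    return float(100.0 * col.loc[present].sum() / total) if present else 0.0


# ---------------------------------------------------------------------------
# ranking and cumulative curves


def rank_genes(m: ExpressionMatrix, sample_id: str) -> list[str]:
    """Genes ordered from most to least expressed (ties: ascending gene ID)."""
    values = _sample_values(m, sample_id)
    order = _descending_order(values, m.gene_ids)
    ids = np.asarray(m.gene_ids, dtype=object)
    return list(ids[order])


@dataclass(frozen=True)
class CumulativeCurve:
    """Ranked cumulative effort of one sample.

    ``effort`` holds the per-rank increments; ``cumulative_effort`` is its
    running sum and is nondecreasing, ending at 100 for a full matrix.
    """

    sample_id: str
    ranks: np.ndarray
    gene_ids: tuple[str, ...]
    effort: np.ndarray
    cumulative_effort: np.ndarray


def cumulative_effort_curve(
    m: ExpressionMatrix,
    sample_id: str,
    total: float = PER_MILLION_TOTAL,
) -> CumulativeCurve:
    _require_per_million(m)
    if total <= 0:
        raise ValueError("total must be positive")
    values = _sample_values(m, sample_id)
    order = _descending_order(values, m.gene_ids)
    sorted_values = values[order]
    effort = 100.0 * sorted_values / total
    ids = np.asarray(m.gene_ids, dtype=object)
    return CumulativeCurve(
        sample_id=sample_id,
        ranks=np.arange(1, len(values) + 1),
        gene_ids=tuple(ids[order]),
        effort=effort,
        cumulative_effort=np.cumsum(effort),
    )


@dataclass(frozen=True)
class LogFitResult:
    """Least-squares fit of cumulative effort to ``a·ln(rank) + b``."""

    a: float
    b: float
    r_squared: float
    n_points: int
    degenerate: bool = False


def fit_log_curve(
    curve: CumulativeCurve,
    use_ranks: tuple[int, int] | None = None,
) -> LogFitResult:
    """Fit ``cumulative_effort ≈ a·ln(rank) + b`` by ordinary least squares.

    By default only ranks with nonzero expression enter the fit: trailing
    zero-expression ranks add no cumulative mass and would distort R².
    ``use_ranks=(lo, hi)`` selects an inclusive rank window instead.  The
    natural logarithm is used; the base only rescales ``a``, never R².
    """
    if use_ranks is None:
        mask = curve.effort > 0
    else:
        lo, hi = use_ranks
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid rank range ({lo}, {hi})")
        mask = (curve.ranks >= lo) & (curve.ranks <= hi)
    x = np.log(curve.ranks[mask].astype(float))
    y = curve.cumulative_effort[mask]
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"log fit needs at least 3 points, got {n}")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        # constant curve: define a=0 and a perfect fit, flagged degenerate
        return LogFitResult(a=0.0, b=float(y.mean()), r_squared=1.0, n_points=n, degenerate=True)
    res = _sps.linregress(x, y)
    return LogFitResult(
        a=float(res.slope),
        b=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=n,
    )


# ---------------------------------------------------------------------------
# concentration statistics


def min_genes_for_effort(
    m: ExpressionMatrix,
    sample_id: str,
    threshold: float,
    total: float = PER_MILLION_TOTAL,
) -> int:
    """Smallest k such that the top-k genes reach ``threshold`` % of effort.

    Returns 0 for threshold 0.  For a partial matrix a threshold beyond the
    provided genes' cumulative mass raises :class:`InsufficientDataError`.
    """
    _require_per_million(m)
    if not 0.0 <= threshold <= 100.0:
        raise ValueError(f"threshold must be in [0, 100], got {threshold}")
    if threshold == 0.0:
        return 0
    values = np.sort(_sample_values(m, sample_id))[::-1]
    cumulative = np.cumsum(100.0 * values / total)
    if cumulative[-1] < threshold - 1e-9:
        raise InsufficientDataError(
            f"sample {sample_id!r}: provided genes reach only "
            f"{cumulative[-1]:.4f}% cumulative effort, below threshold {threshold}%"
        )
    return int(np.searchsorted(cumulative, threshold - 1e-9, side="left")) + 1


@dataclass(frozen=True)
class ExpressedStats:
    sample_id: str
    expressed_genes: int
    expressed_fraction: float  # percent of the gene catalog


def expressed_fraction(expressed_genes: int, catalog_size: int) -> float:
    """Percent of the gene catalog with detected expression."""
    if catalog_size <= 0:
        raise ValueError("catalog_size must be positive")
    if expressed_genes > catalog_size:
        raise ValueError(
            f"expressed_genes ({expressed_genes}) exceeds catalog_size ({catalog_size})"
        )
    return 100.0 * expressed_genes / catalog_size


def expressed_gene_stats(
    m: ExpressionMatrix,
    detection_threshold: float = 0.0,
    catalog_size: int | None = None,
) -> dict[str, ExpressedStats]:
    """Per-sample count and catalog fraction of genes with value > threshold.

    "Expressed" means strictly greater than ``detection_threshold`` (default
    0, i.e. any signal counts).  ``catalog_size`` defaults to the number of
    genes in the matrix and must not be smaller than it.
    """
    catalog = m.n_genes if catalog_size is None else catalog_size
    if catalog < m.n_genes:
        raise ValueError(
            f"catalog_size ({catalog}) smaller than matrix gene count ({m.n_genes})"
        )
    out: dict[str, ExpressedStats] = {}
    for sample_id in m.sample_ids:
        expressed = int((_sample_values(m, sample_id) > detection_threshold).sum())
        out[sample_id] = ExpressedStats(
            sample_id=sample_id,
            expressed_genes=expressed,
            expressed_fraction=expressed_fraction(expressed, catalog),
        )
    return out


@dataclass(frozen=True)
class ParetoSummary:
    sample_id: str
    effort_threshold: float
    genes_for_threshold: int
    gene_fraction: float  # percent of the catalog


def pareto_summary(
    m: ExpressionMatrix,
    sample_id: str,
    effort_threshold: float = 80.0,
    catalog_size: int | None = None,
    total: float = PER_MILLION_TOTAL,
) -> ParetoSummary:
    """How many genes (and what catalog fraction) carry ``effort_threshold`` %."""
    if m.partial:
        raise ValueError("pareto_summary needs a full matrix")
    catalog = m.n_genes if catalog_size is None else catalog_size
    if catalog < m.n_genes:
        raise ValueError("catalog_size smaller than matrix gene count")
    k = min_genes_for_effort(m, sample_id, effort_threshold, total=total)
    return ParetoSummary(
        sample_id=sample_id,
        effort_threshold=effort_threshold,
        genes_for_threshold=k,
        gene_fraction=100.0 * k / catalog,
    )


@dataclass(frozen=True)
class ConcentrationSummary:
    """Per-sample concentration profile at a ladder of effort thresholds."""

    sample_id: str
    threshold_to_k: Mapping[float, int]
    expressed_genes: int
    expressed_fraction: float
    genes_for_80pct: int
    pareto_gene_fraction_at_80: float
    log_fit: LogFitResult | None = None


def concentration_summary(
    m: ExpressionMatrix,
    sample_id: str,
    thresholds: Sequence[float] = (10.0, 75.0, 80.0),
    detection_threshold: float = 0.0,
    catalog_size: int | None = None,
    total: float = PER_MILLION_TOTAL,
    fit: bool = True,
) -> ConcentrationSummary:
    """Assemble the concentration report for one sample.

    Thresholds must be strictly increasing in (0, 100].  For partial
    matrices the log fit is skipped and unreachable thresholds raise.
    """
    ts = list(thresholds)
    if any(not 0 < t <= 100 for t in ts) or any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError(f"thresholds must be strictly increasing within (0, 100]: {ts}")
    catalog = m.n_genes if catalog_size is None else catalog_size
    if catalog < m.n_genes:
        raise ValueError("catalog_size smaller than matrix gene count")
    threshold_to_k = {t: min_genes_for_effort(m, sample_id, t, total=total) for t in ts}
    expressed = int((_sample_values(m, sample_id) > detection_threshold).sum())
    try:
        k80 = min_genes_for_effort(m, sample_id, 80.0, total=total)
        frac80 = 100.0 * k80 / catalog
    except InsufficientDataError:
        if not m.partial:
            raise
        k80, frac80 = -1, float("nan")
    log_fit = None
    if fit and not m.partial:
        curve = cumulative_effort_curve(m, sample_id, total=total)
        log_fit = fit_log_curve(curve)
    return ConcentrationSummary(
        sample_id=sample_id,
        threshold_to_k=threshold_to_k,
        expressed_genes=expressed,
        expressed_fraction=expressed_fraction(expressed, catalog),
        genes_for_80pct=k80,
        pareto_gene_fraction_at_80=frac80,
        log_fit=log_fit,
    )
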