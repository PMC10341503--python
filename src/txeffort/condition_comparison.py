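"""Pairwise comparison of culture conditions.

Two samples are compared by Pearson correlation of their per-million
values (linear scale by default; identical-media replicates then show
r close to 1) and by a rough twofold-limit rule: a gene whose
pseudocount-stabilised expression ratio exceeds the fold limit in either
direction is an outlier.  Both r and r² are always reported side by side —
they are distinct quantities and are never conflated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .expression_io import ExpressionMatrix, GeneSetCollection


@dataclass(frozen=True)
class FoldChangeOutlier:
    gene_id: str
    value_a: float
    value_b: float
    log2_ratio: float
    infinite: bool = False  # one value was zero with pseudocount 0


@dataclass(frozen=True)
class ComparisonResult:
    sample_a: str
    sample_b: str
    subset_name: str
    n_genes_used: int
    pearson_r: float
    r_squared: float
    r_defined: bool = True
    outliers: tuple[FoldChangeOutlier, ...] = ()


def _pair_values(
    m: ExpressionMatrix,
    sample_a: str,
    sample_b: str,
    subset: Sequence[str] | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    col_a, col_b = m.sample(sample_a), m.sample(sample_b)
    if subset is None:
        genes = list(m.gene_ids)
    else:
        wanted = set(subset)
        genes = [g for g in m.gene_ids if g in wanted]
    return (
        col_a.loc[genes].to_numpy(dtype=float),
        col_b.loc[genes].to_numpy(dtype=float),
        genes,
    )


def pairwise_correlation(
    m: ExpressionMatrix,
    sample_a: str,
    sample_b: str,
    subset: Sequence[str] | None = None,
    subset_name: str = "all",
    log_scale: bool = False,
    pseudocount: float = 1.0,
) -> ComparisonResult:
    """Pearson correlation (and its square) between two samples.

    ``subset`` restricts the comparison to a gene list (e.g. a pathway); at
    least 3 genes must remain.  ``log_scale`` compares
    ``log2(value + pseudocount)`` instead of linear values (off by default).
    Zero variance in either vector yields a defined result with the
    ``r_defined`` flag cleared rather than a crash.
    """
    va, vb, genes = _pair_values(m, sample_a, sample_b, subset)
    if len(genes) < 3:
        raise ValueError(
            f"comparison needs at least 3 genes, got {len(genes)} after subsetting"
        )
    if log_scale:
        va = np.log2(va + pseudocount)
        vb = np.log2(vb + pseudocount)
    if va.std() == 0.0 or vb.std() == 0.0:
        return ComparisonResult(
            sample_a=sample_a,
            sample_b=sample_b,
            subset_name=subset_name,
            n_genes_used=len(genes),
            pearson_r=float("nan"),
            r_squared=float("nan"),
            r_defined=False,
        )
    r = float(_sps.pearsonr(va, vb).statistic)
    return ComparisonResult(
        sample_a=sample_a,
        sample_b=sample_b,
        subset_name=subset_name,
        n_genes_used=len(genes),
        pearson_r=r,
        r_squared=r * r,
    )


def fold_change_outliers(
    m: ExpressionMatrix,
    sample_a: str,
    sample_b: str,
    fold_limit: float = 2.0,
    pseudocount: float = 1.0,
    subset: Sequence[str] | None = None,
) -> list[FoldChangeOutlier]:
    """Genes strictly outside the fold limit between two samples.

    A gene is an outlier when ``|log2((a+p)/(b+p))| > log2(fold_limit)``
    (strict: a gene at exactly the limit is not an outlier).  With
    pseudocount 0 a zero value against a nonzero one is flagged as an
    infinite ratio instead of overflowing; genes at (0, 0) are equal and
    never outliers.  The result is sorted by |log2 ratio| descending
    (infinite ratios first, ties by gene ID).
    """
    if fold_limit <= 1.0:
        raise ValueError("fold_limit must be > 1")
    if pseudocount < 0.0:
        raise ValueError("pseudocount must be >= 0")
    va, vb, genes = _pair_values(m, sample_a, sample_b, subset)
    limit = math.log2(fold_limit)
    out: list[FoldChangeOutlier] = []
    for gene, a, b in zip(genes, va, vb):
        na, nb = a + pseudocount, b + pseudocount
        if na == 0.0 and nb == 0.0:
            continue
        if na == 0.0 or nb == 0.0:
            out.append(
                FoldChangeOutlier(
                    gene_id=gene,
                    value_a=float(a),
                    value_b=float(b),
                    log2_ratio=math.inf if nb == 0.0 else -math.inf,
                    infinite=True,
                )
            )
            continue
        log2_ratio = math.log2(na / nb)
        if abs(log2_ratio) > limit:
            out.append(
                FoldChangeOutlier(
                    gene_id=gene, value_a=float(a), value_b=float(b), log2_ratio=log2_ratio
                )
            )
    out.sort(key=lambda o: (-abs(o.log2_ratio), o.gene_id))
    return out


def compare_all_pairs(
    m: ExpressionMatrix,
    subsets: GeneSetCollection | None = None,
    fold_limit: float = 2.0,
    pseudocount: float = 1.0,
) -> dict[tuple[str, str], dict[str, ComparisonResult]]:
    """All unordered sample pairs, over all genes and optionally per gene set.

    The returned mapping carries both (a, b) and (b, a) keys pointing at the
    same result dictionary, so lookups are order-independent.  Each inner
    dictionary maps ``"all"`` (full-matrix comparison, with fold-change
    outliers attached) and, if ``subsets`` is given, each set name to its
    subset comparison.
    """
    samples = m.sample_ids
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to compare")
    results: dict[tuple[str, str], dict[str, ComparisonResult]] = {}
    for a, b in itertools.combinations(samples, 2):
        res_all = pairwise_correlation(m, a, b)
        outliers = tuple(
            fold_change_outliers(m, a, b, fold_limit=fold_limit, pseudocount=pseudocount)
        )
        entry: dict[str, ComparisonResult] = {
            "all": ComparisonResult(
                sample_a=res_all.sample_a,
                sample_b=res_all.sample_b,
                subset_name="all",
                n_genes_used=res_all.n_genes_used,
                pearson_r=res_all.pearson_r,
                r_squared=res_all.r_squared,
                r_defined=res_all.r_defined,
                outliers=outliers,
            )
        }
        if subsets is not None:
            for gene_set in subsets:
                present = [g for g in gene_set.members if g in m.data.index]
                if len(present) < 3:
                    continue
                entry[gene_set.name] = pairwise_correlation(
                    m, a, b, subset=present, subset_name=gene_set.name
                )
        results[(a, b)] = entry
        results[(b, a)] = entry
    return results
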