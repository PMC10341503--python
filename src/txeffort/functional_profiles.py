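"""Effort decomposition by KOG functional category and by named gene sets.

KOG category profiles answer "how many expressed genes carry each
functional class, and what share of the transcription does each class
absorb".  For the effort partition a gene annotated with several classes
splits its effort equally across them (so class efforts plus the
unannotated remainder always sum to 100), whereas gene *counts* tally the
gene once per class, the way category bar charts are conventionally drawn.

Gene-set profiles (pathways, secondary-metabolite clusters, aroma panels)
are overlays, not partitions: a gene belonging to two sets contributes its
full effort to both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .effort_stats import rank_genes
from .expression_io import (
    PER_MILLION,
    PER_MILLION_TOTAL,
    AnnotationTable,
    ExpressionMatrix,
    GeneSetCollection,
    KOG_CLASSES,
)


@dataclass(frozen=True)
class CategoryTally:
    gene_count: int
    effort: float | None  # None when only counts were requested


@dataclass(frozen=True)
class CategoryProfile:
    sample_id: str
    per_category: dict[str, CategoryTally]
    unannotated: CategoryTally

    def effort_partition_total(self) -> float:
        """Sum of category efforts plus the unannotated remainder."""
        total = sum(t.effort for t in self.per_category.values() if t.effort is not None)
        if self.unannotated.effort is not None:
            total += self.unannotated.effort
        return total


def _require_per_million(m: ExpressionMatrix) -> None:
    if m.unit != PER_MILLION:
        raise ValueError("functional profiles need a per_million matrix")


def kog_category_counts(
    m: ExpressionMatrix,
    annotation: AnnotationTable,
    sample_id: str,
    detection_threshold: float = 0.0,
) -> CategoryProfile:
    """Expressed-gene counts per KOG category (multi-class genes counted once
    per class); the unannotated bucket collects expressed genes with no class."""
    col = m.sample(sample_id)
    class_map = annotation.class_map()
    counts = {letter: 0 for letter in sorted(KOG_CLASSES)}
    unannotated = 0
    for gene, value in col.items():
        if value <= detection_threshold:
            continue
        classes = class_map.get(gene, ())
        if not classes:
            unannotated += 1
        else:
            for letter in classes:
                counts[letter] += 1
    return CategoryProfile(
        sample_id=sample_id,
        per_category={k: CategoryTally(v, None) for k, v in counts.items()},
        unannotated=CategoryTally(unannotated, None),
    )


def kog_category_effort(
    m: ExpressionMatrix,
    annotation: AnnotationTable,
    sample_id: str,
    total: float = PER_MILLION_TOTAL,
) -> CategoryProfile:
    """Effort per KOG category plus the unannotated remainder (a partition).

    A gene with c classes contributes effort/c to each, so category efforts
    and the unannotated bucket sum to 100 for a full matrix.  Gene counts in
    the result tally every gene carrying the class, once per class.
    """
    _require_per_million(m)
    col = m.sample(sample_id)
    class_map = annotation.class_map()
    effort = {letter: 0.0 for letter in sorted(KOG_CLASSES)}
    counts = {letter: 0 for letter in sorted(KOG_CLASSES)}
    un_effort = 0.0
    un_count = 0
    for gene, value in col.items():
        e = 100.0 * float(value) / total
        classes = class_map.get(gene, ())
        if not classes:
            un_effort += e
            un_count += 1
        else:
            share = e / len(classes)
            for letter in classes:
                effort[letter] += share
                counts[letter] += 1
    return CategoryProfile(
        sample_id=sample_id,
        per_category={
            k: CategoryTally(counts[k], effort[k]) for k in sorted(KOG_CLASSES)
        },
        unannotated=CategoryTally(un_count, un_effort),
    )


@dataclass(frozen=True)
class GeneSetMemberRecord:
    gene_id: str
    value: float  # per-million
    effort: float  # percent
    rank: int  # overall rank in the sample (1 = most expressed)


@dataclass(frozen=True)
class GeneSetProfile:
    set_name: str
    sample_id: str
    member_count: int
    members_present: int
    members_expressed: int
    set_effort: float
    per_gene: tuple[GeneSetMemberRecord, ...]


def gene_set_effort(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    set_name: str,
    sample_id: str,
    total: float = PER_MILLION_TOTAL,
    detection_threshold: float = 0.0,
) -> GeneSetProfile:
    """Effort profile of one gene set in one sample.

    Members absent from the matrix reduce ``members_present`` but are never
    an error (printed partial tables routinely omit genes).  ``rank`` is the
    member's overall expression rank in the sample.
    """
    _require_per_million(m)
    gene_set = sets.get(set_name)
    col = m.sample(sample_id)
    rank_of = {g: i + 1 for i, g in enumerate(rank_genes(m, sample_id))}
    records = []
    expressed = 0
    for gene in gene_set.members:
        if gene not in col.index:
            continue
        value = float(col.at[gene])
        if value > detection_threshold:
            expressed += 1
        records.append(
            GeneSetMemberRecord(
                gene_id=gene,
                value=value,
                effort=100.0 * value / total,
                rank=rank_of[gene],
            )
        )
    return GeneSetProfile(
        set_name=set_name,
        sample_id=sample_id,
        member_count=len(gene_set.members),
        members_present=len(records),
        members_expressed=expressed,
        set_effort=float(sum(r.effort for r in records)),
        per_gene=tuple(records),
    )


def count_expressed_in_set(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    set_name: str,
    detection_threshold: float = 0.0,
    mode: str = "all_samples",
) -> int:
    """Members expressed in every sample (``all_samples``) or in at least one
    (``any_sample``); members absent from the matrix count as unexpressed."""
    if mode not in ("all_samples", "any_sample"):
        raise ValueError(f"mode must be 'all_samples' or 'any_sample', got {mode!r}")
    gene_set = sets.get(set_name)
    present = [g for g in gene_set.members if g in m.data.index]
    if not present:
        return 0
    sub = m.data.loc[present].to_numpy(dtype=float) > detection_threshold
    per_gene = sub.all(axis=1) if mode == "all_samples" else sub.any(axis=1)
    return int(per_gene.sum())


def top_genes_in_set(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    set_name: str,
    n: int = 10,
) -> pd.DataFrame:
    """Top-n set members by maximum value across samples (ties: gene ID).

    Returns a DataFrame (one row per member present in the matrix, ordered)
    with the per-sample values and a ``max_value`` column; if n exceeds the
    set size the whole set is returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    gene_set = sets.get(set_name)
    present = [g for g in gene_set.members if g in m.data.index]
    sub = m.data.loc[present].astype(float)
    sub = sub.copy()
    sub["max_value"] = sub.max(axis=1)
    order = sorted(present, key=lambda g: (-sub.at[g, "max_value"], g))
    return sub.loc[order[:n]]


def set_effort_table(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    set_names: Sequence[str] | None = None,
    total: float = PER_MILLION_TOTAL,
) -> pd.DataFrame:
    """Set × sample table of efforts (long-form helper for reports)."""
    names = list(set_names) if set_names is not None else list(sets.names)
    rows = []
    for name in names:
        for sample_id in m.sample_ids:
            profile = gene_set_effort(m, sets, name, sample_id, total=total)
            rows.append(
                {
                    "set_name": name,
                    "sample_id": sample_id,
                    "member_count": profile.member_count,
                    "members_present": profile.members_present,
                    "members_expressed": profile.members_expressed,
                    "set_effort": profile.set_effort,
                }
            )
    return pd.DataFrame(rows)
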