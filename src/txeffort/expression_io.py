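"""I/O and normalisation for gene × sample expression matrices.

Matrices are plain delimited text (TSV or CSV, auto-detected): first column
gene identifiers, header row of sample identifiers, numeric body.  Gene IDs
are opaque strings — numeric-looking protein IDs such as ``990338`` are
labels, never parsed as numbers.

The only normalisation offered is per-million scaling: every sample column
is rescaled so its total equals 10^6, the unit the transcription-effort
statistics operate on.  A classic length-normalised TPM variant is available
by passing gene lengths, but is off by default because the effort statistic
is defined on plain per-million counts.

A *partial* matrix (e.g. a printed top-10 table) carries only a subset of a
sample's genes; the column-sum invariant is suspended for it and downstream
effort computations must receive the true total explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PER_MILLION_TOTAL = 1_000_000.0
#: relative tolerance for the per-million column-sum invariant
COLUMN_SUM_RTOL = 1e-9

RAW_COUNTS = "raw_counts"
PER_MILLION = "per_million"

#: The 25 KOG functional category letters (A–Z without X).
KOG_CLASSES = frozenset("ABCDEFGHIJKLMNOPQRSTUVWYZ")


class ExpressionParseError(ValueError):
    """A delimited input file violates the expected format."""


class UnknownGeneError(KeyError):
    """Requested gene ID is not present in the matrix."""


class UnknownSampleError(KeyError):
    """Requested sample ID is not present in the matrix."""


class UnknownGeneSetError(KeyError):
    """Requested gene set is not present in the collection."""


# ---------------------------------------------------------------------------
# expression matrix


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative gene × sample matrix with a declared unit.

    Parameters
    ----------
    data:
        DataFrame, genes in rows (index = gene IDs), samples in columns.
    unit:
        ``"raw_counts"`` or ``"per_million"``.
    partial:
        True when the matrix holds only a subset of each sample's genes;
        suspends the per-million column-sum invariant.
    """

    data: pd.DataFrame
    unit: str
    partial: bool = False

    def __post_init__(self) -> None:
        if self.unit not in (RAW_COUNTS, PER_MILLION):
            raise ValueError(f"unknown unit {self.unit!r}")
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ID(s): {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ID(s): {dups[:5]}")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric expression values: {exc}") from exc
        if np.isnan(values).any():
            gi, si = map(int, np.argwhere(np.isnan(values))[0])
            raise ValueError(
                f"missing value at gene {df.index[gi]!r}, sample {df.columns[si]!r}"
                " (absence must be encoded as 0)"
            )
        if (values < 0).any():
            gi, si = map(int, np.argwhere(values < 0)[0])
            raise ValueError(
                f"negative value at gene {df.index[gi]!r}, sample {df.columns[si]!r}"
            )
        if self.unit == PER_MILLION and not self.partial:
            colsums = values.sum(axis=0)
            bad = ~np.isclose(colsums, PER_MILLION_TOTAL, rtol=COLUMN_SUM_RTOL, atol=0.0)
            if bad.any():
                sample = df.columns[int(np.argmax(bad))]
                raise ValueError(
                    f"per_million sample {sample!r} sums to {colsums[np.argmax(bad)]:.6f},"
                    f" expected {PER_MILLION_TOTAL:g}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def n_genes(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def sample(self, sample_id: str) -> pd.Series:
        """Return one sample column; raise :class:`UnknownSampleError` otherwise."""
        if sample_id not in self.data.columns:
            raise UnknownSampleError(f"unknown sample {sample_id!r}")
        return self.data[sample_id]

    def value(self, gene_id: str, sample_id: str) -> float:
        if gene_id not in self.data.index:
            raise UnknownGeneError(f"unknown gene {gene_id!r}")
        if sample_id not in self.data.columns:
            raise UnknownSampleError(f"unknown sample {sample_id!r}")
        return float(self.data.at[gene_id, sample_id])


def matrix_from_mapping(
    values: Mapping[str, Mapping[str, float]],
    unit: str = RAW_COUNTS,
    partial: bool = False,
) -> ExpressionMatrix:
    """Build a matrix from ``{sample_id: {gene_id: value}}`` (missing -> 0)."""
    df = pd.DataFrame(values).fillna(0.0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, unit=unit, partial=partial)


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise ExpressionParseError(f"{path}: file is empty")


def read_expression_matrix(
    path: str | Path,
    unit_hint: str = RAW_COUNTS,
    partial: bool = False,
) -> ExpressionMatrix:
    """Read a delimited gene × sample matrix.

    The delimiter is auto-detected (TAB vs comma); ``#`` lines are comments.
    Duplicate gene IDs, negative values and non-numeric cells are rejected
    with an error naming the offending row/column.
    """
    path = Path(path)
    sep = _detect_delimiter(path)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, comment="#", float_precision="round_trip")
    except Exception as exc:  # malformed header / ragged rows
        raise ExpressionParseError(f"{path}: cannot parse: {exc}") from exc
    if raw.shape[1] == 0:
        raise ExpressionParseError(f"{path}: header has no sample columns")
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ExpressionParseError(f"{path}: duplicate gene ID(s): {', '.join(dups[:5])}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        gi, si = map(int, np.argwhere(bad.to_numpy())[0])
        raise ExpressionParseError(
            f"{path}: non-numeric or missing cell at gene {raw.index[gi]!r},"
            f" sample {raw.columns[si]!r}"
        )
    neg = numeric.to_numpy() < 0
    if neg.any():
        gi, si = map(int, np.argwhere(neg)[0])
        raise ExpressionParseError(
            f"{path}: negative value at gene {raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    try:
        return ExpressionMatrix(numeric.astype(float), unit=unit_hint, partial=partial)
    except ValueError as exc:
        raise ExpressionParseError(f"{path}: {exc}") from exc


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write as TSV with a lossless decimal float format (round-trips exactly)."""
    m.data.to_csv(path, sep="\t", float_format="%.17g", index_label="gene_id")


def normalize_per_million(
    m: ExpressionMatrix,
    gene_lengths: Mapping[str, float] | pd.Series | None = None,
) -> ExpressionMatrix:
    """Scale every sample column to a total of 10^6.

    Each value v becomes ``v * 1e6 / column_sum``; gene order is preserved and
    the operation is idempotent on per-million input.  When ``gene_lengths``
    is given, counts are divided by gene length before scaling (classic
    length-normalised TPM); by default no length term is applied.
    """
    if m.partial:
        raise ValueError(
            "cannot per-million normalize a partial matrix: column totals are unknown"
        )
    values = m.values
    if gene_lengths is not None:
        lengths = pd.Series(gene_lengths).reindex(m.data.index)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()][0]
            raise ValueError(f"missing gene length for {missing!r}")
        if (lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        values = values / lengths.to_numpy(dtype=float)[:, None]
    colsums = values.sum(axis=0)
    if (colsums <= 0).any():
        sample = m.data.columns[int(np.argmax(colsums <= 0))]
        raise ValueError(f"sample {sample!r} has zero total expression")
    out = values * (PER_MILLION_TOTAL / colsums)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        unit=PER_MILLION,
    )


# ---------------------------------------------------------------------------
# gene annotation


@dataclass(frozen=True)
class AnnotationTable:
    """Gene → KOG class letters (zero or more) and a free-text function label.

    Covers any subset of a matrix's genes; genes absent from the table are
    treated as unannotated downstream.
    """

    data: pd.DataFrame  # index gene_id; columns: kog_class (str), function_label (str)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ID(s) in annotation: {dups[:5]}")
        for gene, letters in self.data["kog_class"].items():
            for letter in letters:
                if letter not in KOG_CLASSES:
                    raise ValueError(
                        f"gene {gene!r}: unknown KOG class letter {letter!r}"
                    )

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    def classes(self, gene_id: str) -> tuple[str, ...]:
        """KOG class letters of a gene; empty tuple if unannotated/unknown."""
        if gene_id not in self.data.index:
            return ()
        return tuple(self.data.at[gene_id, "kog_class"])

    def class_map(self) -> dict[str, tuple[str, ...]]:
        return {g: tuple(k) for g, k in self.data["kog_class"].items()}


_EMPTY_KOG = {"", "-", "NA", "N/A", "NONE"}


def _parse_kog_field(raw: object) -> str:
    text = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
    if text.upper() in _EMPTY_KOG:
        return ""
    # deduplicate while preserving order
    seen: list[str] = []
    for letter in text:
        if letter not in seen:
            seen.append(letter)
    return "".join(seen)


def make_annotation(
    records: Iterable[tuple[str, str, str]],
) -> AnnotationTable:
    """Build an annotation table from ``(gene_id, kog_letters, function_label)``."""
    rows = [(str(g), _parse_kog_field(k), "" if f is None else str(f)) for g, k, f in records]
    df = pd.DataFrame(rows, columns=["gene_id", "kog_class", "function_label"])
    df = df.set_index("gene_id")
    return AnnotationTable(df)


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a TSV/CSV with columns gene_id, kog_class, function_label."""
    path = Path(path)
    sep = _detect_delimiter(path)
    raw = pd.read_csv(path, sep=sep, comment="#", dtype=str).fillna("")
    required = {"gene_id", "kog_class", "function_label"}
    if not required.issubset(raw.columns):
        raise ExpressionParseError(
            f"{path}: annotation needs columns {sorted(required)}, got {list(raw.columns)}"
        )
    try:
        return make_annotation(
            raw[["gene_id", "kog_class", "function_label"]].itertuples(index=False)
        )
    except ValueError as exc:
        raise ExpressionParseError(f"{path}: {exc}") from exc


def write_annotation(table: AnnotationTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# gene sets (GMT)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (pathways, clusters, marker panels); members may overlap."""

    sets: Mapping[str, GeneSet] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.sets)

    def get(self, name: str) -> GeneSet:
        if name not in self.sets:
            raise UnknownGeneSetError(f"unknown gene set {name!r}")
        return self.sets[name]

    def sizes(self) -> dict[str, int]:
        return {name: len(s.members) for name, s in self.sets.items()}


def make_gene_sets(
    definition: Mapping[str, tuple[str, Sequence[str]]],
) -> GeneSetCollection:
    """Build a collection from ``{name: (description, members)}``."""
    sets: dict[str, GeneSet] = {}
    for name, (description, members) in definition.items():
        deduped = list(dict.fromkeys(str(g) for g in members))
        if not deduped:
            raise ValueError(f"gene set {name!r} has no members")
        sets[name] = GeneSet(name=name, description=description, members=tuple(deduped))
    return GeneSetCollection(sets)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read GMT: one set per line, ``name TAB description TAB member...``."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[0].strip()
            members = [p.strip() for p in parts[2:] if p.strip()]
            if not name:
                raise ExpressionParseError(f"{path}:{lineno}: set line without a name")
            if len(parts) < 3 or not members:
                raise ExpressionParseError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise ExpressionParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            description = parts[1].strip() if len(parts) > 1 else ""
            deduped = tuple(dict.fromkeys(members))
            sets[name] = GeneSet(name=name, description=description, members=deduped)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def missing_members(collection: GeneSetCollection, m: ExpressionMatrix) -> dict[str, tuple[str, ...]]:
    """Set members absent from a matrix, per set (reported, never an error)."""
    index = set(m.data.index)
    return {
        s.name: tuple(g for g in s.members if g not in index)
        for s in collection
    }
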