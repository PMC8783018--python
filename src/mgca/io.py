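"""Data containers and delimited-text readers/writers.

Three containers travel through the whole pipeline:

* :class:`ExpressionMatrix` — genes x samples non-negative normalized
  expression (RPKM-like) with per-sample metadata (region, stage, sex).
* :class:`GeneFeatureTable` — per-gene mRNA abundance (RPKM), gDNA size
  (bp) and GC content (%): the three ranking axes used for matching.
* :class:`GeneSet` — a named, ordered collection of gene identifiers.

Gene identifiers are opaque text; no symbol/accession mapping is attempted.
Every downstream module consumes only these types and never re-reads files.
"""

from __future__ import annotations

import io as _stdio
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mgca")

__all__ = [
    "ExpressionMatrix",
    "GeneFeatureTable",
    "GeneSet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_feature_table",
    "write_feature_table",
    "read_gene_sets",
    "write_gene_set",
]

FEATURE_NAMES = ("abundance", "gdna_size", "gc_content")

#: float format used by all writers (6 significant digits)
FLOAT_FMT = "%.6g"


class MgcaDataError(ValueError):
    """Raised when an input file or container violates a data invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dupes = []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise MgcaDataError(f"duplicate {what}: {sorted(set(dupes))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative normalized expression.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers, unique, in matrix order.
    values : ndarray of shape (n_genes, n_samples)
        Finite, non-negative expression values (RPKM-like, unitless).
    samples : pandas.DataFrame
        One row per column with at least a ``sample_id`` column; optional
        ``region``, ``stage`` and ``sex`` columns enable stratified reruns.
    """

    gene_ids: list[str]
    values: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise MgcaDataError("expression values must be 2-D")
        if len(self.gene_ids) != self.values.shape[0]:
            raise MgcaDataError("gene_ids length does not match value rows")
        if self.values.shape[1] < 2:
            raise MgcaDataError(
                "expression matrix needs at least 2 samples "
                "(Pearson correlation is undefined otherwise)"
            )
        _check_unique(self.gene_ids, "gene IDs")
        if "sample_id" not in self.samples.columns:
            raise MgcaDataError("sample metadata must have a 'sample_id' column")
        if len(self.samples) != self.values.shape[1]:
            raise MgcaDataError("sample metadata rows do not match value columns")
        _check_unique(list(self.samples["sample_id"]), "sample IDs")
        if not np.isfinite(self.values).all():
            raise MgcaDataError("expression values must be finite")
        if (self.values < 0).any():
            raise MgcaDataError("expression values must be non-negative")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._index[gene_id]]

    def index_of(self, gene_id: str) -> int:
        return self._index[gene_id]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.values[idx], self.samples.copy())

    def subset_samples(self, mask: np.ndarray) -> "ExpressionMatrix":
        """Column subset by boolean mask; used by stratified reruns."""
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() < 2:
            raise MgcaDataError("stratum has fewer than 2 samples")
        return ExpressionMatrix(
            list(self.gene_ids),
            self.values[:, mask],
            self.samples.loc[mask].reset_index(drop=True),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=list(self.samples["sample_id"])
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, samples: pd.DataFrame | None = None
    ) -> "ExpressionMatrix":
        if samples is None:
            samples = pd.DataFrame({"sample_id": [str(c) for c in df.columns]})
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), samples)


@dataclass
class GeneFeatureTable:
    """Per-gene values of the three confounding features.

    ``abundance`` is mean expression over all samples (RPKM), ``gdna_size``
    gene length in bp, ``gc_content`` percent GC in (0, 100).  Backed by a
    DataFrame indexed by gene ID.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("gene_id", *FEATURE_NAMES) if c not in self.table.columns]
        if missing:
            raise MgcaDataError(f"feature table missing columns: {missing}")
        tab = self.table.copy()
        tab["gene_id"] = tab["gene_id"].astype(str)
        _check_unique(list(tab["gene_id"]), "gene IDs")
        for col in FEATURE_NAMES:
            tab[col] = pd.to_numeric(tab[col])
            if not np.isfinite(tab[col].to_numpy()).all():
                raise MgcaDataError(f"non-finite values in feature '{col}'")
        if (tab["gdna_size"] <= 0).any():
            raise MgcaDataError("gdna_size must be positive")
        gc = tab["gc_content"].to_numpy()
        if ((gc <= 0) | (gc >= 100)).any():
            raise MgcaDataError("gc_content must lie strictly between 0 and 100")
        self.table = tab.set_index(tab["gene_id"].to_numpy())

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    def feature(self, name: str) -> pd.Series:
        if name not in FEATURE_NAMES:
            raise MgcaDataError(
                f"unknown feature {name!r}; expected one of {FEATURE_NAMES}"
            )
        return self.table[name]

    def value(self, gene_id: str, name: str) -> float:
        return float(self.feature(name).loc[gene_id])

    def subset(self, gene_ids: Iterable[str]) -> "GeneFeatureTable":
        ids = list(gene_ids)
        return GeneFeatureTable(self.table.loc[ids].reset_index(drop=True))

    @classmethod
    def from_columns(
        cls,
        gene_ids: Sequence[str],
        abundance: np.ndarray,
        gdna_size: np.ndarray,
        gc_content: np.ndarray,
    ) -> "GeneFeatureTable":
        return cls(
            pd.DataFrame(
                {
                    "gene_id": list(gene_ids),
                    "abundance": np.asarray(abundance, dtype=float),
                    "gdna_size": np.asarray(gdna_size, dtype=float),
                    "gc_content": np.asarray(gc_content, dtype=float),
                }
            )
        )


@dataclass
class GeneSet:
    """Named, ordered collection of unique gene identifiers."""

    name: str
    gene_ids: list[str]
    description: str = ""
    n_raw: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        raw = [str(g) for g in self.gene_ids]
        if not raw:
            raise MgcaDataError(f"gene set {self.name!r} is empty")
        self.n_raw = self.n_raw or len(raw)
        unique: list[str] = []
        seen: set[str] = set()
        for g in raw:
            if g not in seen:
                unique.append(g)
                seen.add(g)
        if len(unique) < len(raw):
            logger.warning(
                "gene set %r: %d duplicate IDs removed (raw size %d, unique %d)",
                self.name, len(raw) - len(unique), len(raw), len(unique),
            )
        self.gene_ids = unique
        self._members = seen

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._members

    def __iter__(self):
        return iter(self.gene_ids)

    def resolve(self, features: GeneFeatureTable) -> tuple["GeneSet", list[str]]:
        """Split members into (resolvable subset, unresolvable IDs)."""
        ok = [g for g in self.gene_ids if g in features]
        bad = [g for g in self.gene_ids if g not in features]
        if bad:
            logger.warning(
                "gene set %r: %d of %d IDs not in feature table",
                self.name, len(bad), len(self.gene_ids),
            )
        if not ok:
            raise MgcaDataError(f"gene set {self.name!r}: no member resolves")
        return GeneSet(self.name, ok, self.description), bad

    def intersection(self, other: "GeneSet", name: str = "") -> "GeneSet":
        return GeneSet(name or f"{self.name}&{other.name}",
                       [g for g in self.gene_ids if g in other])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path, dialect: str | None) -> str:
    if dialect in ("\t", "tab", "tsv"):
        return "\t"
    if dialect in (",", "comma", "csv"):
        return ","
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_expression_matrix(
    path: str | Path,
    dialect: str | None = None,
    sample_metadata: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples matrix from delimited text.

    Header row holds sample IDs; first column holds gene IDs.  Rows with any
    negative or non-finite value are dropped with a logged report.  Duplicate
    gene or sample IDs are a hard error.  An optional companion metadata
    table (columns ``sample_id`` plus e.g. ``region``/``stage``/``sex``) is
    joined by sample ID.
    """
    path = Path(path)
    sep = _sniff_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise MgcaDataError(f"duplicate gene IDs in {path.name}: {dup}")
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(vals).all(axis=1) | (np.nan_to_num(vals, nan=-1.0) < 0).any(axis=1)
    if bad.any():
        names = df.index[bad].tolist()
        logger.warning(
            "dropping %d gene rows with missing/negative/non-finite values: %s%s",
            bad.sum(), names[:10], "..." if len(names) > 10 else "",
        )
        df = df.loc[~bad]
        vals = vals[~bad]
    if sample_metadata is not None:
        meta = pd.read_csv(Path(sample_metadata), sep=sep, dtype={"sample_id": str})
        meta = meta.set_index("sample_id").loc[[str(c) for c in df.columns]]
        meta = meta.reset_index()
    else:
        meta = pd.DataFrame({"sample_id": [str(c) for c in df.columns]})
    return ExpressionMatrix(list(df.index), vals, meta)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    sep: str = "\t",
    float_format: str = FLOAT_FMT,
) -> None:
    df = matrix.to_dataframe()
    df.index.name = "gene_id"
    df.to_csv(Path(path), sep=sep, float_format=float_format, lineterminator="\n")


def write_sample_metadata(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.samples.to_csv(Path(path), sep=sep, index=False, lineterminator="\n")


def read_feature_table(path: str | Path, dialect: str | None = None) -> GeneFeatureTable:
    """Read a TSV/CSV with columns gene_id, abundance, gdna_size, gc_content."""
    path = Path(path)
    sep = _sniff_sep(path, dialect)
    return GeneFeatureTable(pd.read_csv(path, sep=sep, dtype={"gene_id": str}))


def write_feature_table(
    features: GeneFeatureTable, path: str | Path, sep: str = "\t",
    float_format: str = FLOAT_FMT,
) -> None:
    features.table.to_csv(
        Path(path), sep=sep, index=False, float_format=float_format,
        lineterminator="\n",
    )


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a plain list or a GMT file.

    A line containing tabs is treated as GMT (name, description, members);
    otherwise the whole file is one unnamed set, one ID per line.  Blank
    lines are skipped with a log entry; an empty file is an error.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln.rstrip("\n").rstrip("\r") for ln in text.splitlines()]
    n_blank = sum(1 for ln in lines if not ln.strip())
    if n_blank:
        logger.info("%s: skipped %d blank lines", path.name, n_blank)
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise MgcaDataError(f"gene set file {path} is empty")
    if any("\t" in ln for ln in lines):
        sets = []
        for ln in lines:
            parts = ln.split("\t")
            if len(parts) < 3:
                raise MgcaDataError(f"malformed GMT line in {path.name}: {ln[:60]!r}")
            sets.append(GeneSet(parts[0], parts[2:], description=parts[1]))
        return sets
    return [GeneSet(path.stem, [ln.strip() for ln in lines])]


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        for g in gene_set.gene_ids:
            fh.write(g + "\n")


def write_gene_sets_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8", newline="\n") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.gene_ids]) + "\n")
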