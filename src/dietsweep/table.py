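"""Taxon-by-sample read-count tables and their on-disk formats.

The central container is :class:`ReadCountTable`: a non-negative integer
matrix of sequence-read counts (taxa as rows, samples as columns) together
with per-sample metadata (e.g. consumer species, season) and optional
per-taxon taxonomy annotations (family/genus/species, any of which may be
missing).  Tables are interchanged as plain TSV (counts) plus sidecar CSVs
(metadata, taxonomy), the dominant shape for metabarcoding count data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ReadCountTable", "read_count_table", "write_count_table"]

TAXONOMY_RANKS = ("family", "genus", "species")


class ValidationError(ValueError):
    """Raised when an input table or parameter violates its contract."""


def _unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if list(ids).count(x) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ReadCountTable:
    """Taxon × sample integer count matrix with sample metadata.

    Parameters
    ----------
    taxon_ids : sequence of str
        Unique row labels.
    sample_ids : sequence of str
        Unique column labels.
    counts : ndarray of shape (n_taxa, n_samples)
        Non-negative integer read counts.
    sample_meta : DataFrame, optional
        Indexed by sample id; free-form per-sample attributes
        (``species``, ``season``, ``alpha`` ...).
    taxonomy : DataFrame, optional
        Indexed by taxon id with columns among ``family``, ``genus``,
        ``species``; missing annotations are NaN.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    sample_meta: pd.DataFrame | None = None
    taxonomy: pd.DataFrame | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D array")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValidationError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        _unique(self.taxon_ids, "taxon ids")
        _unique(self.sample_ids, "sample ids")
        if self.sample_meta is not None:
            missing = set(self.sample_ids) - set(self.sample_meta.index.astype(str))
            extra = set(self.sample_meta.index.astype(str)) - set(self.sample_ids)
            if missing or extra:
                raise ValidationError(
                    "sample metadata does not match table columns; "
                    f"missing from metadata: {sorted(missing)}; "
                    f"not in table: {sorted(extra)}"
                )
            self.sample_meta = self.sample_meta.loc[self.sample_ids]
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.taxon_ids)

    # -- basic properties -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def richness(self) -> pd.Series:
        """Observed richness (taxa with at least one read) per sample."""
        return pd.Series((self.counts > 0).sum(axis=0), index=self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id}") from None

    # -- conversions ------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.taxon_ids, name="taxon_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        sample_meta: pd.DataFrame | None = None,
        taxonomy: pd.DataFrame | None = None,
        **attrs,
    ) -> "ReadCountTable":
        return cls(
            taxon_ids=list(df.index.astype(str)),
            sample_ids=list(df.columns.astype(str)),
            counts=df.to_numpy(),
            sample_meta=sample_meta,
            taxonomy=taxonomy,
            attrs=dict(attrs),
        )

    def copy_with_counts(self, counts: np.ndarray) -> "ReadCountTable":
        """New table with identical labels/metadata but different counts."""
        return ReadCountTable(
            taxon_ids=list(self.taxon_ids),
            sample_ids=list(self.sample_ids),
            counts=counts,
            sample_meta=None if self.sample_meta is None else self.sample_meta.copy(),
            taxonomy=None if self.taxonomy is None else self.taxonomy.copy(),
            attrs=dict(self.attrs),
        )

    def select(self, taxa: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "ReadCountTable":
        """Subset by taxon and/or sample ids, preserving order of the lists."""
        taxa = list(taxa) if taxa is not None else list(self.taxon_ids)
        samples = list(samples) if samples is not None else list(self.sample_ids)
        ti = [self.taxon_ids.index(t) for t in taxa]
        si = [self.sample_ids.index(s) for s in samples]
        return ReadCountTable(
            taxon_ids=taxa,
            sample_ids=samples,
            counts=self.counts[np.ix_(ti, si)],
            sample_meta=None if self.sample_meta is None else self.sample_meta.loc[samples],
            taxonomy=None if self.taxonomy is None else self.taxonomy.loc[taxa],
            attrs=dict(self.attrs),
        )

    def drop_empty_taxa(self) -> "ReadCountTable":
        keep = [t for t, row in zip(self.taxon_ids, self.counts) if row.sum() > 0]
        return self.select(taxa=keep)

    def groups(self, group_by: Sequence[str] | str) -> dict[str, list[str]]:
        """Map group label -> sample ids, grouping on metadata columns.

        Group labels join the metadata values with ``_`` (e.g.
        ``bison_summer`` for ``group_by=("species", "season")``).
        """
        if self.sample_meta is None:
            raise ValidationError("table has no sample metadata to group on")
        if isinstance(group_by, str):
            group_by = [group_by]
        for key in group_by:
            if key not in self.sample_meta.columns:
                raise ValidationError(
                    f"unknown metadata key {key!r}; available: "
                    f"{list(self.sample_meta.columns)}"
                )
        labels = self.sample_meta[list(group_by)].astype(str).agg("_".join, axis=1)
        out: dict[str, list[str]] = {}
        for sid, lab in labels.items():
            out.setdefault(lab, []).append(sid)
        return out


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def _read_commented(path: str | Path, **kw) -> pd.DataFrame:
    """Read a CSV/TSV, skipping ``#`` provenance-comment lines."""
    return pd.read_csv(path, comment="#", **kw)


def read_count_table(
    path: str | Path,
    meta_path: str | Path | None = None,
    taxonomy_path: str | Path | None = None,
) -> ReadCountTable:
    """Read a taxon-by-sample count TSV plus optional sidecar CSVs.

    The TSV must have ``taxon_id`` as its first column and one integer
    column per sample.  The metadata CSV must have a ``sample_id`` column
    whose values match the TSV header exactly; mismatches raise a
    :class:`ValidationError` naming the offending samples.
    """
    df = _read_commented(path, sep="\t", dtype={0: str})
    if df.columns[0] != "taxon_id":
        raise ValidationError(
            f"first column of {path} must be 'taxon_id', got {df.columns[0]!r}"
        )
    df = df.set_index("taxon_id")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals, np.rint(vals)):
            raise ValidationError(f"non-integer counts in sample column {col!r}")
        df[col] = vals.astype(np.int64)

    meta = None
    if meta_path is not None:
        meta = _read_commented(meta_path, dtype={"sample_id": str})
        if "sample_id" not in meta.columns:
            raise ValidationError(f"{meta_path} must contain a 'sample_id' column")
        meta = meta.set_index("sample_id")

    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = _read_commented(taxonomy_path, dtype={"taxon_id": str})
        if "taxon_id" not in taxonomy.columns:
            raise ValidationError(f"{taxonomy_path} must contain a 'taxon_id' column")
        taxonomy = taxonomy.set_index("taxon_id")

    return ReadCountTable.from_dataframe(df, sample_meta=meta, taxonomy=taxonomy)


def write_count_table(
    table: ReadCountTable,
    path: str | Path,
    meta_path: str | Path | None = None,
    taxonomy_path: str | Path | None = None,
    header_lines: Sequence[str] = (),
) -> None:
    """Write the count TSV (and sidecars) with optional ``#`` provenance lines."""
    def _dump(df: pd.DataFrame, p: str | Path, sep: str, index_label: str) -> None:
        buf = io.StringIO()
        for line in header_lines:
            buf.write(f"# {line}\n")
        df.to_csv(buf, sep=sep, index_label=index_label)
        Path(p).write_text(buf.getvalue())

    _dump(table.to_dataframe(), path, "\t", "taxon_id")
    if meta_path is not None and table.sample_meta is not None:
        _dump(table.sample_meta, meta_path, ",", "sample_id")
    if taxonomy_path is not None and table.taxonomy is not None:
        _dump(table.taxonomy, taxonomy_path, ",", "taxon_id")
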