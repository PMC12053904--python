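"""Abundance tables, metadata, feature maps, and normalisation.

The central container is :class:`FeatureTable`, a thin wrapper around a
samples x features :class:`pandas.DataFrame` of nonnegative abundances
(RPKM or relative abundance) that validates its invariants on
construction.  Sample metadata and child->parent feature maps
(genus->family, KO->KEGG-module) have dedicated readers.  All on-disk
formats are plain TSV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

log = logging.getLogger("tideline")

#: recognised feature kinds
FEATURE_KINDS = ("genus", "family", "ko", "module", "taxon")
#: recognised value kinds for a FeatureTable
VALUE_KINDS = ("rpkm", "relative")


@dataclass
class FeatureTable:
    """Samples x features nonnegative abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are features.  Entries must be finite
        and nonnegative.
    feature_kind : str
        One of ``genus``, ``family``, ``ko``, ``module`` or the generic
        ``taxon``.
    value_kind : str
        ``rpkm`` or ``relative``.
    """

    data: pd.DataFrame
    feature_kind: str = "taxon"
    value_kind: str = "rpkm"

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise DataError(f"unknown feature_kind {self.feature_kind!r}")
        if self.value_kind not in VALUE_KINDS:
            raise DataError(f"unknown value_kind {self.value_kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise DataError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise DataError(f"duplicate feature ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise DataError("non-finite entries in feature table")
        if values.size and (values < 0).any():
            raise DataError("negative entries in feature table")

    # -- convenience ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, value_kind: str | None = None,
                  feature_kind: str | None = None) -> "FeatureTable":
        return FeatureTable(data,
                            feature_kind or self.feature_kind,
                            value_kind or self.value_kind)

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column ``sample_id``, header of feature ids."""
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, feature_kind: str = "taxon",
                 value_kind: str = "rpkm") -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str).rename(None)
        df.columns = df.columns.astype(str)
        return cls(df, feature_kind, value_kind)


@dataclass
class FeatureMap:
    """Child -> parent(s) feature map.

    genus->family maps are one-to-one; KO->module maps may be
    one-to-many, in which case a child contributes its full value to
    every parent on aggregation.
    """

    parents: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, ps in self.parents.items():
            if not ps:
                raise DataError(f"feature map: empty parent set for {child!r}")
        self.parents = {c: frozenset(p) for c, p in self.parents.items()}

    def __contains__(self, child: str) -> bool:
        return child in self.parents

    def __getitem__(self, child: str) -> frozenset[str]:
        return self.parents[child]

    @property
    def parent_ids(self) -> list[str]:
        out: set[str] = set()
        for ps in self.parents.values():
            out |= ps
        return sorted(out)

    def is_one_to_one(self) -> bool:
        return all(len(p) == 1 for p in self.parents.values())

    def to_tsv(self, path: str | Path) -> None:
        rows = [(c, p) for c, ps in sorted(self.parents.items()) for p in sorted(ps)]
        pd.DataFrame(rows, columns=["child_id", "parent_id"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns[:2]) != ["child_id", "parent_id"]:
            raise DataError(
                f"feature map {path}: expected columns child_id, parent_id")
        parents: dict[str, set[str]] = {}
        for child, parent in zip(df["child_id"], df["parent_id"]):
            parents.setdefault(child, set()).add(parent)
        return cls({c: frozenset(p) for c, p in parents.items()})

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "FeatureMap":
        parents: dict[str, set[str]] = {}
        for child, parent in pairs:
            parents.setdefault(child, set()).add(parent)
        return cls({c: frozenset(p) for c, p in parents.items()})


# ---------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------

METADATA_COLUMNS = ("date", "year", "month", "stage", "period")


def make_metadata(sample_ids: Iterable[str], dates: Iterable, stage: Iterable[str],
                  period: Iterable[str]) -> pd.DataFrame:
    """Assemble a validated metadata frame from parallel columns.

    ``year`` and ``month`` are derived from ``date``; ``period`` must be
    ``baseline`` or ``post``.
    """
    dates = pd.to_datetime(list(dates))
    md = pd.DataFrame({
        "date": dates,
        "year": dates.year,
        "month": dates.month,
        "stage": list(stage),
        "period": list(period),
    }, index=pd.Index([str(s) for s in sample_ids], name="sample_id"))
    return validate_metadata(md)


def validate_metadata(md: pd.DataFrame) -> pd.DataFrame:
    if md.index.has_duplicates:
        raise DataError("metadata: duplicate sample ids")
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise DataError(f"metadata: missing columns {missing}")
    md = md.copy()
    md["date"] = pd.to_datetime(md["date"])
    bad_month = ~md["month"].between(1, 12)
    if bad_month.any():
        raise DataError(f"metadata: month out of range for {md.index[bad_month].tolist()}")
    mism = (md["year"] != md["date"].dt.year) | (md["month"] != md["date"].dt.month)
    if mism.any():
        raise DataError(
            f"metadata: year/month inconsistent with date for {md.index[mism].tolist()}")
    bad_period = ~md["period"].isin(["baseline", "post"])
    if bad_period.any():
        raise DataError(
            f"metadata: period must be baseline|post, got "
            f"{sorted(md.loc[bad_period, 'period'].unique())}")
    return md


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, date ISO-8601, stage, period)."""
    md = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    dates = pd.to_datetime(md["date"])
    md["year"] = dates.dt.year
    md["month"] = dates.dt.month
    return validate_metadata(md)


def write_metadata(md: pd.DataFrame, path: str | Path) -> None:
    out = md.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.index.name = "sample_id"
    out[["date", "stage", "period"]].to_csv(path, sep="\t")


def check_table_metadata(table: FeatureTable, metadata: pd.DataFrame) -> None:
    """Every table sample must have a metadata row."""
    missing = [s for s in table.sample_ids if s not in metadata.index]
    if missing:
        raise DataError(f"samples without metadata: {missing}")


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------

def rpkm_normalize(counts: pd.DataFrame, feature_lengths: Mapping[str, float] | pd.Series,
                   library_sizes: Mapping[str, float] | pd.Series,
                   feature_kind: str = "taxon") -> FeatureTable:
    """Reads-per-kilobase-per-million normalisation of a raw count table.

    ``value[s, f] = counts[s, f] / (length_kb[f] * library_size[s] / 1e6)``

    Parameters
    ----------
    counts : DataFrame
        Samples x features integer (or real) counts, all >= 0.
    feature_lengths : mapping feature_id -> length in base pairs (> 0).
    library_sizes : mapping sample_id -> total reads (> 0).
    """
    lengths = pd.Series(feature_lengths, dtype=float).reindex(counts.columns)
    libs = pd.Series(library_sizes, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        raise DataError(
            f"rpkm: missing length for features {lengths.index[lengths.isna()].tolist()}")
    if libs.isna().any():
        raise DataError(
            f"rpkm: missing library size for samples {libs.index[libs.isna()].tolist()}")
    bad_len = lengths <= 0
    if bad_len.any():
        raise DataError(
            f"rpkm: nonpositive length for features {lengths.index[bad_len].tolist()}")
    bad_lib = libs <= 0
    if bad_lib.any():
        raise DataError(
            f"rpkm: nonpositive library size for samples {libs.index[bad_lib].tolist()}")
    vals = counts.to_numpy(dtype=float)
    if (vals < 0).any():
        raise DataError("rpkm: negative counts")
    kb = lengths.to_numpy() / 1e3
    millions = libs.to_numpy() / 1e6
    rpkm = vals / kb[None, :] / millions[:, None]
    return FeatureTable(pd.DataFrame(rpkm, index=counts.index, columns=counts.columns),
                        feature_kind=feature_kind, value_kind="rpkm")


def aggregate_features(table: FeatureTable, fmap: FeatureMap, target_kind: str,
                       strict: bool = True) -> FeatureTable:
    """Sum child features into their parents (genus->family, KO->module).

    For one-to-many maps a child contributes its full value to each of
    its parents; one-to-one aggregation conserves per-sample totals.

    With ``strict=True`` (default) unmapped features raise; otherwise
    they are dropped with a warning.
    """
    unmapped = [f for f in table.feature_ids if f not in fmap]
    if unmapped:
        if strict:
            raise DataError(f"aggregate: unmapped features {unmapped}")
        warnings.warn(f"aggregate: dropping {len(unmapped)} unmapped features",
                      stacklevel=2)
    parent_cols: dict[str, np.ndarray] = {}
    vals = table.data
    for child in table.feature_ids:
        if child not in fmap:
            continue
        col = vals[child].to_numpy(dtype=float)
        for parent in fmap[child]:
            if parent in parent_cols:
                parent_cols[parent] = parent_cols[parent] + col
            else:
                parent_cols[parent] = col.copy()
    out = pd.DataFrame(parent_cols, index=vals.index)
    out = out[sorted(out.columns)]
    return FeatureTable(out, feature_kind=target_kind, value_kind=table.value_kind)


def drop_unassigned(table: FeatureTable, unassigned_labels: Iterable[str]) -> FeatureTable:
    """Remove features whose ids are in ``unassigned_labels``.

    Column order of survivors is preserved; dropping every feature
    yields an empty-feature table and a warning.
    """
    labels = set(unassigned_labels)
    keep = [f for f in table.feature_ids if f not in labels]
    if not keep:
        warnings.warn("drop_unassigned: all features dropped", stacklevel=2)
    return table.with_data(table.data[keep])


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Scale each sample row to sum to 1."""
    totals = table.data.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        raise DataError(
            f"relative_abundance: zero total for samples {totals.index[zero].tolist()}")
    rel = table.data.div(totals, axis=0)
    return table.with_data(rel, value_kind="relative")


def top_k_features(table: FeatureTable, k: int) -> list[str]:
    """The ``k`` features with highest mean relative abundance.

    Ranking is by mean relative abundance across samples, descending,
    ties broken lexicographically by feature id.  Returns
    ``min(k, n_features)`` ids.
    """
    if k < 1:
        raise DataError("top_k_features: k must be >= 1")
    rel = table if table.value_kind == "relative" else relative_abundance(table)
    means = rel.data.mean(axis=0)
    ranked = sorted(means.index, key=lambda f: (-means[f], f))
    return ranked[:k]
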