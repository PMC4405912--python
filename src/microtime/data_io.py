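"""Readers, writers and sample quality control for OTU time series.

The universal container is :class:`OtuTimeSeries`: a (days x OTUs) count
matrix indexed by integer study day, with optional per-OTU taxonomy strings
and optional fractional abundances.  Host metadata arrives as long-format
``date,variable,value`` tables and is split into one :class:`MetadataSeries`
per variable.  Reference phylogenies are Newick files read into scikit-bio
``TreeNode`` objects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: Default per-subject detection limit for fractional abundances
#: (the deepest sequenced subject resolves roughly 10**-5.8).
DEFAULT_DETECTION_LIMIT = 10.0 ** -5.8


class EmptySeriesError(ValueError):
    """Raised when an operation would leave no samples."""


@dataclass
class OtuTimeSeries:
    """Dated OTU count matrix for one subject and body site.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, index = integer study days (strictly
        increasing; day 0 is the first sample), columns = unique OTU ids.
    taxonomy : pandas.Series, optional
        Per-OTU lineage string (phylum ... species), indexed by OTU id.
    fractions : pandas.DataFrame, optional
        Per-day fractional abundances; each row sums to 1 (+/- 1e-9).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    fractions: pd.DataFrame | None = None
    body_site: str = "gut"
    subject: str = "A"
    detection_limit: float = DEFAULT_DETECTION_LIMIT

    def __post_init__(self) -> None:
        self.counts = self.counts.sort_index()
        idx = self.counts.index
        if len(idx) == 0:
            raise EmptySeriesError("OTU time series has no samples")
        if not idx.is_unique or not idx.is_monotonic_increasing:
            raise ValueError("study days must be unique and increasing")
        if not self.counts.columns.is_unique:
            raise ValueError("duplicate otu_id in table")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.fractions is not None:
            frac = self.fractions
            if not frac.index.equals(idx) or not frac.columns.equals(self.counts.columns):
                raise ValueError("fractions must be aligned with counts")
            sums = frac.sum(axis=1).to_numpy()
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError("fractions must sum to 1 per day")
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.columns)

    @property
    def dates(self) -> np.ndarray:
        return self.counts.index.to_numpy()

    @property
    def otu_ids(self) -> pd.Index:
        return self.counts.columns

    def total_reads(self) -> pd.Series:
        """Per-day total read counts."""
        return self.counts.sum(axis=1)

    def with_fractions(self) -> "OtuTimeSeries":
        """Return a copy carrying standard sum-to-one fractions."""
        from .stability import fractional_normalize

        return fractional_normalize(self)


@dataclass
class MetadataSeries:
    """One host variable tracked daily (e.g. ``"Nutrition: Fiber"``)."""

    name: str
    values: pd.Series  # index = integer study day
    category: str = ""

    def __post_init__(self) -> None:
        self.values = self.values.sort_index()
        if not self.values.index.is_unique:
            raise ValueError(f"duplicate dates for variable {self.name!r}")

    @property
    def binary_dominant(self) -> bool:
        """True when at least 75% of observed values are exactly zero."""
        from .detrending import is_binary_dominant

        return is_binary_dominant(self.values)


def _parse_day_columns(columns) -> list[int]:
    """Interpret table columns as study days: plain integers, or ISO dates
    converted to day offsets from the earliest date."""
    try:
        return [int(c) for c in columns]
    except (TypeError, ValueError):
        pass
    dates = pd.to_datetime(list(columns), format="ISO8601")
    return [int(d) for d in (dates - dates.min()).days]


def read_otu_table(path, format: str = "tsv", **kwargs) -> OtuTimeSeries:
    """Read an OTU table (rows = OTUs, columns = days or ISO dates).

    ``format`` is ``"tsv"`` (first column ``otu_id``, optional trailing
    ``taxonomy`` column) or ``"biom-json"`` (BIOM v1.0 JSON).
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        taxonomy = None
        if len(df.columns) and str(df.columns[-1]).lower() == "taxonomy":
            taxonomy = df.iloc[:, -1].astype(str)
            df = df.iloc[:, :-1]
        if not df.index.is_unique:
            raise ValueError("duplicate otu_id in table")
        mat = df.T
        mat.index = pd.Index(_parse_day_columns(df.columns), name="day")
        counts = mat.astype(np.int64)
        if (counts.to_numpy() != mat.to_numpy()).any():
            raise ValueError("counts must be integers")
        return OtuTimeSeries(counts=counts, taxonomy=taxonomy, **kwargs)
    if format == "biom-json":
        return _read_biom_json(path, **kwargs)
    raise ValueError(f"unknown format {format!r}")


def _read_biom_json(path, **kwargs) -> OtuTimeSeries:
    # Minimal BIOM v1.0 (JSON) support: dense or sparse, rows = OTUs.
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    tax = {}
    for r in doc["rows"]:
        md = r.get("metadata") or {}
        t = md.get("taxonomy")
        if t is not None:
            tax[r["id"]] = "; ".join(t) if isinstance(t, (list, tuple)) else str(t)
    days = _parse_day_columns([c["id"] for c in doc["columns"]])
    shape = doc["shape"]
    mat = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    counts = pd.DataFrame(mat.T, index=pd.Index(days, name="day"), columns=otu_ids)
    taxonomy = pd.Series(tax).reindex(otu_ids) if tax else None
    return OtuTimeSeries(counts=counts, taxonomy=taxonomy, **kwargs)


def write_otu_table(series: OtuTimeSeries, path) -> None:
    """Write the TSV layout accepted by :func:`read_otu_table`."""
    df = series.counts.T
    df.index.name = "otu_id"
    df.columns = [str(d) for d in df.columns]
    if series.taxonomy is not None:
        df = df.assign(taxonomy=series.taxonomy.values)
    df.to_csv(path, sep="\t")


def apply_sample_qc(series: OtuTimeSeries, min_reads: int = 10_000) -> OtuTimeSeries:
    """Drop days with fewer than ``min_reads`` total reads.

    The boundary is strict: a day with exactly ``min_reads`` reads is kept.
    """
    if min_reads <= 0:
        raise ValueError("min_reads must be positive")
    totals = series.total_reads()
    keep = totals >= min_reads
    removed = totals.index[~keep].tolist()
    if removed:
        logger.info("sample QC removed %d day(s): %s", len(removed), removed)
    if not keep.any():
        raise EmptySeriesError("sample QC removed every day")
    counts = series.counts.loc[keep]
    fractions = series.fractions.loc[keep] if series.fractions is not None else None
    return replace(series, counts=counts, fractions=fractions)


def read_metadata_log(path) -> list[MetadataSeries]:
    """Read a long-format ``date,variable,value[,category]`` CSV into one
    :class:`MetadataSeries` per variable (empty file -> empty list)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if len(df) == 0:
        return []
    required = {"date", "variable", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata log must have columns {sorted(required)}")
    if df.duplicated(subset=["date", "variable"]).any():
        raise ValueError("duplicate (date, variable) rows in metadata log")
    df["date"] = _parse_day_columns(df["date"])
    out = []
    for name, grp in df.groupby("variable", sort=True):
        values = pd.Series(
            grp["value"].to_numpy(dtype=float),
            index=pd.Index(grp["date"].to_numpy(), name="day"),
        )
        category = str(grp["category"].iloc[0]) if "category" in grp else ""
        out.append(MetadataSeries(name=str(name), values=values, category=category))
    return out


def read_tree(path) -> TreeNode:
    """Read a rooted Newick phylogeny whose tips are OTU ids."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError("negative branch length in phylogeny")
    return tree
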