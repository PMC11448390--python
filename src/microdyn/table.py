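"""Feature-table and tree I/O.

The universal input of the pipeline is a daily ASV count table: rows are
integer day indices (days since the first sample), columns are ASV
identifiers, cells are non-negative read counts.  Missing days are
simply absent rows; they are preserved on read and filled later by
interpolation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import skbio


@dataclasses.dataclass
class AbundanceSeriesTable:
    """A daily-resolved ASV count matrix for one subject.

    Parameters
    ----------
    data : pandas.DataFrame
        Counts, indexed by integer day, one column per ASV.
    subject_id : str
        Free-text subject label.
    interpolated_days : frozenset of int
        Days whose rows were produced by interpolation rather than
        observation.
    is_rarefied : bool
        Whether every row has been subsampled to a common depth.
    """

    data: pd.DataFrame
    subject_id: str = "subject"
    interpolated_days: frozenset = frozenset()
    is_rarefied: bool = False

    def __post_init__(self) -> None:
        df = self.data
        if df.empty:
            raise ValueError("no data rows")
        if not df.index.is_monotonic_increasing or df.index.has_duplicates:
            raise ValueError("day index must be strictly increasing")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate ASV ids: {dupes}")
        values = df.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("counts contain non-finite values")
        if (values < 0).any():
            day, col = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at day {df.index[day]}, ASV {df.columns[col]!r}"
            )

    # -- convenience ---------------------------------------------------
    @property
    def days(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def is_contiguous(self) -> bool:
        d = self.days
        return len(d) == d[-1] - d[0] + 1

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AbundanceSeriesTable({self.subject_id!r}, "
            f"{self.data.shape[0]} days x {self.data.shape[1]} ASVs, "
            f"rarefied={self.is_rarefied})"
        )

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "day"
        out.to_csv(path, sep="\t")


def read_feature_table(
    path: str | Path, fmt: str = "tsv", subject_id: str | None = None
) -> AbundanceSeriesTable:
    """Read a daily ASV count table from TSV or BIOM-JSON.

    TSV layout: first column ``day`` (integer), remaining columns one
    per ASV.  BIOM-JSON: the standard sparse/dense JSON dialect with
    integer-parseable sample ids (days).

    Missing-day gaps are preserved, not filled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tsv":
        df = _read_tsv(path)
    elif fmt in ("biom", "biom-json"):
        df = _read_biom_json(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    df = df.sort_index()
    sums = df.sum(axis=1).to_numpy()
    rarefied = bool(len(sums) and np.allclose(sums, sums[0]))
    return AbundanceSeriesTable(
        df, subject_id=subject_id or path.stem, is_rarefied=rarefied
    )


def _read_tsv(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    asv_header = header[1:]
    if len(set(asv_header)) != len(asv_header):
        dupes = sorted({a for a in asv_header if asv_header.count(a) > 1})
        raise ValueError(f"duplicate ASV ids: {dupes}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError("no data rows") from None
    df.index.name = None
    if df.empty:
        raise ValueError("no data rows")
    try:
        df.index = df.index.astype(int)
    except (TypeError, ValueError):
        raise ValueError(f"day labels must be integers, got {df.index[:3].tolist()}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            bad_day = df.index[coerced.isna()][0]
            raise ValueError(f"non-numeric cell at day {bad_day}, column {col!r}")
        df[col] = coerced
    return df


def _read_biom_json(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        biom = json.load(fh)
    asv_ids = [row["id"] for row in biom["rows"]]
    day_labels = [col["id"] for col in biom["columns"]]
    try:
        days = [int(d) for d in day_labels]
    except ValueError:
        raise ValueError(f"sample ids must parse as integer days: {day_labels[:3]}")
    shape = (len(asv_ids), len(days))
    mat = np.zeros(shape)
    if biom.get("matrix_type") == "sparse":
        for i, j, v in biom["data"]:
            mat[int(i), int(j)] = v
    else:
        mat = np.asarray(biom["data"], dtype=float)
    # BIOM stores observations x samples; we want days x ASVs
    return pd.DataFrame(mat.T, index=days, columns=asv_ids)


def align_daily_index(table: AbundanceSeriesTable) -> tuple[AbundanceSeriesTable, list[int]]:
    """Return the table unchanged plus the sorted list of missing days.

    A day is missing if it lies strictly between the first and last
    observed day but has no row.
    """
    days = table.days
    if len(days) < 2:
        raise ValueError("need at least 2 days to define an interval")
    full = set(range(int(days[0]), int(days[-1]) + 1))
    missing = sorted(full - set(int(d) for d in days))
    return table, missing


def read_tree(path: str | Path) -> skbio.TreeNode:
    """Read a rooted newick tree whose tips are ASV identifiers.

    Raises if any branch length is missing/negative or if tip labels
    collide; those would silently corrupt Faith's PD downstream.
    """
    tree = skbio.TreeNode.read(str(path))
    seen: set[str] = set()
    for node in tree.traverse(include_self=False):
        if node.length is None:
            name = node.name or "<internal>"
            raise ValueError(f"branch above {name!r} has no length")
        if node.length < 0:
            raise ValueError(f"negative branch length above {node.name!r}")
    for tip in tree.tips():
        if tip.name in seen:
            raise ValueError(f"duplicate tip label {tip.name!r}")
        seen.add(tip.name)
    return tree


def concat_tables(tables: Sequence[AbundanceSeriesTable]) -> pd.DataFrame:
    """Stack several subjects' tables on a union of ASV columns.

    Used for between-subject ordination; rows are (subject, day).
    """
    frames = []
    for t in tables:
        df = t.data.copy()
        df.index = pd.MultiIndex.from_product(
            [[t.subject_id], df.index], names=["subject", "day"]
        )
        frames.append(df)
    return pd.concat(frames).fillna(0.0)
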