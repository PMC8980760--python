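"""Data model and delimited-text I/O for per-nucleus crossover counts.

The universal currency of the pipeline is the :class:`NucleusMatrix`: a dense
nuclei x chromosomes grid of non-negative integer crossover (CO) counts, one
row per meiotic nucleus (spermatocyte, oocyte "tetrad", gamete or progeny),
optionally paired with a same-shaped grid of chromosome axis lengths in
microns.  Two plain-text layouts are supported:

* ``wide``  -- one row per nucleus; one column per chromosome (axis lengths,
  when present, in parallel ``axis:<chromosome>`` columns);
* ``long``  -- one row per bivalent with columns
  ``nucleus_id, chromosome_id, co_count, axis_length_um``.

Nuclei that do not cover every chromosome are dropped (and counted in a log
message) rather than imputed: every downstream statistic needs complete rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TableParseError, ValidationError

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["nucleus_id", "chromosome_id", "co_count", "axis_length_um"]
AXIS_PREFIX = "axis:"

Layout = Literal["wide", "long"]


@dataclass(frozen=True)
class BivalentRecord:
    """One bivalent: the CO count (MLH1 foci or sequencing-called COs) on one
    chromosome pair in one nucleus, optionally with its axis length (um)."""

    nucleus_id: str
    chromosome_id: str
    co_count: int
    axis_length: float | None = None

    def __post_init__(self) -> None:
        if self.co_count < 0 or int(self.co_count) != self.co_count:
            raise ValidationError(
                f"co_count must be a non-negative integer, got {self.co_count!r}"
            )
        if self.axis_length is not None and not self.axis_length > 0:
            raise ValidationError(
                f"axis_length must be positive, got {self.axis_length!r}"
            )


@dataclass
class NucleusMatrix:
    """Dense per-nucleus, per-chromosome CO counts (+ optional axis lengths).

    Parameters
    ----------
    co_counts
        DataFrame indexed by nucleus id with one integer column per
        chromosome.  No missing cells are allowed.
    axis_lengths
        Optional DataFrame of positive axis lengths (microns) with the same
        index and columns as ``co_counts``.
    sex_label
        Free-text metadata (e.g. ``"male"``, ``"female-like"``).
    """

    co_counts: pd.DataFrame
    axis_lengths: pd.DataFrame | None = None
    sex_label: str = ""

    def __post_init__(self) -> None:
        c = self.co_counts
        if c.isna().any().any():
            raise ValidationError("co_counts contains missing cells")
        vals = c.to_numpy()
        if vals.size and (
            (vals < 0).any() or not np.allclose(vals, np.round(vals))
        ):
            raise ValidationError("co_counts must be non-negative integers")
        self.co_counts = c.astype(int)
        if self.axis_lengths is not None:
            a = self.axis_lengths
            if list(a.index) != list(c.index) or list(a.columns) != list(c.columns):
                raise ValidationError(
                    "axis_lengths must share index and columns with co_counts"
                )
            if a.isna().any().any() or (a.size and (a.to_numpy() <= 0).any()):
                raise ValidationError("axis_lengths must be positive and complete")
            self.axis_lengths = a.astype(float)

    # -- convenience accessors -------------------------------------------------

    @property
    def nucleus_ids(self) -> list[str]:
        return [str(i) for i in self.co_counts.index]

    @property
    def chromosome_ids(self) -> list[str]:
        return [str(c) for c in self.co_counts.columns]

    @property
    def n_nuclei(self) -> int:
        return self.co_counts.shape[0]

    @property
    def n_chromosomes(self) -> int:
        return self.co_counts.shape[1]

    def totals(self) -> np.ndarray:
        """Per-nucleus total CO count."""
        return self.co_counts.to_numpy().sum(axis=1)

    def metric_frame(self, metric: Literal["co", "axis"]) -> pd.DataFrame:
        if metric == "co":
            return self.co_counts
        if metric == "axis":
            if self.axis_lengths is None:
                raise ConfigurationError("matrix has no axis-length data")
            return self.axis_lengths
        raise ConfigurationError(f"unknown metric {metric!r}")

    def drop_chromosomes(self, chromosome_ids: Sequence[str]) -> "NucleusMatrix":
        """Return a copy without the given chromosomes (e.g. sex-linked)."""
        keep = [c for c in self.co_counts.columns if str(c) not in set(chromosome_ids)]
        axis = self.axis_lengths[keep] if self.axis_lengths is not None else None
        return NucleusMatrix(self.co_counts[keep].copy(),
                             axis.copy() if axis is not None else None,
                             self.sex_label)

    def __eq__(self, other: object) -> bool:  # value equality for round-trips
        if not isinstance(other, NucleusMatrix):
            return NotImplemented
        if not self.co_counts.equals(other.co_counts):
            return False
        if (self.axis_lengths is None) != (other.axis_lengths is None):
            return False
        if self.axis_lengths is not None:
            if not np.allclose(self.axis_lengths.to_numpy(),
                               other.axis_lengths.to_numpy()):
                return False
            if list(self.axis_lengths.columns) != list(other.axis_lengths.columns):
                return False
        return True


@dataclass
class ChromosomePool:
    """All bivalents of one chromosome, pooled across nuclei and sorted
    ascending (stably) by CO count or axis length."""

    chromosome_id: str
    sorted_values: list[tuple[int, float | None]] = field(default_factory=list)

    @property
    def co_counts(self) -> np.ndarray:
        return np.array([v[0] for v in self.sorted_values], dtype=int)

    @property
    def axis_lengths(self) -> np.ndarray | None:
        if any(v[1] is None for v in self.sorted_values):
            return None
        return np.array([v[1] for v in self.sorted_values], dtype=float)

    def __len__(self) -> int:
        return len(self.sorted_values)


# -- I/O ----------------------------------------------------------------------


def _detect_delimiter(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"comma": ",", "tab": "\t", ",": ",", "\t": "\t"}.get(dialect, dialect)
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_nucleus_table(
    path: str | Path,
    layout: Layout = "wide",
    dialect: str | None = None,
    sex_label: str = "",
) -> NucleusMatrix:
    """Read a delimited nucleus table into a validated :class:`NucleusMatrix`.

    Nuclei missing any chromosome (long layout) are dropped; the number
    dropped is logged at WARNING level.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_delimiter(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableParseError(f"cannot parse {path}: {exc}") from exc

    if layout == "long":
        return _from_long(df, path, sex_label)
    if layout == "wide":
        return _from_wide(df, path, sex_label)
    raise ConfigurationError(f"unknown layout {layout!r}")


def _parse_count(raw: str, path: Path, line: int) -> int:
    try:
        val = float(raw)
    except ValueError:
        raise TableParseError(f"{path}:{line}: non-numeric CO count {raw!r}") from None
    if val < 0 or val != int(val):
        raise ValidationError(f"{path}:{line}: CO count must be a non-negative "
                              f"integer, got {raw!r}")
    return int(val)


def _from_long(df: pd.DataFrame, path: Path, sex_label: str) -> NucleusMatrix:
    missing = [c for c in LONG_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: long layout lacks columns {missing}")
    has_axis = "axis_length_um" in df.columns and (df["axis_length_um"] != "").any()
    counts = {}
    axes = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        nid, cid = str(row.nucleus_id), str(row.chromosome_id)
        counts[(nid, cid)] = _parse_count(str(row.co_count), path, i)
        if has_axis:
            raw = str(getattr(row, "axis_length_um", ""))
            if raw == "":
                raise TableParseError(f"{path}:{i}: missing axis_length_um")
            a = float(raw)
            if a <= 0:
                raise ValidationError(f"{path}:{i}: axis length must be > 0")
            axes[(nid, cid)] = a

    cseries = pd.Series(counts)
    wide = cseries.unstack()
    # preserve first-appearance order of ids
    nuc_order = list(dict.fromkeys(str(v) for v in df["nucleus_id"]))
    chrom_order = list(dict.fromkeys(str(v) for v in df["chromosome_id"]))
    wide = wide.reindex(index=nuc_order, columns=chrom_order)
    complete = wide.dropna()
    n_dropped = wide.shape[0] - complete.shape[0]
    if n_dropped:
        logger.warning("dropped %d nuclei with incomplete chromosome coverage",
                       n_dropped)
    axis_df = None
    if has_axis:
        axis_df = (pd.Series(axes).unstack()
                   .reindex(index=complete.index, columns=chrom_order))
    return NucleusMatrix(complete, axis_df, sex_label)


def _from_wide(df: pd.DataFrame, path: Path, sex_label: str) -> NucleusMatrix:
    if df.shape[1] < 2:
        raise TableParseError(f"{path}: wide layout needs an id column plus "
                              "at least one chromosome column")
    idcol = df.columns[0]
    chrom_cols = [c for c in df.columns[1:] if not c.startswith(AXIS_PREFIX)]
    axis_cols = [c for c in df.columns[1:] if c.startswith(AXIS_PREFIX)]
    counts = pd.DataFrame(index=pd.Index(df[idcol].astype(str), name="nucleus_id"))
    for c in chrom_cols:
        counts[c] = [
            _parse_count(str(v), path, i + 2) for i, v in enumerate(df[c])
        ]
    axis_df = None
    if axis_cols:
        expected = [AXIS_PREFIX + c for c in chrom_cols]
        if axis_cols != expected:
            raise TableParseError(
                f"{path}: axis columns {axis_cols} do not mirror chromosome "
                f"columns (expected {expected})")
        axis_df = pd.DataFrame(
            {c: df[AXIS_PREFIX + c].astype(float).to_numpy() for c in chrom_cols},
            index=counts.index,
        )
    return NucleusMatrix(counts, axis_df, sex_label)


def write_nucleus_table(
    matrix: NucleusMatrix,
    path: str | Path,
    layout: Layout = "wide",
    dialect: str | None = None,
) -> None:
    """Write ``matrix`` so that :func:`read_nucleus_table` round-trips it."""
    path = Path(path)
    sep = _detect_delimiter(path, dialect)
    if layout == "wide":
        out = matrix.co_counts.copy()
        out.index.name = "nucleus_id"
        if matrix.axis_lengths is not None:
            for c in matrix.co_counts.columns:
                out[AXIS_PREFIX + str(c)] = matrix.axis_lengths[c]
        out.to_csv(path, sep=sep)
    elif layout == "long":
        rows = []
        has_axis = matrix.axis_lengths is not None
        for nid in matrix.co_counts.index:
            for cid in matrix.co_counts.columns:
                row = {
                    "nucleus_id": nid,
                    "chromosome_id": cid,
                    "co_count": int(matrix.co_counts.at[nid, cid]),
                }
                if has_axis:
                    row["axis_length_um"] = float(matrix.axis_lengths.at[nid, cid])
                rows.append(row)
        cols = LONG_COLUMNS if has_axis else LONG_COLUMNS[:3]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)
    else:
        raise ConfigurationError(f"unknown layout {layout!r}")


def pool_bivalents(
    matrix: NucleusMatrix, key: Literal["co", "axis"] = "co"
) -> list[ChromosomePool]:
    """Pool each chromosome's bivalents across nuclei, sorted ascending.

    Sorting is stable: ties keep their original nucleus order.  With
    ``key="axis"`` the (count, axis) pairs are ordered by axis length.
    """
    if key == "axis" and matrix.axis_lengths is None:
        raise ConfigurationError('key="axis" requires axis-length data')
    if key not in ("co", "axis"):
        raise ConfigurationError(f"unknown pool key {key!r}")
    pools = []
    for cid in matrix.co_counts.columns:
        cos = matrix.co_counts[cid].to_numpy()
        axes = (matrix.axis_lengths[cid].to_numpy()
                if matrix.axis_lengths is not None else [None] * len(cos))
        pairs = list(zip(cos.tolist(), list(axes)))
        keyfun = (lambda p: p[0]) if key == "co" else (lambda p: p[1])
        pairs.sort(key=keyfun)  # timsort is stable
        pools.append(ChromosomePool(str(cid), pairs))
    return pools
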