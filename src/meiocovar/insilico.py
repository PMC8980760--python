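"""Artificial ("in silico") nucleus sets with tunable CO correlation.

Bivalents are pooled per chromosome across all nuclei and sorted ascending.
Re-assembling nuclei by rank — nucleus *i* gets the *i*-th smallest bivalent
of every chromosome — produces the maximal-correlation configuration.
Partially re-permuting a fraction *f* of each sorted pool then degrades the
correlation smoothly from maximal (f=0) to independence (f=1), without ever
changing any chromosome's marginal distribution (so the intrinsic variance
is invariant along the whole sweep).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .covariation import (
    CovariationSummary,
    PartitionSweepResult,
    VariabilityIndex,
    partition_sweep,
    variability_index,
    variance_decomposition,
)
from .errors import ConfigurationError, ValidationError
from .nucleus_data import ChromosomePool, NucleusMatrix, pool_bivalents

ShuffleMode = Literal["entries", "pools"]


@dataclass(frozen=True)
class SweepRecord:
    """One (shuffle fraction, replicate) point of a correlation sweep."""

    shuffle_fraction: float
    replicate: int
    mean_r: float
    r_se: float
    summary: CovariationSummary
    variability: VariabilityIndex


@dataclass(frozen=True)
class CorrelationSeries:
    """All records of a correlation sweep, with its seed and replicate count."""

    records: tuple[SweepRecord, ...]
    seed: int | None
    replicates: int

    def mean_by_fraction(self, attr: str = "mean_r") -> dict[float, float]:
        """Replicate-averaged value of a record attribute per fraction."""
        out: dict[float, list[float]] = {}
        for rec in self.records:
            out.setdefault(rec.shuffle_fraction, []).append(_get(rec, attr))
        return {f: float(np.mean(v)) for f, v in sorted(out.items())}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            rows.append({
                "shuffle_fraction": rec.shuffle_fraction,
                "replicate": rec.replicate,
                "mean_r": rec.mean_r,
                "r_se": rec.r_se,
                "total_variance": rec.summary.total_variance,
                "intrinsic_variance": rec.summary.intrinsic_variance,
                "covariance": rec.summary.covariance,
                "covariance_contribution": rec.summary.covariance_contribution,
                "mean_total": rec.summary.mean_total,
                "variability_index": rec.variability.index,
            })
        return pd.DataFrame(rows)


def _get(rec: SweepRecord, attr: str) -> float:
    if hasattr(rec, attr):
        return float(getattr(rec, attr))
    if hasattr(rec.summary, attr):
        return float(getattr(rec.summary, attr))
    if attr == "variability_index":
        return float(rec.variability.index)
    raise AttributeError(attr)


def assemble_sorted(pools: Sequence[ChromosomePool]) -> NucleusMatrix:
    """Assemble pseudo-nuclei from sorted chromosome pools by rank.

    Pseudo-nucleus *i* receives the *i*-th smallest bivalent of every
    chromosome, yielding co-monotone columns (the maximal-correlation set).
    """
    if not pools:
        raise ValidationError("no chromosome pools given")
    n = len(pools[0])
    if any(len(p) != n for p in pools):
        raise ValidationError("chromosome pools have unequal lengths")
    counts = pd.DataFrame(
        {p.chromosome_id: p.co_counts for p in pools},
        index=pd.Index([f"pseudo{i}" for i in range(n)], name="nucleus_id"),
    )
    axes = [p.axis_lengths for p in pools]
    axis_df = None
    if all(a is not None for a in axes):
        axis_df = pd.DataFrame(
            {p.chromosome_id: a for p, a in zip(pools, axes)},
            index=counts.index,
        )
    return NucleusMatrix(counts, axis_df, sex_label="in-silico")


def partial_shuffle(
    sorted_matrix: NucleusMatrix,
    f: float,
    seed: int | np.random.Generator | None = None,
    mode: ShuffleMode = "entries",
) -> NucleusMatrix:
    """Degrade column co-monotonicity by re-permuting a fraction of entries.

    ``mode="entries"`` (default): independently for each chromosome column a
    uniformly chosen fraction *f* of its rows are re-permuted among
    themselves.  ``mode="pools"``: a fraction *f* of whole chromosome columns
    are fully re-permuted.  Either way every column's multiset of values —
    and hence its variance — is preserved exactly.  Axis lengths, when
    present, travel with their bivalent.
    """
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError(f"shuffle fraction must be in [0, 1], got {f}")
    rng = np.random.default_rng(seed)
    counts = sorted_matrix.co_counts.to_numpy().copy()
    axes = (sorted_matrix.axis_lengths.to_numpy().copy()
            if sorted_matrix.axis_lengths is not None else None)
    n, m = counts.shape

    if mode == "entries":
        k = int(round(f * n))
        for j in range(m):
            if k < 2:
                continue
            rows = rng.choice(n, size=k, replace=False)
            perm = rng.permutation(k)
            counts[rows, j] = counts[rows[perm], j]
            if axes is not None:
                axes[rows, j] = axes[rows[perm], j]
    elif mode == "pools":
        kcols = int(round(f * m))
        cols = rng.choice(m, size=kcols, replace=False)
        for j in cols:
            perm = rng.permutation(n)
            counts[:, j] = counts[perm, j]
            if axes is not None:
                axes[:, j] = axes[perm, j]
    else:
        raise ConfigurationError(f"unknown shuffle mode {mode!r}")

    counts_df = pd.DataFrame(counts, index=sorted_matrix.co_counts.index,
                             columns=sorted_matrix.co_counts.columns)
    axis_df = None
    if axes is not None:
        axis_df = pd.DataFrame(axes, index=counts_df.index,
                               columns=counts_df.columns)
    return NucleusMatrix(counts_df, axis_df, sorted_matrix.sex_label)


def correlation_sweep(
    matrix: NucleusMatrix,
    fractions: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    replicates: int = 10,
    seed: int | None = None,
    pool_key: Literal["co", "axis"] = "co",
    shuffle_mode: ShuffleMode = "entries",
    max_partitions: int = 200,
) -> CorrelationSeries:
    """Sweep the in-silico construction over shuffle fractions.

    For every fraction and replicate: pool -> assemble_sorted ->
    partial_shuffle(f) -> matched-group correlation (partition sweep),
    variance decomposition and variability index.  Per-replicate RNG streams
    derive from the master seed.
    """
    if len(set(fractions)) != len(fractions):
        raise ConfigurationError("shuffle fractions must be distinct")
    pools = pool_bivalents(matrix, key=pool_key)
    base = assemble_sorted(pools)
    master = np.random.default_rng(seed)
    records = []
    for f in fractions:
        for rep in range(replicates):
            rng = np.random.default_rng(master.integers(2**31))
            shuffled = partial_shuffle(base, f, seed=rng, mode=shuffle_mode)
            sweep = partition_sweep(shuffled, max_partitions=max_partitions,
                                    seed=rng)
            summary = variance_decomposition(shuffled)
            vi = variability_index(shuffled, null_mode="analytic")
            records.append(SweepRecord(float(f), rep, sweep.mean_r, sweep.se,
                                       summary, vi))
    return CorrelationSeries(tuple(records), seed, replicates)
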