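"""Core per-nucleus crossover covariation statistics.

Covariation — the tendency of CO numbers on different chromosomes of the same
nucleus to rise and fall together — is quantified three ways:

1. **Matched-group correlation**: the Pearson correlation, across nuclei,
   between the summed CO counts of two balanced chromosome groups (e.g. odd-
   vs even-numbered chromosomes), optionally averaged over many balanced
   partitions.
2. **Variance decomposition**: the variance of per-nucleus totals splits as
   ``total = intrinsic + covariance`` where the intrinsic variance is the sum
   of per-chromosome variances (what the total variance would be if
   chromosomes were independent) and the covariance term collects all
   between-chromosome covariances.  ``covariance / total`` is the covariance
   contribution.  Population (divide-by-n) variances are used throughout so
   the identity is exact.
3. **Variability index**: normals are moment-fitted to the observed
   per-nucleus totals and to the totals expected under chromosome
   independence; the index is the summed excess fraction of nuclei in the
   hyper-CO and hypo-CO tails of the observed fit relative to the null fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, UndefinedCorrelationError, ValidationError
from .nucleus_data import NucleusMatrix

logger = logging.getLogger(__name__)


# -- domain types -------------------------------------------------------------


@dataclass(frozen=True)
class GroupPartition:
    """A balanced split of the chromosomes into two disjoint groups.

    Group sizes differ by at most one (the convention when the chromosome
    number is odd).
    """

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if a & b:
            raise ValidationError("partition groups overlap")
        if abs(len(a) - len(b)) > 1:
            raise ValidationError("partition groups differ by more than one")

    def validate_against(self, chromosome_ids: Sequence[str]) -> None:
        if set(self.group_a) | set(self.group_b) != set(chromosome_ids):
            raise ValidationError("partition does not cover all chromosomes")

    def canonical(self) -> frozenset:
        return frozenset((frozenset(self.group_a), frozenset(self.group_b)))


@dataclass(frozen=True)
class CovariationSummary:
    """Variance decomposition of per-nucleus CO totals."""

    total_variance: float
    intrinsic_variance: float
    covariance: float
    covariance_contribution: float
    mean_total: float
    cv_total: float
    per_chromosome_variance: dict[str, float]

    @property
    def X(self) -> float:
        """Mean per-nucleus CO count (the field's conventional symbol)."""
        return self.mean_total


@dataclass(frozen=True)
class VariabilityIndex:
    """Excess hyper-/hypo-CO nucleus fractions from two fitted normals."""

    data_fit: tuple[float, float]
    null_fit: tuple[float, float]
    hyper_fraction: float
    hypo_fraction: float

    @property
    def index(self) -> float:
        return self.hyper_fraction + self.hypo_fraction


@dataclass(frozen=True)
class PartitionSweepResult:
    """Mean and SE of the matched-group correlation over balanced partitions."""

    mean_r: float
    se: float
    n_partitions: int
    enumerated: bool
    correlations: tuple[float, ...]


# -- elementary statistics ----------------------------------------------------


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson's linear correlation coefficient.

    Raises :class:`UndefinedCorrelationError` for vectors shorter than 3 or
    with zero variance rather than silently returning 0 or NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson requires two equal-length 1-d vectors")
    if x.size < 3:
        raise UndefinedCorrelationError(f"need >= 3 points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    return float(stats.pearsonr(x, y).statistic)


def group_totals(matrix: NucleusMatrix, partition: GroupPartition
                 ) -> tuple[np.ndarray, np.ndarray]:
    partition.validate_against(matrix.chromosome_ids)
    a = matrix.co_counts[list(partition.group_a)].to_numpy().sum(axis=1)
    b = matrix.co_counts[list(partition.group_b)].to_numpy().sum(axis=1)
    return a, b


def grouped_correlation(matrix: NucleusMatrix, partition: GroupPartition) -> float:
    """Pearson r between the per-nucleus CO totals of two chromosome groups."""
    a, b = group_totals(matrix, partition)
    return pearson(a, b)


def odd_even_partition(chromosome_ids: Sequence[str]) -> GroupPartition:
    """Split chromosomes into odd- and even-numbered groups.

    Chromosome numbers are parsed as the trailing integer of each id
    (``chr17`` -> 17).  Fails loudly on unparseable ids.
    """
    odd, even = [], []
    for cid in chromosome_ids:
        digits = ""
        for ch in reversed(str(cid)):
            if ch.isdigit():
                digits = ch + digits
            else:
                break
        if not digits:
            raise ConfigurationError(
                f"cannot parse a chromosome number from id {cid!r}")
        (odd if int(digits) % 2 else even).append(str(cid))
    if abs(len(odd) - len(even)) > 1:
        raise ConfigurationError(
            "odd/even split is unbalanced for these chromosome ids; "
            "supply an explicit GroupPartition instead")
    return GroupPartition(tuple(odd), tuple(even))


# -- balanced partitions ------------------------------------------------------


def n_balanced_partitions(n: int) -> int:
    """Number of distinct balanced two-group partitions of n chromosomes."""
    k = (n + 1) // 2
    count = math.comb(n, k)
    return count // 2 if n % 2 == 0 else count


def balanced_partitions(chromosome_ids: Sequence[str]) -> Iterable[GroupPartition]:
    """Enumerate every distinct balanced partition.

    For an even number of chromosomes, the first chromosome is anchored in
    group A so each unordered partition appears exactly once.
    """
    ids = [str(c) for c in chromosome_ids]
    n = len(ids)
    if n < 2:
        raise ConfigurationError("need at least 2 chromosomes to partition")
    k = (n + 1) // 2
    if n % 2 == 0:
        first, rest = ids[0], ids[1:]
        for combo in combinations(rest, k - 1):
            a = (first, *combo)
            b = tuple(c for c in ids if c not in set(a))
            yield GroupPartition(a, b)
    else:
        for combo in combinations(ids, k):
            a = tuple(combo)
            b = tuple(c for c in ids if c not in set(a))
            yield GroupPartition(a, b)


def sample_balanced_partitions(
    chromosome_ids: Sequence[str], n_sample: int, rng: np.random.Generator
) -> list[GroupPartition]:
    """Uniformly sample ``n_sample`` distinct balanced partitions."""
    ids = [str(c) for c in chromosome_ids]
    n = len(ids)
    k = (n + 1) // 2
    seen: set[frozenset] = set()
    out: list[GroupPartition] = []
    while len(out) < n_sample:
        a = tuple(sorted(rng.choice(ids, size=k, replace=False).tolist()))
        b = tuple(c for c in ids if c not in set(a))
        p = GroupPartition(a, b)
        key = p.canonical()
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def partition_sweep(
    matrix: NucleusMatrix,
    max_partitions: int = 10_000,
    seed: int | np.random.Generator | None = None,
    full_enumeration_limit: int = 16,
) -> PartitionSweepResult:
    """Mean +- SE of the matched-group correlation over balanced partitions.

    All balanced partitions are enumerated when the chromosome count is at
    most ``full_enumeration_limit`` and their number does not exceed
    ``max_partitions``; otherwise ``max_partitions`` distinct partitions are
    sampled with the given seed.
    """
    ids = matrix.chromosome_ids
    n = len(ids)
    total = n_balanced_partitions(n)
    enumerated = n <= full_enumeration_limit and total <= max_partitions
    if enumerated:
        parts: Iterable[GroupPartition] = balanced_partitions(ids)
    else:
        rng = np.random.default_rng(seed)
        parts = sample_balanced_partitions(ids, min(max_partitions, total), rng)
    counts = matrix.co_counts.to_numpy(dtype=float)
    col_of = {c: i for i, c in enumerate(ids)}
    rs = []
    for p in parts:
        a = counts[:, [col_of[c] for c in p.group_a]].sum(axis=1)
        b = counts[:, [col_of[c] for c in p.group_b]].sum(axis=1)
        rs.append(pearson(a, b))
    rs_arr = np.array(rs)
    se = float(rs_arr.std(ddof=1) / np.sqrt(rs_arr.size)) if rs_arr.size > 1 else 0.0
    return PartitionSweepResult(float(rs_arr.mean()), se, rs_arr.size,
                                enumerated, tuple(rs))


# -- variance decomposition ---------------------------------------------------


def variance_decomposition(matrix: NucleusMatrix) -> CovariationSummary:
    """Decompose the variance of per-nucleus CO totals.

    ``covariance = total - intrinsic``, equal to the sum of all off-diagonal
    entries of the chromosome covariance matrix.  Population variances
    (ddof=0) keep the identity exact.
    """
    if matrix.n_nuclei < 2:
        raise ValidationError("variance decomposition needs >= 2 nuclei")
    counts = matrix.co_counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    total_var = float(totals.var(ddof=0))
    per_chrom = counts.var(axis=0, ddof=0)
    intrinsic = float(per_chrom.sum())
    cov = total_var - intrinsic
    contribution = cov / total_var if total_var > 0 else float("nan")
    mean_total = float(totals.mean())
    cv = float(totals.std(ddof=0) / mean_total) if mean_total > 0 else float("nan")
    return CovariationSummary(
        total_variance=total_var,
        intrinsic_variance=intrinsic,
        covariance=cov,
        covariance_contribution=contribution,
        mean_total=mean_total,
        cv_total=cv,
        per_chromosome_variance={
            c: float(v) for c, v in zip(matrix.chromosome_ids, per_chrom)
        },
    )


def per_chromosome_cv(matrix: NucleusMatrix,
                      metric: Literal["co", "axis"] = "co") -> dict[str, float]:
    """Coefficient of variation (sd/mean, population sd) per chromosome."""
    frame = matrix.metric_frame(metric)
    out = {}
    for cid in frame.columns:
        col = frame[cid].to_numpy(dtype=float)
        mean = col.mean()
        if mean <= 0:
            raise ValidationError(f"chromosome {cid!r} has non-positive mean; "
                                  "CV undefined")
        out[str(cid)] = float(col.std(ddof=0) / mean)
    return out


# -- variability index --------------------------------------------------------


def _normal_crossings(m1: float, s1: float, m2: float, s2: float) -> list[float]:
    """Solve f1(x) = f2(x) for two normal densities (0, 1 or 2 roots)."""
    if np.isclose(s1, s2):
        if np.isclose(m1, m2):
            return []
        return [(m1 + m2) / 2.0]
    a = 1.0 / s2**2 - 1.0 / s1**2
    b = 2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m2**2 / s2**2 - m1**2 / s1**2 + 2.0 * math.log(s2 / s1)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return []
    r = math.sqrt(disc)
    return sorted([(-b - r) / (2 * a), (-b + r) / (2 * a)])


def _excess_fractions(data_fit: tuple[float, float],
                      null_fit: tuple[float, float]) -> tuple[float, float]:
    """Integrate max(f_data - f_null, 0) over the lower (hypo) and upper
    (hyper) tails, split at the density crossings."""
    (md, sd), (mn, sn) = data_fit, null_fit
    if sd <= 0 or sn <= 0:
        raise ValidationError("degenerate (zero-sd) normal fit")
    fd = stats.norm(md, sd)
    fn = stats.norm(mn, sn)

    def pos_excess(lo: float, hi: float) -> float:
        """Integral of (f_data - f_null) over [lo, hi], floored at 0."""
        v = (fd.cdf(hi) - fd.cdf(lo)) - (fn.cdf(hi) - fn.cdf(lo))
        return max(v, 0.0)

    crossings = _normal_crossings(md, sd, mn, sn)
    if not crossings:  # identical fits
        return 0.0, 0.0
    if len(crossings) == 1:
        x = crossings[0]
        return pos_excess(-np.inf, x), pos_excess(x, np.inf)
    lo, hi = crossings
    if sd > sn:  # data broader than null: excess lies in the two tails
        return pos_excess(-np.inf, lo), pos_excess(hi, np.inf)
    # data narrower: excess lies between the crossings; split at the data mean
    mid = min(max(md, lo), hi)
    return pos_excess(lo, mid), pos_excess(mid, hi)


def variability_index(
    matrix: NucleusMatrix,
    null_mode: Literal["analytic", "permutation"] = "analytic",
    n_null: int = 20,
    seed: int | np.random.Generator | None = None,
) -> VariabilityIndex:
    """Summed excess of hyper- and hypo-CO nuclei over the independence null.

    A normal is moment-fitted to the observed per-nucleus totals; the null
    normal describes totals expected if chromosomes were independent —
    analytically (mean = observed mean, variance = intrinsic variance) or by
    pooling totals from ``n_null`` independent column-wise shuffles.
    """
    if matrix.n_nuclei < 30:
        logger.warning("variability_index on %d nuclei (< 30): fits are noisy",
                       matrix.n_nuclei)
    counts = matrix.co_counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    data_fit = (float(totals.mean()), float(totals.std(ddof=0)))
    if data_fit[1] == 0:
        raise ValidationError("observed totals have zero sd")

    if null_mode == "analytic":
        intrinsic = counts.var(axis=0, ddof=0).sum()
        null_fit = (data_fit[0], float(np.sqrt(intrinsic)))
    elif null_mode == "permutation":
        rng = np.random.default_rng(seed)
        pooled = []
        for _ in range(n_null):
            shuffled = np.column_stack(
                [rng.permutation(counts[:, j]) for j in range(counts.shape[1])]
            )
            pooled.append(shuffled.sum(axis=1))
        pooled_arr = np.concatenate(pooled)
        null_fit = (float(pooled_arr.mean()), float(pooled_arr.std(ddof=0)))
    else:
        raise ConfigurationError(f"unknown null_mode {null_mode!r}")
    if null_fit[1] == 0:
        raise ValidationError("null totals have zero sd")

    hypo, hyper = _excess_fractions(data_fit, null_fit)
    return VariabilityIndex(data_fit, null_fit, hyper, hypo)
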