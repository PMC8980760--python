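"""Chromosome-pair correlation analyses.

Correlations (across nuclei) of axis length or CO count between individual
chromosome pairs, plotted against the pair's mean metric, reveal whether
longer chromosomes are more coordinately regulated.  Uncertainty comes from
a percentile bootstrap over nuclei; the standard error is recovered from the
95% CI width as SE = dCI / 3.92 (the normal-theory conversion).  A linear
trend fit summarises the size -> correlation relationship, and a sweep-based
correspondence curve maps mean pairwise correlations onto the matched-group
correlation scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .covariation import pearson
from .errors import ConfigurationError, ValidationError
from .insilico import correlation_sweep
from .nucleus_data import NucleusMatrix

Metric = Literal["co", "axis"]

CI_TO_SE = 3.92  # width of a 95% normal CI in SE units (2 * 1.96)


@dataclass(frozen=True)
class PairResult:
    """Correlation of one chromosome pair with bootstrap uncertainty."""

    pair: tuple[str, str]
    metric: Metric
    mean_metric: float
    r: float
    ci95: tuple[float, float]

    @property
    def se(self) -> float:
        return (self.ci95[1] - self.ci95[0]) / CI_TO_SE


@dataclass(frozen=True)
class TrendFit:
    """Least-squares line of pair correlation against pair mean metric."""

    slope: float
    intercept: float
    trend_r: float

    def predict(self, mean_metric: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(mean_metric, dtype=float)


def _column_means(matrix: NucleusMatrix, metric: Metric) -> dict[str, float]:
    frame = matrix.metric_frame(metric)
    return {str(c): float(frame[c].mean()) for c in frame.columns}


def adjacent_pairs(matrix: NucleusMatrix, metric: Metric = "co"
                   ) -> list[tuple[str, str]]:
    """Pair each chromosome with its larger neighbour by mean metric.

    Chromosomes are sorted ascending by mean CO count or mean axis length
    (ties broken by id, lexicographically) and consecutive chromosomes are
    paired: (1,2), (2,3), ..., (n-1,n).
    """
    means = _column_means(matrix, metric)
    if len(means) < 2:
        raise ConfigurationError("need at least 2 chromosomes to pair")
    order = sorted(means, key=lambda c: (means[c], c))
    return [(order[i], order[i + 1]) for i in range(len(order) - 1)]


def pair_correlation(
    matrix: NucleusMatrix,
    pair: tuple[str, str],
    metric: Metric = "co",
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> PairResult:
    """Pearson r of a chromosome pair with a percentile-bootstrap 95% CI.

    Nuclei (rows) are resampled with replacement ``n_boot`` times; the CI is
    the 2.5/97.5 percentile of the bootstrap r distribution.  Degenerate
    (zero-variance) bootstrap resamples are redrawn.
    """
    frame = matrix.metric_frame(metric)
    x = frame[pair[0]].to_numpy(dtype=float)
    y = frame[pair[1]].to_numpy(dtype=float)
    r = pearson(x, y)
    rng = np.random.default_rng(seed)
    n = x.size
    boots = np.empty(n_boot)
    filled = 0
    attempts = 0
    while filled < n_boot:
        draw = min(n_boot - filled, n_boot)
        idx = rng.integers(0, n, size=(draw, n))
        bx, by = x[idx], y[idx]
        sx = bx.std(axis=1)
        sy = by.std(axis=1)
        ok = (sx > 0) & (sy > 0)
        mx = bx.mean(axis=1, keepdims=True)
        my = by.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rs = ((bx - mx) * (by - my)).mean(axis=1) / (sx * sy)
        good = rs[ok]
        take = good[: n_boot - filled]
        boots[filled:filled + take.size] = take
        filled += take.size
        attempts += 1
        if attempts > 50:
            raise ValidationError("bootstrap keeps producing degenerate resamples")
    lo, hi = np.percentile(boots, [2.5, 97.5])
    means = _column_means(matrix, metric)
    mean_metric = (means[str(pair[0])] + means[str(pair[1])]) / 2.0
    return PairResult((str(pair[0]), str(pair[1])), metric, mean_metric,
                      r, (float(lo), float(hi)))


def all_pairs_correlation(
    matrix: NucleusMatrix,
    metric: Metric = "co",
    n_boot: int = 2000,
    seed: int | None = None,
) -> list[PairResult]:
    """:func:`pair_correlation` over every unordered chromosome pair."""
    ids = matrix.chromosome_ids
    master = np.random.default_rng(seed)
    results = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rng = np.random.default_rng(master.integers(2**31))
            results.append(pair_correlation(matrix, (ids[i], ids[j]), metric,
                                            n_boot, rng))
    return results


def pairs_correlation(
    matrix: NucleusMatrix,
    pairs: Sequence[tuple[str, str]],
    metric: Metric = "co",
    n_boot: int = 2000,
    seed: int | None = None,
) -> list[PairResult]:
    """:func:`pair_correlation` over an explicit pair list (one seed stream)."""
    master = np.random.default_rng(seed)
    return [
        pair_correlation(matrix, p, metric, n_boot,
                         np.random.default_rng(master.integers(2**31)))
        for p in pairs
    ]


def trend_fit(results: Sequence[PairResult]) -> TrendFit:
    """OLS line of pair correlation r against pair mean metric.

    ``trend_r`` is the Pearson correlation of the scatter (the "R" printed
    on size-vs-correlation panels).
    """
    if len(results) < 3:
        raise ConfigurationError("trend fit needs >= 3 pair results")
    x = np.array([p.mean_metric for p in results], dtype=float)
    y = np.array([p.r for p in results], dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("all pairs share one mean metric; trend undefined")
    slope, intercept = np.polyfit(x, y, 1)
    r = pearson(x, y) if np.ptp(y) > 0 else 0.0
    return TrendFit(float(slope), float(intercept), float(r))


def pair_to_group_correspondence(
    matrix: NucleusMatrix,
    metric: Metric = "co",
    fractions: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    replicates: int = 5,
    seed: int | None = None,
    n_boot: int = 0,
) -> list[tuple[float, float]]:
    """Map mean adjacent-pair correlation onto matched-group correlation.

    Runs the in-silico correlation sweep on the chosen metric; at each
    shuffle fraction records (replicate-mean adjacent-pair r, replicate-mean
    grouped r).  The returned points, ordered by decreasing shuffle fraction,
    form an interpolable (pairwise r -> grouped r) curve.
    """
    pool_key = metric
    master = np.random.default_rng(seed)
    series = correlation_sweep(matrix, fractions=fractions,
                               replicates=replicates,
                               seed=int(master.integers(2**31)),
                               pool_key=pool_key)
    # re-run the per-record matrices is wasteful; instead recompute pairwise r
    # on freshly shuffled matrices with the same construction
    from .insilico import assemble_sorted, partial_shuffle
    from .nucleus_data import pool_bivalents

    pools = pool_bivalents(matrix, key=pool_key)
    base = assemble_sorted(pools)
    grouped_by_f = series.mean_by_fraction("mean_r")
    points = []
    pairs = adjacent_pairs(matrix, metric)
    for f in fractions:
        pair_rs = []
        for rep in range(replicates):
            rng = np.random.default_rng(master.integers(2**31))
            shuffled = partial_shuffle(base, f, seed=rng)
            frame = shuffled.metric_frame(metric)
            for a, b in pairs:
                pair_rs.append(pearson(frame[a].to_numpy(dtype=float),
                                       frame[b].to_numpy(dtype=float)))
        points.append((float(np.mean(pair_rs)), grouped_by_f[float(f)]))
    points.sort(key=lambda p: p[0])
    return points


def interpolate_correspondence(points: Sequence[tuple[float, float]],
                               pair_r: float) -> float:
    """Linear interpolation of a (pairwise r -> grouped r) curve."""
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    order = np.argsort(xs)
    return float(np.interp(pair_r, xs[order], ys[order]))
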