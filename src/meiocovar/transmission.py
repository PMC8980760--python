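"""Gamete/progeny CO prediction from meiocytes under no chromatid interference.

Each CO on a bivalent joins two of the four chromatids, one from each
homolog.  Absent chromatid interference, the non-sister pair is chosen
uniformly among the four possibilities, so any single chromatid (gamete)
carries each CO independently with probability 1/2 — a Binomial(k, 1/2)
count per chromosome for a bivalent with k COs.

Closed-form consequences (population variances, meiocyte subscript m,
gamete subscript g, X = mean per-meiocyte CO total):

    total_g        = intrinsic_m/4 + X/4 + covariance_m/4
    contribution_m / contribution_g = 1 + X/total_m = 1 + 1/(X * CV^2)

Both are evaluated by :func:`gamete_variance_prediction` and verified
against simulation in the test-suite.

Also here: interference-free "Type II" CO augmentation (~10% of totals in
humans) and binomial maturation thinning (efficiency M < 1 models the human
female CO maturation inefficiency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariation import CovariationSummary
from .errors import ConfigurationError, ValidationError
from .nucleus_data import NucleusMatrix


@dataclass
class GameteSet:
    """Gamete x chromosome CO counts derived from a meiocyte matrix."""

    matrix: NucleusMatrix
    source_nucleus_ids: list[str]
    gametes_per_meiocyte: int


@dataclass(frozen=True)
class TransmissionPrediction:
    """Closed-form meiocyte -> gamete variance relations."""

    predicted_total_variance_g: float
    predicted_contribution_ratio: float
    reduction_term: float  # X / total_m, also 1/(X * CV^2)
    intrinsic_m: float
    covariance_m: float
    total_m: float
    X: float


def predict_gametes(
    matrix: NucleusMatrix,
    gametes_per_meiocyte: int = 1,
    seed: int | np.random.Generator | None = None,
) -> GameteSet:
    """Sample gametes from meiocytes assuming no chromatid interference.

    Mode 1 (default): one chromatid per meiocyte; each bivalent's k COs are
    transmitted as Binomial(k, 1/2).  Mode 4: all four chromatids; every CO
    is assigned to one of the four non-sister chromatid pairings uniformly,
    so the four counts for a bivalent sum to exactly 2k and each chromatid
    marginally remains Binomial(k, 1/2), but sister totals are coupled.
    """
    rng = np.random.default_rng(seed)
    counts = matrix.co_counts.to_numpy()
    nuc_ids = matrix.nucleus_ids

    if gametes_per_meiocyte == 1:
        g = rng.binomial(counts, 0.5)
        idx = pd.Index([f"{i}:g0" for i in nuc_ids], name="nucleus_id")
        gdf = pd.DataFrame(g, index=idx, columns=matrix.co_counts.columns)
        source = list(nuc_ids)
    elif gametes_per_meiocyte == 4:
        # pairings of chromatids (a,b | c,d): ac, ad, bc, bd
        n, m = counts.shape
        assign = np.array([rng.multinomial(k, [0.25] * 4)
                           for k in counts.ravel()]).reshape(n, m, 4)
        a = assign[..., 0] + assign[..., 1]  # ac + ad
        b = assign[..., 2] + assign[..., 3]  # bc + bd
        c = assign[..., 0] + assign[..., 2]  # ac + bc
        d = assign[..., 1] + assign[..., 3]  # ad + bd
        rows = []
        ids = []
        source = []
        for i, nid in enumerate(nuc_ids):
            for label, grid in zip("abcd", (a, b, c, d)):
                rows.append(grid[i])
                ids.append(f"{nid}:{label}")
                source.append(nid)
        gdf = pd.DataFrame(np.array(rows),
                           index=pd.Index(ids, name="nucleus_id"),
                           columns=matrix.co_counts.columns)
    else:
        raise ConfigurationError("gametes_per_meiocyte must be 1 or 4")

    gm = NucleusMatrix(gdf, None, sex_label=f"{matrix.sex_label}:gametes")
    return GameteSet(gm, source, gametes_per_meiocyte)


def gamete_variance_prediction(summary_m: CovariationSummary
                               ) -> TransmissionPrediction:
    """Evaluate the closed-form meiocyte -> gamete variance relations."""
    if summary_m.total_variance <= 0:
        raise ValidationError("meiocyte total variance must be positive")
    X = summary_m.mean_total
    total_g = (summary_m.intrinsic_variance + X + summary_m.covariance) / 4.0
    reduction = X / summary_m.total_variance
    return TransmissionPrediction(
        predicted_total_variance_g=total_g,
        predicted_contribution_ratio=1.0 + reduction,
        reduction_term=reduction,
        intrinsic_m=summary_m.intrinsic_variance,
        covariance_m=summary_m.covariance,
        total_m=summary_m.total_variance,
        X=X,
    )


def add_type2_cos(
    matrix: NucleusMatrix,
    fraction: float = 0.10,
    seed: int | np.random.Generator | None = None,
) -> NucleusMatrix:
    """Add interference-free ("Type II") COs, ~``fraction`` of the totals.

    Each chromosome c gains, per nucleus, an independent Poisson number of
    extra COs with mean ``fraction * mean(c)``, so longer (higher-mean)
    chromosomes receive proportionally more random COs and the expected
    per-nucleus total rises by ~``fraction``.
    """
    if fraction < 0:
        raise ConfigurationError("type-II fraction must be >= 0")
    if fraction == 0:
        return NucleusMatrix(matrix.co_counts.copy(),
                             None if matrix.axis_lengths is None
                             else matrix.axis_lengths.copy(),
                             matrix.sex_label)
    rng = np.random.default_rng(seed)
    counts = matrix.co_counts.to_numpy()
    means = counts.mean(axis=0)
    extra = rng.poisson(fraction * means, size=counts.shape)
    out = pd.DataFrame(counts + extra, index=matrix.co_counts.index,
                       columns=matrix.co_counts.columns)
    axis = matrix.axis_lengths.copy() if matrix.axis_lengths is not None else None
    return NucleusMatrix(out, axis, matrix.sex_label)


def apply_maturation(
    matrix: NucleusMatrix,
    efficiency: float,
    seed: int | np.random.Generator | None = None,
) -> NucleusMatrix:
    """Binomially thin COs: each matures independently with probability M.

    Models CO maturation inefficiency (M < 1): designated CO sites that fail
    to become mature COs, as in human females.
    """
    if not 0 < efficiency <= 1:
        raise ConfigurationError("maturation efficiency must be in (0, 1]")
    if efficiency == 1:
        return NucleusMatrix(matrix.co_counts.copy(),
                             None if matrix.axis_lengths is None
                             else matrix.axis_lengths.copy(),
                             matrix.sex_label)
    rng = np.random.default_rng(seed)
    counts = rng.binomial(matrix.co_counts.to_numpy(), efficiency)
    out = pd.DataFrame(counts, index=matrix.co_counts.index,
                       columns=matrix.co_counts.columns)
    axis = matrix.axis_lengths.copy() if matrix.axis_lengths is not None else None
    return NucleusMatrix(out, axis, matrix.sex_label)
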