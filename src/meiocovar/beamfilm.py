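"""Beam-film ("fill-in-the-holes") crossover-patterning simulator.

Each bivalent carries an array of CO precursors.  A designation driving
force designates the most sensitive precursor as the first (obligatory) CO;
an interference signal then spreads from every designation along the axis,
reducing the driving force available nearby, so later designations are
pushed apart (CO interference) and the CO number responds sub-proportionally
to precursor number (CO homeostasis).  Designated sites finally mature into
COs with efficiency M (M < 1 models the human female maturation
inefficiency).

Parameter roles (the classical beam-film parameter names):

* ``N`` — mean precursor number per bivalent; ``B`` — inter-nucleus
  precursor-number regularity in (0, 1] (counts ~ Binomial(round(N/B), B),
  so B = 1 gives exactly N precursors every nucleus);
* ``E`` — placement regularity in [0, 1]: positions blend evenly spaced
  anchors (weight E) with sorted uniform draws (weight 1 - E);
* ``Smax`` — maximal designation driving force; ``A`` — sensitivity shape
  (sensitivities ~ Uniform^(1/A)); ``L`` — interference distance in microns
  of axis; the interference factor at distance d is 1 - exp(-d/L), and the
  designation threshold is fixed at 1;
* ``M`` — maturation efficiency; ``axis_length`` — bivalent axis length (um).

These functional forms are one admissible instantiation of the model's
stated roles; each is isolated so alternates can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .nucleus_data import NucleusMatrix

DESIGNATION_THRESHOLD = 1.0


@dataclass(frozen=True)
class BeamFilmParams:
    """Parameters of the beam-film CO-patterning simulation (one bivalent)."""

    N: float
    B: float = 1.0
    E: float = 0.6
    Smax: float = 3.5
    L: float = 10.0
    A: float = 1.0
    M: float = 1.0
    axis_length: float = 15.0

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValidationError("mean precursor number N must be > 0")
        if not 0 < self.B <= 1:
            raise ValidationError("B must be in (0, 1]")
        if not 0 <= self.E <= 1:
            raise ValidationError("E must be in [0, 1]")
        if not 0 < self.M <= 1:
            raise ValidationError("maturation efficiency M must be in (0, 1]")
        if self.L <= 0 or self.axis_length <= 0:
            raise ValidationError("L and axis_length must be positive")
        if self.Smax <= 0 or self.A <= 0:
            raise ValidationError("Smax and A must be positive")

    def scaled(self, factor: float) -> "BeamFilmParams":
        """Scale axis length with proportionally scaled precursor number
        (constant precursor density), keeping L fixed in microns."""
        return replace(self, N=self.N * factor,
                       axis_length=self.axis_length * factor)


@dataclass(frozen=True)
class BivalentOutcome:
    """Precursor, designation and maturation positions for one bivalent."""

    precursor_positions: tuple[float, ...]
    designated_positions: tuple[float, ...]
    mature_positions: tuple[float, ...]

    @property
    def co_count(self) -> int:
        return len(self.mature_positions)


@dataclass(frozen=True)
class MixedPopulationSpec:
    """Two beam-film subpopulations (short/long axes) sharing L, mixed to
    emulate per-nucleus axis-length covariation."""

    params_short: BeamFilmParams
    params_long: BeamFilmParams
    mix_fraction: float = 0.5  # proportion of nuclei from the long subpopulation
    randomize_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.params_short.L != self.params_long.L:
            raise ValidationError(
                "the two subpopulations must share the interference distance L")
        if not 0 < self.mix_fraction < 1:
            raise ValidationError("mix_fraction must be in (0, 1)")
        if not 0 <= self.randomize_fraction <= 1:
            raise ValidationError("randomize_fraction must be in [0, 1]")


def _draw_precursors(params: BeamFilmParams, rng: np.random.Generator
                     ) -> np.ndarray:
    n_max = max(1, int(round(params.N / params.B)))
    n = int(rng.binomial(n_max, params.B))
    if n == 0:
        return np.empty(0)
    anchors = (np.arange(n) + 0.5) / n * params.axis_length
    uniform = np.sort(rng.uniform(0.0, params.axis_length, size=n))
    return params.E * anchors + (1.0 - params.E) * uniform


def simulate_bivalent(params: BeamFilmParams,
                      seed: int | np.random.Generator | None = None
                      ) -> BivalentOutcome:
    """Simulate precursors, iterative CO designation and maturation.

    Designation is greedy: repeatedly designate the precursor whose
    sensitivity times the locally available driving force (Smax reduced by
    the interference factor 1 - exp(-d/L) of every prior designation, both
    directions, ends truncating naturally) is highest, while it exceeds the
    threshold of 1.
    """
    rng = np.random.default_rng(seed)
    pos = _draw_precursors(params, rng)
    if pos.size == 0:
        return BivalentOutcome((), (), ())
    sens = rng.uniform(0.0, 1.0, size=pos.size) ** (1.0 / params.A)

    interference = np.ones(pos.size)  # running product of interference factors
    designated: list[float] = []
    available = np.ones(pos.size, dtype=bool)
    while True:
        force = params.Smax * sens * interference
        force[~available] = -np.inf
        i = int(np.argmax(force))
        if force[i] < DESIGNATION_THRESHOLD:
            break
        designated.append(float(pos[i]))
        available[i] = False
        interference *= 1.0 - np.exp(-np.abs(pos - pos[i]) / params.L)

    mature = [d for d in designated if rng.random() < params.M]
    return BivalentOutcome(tuple(pos.tolist()), tuple(designated),
                           tuple(sorted(mature)))


def coefficient_of_coincidence(
    position_lists: Sequence[Sequence[float]],
    axis_length: float,
    n_bins: int = 12,
) -> pd.DataFrame:
    """Coefficient of coincidence (CoC) of CO positions by interval distance.

    The axis is cut into ``n_bins`` equal intervals.  For every interval
    pair, CoC = (fraction of bivalents with a CO in both) / (product of the
    single-interval fractions); values are averaged over pairs at the same
    inter-interval distance.  CoC < 1 at short distances is the signature of
    interference; CoC -> 1 where the intervals are independent.
    """
    edges = np.linspace(0.0, axis_length, n_bins + 1)
    hits = np.zeros((len(position_lists), n_bins), dtype=bool)
    for i, positions in enumerate(position_lists):
        if len(positions):
            idx = np.clip(np.searchsorted(edges, positions, side="right") - 1,
                          0, n_bins - 1)
            hits[i, idx] = True
    p = hits.mean(axis=0)
    rows = []
    for i in range(n_bins):
        for j in range(i + 1, n_bins):
            if p[i] == 0 or p[j] == 0:
                continue
            both = (hits[:, i] & hits[:, j]).mean()
            rows.append({
                "distance": (j - i) * axis_length / n_bins,
                "coc": both / (p[i] * p[j]),
            })
    df = pd.DataFrame(rows)
    return df.groupby("distance", as_index=False)["coc"].mean()


def simulate_population(
    per_chromosome_params: Sequence[BeamFilmParams],
    n_nuclei: int,
    seed: int | None = None,
    chromosome_ids: Sequence[str] | None = None,
) -> NucleusMatrix:
    """Simulate every chromosome of every nucleus independently.

    Returns a :class:`NucleusMatrix` carrying both mature CO counts and the
    (per-chromosome, here fixed) axis lengths.
    """
    if not per_chromosome_params:
        raise ConfigurationError("need at least one chromosome's parameters")
    master = np.random.default_rng(seed)
    m = len(per_chromosome_params)
    ids = (list(chromosome_ids) if chromosome_ids is not None
           else [f"chr{j + 1}" for j in range(m)])
    counts = np.zeros((n_nuclei, m), dtype=int)
    axes = np.zeros((n_nuclei, m))
    for j, p in enumerate(per_chromosome_params):
        rng = np.random.default_rng(master.integers(2**31))
        for i in range(n_nuclei):
            counts[i, j] = simulate_bivalent(p, rng).co_count
            axes[i, j] = p.axis_length
    idx = pd.Index([f"sim{i}" for i in range(n_nuclei)], name="nucleus_id")
    return NucleusMatrix(pd.DataFrame(counts, index=idx, columns=ids),
                         pd.DataFrame(axes, index=idx, columns=ids),
                         sex_label="beam-film")


def simulate_mixed(
    spec: MixedPopulationSpec,
    n_nuclei: int,
    n_chromosomes: int,
    seed: int | None = None,
    size_factors: Sequence[float] | None = None,
) -> NucleusMatrix:
    """Mix short- and long-axis subpopulations with tunable axis covariation.

    Every nucleus is drawn from the short- or long-axis subpopulation (all
    its chromosomes share the label), giving maximal per-nucleus axis-length
    covariation; ``randomize_fraction`` of each chromosome column is then
    re-assorted across nuclei (counts and axis lengths travelling together),
    degrading the covariation down to independence at 1.  Chromosomes differ
    by the ``size_factors`` applied to both subpopulation parameter sets.
    """
    master = np.random.default_rng(seed)
    if size_factors is None:
        size_factors = np.linspace(0.7, 1.3, n_chromosomes)
    if len(size_factors) != n_chromosomes:
        raise ConfigurationError("need one size factor per chromosome")
    labels = master.random(n_nuclei) < spec.mix_fraction  # True -> long
    counts = np.zeros((n_nuclei, n_chromosomes), dtype=int)
    axes = np.zeros((n_nuclei, n_chromosomes))
    for j in range(n_chromosomes):
        p_short = spec.params_short.scaled(size_factors[j])
        p_long = spec.params_long.scaled(size_factors[j])
        rng = np.random.default_rng(master.integers(2**31))
        for i in range(n_nuclei):
            p = p_long if labels[i] else p_short
            counts[i, j] = simulate_bivalent(p, rng).co_count
            axes[i, j] = p.axis_length
    # re-assort a fraction of each column to tune axis-length correlation
    f = spec.randomize_fraction
    if f > 0:
        k = int(round(f * n_nuclei))
        if k >= 2:
            for j in range(n_chromosomes):
                rows = master.choice(n_nuclei, size=k, replace=False)
                perm = master.permutation(k)
                counts[rows, j] = counts[rows[perm], j]
                axes[rows, j] = axes[rows[perm], j]
    idx = pd.Index([f"mix{i}" for i in range(n_nuclei)], name="nucleus_id")
    ids = [f"chr{j + 1}" for j in range(n_chromosomes)]
    return NucleusMatrix(pd.DataFrame(counts, index=idx, columns=ids),
                         pd.DataFrame(axes, index=idx, columns=ids),
                         sex_label="beam-film-mixed")
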