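"""Synthetic per-nucleus CO-count matrices with controllable covariation.

The generator emulates the statistical structure of human pachytene data: a
per-nucleus latent scaling factor *g* (gamma-distributed, unit mean) —
standing in for nucleus-wide axis-length scaling — multiplies every
chromosome's Poisson CO rate, so chromosomes covary within nuclei.  The
knob ``rho`` in [0, 1) sets the latent variance so that the *expected*
matched-group correlation of the observed counts equals ``rho``.  Under the
pure Poisson mixture this is the closed form
``sigma_g^2 = 2 rho / ((1 - rho) X)`` (X the mean per-nucleus total); the
obligatory-CO floor and maturation thinning attenuate the correlation, so
the variance is solved numerically through the full observation model
(zero-truncation + binomial thinning, quadrature over the latent factor).
The shipped calibration table records the empirically achieved
correlations.

Features emulated: ~22 bivalents per nucleus, an obligatory-CO floor
(zero-count bivalents redrawn, with the underlying rate calibrated so the
observed mean still hits its target), axis lengths coupled to the latent
factor, binomial maturation thinning, and a female-like regime with
1.5-fold the male CO count and sub-unity maturation efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .covariation import partition_sweep
from .errors import ConfigurationError
from .insilico import assemble_sorted
from .nucleus_data import NucleusMatrix, pool_bivalents, write_nucleus_table

N_CHROMOSOMES_DEFAULT = 22
MALE_MEAN_TOTAL = 50.0      # observed mean MLH1 foci per spermatocyte
FEMALE_MALE_RATIO = 1.5     # females carry ~1.5-fold the male CO count
FEMALE_MATURATION = 0.6     # female CO maturation efficiency (M < 1)
MALE_RHO = 0.65             # male meiocyte matched-group CO correlation
FEMALE_RHO = 0.78           # female meiocyte matched-group CO correlation
MALE_MEAN_AXIS = 15.0       # mean per-chromosome axis length, microns
AXIS_NOISE_SD = 0.08        # lognormal sd of axis noise around the latent


def _default_means(total: float, n_chromosomes: int) -> tuple[float, ...]:
    """Descending per-chromosome means (chr1 largest) summing to ``total``."""
    raw = np.linspace(3.5, 1.05, n_chromosomes)
    return tuple(raw / raw.sum() * total)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic nucleus-matrix generator.

    ``chrom_means`` are the target *observed* per-chromosome mean CO counts
    (after the obligatory-CO floor and maturation thinning).
    """

    n_nuclei: int = 755
    chrom_means: tuple[float, ...] = field(
        default_factory=lambda: _default_means(MALE_MEAN_TOTAL,
                                               N_CHROMOSOMES_DEFAULT))
    rho: float = 0.0
    obligatory_floor: bool = True
    axis_mode: Literal["none", "coupled"] = "coupled"
    base_axis_lengths: tuple[float, ...] | None = None
    maturation: float = 1.0
    sex_label: str = "synthetic"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ConfigurationError("n_nuclei must be >= 1")
        if any(m <= 0 for m in self.chrom_means):
            raise ConfigurationError("chromosome means must be positive")
        if not 0 <= self.rho < 1:
            raise ConfigurationError("rho must be in [0, 1)")
        if not 0 < self.maturation <= 1:
            raise ConfigurationError("maturation must be in (0, 1]")
        if (self.base_axis_lengths is not None
                and len(self.base_axis_lengths) != len(self.chrom_means)):
            raise ConfigurationError("need one base axis length per chromosome")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_means)

    @property
    def mean_total(self) -> float:
        return float(sum(self.chrom_means))

    @property
    def latent_variance(self) -> float:
        """Latent-factor variance calibrated so the expected matched-group
        correlation of the *observed* counts equals ``rho``."""
        if self.rho == 0:
            return 0.0
        return _solve_latent_variance(self.chrom_means, self.rho,
                                      self.maturation, self.obligatory_floor)


def male_like_config(n_nuclei: int = 755, seed: int | None = None,
                     rho: float = MALE_RHO) -> GeneratorConfig:
    """Spermatocyte-like preset: ~50 MLH1 foci/nucleus over 22 bivalents,
    matched-group correlation targeting the male meiocyte value, M = 1."""
    means = _default_means(MALE_MEAN_TOTAL, N_CHROMOSOMES_DEFAULT)
    axes = tuple(np.array(means) / np.mean(means) * MALE_MEAN_AXIS)
    return GeneratorConfig(n_nuclei=n_nuclei, chrom_means=means, rho=rho,
                           obligatory_floor=True, axis_mode="coupled",
                           base_axis_lengths=axes, maturation=1.0,
                           sex_label="male-like", seed=seed)


def female_like_config(n_nuclei: int = 69, seed: int | None = None,
                       rho: float = FEMALE_RHO) -> GeneratorConfig:
    """Oocyte-like preset: 1.5-fold the male CO count, ~2-fold axes,
    maturation inefficiency M < 1."""
    means = _default_means(MALE_MEAN_TOTAL * FEMALE_MALE_RATIO,
                           N_CHROMOSOMES_DEFAULT)
    axes = tuple(np.array(means) / np.mean(means) * MALE_MEAN_AXIS * 2.0)
    return GeneratorConfig(n_nuclei=n_nuclei, chrom_means=means, rho=rho,
                           obligatory_floor=True, axis_mode="coupled",
                           base_axis_lengths=axes,
                           maturation=FEMALE_MATURATION,
                           sex_label="female-like", seed=seed)


# -- rate calibration ---------------------------------------------------------


def _gamma_quadrature(sigma_g2: float, n_quad: int = 200) -> np.ndarray:
    """Quantile-midpoint grid of the unit-mean gamma latent factor."""
    if sigma_g2 <= 0:
        return np.array([1.0])
    shape = 1.0 / sigma_g2
    qs = (np.arange(n_quad) + 0.5) / n_quad
    return stats.gamma.ppf(qs, a=shape, scale=sigma_g2)


def _observed_moments(lam_g: np.ndarray, maturation: float, floor: bool
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the observed count given the latent rate.

    Poisson(lam*g), optionally zero-truncated (obligatory-CO floor), then
    binomially thinned with probability M.
    """
    if floor:
        denom = -np.expm1(-lam_g)
        mt = lam_g / denom
        ex2 = (lam_g + lam_g**2) / denom
        vt = ex2 - mt**2
    else:
        mt = lam_g
        vt = lam_g
    mean = maturation * mt
    var = maturation**2 * vt + maturation * (1 - maturation) * mt
    return mean, var


def _expected_grouped_r(sigma_g2: float, chrom_means: Sequence[float],
                        maturation: float, floor: bool) -> float:
    """Expected matched-group correlation of observed counts, by quadrature
    over the latent factor, for an alternating balanced partition."""
    g = _gamma_quadrature(sigma_g2)
    lam = np.array([
        _rate_for_target_mean(m / maturation, sigma_g2, floor)
        for m in chrom_means
    ])
    means = np.empty((len(lam), g.size))
    varis = np.empty((len(lam), g.size))
    for c, l in enumerate(lam):
        means[c], varis[c] = _observed_moments(l * g, maturation, floor)
    idx = np.arange(len(lam))
    a, b = idx % 2 == 0, idx % 2 == 1
    sa, sb = means[a].sum(axis=0), means[b].sum(axis=0)
    var_a = varis[a].sum(axis=0).mean() + sa.var()
    var_b = varis[b].sum(axis=0).mean() + sb.var()
    cov_ab = np.cov(sa, sb, ddof=0)[0, 1]
    return float(cov_ab / np.sqrt(var_a * var_b))


_LATENT_CACHE: dict[tuple, float] = {}


def _solve_latent_variance(chrom_means: tuple[float, ...], rho: float,
                           maturation: float, floor: bool) -> float:
    """Latent variance at which the expected matched-group correlation of
    the observed counts equals rho."""
    key = (chrom_means, rho, maturation, floor)
    if key in _LATENT_CACHE:
        return _LATENT_CACHE[key]
    total = float(sum(chrom_means))
    # closed-form Poisson-mixture value; truncation only attenuates, so it
    # brackets the solution from below
    lo = 2.0 * rho / ((1.0 - rho) * total)
    hi = lo
    for _ in range(40):
        if _expected_grouped_r(hi, chrom_means, maturation, floor) >= rho:
            break
        hi *= 1.5
    else:
        raise ConfigurationError(f"rho={rho} unreachable for this configuration")
    if _expected_grouped_r(lo, chrom_means, maturation, floor) >= rho:
        sol = lo
    else:
        sol = float(optimize.brentq(
            lambda s: _expected_grouped_r(s, chrom_means, maturation, floor)
            - rho, lo, hi, xtol=1e-8))
    _LATENT_CACHE[key] = sol
    return sol


def _rate_for_target_mean(target: float, sigma_g2: float, floor: bool,
                          n_quad: int = 200) -> float:
    """Poisson rate whose floored, latent-mixed mean equals ``target``.

    The observed mean of a zero-redrawn Poisson(lam * g) count, averaged
    over the gamma latent g, is E_g[lam*g / (1 - exp(-lam*g))]; solved for
    lam by bracketing.  Without the floor the mean is lam exactly.
    """
    if not floor:
        return target
    if sigma_g2 > 0:
        shape = 1.0 / sigma_g2
        qs = (np.arange(n_quad) + 0.5) / n_quad
        g = stats.gamma.ppf(qs, a=shape, scale=sigma_g2)
    else:
        g = np.array([1.0])

    def mean_at(lam: float) -> float:
        lg = lam * g
        return float(np.mean(lg / -np.expm1(-lg)))

    # mean_at(lam) >= max(lam, 1) and -> 1 as lam -> 0
    if target <= 1.0:
        raise ConfigurationError(
            f"target mean {target} unreachable with an obligatory-CO floor")
    return float(optimize.brentq(lambda lam: mean_at(lam) - target,
                                 1e-9, target, xtol=1e-10))


def generate(config: GeneratorConfig) -> NucleusMatrix:
    """Draw a synthetic :class:`NucleusMatrix` from the generator model."""
    rng = np.random.default_rng(config.seed)
    sigma_g2 = config.latent_variance
    if sigma_g2 > 0:
        g = rng.gamma(shape=1.0 / sigma_g2, scale=sigma_g2,
                      size=config.n_nuclei)
    else:
        g = np.ones(config.n_nuclei)

    pre_means = np.array(config.chrom_means) / config.maturation
    lam = np.array([
        _rate_for_target_mean(m, sigma_g2, config.obligatory_floor)
        for m in pre_means
    ])
    rates = np.outer(g, lam)
    counts = rng.poisson(rates)
    if config.obligatory_floor:
        zero = counts == 0
        while zero.any():  # redraw zeros: truncated-at->=1 sampling
            counts[zero] = rng.poisson(rates[zero])
            zero = counts == 0
    if config.maturation < 1:
        counts = rng.binomial(counts, config.maturation)

    ids = [f"chr{j + 1}" for j in range(config.n_chromosomes)]
    idx = pd.Index([f"n{i}" for i in range(config.n_nuclei)],
                   name="nucleus_id")
    counts_df = pd.DataFrame(counts, index=idx, columns=ids)

    axis_df = None
    if config.axis_mode == "coupled":
        base = (np.array(config.base_axis_lengths)
                if config.base_axis_lengths is not None
                else np.array(config.chrom_means)
                / np.mean(config.chrom_means) * MALE_MEAN_AXIS)
        noise = rng.lognormal(-AXIS_NOISE_SD**2 / 2.0, AXIS_NOISE_SD,
                              size=(config.n_nuclei, config.n_chromosomes))
        axis_df = pd.DataFrame(np.outer(g, base) * noise, index=idx,
                               columns=ids)
    elif config.axis_mode != "none":
        raise ConfigurationError(f"unknown axis_mode {config.axis_mode!r}")
    return NucleusMatrix(counts_df, axis_df, config.sex_label)


# -- calibration table --------------------------------------------------------

CALIBRATION_FILENAME = "calibration_rho.csv"


def calibrate_rho(
    rhos: Sequence[float],
    preset: Literal["male-like", "female-like"] = "male-like",
    n_nuclei: int = 4000,
    replicates: int = 5,
    seed: int | None = 0,
    max_partitions: int = 100,
) -> pd.DataFrame:
    """Empirical rho -> achieved matched-group correlation mapping.

    Generates ``replicates`` matrices per rho and measures the mean
    matched-group correlation by partition sweep; returns a table with
    columns ``preset, rho, measured_r, se, n_nuclei``.
    """
    builder = male_like_config if preset == "male-like" else female_like_config
    master = np.random.default_rng(seed)
    rows = []
    for rho in rhos:
        rs = []
        for _ in range(replicates):
            cfg = builder(n_nuclei=n_nuclei,
                          seed=int(master.integers(2**31)), rho=rho)
            mat = generate(cfg)
            rs.append(partition_sweep(mat, max_partitions=max_partitions,
                                      seed=int(master.integers(2**31))).mean_r)
        rows.append({
            "preset": preset,
            "rho": float(rho),
            "measured_r": float(np.mean(rs)),
            "se": float(np.std(rs, ddof=1) / np.sqrt(len(rs))),
            "n_nuclei": n_nuclei,
        })
    return pd.DataFrame(rows)


def load_calibration_table() -> pd.DataFrame:
    """Load the calibration table shipped with the package."""
    ref = resources.files("meiocovar").joinpath("data", CALIBRATION_FILENAME)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


# -- fixtures -----------------------------------------------------------------


def make_fixture_suite(out_dir: str | Path, seed: int = 0,
                       n_nuclei: int = 150) -> dict[str, Path]:
    """Write the canonical small fixtures used by the test-suite.

    Deterministic given ``seed``: male-like, female-like, independent
    (rho = 0) and perfectly-sorted (maximal-correlation) matrices in wide
    layout.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    male = generate(male_like_config(n_nuclei, seed=int(rng.integers(2**31))))
    female = generate(female_like_config(n_nuclei,
                                         seed=int(rng.integers(2**31))))
    indep_cfg = replace(male_like_config(n_nuclei,
                                         seed=int(rng.integers(2**31))),
                        rho=0.0, sex_label="independent")
    indep = generate(indep_cfg)
    sorted_mat = assemble_sorted(pool_bivalents(male, key="co"))

    for name, mat in [("male_like", male), ("female_like", female),
                      ("independent", indep),
                      ("perfectly_sorted", sorted_mat)]:
        path = out / f"{name}.csv"
        write_nucleus_table(mat, path, layout="wide")
        paths[name] = path
    return paths
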