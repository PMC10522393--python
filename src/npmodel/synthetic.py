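"""Synthetic schedules, noisy observed-incidence tables, and a bead simulator.

Three generators make every stage of the pipeline testable without any
external download:

* :func:`make_default_schedule` returns the packaged 19-bracket UK table
  (generations, annual turnover, observed 5-year incidence) exactly as
  shipped in ``data/uk_schedule.csv``;
* :func:`make_synthetic_schedule` / :func:`generate_observed_incidence`
  build schedules from parametric generation and turnover profiles and
  attach observed incidence drawn from the forward model under
  mean-preserving multiplicative log-normal noise;
* :func:`simulate_raining_beads` is a direct Monte-Carlo realisation of the
  mutation-accumulation picture — each cell is a bowl into which mutations
  rain as i.i.d. Poisson increments per division, transforming the cell
  when the accumulated count reaches the threshold — whose cancerous
  fraction converges to the analytic Poisson upper tail.

The simulator is meant for desk-scale parameters (q <= ~20, <= ~1e6
cells): the fitted human regime (q = 118, tail ~ 1e-19) is far beyond the
reach of naive Monte Carlo, so simulator/analytic agreement is checked in
the reachable regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .io import read_schedule
from .model import (
    HAYFLICK_LIMIT,
    AgeGroupRow,
    ModelParams,
    Schedule,
    predict_incidence_table,
)

#: Per-bracket generation increments of the default human schedule: four
#: extra generations over the first five years beyond the 41 reached at
#: birth (start 45), one per bracket to age 15, then 0.5 per bracket.
DEFAULT_GENERATION_INCREMENTS = (1.0, 1.0) + (0.5,) * 16

#: Per-bracket turnover factors of the default human schedule: constant to
#: age 35, then a 25% decline per 5 years to 75, 35% to 85, 40% to 90 and
#: 50% beyond.
DEFAULT_TURNOVER_FACTORS = (
    (1.0,) * 6 + (0.75,) * 8 + (0.65,) * 2 + (0.60,) + (0.50,)
)


def make_default_schedule() -> Schedule:
    """Load the packaged 19-bracket UK schedule with its observed column."""
    with resources.as_file(
        resources.files("npmodel").joinpath("data/uk_schedule.csv")
    ) as path:
        return read_schedule(path)


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and noise model for a synthetic incidence table.

    The defaults mirror the human study conditions: p_c = 2.38e-18,
    q = 118, 19 five-year brackets starting at generation 45 with the
    default increment pattern capped at the Hayflick limit, baseline
    turnover 4.2e13/year with the default decline factors, and noise-free
    observation (cv = 0).
    """

    p_c: float = 2.38e-18
    q: int = 118
    n_brackets: int = 19
    generation_start: float = 45.0
    generation_increments: tuple[float, ...] = DEFAULT_GENERATION_INCREMENTS
    generation_cap: float = HAYFLICK_LIMIT
    turnover_base: float = 4.2e13
    turnover_factors: tuple[float, ...] = DEFAULT_TURNOVER_FACTORS
    cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("noise coefficient of variation must be >= 0")
        if self.n_brackets < 1:
            raise ValueError("need at least one bracket")
        if len(self.generation_increments) < self.n_brackets - 1:
            raise ValueError("not enough generation increments for the brackets")
        if len(self.turnover_factors) < self.n_brackets - 1:
            raise ValueError("not enough turnover factors for the brackets")
        if any(not (0.0 < f <= 1.0) for f in self.turnover_factors):
            raise ValueError("turnover factors must lie in (0, 1]")

    @property
    def params(self) -> ModelParams:
        return ModelParams(p_c=self.p_c, q=self.q, n_base=self.turnover_base)


def scaled_config(q: int, *, cv: float = 0.0, seed: int = 0) -> SyntheticConfig:
    """Build a config at threshold ``q`` in the identifiable incidence regime.

    The Poisson tail Q(q, mean) changes by orders of magnitude with q, so a
    recoverable ground truth must keep the product n*Q — the accumulation
    hazard — on the human scale. The generation profile is scaled by
    q / 118 (keeping mean/threshold ratios fixed) and the baseline turnover
    is rescaled so the first bracket's accumulation hazard matches the
    default human config; p_c is rescaled inversely so the background
    hazard n*p_c is unchanged.
    """
    from .model import poisson_upper_tail

    f = q / 118.0
    g0 = 45.0 * f
    base = SyntheticConfig()
    n = (
        base.turnover_base
        * poisson_upper_tail(base.q, base.generation_start)
        / poisson_upper_tail(q, g0)
    )
    return SyntheticConfig(
        p_c=base.p_c * base.turnover_base / n,
        q=q,
        generation_start=g0,
        generation_increments=tuple(
            i * f for i in DEFAULT_GENERATION_INCREMENTS
        ),
        generation_cap=base.generation_cap * f,
        turnover_base=n,
        cv=cv,
        seed=seed,
    )


def make_synthetic_schedule(config: SyntheticConfig) -> Schedule:
    """Build a 5-year-bracket schedule from the config's parametric profiles."""
    rows = []
    gen = config.generation_start
    n = config.turnover_base
    for i in range(config.n_brackets):
        start = 5.0 * i
        rows.append(
            AgeGroupRow(
                label=f"{start:.0f}-{start + 5:.0f}",
                age_start=start,
                age_end=start + 5.0,
                generation=min(gen, config.generation_cap),
                turnover_per_year=n,
            )
        )
        if i < config.n_brackets - 1:
            gen += config.generation_increments[i]
            n *= config.turnover_factors[i]
    return Schedule(tuple(rows), generation_cap=config.generation_cap)


def generate_observed_incidence(config: SyntheticConfig) -> Schedule:
    """Attach noisy observed 5-year incidence to a synthetic schedule.

    The observed column is the forward-model 5-year percentage multiplied
    by exp(eps) with eps ~ Normal(-cv^2/2, cv) per bracket — multiplicative
    log-normal noise whose mean-correction keeps E[observed] equal to the
    model value. With cv = 0 the observed column equals the model exactly;
    identical configs (including seed) give identical tables.
    """
    schedule = make_synthetic_schedule(config)
    table = predict_incidence_table(schedule, config.params)
    pct = table.five_year_pct
    if np.all(pct == 0.0):
        raise ValueError("degenerate profile: forward model is identically zero")
    if config.cv > 0:
        rng = np.random.default_rng(config.seed)
        eps = rng.normal(-config.cv**2 / 2.0, config.cv, size=pct.shape)
        pct = pct * np.exp(eps)
    return schedule.with_observed(pct)


def simulate_raining_beads(
    n_cells: int,
    generations: int,
    mutations_per_division: float,
    q: int,
    seed: int,
) -> np.ndarray:
    """Monte-Carlo mutation accumulation in a population of cells.

    Each of ``n_cells`` cells independently gains
    Poisson(``mutations_per_division``) effective mutations per generation;
    a cell is cancerous once its accumulated total reaches ``q`` (inclusive
    threshold, matching the analytic upper tail). Returns the cumulative
    cancerous fraction after each generation, an array of length
    ``generations + 1`` whose entry g corresponds to g completed divisions;
    the final entry estimates P(X >= q) for
    X ~ Poisson(generations * mutations_per_division).
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if mutations_per_division < 0:
        raise ValueError("mutation rate must be >= 0")
    if q < 0:
        raise ValueError("threshold must be >= 0")
    rng = np.random.default_rng(seed)
    totals = np.zeros(n_cells, dtype=np.int64)
    fractions = np.empty(generations + 1)
    fractions[0] = float(np.mean(totals >= q))
    for g in range(1, generations + 1):
        totals += rng.poisson(mutations_per_division, size=n_cells)
        fractions[g] = float(np.mean(totals >= q))
    return fractions
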