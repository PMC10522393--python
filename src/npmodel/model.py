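"""Forward mathematics of the Poisson cell-turnover ("np") cancer incidence model.

The model treats cancer initiation as a two-level Poisson process. At the
population-of-cells level, the number of transforming events among ``n``
cell turnovers per year, each with per-turnover transformation probability
``p``, is Poisson with mean lambda = n*p, so the probability of staying
cancer-free for a year is exp(-n*p). At the single-cell level, ``p`` is the
sum of a constant background component ``p_c`` and an accumulation component
``p_a``: cells collect "effective mutations" at one per division generation
on average (Poisson deposition), and a cell transforms once its accumulated
count reaches a threshold ``q``. ``p_a`` for an age bracket is therefore the
probability mass of the Poisson upper tail newly crossed as the mean
accumulated count advances from one bracket's generation to the next.

Age structure enters through a :class:`Schedule` of 5-year brackets, each
carrying the mean division generation reached (capped at the Hayflick limit)
and the annual cell turnover for that bracket.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

logger = logging.getLogger(__name__)

#: Default generation cap: the Hayflick division limit used for schedules.
HAYFLICK_LIMIT = 55.0


@dataclass(frozen=True)
class ModelParams:
    """Global constants of the incidence model.

    Parameters
    ----------
    p_c : float
        Background probability that a single cell transforms in one
        division, independent of accumulated mutations (~1e-18).
    q : int
        Effective-mutation threshold: a cell transforms once it has
        accumulated ``q`` effective mutations. Dimensionless count, >= 1.
    n_base : float
        Baseline annual cell turnover (nucleated-cell replications per
        year); the adult reference value is 4.2e13/year.
    """

    p_c: float
    q: int
    n_base: float = 4.2e13

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_c < 1.0):
            raise ValueError(f"p_c must be in [0, 1), got {self.p_c}")
        if self.q < 1 or int(self.q) != self.q:
            raise ValueError(f"q must be a positive integer, got {self.q}")
        if self.n_base <= 0:
            raise ValueError(f"n_base must be positive, got {self.n_base}")


@dataclass(frozen=True)
class AgeGroupRow:
    """One 5-year age bracket of a turnover/generation schedule."""

    label: str
    age_start: float
    age_end: float
    generation: float
    turnover_per_year: float
    observed_5yr_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.age_end != self.age_start + 5:
            raise ValueError(
                f"bracket {self.label!r}: age_end must equal age_start + 5 "
                f"(got [{self.age_start}, {self.age_end}))"
            )
        if self.generation <= 0:
            raise ValueError(f"bracket {self.label!r}: generation must be > 0")
        if self.turnover_per_year <= 0:
            raise ValueError(f"bracket {self.label!r}: turnover must be > 0")


@dataclass(frozen=True)
class Schedule:
    """Ordered, contiguous sequence of 5-year age brackets.

    Generations must be non-decreasing; values above ``generation_cap``
    (default the Hayflick limit of 55) are clamped with a warning.
    """

    rows: tuple[AgeGroupRow, ...]
    generation_cap: float = HAYFLICK_LIMIT

    def __post_init__(self) -> None:
        rows = tuple(self.rows)
        if not rows:
            raise ValueError("schedule must contain at least one bracket")
        for prev, cur in zip(rows, rows[1:]):
            if cur.age_start != prev.age_end:
                raise ValueError(
                    f"brackets must be contiguous: {prev.label!r} ends at "
                    f"{prev.age_end} but {cur.label!r} starts at {cur.age_start}"
                )
            if cur.generation < prev.generation:
                raise ValueError(
                    f"generation must be non-decreasing: {cur.label!r} has "
                    f"{cur.generation} after {prev.generation}"
                )
        clamped = []
        for r in rows:
            if r.generation > self.generation_cap:
                logger.warning(
                    "bracket %r: generation %.1f exceeds cap %.1f; clamping",
                    r.label, r.generation, self.generation_cap,
                )
                r = replace(r, generation=self.generation_cap)
            clamped.append(r)
        object.__setattr__(self, "rows", tuple(clamped))

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def age_end(self) -> float:
        return self.rows[-1].age_end

    @property
    def has_observed(self) -> bool:
        return all(r.observed_5yr_pct is not None for r in self.rows)

    def with_constant_turnover(self, n: float) -> "Schedule":
        """Return a copy with every bracket's turnover replaced by ``n``."""
        return Schedule(
            tuple(replace(r, turnover_per_year=n) for r in self.rows),
            generation_cap=self.generation_cap,
        )

    def with_observed(self, observed_5yr_pct: Sequence[float]) -> "Schedule":
        """Return a copy carrying the given observed 5-year percentages."""
        if len(observed_5yr_pct) != len(self.rows):
            raise ValueError("observed vector length must match bracket count")
        return Schedule(
            tuple(
                replace(r, observed_5yr_pct=float(o))
                for r, o in zip(self.rows, observed_5yr_pct)
            ),
            generation_cap=self.generation_cap,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "label": [r.label for r in self.rows],
                "age_start": [r.age_start for r in self.rows],
                "age_end": [r.age_end for r in self.rows],
                "generation": [r.generation for r in self.rows],
                "turnover_per_year": [r.turnover_per_year for r in self.rows],
            }
        )
        if any(r.observed_5yr_pct is not None for r in self.rows):
            df["observed_5yr_pct"] = [r.observed_5yr_pct for r in self.rows]
        return df


@dataclass(frozen=True)
class IncidenceRow:
    """Computed incidence quantities for one age bracket."""

    label: str
    age_start: float
    age_end: float
    generation: float
    turnover_per_year: float
    p_a: float
    p_total: float
    lambda_annual: float
    p_health_annual: float
    p_cancer_annual: float
    p_cancer_5yr_pct: float
    observed_5yr_pct: Optional[float] = None


@dataclass(frozen=True)
class IncidenceTable:
    """Per-bracket model output (one :class:`IncidenceRow` per bracket)."""

    rows: tuple[IncidenceRow, ...]
    params: ModelParams = field(compare=False, default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def annual(self) -> np.ndarray:
        return np.array([r.p_cancer_annual for r in self.rows])

    @property
    def five_year_pct(self) -> np.ndarray:
        return np.array([r.p_cancer_5yr_pct for r in self.rows])

    @property
    def observed_5yr_pct(self) -> np.ndarray:
        return np.array(
            [math.nan if r.observed_5yr_pct is None else r.observed_5yr_pct
             for r in self.rows]
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "label", "age_start", "age_end", "generation", "turnover_per_year",
            "p_a", "p_total", "lambda_annual", "p_health_annual",
            "p_cancer_annual", "p_cancer_5yr_pct",
        ]
        df = pd.DataFrame({c: [getattr(r, c) for r in self.rows] for c in cols})
        if any(r.observed_5yr_pct is not None for r in self.rows):
            df["observed_5yr_pct"] = [r.observed_5yr_pct for r in self.rows]
        return df


def poisson_upper_tail(q: int, mean: float) -> float:
    """Upper cumulative Poisson probability P(X >= q) for X ~ Poisson(mean).

    The tail is inclusive at ``q`` (the accumulated count *reaching* the
    threshold transforms the cell). The mean may be non-integer; results are
    numerically stable down to ~1e-22 via the regularized gamma survival
    function underlying :func:`scipy.stats.poisson.sf`.
    """
    if q < 0:
        raise ValueError(f"threshold q must be >= 0, got {q}")
    if mean < 0:
        raise ValueError(f"mean must be non-negative, got {mean}")
    if q == 0:
        return 1.0
    # P(X >= q) = sf(q - 1)
    return float(poisson.sf(q - 1, mean))


def p_accumulate(
    prev_generation: Optional[float],
    generation: float,
    q: int,
    *,
    mode: str = "conditional",
) -> float:
    """Accumulation-driven transformation probability for one bracket.

    For the first bracket (``prev_generation`` is None) this is simply the
    tail Q(generation) = P(X >= q | mean=generation): the probability that a
    cell born into this bracket already carries a threshold-crossing count.
    For later brackets it is the probability of newly crossing the threshold
    as the mean advances, conditional on not having crossed before::

        (Q(gen) - Q(prev)) / (1 - Q(prev))

    ``mode="difference"`` selects the plain difference Q(gen) - Q(prev),
    the small-Q simplification; at tail magnitudes ~1e-19 the two agree to
    more than ten significant figures.
    """
    if mode not in ("conditional", "difference"):
        raise ValueError(f"unknown mode {mode!r}")
    q_now = poisson_upper_tail(q, generation)
    if prev_generation is None:
        return q_now
    if generation < prev_generation:
        raise ValueError(
            f"generation must not decrease ({prev_generation} -> {generation})"
        )
    q_prev = poisson_upper_tail(q, prev_generation)
    if q_prev < 0.5:
        diff = q_now - q_prev
        denom = 1.0 - q_prev
    else:
        # Q near 1: the complement cdf(q-1) is the small quantity, so work
        # with lower tails to avoid cancellation (Q_now-Q_prev = c_prev-c_now
        # and 1-Q_prev = c_prev exactly).
        c_prev = float(poisson.cdf(q - 1, prev_generation)) if q > 0 else 0.0
        c_now = float(poisson.cdf(q - 1, generation)) if q > 0 else 0.0
        diff = c_prev - c_now
        denom = c_prev
    if mode == "difference":
        return max(diff, 0.0)
    if denom == 0.0:
        # no surviving (un-transformed) cells: no further accumulation mass
        return 0.0
    return max(diff / denom, 0.0)


def annual_cancer_probability(turnover_per_year: float, p_total: float) -> float:
    """Probability of at least one transforming event in a year.

    With lambda = n*p transforming events per year (Poisson), the chance of
    staying healthy is exp(-lambda), so this returns 1 - exp(-n*p). The
    identity ``1 - result == exp(-lambda)`` holds to machine precision
    (computed via expm1), so log-survival is additive across years.
    """
    if turnover_per_year < 0 or p_total < 0:
        raise ValueError("turnover and probability must be non-negative")
    return -math.expm1(-turnover_per_year * p_total)


def five_year_probability(annual: float) -> float:
    """Convert an annual cancer probability to a 5-year percentage.

    Returns ``100 * (1 - (1 - annual)^5)``; approximately 500*annual for
    small annual probabilities.
    """
    if not (0.0 <= annual <= 1.0):
        raise ValueError(f"annual probability must be in [0, 1], got {annual}")
    return 100.0 * -math.expm1(5.0 * math.log1p(-annual)) if annual < 1 else 100.0


def predict_incidence_table(
    schedule: Schedule,
    params: ModelParams,
    *,
    accumulate_mode: str = "conditional",
) -> IncidenceTable:
    """Run the forward chain over a schedule: tail -> p_a -> lambda -> incidence.

    All intermediates are kept unrounded. Observed incidence values carried
    by the schedule are attached to the output rows.
    """
    rows = []
    prev_gen: Optional[float] = None
    for r in schedule:
        pa = p_accumulate(prev_gen, r.generation, params.q, mode=accumulate_mode)
        p_total = params.p_c + pa
        lam = r.turnover_per_year * p_total
        annual = annual_cancer_probability(r.turnover_per_year, p_total)
        rows.append(
            IncidenceRow(
                label=r.label,
                age_start=r.age_start,
                age_end=r.age_end,
                generation=r.generation,
                turnover_per_year=r.turnover_per_year,
                p_a=pa,
                p_total=p_total,
                lambda_annual=lam,
                p_health_annual=math.exp(-lam),
                p_cancer_annual=annual,
                p_cancer_5yr_pct=five_year_probability(annual),
                observed_5yr_pct=r.observed_5yr_pct,
            )
        )
        prev_gen = r.generation
    return IncidenceTable(tuple(rows), params=params)


def simple_model_probability(p: float, x: int) -> float:
    """Cancerization probability of an unconstrained exponential aggregate.

    After ``x`` division generations the aggregate holds 2**x cells; with
    per-division transformation probability ``p`` the number of transformed
    cells is Poisson(2**x * p), so P(cancer) = 1 - exp(-2**x * p). The curve
    is S-shaped in x and tends to 1 for any p > 0: under exponential growth
    cancer is eventually certain.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    if x < 0:
        raise ValueError(f"generation must be >= 0, got {x}")
    return -math.expm1(-(2.0 ** x) * p)


def simple_model_crossing_generation(p: float, threshold: float = 0.5) -> int:
    """Smallest integer generation at which the aggregate model reaches ``threshold``."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    x = 0
    while simple_model_probability(p, x) < threshold:
        x += 1
    return x


def generations_to_cell_count(cells: float) -> int:
    """Smallest number of doublings g with 2**g >= cells (cells >= 1)."""
    if cells < 1:
        raise ValueError(f"cell count must be >= 1, got {cells}")
    g = 0
    while 2.0 ** g < cells:
        g += 1
    return g


def lifetime_cell_budget(schedule: Sequence[AgeGroupRow] | Schedule) -> float:
    """Total cells generated over the schedule: sum of turnover x bracket width.

    This is the area under the n(t) step curve — the lifetime cell budget N
    that the turnover-reduction strategy rations out.
    """
    rows = schedule.rows if isinstance(schedule, Schedule) else tuple(schedule)
    return float(sum(r.turnover_per_year * (r.age_end - r.age_start) for r in rows))
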