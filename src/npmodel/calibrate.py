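"""Calibration of the incidence model against observed age-specific rates.

Four inverse problems are covered:

* deducing the background per-turnover probability ``p_c`` from early-life
  incidence, where mutation accumulation is still negligible;
* fitting the effective-mutation threshold ``q`` by grid search on a
  goodness-of-fit score;
* reverse-deducing the age-dependent turnover schedule n(t) from observed
  incidence, assuming the model holds;
* measuring the log-log slope of incidence against age (the classic
  multistage power-law signature).

The goodness-of-fit score is R^2 = 1 - RSS/TSS with TSS defined as the sum
of squares of the *model* (theoretical) incidence, not of centred observed
values. This is a nonstandard normalisation, implemented deliberately: it
is the score under which the threshold grid search selects q = 118 on the
packaged UK table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import (
    ModelParams,
    Schedule,
    p_accumulate,
    predict_incidence_table,
    IncidenceTable,
)


@dataclass(frozen=True)
class FitResult:
    """Outcome of the threshold grid search."""

    q_best: int
    r_squared: float
    rss: float
    tss: float
    trace: dict[int, float]


@dataclass(frozen=True)
class TurnoverRow:
    """Deduced turnover for one bracket."""

    label: str
    age_start: float
    age_end: float
    observed_5yr_pct: float
    p_total: float
    turnover_per_year: Optional[float]
    pct_change: Optional[float]  # percent change vs previous bracket


@dataclass(frozen=True)
class TurnoverDeduction:
    rows: tuple[TurnoverRow, ...]

    def __iter__(self):
        return iter(self.rows)

    @property
    def turnover(self) -> np.ndarray:
        return np.array(
            [math.nan if r.turnover_per_year is None else r.turnover_per_year
             for r in self.rows]
        )

    @property
    def pct_change(self) -> np.ndarray:
        return np.array(
            [math.nan if r.pct_change is None else r.pct_change for r in self.rows]
        )


def deduce_pc(early_incidence_5yr: float, turnover_per_year: float) -> float:
    """Deduce the background probability p_c from early-life incidence.

    ``early_incidence_5yr`` is the 5-year cancer probability observed at ages
    where accumulation is negligible (p ~ p_c). It is converted to an annual
    rate by dividing by 5 (small-probability reading), then inverted through
    the survival identity: p_c = -ln(1 - annual) / n.

    With a 5-year incidence of 0.05% and n = 4.2e13/year this gives 2.38e-18.
    """
    if not (0.0 <= early_incidence_5yr < 1.0):
        raise ValueError("5-year incidence must be in [0, 1)")
    if turnover_per_year <= 0:
        raise ValueError("turnover must be positive")
    annual = early_incidence_5yr / 5.0
    return -math.log1p(-annual) / turnover_per_year


def r_squared(
    model_incidence: Sequence[float], observed_incidence: Sequence[float]
) -> tuple[float, float, float]:
    """Coefficient of determination with model-sum-of-squares normalisation.

    Returns ``(r2, rss, tss)`` where RSS = sum((obs - model)^2) and
    TSS = sum(model^2). Note TSS is the sum of squared *theoretical* values,
    not the centred observed sum of squares.
    """
    model = np.asarray(model_incidence, dtype=float)
    obs = np.asarray(observed_incidence, dtype=float)
    if model.shape != obs.shape or model.ndim != 1 or model.size < 1:
        raise ValueError("model and observed must be equal-length 1-D vectors")
    tss = float(np.sum(model**2))
    if tss == 0.0:
        raise ZeroDivisionError("all-zero model incidence: TSS is zero")
    rss = float(np.sum((obs - model) ** 2))
    return 1.0 - rss / tss, rss, tss


def fit_threshold_q(
    schedule: Schedule,
    p_c: float,
    q_grid: Iterable[int],
    *,
    max_age: Optional[float] = None,
) -> FitResult:
    """Grid-search the effective-mutation threshold q against observed incidence.

    For each candidate q the forward model is run over the schedule and the
    predicted 5-year percentages are scored against the observed column with
    :func:`r_squared`. Returns the q with the highest score (smallest q on a
    tie) together with the full trace.

    ``max_age`` restricts scoring to brackets whose upper bound does not
    exceed it (e.g. 35 to fit only the constant-turnover early-life range).
    """
    grid = sorted(set(int(q) for q in q_grid))
    if not grid:
        raise ValueError("q grid must be non-empty")
    if not schedule.has_observed:
        raise ValueError("schedule must carry observed 5-year incidence")
    mask = np.array(
        [max_age is None or r.age_end <= max_age for r in schedule], dtype=bool
    )
    if not mask.any():
        raise ValueError(f"no brackets with upper bound <= {max_age}")
    observed = np.array([r.observed_5yr_pct for r in schedule])[mask]
    if not np.any(observed):
        raise ValueError("observed incidence is all zero")

    best: Optional[tuple[int, float, float, float]] = None
    trace: dict[int, float] = {}
    for q in grid:
        table = predict_incidence_table(schedule, ModelParams(p_c=p_c, q=q))
        r2, rss, tss = r_squared(table.five_year_pct[mask], observed)
        trace[q] = r2
        if best is None or r2 > best[1]:
            best = (q, r2, rss, tss)
    assert best is not None
    return FitResult(
        q_best=best[0], r_squared=best[1], rss=best[2], tss=best[3], trace=trace
    )


def deduce_turnover_schedule(
    schedule: Schedule, params: ModelParams
) -> TurnoverDeduction:
    """Reverse-deduce the turnover n(t) that makes the model match observation.

    Per bracket, the observed 5-year incidence is converted back to an annual
    probability via 1 - (1 - P5)**(1/5), then inverted through the survival
    identity: n = -ln(1 - annual) / p_total, with p_total = p_c + p_a taken
    from the generation schedule. Brackets with zero observed incidence are
    non-invertible and reported with turnover None.

    Also reports the percent change of deduced turnover per 5-year step; on
    the UK table with q=118 this recovers the ~25%-per-5-years decline in
    the 35-75 range.
    """
    if not schedule.has_observed:
        raise ValueError("schedule must carry observed 5-year incidence")
    rows: list[TurnoverRow] = []
    prev_gen: Optional[float] = None
    prev_n: Optional[float] = None
    for r in schedule:
        pa = p_accumulate(prev_gen, r.generation, params.q)
        p_total = params.p_c + pa
        p5 = r.observed_5yr_pct / 100.0
        if not (0.0 <= p5 < 1.0):
            raise ValueError(
                f"bracket {r.label!r}: observed 5-year incidence must be in [0, 1)"
            )
        if p5 == 0.0 or p_total == 0.0:
            n = None
            change = None
        else:
            annual = -math.expm1(math.log1p(-p5) / 5.0)
            n = -math.log1p(-annual) / p_total
            change = (
                None if prev_n is None else 100.0 * (n - prev_n) / prev_n
            )
        rows.append(
            TurnoverRow(
                label=r.label,
                age_start=r.age_start,
                age_end=r.age_end,
                observed_5yr_pct=r.observed_5yr_pct,
                p_total=p_total,
                turnover_per_year=n,
                pct_change=change,
            )
        )
        prev_gen = r.generation
        prev_n = n if n is not None else prev_n
    return TurnoverDeduction(tuple(rows))


def loglog_slope(
    table: IncidenceTable, from_age: float, to_age: float
) -> float:
    """OLS slope of log10(annual cancer probability) vs log10(age).

    Ages are the bracket upper bounds; brackets whose upper bound lies in
    ``[from_age, to_age]`` are included. A slope near 6 is the multistage
    power-law signature of age-specific cancer incidence; the model with
    constant turnover yields ~5.8 over ages 25-75.
    """
    pts = [
        (r.age_end, r.p_cancer_annual)
        for r in table
        if from_age <= r.age_end <= to_age
    ]
    if len(pts) < 2:
        raise ValueError(
            f"need at least 2 brackets with upper bound in [{from_age}, {to_age}]"
        )
    x = np.log10([a for a, _ in pts])
    y = np.log10([p for _, p in pts])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
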