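"""Threshold model of conservation-practice diffusion with program accounting.

Producers in a county hold heterogeneous net returns to adopting a
conservation practice.  A producer's return in period ``t`` is the sum of a
time-invariant individual component, distributed Normal(mu, sigma) across the
county, and a common time-varying component ``L_t`` (prices, practice
effectiveness, adoption costs).  A producer adopts whenever the total return
is positive, so the county adoption share in period ``t`` is::

    share_t = P(r_i + L_t > 0) = Phi((mu + L_t) / sigma)

A payment-for-practice program paying a fixed incentive ``P`` to anyone who
adopts during a window shifts the final-period return by ``P``.  Enrollees
split into *additional* adopters (who adopt only because of the incentive)
and *non-additional* adopters (who would have adopted during the window
anyway but are paid all the same, because the administrator cannot observe
counterfactual returns).  Credits are issued per enrolled producer; the gap
between credits and additional tons is what the cost metrics quantify.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "NetReturnModel",
    "ProgramSpec",
    "CountyScenario",
    "ProgramOutcome",
    "CostMetrics",
    "RoundingPolicy",
    "adoption_share",
    "adoption_path",
    "program_outcome",
    "cost_metrics",
    "simulate_agents",
    "rank_counties",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.625 -> 0.63 at 2 digits).

    Plain :func:`round` uses banker's rounding, which disagrees with the
    convention used for the printed dollar figures in this model.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class NetReturnModel:
    """County-level distribution of producers' net returns to adoption.

    Parameters
    ----------
    county_id:
        Identifier carried through to outputs.
    mu:
        Mean of the time-invariant return component, dollars.
    sigma:
        Standard deviation of the time-invariant component, dollars (>= 0).
    L_path:
        Common time-varying return component per period, dollars.
    """

    county_id: str
    mu: float
    sigma: float = 1.0
    L_path: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if len(self.L_path) == 0:
            raise ValueError("L_path must be non-empty")
        if not all(math.isfinite(v) for v in self.L_path):
            raise ValueError("L_path values must be finite")
        object.__setattr__(self, "L_path", tuple(float(v) for v in self.L_path))


@dataclass(frozen=True)
class ProgramSpec:
    """A payment-for-practice program: per-enrollee incentive plus fixed cost.

    ``window`` is the (start, end) pair of period indices; adoption occurring
    between these periods is compensated at ``incentive`` dollars.
    """

    incentive: float
    fixed_cost: float
    window: tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        if self.incentive < 0:
            raise ValueError("incentive must be >= 0")
        if self.fixed_cost < 0:
            raise ValueError("fixed_cost must be >= 0")
        if self.window[0] >= self.window[1]:
            raise ValueError("window must satisfy start < end")


@dataclass(frozen=True)
class CountyScenario:
    """A county's return model plus sequestration rate and producer count."""

    model: NetReturnModel
    seq_rate: float = 1.0  # tons CO2e per adopting producer per program
    population: int = 1000

    def __post_init__(self) -> None:
        if self.seq_rate < 0:
            raise ValueError("seq_rate must be >= 0")
        if self.population < 1 or int(self.population) != self.population:
            raise ValueError("population must be a positive integer")


@dataclass(frozen=True)
class RoundingPolicy:
    """How adoption shares are converted to producer counts.

    ``exact`` keeps real-valued counts (share x population).
    ``nearest_percent`` first rounds each share to the nearest whole percent
    (ties away from zero), matching how the illustrative two-county figures
    are quoted.
    """

    mode: Literal["exact", "nearest_percent"] = "exact"

    def apply(self, share: float) -> float:
        if self.mode == "nearest_percent":
            return round_half_away(share, 2)
        return share


@dataclass(frozen=True)
class ProgramOutcome:
    """Decomposition of a program window into enrollment and additionality."""

    county_id: str
    share_baseline_start: float
    share_baseline_end: float
    share_with_program: float
    enrollee_share: float
    additional_share: float
    nonadditional_share: float
    enrollee_count: float
    additional_count: float
    nonadditional_count: float
    total_cost: float
    credits: float
    additional_tons: float
    clamped_negative: bool = False


_UNDEFINED_MSG = "undefined: zero denominator ({name})"


@dataclass(frozen=True)
class CostMetrics:
    """Per-unit program cost metrics; NaN marks an undefined metric."""

    county_id: str
    ac_per_enrollee: float
    ac_per_credit: float
    ac_per_additional_ton: float
    quality: float  # additional tons per dollar of credits sold at cost
    notes: tuple[str, ...] = field(default_factory=tuple)


def adoption_share(model: NetReturnModel, period: int) -> float:
    """Fraction of producers adopting in ``period``: Phi((mu + L_t)/sigma).

    With sigma == 0 the return distribution is degenerate at mu + L_t and the
    share is the indicator of that point lying above zero.
    """
    L = model.L_path[period]  # IndexError for invalid period, as documented
    return _share(model.mu, model.sigma, L)


def _share(mu: float, sigma: float, shift: float) -> float:
    if sigma == 0:
        return 1.0 if mu + shift > 0 else 0.0
    return float(norm.cdf((mu + shift) / sigma))


def adoption_path(model: NetReturnModel) -> tuple[float, ...]:
    """Adoption share for every period of ``L_path`` (the diffusion curve)."""
    return tuple(adoption_share(model, t) for t in range(len(model.L_path)))


def program_outcome(
    scenario: CountyScenario,
    program: ProgramSpec,
    rounding: RoundingPolicy = RoundingPolicy("exact"),
) -> ProgramOutcome:
    """Enrollment, additionality, cost and credit accounting for one county.

    Baseline shares come from the no-program path at the window's start and
    end periods; the with-program share shifts the end-period return by the
    incentive.  Non-additional enrollees are the baseline adopters within the
    window; additional enrollees adopt only because of the incentive.
    Negative raw shares (possible when ``L`` declines over the window by more
    than the incentive restores) are clamped to zero and flagged.
    """
    model = scenario.model
    start, end = program.window
    if not (0 <= start < len(model.L_path) and 0 <= end < len(model.L_path)):
        raise IndexError("program window outside L_path")

    s0 = adoption_share(model, start)
    s1 = adoption_share(model, end)
    s_prog = _share(model.mu, model.sigma, model.L_path[end] + program.incentive)

    enroll_raw = s_prog - s0
    nonadd_raw = s1 - s0
    add_raw = s_prog - s1
    clamped = enroll_raw < 0 or nonadd_raw < 0 or add_raw < 0
    if clamped:
        warnings.warn(
            f"county {model.county_id}: negative raw share clamped to 0 "
            "(declining L over the program window)",
            stacklevel=2,
        )
    nonadd = max(nonadd_raw, 0.0)
    add = max(add_raw, 0.0)
    enroll = max(enroll_raw, 0.0) if not clamped else nonadd + add

    enroll_r = rounding.apply(enroll)
    add_r = rounding.apply(add)
    nonadd_r = rounding.apply(nonadd)

    pop = scenario.population
    enroll_n = enroll_r * pop
    add_n = add_r * pop
    nonadd_n = nonadd_r * pop

    total_cost = program.incentive * enroll_n + program.fixed_cost
    credits = enroll_n * scenario.seq_rate
    additional_tons = add_n * scenario.seq_rate
    return ProgramOutcome(
        county_id=model.county_id,
        share_baseline_start=s0,
        share_baseline_end=s1,
        share_with_program=s_prog,
        enrollee_share=enroll_r,
        additional_share=add_r,
        nonadditional_share=nonadd_r,
        enrollee_count=enroll_n,
        additional_count=add_n,
        nonadditional_count=nonadd_n,
        total_cost=total_cost,
        credits=credits,
        additional_tons=additional_tons,
        clamped_negative=bool(clamped),
    )


def cost_metrics(outcome: ProgramOutcome, program: ProgramSpec) -> CostMetrics:
    """Average-cost metrics per enrollee, per credit, and per additional ton.

    Any metric whose denominator is zero is returned as NaN with an
    explanatory note rather than raising, so county sweeps stay total.
    """
    notes: list[str] = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            notes.append(_UNDEFINED_MSG.format(name=name))
            return math.nan
        return num / den

    ac_enrollee = safe(outcome.total_cost, outcome.enrollee_count, "enrollee_count")
    ac_credit = safe(outcome.total_cost, outcome.credits, "credits")
    ac_add = safe(outcome.total_cost, outcome.additional_tons, "additional_tons")
    quality = safe(outcome.additional_tons, outcome.total_cost, "total_cost")
    return CostMetrics(
        county_id=outcome.county_id,
        ac_per_enrollee=ac_enrollee,
        ac_per_credit=ac_credit,
        ac_per_additional_ton=ac_add,
        quality=quality,
        notes=tuple(notes),
    )


def simulate_agents(
    scenario: CountyScenario,
    program: ProgramSpec,
    n_draws: int,
    seed: int,
) -> ProgramOutcome:
    """Monte-Carlo counterpart of :func:`program_outcome`.

    Draws ``n_draws`` producer returns from Normal(mu, sigma) and applies the
    adoption and enrollment rules producer by producer.  Counts are reported
    on the drawn population (``n_draws`` producers), shares empirically.
    Serves as an independent sampling check on the closed form.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    model = scenario.model
    start, end = program.window
    rng = np.random.default_rng(seed)
    r = rng.normal(model.mu, model.sigma, size=n_draws)

    base_start = r + model.L_path[start] > 0
    base_end = r + model.L_path[end] > 0
    with_prog = r + model.L_path[end] + program.incentive > 0

    # Enrollees: adopt during the window once the program is in place.
    enrollee = with_prog & ~base_start
    nonadditional = base_end & ~base_start
    additional = with_prog & ~base_end

    enroll = enrollee.mean()
    add = additional.mean()
    nonadd = nonadditional.mean()
    enroll_n = int(enrollee.sum())
    add_n = int(additional.sum())
    nonadd_n = int(nonadditional.sum())
    total_cost = program.incentive * enroll_n + program.fixed_cost
    return ProgramOutcome(
        county_id=model.county_id,
        share_baseline_start=float(base_start.mean()),
        share_baseline_end=float(base_end.mean()),
        share_with_program=float(with_prog.mean()),
        enrollee_share=float(enroll),
        additional_share=float(add),
        nonadditional_share=float(nonadd),
        enrollee_count=enroll_n,
        additional_count=add_n,
        nonadditional_count=nonadd_n,
        total_cost=total_cost,
        credits=enroll_n * scenario.seq_rate,
        additional_tons=add_n * scenario.seq_rate,
    )


_METRIC_FIELDS = {
    "per_credit": "ac_per_credit",
    "per_additional_ton": "ac_per_additional_ton",
    "quality": "quality",
}


def rank_counties(
    scenarios: Sequence[CountyScenario],
    program: ProgramSpec,
    metric: Literal["per_credit", "per_additional_ton", "quality"] = "per_credit",
    rounding: RoundingPolicy = RoundingPolicy("exact"),
) -> list[tuple[CountyScenario, ProgramOutcome, CostMetrics]]:
    """Rank counties by a cost metric (ascending costs, descending quality).

    Undefined (NaN) metrics sort last; ties break by county_id, and the sort
    is stable.
    """
    if len(scenarios) == 0:
        raise ValueError("need at least one scenario")
    if metric not in _METRIC_FIELDS:
        raise ValueError(f"unknown metric {metric!r}")
    attr = _METRIC_FIELDS[metric]
    rows = []
    for sc in scenarios:
        out = program_outcome(sc, program, rounding)
        met = cost_metrics(out, program)
        rows.append((sc, out, met))

    descending = metric == "quality"

    def key(row: tuple[CountyScenario, ProgramOutcome, CostMetrics]):
        v = getattr(row[2], attr)
        undefined = math.isnan(v)
        sort_v = 0.0 if undefined else (-v if descending else v)
        return (undefined, sort_v, row[0].model.county_id)

    return sorted(rows, key=key)
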