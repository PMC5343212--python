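"""Synthetic two-arm activity trial generator.

Emulates the data-generating conditions the analysis assumes: two arms
(104 intervention / 101 control), weekly MVPA minutes per participant
measured by self-report (PAR) and accelerometer at weeks 0/26/52,
~16% dropout equal across arms, and per-task staff-time logs from
which a personnel cost ledger can be built.

Marginal model
--------------
Weekly MVPA minutes are nonnegative with substantial point mass at
zero in an underactive population.  Each timepoint value is therefore
drawn as a zero-censored (tobit) normal: ``max(N(mu, sigma), 0)``,
with the parent ``(mu, sigma)`` *moment-matched* so the generated
values reproduce the configured mean and SD exactly in expectation.
(A zero-truncated normal cannot: at baseline the coefficient of
variation 15/8 exceeds the truncated-normal supremum of 1.)  The
baseline self-report marginal is additionally conditioned on the
eligibility screen (< 60 min/week); follow-up self-report marginals
are matched *conditional on the screening event*, since the screen
truncates the latent baseline and would otherwise bias correlated
follow-ups downward.

Within a measure, timepoints share a Gaussian copula on the latent
normal scale (default pairwise correlation 0.4, a plausible value for
repeated physical-activity measures); the two measures are generated
independently.  Both are assumptions, not reported facts, and are
exposed in the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .costs import CostItem, PersonnelRate
from .effectiveness import OutcomeSeries, OutcomeTimepoint
from .errors import ConfigurationError, InvalidParameterError
from .money import round_cents, to_cents

__all__ = [
    "TimepointSpec",
    "StaffTask",
    "TrialSimConfig",
    "ParticipantRecord",
    "moment_match_censored_normal",
    "simulate_trial",
    "summarize_to_series",
    "simulate_staff_log",
    "staff_log_to_cost_items",
    "simulate_count_minutes",
    "DEFAULT_OUTCOME_PARAMS",
    "DEFAULT_STAFF_CATALOG",
    "DEFAULT_RATES",
]


@dataclass(frozen=True)
class TimepointSpec:
    """Target mean/SD of weekly MVPA minutes at one study week."""

    week: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"sd must be >= 0, got {self.sd}")
        if self.mean < 0:
            raise ConfigurationError(f"mean must be >= 0, got {self.mean}")


#: Observed completer means/SDs of the emulated trial, by arm and measure.
DEFAULT_OUTCOME_PARAMS: dict[tuple[str, str], tuple[TimepointSpec, ...]] = {
    ("intervention", "par"): (
        TimepointSpec(0, 8.0, 15.0),
        TimepointSpec(26, 112.8, 97.1),
        TimepointSpec(52, 108.6, 107.2),
    ),
    ("control", "par"): (
        TimepointSpec(0, 8.5, 14.6),
        TimepointSpec(26, 63.5, 88.7),
        TimepointSpec(52, 75.9, 89.8),
    ),
    ("intervention", "accelerometer"): (
        TimepointSpec(0, 35.8, 69.7),
        TimepointSpec(26, 75.8, 91.0),
        TimepointSpec(52, 70.4, 86.4),
    ),
    ("control", "accelerometer"): (
        TimepointSpec(0, 28.7, 48.2),
        TimepointSpec(26, 43.0, 60.9),
        TimepointSpec(52, 55.5, 74.6),
    ),
}

#: Staff wage rates used by the staff-time log (loaded annual salaries,
#: 10% overhead, 2000-hour work year).
DEFAULT_RATES: dict[str, PersonnelRate] = {
    "trainer": PersonnelRate("trainer", 86520.0, overhead_frac=0.10),
    "research_associate": PersonnelRate("research_associate", 56153.0, overhead_frac=0.10),
}


@dataclass(frozen=True)
class StaffTask:
    """One logged staff activity.

    ``per`` is "participant" (logged once per enrolled participant) or
    "cohort" (logged once per arm, e.g. staff training).  Failed
    contact attempts are drawn per participant as Poisson with mean
    ``mean_failed_attempts``, each costing ``failed_attempt_minutes``.
    """

    label: str
    arm: str
    category: str  # personnel_training | personnel_delivery | website_maintenance
    phase: int  # 1 = months 0-6, 2 = months 7-12
    minutes: float
    rate_ref: str
    per: str = "participant"
    failed_attempt_minutes: float = 0.0
    mean_failed_attempts: float = 0.0

    def __post_init__(self) -> None:
        if self.per not in ("participant", "cohort"):
            raise ConfigurationError(f"per must be participant|cohort, got {self.per!r}")
        if self.phase not in (1, 2):
            raise ConfigurationError(f"phase must be 1 or 2, got {self.phase}")
        if self.minutes < 0 or self.failed_attempt_minutes < 0 or self.mean_failed_attempts < 0:
            raise ConfigurationError(f"task {self.label!r}: negative time parameter")


def _default_staff_catalog() -> tuple[StaffTask, ...]:
    """Task catalog calibrated so expected arm personnel costs match the
    effort structure observed in the emulated trial (joint 6 h / 2 h
    training sessions; ~106 vs ~38 delivery minutes per participant in
    phase 1; ~45 vs ~22 in phase 2; weekly website maintenance)."""
    i, c = "intervention", "control"
    ra = "research_associate"
    return (
        # one-off joint training session (trainer + trainee hours)
        StaffTask("training_trainer", i, "personnel_training", 1, 360.0, "trainer", per="cohort"),
        StaffTask("training_trainee", i, "personnel_training", 1, 360.0, ra, per="cohort"),
        StaffTask("training_trainer", c, "personnel_training", 1, 120.0, "trainer", per="cohort"),
        StaffTask("training_trainee", c, "personnel_training", 1, 120.0, ra, per="cohort"),
        # intervention delivery, phase 1
        StaffTask("orientation_visit", i, "personnel_delivery", 1, 48.0, ra),
        StaffTask("call_1week", i, "personnel_delivery", 1, 12.0, ra, failed_attempt_minutes=3.0, mean_failed_attempts=0.8),
        StaffTask("call_1month", i, "personnel_delivery", 1, 12.0, ra, failed_attempt_minutes=3.0, mean_failed_attempts=0.8),
        StaffTask("visit_6month", i, "personnel_delivery", 1, 24.0, ra),
        StaffTask("materials_prep", i, "personnel_delivery", 1, 5.0, ra),
        # intervention delivery, phase 2
        StaffTask("call_9month", i, "personnel_delivery", 2, 12.0, ra, failed_attempt_minutes=3.0, mean_failed_attempts=0.8),
        StaffTask("resend_support", i, "personnel_delivery", 2, 30.6, ra),
        # control delivery
        StaffTask("orientation_visit", c, "personnel_delivery", 1, 20.0, ra),
        StaffTask("call_1month", c, "personnel_delivery", 1, 5.0, ra, failed_attempt_minutes=3.0, mean_failed_attempts=0.8),
        StaffTask("visit_6month", c, "personnel_delivery", 1, 7.6, ra),
        StaffTask("materials_prep", c, "personnel_delivery", 1, 3.0, ra),
        StaffTask("call_9month", c, "personnel_delivery", 2, 5.0, ra, failed_attempt_minutes=3.0, mean_failed_attempts=0.8),
        StaffTask("resend_support", c, "personnel_delivery", 2, 14.5, ra),
        # routine website maintenance (message board, ask-the-expert)
        StaffTask("website_maintenance", i, "website_maintenance", 1, 524.0, ra, per="cohort"),
        StaffTask("website_maintenance", i, "website_maintenance", 2, 427.0, ra, per="cohort"),
        StaffTask("website_maintenance", c, "website_maintenance", 1, 15.5, ra, per="cohort"),
        StaffTask("website_maintenance", c, "website_maintenance", 2, 3.9, ra, per="cohort"),
    )


DEFAULT_STAFF_CATALOG = _default_staff_catalog()


@dataclass(frozen=True)
class TrialSimConfig:
    """Generative specification of the synthetic trial."""

    n_intervention: int = 104
    n_control: int = 101
    outcome_params: dict[tuple[str, str], tuple[TimepointSpec, ...]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_PARAMS)
    )
    dropout: float = 0.161
    rho: float = 0.4
    #: eligibility screen: baseline self-reported minutes must be below this
    eligibility_max_baseline: float | None = 60.0
    staff_catalog: tuple[StaffTask, ...] = DEFAULT_STAFF_CATALOG
    rates: dict[str, PersonnelRate] = field(default_factory=lambda: dict(DEFAULT_RATES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_intervention <= 0 or self.n_control <= 0:
            raise ConfigurationError("arm sizes must be positive")
        if not 0 <= self.dropout < 1:
            raise ConfigurationError(f"dropout must be in [0, 1), got {self.dropout}")
        if not -1 < self.rho < 1:
            raise ConfigurationError(f"rho must be in (-1, 1), got {self.rho}")

    def n_for(self, arm: str) -> int:
        return self.n_intervention if arm == "intervention" else self.n_control

    def with_n(self, n_per_arm: int) -> "TrialSimConfig":
        return replace(self, n_intervention=n_per_arm, n_control=n_per_arm)


@dataclass
class ParticipantRecord:
    """One synthetic participant's trajectories."""

    participant_id: str
    arm: str
    completed: bool
    #: (measure, week) -> weekly MVPA minutes; None after baseline for dropouts
    values: dict[tuple[str, float], float | None]


# ---------------------------------------------------------------------------
# moment matching for the censored-normal marginals


def _censored_moments(mu: float, sigma: float, upper: float | None) -> tuple[float, float]:
    """Mean and SD of max(X, 0) where X ~ N(mu, sigma) conditioned on
    X < upper (no conditioning when upper is None)."""
    alpha = (0.0 - mu) / sigma
    beta = math.inf if upper is None else (upper - mu) / sigma
    z_upper = stats.norm.cdf(beta)
    if z_upper <= 0:
        return math.nan, math.nan
    p_pos = (stats.norm.cdf(beta) - stats.norm.cdf(alpha)) / z_upper
    if p_pos <= 1e-300:
        return 0.0, 0.0
    mt, vt = stats.truncnorm.stats(alpha, beta, loc=mu, scale=sigma, moments="mv")
    mean = p_pos * float(mt)
    second = p_pos * (float(vt) + float(mt) ** 2)
    var = max(second - mean**2, 0.0)
    return mean, math.sqrt(var)


def _censored_moments_given_screen(
    mu: float, sigma: float, rho: float, zcap: float
) -> tuple[float, float]:
    """Mean and SD of max(mu + sigma*Z, 0) where (Z, Zb) are standard
    bivariate normal with correlation rho, conditional on the
    eligibility event Zb < zcap (the screened baseline latent).

    Conditional on Zb = z, the value is censored-normal with location
    mu + sigma*rho*z and scale sigma*sqrt(1-rho^2); the event average
    is taken by Gauss-Legendre quadrature over the truncated Zb.
    """
    nodes, weights = np.polynomial.legendre.leggauss(96)
    lo = min(-8.0, zcap - 1.0)
    z = 0.5 * (zcap - lo) * nodes + 0.5 * (zcap + lo)
    w = 0.5 * (zcap - lo) * weights * stats.norm.pdf(z) / stats.norm.cdf(zcap)
    a = mu + sigma * rho * z
    b = sigma * math.sqrt(1.0 - rho**2)
    if b <= 0:
        y = np.clip(a, 0.0, None)
        m1, m2 = y, y**2
    else:
        r = a / b
        m1 = a * stats.norm.cdf(r) + b * stats.norm.pdf(r)
        m2 = (a**2 + b**2) * stats.norm.cdf(r) + a * b * stats.norm.pdf(r)
    mean = float(np.sum(w * m1))
    var = max(float(np.sum(w * m2)) - mean**2, 0.0)
    return mean, math.sqrt(var)


@lru_cache(maxsize=512)
def moment_match_censored_normal(
    mean: float,
    sd: float,
    upper: float | None = None,
    rho: float = 0.0,
    zcap: float | None = None,
) -> tuple[float, float]:
    """Parent (mu, sigma) of a zero-censored normal with given moments.

    Solves for the latent-normal location and scale such that
    ``max(N(mu, sigma), 0)`` — conditioned on being below ``upper``
    when an eligibility cap applies directly, or on the *baseline*
    passing its cap (``zcap`` on the latent baseline, correlation
    ``rho``) for follow-up timepoints — has the requested mean and SD.
    Degenerate targets (sd == 0) return a point mass at the mean.

    Raises ConfigurationError when no parent reproduces the targets
    (e.g. a mean of zero with positive SD under a tight cap).
    """
    if mean < 0 or sd < 0:
        raise ConfigurationError(f"targets must be >= 0, got mean={mean} sd={sd}")
    if upper is not None and mean >= upper:
        raise ConfigurationError(
            f"target mean {mean} is not below the eligibility cap {upper}"
        )
    if sd == 0:
        return float(mean), 0.0

    def residuals(theta: np.ndarray) -> np.ndarray:
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        if zcap is not None and rho != 0.0:
            m, s = _censored_moments_given_screen(mu, sigma, rho, zcap)
        else:
            m, s = _censored_moments(mu, sigma, upper)
        if not (math.isfinite(m) and math.isfinite(s)):
            return np.array([1e6, 1e6])
        return np.array([m - mean, s - sd])

    starts = [
        (mean, sd),
        (mean - sd, 1.5 * sd),
        (0.0, 2.0 * sd),
        (-sd, 2.0 * sd),
        (-2.0 * sd, 3.0 * sd),
    ]
    best = None
    for mu0, s0 in starts:
        sol = optimize.least_squares(
            residuals, x0=[mu0, math.log(max(s0, 1e-6))], xtol=1e-14, ftol=1e-14
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.cost < 1e-16:
            break
    assert best is not None
    resid = residuals(best.x)
    if np.abs(resid).max() > 1e-6 * max(mean, sd, 1.0):
        raise ConfigurationError(
            f"no zero-censored normal reproduces mean={mean}, sd={sd}"
            + (f" under cap {upper}" if upper is not None else "")
        )
    return float(best.x[0]), float(math.exp(best.x[1]))


# ---------------------------------------------------------------------------
# trial simulation


def _equicorr_cholesky(rho: float, k: int) -> np.ndarray:
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    return np.linalg.cholesky(corr)


def _draw_measure(
    rng: np.random.Generator,
    n: int,
    specs: tuple[TimepointSpec, ...],
    rho: float,
    upper_baseline: float | None,
) -> np.ndarray:
    """n x T matrix of weekly minutes for one arm and measure."""
    t = len(specs)
    base = moment_match_censored_normal(specs[0].mean, specs[0].sd, upper_baseline)
    zcap = None
    if upper_baseline is not None and base[1] > 0:
        zcap = (upper_baseline - base[0]) / base[1]
    parents = [base] + [
        moment_match_censored_normal(sp.mean, sp.sd, None, rho, zcap)
        for sp in specs[1:]
    ]
    chol = _equicorr_cholesky(rho, t)
    mus = np.array([p[0] for p in parents])
    sigmas = np.array([p[1] for p in parents])

    out = np.empty((n, t))
    pending = np.arange(n)
    guard = 0
    while pending.size:
        z = rng.standard_normal((pending.size, t)) @ chol.T
        x = mus + sigmas * z
        if upper_baseline is not None:
            ok = x[:, 0] < upper_baseline
        else:
            ok = np.ones(pending.size, dtype=bool)
        out[pending[ok]] = np.clip(x[ok], 0.0, None)
        pending = pending[~ok]
        guard += 1
        if guard > 10_000:  # pragma: no cover - eligibility cap far below mean
            raise ConfigurationError(
                "eligibility rejection sampling failed to terminate; "
                "is the baseline mean far above the cap?"
            )
    return out


def simulate_trial(config: TrialSimConfig) -> list[ParticipantRecord]:
    """Draw the full synthetic trial; reproducible from ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    records: list[ParticipantRecord] = []
    measures = sorted({measure for (_, measure) in config.outcome_params})
    for arm in ("intervention", "control"):
        n = config.n_for(arm)
        values_by_measure: dict[str, tuple[tuple[float, ...], np.ndarray]] = {}
        for measure in measures:
            specs = config.outcome_params[(arm, measure)]
            upper = config.eligibility_max_baseline if measure == "par" else None
            draws = _draw_measure(rng, n, specs, config.rho, upper)
            values_by_measure[measure] = (tuple(sp.week for sp in specs), draws)
        completed = rng.random(n) >= config.dropout
        for idx in range(n):
            values: dict[tuple[str, float], float | None] = {}
            for measure, (weeks, draws) in values_by_measure.items():
                for j, week in enumerate(weeks):
                    if week > 0 and not completed[idx]:
                        values[(measure, week)] = None
                    else:
                        values[(measure, week)] = float(draws[idx, j])
            records.append(
                ParticipantRecord(
                    participant_id=f"{arm[0].upper()}{idx + 1:04d}",
                    arm=arm,
                    completed=bool(completed[idx]),
                    values=values,
                )
            )
    return records


def records_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Long-format view: participant_id, arm, completed, measure, week, minutes."""
    rows = []
    for rec in records:
        for (measure, week), value in sorted(rec.values.items()):
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "arm": rec.arm,
                    "completed": rec.completed,
                    "measure": measure,
                    "week": week,
                    "weekly_minutes": value,
                }
            )
    return pd.DataFrame(rows)


def summarize_to_series(
    records: list[ParticipantRecord],
) -> dict[tuple[str, str], OutcomeSeries]:
    """Completer-only means/SDs/n per arm, measure and week."""
    frame = records_to_frame(records)
    completers = frame[frame["completed"]]
    for arm in frame["arm"].unique():
        n_comp = completers.loc[completers["arm"] == arm, "participant_id"].nunique()
        if n_comp < 2:
            raise ConfigurationError(f"fewer than 2 completers in arm {arm!r}")
    out: dict[tuple[str, str], OutcomeSeries] = {}
    for (arm, measure), grp in completers.groupby(["arm", "measure"]):
        tps = []
        for week, wgrp in grp.groupby("week"):
            vals = wgrp["weekly_minutes"].dropna()
            tps.append(
                OutcomeTimepoint(
                    week=float(week),
                    mean_weekly_minutes=float(vals.mean()),
                    sd=float(vals.std(ddof=1)),
                    n=int(vals.size),
                )
            )
        out[(arm, measure)] = OutcomeSeries(arm=arm, measure=measure, timepoints=tuple(tps))
    return out


# ---------------------------------------------------------------------------
# staff-time log


def simulate_staff_log(config: TrialSimConfig) -> pd.DataFrame:
    """Per-task staff-time entries, including failed contact attempts.

    Columns: arm, participant_id ('' for cohort-level tasks), task,
    category, phase, minutes, rate_ref.  Reproducible from the seed.
    """
    # offset stream so the log does not consume the trial draws
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    rows = []
    for task in config.staff_catalog:
        if task.rate_ref not in config.rates:
            raise ConfigurationError(
                f"task {task.label!r} references unknown rate {task.rate_ref!r}"
            )
        if task.per == "cohort":
            rows.append(
                {
                    "arm": task.arm,
                    "participant_id": "",
                    "task": task.label,
                    "category": task.category,
                    "phase": task.phase,
                    "minutes": task.minutes,
                    "rate_ref": task.rate_ref,
                }
            )
            continue
        n = config.n_for(task.arm)
        if task.mean_failed_attempts > 0:
            failed = rng.poisson(task.mean_failed_attempts, size=n)
        else:
            failed = np.zeros(n, dtype=int)
        for idx in range(n):
            pid = f"{task.arm[0].upper()}{idx + 1:04d}"
            rows.append(
                {
                    "arm": task.arm,
                    "participant_id": pid,
                    "task": task.label,
                    "category": task.category,
                    "phase": task.phase,
                    "minutes": task.minutes,
                    "rate_ref": task.rate_ref,
                }
            )
            if failed[idx]:
                rows.append(
                    {
                        "arm": task.arm,
                        "participant_id": pid,
                        "task": f"{task.label}_failed_attempts",
                        "category": task.category,
                        "phase": task.phase,
                        "minutes": float(failed[idx]) * task.failed_attempt_minutes,
                        "rate_ref": task.rate_ref,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["arm", "participant_id", "task", "category", "phase", "minutes", "rate_ref"],
    )


def staff_log_to_cost_items(
    log: pd.DataFrame, rates: dict[str, PersonnelRate] | None = None
) -> list[CostItem]:
    """Aggregate a staff-time log into personnel ledger lines.

    Phase-1 time feeds the 6-month amount; phases 1+2 the cumulative
    12-month amount.
    """
    rates = dict(DEFAULT_RATES) if rates is None else rates
    unknown = set(log["rate_ref"]) - set(rates)
    if unknown:
        raise ConfigurationError(f"staff log references unknown rates: {sorted(unknown)}")
    items: list[CostItem] = []
    if log.empty:
        return items
    for (arm, category), grp in log.groupby(["arm", "category"]):
        loaded = grp["rate_ref"].map(lambda r: rates[r].hourly_loaded)
        cost = grp["minutes"] / 60.0 * loaded
        amount_6 = round_cents(float(cost[grp["phase"] == 1].sum()))
        amount_12 = round_cents(float(cost.sum()))
        items.append(
            CostItem(
                label=f"{category} (staff log)",
                arm=arm,
                category=category,
                timing="per_phase",
                amount_6mo_cents=to_cents(amount_6),
                amount_12mo_cents=to_cents(amount_12),
                scaling_role="fixed" if category == "personnel_training" else "variable",
            )
        )
    return items


# ---------------------------------------------------------------------------
# count streams (for accelerometer-scoring demos and tests)


def simulate_count_minutes(
    rng: np.random.Generator,
    days: int = 7,
    wear_minutes_per_day: int = 840,
    bouts_per_day: float = 1.0,
    bout_minutes: tuple[int, int] = (10, 20),
    start: str = "2015-01-05 08:00",
) -> pd.DataFrame:
    """A plausible minute-level count stream: mostly sedentary/light
    minutes below the MVPA cut-point with occasional qualifying bouts.

    Returns a frame with columns timestamp, counts, worn.
    """
    if days < 1:
        raise InvalidParameterError("days must be >= 1")
    frames = []
    t0 = pd.Timestamp(start)
    for d in range(days):
        ts = pd.date_range(t0 + pd.Timedelta(days=d), periods=wear_minutes_per_day, freq="min")
        counts = rng.integers(0, 800, size=wear_minutes_per_day)
        n_bouts = rng.poisson(bouts_per_day)
        for _ in range(n_bouts):
            length = int(rng.integers(bout_minutes[0], bout_minutes[1] + 1))
            pos = int(rng.integers(0, wear_minutes_per_day - length))
            counts[pos : pos + length] = rng.integers(2200, 5000, size=length)
        frames.append(
            pd.DataFrame({"timestamp": ts, "counts": counts, "worn": 1})
        )
    return pd.concat(frames, ignore_index=True)
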