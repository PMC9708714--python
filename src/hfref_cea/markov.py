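"""Three-state Markov cohort engine.

States, in fixed order: ``stable`` heart failure, ``hospitalized`` (a
one-cycle transitional state: survivors return to stable in the next
cycle), and ``dead`` (absorbing).  Cardiovascular and background
(non-cardiovascular, age-banded) death probabilities are combined
additively by default, with the stay probability taking the remainder;
set ``mortality_combination="rate"`` for a combination on the hazard
scale (independent competing hazards).

Payoff accrual uses a half-cycle correction: state membership for cost
and QALY accrual in cycle ``k`` is the average of the occupancy at the
start and at the end of the cycle, and discounting is evaluated at the
mid-cycle time ``(k - 0.5)/12`` years with the annual rate compounded
continuously in cycle units, ``(1 + d)^(-t)``.  One-off hospitalization
event costs are attached to entries into the hospitalized state and are
not half-cycle corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    NOT_REACHED,
    InvalidParameterError,
    ModelParameters,
    TransitionSet,
)

__all__ = [
    "STATES",
    "TransitionMatrix",
    "CohortTrace",
    "ArmOutcome",
    "build_transition_matrix",
    "run_cohort",
    "summarize",
    "run_arm",
    "cumulative_incidence",
    "hospitalization_rate_at_risk",
    "EVENTS",
]

STATES = ("stable", "hospitalized", "dead")
EVENTS = ("all_cause_death", "cv_death", "hospitalization", "first_hospitalization")


@dataclass(frozen=True)
class TransitionMatrix:
    """One-cycle 3x3 transition matrix, valid at one cohort age."""

    matrix: np.ndarray

    def validate(self) -> None:
        m = self.matrix
        if m.shape != (3, 3):
            raise InvalidParameterError(f"transition matrix must be 3x3, got {m.shape}")
        if np.any(m < 0) or np.any(m > 1):
            raise InvalidParameterError("transition matrix entries outside [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, rtol=0, atol=1e-12):
            raise InvalidParameterError("transition matrix rows must sum to 1")
        if not (m[2, 0] == 0.0 and m[2, 1] == 0.0 and m[2, 2] == 1.0):
            raise InvalidParameterError("dead state must be absorbing")


def _combine_mortality(p_cv: float, p_ncv: float, how: str) -> float:
    if how == "additive":
        return p_cv + p_ncv
    if how == "rate":
        return 1.0 - (1.0 - p_cv) * (1.0 - p_ncv)
    raise InvalidParameterError(f"unknown mortality combination {how!r}")


def build_transition_matrix(
    params: ModelParameters,
    arm: str,
    age: float,
    mortality_combination: str = "additive",
) -> TransitionMatrix:
    """Assemble the one-cycle transition matrix for ``arm`` at cohort ``age``."""
    ts: TransitionSet = params.arm_transitions(arm)
    p_ncv = params.age_mortality.lookup(age)
    p_sh = ts.p_stable_to_hosp
    p_s_death = _combine_mortality(ts.p_stable_to_cvdeath, p_ncv, mortality_combination)
    p_h_death = _combine_mortality(ts.p_hosp_to_cvdeath, p_ncv, mortality_combination)
    if p_sh + p_s_death > 1.0:
        raise InvalidParameterError(
            f"{arm} at age {age}: stable-state exit probabilities sum to "
            f"{p_sh + p_s_death:.6f} > 1"
        )
    if p_h_death > 1.0:
        raise InvalidParameterError(
            f"{arm} at age {age}: hospitalized-state death probability exceeds 1"
        )
    m = np.array(
        [
            [1.0 - p_sh - p_s_death, p_sh, p_s_death],
            [1.0 - p_h_death, 0.0, p_h_death],
            [0.0, 0.0, 1.0],
        ]
    )
    tm = TransitionMatrix(m)
    tm.validate()
    return tm


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and payoff streams for one arm.

    ``occupancy`` has ``n_cycles + 1`` rows (cycle 0 is the initial
    all-stable cohort).  The increment arrays have one entry per cycle
    (cycle ``k`` covers the interval between occupancy rows ``k-1`` and
    ``k``).  ``hosp_entries`` and ``cv_death_flux`` are per-cycle flows
    per initial cohort member; ``stable_exposure`` is the start-of-cycle
    stable-state occupancy (person-time at risk of admission).
    """

    occupancy: np.ndarray          # (n+1, 3)
    cost_undisc: np.ndarray        # (n,)
    cost_disc: np.ndarray
    qaly_undisc: np.ndarray
    qaly_disc: np.ndarray
    hosp_entries: np.ndarray       # (n,)
    first_hosp_entries: np.ndarray # (n,) entries of never-hospitalized members
    cv_death_flux: np.ndarray      # (n,)
    stable_exposure: np.ndarray    # (n,)
    arm: str

    @property
    def n_cycles(self) -> int:
        return len(self.cost_undisc)

    @property
    def alive(self) -> np.ndarray:
        """Alive fraction at each cycle boundary (length ``n_cycles + 1``)."""
        return 1.0 - self.occupancy[:, 2]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle export: one row per (cycle, state) plus payoff columns."""
        n = self.n_cycles
        rows = []
        for k in range(n + 1):
            for j, state in enumerate(STATES):
                rows.append(
                    {
                        "cycle": k,
                        "state": state,
                        "occupancy": self.occupancy[k, j],
                        "cost_undiscounted": self.cost_undisc[k - 1] if k > 0 and j == 0 else np.nan,
                        "cost_discounted": self.cost_disc[k - 1] if k > 0 and j == 0 else np.nan,
                        "qaly_undiscounted": self.qaly_undisc[k - 1] if k > 0 and j == 0 else np.nan,
                        "qaly_discounted": self.qaly_disc[k - 1] if k > 0 and j == 0 else np.nan,
                        "hosp_entries": self.hosp_entries[k - 1] if k > 0 and j == 0 else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def run_cohort(
    params: ModelParameters,
    arm: str,
    mortality_combination: str = "additive",
) -> CohortTrace:
    """Iterate the cohort through ``n_cycles`` monthly cycles.

    The cohort starts fully in the stable state; its age advances by one
    month per cycle for the background-mortality lookup.
    """
    econ = params.econ
    n = econ.n_cycles
    ts = params.arm_transitions(arm)
    cs = params.arm_costs(arm)
    ut = params.utilities
    d = econ.discount_rate_annual

    occ = np.zeros((n + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    cost_u = np.zeros(n)
    cost_d = np.zeros(n)
    qaly_u = np.zeros(n)
    qaly_d = np.zeros(n)
    entries = np.zeros(n)
    first_entries = np.zeros(n)
    cv_flux = np.zeros(n)
    exposure = np.zeros(n)

    never_hosp = 1.0  # fraction still stable and never hospitalized
    for k in range(1, n + 1):
        age = econ.start_age + (k - 1) / 12.0
        p_ncv = params.age_mortality.lookup(age)
        p_sh = ts.p_stable_to_hosp
        p_s_death = _combine_mortality(ts.p_stable_to_cvdeath, p_ncv, mortality_combination)
        p_h_death = _combine_mortality(ts.p_hosp_to_cvdeath, p_ncv, mortality_combination)
        if p_sh + p_s_death > 1.0 or p_h_death > 1.0:
            raise InvalidParameterError(
                f"{arm} at age {age}: exit probabilities exceed 1"
            )
        S, H, D = occ[k - 1]
        new_h = S * p_sh
        S_next = S * (1.0 - p_sh - p_s_death) + H * (1.0 - p_h_death)
        occ[k] = (S_next, new_h, 1.0 - S_next - new_h)

        entries[k - 1] = new_h
        first_entries[k - 1] = never_hosp * p_sh
        never_hosp *= 1.0 - p_sh - p_s_death
        if mortality_combination == "additive":
            cv_flux[k - 1] = S * ts.p_stable_to_cvdeath + H * ts.p_hosp_to_cvdeath
        else:
            # hazard-scale split of the combined death probability
            for state_occ, p_cv in ((S, ts.p_stable_to_cvdeath), (H, ts.p_hosp_to_cvdeath)):
                p_all = 1.0 - (1.0 - p_cv) * (1.0 - p_ncv)
                r_cv = -math.log1p(-p_cv) if p_cv < 1 else math.inf
                r_all = r_cv + (-math.log1p(-p_ncv))
                share = r_cv / r_all if r_all > 0 else 0.0
                cv_flux[k - 1] += state_occ * p_all * share
        exposure[k - 1] = S

        # half-cycle-corrected occupancy for payoff accrual
        S_mid = 0.5 * (S + S_next)
        H_mid = 0.5 * (H + new_h)
        cu = (S_mid + H_mid) * cs.c_monthly_treatment + new_h * cs.c_hospitalization
        qu = (S_mid * ut.u_stable + H_mid * ut.u_hosp) / 12.0
        df = (1.0 + d) ** (-(k - 0.5) / 12.0)
        cost_u[k - 1] = cu
        cost_d[k - 1] = cu * df
        qaly_u[k - 1] = qu
        qaly_d[k - 1] = qu * df

    return CohortTrace(
        occupancy=occ,
        cost_undisc=cost_u,
        cost_disc=cost_d,
        qaly_undisc=qaly_u,
        qaly_disc=qaly_d,
        hosp_entries=entries,
        first_hosp_entries=first_entries,
        cv_death_flux=cv_flux,
        stable_exposure=exposure,
        arm=arm,
    )


def cumulative_incidence(trace: CohortTrace, event: str, at_cycle: int) -> float:
    """Cumulative incidence of ``event`` at ``at_cycle``, in percent.

    ``hospitalization`` counts recurrent admissions per initial cohort
    member, so it may exceed 100%; ``first_hospitalization`` counts each
    member at most once.
    """
    if not 0 <= at_cycle <= trace.n_cycles:
        raise ValueError(f"at_cycle {at_cycle} outside [0, {trace.n_cycles}]")
    if event == "all_cause_death":
        return float(trace.occupancy[at_cycle, 2]) * 100.0
    if event == "cv_death":
        return float(trace.cv_death_flux[:at_cycle].sum()) * 100.0
    if event == "hospitalization":
        return float(trace.hosp_entries[:at_cycle].sum()) * 100.0
    if event == "first_hospitalization":
        return float(trace.first_hosp_entries[:at_cycle].sum()) * 100.0
    raise ValueError(f"unknown event {event!r}; expected one of {EVENTS}")


def hospitalization_rate_at_risk(trace: CohortTrace, at_cycle: int) -> float:
    """Admission rate per at-risk person-month, scaled to ``at_cycle`` months (%).

    Events are admissions during the first ``at_cycle`` cycles and the
    denominator is stable-state person-time, so unlike the per-initial-member
    cumulative count this summary is not depleted by death.  It is the
    recurrent-event "hospitalization rate" convention used when trial event
    totals are divided by randomized patients over a fixed follow-up.
    """
    if not 1 <= at_cycle <= trace.n_cycles:
        raise ValueError(f"at_cycle {at_cycle} outside [1, {trace.n_cycles}]")
    events = trace.hosp_entries[:at_cycle].sum()
    exposure = trace.stable_exposure[:at_cycle].sum()
    if exposure == 0:
        return 0.0
    return float(events / exposure) * at_cycle * 100.0


def _median_survival_years(trace: CohortTrace) -> float:
    alive = trace.alive
    below = np.nonzero(alive < 0.5)[0]
    if len(below) == 0:
        return NOT_REACHED
    k = int(below[0])
    a0, a1 = alive[k - 1], alive[k]
    frac = (a0 - 0.5) / (a0 - a1)
    return ((k - 1) + frac) / 12.0


@dataclass(frozen=True)
class ArmOutcome:
    """Totals for one arm of the base-case (or scenario) cohort run."""

    arm: str
    total_cost: float            # discounted USD
    total_qalys: float           # discounted
    total_cost_undiscounted: float
    total_qalys_undiscounted: float
    life_years: float            # undiscounted
    median_survival_years: float # NOT_REACHED (inf) if never below 0.5
    trace: CohortTrace

    def survival_curve(self) -> np.ndarray:
        return self.trace.alive

    def incidence(self, event: str, at_cycle: int) -> float:
        return cumulative_incidence(self.trace, event, at_cycle)


def summarize(trace: CohortTrace, params: ModelParameters) -> ArmOutcome:
    """Reduce a trace to its decision-relevant totals."""
    alive_mid = 0.5 * (trace.alive[:-1] + trace.alive[1:])
    life_years = float(alive_mid.sum() / 12.0)
    return ArmOutcome(
        arm=trace.arm,
        total_cost=float(trace.cost_disc.sum()),
        total_qalys=float(trace.qaly_disc.sum()),
        total_cost_undiscounted=float(trace.cost_undisc.sum()),
        total_qalys_undiscounted=float(trace.qaly_undisc.sum()),
        life_years=life_years,
        median_survival_years=_median_survival_years(trace),
        trace=trace,
    )


def run_arm(params: ModelParameters, arm: str, **kwargs) -> ArmOutcome:
    """Convenience: :func:`run_cohort` followed by :func:`summarize`."""
    return summarize(run_cohort(params, arm, **kwargs), params)
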