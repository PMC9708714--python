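"""Synthetic two-arm randomized trial generator and transition-probability
estimator.

The simulator is the patient-level counterpart of the cohort engine: each
patient advances on the same discrete monthly grid under their arm's
transition probabilities (hospitalization occupies at most one cycle,
death is absorbing, recurrent admissions allowed), with background
non-cardiovascular mortality read from the age-banded table at the
patient's own age.  Enrollment ages are Normal(67, 10) truncated to
[40, 90], mirroring the age distribution of contemporary HFrEF trial
cohorts.

The estimator inverts the simulation: per-cycle transition probabilities
are events divided by person-cycles at risk in the source state, with
Wilson score 95% intervals.

Timing convention (identical to the cohort trace): a patient occupies a
state at each integer cycle index 0, 1, 2, ...; a hospitalization "at
cycle k" means the patient occupies the hospitalized state at index k,
and a death "at cycle k" means the patient is first dead at index k.
Follow-up of ``m`` months observes transitions into indices 1..m.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .parameters import ModelParameters

__all__ = [
    "TrialDataset",
    "TransitionEstimate",
    "simulate_trial",
    "estimate_transitions",
    "write_trial",
    "read_trial",
]

CV = "cv"
NON_CV = "non_cv"


@dataclass(frozen=True)
class TrialDataset:
    """Patient-level synthetic trial records.

    ``patients`` has one row per patient: ``patient_id, arm, age,
    followup_months, death_cycle`` (NaN when censored alive) and
    ``death_cause`` (``"cv"``/``"non_cv"``/missing).  ``events`` is long
    format, one row per hospitalization: ``patient_id, cycle``.
    """

    patients: pd.DataFrame
    events: pd.DataFrame

    def arm_view(self, arm: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        pts = self.patients[self.patients["arm"] == arm]
        if pts.empty:
            raise ValueError(f"arm {arm!r} not present in trial dataset")
        ev = self.events[self.events["patient_id"].isin(pts["patient_id"])]
        return pts, ev


def _truncated_normal_ages(rng: np.random.Generator, n: int) -> np.ndarray:
    # inverse-CDF sampling of Normal(67, 10) truncated to [40, 90]
    lo, hi = norm.cdf(40.0, 67.0, 10.0), norm.cdf(90.0, 67.0, 10.0)
    return norm.ppf(rng.uniform(lo, hi, size=n), 67.0, 10.0)


def simulate_trial(
    true_params: ModelParameters,
    n_per_arm: int,
    followup_months: int,
    seed: int,
) -> TrialDataset:
    """Simulate both arms for ``followup_months`` monthly cycles.

    Deterministic given ``seed``.  Patients are censored alive at the end
    of follow-up unless they die first.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    if followup_months < 1:
        raise ValueError("followup_months must be >= 1")
    true_params.validate()
    rng = np.random.default_rng(seed)

    patient_frames = []
    ev_pids: list[np.ndarray] = []
    ev_cycles: list[np.ndarray] = []
    next_id = 0
    for arm in ("empagliflozin", "standard"):
        ts = true_params.arm_transitions(arm)
        ages = _truncated_normal_ages(rng, n_per_arm)
        ids = np.arange(next_id, next_id + n_per_arm)
        next_id += n_per_arm

        # vectorized over patients, one cycle at a time
        STABLE, HOSP, DEAD = 0, 1, 2
        state = np.zeros(n_per_arm, dtype=np.int8)
        death_cycle = np.full(n_per_arm, np.nan)
        death_cause = np.full(n_per_arm, "", dtype=object)
        for k in range(1, followup_months + 1):
            active = state != DEAD
            if not active.any():
                break
            age_now = ages + (k - 1) / 12.0
            p_ncv = true_params.age_mortality.lookup_array(age_now)
            u = rng.uniform(size=n_per_arm)

            in_stable = active & (state == STABLE)
            in_hosp = active & (state == HOSP)

            new_state = state.copy()
            # stable: hosp | cv death | non-cv death | stay, in that order
            p1 = np.full(n_per_arm, ts.p_stable_to_hosp)
            p2 = p1 + ts.p_stable_to_cvdeath
            p3 = p2 + p_ncv
            hosp_now = in_stable & (u < p1)
            cv_now = in_stable & (u >= p1) & (u < p2)
            ncv_now = in_stable & (u >= p2) & (u < p3)
            new_state[hosp_now] = HOSP
            new_state[cv_now | ncv_now] = DEAD
            # hospitalized: cv death | non-cv death | back to stable
            q1 = np.full(n_per_arm, ts.p_hosp_to_cvdeath)
            q2 = q1 + p_ncv
            cv_h = in_hosp & (u < q1)
            ncv_h = in_hosp & (u >= q1) & (u < q2)
            back = in_hosp & (u >= q2)
            new_state[cv_h | ncv_h] = DEAD
            new_state[back] = STABLE

            died = (cv_now | ncv_now | cv_h | ncv_h)
            death_cycle[died] = k
            death_cause[cv_now | cv_h] = CV
            death_cause[ncv_now | ncv_h] = NON_CV
            ev_pids.append(ids[hosp_now])
            ev_cycles.append(np.full(int(hosp_now.sum()), k))
            state = new_state

        patient_frames.append(
            pd.DataFrame(
                {
                    "patient_id": ids,
                    "arm": arm,
                    "age": ages,
                    "followup_months": followup_months,
                    "death_cycle": death_cycle,
                    "death_cause": [c or None for c in death_cause],
                }
            )
        )

    patients = pd.concat(patient_frames, ignore_index=True)
    if ev_pids:
        events = pd.DataFrame(
            {"patient_id": np.concatenate(ev_pids), "cycle": np.concatenate(ev_cycles)}
        ).sort_values(["patient_id", "cycle"], kind="stable").reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=["patient_id", "cycle"])
    return TrialDataset(patients=patients, events=events)


@dataclass(frozen=True)
class TransitionEstimate:
    """events / person-cycles at risk, with a Wilson score 95% interval."""

    events: int
    at_risk_cycles: int
    estimate: float | None     # None when no person-time was observed
    ci_low: float | None
    ci_high: float | None

    def covers(self, truth: float) -> bool:
        return self.estimate is not None and self.ci_low <= truth <= self.ci_high


def _wilson(events: int, trials: int, z: float = 1.959963984540054) -> TransitionEstimate:
    if trials == 0:
        return TransitionEstimate(events, 0, None, None, None)
    p = events / trials
    denom = 1.0 + z * z / trials
    center = (p + z * z / (2 * trials)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / trials + z * z / (4 * trials * trials))
    return TransitionEstimate(events, trials, p, max(center - half, 0.0), min(center + half, 1.0))


def estimate_transitions(trial: TrialDataset, arm: str) -> dict[str, TransitionEstimate]:
    """Recover per-cycle transition probabilities from one arm's records.

    Returns estimates keyed ``p_stable_to_hosp``, ``p_stable_to_cvdeath``,
    ``p_hosp_to_cvdeath``.  Each is events over person-cycles at risk in
    the source state; a state with zero observed person-time yields an
    estimate of ``None`` (undefined).
    """
    pts, ev = trial.arm_view(arm)
    died = pts["death_cycle"].notna()
    # transitions out of index k are observed for k = 0 .. end-1
    end = np.where(died, pts["death_cycle"], pts["followup_months"]).astype(int)
    end_by_id = dict(zip(pts["patient_id"].astype(int), end))

    ev_pid = ev["patient_id"].astype(int).to_numpy()
    ev_cycle = ev["cycle"].astype(int).to_numpy()
    ev_end = np.array([end_by_id[p] for p in ev_pid], dtype=int) if len(ev_pid) else np.array([], dtype=int)
    hosp_index = set(zip(ev_pid.tolist(), ev_cycle.tolist()))

    # exposure: a hospitalization at cycle k < end is an at-risk hospitalized
    # cycle; every other at-risk cycle is stable
    h_cycles = int(np.sum(ev_cycle < ev_end)) if len(ev_pid) else 0
    s_cycles = int(end.sum()) - h_cycles

    # every admission is an entry from stable unless the previous cycle was
    # also spent hospitalized (never the case for data from this simulator)
    sh_events = sum(
        1 for p, c in zip(ev_pid.tolist(), ev_cycle.tolist()) if (p, c - 1) not in hosp_index
    )

    cv_rows = pts[died & (pts["death_cause"] == CV)]
    cv_end = cv_rows["death_cycle"].astype(int)
    hc_events = sum(
        1
        for p, e in zip(cv_rows["patient_id"].astype(int).tolist(), cv_end.tolist())
        if (p, e - 1) in hosp_index
    )
    sc_events = len(cv_rows) - hc_events

    return {
        "p_stable_to_hosp": _wilson(sh_events, s_cycles),
        "p_stable_to_cvdeath": _wilson(sc_events, s_cycles),
        "p_hosp_to_cvdeath": _wilson(hc_events, h_cycles),
    }


def write_trial(trial: TrialDataset, patients_path: str | Path, events_path: str | Path) -> None:
    """Write the two tidy CSVs (patients, long-format hospitalization events)."""
    trial.patients.to_csv(patients_path, index=False)
    trial.events.to_csv(events_path, index=False)


def read_trial(patients_path: str | Path, events_path: str | Path) -> TrialDataset:
    patients = pd.read_csv(patients_path)
    events = pd.read_csv(events_path)
    if events.empty:
        events = pd.DataFrame(columns=["patient_id", "cycle"])
    return TrialDataset(patients=patients, events=events)
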