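"""Deterministic and probabilistic sensitivity analysis.

One-way analysis sweeps each registered uncertain input across its
declared range with everything else at base case and records the ICER at
both ends (tornado diagram input).  Scenario analysis reruns the model
under the published what-if settings (drug price cuts, hospital-level
admission costs, alternative horizons).  The probabilistic analysis
draws every uncertain parameter independently from its moment-matched
distribution (Beta for probabilities and utilities, Gamma for costs) and
records per-iteration incremental cost and QALYs, from which the
cost-effectiveness acceptability curve is the fraction of iterations
with positive incremental net monetary benefit at each threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cea
from .markov import ArmOutcome, run_arm
from .parameters import (
    InvalidParameterError,
    ModelParameters,
    beta_from_moments,
    gamma_from_moments,
)

__all__ = [
    "TornadoEntry",
    "ScenarioResult",
    "PSAResult",
    "apply_parameter",
    "one_way",
    "tornado",
    "scenario_drug_cost",
    "scenario_hospital_cost",
    "scenario_horizon",
    "psa_draw",
    "run_psa",
    "ceac",
    "default_wtp_grid",
]

INTERVENTION = "empagliflozin"
COMPARATOR = "standard"


def _base_icer(params: ModelParameters, **run_kwargs) -> cea.IncrementalResult:
    out_i = run_arm(params, INTERVENTION, **run_kwargs)
    out_c = run_arm(params, COMPARATOR, **run_kwargs)
    return cea.icer(out_i, out_c, params.econ.wtp_thresholds)


def apply_parameter(params: ModelParameters, parameter_id: str, value: float) -> ModelParameters:
    """Return a copy of ``params`` with one registered input replaced.

    ``parameter_id`` uses the dotted ids of the uncertainty registry:
    ``"<arm>.<transition field>"``, ``"cost.empagliflozin_monthly"``,
    ``"cost.standard_monthly"``, ``"cost.hospitalization"``,
    ``"utility.stable"``, ``"utility.hosp"``, ``"econ.discount_rate_annual"``.
    """
    head, _, tail = parameter_id.partition(".")
    if head in params.transitions:
        if tail not in ("p_stable_to_hosp", "p_stable_to_cvdeath", "p_hosp_to_cvdeath"):
            raise KeyError(f"unknown transition field {tail!r}")
        transitions = dict(params.transitions)
        transitions[head] = dataclasses.replace(transitions[head], **{tail: value})
        return dataclasses.replace(params, transitions=transitions)
    if head == "cost":
        costs = dict(params.costs)
        if tail == "empagliflozin_monthly":
            costs["empagliflozin"] = dataclasses.replace(
                costs["empagliflozin"], c_monthly_treatment=value
            )
        elif tail == "standard_monthly":
            costs["standard"] = dataclasses.replace(
                costs["standard"], c_monthly_treatment=value
            )
        elif tail == "hospitalization":
            costs = {
                arm: dataclasses.replace(cs, c_hospitalization=value)
                for arm, cs in costs.items()
            }
        else:
            raise KeyError(f"unknown cost component {tail!r}")
        return dataclasses.replace(params, costs=costs)
    if head == "utility":
        if tail == "stable":
            utilities = dataclasses.replace(params.utilities, u_stable=value)
        elif tail == "hosp":
            utilities = dataclasses.replace(params.utilities, u_hosp=value)
        else:
            raise KeyError(f"unknown utility {tail!r}")
        return dataclasses.replace(params, utilities=utilities)
    if head == "econ":
        if tail != "discount_rate_annual":
            raise KeyError(f"unknown econ field {tail!r}")
        return dataclasses.replace(
            params, econ=dataclasses.replace(params.econ, discount_rate_annual=value)
        )
    raise KeyError(f"unknown parameter id {parameter_id!r}")


# ---------------------------------------------------------------------------
# one-way / tornado
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    parameter_id: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _validated(params: ModelParameters) -> ModelParameters:
    params.validate()
    return params


def one_way(
    params: ModelParameters, parameter_id: str, low: float, high: float
) -> TornadoEntry:
    """ICER with one input at its low and at its high value, all else base."""
    if parameter_id not in params.uncertainty.entries:
        raise KeyError(f"{parameter_id!r} is not a registered uncertain input")
    if low > high:
        raise ValueError(f"low {low} exceeds high {high}")
    res_low = _base_icer(_validated(apply_parameter(params, parameter_id, low)))
    res_high = _base_icer(_validated(apply_parameter(params, parameter_id, high)))
    return TornadoEntry(
        parameter_id=parameter_id,
        low=low,
        high=high,
        icer_low=res_low.icer,
        icer_high=res_high.icer,
    )


def tornado(params: ModelParameters) -> list[TornadoEntry]:
    """One entry per registered input, widest ICER span first (ties by id)."""
    entries = [
        one_way(params, pid, u.low, u.high)
        for pid, u in params.uncertainty.entries.items()
    ]
    return sorted(entries, key=lambda e: (-e.width, e.parameter_id))


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter_id,
                "low": e.low,
                "high": e.high,
                "icer_low": round(e.icer_low, 2),
                "icer_high": round(e.icer_high, 2),
                "width": round(e.width, 2),
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioResult:
    label: str
    value: float
    icer: float


def drug_cost_component(params: ModelParameters) -> float:
    """Monthly empagliflozin price: intervention-arm minus comparator-arm cost."""
    return (
        params.costs[INTERVENTION].c_monthly_treatment
        - params.costs[COMPARATOR].c_monthly_treatment
    )


def scenario_drug_cost(params: ModelParameters, reduction_fraction: float) -> ScenarioResult:
    """Cut the empagliflozin-specific monthly cost by ``reduction_fraction``."""
    if not 0.0 <= reduction_fraction <= 1.0:
        raise ValueError(f"reduction fraction must be in [0, 1], got {reduction_fraction}")
    component = drug_cost_component(params) * (1.0 - reduction_fraction)
    new_monthly = params.costs[COMPARATOR].c_monthly_treatment + component
    modified = apply_parameter(params, "cost.empagliflozin_monthly", new_monthly)
    return ScenarioResult(
        label=f"drug cost -{reduction_fraction:.0%}",
        value=round(component, 2),
        icer=_base_icer(modified).icer,
    )


def scenario_hospital_cost(params: ModelParameters, cost_per_hosp: float) -> ScenarioResult:
    """Replace the per-admission cost in both arms."""
    if cost_per_hosp < 0:
        raise ValueError("hospitalization cost must be non-negative")
    modified = apply_parameter(params, "cost.hospitalization", cost_per_hosp)
    return ScenarioResult(
        label=f"hospitalization cost {cost_per_hosp:.2f}",
        value=cost_per_hosp,
        icer=_base_icer(modified).icer,
    )


def scenario_horizon(params: ModelParameters, years: float) -> ScenarioResult:
    """Rerun with the time horizon set to ``years`` (12 cycles per year)."""
    if years <= 0:
        raise ValueError("horizon must be positive")
    n_cycles = int(round(12 * years))
    modified = dataclasses.replace(
        params, econ=dataclasses.replace(params.econ, n_cycles=n_cycles)
    )
    return ScenarioResult(
        label=f"horizon {years:g} years",
        value=years,
        icer=_base_icer(modified).icer,
    )


def scenario_table(params: ModelParameters) -> pd.DataFrame:
    """The published scenario grid: drug-price cuts, hospital levels, horizons."""
    rows = []
    for frac in (0.10, 0.20, 0.40, 0.60):
        r = scenario_drug_cost(params, frac)
        rows.append({"block": "drug_cost", "scenario": r.label, "value": r.value, "icer": round(r.icer, 2)})
    for level, cost in (
        ("town", 974.20),
        ("county", 1132.53),
        ("municipal", 1804.13),
        ("provincial", 1853.54),
        ("ministerial", 3243.21),
    ):
        r = scenario_hospital_cost(params, cost)
        rows.append({"block": "hospital_level", "scenario": level, "value": cost, "icer": round(r.icer, 2)})
    for years in (10, 15, 20, 25):
        r = scenario_horizon(params, years)
        rows.append({"block": "horizon", "scenario": f"{years} years", "value": years, "icer": round(r.icer, 2)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

#: ids drawn in the PSA, in the documented (fixed) sampling order.
def sampled_parameter_ids(params: ModelParameters) -> list[str]:
    return [pid for pid, u in params.uncertainty.entries.items() if u.family is not None]


def psa_draw(
    params: ModelParameters, rng: np.random.Generator
) -> tuple[ModelParameters, dict[str, float], int]:
    """One joint draw of all sampled parameters.

    Returns the modified parameter set, the draw as an id->value mapping,
    and the number of redraws needed to satisfy the joint invariants
    (essentially always 0; a redraw can occur when the sampled
    hospitalized-state utility exceeds the stable-state utility).
    """
    ids = sampled_parameter_ids(params)
    samplers = {}
    for pid in ids:
        u = params.uncertainty[pid]
        if u.sd == 0:  # degenerate distribution: always the mean
            samplers[pid] = ("point", u.mean, None)
        elif u.family == "beta":
            a, b = beta_from_moments(u.mean, u.sd)
            samplers[pid] = ("beta", a, b)
        else:
            shape, scale = gamma_from_moments(u.mean, u.sd)
            samplers[pid] = ("gamma", shape, scale)

    redraws = 0
    while True:
        draw: dict[str, float] = {}
        for pid in ids:
            kind, p1, p2 = samplers[pid]
            if kind == "point":
                draw[pid] = p1
            elif kind == "beta":
                draw[pid] = float(rng.beta(p1, p2))
            else:
                draw[pid] = float(rng.gamma(p1, p2))
        candidate = params
        for pid, value in draw.items():
            candidate = apply_parameter(candidate, pid, value)
        try:
            candidate.validate()
        except InvalidParameterError:
            redraws += 1
            continue
        return candidate, draw, redraws


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration incremental outcomes with the sampled parameter draws."""

    draws: pd.DataFrame        # one column per sampled parameter id
    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    seed: int
    n_redraws: int

    @property
    def n_iterations(self) -> int:
        return len(self.delta_cost)

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "delta_cost": self.delta_cost,
                "delta_qalys": self.delta_qalys,
            }
        )


def run_psa(params: ModelParameters, n_iterations: int, seed: int) -> PSAResult:
    """Monte-Carlo PSA: ``n_iterations`` joint draws, full two-arm run each."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    dc = np.empty(n_iterations)
    de = np.empty(n_iterations)
    total_redraws = 0
    for i in range(n_iterations):
        sampled, draw, redraws = psa_draw(params, rng)
        total_redraws += redraws
        out_i = run_arm(sampled, INTERVENTION)
        out_c = run_arm(sampled, COMPARATOR)
        dc[i] = out_i.total_cost - out_c.total_cost
        de[i] = out_i.total_qalys - out_c.total_qalys
        records.append(draw)
    return PSAResult(
        draws=pd.DataFrame.from_records(records),
        delta_cost=dc,
        delta_qalys=de,
        seed=seed,
        n_redraws=total_redraws,
    )


def default_wtp_grid() -> np.ndarray:
    """0 to 50,000 USD/QALY in 500 steps, always including both GDP thresholds."""
    grid = np.arange(0.0, 50_000.0 + 1, 500.0)
    grid = np.union1d(grid, [11_981.0, 35_943.0])
    return grid


def ceac(psa: PSAResult, wtp_grid=None) -> pd.DataFrame:
    """P(intervention cost-effective) = P(lambda*dE - dC > 0) per threshold."""
    if psa.n_iterations == 0:
        raise ValueError("empty PSA result")
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("willingness-to-pay grid is empty")
    if np.any(wtp_grid < 0):
        raise ValueError("willingness-to-pay values must be non-negative")
    prob = [
        float(np.mean(w * psa.delta_qalys - psa.delta_cost > 0)) for w in wtp_grid
    ]
    return pd.DataFrame({"wtp": wtp_grid, "probability_cost_effective": prob})
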