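"""Model inputs: transition probabilities, costs, utilities, and the
conversions that relate them.

All transition probabilities are stored at the model's native monthly
(per-cycle) resolution.  Conversions between cumulative probabilities,
instantaneous rates and per-cycle probabilities assume a constant hazard
within the observation window:

    r = -ln(1 - P) / T        (cumulative probability over T cycles -> rate)
    p = 1 - exp(-r t)         (rate -> probability over t cycles)

Probabilistic-sensitivity sampling distributions are parameterised by
moment matching: Beta for probabilities and utilities, Gamma for costs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "TransitionSet",
    "AgeMortalityTable",
    "CostSet",
    "UtilitySet",
    "EconSettings",
    "Uncertain",
    "UncertaintySpec",
    "ModelParameters",
    "InvalidParameterError",
    "InfeasibleDistributionError",
    "prob_to_rate",
    "rate_to_prob",
    "rescale_probability",
    "beta_from_moments",
    "gamma_from_moments",
    "cny_to_usd",
    "base_case_parameters",
    "load_config",
    "save_config",
    "ARMS",
]

ARMS = ("empagliflozin", "standard")

#: Sentinel for "median survival not reached within the horizon".
NOT_REACHED = math.inf


class InvalidParameterError(ValueError):
    """A model input violates one of its declared invariants."""


class InfeasibleDistributionError(ValueError):
    """Requested moments cannot be matched by the distribution family."""


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def prob_to_rate(P: float, T: float) -> float:
    """Instantaneous rate per cycle from a cumulative probability over ``T`` cycles.

    ``r = -ln(1 - P) / T`` under the constant-hazard assumption.
    """
    if not 0.0 <= P < 1.0:
        raise InvalidParameterError(f"cumulative probability must be in [0, 1), got {P}")
    if T <= 0:
        raise InvalidParameterError(f"duration must be positive, got {T}")
    return -math.log1p(-P) / T


def rate_to_prob(r: float, t: float) -> float:
    """Probability over ``t`` cycles from a constant rate: ``p = 1 - exp(-r t)``."""
    if r < 0:
        raise InvalidParameterError(f"rate must be non-negative, got {r}")
    if t < 0:
        raise InvalidParameterError(f"duration must be non-negative, got {t}")
    return -math.expm1(-r * t)


def rescale_probability(P: float, T_from: float, T_to: float) -> float:
    """Re-express a cumulative probability over ``T_from`` cycles on ``T_to`` cycles."""
    return rate_to_prob(prob_to_rate(P, T_from), T_to)


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Beta shape parameters ``(alpha, beta)`` with the given mean and sd.

    Raises :class:`InfeasibleDistributionError` when ``sd**2 >= mean*(1-mean)``,
    the hard variance bound for a Beta distribution.
    """
    if not 0.0 < mean < 1.0:
        raise InvalidParameterError(f"Beta mean must be in (0, 1), got {mean}")
    if sd <= 0:
        raise InvalidParameterError(f"sd must be positive, got {sd}")
    var = sd * sd
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise InfeasibleDistributionError(
            f"sd^2={var:g} >= mean*(1-mean)={bound:g}: no Beta distribution has these moments"
        )
    k = bound / var - 1.0
    return mean * k, (1.0 - mean) * k


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma ``(shape, scale)`` with the given mean and sd (shape*scale == mean)."""
    if mean <= 0 or sd <= 0:
        raise InvalidParameterError("Gamma moment matching requires positive mean and sd")
    return (mean / sd) ** 2, sd * sd / mean


def cny_to_usd(amount_cny: float, rate: float) -> float:
    """Convert CNY to USD at ``rate`` yuan per dollar."""
    if rate <= 0:
        raise InvalidParameterError(f"exchange rate must be positive, got {rate}")
    return amount_cny / rate


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"{name}={p} is not a probability in [0, 1]")


@dataclass(frozen=True)
class TransitionSet:
    """Per-cycle (monthly) transition probabilities for one treatment arm."""

    p_stable_to_hosp: float
    p_stable_to_cvdeath: float
    p_hosp_to_cvdeath: float

    def validate(self, prefix: str = "transitions") -> None:
        for name in ("p_stable_to_hosp", "p_stable_to_cvdeath", "p_hosp_to_cvdeath"):
            _check_prob(f"{prefix}.{name}", getattr(self, name))
        if self.p_stable_to_hosp + self.p_stable_to_cvdeath > 1.0:
            raise InvalidParameterError(
                f"{prefix}: p_stable_to_hosp + p_stable_to_cvdeath exceeds 1"
            )


@dataclass(frozen=True)
class AgeMortalityTable:
    """Monthly non-cardiovascular death probability by age band.

    Bands are half-open ``[lower, upper)``, contiguous and ascending.
    Lookups beyond the last band reuse the last band; lookups below the
    first band (only relevant for trial simulation, where enrollment ages
    spread below the cohort start age) reuse the first band.
    """

    bands: tuple[tuple[float, float, float], ...]  # (age_lower, age_upper, p)

    def validate(self, prefix: str = "age_mortality") -> None:
        if not self.bands:
            raise InvalidParameterError(f"{prefix}: table is empty")
        prev_upper = None
        for lo, hi, p in self.bands:
            if hi <= lo:
                raise InvalidParameterError(f"{prefix}: band [{lo}, {hi}) is empty")
            if prev_upper is not None and lo != prev_upper:
                raise InvalidParameterError(
                    f"{prefix}: bands not contiguous at age {lo} (previous upper {prev_upper})"
                )
            _check_prob(f"{prefix}[{lo}-{hi})", p)
            prev_upper = hi

    def lookup(self, age: float) -> float:
        if age < self.bands[0][0]:
            return self.bands[0][2]
        for lo, hi, p in self.bands:
            if lo <= age < hi:
                return p
        return self.bands[-1][2]

    def lookup_array(self, ages) -> "np.ndarray":
        """Vectorized :meth:`lookup` (clamped at both ends)."""
        import numpy as np

        uppers = np.array([hi for _, hi, _ in self.bands])
        probs = np.array([p for _, _, p in self.bands])
        idx = np.clip(np.searchsorted(uppers, ages, side="right"), 0, len(probs) - 1)
        return probs[idx]


@dataclass(frozen=True)
class CostSet:
    """Direct medical costs for one arm (USD)."""

    c_monthly_treatment: float  # per cycle while alive
    c_hospitalization: float    # per hospitalization event

    def validate(self, prefix: str = "costs") -> None:
        if self.c_monthly_treatment < 0:
            raise InvalidParameterError(f"{prefix}.c_monthly_treatment is negative")
        if self.c_hospitalization < 0:
            raise InvalidParameterError(f"{prefix}.c_hospitalization is negative")


@dataclass(frozen=True)
class UtilitySet:
    """Annual utility weights of the two alive states."""

    u_stable: float
    u_hosp: float

    def validate(self, prefix: str = "utilities") -> None:
        if not 0.0 <= self.u_hosp <= self.u_stable <= 1.0:
            raise InvalidParameterError(
                f"{prefix}: require 0 <= u_hosp ({self.u_hosp}) <= u_stable ({self.u_stable}) <= 1"
            )


@dataclass(frozen=True)
class EconSettings:
    """Horizon, discounting and decision-threshold settings."""

    discount_rate_annual: float = 0.05
    cycle_length_months: float = 1.0
    n_cycles: int = 240
    start_age: float = 67.0
    wtp_thresholds: tuple[float, ...] = (11981.0, 35943.0)
    cny_per_usd: float = 6.373

    def validate(self, prefix: str = "econ") -> None:
        if self.discount_rate_annual < 0:
            raise InvalidParameterError(f"{prefix}.discount_rate_annual is negative")
        if self.n_cycles < 1:
            raise InvalidParameterError(f"{prefix}.n_cycles must be >= 1")
        if any(w <= 0 for w in self.wtp_thresholds):
            raise InvalidParameterError(f"{prefix}.wtp_thresholds must be positive")
        if self.cny_per_usd <= 0:
            raise InvalidParameterError(f"{prefix}.cny_per_usd must be positive")


@dataclass(frozen=True)
class Uncertain:
    """Sampling and one-way range information for one uncertain input.

    ``family`` is ``"beta"``, ``"gamma"`` or ``None`` (varied one-way only,
    e.g. the discount rate, which has a range but no sampling distribution).
    """

    mean: float
    sd: float | None
    family: str | None
    low: float
    high: float

    def validate(self, prefix: str) -> None:
        if self.sd is not None and self.sd < 0:
            raise InvalidParameterError(f"{prefix}.sd is negative")
        if not self.low <= self.mean <= self.high:
            raise InvalidParameterError(
                f"{prefix}: range [{self.low}, {self.high}] does not bracket mean {self.mean}"
            )
        if self.family in ("beta", "gamma") and self.sd == 0:
            pass  # degenerate (point-mass) distribution: sampled as the mean
        elif self.family == "beta":
            beta_from_moments(self.mean, self.sd)
        elif self.family == "gamma":
            gamma_from_moments(self.mean, self.sd)
        elif self.family is not None:
            raise InvalidParameterError(f"{prefix}: unknown distribution family {self.family!r}")


@dataclass(frozen=True)
class UncertaintySpec:
    """Mapping from parameter id to its :class:`Uncertain` description.

    Parameter ids are dotted paths understood by
    :func:`hfref_cea.sensitivity.apply_parameter`, e.g.
    ``"empagliflozin.p_stable_to_cvdeath"`` or ``"cost.hospitalization"``.
    """

    entries: dict[str, Uncertain] = field(default_factory=dict)

    def validate(self) -> None:
        for key, u in self.entries.items():
            u.validate(key)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __getitem__(self, key: str) -> Uncertain:
        return self.entries[key]


@dataclass(frozen=True)
class ModelParameters:
    """The complete input set of the cohort model (both arms)."""

    transitions: dict[str, TransitionSet]
    costs: dict[str, CostSet]
    age_mortality: AgeMortalityTable
    utilities: UtilitySet
    econ: EconSettings
    uncertainty: UncertaintySpec

    def validate(self) -> None:
        for container, label in ((self.transitions, "transitions"), (self.costs, "costs")):
            if set(container) != set(ARMS):
                raise InvalidParameterError(
                    f"{label}: expected arms {ARMS}, got {tuple(container)}"
                )
        for arm in ARMS:
            self.transitions[arm].validate(f"transitions.{arm}")
            self.costs[arm].validate(f"costs.{arm}")
        self.age_mortality.validate()
        self.utilities.validate()
        self.econ.validate()
        self.uncertainty.validate()
        last_upper = self.age_mortality.bands[-1][1]
        if self.age_mortality.bands[0][0] > self.econ.start_age:
            raise InvalidParameterError(
                "age_mortality: first band starts above the cohort start age"
            )

    # convenience accessors -------------------------------------------------
    def arm_transitions(self, arm: str) -> TransitionSet:
        try:
            return self.transitions[arm]
        except KeyError:
            raise InvalidParameterError(f"unknown arm {arm!r}; expected one of {ARMS}") from None

    def arm_costs(self, arm: str) -> CostSet:
        try:
            return self.costs[arm]
        except KeyError:
            raise InvalidParameterError(f"unknown arm {arm!r}; expected one of {ARMS}") from None


# ---------------------------------------------------------------------------
# base case
# ---------------------------------------------------------------------------

def _pm(mean: float, frac: float) -> tuple[float, float]:
    return mean * (1 - frac), mean * (1 + frac)


def base_case_parameters() -> ModelParameters:
    """The built-in base-case input set (monthly cycle, 20-year horizon).

    Transition probabilities are monthly; utilities are annual weights;
    costs are USD.  One-way ranges are +/-10% of the mean for transition
    probabilities, +/-20% for treatment costs, the published local range
    for the hospitalization cost, and 1-8% for the discount rate.
    """
    transitions = {
        "empagliflozin": TransitionSet(0.01449, 0.00624, 0.03865),
        "standard": TransitionSet(0.02171, 0.00657, 0.04392),
    }
    costs = {
        "empagliflozin": CostSet(55.07, 1408.13),
        "standard": CostSet(35.11, 1408.13),
    }
    age_mortality = AgeMortalityTable(
        bands=(
            (67.0, 70.0, 0.00082),
            (70.0, 75.0, 0.00103),
            (75.0, 80.0, 0.00143),
            (80.0, 85.0, 0.00291),
            (85.0, 87.0, 0.00822),
        )
    )
    utilities = UtilitySet(u_stable=0.871, u_hosp=0.215)
    econ = EconSettings()

    entries: dict[str, Uncertain] = {}
    for arm, ts in transitions.items():
        sds = {
            "empagliflozin": (0.00074, 0.00032, 0.00197),
            "standard": (0.00111, 0.00034, 0.00224),
        }[arm]
        for (name, sd) in zip(
            ("p_stable_to_hosp", "p_stable_to_cvdeath", "p_hosp_to_cvdeath"), sds
        ):
            mean = getattr(ts, name)
            lo, hi = _pm(mean, 0.10)
            entries[f"{arm}.{name}"] = Uncertain(mean, sd, "beta", lo, hi)
    entries["cost.empagliflozin_monthly"] = Uncertain(55.07, 5.62, "gamma", *_pm(55.07, 0.20))
    entries["cost.standard_monthly"] = Uncertain(35.11, 3.58, "gamma", *_pm(35.11, 0.20))
    # hospitalization cost: published local range, asymmetric around the mean
    entries["cost.hospitalization"] = Uncertain(1408.13, 578.83, "gamma", 974.20, 3243.21)
    entries["utility.stable"] = Uncertain(0.871, 0.088, "beta", 0.783, 0.959)
    entries["utility.hosp"] = Uncertain(0.215, 0.174, "beta", 0.041, 0.389)
    entries["econ.discount_rate_annual"] = Uncertain(0.05, None, None, 0.01, 0.08)

    params = ModelParameters(
        transitions=transitions,
        costs=costs,
        age_mortality=age_mortality,
        utilities=utilities,
        econ=econ,
        uncertainty=UncertaintySpec(entries),
    )
    params.validate()
    return params


# ---------------------------------------------------------------------------
# config file round trip
# ---------------------------------------------------------------------------

def _params_to_dict(params: ModelParameters) -> dict:
    return {
        "transitions": {
            arm: {
                "p_stable_to_hosp": ts.p_stable_to_hosp,
                "p_stable_to_cvdeath": ts.p_stable_to_cvdeath,
                "p_hosp_to_cvdeath": ts.p_hosp_to_cvdeath,
            }
            for arm, ts in params.transitions.items()
        },
        "costs": {
            arm: {
                "c_monthly_treatment": cs.c_monthly_treatment,
                "c_hospitalization": cs.c_hospitalization,
            }
            for arm, cs in params.costs.items()
        },
        "age_mortality": [list(band) for band in params.age_mortality.bands],
        "utilities": {
            "u_stable": params.utilities.u_stable,
            "u_hosp": params.utilities.u_hosp,
        },
        "econ": {
            "discount_rate_annual": params.econ.discount_rate_annual,
            "cycle_length_months": params.econ.cycle_length_months,
            "n_cycles": params.econ.n_cycles,
            "start_age": params.econ.start_age,
            "wtp_thresholds": list(params.econ.wtp_thresholds),
            "cny_per_usd": params.econ.cny_per_usd,
        },
        "uncertainty": {
            key: {
                "mean": u.mean,
                "sd": u.sd,
                "family": u.family,
                "low": u.low,
                "high": u.high,
            }
            for key, u in params.uncertainty.entries.items()
        },
    }


def _params_from_dict(doc: dict) -> ModelParameters:
    try:
        transitions = {
            arm: TransitionSet(**fields) for arm, fields in doc["transitions"].items()
        }
        costs = {arm: CostSet(**fields) for arm, fields in doc["costs"].items()}
        age_mortality = AgeMortalityTable(
            bands=tuple(tuple(band) for band in doc["age_mortality"])
        )
        utilities = UtilitySet(**doc["utilities"])
        econ_doc = dict(doc["econ"])
        econ_doc["wtp_thresholds"] = tuple(econ_doc["wtp_thresholds"])
        econ = EconSettings(**econ_doc)
        uncertainty = UncertaintySpec(
            {key: Uncertain(**fields) for key, fields in doc.get("uncertainty", {}).items()}
        )
    except (KeyError, TypeError) as exc:
        raise InvalidParameterError(f"malformed configuration: {exc}") from exc
    params = ModelParameters(
        transitions=transitions,
        costs=costs,
        age_mortality=age_mortality,
        utilities=utilities,
        econ=econ,
        uncertainty=uncertainty,
    )
    params.validate()
    return params


def save_config(params: ModelParameters, path: str | Path) -> None:
    """Write a parameter set to a YAML configuration file."""
    Path(path).write_text(yaml.safe_dump(_params_to_dict(params), sort_keys=True))


def load_config(path: str | Path) -> ModelParameters:
    """Read and validate a YAML configuration file.

    Validation errors name the offending key.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise InvalidParameterError(f"{path}: configuration must be a mapping")
    return _params_from_dict(doc)
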