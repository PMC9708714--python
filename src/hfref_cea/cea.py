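"""Incremental cost-effectiveness analysis between two arms, plus the
population-level impact projection.

The ICER is always computed from full-precision totals; rounding to the
reporting grain is left to the exporters.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .markov import ArmOutcome

__all__ = [
    "IncrementalResult",
    "icer",
    "net_monetary_benefit",
    "population_impact",
    "incremental_table",
]

# dominance / degeneracy labels attached in place of a numeric ICER
DOMINANT = "dominant"          # cheaper and at least as effective
DOMINATED = "dominated"        # dearer and at most as effective
ZERO_INCREMENT = "zero-increment"
UNDEFINED = "undefined"        # equal effect, unequal cost


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise incremental comparison (intervention minus comparator)."""

    intervention: str
    comparator: str
    cost_intervention: float
    cost_comparator: float
    qalys_intervention: float
    qalys_comparator: float
    delta_cost: float
    delta_qalys: float
    icer: float | None
    label: str | None                 # set when icer is None
    wtp_verdicts: dict[float, bool]   # threshold -> cost-effective?

    def is_cost_effective(self, wtp: float) -> bool:
        """Cost-effective at ``wtp`` iff dominant or ICER <= threshold."""
        if self.label == DOMINANT:
            return True
        if self.label in (DOMINATED, UNDEFINED):
            return False
        if self.label == ZERO_INCREMENT:
            return True
        return self.icer <= wtp


def icer(
    outcome_intervention: ArmOutcome,
    outcome_comparator: ArmOutcome,
    wtp_thresholds: tuple[float, ...] = (),
) -> IncrementalResult:
    """Incremental cost, incremental QALYs and their ratio (or a quadrant label)."""
    dc = outcome_intervention.total_cost - outcome_comparator.total_cost
    de = outcome_intervention.total_qalys - outcome_comparator.total_qalys

    # Numeric ICER only in the NE quadrant (more costly, more effective) and
    # the SW quadrant (savings per QALY forgone); dominance labels otherwise.
    # A zero QALY difference leaves icer=None — the undefined-ICER signal.
    ratio: float | None = None
    label: str | None = None
    if dc == 0.0 and de == 0.0:
        label = ZERO_INCREMENT
    elif dc <= 0.0 and de >= 0.0:
        label = DOMINANT
    elif dc >= 0.0 and de <= 0.0:
        label = DOMINATED
    else:
        ratio = dc / de

    result = IncrementalResult(
        intervention=outcome_intervention.arm,
        comparator=outcome_comparator.arm,
        cost_intervention=outcome_intervention.total_cost,
        cost_comparator=outcome_comparator.total_cost,
        qalys_intervention=outcome_intervention.total_qalys,
        qalys_comparator=outcome_comparator.total_qalys,
        delta_cost=dc,
        delta_qalys=de,
        icer=ratio,
        label=label,
        wtp_verdicts={},
    )
    verdicts = {w: result.is_cost_effective(w) for w in wtp_thresholds}
    object.__setattr__(result, "wtp_verdicts", verdicts)
    return result


def net_monetary_benefit(outcome: ArmOutcome, wtp: float) -> float:
    """``wtp * QALYs - cost`` for a single arm at willingness-to-pay ``wtp``."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be non-negative, got {wtp}")
    return wtp * outcome.total_qalys - outcome.total_cost


def population_impact(
    n_patients: float,
    incidence_diff_hosp: float,
    incidence_diff_death: float,
    cost_per_hosp: float,
) -> tuple[float, float, float]:
    """Scale per-patient incidence differences (percentage points) to a population.

    Returns ``(hospitalizations averted, deaths averted, hospitalization
    cost averted in USD)``.  Negative differences yield negative aversions.
    """
    if n_patients < 0:
        raise ValueError("n_patients must be non-negative")
    hosp_averted = n_patients * incidence_diff_hosp / 100.0
    deaths_averted = n_patients * incidence_diff_death / 100.0
    return hosp_averted, deaths_averted, hosp_averted * cost_per_hosp


def incremental_table(result: IncrementalResult) -> pd.DataFrame:
    """Two-row summary table (intervention first), reporting grain: 2 decimals."""
    icer_repr = round(result.icer, 2) if result.icer is not None else result.label
    return pd.DataFrame(
        [
            {
                "arm": result.intervention,
                "total_cost": round(result.cost_intervention, 2),
                "incremental_cost": round(result.delta_cost, 2),
                "total_qalys": round(result.qalys_intervention, 2),
                "incremental_qalys": round(result.delta_qalys, 2),
                "icer": icer_repr,
            },
            {
                "arm": result.comparator,
                "total_cost": round(result.cost_comparator, 2),
                "incremental_cost": None,
                "total_qalys": round(result.qalys_comparator, 2),
                "incremental_qalys": None,
                "icer": None,
            },
        ]
    )
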