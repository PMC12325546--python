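"""Directional summary of myofilament passive-stiffness contributions.

Treatment effects (median % stiffness reductions after disrupting one
filament system) measured transversely (AFM indentation of tissue slices)
and longitudinally (fiber-bundle / cardiomyocyte stretch) are combined into:

* the **longitudinal-to-transverse quotient (LTQ)** — the ratio of a
  filament system's longitudinal to transverse stiffness contribution at a
  matched mechanical level; LTQ = 1 denotes equal contributions along both
  axes;
* a sequential-treatment **additivity analysis** — whether the combined
  reduction of two successive interventions matches the sum of their
  standalone effects (a shortfall indicates cooperative, tensegrity-like
  filament interaction).

Level pairing convention: "low" couples 10-12% fiber strain with the
2.00-2.25 nN indentation window, "high" couples 20% strain with
4.00-4.25 nN. The longitudinal strain entering the low level is 10% for the
titin and thick-filament interventions and 12% for actin (the lowest strain
at which each intervention's reduction is resolved).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "TreatmentEffect",
    "LTQResult",
    "AdditivityResult",
    "REFERENCE_EFFECTS",
    "REFERENCE_ADDITIVITY",
    "compute_ltq",
    "additivity_analysis",
    "summarize_directional_contributions",
    "reproduce_reference_values",
]

FILAMENTS = ("actin", "titin", "thick")
DIRECTIONS = ("transverse", "longitudinal")
LEVELS = ("low", "high")


@dataclass(frozen=True)
class TreatmentEffect:
    """Median % stiffness reduction for one filament x direction x level."""

    filament: str
    direction: str
    level: str
    preparation: str
    median_reduction: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.filament not in FILAMENTS:
            raise ValueError(f"filament must be one of {FILAMENTS}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        if not 0 <= self.median_reduction <= 100:
            raise ValueError("median_reduction must be in [0, 100]")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.median_reduction <= self.ci_high:
                raise ValueError("CI must bracket the median")


@dataclass(frozen=True)
class LTQResult:
    """Longitudinal-to-transverse quotient for one filament system and level."""

    filament: str
    level: str
    ltq: float
    longitudinal_input: float
    transverse_input: float


@dataclass(frozen=True)
class AdditivityResult:
    """Sequential two-step intervention vs the sum of standalone effects.

    All quantities are percentage points of the untreated baseline; ``gap`` =
    predicted_sum - combined_observed (> 0 means sub-additive interaction).
    """

    step1_reduction: float
    step2_additional_reduction: float
    combined_observed: float
    predicted_sum: float
    gap: float


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def compute_ltq(
    longitudinal: TreatmentEffect,
    transverse: TreatmentEffect,
    ndigits: int = 2,
) -> LTQResult:
    """LTQ = longitudinal median reduction / transverse median reduction,
    reported half-up at ``ndigits`` decimals (2, matching the convention the
    quotients are quoted at)."""
    if longitudinal.filament != transverse.filament:
        raise ValueError(
            f"filament mismatch: {longitudinal.filament} vs {transverse.filament}"
        )
    if longitudinal.direction != "longitudinal" or transverse.direction != "transverse":
        raise ValueError("arguments must be a (longitudinal, transverse) effect pair")
    if longitudinal.level != transverse.level:
        raise ValueError(f"level mismatch: {longitudinal.level} vs {transverse.level}")
    if transverse.median_reduction == 0:
        raise ValueError("undefined quotient: zero transverse effect")
    ratio = longitudinal.median_reduction / transverse.median_reduction
    return LTQResult(
        filament=longitudinal.filament,
        level=longitudinal.level,
        ltq=_round_half_up(ratio, ndigits),
        longitudinal_input=longitudinal.median_reduction,
        transverse_input=transverse.median_reduction,
    )


def additivity_analysis(
    step1: float, step2: float, solo1: float, solo2: float
) -> AdditivityResult:
    """Compare a sequential two-step reduction with the sum of standalone
    effects.

    All four inputs are % of the untreated baseline; the second step's
    "additional" reduction is counted in baseline percentage points, so the
    combined observed reduction is simply ``step1 + step2``.
    """
    for name, v in (("step1", step1), ("step2", step2), ("solo1", solo1), ("solo2", solo2)):
        if not 0 <= v < 100:
            raise ValueError(f"{name} must be in [0, 100), got {v}")
    combined = step1 + step2
    predicted = solo1 + solo2
    return AdditivityResult(
        step1_reduction=step1,
        step2_additional_reduction=step2,
        combined_observed=_round_half_up(combined, 2),
        predicted_sum=_round_half_up(predicted, 2),
        gap=_round_half_up(predicted - combined, 2),
    )


def summarize_directional_contributions(
    effects: list[TreatmentEffect],
    levels: tuple = LEVELS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the filament x direction x level contribution table and the
    per-filament LTQ table.

    For each filament present, every requested level must have exactly one
    transverse and one longitudinal effect; a missing cell raises with the
    filament/level named.
    """
    rows = [
        {
            "filament": e.filament,
            "direction": e.direction,
            "level": e.level,
            "preparation": e.preparation,
            "median_reduction_pct": e.median_reduction,
            "ci_low_pct": e.ci_low,
            "ci_high_pct": e.ci_high,
        }
        for e in effects
    ]
    table = pd.DataFrame(rows)
    filaments = [f for f in FILAMENTS if f in set(table["filament"])]

    ltq_rows = []
    for fil in filaments:
        for level in levels:
            cell = {}
            for direction in DIRECTIONS:
                match = [
                    e
                    for e in effects
                    if e.filament == fil and e.direction == direction and e.level == level
                ]
                if not match:
                    raise ValueError(f"missing {direction} effect for {fil} at level {level!r}")
                if len(match) > 1:
                    raise ValueError(f"multiple {direction} effects for {fil} at level {level!r}")
                cell[direction] = match[0]
            res = compute_ltq(cell["longitudinal"], cell["transverse"])
            ltq_rows.append(
                {
                    "filament": fil,
                    "level": level,
                    "ltq": res.ltq,
                    "longitudinal_pct": res.longitudinal_input,
                    "transverse_pct": res.transverse_input,
                }
            )
    return table, pd.DataFrame(ltq_rows)


#: Reference worked example: reported median % reductions in passive
#: stiffness of mouse LV myocardium after filament-specific disruption
#: (GLN-40 actin severing, TEVp titin cleavage, 1 M KCl thick-filament
#: extraction). Transverse values come from AFM indentation of tissue slices
#: at the 2.00-2.25 nN (low) and 4.00-4.25 nN (high) windows; longitudinal
#: values from fiber-bundle stretch at 10-12% (low) and 20% (high) strain.
REFERENCE_EFFECTS: list[TreatmentEffect] = [
    TreatmentEffect("actin", "transverse", "low", "slice", 25.7, 4.6, 35.3),
    TreatmentEffect("actin", "transverse", "high", "slice", 20.6, 10.5, 40.1),
    TreatmentEffect("actin", "longitudinal", "low", "fiber", 18.7, 13.5, 22.8),
    TreatmentEffect("actin", "longitudinal", "high", "fiber", 17.3, 12.3, 21.0),
    TreatmentEffect("titin", "transverse", "low", "slice", 24.6, 17.0, 38.7),
    TreatmentEffect("titin", "transverse", "high", "slice", 20.3, 10.9, 38.0),
    TreatmentEffect("titin", "longitudinal", "low", "fiber", 71.5, 31.5, 100.0),
    TreatmentEffect("titin", "longitudinal", "high", "fiber", 53.9, 27.6, 67.5),
    TreatmentEffect("thick", "transverse", "low", "slice", 35.6, 10.8, 54.3),
    TreatmentEffect("thick", "transverse", "high", "slice", 33.5, 21.6, 44.5),
    TreatmentEffect("thick", "longitudinal", "low", "fiber", 50.5, 47.7, 76.2),
    TreatmentEffect("thick", "longitudinal", "high", "fiber", 52.6, 40.5, 68.4),
]

#: Sequential actin-severing-then-KCl experiment at the high window:
#: step reductions observed in the two-step protocol and the standalone
#: effects whose sum is the additive prediction.
REFERENCE_ADDITIVITY = {"step1": 24.2, "step2": 18.7, "solo1": 20.6, "solo2": 33.5}

#: The quotients the reference medians are expected to reproduce.
_EXPECTED_LTQ = {
    ("actin", "low"): 0.73,
    ("actin", "high"): 0.84,
    ("titin", "low"): 2.91,
    ("titin", "high"): 2.66,
    ("thick", "low"): 1.42,
    ("thick", "high"): 1.57,
}
_EXPECTED_COMBINED = 42.9
_EXPECTED_PREDICTED = 54.1


def reproduce_reference_values(
    effects: list[TreatmentEffect] | None = None,
    additivity: dict | None = None,
) -> dict:
    """Recompute the reference LTQs and additivity numbers and report
    pass/fail per quantity (at 2-decimal / 1-decimal precision respectively).

    Passing perturbed ``effects`` or ``additivity`` inputs makes the
    corresponding checks fail — the built-in negative control of the harness.
    """
    effects = REFERENCE_EFFECTS if effects is None else effects
    additivity = REFERENCE_ADDITIVITY if additivity is None else additivity
    _, ltq_table = summarize_directional_contributions(effects)
    report: dict = {"ltq": {}, "all_pass": True}
    for _, row in ltq_table.iterrows():
        key = (row["filament"], row["level"])
        expected = _EXPECTED_LTQ[key]
        ok = abs(row["ltq"] - expected) < 0.005
        report["ltq"][f"{key[0]}_{key[1]}"] = {
            "value": float(row["ltq"]),
            "expected": expected,
            "pass": bool(ok),
        }
        report["all_pass"] &= ok
    add = additivity_analysis(**additivity)
    ok_comb = abs(add.combined_observed - _EXPECTED_COMBINED) < 0.05
    ok_pred = abs(add.predicted_sum - _EXPECTED_PREDICTED) < 0.05
    report["additivity"] = {
        "combined_observed": {
            "value": add.combined_observed,
            "expected": _EXPECTED_COMBINED,
            "pass": bool(ok_comb),
        },
        "predicted_sum": {
            "value": add.predicted_sum,
            "expected": _EXPECTED_PREDICTED,
            "pass": bool(ok_pred),
        },
        "gap": add.gap,
    }
    report["all_pass"] = bool(report["all_pass"] and ok_comb and ok_pred)
    return report
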