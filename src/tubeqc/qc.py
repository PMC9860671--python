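"""Anticoagulant amount / volume / concentration back-calculation.

An evacuated citrate tube is dosed at production with an anticoagulant
amount n_ac = c_nom * V_ac_nom. The liquid volume V_ac shrinks on the
shelf by water evaporation while n_ac stays fixed, so two complementary
determinations on a purified-water model recover both:

* composite extraction — the citrate of N tubes is washed into one
  volumetric flask of volume V_f; the flask concentration gives the
  amount per tube  n_ac = c_comp * V_f / N;
* per-tube fill — water is added to a single tube in exactly the
  nominal draw volume V_draw; the measured concentration c then closes
  the mass balance  n_ac = c * (V_draw + V_ac), i.e.
  V_ac = (n_ac - V_draw * c) / c.

Amount concentrations are in mmol/L and volumes in mL, so amounts come
out directly in micromoles (mmol/L == umol/mL). Compliance is judged by
relative bias against the nominal declaration at a 10 % tolerance,
boundary inclusive.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .exceptions import DegenerateComputationError, InvalidInputError

__all__ = [
    "TubeSpec",
    "CompositeDetermination",
    "PerTubeDetermination",
    "QCVerdict",
    "amount_per_tube",
    "expected_amount",
    "expected_conc_at_draw",
    "anticoagulant_volume",
    "conc_at_nominal_total",
    "relative_bias",
    "assess_tolerance",
    "qc_report",
    "DEFAULT_TOLERANCE_PCT",
]

#: Tolerance on relative bias for declaring a tube parameter compliant.
DEFAULT_TOLERANCE_PCT = 10.0


@dataclass(frozen=True)
class TubeSpec:
    """Producer declaration for one tube type.

    ``label`` encodes producer letter, nominal draw volume and
    expiration date, e.g. ``"A_1.8_9.4."``.
    """

    label: str
    nominal_conc: float  # mmol/L citrate in the anticoagulant solution
    nominal_ac_volume: float  # mL of anticoagulant solution
    nominal_draw_volume: float  # mL the vacuum draws
    expiration_date: dt.date | None = None
    buffered: bool = False

    def __post_init__(self) -> None:
        for name in ("nominal_conc", "nominal_ac_volume", "nominal_draw_volume"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidInputError(f"{self.label!r}: {name} must be > 0, got {v}")

    @property
    def nominal_total_volume(self) -> float:
        """Nominal draw plus nominal anticoagulant volume, mL."""
        return self.nominal_draw_volume + self.nominal_ac_volume


@dataclass(frozen=True)
class CompositeDetermination:
    """Citrate concentration measured in a composite-extraction flask."""

    concentration: float  # mmol/L in the flask
    flask_volume: float  # mL
    tube_count: int

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise InvalidInputError("composite concentration must be >= 0")
        if self.flask_volume <= 0:
            raise InvalidInputError("flask volume must be > 0")
        if self.tube_count < 1:
            raise InvalidInputError("tube count must be >= 1")


@dataclass(frozen=True)
class PerTubeDetermination:
    """Citrate concentration after filling one tube with water in the
    nominal draw volume (``added_volume``)."""

    concentration: float  # mmol/L in the filled tube
    added_volume: float  # mL, equals the nominal draw volume by procedure

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise InvalidInputError("per-tube concentration must be >= 0")
        if self.added_volume <= 0:
            raise InvalidInputError("added volume must be > 0")


@dataclass(frozen=True)
class QCVerdict:
    """Derived quantities and compliance flags for one tube type."""

    label: str
    amount_per_tube: float  # umol, determined
    expected_amount: float  # umol, from the declaration
    amount_bias_pct: float
    ac_volume: float  # mL at the instant of examination
    ac_volume_bias_pct: float
    conc_at_nominal_total: float  # mmol/L if declaration held
    expected_conc: float  # mmol/L at nominal draw
    determined_conc: float  # mmol/L measured at nominal draw fill
    conc_bias_pct: float
    compliant_amount: bool
    compliant_volume: bool
    compliant_conc: bool
    warnings: tuple[str, ...] = field(default=())


def amount_per_tube(comp: CompositeDetermination) -> float:
    """Anticoagulant amount per tube (umol) from a composite extraction."""
    return comp.concentration * comp.flask_volume / comp.tube_count


def expected_amount(spec: TubeSpec) -> float:
    """Amount (umol) the declaration implies: c_nom * V_ac_nom."""
    return spec.nominal_conc * spec.nominal_ac_volume


def expected_conc_at_draw(spec: TubeSpec) -> float:
    """Citrate concentration (mmol/L) expected after a nominal draw."""
    return expected_amount(spec) / spec.nominal_total_volume


def anticoagulant_volume(amount: float, per_tube: PerTubeDetermination) -> float:
    """Residual anticoagulant volume (mL) closing the mass balance
    ``amount = c * (V_added + V_ac)``.

    May come out negative under measurement noise; callers should flag
    (not clamp) such values.
    """
    if per_tube.concentration <= 0:
        raise DegenerateComputationError(
            "per-tube concentration must be > 0 to solve for the volume"
        )
    c = per_tube.concentration
    return (amount - per_tube.added_volume * c) / c


def conc_at_nominal_total(amount: float, spec: TubeSpec) -> float:
    """Concentration (mmol/L) the determined amount would give if both
    nominal volumes held: amount / (V_draw_nom + V_ac_nom)."""
    return amount / spec.nominal_total_volume


def relative_bias(observed: float, expected: float) -> float:
    """Relative bias in percent: 100 * (observed - expected) / expected."""
    if expected == 0:
        raise InvalidInputError("expected value must be non-zero")
    return 100.0 * (observed - expected) / expected


def assess_tolerance(
    bias_pct: float, tolerance_pct: float = DEFAULT_TOLERANCE_PCT
) -> bool:
    """True iff |bias| <= tolerance (boundary inclusive)."""
    if tolerance_pct <= 0:
        raise InvalidInputError("tolerance must be > 0")
    return abs(bias_pct) <= tolerance_pct


def evaluate_tube(
    spec: TubeSpec,
    composite: CompositeDetermination,
    per_tube: PerTubeDetermination,
    tolerance_pct: float = DEFAULT_TOLERANCE_PCT,
) -> QCVerdict:
    """Full verdict for one tube type from its two determinations."""
    n_dtmn = amount_per_tube(composite)
    n_expt = expected_amount(spec)
    amount_bias = relative_bias(n_dtmn, n_expt)

    v_ac = anticoagulant_volume(n_dtmn, per_tube)
    v_bias = relative_bias(v_ac, spec.nominal_ac_volume)

    c_total = conc_at_nominal_total(n_dtmn, spec)
    c_expt = expected_conc_at_draw(spec)
    c_bias = relative_bias(per_tube.concentration, c_expt)

    warnings: list[str] = []
    if v_ac < 0:
        warnings.append(
            f"{spec.label}: computed anticoagulant volume is negative "
            f"({v_ac:.4f} mL); measurement noise exceeds the residual volume"
        )

    return QCVerdict(
        label=spec.label,
        amount_per_tube=n_dtmn,
        expected_amount=n_expt,
        amount_bias_pct=amount_bias,
        ac_volume=v_ac,
        ac_volume_bias_pct=v_bias,
        conc_at_nominal_total=c_total,
        expected_conc=c_expt,
        determined_conc=per_tube.concentration,
        conc_bias_pct=c_bias,
        compliant_amount=assess_tolerance(amount_bias, tolerance_pct),
        compliant_volume=assess_tolerance(v_bias, tolerance_pct),
        compliant_conc=assess_tolerance(c_bias, tolerance_pct),
        warnings=tuple(warnings),
    )


def qc_report(
    specs: Sequence[TubeSpec],
    composites: Mapping[str, CompositeDetermination],
    per_tube_determinations: Mapping[str, PerTubeDetermination],
    tolerance_pct: float = DEFAULT_TOLERANCE_PCT,
) -> list[QCVerdict]:
    """Verdicts for a batch of tube types.

    Every spec must have a composite and a per-tube determination under
    its label; a missing one raises naming the offending label.
    """
    verdicts = []
    for spec in specs:
        if spec.label not in composites:
            raise InvalidInputError(
                f"no composite determination for tube type {spec.label!r}"
            )
        if spec.label not in per_tube_determinations:
            raise InvalidInputError(
                f"no per-tube determination for tube type {spec.label!r}"
            )
        verdicts.append(
            evaluate_tube(
                spec,
                composites[spec.label],
                per_tube_determinations[spec.label],
                tolerance_pct,
            )
        )
    return verdicts
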