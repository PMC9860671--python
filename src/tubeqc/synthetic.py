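"""Seeded simulator of citrate tube batches and their measurements.

Generates what the laboratory would observe — tube masses over time,
absorbances of diluted extracts, composite-flask and per-tube-fill
concentrations — from a known ground truth, so every stage of the QC
pipeline can be exercised and its parameter recovery verified without
an instrument.

The generative model:

* production doses each tube with an amount
  ``n = c_nom * V_ac_nom * (1 + bias) * (1 + eps)``, ``eps ~ N(0, fill_cv)``,
  i.e. a systematic dosing bias plus tube-to-tube fill scatter;
* the dispensed liquid volume gets the same relative fill scatter and
  then loses water linearly in time, ``V(t) = max(0, V0 - rate * t)``
  (the observed mass drift over a few months is close to linear);
* a weighing reads tare + liquid mass (water density 1 g/mL) plus
  balance noise;
* a spectrometer reads ``A = a * c/dilution + b`` plus additive
  absorbance noise, inverting the quantification chain exactly when
  the noise is zero.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; equal seeds give identical output.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationFit
from .exceptions import InvalidInputError
from .qc import CompositeDetermination, PerTubeDetermination, TubeSpec, expected_amount

__all__ = [
    "TrueTubeState",
    "SimulationConfig",
    "simulate_batch",
    "virtual_measurement",
    "simulate_mass_series",
    "composite_from_batch",
    "per_tube_fill",
    "simulate_draw_volumes",
]

#: Density of water at ambient temperature, g/mL (mass bookkeeping).
WATER_DENSITY = 1.0

#: Arbitrary tare mass of an empty tube, g. Only mass *differences*
#: matter to the water-loss ANOVA.
DEFAULT_TARE_G = 6.25


@dataclass(frozen=True)
class TrueTubeState:
    """Ground truth for a single simulated tube."""

    spec: TubeSpec
    true_amount: float  # umol of citrate, fixed at production
    true_ac_volume: float  # mL of liquid left after evaporation
    age_days: float
    tube_mass: float  # g, tare + liquid

    def __post_init__(self) -> None:
        if self.true_amount < 0 or self.true_ac_volume < 0:
            raise InvalidInputError("true amount and volume must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model; all noise scales >= 0.

    Defaults emulate a realistic production batch: a few-percent
    dosing bias, 1 % fill scatter, a slow evaporation of order
    1e-4 mL/day, milli-absorbance spectrometer noise and a 20-mg
    balance scatter over ten tubes per weighing date.
    """

    seed: int = 0
    production_amount_bias_rel: float = 0.05
    fill_cv: float = 0.01
    evaporation_rate: float = 1e-4  # mL/day
    absorbance_noise_sd: float = 0.001
    mass_noise_sd: float = 0.022  # g, matches observed weighing scatter
    n_tubes: int = 10
    tare_mass: float = DEFAULT_TARE_G

    def __post_init__(self) -> None:
        for name in (
            "fill_cv",
            "evaporation_rate",
            "absorbance_noise_sd",
            "mass_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if self.n_tubes < 1:
            raise InvalidInputError("n_tubes must be >= 1")


def simulate_batch(
    config: SimulationConfig, spec: TubeSpec, age_days: float = 0.0
) -> list[TrueTubeState]:
    """Draw a batch of ``config.n_tubes`` tubes of one type at a given age."""
    rng = np.random.default_rng(config.seed)
    n = config.n_tubes
    amount_scatter = rng.normal(0.0, config.fill_cv, size=n) if config.fill_cv else np.zeros(n)
    volume_scatter = rng.normal(0.0, config.fill_cv, size=n) if config.fill_cv else np.zeros(n)

    nominal_amount = expected_amount(spec)
    amounts = nominal_amount * (1 + config.production_amount_bias_rel) * (1 + amount_scatter)
    volumes = np.maximum(
        0.0,
        spec.nominal_ac_volume * (1 + volume_scatter)
        - config.evaporation_rate * age_days,
    )
    return [
        TrueTubeState(
            spec=spec,
            true_amount=float(a),
            true_ac_volume=float(v),
            age_days=age_days,
            tube_mass=config.tare_mass + WATER_DENSITY * float(v),
        )
        for a, v in zip(amounts, volumes)
    ]


def virtual_measurement(
    state: TrueTubeState,
    fill_volume: float,
    fit: CalibrationFit,
    noise_sd: float = 0.0,
    dilution: float = 10.0,
    seed: int = 0,
) -> float:
    """Absorbance the spectrometer would read for one tube filled with
    ``fill_volume`` mL of water, after the procedural dilution."""
    if fill_volume <= 0:
        raise InvalidInputError("fill volume must be > 0")
    c_total = state.true_amount / (fill_volume + state.true_ac_volume)
    absorbance = fit.predict(c_total / dilution)
    if noise_sd > 0:
        absorbance += float(np.random.default_rng(seed).normal(0.0, noise_sd))
    return float(absorbance)


def composite_from_batch(
    batch: Sequence[TrueTubeState], flask_volume: float = 50.0
) -> CompositeDetermination:
    """Noise-free composite extraction of a batch into one flask."""
    if not batch:
        raise InvalidInputError("empty batch")
    total = sum(t.true_amount for t in batch)
    return CompositeDetermination(
        concentration=total / flask_volume,
        flask_volume=flask_volume,
        tube_count=len(batch),
    )


def per_tube_fill(state: TrueTubeState, fill_volume: float | None = None) -> PerTubeDetermination:
    """Noise-free per-tube fill at the nominal draw volume (or an
    explicit ``fill_volume``)."""
    v = state.spec.nominal_draw_volume if fill_volume is None else fill_volume
    if v <= 0:
        raise InvalidInputError("fill volume must be > 0")
    return PerTubeDetermination(
        concentration=state.true_amount / (v + state.true_ac_volume),
        added_volume=v,
    )


def simulate_mass_series(
    config: SimulationConfig,
    spec: TubeSpec,
    dates: Sequence[dt.date],
) -> pd.DataFrame:
    """Tube-mass table for repeated weighings of ``n_tubes`` random
    tubes on each date.

    The group mean drifts down by ``evaporation_rate * days * 1 g/mL``
    from the first date; within-group scatter is ``mass_noise_sd``.
    Columns: tube_type, date, replicate, mass_g.
    """
    dates = list(dates)
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise InvalidInputError("dates must be in ascending order")
    rng = np.random.default_rng(config.seed)
    base = config.tare_mass + WATER_DENSITY * spec.nominal_ac_volume
    rows = []
    t0 = dates[0]
    for date in dates:
        delta = (date - t0).days
        mean = base - WATER_DENSITY * config.evaporation_rate * delta
        masses = mean + (
            rng.normal(0.0, config.mass_noise_sd, size=config.n_tubes)
            if config.mass_noise_sd
            else np.zeros(config.n_tubes)
        )
        for rep, m in enumerate(masses, start=1):
            rows.append(
                {
                    "tube_type": spec.label,
                    "date": date.isoformat(),
                    "replicate": rep,
                    "mass_g": float(m),
                }
            )
    return pd.DataFrame(rows)


def simulate_draw_volumes(
    config: SimulationConfig, spec: TubeSpec, n: int | None = None, cv: float = 0.02
) -> np.ndarray:
    """Draw-volume measurements scattered around the nominal value with
    relative standard deviation ``cv``."""
    rng = np.random.default_rng(config.seed)
    size = config.n_tubes if n is None else n
    return spec.nominal_draw_volume * (1 + rng.normal(0.0, cv, size=size))


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed (convenience for
    replicate studies)."""
    return replace(config, seed=seed)
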