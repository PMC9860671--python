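"""Linear calibration for UV spectrometric citrate determination.

A citrate working solution absorbs at 210 nm proportionally to its
concentration (Beer-Lambert), so a six-point external-standard line
``y = a*x + b`` fitted by ordinary least squares converts an absorbance
reading into an amount concentration. Because a concentration read off
a fitted line inherits the scatter of the calibration itself, every
interpolated value carries a standard uncertainty of interpolation

    s_x0 = (s_yx / a) * sqrt(1/m + 1/n + (y0 - ybar)^2 / (a^2 * Sxx))

where ``s_yx`` is the residual standard deviation of the fit (n - 2
degrees of freedom), ``n`` the number of calibration points, ``m`` the
number of replicate readings of the unknown, and ``Sxx`` the centred
sum of squares of the calibration concentrations. The relative
uncertainty of interpolation is combined in quadrature with the
relative uncertainty of the ten-fold dilution the procedure requires.

The standard-additions variant quantifies the same analyte when matrix
effects are suspected: known spikes are added to aliquots of the
unknown and the fitted line's x-axis intercept magnitude estimates the
unspiked concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateComputationError, InvalidInputError

__all__ = [
    "CalibrationPoint",
    "CalibrationFit",
    "ConcentrationEstimate",
    "fit_calibration",
    "interpolate",
    "combine_relative_uncertainties",
    "apply_dilution",
    "standard_additions",
    "repeatability",
    "DEFAULT_DILUTION_FACTOR",
    "DILUTION_REL_U",
]

#: Ten-fold dilution of the tube extract into the HCl working medium.
DEFAULT_DILUTION_FACTOR = 10.0

#: Relative standard uncertainty of the 10-fold volumetric dilution
#: (1-mL class-A pipette into a 10-mL class-A flask).
DILUTION_REL_U = 0.0087


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration level: concentration (mmol/L) and absorbance."""

    concentration: float
    absorbance: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise InvalidInputError(
                f"concentration must be finite and >= 0, got {self.concentration}"
            )
        if not math.isfinite(self.absorbance):
            raise InvalidInputError(f"absorbance must be finite, got {self.absorbance}")


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary least-squares line ``y = slope*x + intercept`` with its
    dispersion statistics.

    Attributes
    ----------
    slope, intercept:
        Line coefficients (absorbance per mmol/L; absorbance).
    slope_sd, intercept_sd:
        Standard deviations of the coefficients.
    residual_sd:
        Residual standard deviation s_yx with n - 2 degrees of freedom.
    r_squared:
        Coefficient of determination.
    n_points, x_mean, y_mean, sxx:
        Design summaries needed for the uncertainty of interpolation.
    """

    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float
    residual_sd: float
    r_squared: float
    n_points: int
    x_mean: float
    y_mean: float
    sxx: float

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise InvalidInputError("a calibration fit needs at least 3 points")
        if not 0.0 <= self.r_squared <= 1.0:
            raise InvalidInputError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.residual_sd < 0:
            raise InvalidInputError("residual_sd must be >= 0")
        if self.sxx <= 0:
            raise InvalidInputError("sxx must be > 0")

    def predict(self, concentration: float) -> float:
        """Absorbance the line predicts at ``concentration``."""
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Concentration interpolated from a calibration line.

    ``value`` is on the scale of the measured solution times
    ``dilution_factor`` (factor 1 means the working solution itself).
    ``quantifiable`` is False when the interpolated value is not
    positive; such results are flagged rather than raised so that a
    batch of tubes keeps processing.
    """

    value: float
    interp_sd: float
    rel_interp_sd: float
    combined_sd: float
    dilution_factor: float = 1.0
    quantifiable: bool = True


def _as_arrays(points: Iterable[CalibrationPoint]) -> tuple[np.ndarray, np.ndarray]:
    pts = list(points)
    if len(pts) < 3:
        raise InvalidInputError(f"need at least 3 calibration points, got {len(pts)}")
    x = np.array([p.concentration for p in pts], dtype=float)
    y = np.array([p.absorbance for p in pts], dtype=float)
    return x, y


def fit_calibration(points: Iterable[CalibrationPoint]) -> CalibrationFit:
    """Fit ``y = a*x + b`` by unweighted ordinary least squares.

    Raises
    ------
    InvalidInputError
        Fewer than 3 points.
    DegenerateComputationError
        All concentrations identical (no design spread).
    """
    x, y = _as_arrays(points)
    if np.ptp(x) == 0:
        raise DegenerateComputationError(
            "all calibration concentrations are identical; cannot fit a line"
        )
    n = x.size
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)

    x_mean = float(x.mean())
    y_mean = float(y.mean())
    sxx = float(np.sum((x - x_mean) ** 2))
    resid = y - (slope * x + intercept)
    sse = float(np.dot(resid, resid))
    residual_sd = math.sqrt(sse / (n - 2))
    slope_sd = residual_sd / math.sqrt(sxx)
    intercept_sd = residual_sd * math.sqrt(float(np.sum(x * x)) / (n * sxx))
    # collinear input: clamp tiny negative rounding of 1 - SSE/SST
    r_squared = min(1.0, float(res.rvalue) ** 2)

    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        slope_sd=slope_sd,
        intercept_sd=intercept_sd,
        residual_sd=residual_sd,
        r_squared=r_squared,
        n_points=n,
        x_mean=x_mean,
        y_mean=y_mean,
        sxx=sxx,
    )


def interpolate(
    fit: CalibrationFit, y0: float, replicates: int = 1
) -> ConcentrationEstimate:
    """Read a concentration off the calibration line.

    ``replicates`` is the number of absorbance readings averaged into
    ``y0``; it replaces the leading 1 of the uncertainty formula by
    ``1/replicates``. A non-positive interpolated concentration is
    returned flagged as non-quantifiable rather than raised.
    """
    if replicates < 1:
        raise InvalidInputError(f"replicates must be >= 1, got {replicates}")
    if fit.slope == 0:
        raise DegenerateComputationError("calibration slope is zero")
    value = (y0 - fit.intercept) / fit.slope
    interp_sd = (fit.residual_sd / abs(fit.slope)) * math.sqrt(
        1.0 / replicates
        + 1.0 / fit.n_points
        + (y0 - fit.y_mean) ** 2 / (fit.slope**2 * fit.sxx)
    )
    quantifiable = value > 0
    rel = interp_sd / value if quantifiable else math.nan
    return ConcentrationEstimate(
        value=value,
        interp_sd=interp_sd,
        rel_interp_sd=rel,
        combined_sd=interp_sd,
        dilution_factor=1.0,
        quantifiable=quantifiable,
    )


def combine_relative_uncertainties(components: Sequence[float]) -> float:
    """Root-sum-of-squares combination of relative standard uncertainties."""
    if len(components) == 0:
        raise InvalidInputError("no uncertainty components given")
    comps = np.asarray(components, dtype=float)
    if np.any(comps < 0):
        raise InvalidInputError("relative uncertainties must be >= 0")
    return float(math.sqrt(float(np.dot(comps, comps))))


def apply_dilution(measured: float, factor: float = DEFAULT_DILUTION_FACTOR) -> float:
    """Back-calculate the in-tube concentration from the diluted reading."""
    if factor <= 0:
        raise InvalidInputError(f"dilution factor must be > 0, got {factor}")
    return measured * factor


def estimate_concentration(
    fit: CalibrationFit,
    y0: float,
    replicates: int = 1,
    dilution_factor: float = DEFAULT_DILUTION_FACTOR,
    dilution_rel_u: float = DILUTION_REL_U,
) -> ConcentrationEstimate:
    """Full quantification chain: interpolate, undo the dilution, and
    combine the interpolation and dilution relative uncertainties.

    ``combined_sd`` is expressed on the in-tube concentration scale.
    """
    base = interpolate(fit, y0, replicates=replicates)
    value = apply_dilution(base.value, dilution_factor)
    if base.quantifiable:
        rel_combined = combine_relative_uncertainties(
            [base.rel_interp_sd, dilution_rel_u]
        )
        combined_sd = abs(value) * rel_combined
    else:
        combined_sd = math.nan
    return ConcentrationEstimate(
        value=value,
        interp_sd=base.interp_sd,
        rel_interp_sd=base.rel_interp_sd,
        combined_sd=combined_sd,
        dilution_factor=dilution_factor,
        quantifiable=base.quantifiable,
    )


def standard_additions(points: Sequence[tuple[float, float]]) -> float:
    """Quantify an unknown by the method of standard additions.

    ``points`` are (added concentration, absorbance) pairs including a
    zero-addition point. The unknown concentration is the magnitude of
    the x-axis intercept of the fitted line, ``intercept/slope``.
    """
    if len(points) < 3:
        raise InvalidInputError(
            f"standard additions needs at least 3 points, got {len(points)}"
        )
    added = np.array([p[0] for p in points], dtype=float)
    if not np.any(added == 0):
        raise InvalidInputError("standard additions requires a zero-addition point")
    absorb = np.array([p[1] for p in points], dtype=float)
    if np.ptp(added) == 0:
        raise DegenerateComputationError("all addition levels are identical")
    res = stats.linregress(added, absorb)
    if res.slope <= 0:
        raise DegenerateComputationError(
            f"non-positive standard-additions slope ({res.slope:g})"
        )
    return float(res.intercept / res.slope)


def repeatability(values: Sequence[float]) -> tuple[float, float, float]:
    """Mean, sample standard deviation and relative sd (%) of replicate
    determinations, as reported for within-day repeatability checks."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidInputError("repeatability needs at least 2 replicates")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    rsd_pct = 100.0 * sd / mean if mean != 0 else math.inf
    return mean, sd, rsd_pct
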