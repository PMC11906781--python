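"""External-standard calibration and semi-quantification.

Linear calibration curves (response = a * concentration + b) fitted by
ordinary least squares supply slope, intercept, R-squared, and the limits
of detection and quantification (LOD = 3.3 * SD / slope, LOQ = 10 * SD /
slope, SD being the standard deviation of the regression residuals by
default).  Sample responses are inverted through the curve and expressed
as milligram standard-equivalents per gram of dried extract; responses
below the LOQ propagate as the string ``"< LOQ"``.  The same inversion
serves colorimetric total-phenolic / total-flavonoid assay curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationCurve:
    analyte: str
    slope: float
    intercept: float
    r_squared: float
    response_sd: float
    lod: float
    loq: float
    conc_range: tuple[float, float]
    mode: str = "xic_area"  # or "absorbance"

    def predict_response(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def invert(self, response: float) -> float:
        if self.slope == 0:
            raise CalibrationError("calibration slope is zero; curve not invertible")
        return (response - self.intercept) / self.slope


def fit_calibration(
    concentrations,
    responses,
    analyte: str = "",
    sd_source: str = "residuals",
    mode: str = "xic_area",
) -> CalibrationCurve:
    """OLS calibration fit with LOD/LOQ from the 3.3/10 rule.

    ``sd_source`` selects the SD entering the limit formulas: ``residuals``
    (default, SD of regression residuals with n-2 degrees of freedom) or
    ``intercept`` (standard error of the intercept estimate).
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("concentrations and responses must be equal-length vectors")
    if len(np.unique(x)) < 3:
        raise CalibrationError("need at least 3 distinct concentration levels")
    if np.var(x) == 0:
        raise CalibrationError("zero concentration variance")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    n = len(x)
    if sd_source == "residuals":
        sd = float(np.sqrt((resid**2).sum() / (n - 2))) if n > 2 else 0.0
    elif sd_source == "intercept":
        sd = float(fit.intercept_stderr)
    else:
        raise CalibrationError(f"unknown sd_source {sd_source!r}")
    if fit.slope == 0:
        raise CalibrationError("fitted slope is zero")
    lod = 3.3 * sd / abs(fit.slope)
    loq = 10.0 * sd / abs(fit.slope)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        response_sd=sd,
        lod=lod,
        loq=loq,
        conc_range=(float(x.min()), float(x.max())),
        mode=mode,
    )


def quantify_equivalents(
    xic_area: float,
    curve: CalibrationCurve,
    extract_mass_g: float,
    volume_ml: float,
) -> float | str:
    """Concentration from an XIC area, scaled to mg-equivalents per g extract.

    concentration (ug/mL) = (area - intercept) / slope; the amount in the
    injected volume divided by the extract mass gives ug/mg = mg/g.
    Responses below the curve-predicted LOQ response return ``"< LOQ"``.
    """
    if extract_mass_g <= 0 or volume_ml <= 0:
        raise CalibrationError("extract mass and volume must be positive")
    conc = curve.invert(xic_area)
    if conc < curve.loq:
        return "< LOQ"
    # ug/mL * mL / g = ug/g; /1000 -> mg/g
    return conc * volume_ml / extract_mass_g / 1000.0


def invert_assay_curve(absorbance: float, curve: CalibrationCurve) -> float:
    """Concentration read off a colorimetric standard curve, x = (y - b)/a."""
    return curve.invert(absorbance)


def assay_curve(slope: float, intercept: float, analyte: str = "") -> CalibrationCurve:
    """Wrap published curve coefficients (no raw series available) for inversion."""
    if slope == 0:
        raise CalibrationError("slope must be non-zero")
    return CalibrationCurve(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        r_squared=float("nan"),
        response_sd=float("nan"),
        lod=float("nan"),
        loq=float("nan"),
        conc_range=(float("nan"), float("nan")),
        mode="absorbance",
    )
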