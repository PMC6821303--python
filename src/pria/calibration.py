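"""Linear ΔS-versus-content calibration models.

The retardation statistic ΔS is linear in the modified-base content m over
the assay's working range, ΔS = a·m + b, so quantification is a straight
standard-curve problem: fit (content, ΔS) calibration points by ordinary
least squares, then invert the line at a measured ΔS to obtain content.
The published calibration lines for the three cytosine oxides (on defined
test duplexes and on genomic DNA) are bundled as ready-made models.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import DegenerateDesignError

__all__ = [
    "CalibrationModel",
    "ContentEstimate",
    "LinearCalibration",
    "builtin_calibrations",
    "fit_calibration",
    "predict_delta_s",
    "invert_calibration",
]

#: content_units value for genomic calibrations: content is % of total dN.
PERCENT_OF_DN = "percent_of_dN"
#: content_units for the test-duplex calibrations, whose printed coefficient
#: units are internally ambiguous; coefficients are kept exactly as printed.
AS_PRINTED_AMBIGUOUS = "as_printed_ambiguous"


@dataclass(frozen=True)
class CalibrationModel:
    """Linear calibration ΔS(%) = a·content + b.

    ``a`` is the sensitivity (ΔS % per content unit), ``b`` the blank
    intercept (ΔS %), ``fit_r2`` the R² of the calibration fit.
    """

    analyte: str
    a: float
    b: float
    fit_r2: float = math.nan
    content_units: str = "custom"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("calibration slope a must be nonzero")
        if math.isfinite(self.fit_r2) and self.fit_r2 > 1:
            raise ValueError("fit_r2 cannot exceed 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(**d)


@dataclass(frozen=True)
class ContentEstimate:
    """Modified-base content inferred from one ΔS measurement.

    Negative contents (ΔS below the calibration blank) are preserved and
    flagged ``below_calibration`` rather than clipped, so near-blank
    samples stay diagnosable.
    """

    analyte: str
    content: float
    delta_s_used: float
    model_provenance: str = ""
    below_calibration: bool = False


def builtin_calibrations() -> dict[tuple[str, str], CalibrationModel]:
    """Published calibration lines, keyed by (analyte, context).

    Context "test" = synthetic test-duplex mixture series; "genomic" =
    dilution series of tagged genomic fragments. Coefficients are stored at
    printed precision (1.56 × 10² is stored as 156), with no invented
    digits.
    """
    return {
        ("5fC", "test"): CalibrationModel(
            "5fC", 4.22, 0.757, 0.979, AS_PRINTED_AMBIGUOUS,
            "PHPA-tagged test-duplex mixture series",
        ),
        ("5hmC", "test"): CalibrationModel(
            "5hmC", 8.60, 0.857, 0.993, AS_PRINTED_AMBIGUOUS,
            "glucosylation/3-CPBA-tagged test-duplex mixture series",
        ),
        ("5caC", "test"): CalibrationModel(
            "5caC", 9.08, -2.11, 0.994, AS_PRINTED_AMBIGUOUS,
            "LY-tagged test-duplex mixture series",
        ),
        ("5fC", "genomic"): CalibrationModel(
            "5fC", 1030.0, 0.101, 0.932, PERCENT_OF_DN,
            "PHPA-tagged mESC genomic fragment dilution series",
        ),
        ("5hmC", "genomic"): CalibrationModel(
            "5hmC", 156.0, -2.25, 0.981, PERCENT_OF_DN,
            "glucosylation/3-CPBA-tagged adult human brain genomic DNA "
            "dilution series",
        ),
    }


class LinearCalibration(RegressorMixin, BaseEstimator):
    """Ordinary least-squares ΔS-on-content calibration estimator.

    ``fit(X, y)`` takes contents as a single-column ``X`` and ΔS values as
    ``y``; fitted attributes are ``a_`` (slope), ``b_`` (intercept),
    ``r2_`` and the bundled ``model_``. ``predict`` maps content to ΔS and
    ``inverse`` maps measured ΔS back to content estimates.
    """

    def __init__(self, analyte: str = "custom", content_units: str = "custom"):
        self.analyte = analyte
        self.content_units = content_units

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if X.shape[1] != 1:
            raise ValueError("calibration expects a single content column")
        x = X[:, 0]
        if np.unique(x).size < 2:
            raise DegenerateDesignError(
                "calibration needs at least 2 distinct content values"
            )
        res = stats.linregress(x, y)
        self.a_ = float(res.slope)
        self.b_ = float(res.intercept)
        self.r2_ = float(res.rvalue**2)
        self.n_features_in_ = 1
        self.model_ = CalibrationModel(
            self.analyte,
            self.a_,
            self.b_,
            self.r2_,
            self.content_units,
            f"OLS fit of {len(x)} calibration points",
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "a_")
        X = check_array(X)
        return self.a_ * X[:, 0] + self.b_

    def inverse(self, delta_s: float) -> ContentEstimate:
        """Invert the fitted line at one measured ΔS (%)."""
        check_is_fitted(self, "a_")
        return invert_calibration(self.model_, delta_s)


def fit_calibration(points, analyte: str = "custom",
                    content_units: str = "custom") -> CalibrationModel:
    """OLS calibration from (content, ΔS) pairs.

    ``points`` is any iterable of (content, delta_s) pairs or a DataFrame
    with ``content`` and ``delta_s`` columns. Needs at least two distinct
    content values.
    """
    if hasattr(points, "columns"):
        arr = np.asarray(points[["content", "delta_s"]], dtype=float)
    else:
        arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DegenerateDesignError(
            "need at least two (content, delta_s) points"
        )
    est = LinearCalibration(analyte=analyte, content_units=content_units)
    est.fit(arr[:, :1], arr[:, 1])
    return est.model_


def predict_delta_s(model: CalibrationModel, content: float) -> float:
    """Forward evaluation a·content + b, in ΔS percent."""
    return model.a * content + model.b


def invert_calibration(model: CalibrationModel, delta_s: float) -> ContentEstimate:
    """Content = (ΔS − b)/a in the model's content units.

    A negative content (ΔS below the blank intercept) is flagged
    ``below_calibration``.
    """
    content = (delta_s - model.b) / model.a
    return ContentEstimate(
        analyte=model.analyte,
        content=float(content),
        delta_s_used=float(delta_s),
        model_provenance=model.provenance,
        below_calibration=content < 0,
    )
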