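"""Credible-slope screening by exhaustive interval regression.

The per-well summary statistic of the assay is the *credible slope*: the
maximal slope of the fluorescence-vs-cycle plot over any contiguous cycle
window whose linear fit clears an R² threshold. Screening proceeds in three
steps, applied to every window [i, j]:

1. slope_{i,j} — the mean of successive intensity differences over the
   window, which telescopes to (value_j − value_i)/(j − i);
2. bias — the intercept minimizing the sum of squared residuals of
   slope·x + bias against the window values, for that fixed slope;
3. R² — the coefficient of determination of that fixed-slope line.

Windows whose R² exceeds the threshold form the *confidence set*; the
maximal slope among them is the credible slope. An ``ols`` slope mode is
also provided, which replaces step 1 with the ordinary least-squares slope
on the window (it never has lower R² than the endpoint slope).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import DegenerateWindowError
from .trace import FluorescenceTrace

__all__ = [
    "IntervalFit",
    "ScreenConfig",
    "ScreenResult",
    "CredibleSlopeScreener",
    "endpoint_slope",
    "fit_bias_for_slope",
    "window_r2",
    "enumerate_interval_fits",
    "screen_credible_slope",
]

logger = logging.getLogger(__name__)

_SLOPE_MODES = ("endpoint", "ols")


@dataclass(frozen=True)
class IntervalFit:
    """A candidate slope on the inclusive cycle window [i, j].

    ``slope`` and ``bias`` are in intensity units per cycle and intensity
    units; ``sse`` is the minimized residual sum of squares; ``r2`` may be
    negative for a poor fixed slope and is NaN on a constant window.
    """

    i: int
    j: int
    slope: float
    bias: float
    sse: float
    r2: float

    @property
    def length(self) -> int:
        return self.j - self.i + 1


@dataclass(frozen=True)
class ScreenConfig:
    """Screening parameters.

    r2_threshold
        Windows must exceed this R² to enter the confidence set
        (default 0.999).
    min_window
        Minimum cycles per window (default 10): short windows make R²
        uninformative on a 30–60 cycle run.
    slope_mode
        "endpoint" (mean successive difference) or "ols".
    require_positive_slope
        Amplification increases fluorescence, so only positive slopes are
        credible by default; disable for diagnostics of decaying signals.
    """

    r2_threshold: float = 0.999
    min_window: int = 10
    slope_mode: str = "endpoint"
    require_positive_slope: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.min_window < 3:
            raise ValueError("min_window must be at least 3")
        if self.slope_mode not in _SLOPE_MODES:
            raise ValueError(f"slope_mode must be one of {_SLOPE_MODES}")


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of screening one trace.

    ``credible`` is True iff at least one window passed the threshold; if it
    is False, ``best`` holds the highest-R² window for diagnostics (or None
    when every window was degenerate).
    """

    best: IntervalFit | None
    credible: bool
    n_candidates: int
    n_passing: int

    def to_record(self, label: str = "") -> dict:
        """Flat JSON-ready record of the screening outcome."""
        rec = {
            "label": label,
            "i": None,
            "j": None,
            "slope": None,
            "bias": None,
            "r2": None,
            "credible": self.credible,
            "n_passing": self.n_passing,
        }
        if self.best is not None:
            rec.update(
                i=self.best.i,
                j=self.best.j,
                slope=self.best.slope,
                bias=self.best.bias,
                r2=self.best.r2,
            )
        return rec


def endpoint_slope(trace: FluorescenceTrace, i: int, j: int) -> float:
    """Mean successive intensity difference over [i, j).

    By telescoping this equals (value_j − value_i)/(j − i); units are
    intensity per cycle.
    """
    if i >= j:
        raise ValueError(f"need i < j, got i={i}, j={j}")
    p, q = trace.position(i), trace.position(j)
    return float(
        (trace.intensities[q] - trace.intensities[p])
        / (trace.cycles[q] - trace.cycles[p])
    )


def fit_bias_for_slope(
    trace: FluorescenceTrace, i: int, j: int, slope: float
) -> tuple[float, float]:
    """Least-squares intercept for a fixed slope on window [i, j].

    Returns ``(bias, sse)`` where bias = mean(y) − slope·mean(x) minimizes
    the sum of squared residuals of slope·x + bias, and sse is that minimum.
    """
    if not math.isfinite(slope):
        raise ValueError("slope must be finite")
    x, y = trace.window(i, j)
    bias = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + bias)
    return bias, float(resid @ resid)


def window_r2(
    trace: FluorescenceTrace, i: int, j: int, slope: float, bias: float
) -> float:
    """Coefficient of determination of slope·x + bias on window [i, j].

    Returns 1 − SSE/SST with SST the total sum of squares about the window
    mean. Raises DegenerateWindowError on a constant window (SST = 0).
    """
    x, y = trace.window(i, j)
    centered = y - y.mean()
    sst = float(centered @ centered)
    if sst == 0.0:
        raise DegenerateWindowError(
            f"window [{i}, {j}] is constant; R² undefined"
        )
    resid = y - (slope * x + bias)
    return 1.0 - float(resid @ resid) / sst


def _fit_window(x: np.ndarray, y: np.ndarray, slope_mode: str) -> IntervalFit:
    """Fit one window; R² is NaN when the window is constant."""
    ybar = y.mean()
    centered = y - ybar
    sst = float(centered @ centered)
    if slope_mode == "endpoint":
        slope = float((y[-1] - y[0]) / (x[-1] - x[0]))
    else:  # ols
        xc = x - x.mean()
        slope = float((xc @ y) / (xc @ xc))
    bias = float(ybar - slope * x.mean())
    resid = y - (slope * x + bias)
    sse = float(resid @ resid)
    r2 = 1.0 - sse / sst if sst > 0.0 else math.nan
    return IntervalFit(int(x[0]), int(x[-1]), slope, bias, sse, r2)


def enumerate_interval_fits(
    trace: FluorescenceTrace, config: ScreenConfig | None = None
) -> list[IntervalFit]:
    """All window fits with length ≥ config.min_window, ordered by (i, j)."""
    config = config or ScreenConfig()
    m = len(trace)
    if m < config.min_window:
        raise ValueError(
            f"trace has {m} cycles, below min_window={config.min_window}"
        )
    x_all = trace.cycles.astype(np.float64)
    y_all = trace.intensities
    fits: list[IntervalFit] = []
    n_degenerate = 0
    for p in range(m - config.min_window + 1):
        for q in range(p + config.min_window - 1, m):
            fit = _fit_window(x_all[p : q + 1], y_all[p : q + 1], config.slope_mode)
            if math.isnan(fit.r2):
                n_degenerate += 1
            fits.append(fit)
    if n_degenerate:
        logger.warning(
            "trace %r: %d constant window(s) excluded from R² screening",
            trace.label,
            n_degenerate,
        )
    return fits


def _select_best(candidates: list[IntervalFit], key) -> IntervalFit:
    return max(candidates, key=key)


def screen_credible_slope(
    trace: FluorescenceTrace, config: ScreenConfig | None = None
) -> ScreenResult:
    """Select the maximal slope among windows passing the R² threshold.

    Ties on slope are broken toward the longer window, then the smaller
    start cycle, so output is deterministic. Never raises on "no credible
    window": the result carries ``credible=False`` and the highest-R² window
    as a diagnostic instead.
    """
    config = config or ScreenConfig()
    fits = enumerate_interval_fits(trace, config)
    passing = [
        f
        for f in fits
        if math.isfinite(f.r2)
        and f.r2 > config.r2_threshold
        and (f.slope > 0 or not config.require_positive_slope)
    ]
    if passing:
        best = _select_best(passing, key=lambda f: (f.slope, f.length, -f.i))
        return ScreenResult(best, True, len(fits), len(passing))
    finite = [f for f in fits if math.isfinite(f.r2)]
    best = (
        _select_best(finite, key=lambda f: (f.r2, f.length, -f.i))
        if finite
        else None
    )
    return ScreenResult(best, False, len(fits), 0)


class CredibleSlopeScreener(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer extracting credible slopes from wells.

    ``X`` is an (n_wells, n_cycles) array of fluorescence readings sampled
    on consecutive cycles; ``transform`` returns an (n_wells, 1) array of
    credible slopes, NaN where no window passed the R² screen. The richer
    per-trace interface is :meth:`screen_trace`.

    Parameters mirror :class:`ScreenConfig`.
    """

    def __init__(
        self,
        r2_threshold: float = 0.999,
        min_window: int = 10,
        slope_mode: str = "endpoint",
        require_positive_slope: bool = True,
    ):
        self.r2_threshold = r2_threshold
        self.min_window = min_window
        self.slope_mode = slope_mode
        self.require_positive_slope = require_positive_slope

    def _config(self) -> ScreenConfig:
        return ScreenConfig(
            r2_threshold=self.r2_threshold,
            min_window=self.min_window,
            slope_mode=self.slope_mode,
            require_positive_slope=self.require_positive_slope,
        )

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self._config()  # validate parameters
        if X.shape[1] < self.min_window:
            raise ValueError(
                f"traces have {X.shape[1]} cycles, below "
                f"min_window={self.min_window}"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} cycles, got {X.shape[1]}"
            )
        config = self._config()
        out = np.full((X.shape[0], 1), np.nan)
        for k, row in enumerate(X):
            res = screen_credible_slope(
                FluorescenceTrace.from_intensities(row), config
            )
            if res.credible:
                out[k, 0] = res.best.slope
        return out

    def screen_trace(self, trace: FluorescenceTrace) -> ScreenResult:
        """Screen one trace, returning the full ScreenResult."""
        return screen_credible_slope(trace, self._config())
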