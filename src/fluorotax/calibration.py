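"""Fluorescence-to-chlorophyll calibration by robust zero-intercept regression.

Total chlorophyll a (TChla, µg/L) is modelled as a zero-intercept linear
function of a single excitation channel's fluorescence,

    TChla = slope · F,

with the slope estimated by M-regression (Tukey bisquare, c = 4.685) so
that gross outliers — quenched surface readings, bad bottle matches — do
not drag the fit.  The zero intercept guarantees non-negative predicted
chlorophyll.  Points whose final robustness weight falls below 1e-3 are
flagged as outliers; the best channel is chosen by coefficient of
determination across channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CHANNELS",
    "CalibrationModel",
    "published_calibration",
    "fit_robust_zero_intercept",
    "select_calibration_channel",
    "estimate_tchla",
]

#: LED excitation wavelengths (nm) of the nine-channel fluorometer.
CHANNELS: tuple[int, ...] = (375, 400, 420, 435, 470, 505, 525, 570, 590)

#: Robustness weight below which a calibration point is declared an outlier.
OUTLIER_WEIGHT_THRESHOLD = 1e-3

#: Tukey bisquare tuning constant (95% Gaussian efficiency).
BISQUARE_C = 4.685


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted zero-intercept fluorescence→TChla conversion for one channel."""

    channel: int
    slope: float
    slope_se: float
    r2: float
    n: int
    weights: np.ndarray | None = None
    outlier_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if self.weights is not None:
            flags = np.asarray(self.weights) < OUTLIER_WEIGHT_THRESHOLD
            if self.outlier_flags is None:
                object.__setattr__(self, "outlier_flags", flags)
            elif not np.array_equal(flags, np.asarray(self.outlier_flags)):
                raise ValueError("outlier flags inconsistent with weights")

    @property
    def n_outliers(self) -> int:
        return 0 if self.outlier_flags is None else int(np.sum(self.outlier_flags))


def published_calibration() -> CalibrationModel:
    """The field-calibrated 435 nm conversion, TChla = 0.54095 · F435nm."""
    return CalibrationModel(channel=435, slope=0.54095, slope_se=0.02205,
                            r2=0.8844, n=271)


def fit_robust_zero_intercept(x: np.ndarray, y: np.ndarray,
                              channel: int = 435) -> CalibrationModel:
    """Fit y = slope·x by iteratively reweighted M-estimation.

    Parameters
    ----------
    x, y
        Fluorescence and TChla (µg/L) arrays of equal length ≥ 3.
    channel
        Wavelength label recorded on the returned model.

    Notes
    -----
    Tukey bisquare ψ with c = 4.685, scale from the MAD of the residuals,
    at most 50 reweighting iterations with a 1e-8 convergence tolerance.
    Bisquare weights reach exactly zero for large residuals, so the
    weight < 1e-3 outlier rule is a genuine rejection rule.  r² is computed
    through the origin on the non-outlier points (1 − SSres/Σy²).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 calibration points")
    if not np.any(x != 0):
        raise ValueError("degenerate fluorescence: all values zero")

    ols_slope = float(np.sum(x * y) / np.sum(x * x))
    ols_resid = y - ols_slope * x
    if np.median(np.abs(ols_resid - np.median(ols_resid))) == 0.0:
        # (near-)exact proportionality: the MAD scale collapses to zero and
        # IRLS is undefined; the OLS fit is already the M-estimate.
        slope, se = ols_slope, _ols_slope_se(x, ols_resid)
        weights = np.ones_like(x)
        flags = np.zeros_like(x, dtype=bool)
    else:
        model = sm.RLM(y, x[:, None], M=sm.robust.norms.TukeyBiweight(BISQUARE_C))
        res = model.fit(maxiter=50, tol=1e-8, scale_est="mad")
        slope = float(res.params[0])
        se = float(res.bse[0])
        weights = np.asarray(res.weights, dtype=float)
        flags = weights < OUTLIER_WEIGHT_THRESHOLD
    if slope <= 0:
        raise ValueError("calibration produced a non-positive slope")

    keep = ~flags
    resid = y[keep] - slope * x[keep]
    ss_y = float(np.sum(y[keep] ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_y if ss_y > 0 else np.nan
    return CalibrationModel(channel=channel, slope=slope, slope_se=se, r2=r2,
                            n=x.size, weights=weights, outlier_flags=flags)


def _ols_slope_se(x: np.ndarray, resid: np.ndarray) -> float:
    dof = max(x.size - 1, 1)
    return float(np.sqrt(np.sum(resid**2) / dof / np.sum(x * x)))


def select_calibration_channel(
    pairs: dict[int, tuple[np.ndarray, np.ndarray]],
) -> tuple[CalibrationModel, pd.DataFrame]:
    """Fit every channel and select the one with the highest r².

    ``pairs`` maps wavelength → (fluorescence, TChla) arrays.  Ties are
    broken toward the shorter wavelength.  Channels whose fit fails
    (e.g. all-zero fluorescence) are recorded with NaN r².

    Returns the winning :class:`CalibrationModel` and a ranking table with
    columns ``channel, slope, slope_se, r2, n_outliers, error``.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two channels to select from")
    rows = []
    fits: dict[int, CalibrationModel] = {}
    for ch in sorted(pairs):
        x, y = pairs[ch]
        try:
            m = fit_robust_zero_intercept(np.asarray(x), np.asarray(y), channel=ch)
        except ValueError as exc:
            rows.append({"channel": ch, "slope": np.nan, "slope_se": np.nan,
                         "r2": np.nan, "n_outliers": 0, "error": str(exc)})
            continue
        fits[ch] = m
        rows.append({"channel": ch, "slope": m.slope, "slope_se": m.slope_se,
                     "r2": m.r2, "n_outliers": m.n_outliers, "error": ""})
    if not fits:
        raise ValueError("no channel could be calibrated")
    table = pd.DataFrame(rows).sort_values(
        ["r2", "channel"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    best = None
    for ch, m in fits.items():  # sorted insertion order → shortest wins ties
        if best is None or m.r2 > fits[best].r2:
            best = ch
    return fits[best], table


def estimate_tchla(f435, model: CalibrationModel):
    """Convert 435 nm fluorescence to TChla (µg/L) via the zero-intercept model.

    Accepts scalars or arrays; raw (unstandardized) fluorescence is expected.
    """
    f = np.asarray(f435, dtype=float)
    if (f < 0).any():
        raise ValueError("fluorescence must be non-negative")
    out = model.slope * f
    return float(out) if np.isscalar(f435) else out
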