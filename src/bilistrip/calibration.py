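"""Linear calibration of channel grayscale against concentration.

The calibration model is the two-parameter line

    Y_i = slope * c_i + intercept + e_i

fitted by ordinary least squares to one point per strip (the ROI-averaged
channel grayscale).  Linearity is scored by the coefficient of
determination in its regression-sum form,

    R^2 = sum_i (Yhat_i - Ybar)^2 / sum_i (Y_i - Ybar)^2,

which for OLS with intercept is algebraically identical to 1 - SSE/SST;
the package computes the regression-sum form directly so that identity is
a testable property rather than a definition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    SingularDesignError,
    UndefinedRSquaredError,
)

__all__ = [
    "CalibrationDataset",
    "CalibrationFit",
    "fit_line",
    "r_squared",
    "rank_channels",
    "CHANNELS",
]

#: Channel order used for tie-breaking and table layout.
CHANNELS = ("R", "G", "B")


@dataclass(frozen=True)
class CalibrationDataset:
    """Paired (concentration, per-channel mean grayscale) records.

    ``data`` is a DataFrame with a ``concentration_mg_dl`` column and one
    or more of ``mean_R``, ``mean_G``, ``mean_B`` (optionally ``sd_*`` and
    ``n_pixels`` carried through from ROI statistics).
    """

    data: pd.DataFrame
    light_source: str = ""

    def __post_init__(self):
        if "concentration_mg_dl" not in self.data.columns:
            raise ValueError("dataset requires a 'concentration_mg_dl' column")

    @property
    def concentrations(self) -> np.ndarray:
        return self.data["concentration_mg_dl"].to_numpy(dtype=float)

    def channel_means(self, channel: str) -> np.ndarray:
        col = f"mean_{channel}"
        if col not in self.data.columns:
            raise KeyError(f"dataset has no column {col!r}")
        return self.data[col].to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path, light_source: str = "") -> "CalibrationDataset":
        return cls(pd.read_csv(Path(path)), light_source=light_source)

    def to_csv(self, path) -> None:
        self.data.to_csv(Path(path), index=False)


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line, Eq.-style R-squared and residual scale for one channel."""

    channel: str
    slope: float          # grayscale counts per mg/dL
    intercept: float      # counts at c = 0
    r_squared: float
    residual_sd: float    # counts, sqrt(SSE / (n - 2))
    n: int
    light_source: str = ""


def _design_checks(c: np.ndarray, y: np.ndarray) -> None:
    if c.size < 3:
        raise InsufficientDataError(
            f"need at least 3 records to fit a calibration line, got {c.size}")
    if np.ptp(c) == 0:
        raise SingularDesignError("all concentrations are equal; slope not identifiable")
    if np.any(~np.isfinite(c)) or np.any(~np.isfinite(y)):
        raise ValueError("non-finite values in calibration data")


def _ols(c: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    cbar, ybar = c.mean(), y.mean()
    sxx = float(((c - cbar) ** 2).sum())
    slope = float(((c - cbar) * (y - ybar)).sum()) / sxx
    return slope, float(ybar - slope * cbar)


def _residual_sd(c: np.ndarray, y: np.ndarray, slope: float, intercept: float) -> float:
    # shared with bilistrip.limits.residual_sd
    resid = y - (slope * c + intercept)
    return float(np.sqrt((resid ** 2).sum() / (c.size - 2)))


def fit_line(ds: CalibrationDataset, channel: str) -> CalibrationFit:
    """Ordinary least-squares calibration line for one channel.

    Returns the fitted slope and intercept together with the
    regression-sum R-squared and the residual standard deviation
    sqrt(SSE / (n - 2)) used by the detection-limit convention.
    """
    c = ds.concentrations
    y = ds.channel_means(channel)
    _design_checks(c, y)
    slope, intercept = _ols(c, y)
    fit = CalibrationFit(channel=channel, slope=slope, intercept=intercept,
                         r_squared=float("nan"), residual_sd=float("nan"),
                         n=c.size, light_source=ds.light_source)
    return replace(fit,
                   r_squared=r_squared(fit, ds),
                   residual_sd=_residual_sd(c, y, slope, intercept))


def r_squared(fit: CalibrationFit, ds: CalibrationDataset) -> float:
    """Coefficient of determination, regression-sum over total-sum form."""
    c = ds.concentrations
    y = ds.channel_means(fit.channel)
    yhat = fit.slope * c + fit.intercept
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise UndefinedRSquaredError("all observations equal; R^2 undefined")
    return float(((yhat - y.mean()) ** 2).sum() / sst)


def rank_channels(fits) -> pd.DataFrame:
    """Rank channels by descending R-squared, per light source.

    ``fits`` is an iterable of :class:`CalibrationFit` (possibly covering
    several light sources).  Ties break by the fixed channel order R, G, B.
    Returns a long-form table with a ``rank`` column (1 = most linear).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("rank_channels requires at least one fit")
    df = pd.DataFrame(
        {
            "light_source": [f.light_source for f in fits],
            "channel": [f.channel for f in fits],
            "slope": [f.slope for f in fits],
            "intercept": [f.intercept for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "residual_sd": [f.residual_sd for f in fits],
            "n": [f.n for f in fits],
        }
    )
    df["_chan_order"] = df["channel"].map({ch: i for i, ch in enumerate(CHANNELS)})
    df = df.sort_values(["light_source", "r_squared", "_chan_order"],
                        ascending=[True, False, True], kind="mergesort")
    df["rank"] = df.groupby("light_source").cumcount() + 1
    return df.drop(columns="_chan_order").reset_index(drop=True)
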