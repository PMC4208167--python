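"""Grayscale-to-concentration calibration and inverse prediction.

Classical calibration: the band grayscale signal is regressed on the
standard concentrations (ordinary least squares, straight line over the
assay's working range, 6.25-50 mIU/mL for the hCG strips), and unknowns
are quantified by algebraic inversion of the fitted line.  Precision is
summarized per level as the coefficient of variation of the back-calculated
concentrations; accuracy as the percent error of their mean against the
nominal value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, InputError

__all__ = [
    "CalibrationModel",
    "CalibrationResults",
    "QuantResult",
    "fit_calibration",
]


@dataclass(frozen=True)
class QuantResult:
    """One inverse prediction, optionally with replicate-level precision."""

    estimated_concentration: float
    in_range: bool
    percent_error: float | None = None
    cv: float | None = None


class CalibrationModel:
    """Linear calibration of signal against concentration.

    Parameters
    ----------
    concentration, signal : array-like
        Replicate standard measurements; at least two distinct
        concentrations are required.
    replicate_id : array-like, optional
        Replicate labels (only used for bookkeeping in reports).
    polarity : "net" or "raw"
        Which signal convention the data carry; with "net"
        (background-corrected) signals increase with concentration, with
        "raw" the line grayscale decreases.
    log_concentration : bool
        Fit signal against log10(concentration) instead (off by default;
        the working range here is well described by a straight line).
    """

    def __init__(
        self,
        concentration,
        signal,
        replicate_id=None,
        polarity: str = "net",
        log_concentration: bool = False,
    ):
        conc = np.asarray(concentration, dtype=float)
        sig = np.asarray(signal, dtype=float)
        if conc.ndim != 1 or conc.shape != sig.shape:
            raise InputError("concentration and signal must be 1-D of equal length")
        if conc.size < 2 or np.unique(conc).size < 2:
            raise DegenerateDataError("need at least two distinct concentrations")
        if (conc <= 0).any() and log_concentration:
            raise InputError("log-concentration fit requires positive concentrations")
        if (conc < 0).any():
            raise InputError("concentrations must be non-negative")
        if polarity not in ("net", "raw"):
            raise InputError(f"unknown polarity {polarity!r}")
        self.concentration = conc
        self.signal = sig
        self.replicate_id = (
            np.asarray(replicate_id) if replicate_id is not None else None
        )
        self.polarity = polarity
        self.log_concentration = log_concentration

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CalibrationModel":
        """Build from the calibration-CSV layout
        (columns concentration, signal, optional replicate_id)."""
        missing = {"concentration", "signal"} - set(df.columns)
        if missing:
            raise InputError(f"calibration table missing columns: {sorted(missing)}")
        rep = df["replicate_id"] if "replicate_id" in df.columns else None
        return cls(df["concentration"], df["signal"], rep, **kwargs)

    def _x(self) -> np.ndarray:
        return np.log10(self.concentration) if self.log_concentration else self.concentration

    def fit(self) -> "CalibrationResults":
        """Ordinary least squares of signal on concentration."""
        x = self._x()
        res = stats.linregress(x, self.signal)
        if res.slope == 0 or not math.isfinite(res.slope):
            raise DegenerateDataError(
                "flat calibration (zero slope): signal does not respond to concentration"
            )
        fitted = res.intercept + res.slope * x
        ss_res = float(((self.signal - fitted) ** 2).sum())
        n = x.size
        residual_sd = math.sqrt(ss_res / (n - 2)) if n > 2 else 0.0
        return CalibrationResults(
            model=self,
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue**2),
            residual_sd=residual_sd,
            conc_range=(float(self.concentration.min()), float(self.concentration.max())),
            n_points=int(n),
        )


class CalibrationResults:
    """Fitted calibration line with inverse prediction and precision profile."""

    def __init__(self, model, slope, intercept, r_squared, residual_sd, conc_range,
                 n_points, polarity=None, log_concentration=None):
        self.model = model
        self.slope = slope
        self.intercept = intercept
        self.r_squared = r_squared
        self.residual_sd = residual_sd
        self.conc_range = tuple(conc_range)
        self.n_points = n_points
        self.polarity = polarity if polarity is not None else model.polarity
        self.log_concentration = (
            log_concentration if log_concentration is not None else model.log_concentration
        )

    # -- forward and inverse ------------------------------------------------

    def predict(self, concentration) -> np.ndarray:
        c = np.asarray(concentration, dtype=float)
        x = np.log10(c) if self.log_concentration else c
        return self.intercept + self.slope * x

    def invert(self, signal: float, nominal: float | None = None) -> QuantResult:
        """Back-calculate concentration from a measured signal.

        Readings outside the fitted concentration range are flagged
        (``in_range=False``) rather than refused; extrapolated values should
        not be reported quantitatively.
        """
        if self.slope == 0:
            raise DegenerateDataError("zero-slope model is not invertible")
        x = (float(signal) - self.intercept) / self.slope
        conc = float(10.0**x) if self.log_concentration else float(x)
        lo, hi = self.conc_range
        in_range = lo <= conc <= hi
        pe = None
        if nominal is not None:
            if nominal <= 0:
                raise InputError("nominal concentration must be positive")
            pe = 100.0 * abs(conc - nominal) / nominal
        return QuantResult(estimated_concentration=conc, in_range=in_range, percent_error=pe)

    def precision_profile(self, points: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-level precision of back-calculated concentrations.

        For each nominal level: n replicates, mean estimate, CV (%) of the
        estimates (sd/mean, n-1 divisor; NaN and flagged for a single
        replicate) and percent error of the mean against nominal.
        """
        if points is None:
            if self.model is None:
                raise InputError(
                    "a loaded model carries no replicate data; pass a points table"
                )
            points = pd.DataFrame(
                {"concentration": self.model.concentration, "signal": self.model.signal}
            )
        rows = []
        for nominal, grp in points.groupby("concentration", sort=True):
            est = np.array(
                [self.invert(s).estimated_concentration for s in grp["signal"]]
            )
            mean = est.mean()
            if est.size >= 2:
                cv = 100.0 * est.std(ddof=1) / mean if mean != 0 else math.inf
                single = False
            else:
                cv = math.nan
                single = True
            rows.append(
                {
                    "concentration": float(nominal),
                    "n": int(est.size),
                    "mean_estimate": float(mean),
                    "cv": float(cv),
                    "percent_error": 100.0 * abs(mean - nominal) / nominal
                    if nominal > 0
                    else math.nan,
                    "single_replicate": single,
                }
            )
        return pd.DataFrame(rows)

    # -- persistence and reporting ------------------------------------------

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "conc_range": list(self.conc_range),
            "n_points": self.n_points,
            "polarity": self.polarity,
            "log_concentration": self.log_concentration,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResults":
        return cls(
            model=None,
            slope=d["slope"],
            intercept=d["intercept"],
            r_squared=d["r_squared"],
            residual_sd=d["residual_sd"],
            conc_range=tuple(d["conc_range"]),
            n_points=d["n_points"],
            polarity=d.get("polarity", "net"),
            log_concentration=d.get("log_concentration", False),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationResults":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def summary(self) -> str:
        lo, hi = self.conc_range
        lines = [
            "Linear calibration (signal ~ concentration)",
            f"  slope:       {self.slope:.6g} grayscale per mIU/mL",
            f"  intercept:   {self.intercept:.6g} grayscale",
            f"  R^2:         {self.r_squared:.4f}",
            f"  residual sd: {self.residual_sd:.4g} grayscale",
            f"  range:       {lo:g}-{hi:g} mIU/mL ({self.n_points} points, "
            f"{self.polarity} polarity)",
        ]
        return "\n".join(lines)


def fit_calibration(points: pd.DataFrame, **kwargs) -> CalibrationResults:
    """Convenience wrapper: fit the calibration line from a points table."""
    return CalibrationModel.from_dataframe(points, **kwargs).fit()
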