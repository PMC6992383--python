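"""Line-scan intensity statistics: ensemble mean profiles with confidence
bands, integrated intensity (AUC), and intensity-versus-length regression."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import IntensityProfile, ParameterError
from .results import FitResult

__all__ = [
    "ProfileEnsemble",
    "mean_profile_with_ci",
    "integrated_intensity",
    "intensity_vs_length_regression",
]


@dataclass
class ProfileEnsemble:
    """Pointwise mean (and 95% CI) of profiles resampled to a common axis.

    ``position`` is the normalised position in [0, 1] (0 = profile origin).
    CI arrays are None for a single-profile ensemble.
    """

    position: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    n: int

    def to_frame(self) -> pd.DataFrame:
        d = {"position": self.position, "mean": self.mean}
        if self.ci_low is not None:
            d["ci_low"] = self.ci_low
            d["ci_high"] = self.ci_high
        return pd.DataFrame(d)


def mean_profile_with_ci(
    profiles: Sequence[IntensityProfile], n_points: int = 200
) -> ProfileEnsemble:
    """Ensemble mean profile with pointwise t-based 95% CI.

    Each profile is linearly resampled onto ``n_points`` normalised
    positions x/x_max ∈ [0, 1] so that flagella of different lengths can be
    averaged.  With a single profile only the mean is reported.
    """
    if len(profiles) < 1:
        raise ParameterError("need at least one profile")
    grid = np.linspace(0.0, 1.0, n_points)
    resampled = []
    for p in profiles:
        if p.x.size < 2:
            raise ParameterError("profiles need at least 2 points")
        span = p.x[-1] - p.x[0]
        if span <= 0:
            raise ParameterError("degenerate profile axis")
        resampled.append(np.interp(grid, (p.x - p.x[0]) / span, p.intensity))
    arr = np.asarray(resampled)
    mean = arr.mean(axis=0)
    n = arr.shape[0]
    if n == 1:
        return ProfileEnsemble(grid, mean, None, None, n=1)
    half = stats.t.ppf(0.975, n - 1) * arr.std(axis=0, ddof=1) / np.sqrt(n)
    return ProfileEnsemble(grid, mean, mean - half, mean + half, n=n)


def integrated_intensity(profile: IntensityProfile) -> float:
    """Total area under the curve (trapezoidal), a.u.·µm."""
    if profile.x.size < 2:
        raise ParameterError("profile needs at least 2 points")
    return float(np.trapezoid(profile.intensity, profile.x))


def intensity_vs_length_regression(points: pd.DataFrame) -> FitResult:
    """OLS of total integrated intensity (AUC) against flagellar length.

    ``points`` must carry columns ``length`` (µm) and ``auc``; fit one
    condition at a time (e.g. DMSO and Taxol separately) for per-condition
    slopes.  Returns slope, intercept and R² with 95% CIs.
    """
    if len(points) < 3:
        raise ParameterError("need at least 3 points")
    x = np.asarray(points["length"], dtype=float)
    y = np.asarray(points["auc"], dtype=float)
    if np.ptp(x) == 0:
        raise ParameterError("degenerate regressor: all lengths equal")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return FitResult(
        {"slope": res.params[1], "intercept": res.params[0],
         "r_squared": res.rsquared},
        {"slope": tuple(ci[1]), "intercept": tuple(ci[0]),
         "r_squared": (np.nan, np.nan)},
        rss=float(res.ssr), converged=True, nobs=int(res.nobs),
        model="intensity-vs-length",
    )
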