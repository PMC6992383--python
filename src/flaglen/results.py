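"""Lightweight results container shared by all fitted models."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["FitResult"]


class FitResult:
    """Point estimates with 95% confidence intervals and fit diagnostics.

    Attributes
    ----------
    params : pd.Series
        Point estimates, indexed by parameter name.
    conf_int : pd.DataFrame
        Columns ``lower`` and ``upper`` (95% unless stated otherwise).
    rss : float
        Residual sum of squares of the fit.
    converged : bool
        False flags an unreliable (degenerate or non-converged) fit.
    nobs : int
        Number of observations used.
    window : tuple or None
        The data window the fit was restricted to, if any.
    extra : dict
        Model-specific diagnostics (e.g. histogram-fit estimates).
    """

    def __init__(
        self,
        params: Mapping[str, float],
        conf_int: Mapping[str, tuple] | None = None,
        *,
        rss: float = np.nan,
        converged: bool = True,
        nobs: int = 0,
        window=None,
        model: str = "",
        extra: dict | None = None,
    ):
        self.params = pd.Series(dict(params), dtype=float)
        if conf_int is None:
            ci = pd.DataFrame(
                np.nan, index=self.params.index, columns=["lower", "upper"]
            )
        else:
            ci = pd.DataFrame.from_dict(
                {k: list(v) for k, v in conf_int.items()},
                orient="index",
                columns=["lower", "upper"],
            ).reindex(self.params.index)
        self.conf_int = ci
        self.rss = float(rss)
        self.converged = bool(converged)
        self.nobs = int(nobs)
        self.window = window
        self.model = model
        self.extra = extra or {}

    def __getitem__(self, name: str) -> float:
        return float(self.params[name])

    def summary(self) -> str:
        lines = [
            f"{self.model or 'Fit'} results",
            "=" * 46,
            f"{'parameter':<16}{'estimate':>10}{'[0.025':>10}{'0.975]':>10}",
            "-" * 46,
        ]
        for name, est in self.params.items():
            lo, hi = self.conf_int.loc[name]
            lines.append(f"{name:<16}{est:>10.4g}{lo:>10.4g}{hi:>10.4g}")
        lines.append("-" * 46)
        lines.append(f"nobs = {self.nobs}   RSS = {self.rss:.4g}   "
                     f"converged = {self.converged}")
        if self.window is not None:
            lines.append(f"fit window = {self.window}")
        for k, v in self.extra.items():
            lines.append(f"{k} = {v}")
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover - cosmetic
        pairs = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"<FitResult {self.model}: {pairs}, converged={self.converged}>"

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params.to_dict(),
            "conf_int": {k: list(self.conf_int.loc[k]) for k in self.params.index},
            "rss": self.rss,
            "converged": self.converged,
            "nobs": self.nobs,
            "window": self.window,
            **{f"extra_{k}": v for k, v in self.extra.items()},
        }
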