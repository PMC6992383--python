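"""Balance-point flagellar length control with length-dependent disassembly.

The flagellar length L obeys

    dL/dt = I·(N − L) − k⁻·c(L),

where I·(N − L) is IFT-mediated assembly from a depleting precursor pool
(N µm of assemblable material, I the injection-flux coupling) and
k⁻·c(L) is tip disassembly proportional to the kinesin-13 tip
concentration c(L) from the finite-reservoir transport model.  Assembly
decreases linearly with length while disassembly increases with length, so
the rates balance at a unique stable steady state L* = N − k⁻·c(L*)/I:
longer flagella carry less kinesin-13 at their tips.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .datatypes import LengthControlParams, LengthTrajectory, ParameterError
from .transport import tip_concentration

__all__ = [
    "LengthControlModel",
    "assembly_rate",
    "disassembly_rate",
    "dLdt",
    "steady_state_length",
    "integrate_length",
    "balance_curves",
]


class LengthControlModel:
    """Deterministic balance-point model for one flagellum."""

    def __init__(self, params: LengthControlParams):
        self.params = params

    def assembly_rate(self, L: float) -> float:
        """k⁺ = I·(N − L), µm/s; negative (pool overdrawn) if L > N."""
        if L < 0:
            raise ParameterError("L must be >= 0")
        rate = self.params.inj_flux * (self.params.pool - L)
        if rate < 0:
            warnings.warn("L exceeds the precursor pool N; assembly rate is "
                          "negative", RuntimeWarning)
        return rate

    def disassembly_rate(self, L: float) -> float:
        """k⁻·c(L), µm/s; strictly increasing in L."""
        if L < 0:
            raise ParameterError("L must be >= 0")
        return self.params.k_minus * tip_concentration(L, self.params.transport)

    def dLdt(self, L: float) -> float:
        """Net elongation rate I·(N − L) − k⁻·c(L)."""
        return (self.params.inj_flux * (self.params.pool - L)
                - self.params.k_minus
                * tip_concentration(L, self.params.transport))

    def steady_state_length(
        self, bracket: tuple[float, float] | None = None
    ) -> tuple[float, bool]:
        """Balance point L* where assembly equals disassembly.

        Root of dL/dt on the bracket (default [0, N]) by bracketing
        bisection (Brent), resolved to 1e-8 µm.  Returns (L*, stable);
        stability is d(dL/dt)/dL < 0 at L*, by central difference.
        """
        if bracket is None:
            bracket = (0.0, self.params.pool)
        a, b = bracket
        fa, fb = self.dLdt(a), self.dLdt(b)
        if fa == 0.0:
            root = a
        elif fb == 0.0:
            root = b
        elif fa * fb > 0:
            raise ParameterError("dL/dt does not change sign on the bracket")
        else:
            root = brentq(self.dLdt, a, b, xtol=1e-8)
        h = max(1e-6, 1e-6 * max(root, 1.0))
        lo = max(root - h, 0.0)
        deriv = (self.dLdt(root + h) - self.dLdt(lo)) / (root + h - lo)
        return float(root), bool(deriv < 0)

    def integrate_length(
        self, L0: float, t_max: float, dt: float
    ) -> LengthTrajectory:
        """Integrate dL/dt from L0 with adaptive Runge-Kutta (atol 1e-8 µm).

        The trajectory approaches L* monotonically from either side and is
        clamped non-negative (disassembly cannot act on a zero-length
        flagellum).
        """
        if L0 < 0:
            raise ParameterError("L0 must be >= 0")
        if t_max <= 0 or dt <= 0:
            raise ParameterError("t_max and dt must be > 0")

        def rhs(t, y):
            L = y[0]
            r = self.dLdt(max(L, 0.0))
            if L <= 0.0 and r < 0.0:
                return [0.0]
            return [r]

        t_eval = np.arange(0.0, t_max + 0.5 * dt, dt)
        sol = solve_ivp(rhs, (0.0, t_eval[-1]), [L0], method="RK45",
                        t_eval=t_eval, atol=1e-8, rtol=1e-8)
        if not sol.success:
            raise RuntimeError(f"length integration failed: {sol.message}")
        return LengthTrajectory(time=sol.t,
                                length=np.maximum(sol.y[0], 0.0))

    def balance_curves(self, L_grid) -> pd.DataFrame:
        """Assembly and disassembly rate curves on a length grid.

        Crossings of the two curves are the steady states returned by
        :meth:`steady_state_length`.
        """
        L_grid = np.asarray(L_grid, dtype=float)
        if np.any(np.diff(L_grid) <= 0):
            raise ParameterError("L_grid must be strictly increasing")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            assembly = np.array([self.assembly_rate(L) for L in L_grid])
        disassembly = np.array([self.disassembly_rate(L) for L in L_grid])
        return pd.DataFrame({
            "length": L_grid,
            "assembly": assembly,
            "disassembly": disassembly,
        })


# ---- operation-level wrappers ------------------------------------------


def assembly_rate(L: float, params: LengthControlParams) -> float:
    return LengthControlModel(params).assembly_rate(L)


def disassembly_rate(L: float, params: LengthControlParams) -> float:
    return LengthControlModel(params).disassembly_rate(L)


def dLdt(L: float, params: LengthControlParams) -> float:
    return LengthControlModel(params).dLdt(L)


def steady_state_length(params: LengthControlParams,
                        bracket=None) -> tuple[float, bool]:
    return LengthControlModel(params).steady_state_length(bracket)


def integrate_length(params: LengthControlParams, L0: float, t_max: float,
                     dt: float) -> LengthTrajectory:
    return LengthControlModel(params).integrate_length(L0, t_max, dt)


def balance_curves(params: LengthControlParams, L_grid) -> pd.DataFrame:
    return LengthControlModel(params).balance_curves(L_grid)
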