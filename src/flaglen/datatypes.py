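"""Core containers shared across the analysis stages.

Conventions used throughout the package:

* lengths and positions in micrometres (µm), times in seconds,
  diffusion constants in µm²/s, intensities in arbitrary camera units (a.u.);
* kymographs are oriented rows = time (row 0 = t = 0) and
  columns = position from the flagellar base (column 0 = flagellar pore);
* anterograde means position increasing with time (base → tip).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

FLAGELLAR_PAIRS = ("anterior", "caudal", "posteriolateral", "ventral")

__all__ = [
    "FLAGELLAR_PAIRS",
    "FlagellarGeometry",
    "TrainEvent",
    "Kymograph",
    "FrapTrace",
    "FrapModelParams",
    "IntensityProfile",
    "TransportParams",
    "LengthControlParams",
    "LengthTrajectory",
    "ParameterError",
    "ConfigurationError",
    "CorrectionError",
]


class ParameterError(ValueError):
    """A numeric parameter is outside its admissible range."""


class ConfigurationError(KeyError):
    """A scenario configuration is missing required entries."""


class CorrectionError(ValueError):
    """A FRAP correction cannot be applied (e.g. reference at/below background)."""


@dataclass(frozen=True)
class FlagellarGeometry:
    """Per-flagellum geometry: one of the four *Giardia* pairs.

    ``membrane_length`` runs from the flagellar pore to the tip;
    ``cytoplasmic_length`` from the basal body to the pore; their sum is
    the total axoneme length. ``radius`` is the flagellar cross-section
    radius R, which also sets the kinesin-13 decay length λ = R.
    """

    pair: str
    membrane_length: float
    cytoplasmic_length: float
    radius: float = 0.25

    def __post_init__(self):
        if self.pair not in FLAGELLAR_PAIRS:
            raise ConfigurationError(f"unknown flagellar pair {self.pair!r}")
        if self.membrane_length <= 0 or self.cytoplasmic_length <= 0:
            raise ParameterError("lengths must be positive")
        if not 0 < self.radius < 1:
            raise ParameterError("radius must lie in (0, 1) µm")

    @property
    def total_length(self) -> float:
        return self.membrane_length + self.cytoplasmic_length


@dataclass(frozen=True)
class TrainEvent:
    """A single IFT train injection event."""

    injection_time: float
    direction: str = "anterograde"
    speed: float = 3.1
    intensity: float = 100.0

    def __post_init__(self):
        if self.injection_time < 0:
            raise ParameterError("injection_time must be >= 0")
        if self.speed <= 0:
            raise ParameterError("speed must be > 0")
        if self.direction not in ("anterograde", "retrograde"):
            raise ParameterError(f"unknown direction {self.direction!r}")


@dataclass
class Kymograph:
    """Position × time intensity grid.

    ``grid[i, j]`` is the intensity at time ``i * frame_interval`` and
    position ``j * pixel_size`` from the flagellar base.
    """

    grid: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ParameterError("kymograph grid must be 2-D")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ParameterError("calibrations must be positive")

    @property
    def n_frames(self) -> int:
        return self.grid.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.grid.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def length(self) -> float:
        return self.n_pixels * self.pixel_size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.n_pixels) * self.pixel_size


@dataclass
class FrapTrace:
    """A background-corrected photobleaching recovery time series.

    ``time`` has t = 0 at the bleach event; negative times, when present,
    are prebleach samples. ``strip_width`` is the bleached strip width ω.
    """

    time: np.ndarray
    intensity: np.ndarray
    region_label: str = ""
    strip_width: float = 2.0
    prebleach_intensity: float = 1.0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ParameterError("time and intensity must have the same shape")
        if np.any(np.diff(self.time) <= 0):
            raise ParameterError("time must be strictly increasing")
        if self.strip_width <= 0:
            raise ParameterError("strip_width must be > 0")

    def postbleach(self) -> "FrapTrace":
        """Restrict to t >= 0."""
        m = self.time >= 0
        return replace(self, time=self.time[m], intensity=self.intensity[m])


@dataclass(frozen=True)
class FrapModelParams:
    """Parameters of the strip-bleach recovery models.

    D          effective diffusion constant (µm²/s)
    I0         final recovered intensity (a.u.)
    omega      bleach strip width ω (µm)
    flux_coefficient   λ0·C0, the relative membrane-vs-cytoplasmic integrated
                       intensity entering the retrograde-flux term (dimensionless)
    retro_speed        speed v of retrograde IFT (µm/s)
    f_mobile   mobile fraction in [0, 1]
    """

    D: float
    I0: float = 1.0
    omega: float = 2.0
    flux_coefficient: float = 0.0
    retro_speed: float = 3.2
    f_mobile: float = 1.0

    def __post_init__(self):
        if self.D < 0:
            raise ParameterError("D must be >= 0")
        if self.omega <= 0:
            raise ParameterError("omega must be > 0")
        if not 0 <= self.f_mobile <= 1:
            raise ParameterError("f_mobile must lie in [0, 1]")
        if self.flux_coefficient < 0:
            raise ParameterError("flux_coefficient must be >= 0")


@dataclass
class IntensityProfile:
    """A 1-D fluorescence line scan.

    ``x`` is the distance (µm) from the stated ``origin`` — either the
    flagellar ``"tip"`` or the ``"base"`` (flagellar pore).
    """

    x: np.ndarray
    intensity: np.ndarray
    origin: str = "tip"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.x.shape != self.intensity.shape:
            raise ParameterError("x and intensity must have the same shape")
        if self.x.size and (self.x[0] < 0 or np.any(np.diff(self.x) <= 0)):
            raise ParameterError("x must be non-negative and strictly increasing")
        if self.origin not in ("tip", "base"):
            raise ParameterError("origin must be 'tip' or 'base'")


@dataclass(frozen=True)
class TransportParams:
    """Constants of the kinesin-13 diffusion-plus-capture transport model.

    D_k13   diffusion constant of free kinesin-13 in the flagellum (µm²/s)
    k_on    first-order capture rate by anterograde IFT trains (1/s)
    lambda_ decay length λ = sqrt(D_k13/k_on) of the tip gradient (µm)
    R       flagellar cross-section radius (µm); with k_on = D/R², λ = R
    c0      kinesin-13 concentration at the flagellar pore (a.u.)
    c_init  initial reservoir concentration before ciliogenesis (a.u.)
    v       ratio of the volume of a λ-long stretch of flagellum to the
            reservoir volume (dimensionless); 1/v is the tip enhancement factor
    """

    D_k13: float = 0.018
    k_on: float = None  # type: ignore[assignment]
    lambda_: float = None  # type: ignore[assignment]
    R: float = 0.25
    c0: float = 1.0
    c_init: float = 1e-3
    v: float = 1e-3

    def __post_init__(self):
        if self.D_k13 <= 0 or self.R <= 0 or self.c0 <= 0 or self.c_init <= 0 or self.v <= 0:
            raise ParameterError("transport parameters must be positive")
        k_on, lam = self.k_on, self.lambda_
        if k_on is None and lam is None:
            # diffusion-to-capture estimate: k_on = D/R², hence λ = R
            k_on = self.D_k13 / self.R**2
            lam = self.R
        elif k_on is None:
            if lam <= 0:
                raise ParameterError("lambda_ must be > 0")
            k_on = self.D_k13 / lam**2
        elif lam is None:
            if k_on <= 0:
                raise ParameterError("k_on must be > 0")
            lam = float(np.sqrt(self.D_k13 / k_on))
        else:
            if not np.isclose(lam, np.sqrt(self.D_k13 / k_on), rtol=1e-6):
                raise ParameterError("lambda_ inconsistent with sqrt(D_k13/k_on)")
        object.__setattr__(self, "k_on", float(k_on))
        object.__setattr__(self, "lambda_", float(lam))


@dataclass(frozen=True)
class LengthControlParams:
    """Constants of the balance-point length equation dL/dt = I(N−L) − k⁻c(L).

    inj_flux  I — assembly coupling, 1/s per unit of free precursor
    pool      N — total precursor expressed as assemblable length (µm)
    k_minus   k⁻ — disassembly constant; k⁻·c has units µm/s (the
              depolymerisation step size is absorbed, conversion constant 1)
    transport supplies the tip concentration c(L)
    """

    inj_flux: float
    pool: float
    k_minus: float
    transport: TransportParams = field(default_factory=TransportParams)

    def __post_init__(self):
        if self.inj_flux < 0 or self.pool < 0 or self.k_minus < 0:
            raise ParameterError("I, N, k⁻ must be >= 0")


@dataclass
class LengthTrajectory:
    """Flagellar length as a function of time."""

    time: np.ndarray
    length: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        if self.time.shape != self.length.shape:
            raise ParameterError("time and length must have the same shape")
        if np.any(self.length < -1e-12):
            raise ParameterError("length must be non-negative")


def events_sorted(events: Sequence[TrainEvent]) -> list[TrainEvent]:
    return sorted(events, key=lambda e: e.injection_time)
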