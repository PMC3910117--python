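"""Damped-sinusoid-plus-trend model for time-course expression profiles.

The core model for a single gene's expression trajectory is

    x(t) = exp(alpha * t) * [a * cos(omega * t) + b * sin(omega * t)] + c * t + d

sampled at equally spaced times t_i = i * delta, i = 1..m.  The oscillatory
part describes periodic transcription (e.g. cell-cycle regulation), the
exponential envelope its decay (alpha < 0) or growth (alpha > 0) as a
synchronized population dephases, and c*t + d a slow drift plus baseline.

The noise-free trajectory solves the second-order linear ODE

    x''(t) + A x'(t) + B x(t) = C t + D

whenever the characteristic roots are complex, i.e. 4B - A^2 > 0.  The
coefficient maps between the two parameterizations live here; they are the
bridge that turns the nonlinear fitting problem into two linear regressions
(see :mod:`cyclefit.estimation`).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np

__all__ = [
    "ModelParams",
    "OdeParams",
    "Profile",
    "DegenerateModelError",
    "time_grid",
    "evaluate_model",
    "ode_to_model",
    "model_to_ode",
]


class DegenerateModelError(ValueError):
    """The ODE coefficients admit no damped-oscillation solution.

    Raised when the discriminant 4B - A^2 is non-positive (real
    characteristic roots: no oscillation) or when B = 0 (the trend
    coefficients c and d are undefined).  Batch pipelines catch this and
    mark the profile degenerate instead of aborting.
    """

    def __init__(self, reason: str, ode: "OdeParams | None" = None):
        super().__init__(reason)
        self.reason = reason
        self.ode = ode


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """The six coefficients of the damped-sinusoid-plus-trend model.

    Attributes
    ----------
    alpha : float
        Degradation (alpha < 0) or growth rate of the oscillation envelope,
        per unit time.
    omega : float
        Angular frequency of the oscillation in radians per unit time;
        always the positive root.
    a, b : float
        Cosine and sine coefficients, in expression units.
    c : float
        Linear-trend slope, expression units per unit time.
    d : float
        Intercept, expression units.
    """

    alpha: float
    omega: float
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("alpha", "omega", "a", "b", "c", "d"):
            _require_finite(name, getattr(self, name))
        if self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega!r}")

    @property
    def amplitude(self) -> float:
        """Oscillation magnitude sqrt(a^2 + b^2)."""
        return math.hypot(self.a, self.b)

    @property
    def phase(self) -> float:
        """Phase of the equivalent A*sin(omega*t + phase) form, atan2(a, b)."""
        return math.atan2(self.a, self.b)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.omega, self.a, self.b, self.c, self.d], dtype=float
        )


@dataclasses.dataclass(frozen=True)
class OdeParams:
    """Constant coefficients (A, B, C, D) of x'' + A x' + B x = C t + D."""

    A: float
    B: float
    C: float
    D: float

    def __post_init__(self) -> None:
        for name in ("A", "B", "C", "D"):
            _require_finite(name, getattr(self, name))

    @property
    def discriminant(self) -> float:
        """4B - A^2; oscillatory solutions require this to be positive."""
        return 4.0 * self.B - self.A * self.A

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D], dtype=float)


@dataclasses.dataclass(frozen=True)
class Profile:
    """One gene's time series: identifier, m measurements, sampling interval.

    Sample i (1-based) is taken at time t_i = i * delta.  Profiles with
    missing values are excluded upstream (see :mod:`cyclefit.io`); all
    values here must be finite.
    """

    gene_id: str
    values: np.ndarray
    delta: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError(
                f"profile {self.gene_id!r} contains non-finite values"
            )
        if not (math.isfinite(self.delta) and self.delta > 0):
            raise ValueError(f"delta must be positive, got {self.delta!r}")
        object.__setattr__(self, "values", values)

    @property
    def m(self) -> int:
        """Number of time points."""
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sampling times t_i = i * delta, i = 1..m."""
        return time_grid(self.m, self.delta)


def time_grid(m: int, delta: float = 1.0) -> np.ndarray:
    """Return the sampling times t_i = i * delta for i = 1..m."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    return delta * np.arange(1, m + 1, dtype=float)


def evaluate_model(params: ModelParams, m: int, delta: float = 1.0) -> np.ndarray:
    """Evaluate the noise-free model on the grid t_i = i * delta, i = 1..m."""
    t = time_grid(m, delta)
    return (
        np.exp(params.alpha * t)
        * (params.a * np.cos(params.omega * t) + params.b * np.sin(params.omega * t))
        + params.c * t
        + params.d
    )


def ode_to_model(ode: OdeParams) -> tuple[float, float, float, float]:
    """Map ODE coefficients to model parameters (alpha, omega, c, d).

        alpha = -A / 2
        omega = sqrt(4B - A^2) / 2      (positive root)
        c     = C / B
        d     = D / B - A C / B^2

    The oscillation coefficients a and b are independent of (A, B, C, D)
    and are estimated separately.

    Raises
    ------
    DegenerateModelError
        If 4B - A^2 <= 0 (no oscillatory solution) or B = 0 (trend
        undefined).  Such profiles are judged not describable by the model.
    """
    disc = ode.discriminant
    if disc <= 0:
        raise DegenerateModelError(
            f"discriminant 4B - A^2 = {disc:.6g} <= 0: no oscillatory solution",
            ode,
        )
    if ode.B == 0:
        raise DegenerateModelError("B = 0: trend coefficients undefined", ode)
    alpha = -ode.A / 2.0
    omega = math.sqrt(disc) / 2.0
    c = ode.C / ode.B
    d = ode.D / ode.B - ode.A * ode.C / (ode.B * ode.B)
    return alpha, omega, c, d


def model_to_ode(alpha: float, omega: float, c: float, d: float) -> OdeParams:
    """Algebraic inverse of :func:`ode_to_model` (requires omega > 0)."""
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega!r}")
    A = -2.0 * alpha
    B = alpha * alpha + omega * omega
    C = c * B
    D = d * B - 2.0 * alpha * c
    return OdeParams(A, B, C, D)


def profiles_matrix(profiles: Iterable[Profile]) -> tuple[np.ndarray, float]:
    """Stack profiles into an (n, m) matrix, checking equal m and delta.

    Returns the matrix and the shared sampling interval.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    m = profiles[0].m
    delta = profiles[0].delta
    for p in profiles:
        if p.m != m:
            raise ValueError(
                f"profiles have mixed lengths ({p.gene_id!r}: {p.m} != {m})"
            )
        if p.delta != delta:
            raise ValueError(
                f"profiles have mixed sampling intervals ({p.gene_id!r})"
            )
    return np.vstack([p.values for p in profiles]), delta
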