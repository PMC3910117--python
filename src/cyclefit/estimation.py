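"""Two-step linear-least-squares estimation of the damped-sinusoid model.

Estimating (alpha, omega, a, b, c, d) directly is a nonlinear least-squares
problem; iterative solvers are sensitive to starting values and can stall in
local minima.  The estimator here avoids iteration entirely:

Step 1
    Approximate x'(t) and x''(t) at the interior time points by central
    second-order finite differences, then regress x'' on [-x', -x, t, 1] to
    obtain the ODE coefficients (A, B, C, D).  The map of
    :func:`cyclefit.model.ode_to_model` then yields alpha, omega, c, d.

Step 2
    De-trend and de-damp the profile, z(t) = exp(-alpha t) (x(t) - c t - d),
    and regress z on [cos(omega t), sin(omega t)] to obtain a and b.

Both regressions are ordinary linear least squares, solved by a stable
factorization (numpy ``lstsq``) rather than explicit normal-equation
inversion.  The price of linearity is a finite-difference bias of order
delta^2 in Step 1; the residual S1^2 of the assembled fit is therefore an
approximation to — not exactly — the global least-squares optimum.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .model import (
    DegenerateModelError,
    ModelParams,
    OdeParams,
    Profile,
    evaluate_model,
    ode_to_model,
)

__all__ = [
    "FitResult",
    "TooShortProfileError",
    "RankDeficiencyError",
    "SingularityError",
    "finite_first_derivative",
    "finite_second_derivative",
    "estimate_ode_params",
    "estimate_sinusoid_coeffs",
    "fit_profile",
]

#: Minimum profile length for fitting: the Step-1 regression needs
#: l = m - 2 >= 4 rows and the F-test needs m - 6 >= 2 denominator d.f.
MIN_PROFILE_LENGTH = 8

#: Relative condition-number threshold beyond which a design matrix is
#: treated as rank deficient.
COND_THRESHOLD = 1e12

#: Profile length from which the "auto" stencil switches to the five-point
#: fourth-order formulas (they consume two interior points more).
CENTRAL4_MIN_LENGTH = 12


class TooShortProfileError(ValueError):
    """Profile has fewer time points than the operation requires."""


class RankDeficiencyError(np.linalg.LinAlgError):
    """Step-1 design matrix is numerically rank deficient."""


class SingularityError(np.linalg.LinAlgError):
    """Step-2 sinusoid design is numerically singular (pathological omega)."""


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Outcome of fitting the full model to one profile.

    ``degenerate`` profiles — those whose Step-1 estimate gives
    4B - A^2 <= 0 or B = 0 — carry no parameters, fitted values, or
    residual; they are judged not describable by the model and are handled
    (not re-raised) by downstream significance and clustering code.
    """

    gene_id: str
    degenerate: bool
    params: ModelParams | None = None
    ode: OdeParams | None = None
    s1_sq: float | None = None
    fitted: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.degenerate and self.params is not None:
            raise ValueError("degenerate fits carry no parameters")
        if self.s1_sq is not None and self.s1_sq < 0:
            raise ValueError("residual sum of squares must be nonnegative")


def _check_length(profile: Profile, minimum: int) -> None:
    if profile.m < minimum:
        raise TooShortProfileError(
            f"profile {profile.gene_id!r} has m={profile.m} < {minimum} time points"
        )


def finite_first_derivative(profile: Profile) -> np.ndarray:
    """Central-difference first derivative at interior points t_2..t_{m-1}.

    x'(t_i) ~= [x(t_{i+1}) - x(t_{i-1})] / (2 delta); exact for quadratics,
    error O(delta^2) otherwise.  Output length m - 2.
    """
    _check_length(profile, 3)
    x = profile.values
    return (x[2:] - x[:-2]) / (2.0 * profile.delta)


def finite_second_derivative(profile: Profile) -> np.ndarray:
    """Central-difference second derivative at interior points t_2..t_{m-1}.

    x''(t_i) ~= [x(t_{i+1}) + x(t_{i-1}) - 2 x(t_i)] / delta^2; output
    length m - 2.
    """
    _check_length(profile, 3)
    x = profile.values
    return (x[2:] + x[:-2] - 2.0 * x[1:-1]) / (profile.delta**2)


def resolve_stencil(stencil: str, m: int) -> str:
    """Resolve the derivative stencil for a profile of length m.

    ``central2`` is the three-point scheme above; ``central4`` the
    five-point fourth-order scheme, usable when enough interior points
    remain.  ``auto`` picks central4 for m >= 12 — at coarse sampling
    (omega * delta approaching 1) the second-order scheme's truncation
    bias in the derivative estimates dominates every other error source,
    while below 12 points the wider stencil leaves too few rows.
    """
    if stencil == "auto":
        return "central4" if m >= CENTRAL4_MIN_LENGTH else "central2"
    if stencil in ("central2", "central4"):
        if stencil == "central4" and m < 7:
            raise TooShortProfileError(
                f"central4 stencil needs m >= 7 interior coverage, got m={m}"
            )
        return stencil
    raise ValueError(f"unknown stencil {stencil!r}")


def _stencil_derivatives(
    x: np.ndarray, delta: float, stencil: str
) -> tuple[np.ndarray, np.ndarray, slice]:
    """First/second derivative estimates and the interior slice they cover."""
    if stencil == "central2":
        xd1 = (x[2:] - x[:-2]) / (2.0 * delta)
        xd2 = (x[2:] + x[:-2] - 2.0 * x[1:-1]) / delta**2
        return xd1, xd2, slice(1, -1)
    # five-point fourth-order central formulas
    xd1 = (x[:-4] - 8.0 * x[1:-3] + 8.0 * x[3:-1] - x[4:]) / (12.0 * delta)
    xd2 = (
        -x[:-4] + 16.0 * x[1:-3] - 30.0 * x[2:-2] + 16.0 * x[3:-1] - x[4:]
    ) / (12.0 * delta**2)
    return xd1, xd2, slice(2, -2)


def _step1_design(profile: Profile, stencil: str = "central2") -> tuple[np.ndarray, np.ndarray]:
    """Design matrix X = [-x', -x, t, 1] and response Y = x'' at interior points."""
    xd1, xd2, interior = _stencil_derivatives(profile.values, profile.delta, stencil)
    t_int = profile.times[interior]
    X = np.column_stack([-xd1, -profile.values[interior], t_int, np.ones_like(t_int)])
    return X, xd2


def _lstsq_checked(
    X: np.ndarray,
    y: np.ndarray,
    error: type[Exception],
    what: str,
    zero_rhs_ok: bool = False,
) -> np.ndarray:
    """Least squares with a rank/condition guard.

    When the design is rank deficient but the right-hand side is (near)
    zero, the minimum-norm solution — the zero vector — is still the
    meaningful answer (e.g. an exactly linear profile has x'' = 0
    identically); degeneracy is then flagged downstream from B = 0 rather
    than raised here.
    """
    sol, _, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    bad = rank < X.shape[1] or (sv[-1] > 0 and sv[0] / sv[-1] > COND_THRESHOLD)
    if bad:
        rhs_scale = float(np.max(np.abs(y))) if y.size else 0.0
        if zero_rhs_ok and rhs_scale <= 1e-9 * max(1.0, float(np.max(np.abs(X)))):
            return np.zeros(X.shape[1])
        raise error(f"{what} is rank deficient (rank {rank} of {X.shape[1]})")
    return sol


def estimate_ode_params(profile: Profile, stencil: str = "central2") -> OdeParams:
    """Step 1: least-squares estimate of the ODE coefficients (A, B, C, D).

    Regresses the finite-difference second derivative on
    [-x'(t_i), -x(t_i), t_i, 1] over the interior points the stencil
    covers (l = m - 2 for central2, m - 4 for central4).

    Raises
    ------
    TooShortProfileError
        If m < 8.
    RankDeficiencyError
        If the design matrix is numerically rank deficient with a nonzero
        response (e.g. pathological profiles); exactly linear or constant
        profiles instead return all-zero coefficients, which downstream
        conversion flags as degenerate (B = 0).
    """
    _check_length(profile, MIN_PROFILE_LENGTH)
    X, Y = _step1_design(profile, resolve_stencil(stencil, profile.m))
    sol = _lstsq_checked(
        X, Y, RankDeficiencyError, "Step-1 design matrix", zero_rhs_ok=True
    )
    return OdeParams(*sol)


def estimate_sinusoid_coeffs(
    profile: Profile, alpha: float, omega: float, c: float, d: float
) -> tuple[float, float]:
    """Step 2: least-squares estimate of the oscillation coefficients (a, b).

    Forms z(t_i) = exp(-alpha t_i) (x(t_i) - c t_i - d) over all m points
    and regresses it on cos(omega t_i) and sin(omega t_i).

    Raises
    ------
    SingularityError
        If the cos/sin design is numerically singular, e.g. when
        omega * delta is a multiple of pi so both columns degenerate.
    """
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega!r}")
    t = profile.times
    z = np.exp(-alpha * t) * (profile.values - c * t - d)
    M = np.column_stack([np.cos(omega * t), np.sin(omega * t)])
    sol = _lstsq_checked(M, z, SingularityError, "sinusoid design matrix")
    return float(sol[0]), float(sol[1])


def fit_profile(profile: Profile, stencil: str = "central2") -> FitResult:
    """Fit all six model parameters to one profile by the two-step estimator.

    Chains Step 1 (ODE coefficients), the ODE-to-model conversion, and
    Step 2 (sinusoid coefficients), then evaluates the fitted curve on the
    profile's own grid and records the residual sum of squares S1^2 over
    all m points.

    Profiles whose Step-1 estimate has no oscillatory solution come back
    with ``degenerate=True`` rather than raising, so batch runs proceed.
    """
    _check_length(profile, MIN_PROFILE_LENGTH)
    if profile.m < 12:
        warnings.warn(
            f"profile {profile.gene_id!r} has only m={profile.m} time points; "
            "finite-difference error in Step 1 may be large",
            stacklevel=2,
        )
    ode = estimate_ode_params(profile, stencil=stencil)
    try:
        alpha, omega, c, d = ode_to_model(ode)
    except DegenerateModelError:
        return FitResult(gene_id=profile.gene_id, degenerate=True, ode=ode)
    a, b = estimate_sinusoid_coeffs(profile, alpha, omega, c, d)
    params = ModelParams(alpha=alpha, omega=omega, a=a, b=b, c=c, d=d)
    fitted = evaluate_model(params, profile.m, profile.delta)
    s1_sq = float(np.sum((profile.values - fitted) ** 2))
    return FitResult(
        gene_id=profile.gene_id,
        degenerate=False,
        params=params,
        ode=ode,
        s1_sq=s1_sq,
        fitted=fitted,
    )
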