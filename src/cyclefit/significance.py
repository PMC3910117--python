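"""F-test screen separating model-following genes from white noise.

For each profile the null hypothesis is a constant plus Gaussian noise,
x(t) = d + eps(t); the alternative is the full six-parameter
damped-sinusoid-plus-trend model.  With S0^2 the residual about the profile
mean and S1^2 the residual of the fitted full model,

    F = [(S0^2 - S1^2) / 5] / [S1^2 / (m - 6)]

is referred to the F distribution with (5, m - 6) degrees of freedom; a
gene whose F exceeds the upper-gamma critical value is called significant
(not white noise) at level gamma.

Two caveats are inherent to the procedure: the time points of a trajectory
are not independent, and S1^2 comes from the two-step estimator rather than
the exact least-squares optimum, so the reference distribution is
approximate.  In particular S1^2 can exceed S0^2 for near-constant
profiles; the statistic is then clamped at zero.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import fit_profile
from .model import ModelParams, Profile

__all__ = [
    "SignificanceResult",
    "null_residual",
    "f_statistic",
    "f_threshold",
    "classify_profiles",
    "results_to_frame",
]

#: Numerator degrees of freedom: parameters added by the full model over
#: the constant null (alpha, omega, a, b, c).
NUM_DF = 5


@dataclasses.dataclass(frozen=True)
class SignificanceResult:
    """Per-gene outcome of the F-test screen.

    ``f_value`` is 0 and ``significant`` is False for degenerate fits and
    for genes whose fit failed outright (``error`` records why).
    ``p_value`` is the upper-tail probability, reported for convenience;
    the decision rule is the threshold comparison.
    """

    gene_id: str
    f_value: float
    s0_sq: float
    s1_sq: float | None
    threshold: float
    significant: bool
    p_value: float
    degenerate: bool = False
    params: ModelParams | None = None
    error: str | None = None


def null_residual(profile: Profile) -> tuple[float, float]:
    """Residual sum of squares about the profile mean.

    Returns (S0^2, d_hat) where d_hat is the sample mean — the
    least-squares fit of the constant null model.
    """
    if profile.m < 2:
        raise ValueError("need at least 2 time points for the null residual")
    d_hat = float(np.mean(profile.values))
    s0_sq = float(np.sum((profile.values - d_hat) ** 2))
    return s0_sq, d_hat


def f_statistic(s0_sq: float, s1_sq: float, m: int) -> float:
    """F statistic comparing the full-model residual to the null residual.

    F = ((m - 6) / 5) * (S0^2 / S1^2 - 1), clamped at 0 when the full model
    fits worse than the constant (possible because the two-step fit is not
    the exact optimum).  A perfect fit (S1^2 = 0 with S0^2 > 0) returns
    ``inf`` rather than dividing by zero.
    """
    if m < 8:
        raise ValueError(f"F-test requires m >= 8, got {m}")
    if s0_sq < 0 or s1_sq < 0:
        raise ValueError("residual sums of squares must be nonnegative")
    if s1_sq == 0:
        return math.inf if s0_sq > 0 else 0.0
    f = ((m - 6) / NUM_DF) * (s0_sq / s1_sq - 1.0)
    return max(f, 0.0)


def f_threshold(gamma: float, m: int) -> float:
    """Upper-gamma critical value of the F(5, m - 6) distribution."""
    if not 0 < gamma < 1:
        raise ValueError(f"gamma must lie in (0, 1), got {gamma!r}")
    if m < 8:
        raise ValueError(f"F-test requires m >= 8, got {m}")
    return float(stats.f.ppf(1.0 - gamma, NUM_DF, m - 6))


def _p_value(f_value: float, m: int) -> float:
    if math.isinf(f_value):
        return 0.0
    return float(stats.f.sf(f_value, NUM_DF, m - 6))


def classify_profiles(
    profiles: Iterable[Profile], gamma: float = 0.1
) -> list[SignificanceResult]:
    """Run the F-test screen over a batch of equal-length profiles.

    Each profile is fitted with the two-step estimator; degenerate fits —
    judged not describable by the model — are classified not significant
    with F = 0, as are profiles whose fit raised a numerical error (the
    error message is recorded per gene; the batch never aborts).
    """
    profiles = list(profiles)
    if not profiles:
        return []
    m = profiles[0].m
    if any(p.m != m for p in profiles):
        raise ValueError("all profiles must share the same number of time points")
    threshold = f_threshold(gamma, m)
    results: list[SignificanceResult] = []
    for profile in profiles:
        s0_sq, _ = null_residual(profile)
        try:
            fit = fit_profile(profile)
        except np.linalg.LinAlgError as exc:
            results.append(
                SignificanceResult(
                    gene_id=profile.gene_id,
                    f_value=0.0,
                    s0_sq=s0_sq,
                    s1_sq=None,
                    threshold=threshold,
                    significant=False,
                    p_value=1.0,
                    error=str(exc),
                )
            )
            continue
        if fit.degenerate:
            results.append(
                SignificanceResult(
                    gene_id=profile.gene_id,
                    f_value=0.0,
                    s0_sq=s0_sq,
                    s1_sq=None,
                    threshold=threshold,
                    significant=False,
                    p_value=1.0,
                    degenerate=True,
                )
            )
            continue
        f_value = f_statistic(s0_sq, fit.s1_sq, m)
        results.append(
            SignificanceResult(
                gene_id=profile.gene_id,
                f_value=f_value,
                s0_sq=s0_sq,
                s1_sq=fit.s1_sq,
                threshold=threshold,
                significant=f_value > threshold,
                p_value=_p_value(f_value, m),
                params=fit.params,
            )
        )
    return results


def results_to_frame(
    results: Sequence[SignificanceResult], bh: bool = False
) -> pd.DataFrame:
    """Tabulate screen results, one row per gene.

    Parameter columns are empty (NaN) for degenerate or failed fits.  With
    ``bh=True`` an extra ``q_value`` column carries Benjamini-Hochberg
    adjusted p-values; the significance column itself always reflects the
    plain threshold rule.
    """
    rows = []
    for r in results:
        p = r.params
        rows.append(
            {
                "gene_id": r.gene_id,
                "F": r.f_value,
                "p_value": r.p_value,
                "threshold": r.threshold,
                "significant": r.significant,
                "degenerate": r.degenerate,
                "alpha": p.alpha if p else np.nan,
                "omega": p.omega if p else np.nan,
                "a": p.a if p else np.nan,
                "b": p.b if p else np.nan,
                "c": p.c if p else np.nan,
                "d": p.d if p else np.nan,
                "error": r.error or "",
            }
        )
    frame = pd.DataFrame(rows)
    if bh and len(frame):
        frame["q_value"] = _benjamini_hochberg(frame["p_value"].to_numpy())
    return frame


def _benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p_values, method="bh")
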