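"""Probing significant interactions: simple slopes and Johnson-Neyman regions.

The conditional effect of the peer-exposure predictor at moderator value w is
``slope(w) = b1 + b3*w`` with variance ``Var(b1) + w^2 Var(b3) + 2w
Cov(b1,b3)`` taken from the model's robust covariance.  Johnson-Neyman
boundaries are the real roots of ``slope(w)^2 = t_crit^2 * Var(slope(w))``, a
quadratic in w, reported within the observed moderator range.  For the
logistic family slopes are on the linear-predictor (log-odds) scale, where
the Wald machinery carries over exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .moderation import IDX_INT, IDX_PEER, FitResult

__all__ = ["SlopeEstimate", "JNRegion", "simple_slopes", "johnson_neyman",
           "conditional_effects_data"]


@dataclass(frozen=True)
class SlopeEstimate:
    """Conditional peer-influence slope at one moderator value."""

    level: str
    moderator_value: float
    slope: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class JNRegion:
    """Johnson-Neyman region of significance for one model."""

    confidence_level: int  # 95 or 99
    boundaries: tuple[float, ...]  # within the observed moderator range, sorted
    segments: tuple[tuple[float, float, bool], ...]  # (lo, hi, significant)
    extrapolated_roots: tuple[float, ...]  # real roots outside the range
    moderator_range: tuple[float, float]

    @property
    def uniformly_significant(self) -> bool:
        return not self.boundaries and all(s[2] for s in self.segments)

    @property
    def nowhere_significant(self) -> bool:
        return not self.boundaries and not any(s[2] for s in self.segments)


def _focal_terms(fit: FitResult):
    if not fit.ok:
        raise ValueError(f"cannot probe an unfit model: {fit.reason}")
    b1 = float(fit.params[IDX_PEER])
    b3 = float(fit.params[IDX_INT])
    v11 = float(fit.cov[IDX_PEER, IDX_PEER])
    v33 = float(fit.cov[IDX_INT, IDX_INT])
    v13 = float(fit.cov[IDX_PEER, IDX_INT])
    return b1, b3, v11, v33, v13


def _crit(fit: FitResult, alpha: float) -> float:
    if fit.spec.family == "logistic":
        return float(stats.norm.ppf(1 - alpha / 2))
    return float(stats.t.ppf(1 - alpha / 2, fit.df_resid))


def _slope_p(fit: FitResult, t_stat: float) -> float:
    if fit.spec.family == "logistic":
        return float(2 * stats.norm.sf(abs(t_stat)))
    return float(2 * stats.t.sf(abs(t_stat), fit.df_resid))


def simple_slopes(
    fit: FitResult,
    levels: dict[str, float] | None = None,
    alpha: float = 0.05,
) -> list[SlopeEstimate]:
    """Conditional slopes at chosen moderator values.

    Defaults: levels 0 and 1 for a dichotomous moderator; one SD below and
    above the mean (i.e. -SD and +SD after centering) for a continuous one.
    """
    b1, b3, v11, v33, v13 = _focal_terms(fit)
    if levels is None:
        if fit.moderator_kind == "dichotomous":
            levels = {"level 0": 0.0, "level 1": 1.0}
        else:
            sd = fit.moderator_sd
            levels = {"low (-1 SD)": -sd, "high (+1 SD)": +sd}
    crit = _crit(fit, alpha)
    out = []
    for label, w in levels.items():
        slope = b1 + b3 * w
        var = v11 + w**2 * v33 + 2 * w * v13
        se = float(np.sqrt(max(var, 0.0)))
        t_stat = slope / se if se > 0 else np.inf * np.sign(slope)
        out.append(
            SlopeEstimate(
                level=label,
                moderator_value=float(w),
                slope=float(slope),
                se=se,
                ci_low=float(slope - crit * se),
                ci_high=float(slope + crit * se),
                p_value=_slope_p(fit, t_stat),
            )
        )
    return out


def _significant_at(fit, w, crit, b1, b3, v11, v33, v13) -> bool:
    slope = b1 + b3 * w
    se = np.sqrt(max(v11 + w**2 * v33 + 2 * w * v13, 0.0))
    if se == 0:
        return slope != 0
    return abs(slope) / se > crit


def johnson_neyman(
    fit: FitResult,
    level: int = 95,
    moderator_range: tuple[float, float] | None = None,
) -> JNRegion:
    """Region of significance of the conditional peer effect.

    ``level`` is the confidence level (95 or 99).  Boundaries are the real
    roots of the boundary quadratic lying inside the observed moderator
    range (on the centered scale for continuous moderators); roots outside
    the range are reported separately.  Zero interior roots mean the effect
    is uniformly significant or uniformly non-significant over the range.
    """
    if level not in (95, 99):
        raise ValueError("level must be 95 or 99")
    b1, b3, v11, v33, v13 = _focal_terms(fit)
    lo, hi = moderator_range if moderator_range is not None else fit.moderator_range
    crit = _crit(fit, 1 - level / 100)
    c2 = crit**2

    a = b3**2 - c2 * v33
    b = 2 * (b1 * b3 - c2 * v13)
    c = b1**2 - c2 * v11

    roots: list[float] = []
    if abs(a) < 1e-300:
        if abs(b) > 0:
            roots = [-c / b]
    else:
        disc = b**2 - 4 * a * c
        if disc >= 0:
            sq = np.sqrt(disc)
            roots = sorted([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    interior = tuple(r for r in roots if lo < r < hi)
    exterior = tuple(r for r in roots if not lo < r < hi)

    cuts = [lo, *interior, hi]
    segments = []
    for seg_lo, seg_hi in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (seg_lo + seg_hi)
        segments.append(
            (float(seg_lo), float(seg_hi),
             _significant_at(fit, mid, crit, b1, b3, v11, v33, v13))
        )
    return JNRegion(
        confidence_level=level,
        boundaries=tuple(float(r) for r in interior),
        segments=tuple(segments),
        extrapolated_roots=tuple(float(r) for r in exterior),
        moderator_range=(float(lo), float(hi)),
    )


def conditional_effects_data(
    fit: FitResult,
    n_points: int = 50,
    alpha: float = 0.05,
) -> "np.recarray":
    """Slope and CI band over a grid of moderator values (plotting data)."""
    import pandas as pd

    b1, b3, v11, v33, v13 = _focal_terms(fit)
    if fit.moderator_kind == "dichotomous":
        grid = np.array([0.0, 1.0])
    else:
        lo, hi = fit.moderator_range
        grid = np.linspace(lo, hi, n_points)
    crit = _crit(fit, alpha)
    slopes = b1 + b3 * grid
    ses = np.sqrt(np.maximum(v11 + grid**2 * v33 + 2 * grid * v13, 0.0))
    return pd.DataFrame(
        {
            "moderator_value": grid,
            "slope": slopes,
            "se": ses,
            "ci_low": slopes - crit * ses,
            "ci_high": slopes + crit * ses,
        }
    )
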