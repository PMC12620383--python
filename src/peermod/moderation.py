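"""Moderated regressions with heteroskedasticity-robust standard errors.

One model per (outcome x peer group x peer-measurement wave): the follow-up
outcome is regressed on the centered peer exposure, the moderator (centered
if continuous, 0/1 if dichotomous), their product (formed after centering),
the baseline covariates (gender, age band, intervention, ethnicity,
individual SES) and the centered baseline outcome.  Continuous outcomes use
OLS with Huber-White sandwich standard errors (HC1 by default); the binary
susceptibility outcome uses a logistic model with the analogous robust
covariance.  A moderating effect is a significant interaction (p <= 0.01 by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr as _qr

from .config import (
    DICHOTOMOUS_MODERATORS,
    NETWORK_MODERATORS,
    SELF_EFFICACY_MODERATORS,
    SELF_EFFICACY_OUTCOMES,
)
from . import exposure as _exposure

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "ExposureStore",
    "mean_center",
    "build_design",
    "ols_fit_hc",
    "logit_fit_robust",
    "vif",
    "standardized_interaction",
    "interaction_delta_r2",
    "build_model_specs",
    "run_model_grid",
]

#: fixed design-column positions for the focal terms
IDX_PEER, IDX_MOD, IDX_INT = 1, 2, 3

DEFAULT_COVARIATES = ("gender", "age", "intervention", "ethnicity", "ses_individual")


class RankDeficiencyError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """One moderated-regression specification."""

    outcome: str
    family: str  # "linear" | "logistic"
    peer_group: str  # "friends" | "class" | "year"
    wave: int  # wave of peer measurement (0 baseline, 1 follow-up)
    moderator: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alpha_sig: float = 0.01

    def __post_init__(self):
        if self.moderator == self.outcome:
            raise ValueError("moderator must differ from the outcome")


class RegressionFit(NamedTuple):
    """Raw regression output shared by the linear and logistic fitters."""

    params: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    r2: float | None
    resid: np.ndarray | None


@dataclass
class FitResult:
    """One fitted moderated regression (or a recorded failure)."""

    spec: ModelSpec
    ok: bool
    reason: str | None = None
    n: int = 0
    names: tuple[str, ...] = ()
    params: np.ndarray | None = None
    cov: np.ndarray | None = None
    se: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    df_resid: int = 0
    r2: float | None = None
    delta_r2: float | None = None
    beta_std: float | None = None
    vifs: dict[str, float] = field(default_factory=dict)
    vif_flag_5: bool = False
    vif_flag_10: bool = False
    sd_exposure: float | None = None
    sd_outcome: float | None = None
    moderator_kind: str = "continuous"
    moderator_sd: float | None = None
    moderator_range: tuple[float, float] | None = None

    @property
    def interaction_coef(self) -> float:
        return float(self.params[IDX_INT]) if self.ok else np.nan

    @property
    def interaction_se(self) -> float:
        return float(self.se[IDX_INT]) if self.ok else np.nan

    @property
    def interaction_p(self) -> float:
        return float(self.pvalues[IDX_INT]) if self.ok else np.nan

    def significant(self, alpha: float | None = None) -> bool:
        alpha = self.spec.alpha_sig if alpha is None else alpha
        return self.ok and self.interaction_p <= alpha


def mean_center(values) -> np.ndarray:
    """Subtract the (estimation-sample) mean, ignoring missing values."""
    arr = np.asarray(values, dtype=float)
    if np.all(np.isnan(arr)):
        raise ValueError("cannot center an all-missing vector")
    return arr - np.nanmean(arr)


def _rank_check(X: np.ndarray, names) -> None:
    _, R, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise RankDeficiencyError(f"design is rank deficient; collinear columns: {bad}")


def ols_fit_hc(X, y, variant: str = "HC1", names=None) -> RegressionFit:
    """OLS with a heteroskedasticity-consistent sandwich covariance.

    cov = (X'X)^-1 X' diag(w_i e_i^2) X (X'X)^-1 with w per HC variant
    (HC0: 1; HC1: n/(n-k); HC3: 1/(1-h_i)^2).  p-values use t with n-k df.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    names = names if names is not None else [f"x{j}" for j in range(k)]
    _rank_check(X, names)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    if variant == "HC0":
        w = np.ones(n)
    elif variant == "HC1":
        w = np.full(n, n / (n - k))
    elif variant == "HC3":
        h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
        w = 1.0 / (1.0 - h) ** 2
    else:
        raise ValueError(f"unknown HC variant {variant!r}")
    meat = (X * (w * resid**2)[:, None]).T @ X
    cov = XtX_inv @ meat @ XtX_inv
    se = np.sqrt(np.diag(cov))
    df = n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    pvals = np.where(se == 0, np.where(beta == 0, 1.0, 0.0), pvals)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegressionFit(beta, cov, se, pvals, df, r2, resid)


class SeparationError(RuntimeError):
    pass


def logit_fit_robust(
    X, y, variant: str = "HC1", tol: float = 1e-8, max_iter: int = 100, names=None
) -> RegressionFit:
    """Maximum-likelihood logit via IRLS with a sandwich robust covariance.

    Convergence: max absolute coefficient change < ``tol`` within
    ``max_iter`` iterations.  Robust covariance is the sandwich of score
    outer products around the inverse information, with the HC1 n/(n-1)
    small-sample factor.  Diverging coefficients raise
    :class:`SeparationError` (perfect separation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    names = names if names is not None else [f"x{j}" for j in range(k)]
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    _rank_check(X, names)
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1.0 - p)
        info = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(info, X.T @ (y - p))
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 1e2:
            raise SeparationError("diverging coefficients (perfect separation?)")
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise SeparationError("IRLS did not converge")
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    info = (X * (p * (1 - p))[:, None]).T @ X
    info_inv = np.linalg.inv(info)
    scores = X * (y - p)[:, None]
    meat = scores.T @ scores
    factor = n / (n - 1) if variant == "HC1" else 1.0
    cov = factor * info_inv @ meat @ info_inv
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return RegressionFit(beta, cov, se, pvals, n - k, None, None)


def vif(X, names, intercept_name: str = "const") -> dict[str, float]:
    """Variance inflation factors, 1/(1 - R2_j), intercept excluded."""
    X = np.asarray(X, dtype=float)
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        if name == intercept_name:
            continue
        target = X[:, j]
        others = np.delete(X, j, axis=1)
        beta, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((target - target.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.nan
            continue
        r2_j = 1.0 - ss_res / ss_tot
        if r2_j >= 1.0 - 1e-12:
            log.warning("VIF for %s is infinite (R^2 = 1): near rank deficiency", name)
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2_j)
    return out


def standardized_interaction(b_int: float, exposure_values, outcome_values) -> float:
    """Interaction coefficient rescaled to outcome-SD units per exposure SD."""
    sd_x = float(np.std(exposure_values, ddof=1))
    sd_y = float(np.std(outcome_values, ddof=1))
    if sd_y == 0:
        return np.nan
    return float(b_int * sd_x / sd_y)


def interaction_delta_r2(X, y, interaction_idx: int = IDX_INT) -> float:
    """R2 gain of the interaction term over the nested model, same sample."""
    full = ols_fit_hc(X, y, "HC0")
    reduced = ols_fit_hc(np.delete(np.asarray(X, float), interaction_idx, axis=1), y, "HC0")
    return float(full.r2 - reduced.r2)


class ExposureStore:
    """Lazy cache of exposure frames keyed by (outcome, peer_group, wave)."""

    def __init__(self, cohort, nominations, binary_outcomes=frozenset()):
        self.cohort = cohort
        self.nominations = nominations
        self.binary = frozenset(binary_outcomes)
        self._cache: dict[tuple, pd.DataFrame] = {}

    def get(self, outcome: str, peer_group: str, wave: int) -> pd.DataFrame:
        key = (outcome, peer_group, wave)
        if key not in self._cache:
            if outcome in self.binary:
                frame = _exposure.peer_percentage(
                    self.cohort, outcome, peer_group, wave, self.nominations
                )
            else:
                frame = _exposure._exposure_for_group(
                    self.cohort, self.nominations, outcome, peer_group, wave
                )
            self._cache[key] = frame
        return self._cache[key]

    def to_table(self, outcomes, peer_groups=("friends", "class", "year"), waves=(0, 1)):
        return _exposure.build_exposure_table(
            self.cohort, self.nominations, list(outcomes), self.binary,
            peer_groups, waves,
        )


def _moderator_values(cohort: pd.DataFrame, moderator: str, wave: int):
    """Resolve a moderator to (values, kind)."""
    if moderator in DICHOTOMOUS_MODERATORS:
        level0, level1 = DICHOTOMOUS_MODERATORS[moderator]
        raw = cohort[moderator]
        vals = np.where(raw == level1, 1.0, np.where(raw == level0, 0.0, np.nan))
        return vals, "dichotomous"
    if moderator in NETWORK_MODERATORS:
        col = f"{moderator}_w{wave}"
        if col not in cohort.columns:
            raise KeyError(f"network moderator column {col!r} missing from cohort")
        return cohort[col].to_numpy(dtype=float), "continuous"
    if moderator in cohort.columns:
        return cohort[moderator].to_numpy(dtype=float), "continuous"
    # outcome-as-moderator (e.g. self-efficacy subscales): baseline value
    if f"{moderator}_w0" in cohort.columns:
        return cohort[f"{moderator}_w0"].to_numpy(dtype=float), "continuous"
    raise KeyError(f"unknown moderator {moderator!r}")


def build_design(
    spec: ModelSpec,
    cohort: pd.DataFrame,
    exposures: ExposureStore,
    min_extra_rows: int = 5,
):
    """Assemble the design matrix and response for one model.

    Listwise deletion first, then centering on the estimation sample, then
    the exposure-by-moderator product.  Returns ``(X, y, names, meta)`` or
    raises ``ValueError`` with a reason when the model cannot be fit.
    """
    y_col = f"{spec.outcome}_w1"
    y = cohort[y_col].to_numpy(dtype=float)
    exp_frame = exposures.get(spec.outcome, spec.peer_group, spec.wave)
    x = exp_frame["exposure"].reindex(cohort.pupil_id).to_numpy(dtype=float)
    w, kind = _moderator_values(cohort, spec.moderator, spec.wave)
    base = cohort[f"{spec.outcome}_w0"].to_numpy(dtype=float)

    cov_cols: dict[str, np.ndarray] = {}
    for cov_name in spec.covariates:
        if cov_name == spec.moderator:
            continue  # avoid duplicating a dichotomous moderator as covariate
        if cov_name == "gender":
            cov_cols["gender"] = (cohort.gender == "girl").to_numpy(dtype=float)
        elif cov_name == "age":
            cov_cols["age_13"] = (cohort.age_band == "13").to_numpy(dtype=float)
            cov_cols["age_14_15"] = (cohort.age_band == "14-15").to_numpy(dtype=float)
        elif cov_name == "intervention":
            cov_cols["intervention"] = (
                cohort.intervention == "DeadCool"
            ).to_numpy(dtype=float)
        elif cov_name == "ethnicity":
            cov_cols["ethnicity"] = cohort.ethnicity.to_numpy(dtype=float)
        elif cov_name == "ses_individual":
            ses = cohort.ses_individual.to_numpy()
            cov_cols["ses_2"] = (ses == 2).astype(float)
            cov_cols["ses_3"] = (ses >= 3).astype(float)
        else:
            cov_cols[cov_name] = cohort[cov_name].to_numpy(dtype=float)

    stack = [y, x, w, base] + list(cov_cols.values())
    mask = ~np.any(np.isnan(np.column_stack(stack)), axis=1)
    n = int(mask.sum())
    # covariates constant over the estimation sample carry no information
    # and would make the design rank deficient; drop them (logged)
    dropped = [
        name for name, col in cov_cols.items() if n and np.ptp(col[mask]) == 0
    ]
    if dropped:
        log.info("%s/%s: dropping constant covariate(s) %s",
                 spec.outcome, spec.moderator, dropped)
        cov_cols = {k_: v for k_, v in cov_cols.items() if k_ not in dropped}
    names = (
        ["const", "peer_exposure", "moderator", "interaction"]
        + list(cov_cols.keys())
        + ["baseline"]
    )
    k = len(names)
    if n < k + min_extra_rows:
        raise ValueError(f"too few rows after listwise deletion (n={n}, k={k})")

    y_m = y[mask]
    x_m = mean_center(x[mask])
    w_m = w[mask] if kind == "dichotomous" else mean_center(w[mask])
    base_m = mean_center(base[mask])
    product = x_m * w_m

    X = np.column_stack(
        [np.ones(n), x_m, w_m, product]
        + [c[mask] for c in cov_cols.values()]
        + [base_m]
    )
    meta = {
        "n": n,
        "moderator_kind": kind,
        "sd_exposure": float(np.std(x_m, ddof=1)),
        "sd_outcome": float(np.std(y_m, ddof=1)),
        "moderator_sd": float(np.std(w_m, ddof=1)),
        "moderator_range": (float(w_m.min()), float(w_m.max())),
    }
    return X, y_m, tuple(names), meta


def fit_model(
    spec: ModelSpec,
    cohort: pd.DataFrame,
    exposures: ExposureStore,
    hc_variant: str = "HC1",
    compute_vif: bool = True,
) -> FitResult:
    """Fit one moderated regression, recording failures as unfit results."""
    try:
        X, y, names, meta = build_design(spec, cohort, exposures)
    except (ValueError, KeyError) as exc:
        return FitResult(spec, ok=False, reason=str(exc))
    try:
        if spec.family == "logistic":
            fit = logit_fit_robust(X, y, variant=hc_variant, names=names)
            beta_std = None
            delta_r2 = None
        else:
            fit = ols_fit_hc(X, y, variant=hc_variant, names=names)
            beta_std = standardized_interaction(fit.params[IDX_INT], X[:, IDX_PEER], y)
            delta_r2 = interaction_delta_r2(X, y)
    except (RankDeficiencyError, SeparationError, ValueError) as exc:
        return FitResult(spec, ok=False, reason=str(exc), n=meta["n"])
    vifs = vif(X, names) if compute_vif else {}
    finite = [v for v in vifs.values() if np.isfinite(v)]
    return FitResult(
        spec=spec,
        ok=True,
        n=meta["n"],
        names=names,
        params=fit.params,
        cov=fit.cov,
        se=fit.se,
        pvalues=fit.pvalues,
        df_resid=fit.df_resid,
        r2=fit.r2,
        delta_r2=delta_r2,
        beta_std=beta_std,
        vifs=vifs,
        vif_flag_5=bool(vifs) and (max(finite, default=np.inf) > 5 or len(finite) < len(vifs)),
        vif_flag_10=bool(vifs) and (max(finite, default=np.inf) > 10 or len(finite) < len(vifs)),
        sd_exposure=meta["sd_exposure"],
        sd_outcome=meta["sd_outcome"],
        moderator_kind=meta["moderator_kind"],
        moderator_sd=meta["moderator_sd"],
        moderator_range=meta["moderator_range"],
    )


def build_model_specs(
    moderator: str,
    outcomes,
    binary_outcomes=frozenset(),
    peer_groups=("friends", "class", "year"),
    waves=(0, 1),
    alpha_sig: float = 0.01,
) -> list[ModelSpec]:
    """The model grid for one moderator.

    Self-efficacy subscale moderators exclude the three self-efficacy
    outcomes (and any moderator excludes itself as outcome), so the default
    46-outcome battery yields 276 models per moderator, 258 per self-efficacy
    subscale.
    """
    excluded = set()
    if moderator in SELF_EFFICACY_MODERATORS:
        excluded.update(SELF_EFFICACY_OUTCOMES)
    specs = []
    for outcome in outcomes:
        if outcome in excluded or outcome == moderator:
            continue
        family = "logistic" if outcome in binary_outcomes else "linear"
        for group in peer_groups:
            for wave in waves:
                specs.append(
                    ModelSpec(outcome, family, group, wave, moderator,
                              alpha_sig=alpha_sig)
                )
    return specs


def run_model_grid(
    moderator: str,
    cohort: pd.DataFrame,
    exposures: ExposureStore,
    outcomes,
    binary_outcomes=frozenset(),
    peer_groups=("friends", "class", "year"),
    waves=(0, 1),
    hc_variant: str = "HC1",
    alpha_sig: float = 0.01,
    compute_vif: bool = True,
) -> list[FitResult]:
    """Fit the full model grid for one moderator; failures are collected."""
    specs = build_model_specs(
        moderator, outcomes, binary_outcomes, peer_groups, waves, alpha_sig
    )
    return [
        fit_model(spec, cohort, exposures, hc_variant, compute_vif) for spec in specs
    ]


def results_frame(fits: list[FitResult]) -> pd.DataFrame:
    """One row per model: spec fields, interaction estimate/SE/p, effect sizes."""
    rows = []
    for f in fits:
        rows.append(
            {
                "moderator": f.spec.moderator,
                "outcome": f.spec.outcome,
                "family": f.spec.family,
                "peer_group": f.spec.peer_group,
                "wave": f.spec.wave,
                "ok": f.ok,
                "reason": f.reason,
                "n": f.n,
                "b_interaction": f.interaction_coef,
                "se_interaction": f.interaction_se,
                "p_interaction": f.interaction_p,
                "beta_std": f.beta_std if f.beta_std is not None else np.nan,
                "delta_r2": f.delta_r2 if f.delta_r2 is not None else np.nan,
                "r2": f.r2 if f.r2 is not None else np.nan,
                "vif_flag_5": f.vif_flag_5,
                "vif_flag_10": f.vif_flag_10,
            }
        )
    return pd.DataFrame(rows)
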