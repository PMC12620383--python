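"""Seeded synthetic cohorts with planted peer-influence and moderation effects.

The generator emulates the statistical structure the downstream analysis
assumes: pupils clustered in classes within schools across two settings,
homophilous friendship nominations (capped at ten per pupil), bounded outcome
scales with autoregressive dependence of follow-up on baseline, a peer term
driven by the friend out-neighbour mean at baseline, and a planted
moderator-by-peer interaction.  Identical ``(config, seed)`` yields
byte-identical tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .config import (
    NOMINATION_CAP,
    CohortConfig,
    ConfigurationError,
    _as_pair,
)
from .measures import derive_school_ses

__all__ = ["generate_cohort", "generate_nominations", "generate_item_responses"]

AGE_BANDS = ("11-12", "13", "14-15")
AGE_PROBS = (0.363, 0.497, 0.140)
ETHNIC_MINORITY_RATE = 0.109
SES_INDIVIDUAL_PROBS = (0.502, 0.385, 0.113)  # ordinal levels 1..3
NI_DEPRIVATION_RANGE = (5.7, 80.2)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _build_roster(config: CohortConfig, rng) -> pd.DataFrame:
    classes_a, classes_b = _as_pair(config.classes_per_school)
    pupils_a, pupils_b = _as_pair(config.pupils_per_class)
    n_setting_a = int(round(config.setting_split * config.n_schools))

    rows = []
    pupil = 0
    for s in range(config.n_schools):
        setting = "NI" if s < n_setting_a else "Bogota"
        school_id = f"S{s + 1:02d}"
        in_setting = s if setting == "NI" else s - n_setting_a
        n_in_setting = n_setting_a if setting == "NI" else config.n_schools - n_setting_a
        n_assist = int(round(config.intervention_split * n_in_setting))
        intervention = "ASSIST" if in_setting < n_assist else "DeadCool"
        n_classes = classes_a if setting == "NI" else classes_b
        n_pupils = pupils_a if setting == "NI" else pupils_b
        for c in range(n_classes):
            class_id = f"{school_id}C{c + 1:02d}"
            for _ in range(n_pupils):
                pupil += 1
                rows.append((f"P{pupil:05d}", school_id, class_id, setting, intervention))
    roster = pd.DataFrame(
        rows, columns=["pupil_id", "school_id", "class_id", "setting", "intervention"]
    )

    n = len(roster)
    roster["gender"] = np.where(
        rng.random(n) < config.girl_fraction, "girl", "boy"
    )
    roster["age_band"] = rng.choice(AGE_BANDS, size=n, p=np.asarray(AGE_PROBS) / sum(AGE_PROBS))
    roster["ethnicity"] = (rng.random(n) < ETHNIC_MINORITY_RATE).astype(int)
    probs = np.asarray(SES_INDIVIDUAL_PROBS) / sum(SES_INDIVIDUAL_PROBS)
    roster["ses_individual"] = rng.choice([1, 2, 3], size=n, p=probs)
    return roster


def _assign_school_ses(roster: pd.DataFrame, rng) -> pd.DataFrame:
    """School SES on a common ordinal 1-4 scale.

    Setting-A ("NI") schools carry a raw deprivation score (higher = more
    deprived) that is quartiled into the four-category variable; setting-B
    ("Bogota") schools are assigned the ordinal level directly.
    """
    schools = roster[["school_id", "setting"]].drop_duplicates().reset_index(drop=True)
    ni = schools[schools.setting == "NI"]
    dep = pd.Series(np.nan, index=schools.school_id.values, dtype=float)
    ses = pd.Series(0, index=schools.school_id.values, dtype=int)
    if len(ni):
        scores = rng.uniform(*NI_DEPRIVATION_RANGE, size=len(ni))
        dep.loc[ni.school_id.values] = scores
        cats = derive_school_ses(dict(zip(ni.school_id.values, scores)))
        for sid, cat in cats.items():
            ses.loc[sid] = cat
    bog = schools[schools.setting == "Bogota"]
    if len(bog):
        ses.loc[bog.school_id.values] = rng.choice([2, 3], size=len(bog))
    roster = roster.copy()
    roster["school_ses"] = roster.school_id.map(ses).astype(int)
    roster["school_deprivation"] = roster.school_id.map(dep)
    return roster


def generate_nominations(
    cohort: pd.DataFrame,
    config: CohortConfig,
    wave: int = 0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw friendship nominations within each school year group.

    Out-degrees are Poisson(``nomination_mean_outdegree``) truncated at the
    ten-nomination cap; nominee sampling weights are multiplied by the
    within-class and same-gender homophily ratios.  Sampling without
    replacement uses Gumbel top-k keys so whole schools are drawn in one
    vectorized step.
    """
    if len(cohort) == 0:
        raise ConfigurationError("empty roster")
    if rng is None:
        rng = np.random.default_rng(seed)

    log_class = np.log(config.within_class_nomination_prob_ratio)
    log_gender = np.log(config.same_gender_nomination_prob_ratio)

    nominators: list[np.ndarray] = []
    nominees: list[np.ndarray] = []
    for _, school in cohort.groupby("school_id", sort=True):
        ids = school.pupil_id.to_numpy()
        n = len(ids)
        if n < 2:
            continue
        kk = np.minimum(
            rng.poisson(config.nomination_mean_outdegree, size=n),
            min(NOMINATION_CAP, n - 1),
        )
        same_class = (
            school.class_id.to_numpy()[:, None] == school.class_id.to_numpy()[None, :]
        )
        same_gender = (
            school.gender.to_numpy()[:, None] == school.gender.to_numpy()[None, :]
        )
        logw = log_class * same_class + log_gender * same_gender
        np.fill_diagonal(logw, -np.inf)
        keys = logw + rng.gumbel(size=(n, n))
        order = np.argsort(-keys, axis=1)
        for i in range(n):
            k = kk[i]
            if k:
                nominators.append(np.repeat(ids[i], k))
                nominees.append(ids[order[i, :k]])
    if nominators:
        out = pd.DataFrame(
            {
                "nominator_id": np.concatenate(nominators),
                "nominee_id": np.concatenate(nominees),
            }
        )
    else:
        out = pd.DataFrame({"nominator_id": [], "nominee_id": []}, dtype=object)
    out["wave"] = wave
    return out.reset_index(drop=True)


def _friend_baseline_mean(cohort, nominations, values, fallback):
    """Mean of nominated friends' baseline values; school-year mean fallback
    for pupils with no contributing friends (keeps the DGP defined for
    isolates)."""
    idx = pd.Index(cohort.pupil_id)
    pos = pd.Series(np.arange(len(idx)), index=idx)
    src = pos.loc[nominations.nominator_id].to_numpy()
    dst = pos.loc[nominations.nominee_id].to_numpy()
    vals = np.asarray(values, dtype=float)
    ok = ~np.isnan(vals[dst])
    sums = np.zeros(len(idx))
    counts = np.zeros(len(idx))
    np.add.at(sums, src[ok], vals[dst[ok]])
    np.add.at(counts, src[ok], 1.0)
    with np.errstate(invalid="ignore"):
        mean = sums / counts
    mean[counts == 0] = fallback[counts == 0]
    return mean


def generate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort table and its nomination edge list.

    Returns ``(cohort, nominations)``: one row per pupil with attributes,
    moderator scores and per-wave outcome columns (``<name>_w0`` baseline,
    ``<name>_w1`` follow-up); nominations carry both waves.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(seed).spawn(6)
    ]
    rng_attrs, rng_mod, rng_base, rng_nom0, rng_nom1, rng_follow = streams

    cohort = _build_roster(config, rng_attrs)
    cohort = _assign_school_ses(cohort, rng_attrs)
    n = len(cohort)

    new_cols: dict[str, np.ndarray] = {}
    for spec in config.moderator_specs:
        new_cols[spec.name] = _truncated_normal(
            rng_mod, spec.mean, spec.sd, spec.minimum, spec.maximum, n
        )

    # baseline outcomes
    for spec in config.outcome_specs:
        col = f"{spec.name}_w0"
        if spec.is_binary:
            new_cols[col] = (rng_base.random(n) < spec.baseline_mean).astype(float)
        else:
            new_cols[col] = _truncated_normal(
                rng_base, spec.baseline_mean, spec.baseline_sd,
                spec.scale_min, spec.scale_max, n,
            )
    cohort = pd.concat([cohort, pd.DataFrame(new_cols, index=cohort.index)], axis=1)

    nom0 = generate_nominations(cohort, config, wave=0, rng=rng_nom0)
    nom1 = generate_nominations(cohort, config, wave=1, rng=rng_nom1)

    # standardized planted moderator
    w_raw = cohort[config.dgp_moderator].to_numpy()
    w = (w_raw - w_raw.mean()) / w_raw.std() if w_raw.std() > 0 else np.zeros(n)

    dgp = config.dgp
    cov_term = np.zeros(n)
    covariate_columns = {
        "gender": (cohort.gender == "girl").astype(float),
        "setting": (cohort.setting == "Bogota").astype(float),
        "intervention": (cohort.intervention == "DeadCool").astype(float),
        "ethnicity": cohort.ethnicity.astype(float),
        "ses_individual": cohort.ses_individual.astype(float),
    }
    for name, coef in dgp.covariate_effects.items():
        if name not in covariate_columns:
            raise ConfigurationError(f"unknown covariate effect {name!r}")
        cov_term = cov_term + coef * covariate_columns[name].to_numpy()

    school_codes = cohort.school_id.to_numpy()
    follow_cols: dict[str, np.ndarray] = {}
    for spec in config.outcome_specs:
        y0 = cohort[f"{spec.name}_w0"].to_numpy(dtype=float)
        year_mean = pd.Series(y0).groupby(school_codes).transform("mean").to_numpy()
        xbar = _friend_baseline_mean(cohort, nom0, y0, year_mean)
        if spec.is_binary:
            p0 = float(np.mean(y0))
            target = spec.follow_up_mean if spec.follow_up_mean is not None else p0
            eta = (
                np.log(target / (1 - target))
                + dgp.intercept
                + dgp.binary_autoregression * (y0 - p0)
                + dgp.binary_peer * (xbar - p0)
                + dgp.binary_moderator_main * w
                + dgp.binary_interaction * (xbar - p0) * w
                + cov_term
            )
            y1 = (rng_follow.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        else:
            mu, s = spec.baseline_mean, spec.baseline_sd
            y1 = (
                mu
                + dgp.intercept
                + dgp.autoregression * (y0 - mu)
                + dgp.peer * (xbar - mu)
                + dgp.moderator_main * s * w
                + dgp.interaction * (xbar - mu) * w
                + cov_term * s
            )
            if dgp.noise_sd > 0:
                y1 = y1 + rng_follow.normal(0.0, dgp.noise_sd * s, size=n)
            y1 = np.clip(y1, spec.scale_min, spec.scale_max)
        follow_cols[f"{spec.name}_w1"] = y1

    # completely-at-random missing follow-up (whole instrument)
    missing = rng_follow.random(n) < config.missing_rate
    if missing.any():
        for col in follow_cols.values():
            col[missing] = np.nan
    follow_cols["participated_w0"] = np.ones(n, dtype=bool)
    follow_cols["participated_w1"] = ~missing
    cohort = pd.concat([cohort, pd.DataFrame(follow_cols, index=cohort.index)], axis=1)

    nominations = pd.concat([nom0, nom1], ignore_index=True)
    return cohort, nominations


def generate_item_responses(
    scale_scores,
    n_items: int,
    loading: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Item-level responses consistent with given scale scores.

    Each item is ``loading * latent + (1 - loading) * noise`` where the latent
    dimension is the standardized scale score; items are mapped back to the
    score's location/scale (variance preserved) and clipped to ``bounds`` if
    given.  Expected inter-item correlation is ``loading**2 / (loading**2 +
    (1-loading)**2)``, monotone increasing in the loading.
    """
    if n_items < 2:
        raise ConfigurationError("n_items must be >= 2")
    if not 0.0 <= loading <= 1.0:
        raise ConfigurationError("loading must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    scores = np.asarray(scale_scores, dtype=float)
    mean = scores.mean()
    sd = scores.std()
    z = (scores - mean) / sd if sd > 0 else np.zeros_like(scores)
    raw = loading * z[:, None] + (1.0 - loading) * rng.standard_normal(
        (len(scores), n_items)
    )
    denom = np.sqrt(loading**2 + (1.0 - loading) ** 2)
    items = mean + sd * raw / denom
    if bounds is not None:
        items = np.clip(items, bounds[0], bounds[1])
    return items
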