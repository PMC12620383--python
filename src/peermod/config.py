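"""Configuration objects for synthetic cohorts and analysis runs.

The default :class:`CohortConfig` emulates the structure of the motivating
study population: 12 secondary schools split across two settings (a
high-income setting, "NI", and a middle-income setting, "Bogota"), roughly
55 school classes and ~1,400 pupils aged 12-13, each of whom could nominate
up to ten friends in their school year group.  Outcomes are smoking- and
vaping-related norms, behaviours, and psycho-social antecedents measured at
two waves on heterogeneous bounded scales; moderators are individual
dispositions, contextual variables, and social-network positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

NOMINATION_CAP = 10

#: outcome families used by the heatmap / multiverse summaries
FAMILY_EXPERIMENTAL = "experimental_norms"
FAMILY_SELF_REPORT_NORMS = "self_report_norms"
FAMILY_OTHER = "other_smoking_outcomes"


class ConfigurationError(ValueError):
    """Raised when a cohort or run configuration violates its invariants."""


@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome variable measured at both waves.

    ``baseline_mean``/``baseline_sd`` parameterise the truncated-normal
    baseline draw; for a binary outcome ``baseline_mean`` is the baseline
    prevalence and ``follow_up_mean`` the target follow-up prevalence.
    """

    name: str
    scale_min: float
    scale_max: float
    baseline_mean: float
    baseline_sd: float
    is_binary: bool = False
    family: str = FAMILY_OTHER
    follow_up_mean: float | None = None

    def validate(self) -> None:
        if not self.scale_min < self.scale_max:
            raise ConfigurationError(
                f"outcome {self.name!r}: scale_min must be < scale_max "
                f"(got {self.scale_min} >= {self.scale_max})"
            )
        if not self.is_binary and self.baseline_sd <= 0:
            raise ConfigurationError(f"outcome {self.name!r}: baseline_sd must be positive")


@dataclass(frozen=True)
class ModeratorSpec:
    """A pupil-level moderator score drawn at baseline."""

    name: str
    kind: str  # "continuous" | "dichotomous"
    minimum: float
    maximum: float
    mean: float
    sd: float

    def validate(self) -> None:
        if self.kind not in ("continuous", "dichotomous"):
            raise ConfigurationError(f"moderator {self.name!r}: unknown kind {self.kind!r}")
        if not self.minimum < self.maximum:
            raise ConfigurationError(f"moderator {self.name!r}: bounds out of order")


@dataclass(frozen=True)
class DGPCoefficients:
    """Coefficients of the follow-up data-generating process.

    For a continuous outcome y with baseline mean mu and baseline SD s,
    peer exposure x (friend out-neighbour mean at baseline) and standardized
    moderator w::

        y1 = mu + autoregression*(y0 - mu) + peer*(x - mu)
               + moderator_main*s*w + interaction*w*(x - mu)
               + covariate effects + Normal(0, noise_sd*s)

    truncated to the outcome's scale bounds.  ``noise_sd`` is expressed as a
    fraction of the outcome's baseline SD so that one knob serves scales
    ranging from [-1, 1] to [0, 100].  The binary outcome uses the logistic
    analogue with the ``binary_*`` coefficients on the log-odds scale and the
    peer variable entered as the friend fraction.
    """

    intercept: float = 0.0
    autoregression: float = 0.5
    peer: float = 0.3
    moderator_main: float = 0.05
    interaction: float = 0.15
    covariate_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.8
    binary_autoregression: float = 1.5
    binary_peer: float = 1.0
    binary_moderator_main: float = 0.1
    binary_interaction: float = 0.3


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``classes_per_school`` and ``pupils_per_class`` may be a single int or a
    pair (setting A, setting B); the defaults (5, 4) x (24, 30) give 54
    classes and a 1,440-pupil roster across 12 schools.
    """

    n_schools: int = 12
    classes_per_school: int | tuple[int, int] = (5, 4)
    pupils_per_class: int | tuple[int, int] = (24, 30)
    setting_split: float = 0.5
    intervention_split: float = 0.5
    nomination_mean_outdegree: float = 5.0
    within_class_nomination_prob_ratio: float = 4.0
    same_gender_nomination_prob_ratio: float = 3.0
    outcome_specs: tuple[OutcomeSpec, ...] = ()
    moderator_specs: tuple[ModeratorSpec, ...] = ()
    dgp: DGPCoefficients = field(default_factory=DGPCoefficients)
    dgp_moderator: str = "pro_sociality"
    missing_rate: float = 0.07
    girl_fraction: float = 0.52
    seed: int = 0

    def __post_init__(self):
        if not self.outcome_specs:
            object.__setattr__(self, "outcome_specs", default_outcome_specs())
        if not self.moderator_specs:
            object.__setattr__(self, "moderator_specs", default_moderator_specs())

    def validate(self) -> None:
        if self.n_schools < 1:
            raise ConfigurationError("n_schools must be >= 1")
        for label, value in (
            ("classes_per_school", self.classes_per_school),
            ("pupils_per_class", self.pupils_per_class),
        ):
            for v in _as_pair(value):
                if v < 1:
                    raise ConfigurationError(f"{label} must be positive (got {v})")
        for p, label in (
            (self.setting_split, "setting_split"),
            (self.intervention_split, "intervention_split"),
            (self.missing_rate, "missing_rate"),
            (self.girl_fraction, "girl_fraction"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{label} must be in [0, 1] (got {p})")
        if self.nomination_mean_outdegree < 0:
            raise ConfigurationError("nomination_mean_outdegree must be non-negative")
        if self.nomination_mean_outdegree > NOMINATION_CAP:
            raise ConfigurationError(
                f"nomination_mean_outdegree exceeds the cap of {NOMINATION_CAP}"
            )
        if self.within_class_nomination_prob_ratio <= 0:
            raise ConfigurationError("within_class_nomination_prob_ratio must be positive")
        if self.same_gender_nomination_prob_ratio <= 0:
            raise ConfigurationError("same_gender_nomination_prob_ratio must be positive")
        for spec in self.outcome_specs:
            spec.validate()
        names = [s.name for s in self.outcome_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate outcome names")
        for spec in self.moderator_specs:
            spec.validate()
        if self.dgp_moderator not in {m.name for m in self.moderator_specs}:
            raise ConfigurationError(
                f"dgp_moderator {self.dgp_moderator!r} is not a declared moderator"
            )

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)

    @property
    def outcome_names(self) -> list[str]:
        return [s.name for s in self.outcome_specs]


def _as_pair(value) -> tuple[int, int]:
    if isinstance(value, (tuple, list)):
        if len(value) != 2:
            raise ConfigurationError("per-setting values must have exactly 2 entries")
        return int(value[0]), int(value[1])
    return int(value), int(value)


def default_outcome_specs() -> tuple[OutcomeSpec, ...]:
    """The default 46-outcome battery (45 continuous + binary susceptibility)."""
    E, SN, O = FAMILY_EXPERIMENTAL, FAMILY_SELF_REPORT_NORMS, FAMILY_OTHER
    rows = [
        # experimental injunctive norm items and scale (-1..+1)
        ("p2s2", -1, 1, -0.9, 0.3, E), ("p2s3", -1, 1, -0.7, 0.4, E),
        ("p2s4", -1, 1, -0.9, 0.3, E), ("p2s5", -1, 1, -0.4, 0.4, E),
        ("p2s6", -1, 1, -0.5, 0.4, E), ("p2s7", -1, 1, -0.5, 0.4, E),
        ("p2s8", -1, 1, -0.5, 0.4, E), ("p2s9", -1, 1, -0.8, 0.3, E),
        ("exp_injunctive_scale", -1, 1, -0.6, 0.2, E),
        # experimental descriptive norm items and scale (-1..+1)
        ("p3q1", -1, 1, -0.5, 0.5, E), ("p3q2", -1, 1, -0.4, 0.6, E),
        ("exp_descriptive_scale", -1, 1, -0.4, 0.5, E),
        # willingness to pay to support anti-smoking norms (tokens donated)
        ("donation", 0, 10, 3.7, 2.9, E),
        # self-report injunctive norm items and scale (-2..+2)
        ("in1", -2, 2, 1.7, 0.7, SN), ("in2", -2, 2, 1.9, 0.4, SN),
        ("in3", -2, 2, 1.7, 0.7, SN), ("in4", -2, 2, 1.4, 0.9, SN),
        ("in5", -2, 2, 1.4, 0.9, SN), ("in6", -2, 2, 1.4, 0.9, SN),
        ("in7", -2, 2, 1.6, 0.8, SN),
        ("sr_injunctive_scale", -2, 2, 1.6, 0.5, SN),
        # self-report descriptive norms 1 (1..5)
        ("dn1_1", 1, 5, 4.8, 0.7, SN), ("dn1_2", 1, 5, 4.4, 1.2, SN),
        ("dn1_3", 1, 5, 4.3, 1.3, SN), ("dn1_4", 1, 5, 4.7, 0.8, SN),
        ("dn1_5", 1, 5, 4.8, 0.7, SN),
        ("sr_descriptive_scale_1", 1, 5, 4.6, 0.6, SN),
        # self-report descriptive norms 2 (1..5)
        ("dn2_1", 1, 5, 4.7, 0.7, SN), ("dn2_2", 1, 5, 4.3, 1.0, SN),
        ("dn2_3", 1, 5, 4.8, 0.6, SN),
        ("sr_descriptive_scale_2", 1, 5, 4.6, 0.5, SN),
        # behaviour, intentions, knowledge, attitudes
        ("smoking_behavior", 1, 4, 3.8, 0.6, O),
        ("intentions", 1, 6, 5.6, 1.0, O),
        ("knowledge", 0, 6, 2.6, 1.5, O),
        ("attitudes", 1, 5, 3.9, 0.6, O),
        # self-efficacy to resist smoking subscales (1..6)
        ("se_emotional", 1, 6, 5.6, 0.8, O),
        ("se_friends", 1, 6, 5.6, 0.8, O),
        ("se_opportunity", 1, 6, 5.8, 0.6, O),
        # perceived risks / benefits (0..100)
        ("risk_physical", 0, 100, 60.9, 24.2, O),
        ("risk_social", 0, 100, 68.1, 26.8, O),
        ("risk_addiction", 0, 100, 35.2, 26.1, O),
        ("benefits", 0, 100, 23.6, 21.5, O),
        # perceived behavioural control (1..5)
        ("pbc_quit", 1, 5, 3.0, 1.4, O),
        ("pbc_avoid", 1, 5, 4.2, 1.2, O),
        # expelled-air carbon monoxide (ppm)
        ("co_reading", 0, 30, 2.5, 1.7, O),
    ]
    specs = [
        OutcomeSpec(name, lo, hi, mean, sd, family=fam)
        for name, lo, hi, mean, sd, fam in rows
    ]
    specs.append(
        OutcomeSpec(
            "susceptibility", 0, 1, 0.341, 0.0, is_binary=True,
            family=FAMILY_OTHER, follow_up_mean=0.382,
        )
    )
    return tuple(specs)


#: self-efficacy subscales are excluded as outcomes when one of them moderates
SELF_EFFICACY_OUTCOMES = ("se_emotional", "se_friends", "se_opportunity")
SELF_EFFICACY_MODERATORS = ("se_emotional", "se_friends", "se_opportunity")


def default_moderator_specs() -> tuple[ModeratorSpec, ...]:
    """Pupil-level dispositional moderators drawn at baseline."""
    rows = [
        ("rule_following", 0, 5, 3.1, 1.8),
        ("pro_sociality", 0, 10, 7.7, 2.1),
        ("fne", 1, 5, 2.7, 0.7),
        ("ntb", 1, 5, 3.0, 0.6),
        ("openness", 0, 4, 2.6, 0.7),
        ("extraversion", 0, 4, 2.6, 0.7),
        ("agreeableness", 0, 4, 2.6, 0.7),
        ("conscientiousness", 0, 4, 2.3, 0.7),
        ("emotional_stability", 0, 4, 2.0, 0.8),
    ]
    return tuple(
        ModeratorSpec(name, "continuous", lo, hi, mean, sd)
        for name, lo, hi, mean, sd in rows
    )


#: columns of the cohort table treated as dichotomous moderators (0/1 coding)
DICHOTOMOUS_MODERATORS = {
    "setting": ("NI", "Bogota"),       # 0 = NI, 1 = Bogota
    "intervention": ("ASSIST", "DeadCool"),  # 0 = ASSIST, 1 = DeadCool
    "gender": ("boy", "girl"),         # 0 = boy, 1 = girl / prefer not to say
}

#: per-wave network moderators (suffix _w0 / _w1 in the cohort table)
NETWORK_MODERATORS = (
    "clustering", "eigenvector", "closeness", "betweenness", "gini_degree",
)


def default_moderator_list() -> list[str]:
    """All moderators examined by the default run configuration."""
    return (
        ["setting", "intervention", "gender", "school_ses"]
        + [m.name for m in default_moderator_specs()]
        + list(NETWORK_MODERATORS)
        + list(SELF_EFFICACY_MODERATORS)
    )


#: hypothesized direction of moderation per moderator (+1: stronger peer
#: influence at higher values / level 1; -1: stronger at lower values; None:
#: exploratory)
HYPOTHESIZED_DIRECTIONS: dict[str, int | None] = {
    "setting": +1, "intervention": -1, "gender": +1, "school_ses": -1,
    "rule_following": +1, "pro_sociality": +1, "fne": +1, "ntb": +1,
    "openness": None, "extraversion": None, "agreeableness": None,
    "conscientiousness": None, "emotional_stability": None,
    "clustering": +1, "eigenvector": +1, "closeness": +1, "betweenness": +1,
    "gini_degree": -1, "se_emotional": -1, "se_friends": -1,
    "se_opportunity": -1,
}


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration."""

    synthetic: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_path: str | None = None
    nominations_path: str | None = None
    out_dir: str = "peermod_results"
    moderators: tuple[str, ...] = ()
    outcomes: tuple[str, ...] = ()
    peer_groups: tuple[str, ...] = ("friends", "class", "year")
    waves: tuple[int, ...] = (0, 1)
    symmetrization: str = "union"
    hc_variant: str = "HC1"
    alpha_sig: float = 0.01
    family_alpha: float = 0.05
    scale_metrics: bool = True
    plots: bool = False
    seed: int | None = None

    def __post_init__(self):
        if not self.moderators:
            object.__setattr__(self, "moderators", tuple(default_moderator_list()))
        if not self.outcomes:
            object.__setattr__(self, "outcomes", tuple(self.cohort.outcome_names))

    def validate(self) -> None:
        self.cohort.validate()
        for a, label in ((self.alpha_sig, "alpha_sig"), (self.family_alpha, "family_alpha")):
            if not 0.0 < a < 1.0:
                raise ConfigurationError(f"{label} must be in (0, 1)")
        if self.symmetrization not in ("union", "intersection", "directed"):
            raise ConfigurationError(f"unknown symmetrization {self.symmetrization!r}")
        if self.hc_variant not in ("HC0", "HC1", "HC3"):
            raise ConfigurationError(f"unknown HC variant {self.hc_variant!r}")
        if not self.synthetic and not (self.cohort_path and self.nominations_path):
            raise ConfigurationError(
                "non-synthetic mode requires cohort_path and nominations_path"
            )
        known = set(self.cohort.outcome_names)
        for name in self.outcomes:
            if name not in known:
                raise ConfigurationError(f"outcome {name!r} not in the cohort schema")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML file.

    Only scalar fields and the nested ``cohort`` section (scalar fields plus
    ``dgp``) are configurable from text; outcome/moderator spec overrides are
    done in Python.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cohort_raw = raw.pop("cohort", {}) or {}
    dgp_raw = cohort_raw.pop("dgp", {}) or {}
    cohort = CohortConfig(**cohort_raw, dgp=DGPCoefficients(**dgp_raw))
    for key in ("moderators", "outcomes", "peer_groups", "waves"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(cohort=cohort, **raw)
    cfg.validate()
    return cfg
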