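import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peermod.config import (
    CohortConfig,
    DGPCoefficients,
    ModeratorSpec,
    OutcomeSpec,
)
from peermod.moderation import FitResult, ModelSpec


def wide_outcome(name: str, mean: float = 0.0, sd: float = 1.0) -> OutcomeSpec:
    """Outcome with bounds far from the data so clipping never binds."""
    return OutcomeSpec(name, mean - 8 * sd, mean + 8 * sd, mean, sd)


def unit_moderator(name: str = "pro_sociality") -> ModeratorSpec:
    """Standard-normal moderator with effectively unbounded support."""
    return ModeratorSpec(name, "continuous", -8, 8, 0.0, 1.0)


def small_config(**overrides) -> CohortConfig:
    """Two-school cohort with three wide continuous outcomes."""
    base = dict(
        n_schools=2,
        classes_per_school=3,
        pupils_per_class=34,
        outcome_specs=(wide_outcome("y1"), wide_outcome("y2"), wide_outcome("y3")),
        moderator_specs=(unit_moderator(),),
        dgp_moderator="pro_sociality",
        dgp=DGPCoefficients(interaction=0.0, moderator_main=0.05),
        missing_rate=0.05,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    from peermod.synthetic import generate_cohort

    return generate_cohort(small_config(), seed=7)


def make_fit(
    b1: float,
    b3: float,
    v11: float,
    v33: float,
    v13: float,
    df: int = 100,
    family: str = "linear",
    moderator_kind: str = "continuous",
    moderator_sd: float = 1.0,
    moderator_range: tuple = (-3.0, 3.0),
) -> FitResult:
    """A FitResult with controlled focal terms, for probing/meta tests."""
    params = np.array([0.0, b1, 0.0, b3])
    cov = np.zeros((4, 4))
    cov[1, 1], cov[3, 3] = v11, v33
    cov[1, 3] = cov[3, 1] = v13
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, params / se, 0.0)
    if family == "logistic":
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df)
    return FitResult(
        spec=ModelSpec("y", family, "friends", 0, "w"),
        ok=True,
        n=df + 4,
        names=("const", "peer_exposure", "moderator", "interaction"),
        params=params,
        cov=cov,
        se=se,
        pvalues=p,
        df_resid=df,
        moderator_kind=moderator_kind,
        moderator_sd=moderator_sd,
        moderator_range=moderator_range,
    )


def hand_cohort() -> pd.DataFrame:
    """Tiny hand-written cohort for exposure arithmetic."""
    rows = [
        # pupil, school, class, y_w0
        ("a", "S1", "S1C1", 2.0),
        ("b", "S1", "S1C1", 4.0),
        ("c", "S1", "S1C1", 6.0),
        ("d", "S1", "S1C2", np.nan),
        ("e", "S1", "S1C2", 1.0),
        ("f", "S1", "S1C2", 3.0),
    ]
    df = pd.DataFrame(rows, columns=["pupil_id", "school_id", "class_id", "y_w0"])
    df["y_w1"] = df["y_w0"]
    return df


def nominations_frame(edges, wave=0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nominator_id": [a for a, _ in edges],
            "nominee_id": [b for _, b in edges],
            "wave": wave,
        }
    )
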