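"""Peer-exposure predictors: friend, class, and year-group averages.

For each focal pupil *i*, outcome, peer group and wave, the exposure is the
mean of peers' non-missing outcome values: the pupils *i* nominated as
friends at that wave (directed out-neighbours), *i*'s classmates excluding
*i*, or *i*'s school year group excluding *i*.  For the binary outcome the
percentage (0-100) of contributing peers with the outcome is used instead.
Exposures with zero contributing peers are missing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "friend_mean",
    "class_mean_excluding_self",
    "year_mean_excluding_self",
    "peer_percentage",
    "build_exposure_table",
]


def _outcome_column(cohort: pd.DataFrame, outcome: str, wave: int) -> pd.Series:
    col = f"{outcome}_w{wave}"
    if col not in cohort.columns:
        raise KeyError(f"unknown outcome {outcome!r} at wave {wave}")
    return cohort[col].astype(float)


def friend_mean(
    cohort: pd.DataFrame,
    nominations: pd.DataFrame,
    outcome: str,
    wave: int,
) -> pd.DataFrame:
    """Mean outcome over each pupil's nominated friends at the given wave.

    Friends with missing values do not contribute; a pupil whose contributing
    friend count is zero has a missing exposure.  Returns a frame indexed by
    pupil_id with ``exposure`` and ``n_peers`` columns.
    """
    values = _outcome_column(cohort, outcome, wave)
    lookup = pd.Series(values.to_numpy(), index=cohort.pupil_id)
    sub = nominations[nominations["wave"] == wave]
    peer_vals = lookup.reindex(sub["nominee_id"]).to_numpy()
    frame = pd.DataFrame(
        {"nominator_id": sub["nominator_id"].to_numpy(), "value": peer_vals}
    ).dropna(subset=["value"])
    grouped = frame.groupby("nominator_id")["value"].agg(["mean", "count"])
    out = pd.DataFrame(index=pd.Index(cohort.pupil_id, name="pupil_id"))
    out["exposure"] = grouped["mean"].reindex(out.index)
    out["n_peers"] = grouped["count"].reindex(out.index).fillna(0).astype(int)
    return out


def _group_mean_excluding_self(cohort, outcome, wave, group_col):
    values = _outcome_column(cohort, outcome, wave).to_numpy()
    ok = ~np.isnan(values)
    df = pd.DataFrame(
        {
            "group": cohort[group_col].to_numpy(),
            "value": np.where(ok, values, 0.0),
            "ok": ok.astype(float),
        }
    )
    sums = df.groupby("group")["value"].transform("sum").to_numpy()
    counts = df.groupby("group")["ok"].transform("sum").to_numpy()
    own = np.where(ok, values, 0.0)
    n_excl = counts - ok
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (sums - own) / n_excl
    mean[n_excl == 0] = np.nan
    singletons = int((counts - ok == 0).sum())
    if singletons:
        log.info(
            "%s wave %s (%s): %d pupil(s) with no contributing group peers",
            outcome, wave, group_col, singletons,
        )
    out = pd.DataFrame(index=pd.Index(cohort.pupil_id, name="pupil_id"))
    out["exposure"] = mean
    out["n_peers"] = n_excl.astype(int)
    return out


def class_mean_excluding_self(cohort, outcome, wave) -> pd.DataFrame:
    """Mean outcome over classmates other than the focal pupil."""
    return _group_mean_excluding_self(cohort, outcome, wave, "class_id")


def year_mean_excluding_self(cohort, outcome, wave) -> pd.DataFrame:
    """Mean outcome over the school year group, excluding the focal pupil."""
    return _group_mean_excluding_self(cohort, outcome, wave, "school_id")


def peer_percentage(
    cohort, outcome, peer_group, wave, nominations=None
) -> pd.DataFrame:
    """Percentage (0-100) of contributing peers positive on a binary outcome."""
    values = _outcome_column(cohort, outcome, wave).dropna()
    bad = ~values.isin((0.0, 1.0))
    if bad.any():
        raise ValueError(f"outcome {outcome!r} is not binary")
    out = _exposure_for_group(cohort, nominations, outcome, peer_group, wave)
    out["exposure"] = out["exposure"] * 100.0
    return out


def _exposure_for_group(cohort, nominations, outcome, peer_group, wave):
    if peer_group == "friends":
        if nominations is None:
            raise ValueError("friend exposures require a nomination list")
        return friend_mean(cohort, nominations, outcome, wave)
    if peer_group == "class":
        return class_mean_excluding_self(cohort, outcome, wave)
    if peer_group == "year":
        return year_mean_excluding_self(cohort, outcome, wave)
    raise ValueError(f"unknown peer group {peer_group!r}")


def build_exposure_table(
    cohort: pd.DataFrame,
    nominations: pd.DataFrame,
    outcomes: list[str],
    binary_outcomes: set[str] | frozenset[str] = frozenset(),
    peer_groups=("friends", "class", "year"),
    waves=(0, 1),
) -> pd.DataFrame:
    """Long exposure table keyed by (pupil, outcome, peer_group, wave).

    Binary outcomes are expressed as percentages; all others as means on the
    outcome scale.
    """
    parts = []
    for outcome in outcomes:
        binary = outcome in binary_outcomes
        for group in peer_groups:
            for wave in waves:
                if binary:
                    part = peer_percentage(cohort, outcome, group, wave, nominations)
                else:
                    part = _exposure_for_group(cohort, nominations, outcome, group, wave)
                part = part.reset_index()
                part.insert(1, "outcome", outcome)
                part.insert(2, "peer_group", group)
                part.insert(3, "wave", wave)
                parts.append(part)
    return pd.concat(parts, ignore_index=True)
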