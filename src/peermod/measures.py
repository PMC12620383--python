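"""Scale scoring, reliability, and moderator recoding."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["ScaleDefinition", "score_scale", "cronbach_alpha", "derive_school_ses"]


@dataclass(frozen=True)
class ScaleDefinition:
    """A multi-item scale scored as the mean of its items."""

    name: str
    items: tuple[str, ...]
    scale_min: float
    scale_max: float
    min_items: int = 1

    def __post_init__(self):
        if not self.items:
            raise ValueError(f"scale {self.name!r}: item list is empty")
        if not self.scale_min < self.scale_max:
            raise ValueError(f"scale {self.name!r}: bounds out of order")
        if not 1 <= self.min_items <= len(self.items):
            raise ValueError(f"scale {self.name!r}: invalid min_items")


def score_scale(item_values: pd.DataFrame, definition: ScaleDefinition) -> pd.Series:
    """Score a scale as the mean of non-missing items.

    Rows with fewer than ``definition.min_items`` answered items score as
    missing.  An item value outside the declared bounds raises ``ValueError``
    naming the offending item.
    """
    data = item_values[list(definition.items)]
    for item in definition.items:
        col = data[item]
        bad = col.notna() & ((col < definition.scale_min) | (col > definition.scale_max))
        if bad.any():
            raise ValueError(
                f"item {item!r} has values outside "
                f"[{definition.scale_min}, {definition.scale_max}]"
            )
    answered = data.notna().sum(axis=1)
    scores = data.mean(axis=1)
    scores[answered < definition.min_items] = np.nan
    scores.name = definition.name
    return scores


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha, complete-case, sample (ddof=1) variances.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(total score)).
    Returns NaN (with a warning) when the total-score variance is zero.
    """
    X = pd.DataFrame(item_matrix).dropna().to_numpy(dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("cronbach_alpha requires at least 2 items")
    if n < 3:
        raise ValueError("cronbach_alpha requires at least 3 complete rows")
    item_var = X.var(axis=0, ddof=1).sum()
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        warnings.warn("zero total-score variance: alpha undefined", stacklevel=2)
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def derive_school_ses(
    deprivation_scores: dict[str, float],
    higher_means_more_deprived: bool = True,
) -> dict[str, int]:
    """Quartile a school-level deprivation measure into ordinal SES 1-4.

    Category 1 is the lowest SES (most deprived quartile) and 4 the highest,
    matching the orientation of the setting-B index.  Quartiles use inclusive
    linear-interpolation quantiles; a score tied with a quartile boundary is
    assigned to the lower SES category.  Accepts any monotone deprivation
    measure; set ``higher_means_more_deprived=False`` for rank-style measures
    where larger values mean less deprived.
    """
    if len(deprivation_scores) < 4:
        log.warning(
            "derive_school_ses called with %d schools (<4); quartiles are degenerate",
            len(deprivation_scores),
        )
    keys = list(deprivation_scores)
    vals = np.asarray([deprivation_scores[k] for k in keys], dtype=float)
    dep = vals if higher_means_more_deprived else -vals
    q1, q2, q3 = np.quantile(dep, [0.25, 0.5, 0.75], method="linear")
    # more deprived -> lower SES; ties at a boundary fall to the lower category
    cats = 4 - (dep >= q1).astype(int) - (dep >= q2).astype(int) - (dep >= q3).astype(int)
    n_tied = int(np.sum((dep == q1) | (dep == q2) | (dep == q3)))
    if n_tied:
        log.info("derive_school_ses: %d score(s) tied with a quartile boundary", n_tied)
    return dict(zip(keys, (int(c) for c in cats)))
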