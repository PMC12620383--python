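"""Per-moderator aggregation of the model grid.

Significance tallies with direction, Holm-Bonferroni step-down adjustment,
exact one-sided binomial meta-tests of whether the number of significant
interactions exceeds the chance expectation at the grid's significance
criterion, and multiverse-style descriptive summaries (p-value distribution,
volcano coordinates, heatmap cells).  Models that failed to fit count in the
denominator as non-significant: the grid size is fixed by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .config import HYPOTHESIZED_DIRECTIONS
from .moderation import FitResult

__all__ = [
    "holm_bonferroni",
    "binomial_meta_test",
    "ModeratorSummary",
    "MultiverseSummary",
    "summarize_moderator",
    "multiverse_tables",
]


def holm_bonferroni(p_values, family_alpha: float = 0.05):
    """Holm step-down adjustment.

    Adjusted p_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)) over the ascending
    order; rejections are adjusted <= family_alpha.  Returns
    ``(reject, adjusted)`` in the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    factors = m - np.arange(m)
    adj_sorted = np.minimum(1.0, factors * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted <= family_alpha, adjusted


def binomial_meta_test(n_models: int, k_sig: int, p0: float = 0.01) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0).

    Computed by log-space summation of the binomial mass for numerical
    stability at large n and small p0.
    """
    if not 0 <= k_sig <= n_models:
        raise ValueError(f"need 0 <= k <= n (got k={k_sig}, n={n_models})")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if k_sig == 0:
        return 1.0
    i = np.arange(k_sig, n_models + 1)
    log_terms = (
        gammaln(n_models + 1) - gammaln(i + 1) - gammaln(n_models - i + 1)
        + i * np.log(p0) + (n_models - i) * np.log1p(-p0)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


@dataclass
class ModeratorSummary:
    """Evidence summary for one moderator across its model grid."""

    moderator: str
    n_models: int
    k_sig: int
    k_sig_by_group: dict[str, int]
    k_positive: int  # significant interactions with positive coefficient
    k_negative: int
    n_unfit: int
    binomial_p: float
    binomial_p_positive: float
    binomial_p_negative: float
    holm_n_rejected: int
    holm_flags: list[bool] = field(repr=False)
    alpha_sig: float = 0.01
    family_alpha: float = 0.05
    conclusion: str = ""

    @property
    def percent_sig(self) -> float:
        return 100.0 * self.k_sig / self.n_models if self.n_models else np.nan


def _conclusion(moderator: str, p_total: float, p_pos: float, p_neg: float) -> str:
    hypothesized = HYPOTHESIZED_DIRECTIONS.get(moderator)
    if p_total > 0.05:
        return "not a significant moderator"
    direction = ""
    if p_pos <= 0.05 and p_neg > 0.05:
        direction = "peer influence stronger at higher moderator values"
    elif p_neg <= 0.05 and p_pos > 0.05:
        direction = "peer influence stronger at lower moderator values"
    else:
        direction = "no indication of overall direction"
    label = f"significant moderator; {direction}"
    if hypothesized is not None and direction != "no indication of overall direction":
        matches = (hypothesized > 0) == ("higher" in direction)
        label += " (consistent with hypothesis)" if matches else " (opposite to hypothesis)"
    return label


def summarize_moderator(
    fits: list[FitResult],
    alpha_sig: float = 0.01,
    family_alpha: float = 0.05,
    p0: float | None = None,
) -> ModeratorSummary:
    """Tally one moderator's grid and run the binomial meta-tests.

    Unfit models are counted in ``n_models`` with a missing p treated as
    non-significant.  Directional binomial tests use the full grid size as n,
    not the significant count.
    """
    moderators = {f.spec.moderator for f in fits}
    if len(moderators) != 1:
        raise ValueError(f"mixed moderators in input: {sorted(moderators)}")
    (moderator,) = moderators
    p0 = alpha_sig if p0 is None else p0

    n_models = len(fits)
    sig = [f for f in fits if f.significant(alpha_sig)]
    k_sig = len(sig)
    k_pos = sum(1 for f in sig if f.interaction_coef > 0)
    k_neg = sum(1 for f in sig if f.interaction_coef < 0)
    by_group: dict[str, int] = {}
    for f in sig:
        by_group[f.spec.peer_group] = by_group.get(f.spec.peer_group, 0) + 1

    # Holm over the grid's interaction p-values (unfit -> p=1, never rejected)
    pvals = np.array(
        [f.interaction_p if f.ok else 1.0 for f in fits], dtype=float
    )
    reject, _ = holm_bonferroni(pvals, family_alpha)

    p_total = binomial_meta_test(n_models, k_sig, p0)
    p_pos = binomial_meta_test(n_models, k_pos, p0)
    p_neg = binomial_meta_test(n_models, k_neg, p0)
    return ModeratorSummary(
        moderator=moderator,
        n_models=n_models,
        k_sig=k_sig,
        k_sig_by_group=by_group,
        k_positive=k_pos,
        k_negative=k_neg,
        n_unfit=sum(1 for f in fits if not f.ok),
        binomial_p=p_total,
        binomial_p_positive=p_pos,
        binomial_p_negative=p_neg,
        holm_n_rejected=int(reject.sum()),
        holm_flags=list(reject),
        alpha_sig=alpha_sig,
        family_alpha=family_alpha,
        conclusion=_conclusion(moderator, p_total, p_pos, p_neg),
    )


@dataclass
class MultiverseSummary:
    """Descriptive multiverse summaries for one moderator's grid."""

    moderator: str
    p_values: np.ndarray
    mean_p: float
    median_p: float
    prop_le_01: float
    prop_le_05: float
    volcano: pd.DataFrame  # beta_std, p, neg_log10_p (linear models only)
    grid: pd.DataFrame  # per (outcome, peer_group, wave): beta_std, p
    heatmap: pd.DataFrame  # per (moderator, outcome): percent of models p<=0.01


def multiverse_tables(fits: list[FitResult], alpha_sig: float = 0.01) -> MultiverseSummary:
    """Multiverse-style summary of one moderator's grid.

    Logistic models are excluded from the volcano/standardized-coefficient
    views (no standardized coefficient on the outcome-SD scale) but included
    in the p-value summaries and the heatmap.
    """
    moderators = {f.spec.moderator for f in fits}
    if len(moderators) != 1:
        raise ValueError("multiverse_tables expects a single moderator's grid")
    (moderator,) = moderators

    fitted = [f for f in fits if f.ok]
    p = np.array([f.interaction_p for f in fitted], dtype=float)

    linear = [f for f in fitted if f.spec.family == "linear"]
    volcano = pd.DataFrame(
        {
            "outcome": [f.spec.outcome for f in linear],
            "peer_group": [f.spec.peer_group for f in linear],
            "wave": [f.spec.wave for f in linear],
            "beta_std": [f.beta_std for f in linear],
            "p": [f.interaction_p for f in linear],
        }
    )
    volcano["neg_log10_p"] = -np.log10(volcano["p"].clip(lower=1e-300))

    grid = pd.DataFrame(
        {
            "outcome": [f.spec.outcome for f in fitted],
            "peer_group": [f.spec.peer_group for f in fitted],
            "wave": [f.spec.wave for f in fitted],
            "family": [f.spec.family for f in fitted],
            "beta_std": [
                f.beta_std if f.beta_std is not None else np.nan for f in fitted
            ],
            "p": [f.interaction_p for f in fitted],
        }
    )

    cells = []
    all_df = pd.DataFrame(
        {
            "outcome": [f.spec.outcome for f in fits],
            "sig": [f.significant(alpha_sig) for f in fits],
        }
    )
    for outcome, sub in all_df.groupby("outcome", sort=True):
        cells.append(
            {
                "moderator": moderator,
                "outcome": outcome,
                "n_models": len(sub),
                "k_sig": int(sub.sig.sum()),
                "percent_sig": 100.0 * sub.sig.mean(),
            }
        )
    heatmap = pd.DataFrame(cells)

    return MultiverseSummary(
        moderator=moderator,
        p_values=p,
        mean_p=float(np.mean(p)) if p.size else np.nan,
        median_p=float(np.median(p)) if p.size else np.nan,
        prop_le_01=float(np.mean(p <= 0.01)) if p.size else np.nan,
        prop_le_05=float(np.mean(p <= 0.05)) if p.size else np.nan,
        volcano=volcano,
        grid=grid,
        heatmap=heatmap,
    )


def summary_frame(summaries: list[ModeratorSummary]) -> pd.DataFrame:
    """Moderator-overview table (one row per moderator)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "moderator": s.moderator,
                "n_models": s.n_models,
                "k_sig": s.k_sig,
                "percent_sig": s.percent_sig,
                "k_friends": s.k_sig_by_group.get("friends", 0),
                "k_class": s.k_sig_by_group.get("class", 0),
                "k_year": s.k_sig_by_group.get("year", 0),
                "k_positive": s.k_positive,
                "k_negative": s.k_negative,
                "n_unfit": s.n_unfit,
                "binomial_p": s.binomial_p,
                "binomial_p_positive": s.binomial_p_positive,
                "binomial_p_negative": s.binomial_p_negative,
                "holm_n_rejected": s.holm_n_rejected,
                "conclusion": s.conclusion,
            }
        )
    return pd.DataFrame(rows)
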