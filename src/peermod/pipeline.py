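"""End-to-end orchestration: cohort -> networks -> exposures -> model grids
-> probing -> meta-summaries, with delimited-text outputs and a provenance
log."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import NETWORK_MODERATORS, RunConfig
from .meta import (
    ModeratorSummary,
    MultiverseSummary,
    multiverse_tables,
    summarize_moderator,
    summary_frame,
)
from .moderation import ExposureStore, FitResult, results_frame, run_model_grid
from .networks import build_network, node_metrics_table, school_summary
from .probing import johnson_neyman, simple_slopes
from .synthetic import generate_cohort

log = logging.getLogger(__name__)

__all__ = ["ResultBundle", "run_pipeline", "load_inputs", "attach_network_moderators"]


@dataclass
class ResultBundle:
    """In-memory results of one pipeline run."""

    config: RunConfig
    cohort: pd.DataFrame
    nominations: pd.DataFrame
    node_metrics: pd.DataFrame
    school_summaries: pd.DataFrame
    fits: dict[str, list[FitResult]]
    model_results: pd.DataFrame
    summaries: dict[str, ModeratorSummary]
    multiverse: dict[str, MultiverseSummary]
    probing: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def load_inputs(config: RunConfig, seed: int | None = None):
    """Obtain the cohort table and nomination list (synthetic or from disk)."""
    if config.synthetic:
        cohort_cfg = config.cohort
        if seed is not None:
            cohort_cfg = cohort_cfg.with_(seed=seed)
        elif config.seed is not None:
            cohort_cfg = cohort_cfg.with_(seed=config.seed)
        return generate_cohort(cohort_cfg)
    for path, label in (
        (config.cohort_path, "cohort table"),
        (config.nominations_path, "nomination list"),
    ):
        if not Path(path).exists():
            raise FileNotFoundError(f"{label} not found: {path}")
    cohort = pd.read_csv(config.cohort_path)
    nominations = pd.read_csv(config.nominations_path)
    required = {"pupil_id", "school_id", "class_id"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    required_nom = {"nominator_id", "nominee_id", "wave"}
    missing = required_nom - set(nominations.columns)
    if missing:
        raise ValueError(f"nomination list is missing columns: {sorted(missing)}")
    return cohort, nominations


def compute_network_tables(cohort, nominations, waves=(0, 1), symmetrization="union",
                           scale=10.0):
    """Per-school networks at each wave -> node metrics and school summaries."""
    node_parts, school_rows = [], []
    for school_id, school in cohort.groupby("school_id", sort=True):
        roster = school.pupil_id.tolist()
        noms = nominations[nominations.nominator_id.isin(roster)]
        for wave in waves:
            net = build_network(noms, roster, wave, symmetrization, school_id)
            node_parts.append(node_metrics_table(net, scale))
            school_rows.append(school_summary(net, scale))
    node_metrics = pd.concat(node_parts, ignore_index=True)
    school_summaries = pd.DataFrame(school_rows)
    return node_metrics, school_summaries


def attach_network_moderators(cohort, node_metrics, school_summaries) -> pd.DataFrame:
    """Add per-wave network moderator columns (<metric>_w<wave>) to the cohort."""
    cohort = cohort.copy()
    for wave, sub in node_metrics.groupby("wave"):
        indexed = sub.set_index("pupil_id")
        for metric in ("clustering", "eigenvector", "closeness", "betweenness"):
            cohort[f"{metric}_w{wave}"] = cohort.pupil_id.map(indexed[metric])
    for wave, sub in school_summaries.groupby("wave"):
        gini = sub.set_index("school_id")["gini_degree"]
        cohort[f"gini_degree_w{wave}"] = cohort.school_id.map(gini)
    return cohort


def _probe_significant(fits: dict[str, list[FitResult]], alpha: float) -> pd.DataFrame:
    """Simple slopes and JN regions for every significant interaction."""
    rows = []
    for moderator, fit_list in fits.items():
        for fit in fit_list:
            if not fit.significant(alpha):
                continue
            slopes = simple_slopes(fit)
            regions = {lvl: johnson_neyman(fit, lvl) for lvl in (95, 99)}
            for s in slopes:
                rows.append(
                    {
                        "moderator": moderator,
                        "outcome": fit.spec.outcome,
                        "peer_group": fit.spec.peer_group,
                        "wave": fit.spec.wave,
                        "record": "slope",
                        "level": s.level,
                        "moderator_value": s.moderator_value,
                        "estimate": s.slope,
                        "se": s.se,
                        "ci_low": s.ci_low,
                        "ci_high": s.ci_high,
                        "p_value": s.p_value,
                    }
                )
            for lvl, region in regions.items():
                rows.append(
                    {
                        "moderator": moderator,
                        "outcome": fit.spec.outcome,
                        "peer_group": fit.spec.peer_group,
                        "wave": fit.spec.wave,
                        "record": f"jn_{lvl}",
                        "level": ";".join(f"{b:.6g}" for b in region.boundaries),
                        "moderator_value": np.nan,
                        "estimate": np.nan,
                        "se": np.nan,
                        "ci_low": region.moderator_range[0],
                        "ci_high": region.moderator_range[1],
                        "p_value": np.nan,
                    }
                )
    columns = [
        "moderator", "outcome", "peer_group", "wave", "record", "level",
        "moderator_value", "estimate", "se", "ci_low", "ci_high", "p_value",
    ]
    return pd.DataFrame(rows, columns=columns)


def run_pipeline(
    config: RunConfig,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    write: bool = True,
) -> ResultBundle:
    """Execute every stage and (optionally) write the result bundle.

    Deterministic for a fixed (config, seed).  Per-model failures are
    collected on the FitResults; schema problems fail fast.
    """
    config.validate()
    cohort, nominations = load_inputs(config, seed)
    scale = 10.0 if config.scale_metrics else 1.0
    node_metrics, school_summaries = compute_network_tables(
        cohort, nominations, config.waves, config.symmetrization, scale
    )
    cohort = attach_network_moderators(cohort, node_metrics, school_summaries)

    binary = {
        s.name for s in config.cohort.outcome_specs if s.is_binary
    }
    exposures = ExposureStore(cohort, nominations, binary)

    fits: dict[str, list[FitResult]] = {}
    summaries: dict[str, ModeratorSummary] = {}
    multiverse: dict[str, MultiverseSummary] = {}
    for moderator in config.moderators:
        grid = run_model_grid(
            moderator, cohort, exposures, config.outcomes, binary,
            config.peer_groups, config.waves, config.hc_variant, config.alpha_sig,
        )
        fits[moderator] = grid
        summaries[moderator] = summarize_moderator(
            grid, config.alpha_sig, config.family_alpha
        )
        multiverse[moderator] = multiverse_tables(grid, config.alpha_sig)

    model_results = pd.concat(
        [results_frame(grid) for grid in fits.values()], ignore_index=True
    )
    probing = _probe_significant(fits, config.alpha_sig)

    provenance = {
        "peermod_version": __version__,
        "seed": seed if seed is not None else config.seed,
        "symmetrization": config.symmetrization,
        "hc_variant": config.hc_variant,
        "alpha_sig": config.alpha_sig,
        "family_alpha": config.family_alpha,
        "metric_scale": scale,
        "friend_set": "directed out-neighbours at the peer-measurement wave",
        "n_models_total": int(len(model_results)),
        "config": dataclasses.asdict(config),
    }
    bundle = ResultBundle(
        config=config,
        cohort=cohort,
        nominations=nominations,
        node_metrics=node_metrics,
        school_summaries=school_summaries,
        fits=fits,
        model_results=model_results,
        summaries=summaries,
        multiverse=multiverse,
        probing=probing,
        provenance=provenance,
    )
    if write:
        target = Path(out_dir) if out_dir is not None else Path(config.out_dir)
        write_bundle(bundle, target)
    return bundle


def write_bundle(bundle: ResultBundle, out_dir: Path) -> None:
    """Write the bundle as CSV tables + JSON provenance (figures optional)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.cohort.to_csv(out_dir / "cohort.csv", index=False)
    bundle.nominations.to_csv(out_dir / "nominations.csv", index=False)
    bundle.node_metrics.to_csv(out_dir / "node_metrics.csv", index=False)
    bundle.school_summaries.to_csv(out_dir / "school_summaries.csv", index=False)
    bundle.model_results.to_csv(out_dir / "model_results.csv", index=False)
    summary_frame(list(bundle.summaries.values())).to_csv(
        out_dir / "moderator_summaries.csv", index=False
    )
    bundle.probing.to_csv(out_dir / "probing.csv", index=False)
    heatmap = pd.concat(
        [m.heatmap for m in bundle.multiverse.values()], ignore_index=True
    )
    heatmap.to_csv(out_dir / "heatmap.csv", index=False)
    with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.provenance, fh, indent=2, default=str)
    if bundle.config.plots:
        from .plots import render_figures

        render_figures(bundle, out_dir / "figures")
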