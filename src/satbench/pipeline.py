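"""End-to-end assembly: trial tables and prediction tables -> metric report.

The stages, in the analysis order: observer QC -> warm-up discard ->
imputation -> per-observer SAT curves -> normalization by untimed accuracy
-> timestep mapping of model curves -> metrics.  Stage record counts are
logged so every exclusion is auditable.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from .curves import (
    SATCurve,
    compute_curve,
    discard_warmup,
    filter_observers,
    impute_missing,
    map_timesteps,
    model_curves,
    normalize_curve,
    to_family,
    untimed_accuracy,
)
from .design import ExperimentDesign
from .io import ModelPrediction, TrialRecord
from .metrics import MetricReport, ObserverCurves, benchmark

log = logging.getLogger(__name__)

__all__ = ["human_observer_curves", "model_observer_curves", "run_benchmark"]


def _category_curves(
    trials: Sequence[TrialRecord], level: float | None, baseline: float | None
) -> dict[str, SATCurve]:
    """Per-category curves for the category-wise correlation metric.

    By default all conditions of the experiment contribute, keeping every
    (category, latency) cell populated; pass a level to restrict."""
    sub = trials if level is None else [t for t in trials if t.perturbation_level == level]
    curves = compute_curve(sub, group=("true_category",))
    out: dict[str, SATCurve] = {}
    for cv in curves:
        if baseline is not None:
            cv = normalize_curve(cv, baseline)
        out[str(cv.label["true_category"])] = cv
    return out


def human_observer_curves(
    trials: Sequence[TrialRecord],
    design: ExperimentDesign | None = None,
    impute_mode: str = "random",
    seed: int = 0,
    normalize: bool = True,
    per_observer_baseline: bool = False,
    with_categories: bool = True,
    category_level: float | None = None,
) -> tuple[dict[str, ObserverCurves], dict]:
    """Run QC, imputation and aggregation; return curves per kept observer.

    The normalization baseline is the experiment-level mean training
    accuracy of the kept observers (the group curves are normalized by one
    common untimed accuracy); ``per_observer_baseline`` switches to each
    observer's own training accuracy.  Returns the curves and a stage-count
    dict (observers kept/excluded, trials discarded/imputed).
    """
    design = design or ExperimentDesign()
    n_total = len(trials)
    kept, excluded = filter_observers(trials, design)
    kept = discard_warmup(kept, design)
    n_after_warmup = len(kept)
    n_missing = sum(1 for t in kept if t.is_timed and t.missing)
    kept = impute_missing(kept, mode=impute_mode, seed=seed, design=design)
    counts = {
        "trials_total": n_total,
        "observers_excluded": len(excluded),
        "trials_after_warmup_discard": n_after_warmup,
        "trials_missing": n_missing,
        "imputation_mode": impute_mode,
    }
    observers = sorted({t.observer_id for t in kept})
    counts["observers_kept"] = len(observers)
    if not observers:
        raise ValueError("no observers survive quality control")
    pooled_baseline = untimed_accuracy(kept) if normalize else None
    out: dict[str, ObserverCurves] = {}
    for obs in observers:
        mine = [t for t in kept if t.observer_id == obs]
        baseline = None
        if normalize:
            baseline = untimed_accuracy(mine) if per_observer_baseline else pooled_baseline
        curves = compute_curve(mine, group=("perturbation_kind", "perturbation_level"))
        if baseline is not None:
            curves = [normalize_curve(cv, baseline) for cv in curves]
        family = to_family(curves)
        cats = _category_curves(mine, category_level, baseline) if with_categories else None
        out[obs] = ObserverCurves(family=family, by_category=cats)
    return out, counts


def model_observer_curves(
    preds: Sequence[ModelPrediction],
    design: ExperimentDesign | None = None,
    baseline: float | None = None,
    mapping_mode: str = "index",
    reference: SATCurve | Mapping[float, SATCurve] | None = None,
    with_categories: bool = True,
    category_level: float | None = None,
) -> ObserverCurves:
    """Aggregate a prediction table into mapped, normalized model curves.

    Timesteps are placed on the human reaction-time axis (index mapping by
    default) and accuracies optionally divided by the human untimed
    baseline so model and human curves live in the same units.
    """
    design = design or ExperimentDesign()

    def ref_for(cv: SATCurve) -> SATCurve | None:
        if isinstance(reference, Mapping):
            return reference.get(float(cv.label.get("perturbation_level", 0.0)),
                                 reference.get(0.0))
        return reference

    curves = model_curves(preds, group=("perturbation_kind", "perturbation_level"))
    if baseline is not None:
        curves = [normalize_curve(cv, baseline) for cv in curves]
    if mapping_mode == "affine":
        curves = _affine_map_jointly(curves, design, ref_for)
    else:
        curves = [map_timesteps(cv, design, mode=mapping_mode) for cv in curves]
    family = to_family(curves)
    cats = None
    if with_categories:
        cat_preds = (
            preds if category_level is None
            else [p for p in preds if p.perturbation_level == category_level]
        )
        cat_curves = model_curves(cat_preds, group=("true_category",))
        if baseline is not None:
            cat_curves = [normalize_curve(cv, baseline) for cv in cat_curves]
        if mapping_mode == "affine":
            cat_curves = _affine_map_jointly(cat_curves, design, ref_for)
        else:
            cat_curves = [map_timesteps(cv, design, mode=mapping_mode) for cv in cat_curves]
        cats = {str(cv.label["true_category"]): cv for cv in cat_curves}
    return ObserverCurves(family=family, by_category=cats)


def _affine_map_jointly(
    curves: Sequence[SATCurve],
    design: ExperimentDesign,
    ref_for,
) -> list[SATCurve]:
    """Fit one affine timestep->ms map (a*i + b, a > 0) for a whole model.

    The residuals of every curve against its reference (the average human
    curve at the matching level, linearly interpolated at the mapped times)
    are stacked, so speed and delay are shared across conditions, as a
    single network has a single clock.  The mapped curves are then re-
    gridded onto the design's beep latencies by linear interpolation so
    model and human families share one time axis.
    """
    from scipy.optimize import least_squares
    from dataclasses import replace as _replace

    refs = [ref_for(cv) for cv in curves]
    if any(r is None for r in refs) or all(
        float(np.ptp(r.metric_points()[1])) < 1e-9 for r in refs
    ):
        log.warning("affine mapping unidentified; falling back to index mode")
        return [map_timesteps(cv, design, mode="index") for cv in curves]

    def resid(x):
        a, b = x
        parts = []
        for cv, ref in zip(curves, refs):
            rt, ra = ref.metric_points()
            mapped = a * np.asarray(cv.times) + b
            parts.append(np.interp(mapped, rt, ra) - np.asarray(cv.accuracies))
        return np.concatenate(parts)

    lat = np.asarray(design.beep_latencies_ms, dtype=float)
    steps0 = np.asarray(curves[0].times)
    k = min(len(steps0), len(lat))
    a0, b0 = np.polyfit(steps0[:k], lat[:k], 1)
    sol = least_squares(resid, [max(a0, 1.0), b0],
                        bounds=([1e-9, -np.inf], [np.inf, np.inf]))
    a, b = sol.x
    out = []
    for cv in curves:
        mapped = a * np.asarray(cv.times) + b
        acc = np.interp(lat, mapped, np.asarray(cv.accuracies))
        out.append(_replace(cv, times=tuple(lat), accuracies=tuple(acc),
                            n_trials=None, se=None))
    return out


def run_benchmark(
    human_trials: Mapping[str, Sequence[TrialRecord]] | Sequence[TrialRecord],
    model_predictions: Mapping[str, Sequence[ModelPrediction]],
    design: ExperimentDesign | None = None,
    impute_mode: str = "random",
    seed: int = 0,
    normalize: bool = True,
    mapping_mode: str = "index",
    with_categories: bool = True,
    steepness_scale: str = "loglog",
    steepness_grid_n: int = 101,
) -> tuple[MetricReport, dict]:
    """Full pipeline: QC'd human curves vs mapped model curves -> report."""
    design = design or ExperimentDesign()
    if isinstance(human_trials, Mapping):
        all_trials = [t for ts in human_trials.values() for t in ts]
    else:
        all_trials = list(human_trials)
    humans, counts = human_observer_curves(
        all_trials,
        design,
        impute_mode=impute_mode,
        seed=seed,
        normalize=normalize,
        with_categories=with_categories,
    )
    baseline = None
    if normalize:
        kept_ids = set(humans)
        baseline = untimed_accuracy([t for t in all_trials if t.observer_id in kept_ids])
    reference = None
    if mapping_mode == "affine":
        # average human curve per perturbation level anchors the fit
        fams = [humans[h].family for h in sorted(humans)]
        avg_c = np.mean([f.c for f in fams], axis=0)
        f0 = fams[0]
        reference = {
            level: SATCurve(
                label={"perturbation_level": level, "observer_id": "average_human"},
                times=f0.times,
                accuracies=tuple(avg_c[i]),
                normalized=normalize,
                baseline=baseline,
            )
            for i, level in enumerate(f0.perturbation_levels)
        }
    models: dict[str, ObserverCurves] = {}
    for mid, preds in model_predictions.items():
        models[mid] = model_observer_curves(
            preds,
            design,
            baseline=baseline,
            mapping_mode=mapping_mode,
            reference=reference,
            with_categories=with_categories,
        )
    chance = design.chance_accuracy / baseline if baseline else design.chance_accuracy
    report = benchmark(
        models,
        humans,
        steepness_grid_n=steepness_grid_n,
        steepness_scale=steepness_scale,
        chance=chance,
    )
    counts["n_models"] = len(models)
    log.info("benchmark stages: %s", counts)
    return report, counts
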