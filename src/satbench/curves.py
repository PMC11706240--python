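"""Quality control, imputation and aggregation of trials into SAT curves.

The analysis order is: observer-level exclusion -> warm-up discard ->
missing-response imputation -> per-latency accuracy aggregation ->
normalization by untimed (training) accuracy -> timestep mapping for model
observers.  The chance anchor at time 0 is attached last and is used for
display only; every metric ignores it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .design import ExperimentDesign
from .io import ModelPrediction, TrialRecord, predictions_to_frame, trials_to_frame

log = logging.getLogger(__name__)

__all__ = [
    "SATCurve",
    "CurveFamily",
    "filter_observers",
    "discard_warmup",
    "impute_missing",
    "compute_curve",
    "untimed_accuracy",
    "normalize_curve",
    "model_curves",
    "map_timesteps",
    "add_chance_anchor",
    "to_family",
]


@dataclass(frozen=True)
class SATCurve:
    """Accuracy as a function of reaction time (or timestep) for one condition.

    ``times`` is strictly increasing; raw accuracies lie in [0, 1] while
    normalized accuracies (divided by the untimed baseline) may exceed 1.
    When ``anchored`` is set, the first point is the chance anchor at time 0
    and is excluded from every metric computation.
    """

    label: Mapping[str, object]
    times: tuple[float, ...]
    accuracies: tuple[float, ...]
    n_trials: tuple[int, ...] | None = None
    se: tuple[float, ...] | None = None
    normalized: bool = False
    baseline: float | None = None
    anchored: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", dict(self.label))
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "accuracies", tuple(float(a) for a in self.accuracies))
        if self.n_trials is not None:
            object.__setattr__(self, "n_trials", tuple(int(n) for n in self.n_trials))
        if self.se is not None:
            object.__setattr__(self, "se", tuple(float(s) for s in self.se))
        t = self.times
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must be strictly increasing")
        for attr in ("accuracies", "n_trials", "se"):
            v = getattr(self, attr)
            if v is not None and len(v) != len(t):
                raise ValueError(f"{attr} length does not match times")
        if not self.normalized and any(not 0 <= a <= 1 for a in self.accuracies):
            raise ValueError("raw accuracies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.times)

    def metric_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, accuracies) with the chance anchor, if any, removed."""
        i = 1 if self.anchored else 0
        return np.asarray(self.times[i:]), np.asarray(self.accuracies[i:])


@dataclass(frozen=True)
class CurveFamily:
    """N_p x N_t accuracy matrix over perturbation levels and times."""

    perturbation_levels: tuple[float, ...]
    times: tuple[float, ...]
    c: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "perturbation_levels",
                           tuple(float(p) for p in self.perturbation_levels))
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "c", c)
        if len(self.perturbation_levels) == 0 or len(self.times) == 0:
            raise ValueError("both family axes must be nonempty")
        if c.shape != (len(self.perturbation_levels), len(self.times)):
            raise ValueError(
                f"matrix shape {c.shape} does not match axes "
                f"({len(self.perturbation_levels)}, {len(self.times)})"
            )
        if not np.all(np.isfinite(c)):
            raise ValueError("family has missing or non-finite cells")

    @property
    def shape(self) -> tuple[int, int]:
        return self.c.shape

    def to_frame(self) -> pd.DataFrame:
        """Long-format (level, time, accuracy) table."""
        rows = [
            {"perturbation_level": p, "time": t, "accuracy": self.c[i, j]}
            for i, p in enumerate(self.perturbation_levels)
            for j, t in enumerate(self.times)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Quality control


def filter_observers(
    trials: Sequence[TrialRecord], design: ExperimentDesign
) -> tuple[list[TrialRecord], list[str]]:
    """Exclude observers who could not follow the beep timing.

    An observer is excluded when at least ``design.exclusion_outside_fraction``
    of their timed trials have |response_time - beep_latency| greater than the
    acceptance window; missing responses count as outside.  The boundary is
    inclusive: exactly 50% outside excludes under the default design.  Trials
    of kept observers are returned unchanged.
    """
    outside: dict[str, int] = {}
    total: dict[str, int] = {}
    for t in trials:
        if not t.is_timed:
            continue
        total[t.observer_id] = total.get(t.observer_id, 0) + 1
        is_outside = (
            t.response_time_ms is None
            or abs(t.response_time_ms - t.beep_latency_ms) > design.acceptance_window_ms
        )
        if is_outside:
            outside[t.observer_id] = outside.get(t.observer_id, 0) + 1
    excluded = sorted(
        obs
        for obs, n in total.items()
        if outside.get(obs, 0) / n >= design.exclusion_outside_fraction
    )
    excluded_set = set(excluded)
    kept = [t for t in trials if t.observer_id not in excluded_set]
    log.info(
        "observer QC: kept %d, excluded %d of %d observers",
        len(total) - len(excluded), len(excluded), len(total),
    )
    return kept, excluded


def discard_warmup(
    trials: Sequence[TrialRecord], design: ExperimentDesign
) -> list[TrialRecord]:
    """Drop the first ``warmup_discard`` trials of every timed block.

    Observers use the leading trials of a block to adapt to its beep timing,
    so they are never analyzed.  Training trials pass through untouched.
    """
    kept = [
        t
        for t in trials
        if not t.is_timed or t.trial_index > design.warmup_discard
    ]
    n_block = {}
    for t in kept:
        if t.is_timed:
            key = (t.observer_id, t.block_index)
            n_block[key] = n_block.get(key, 0) + 1
    for key, n in n_block.items():
        if n == 0:
            log.warning("block %s empty after warm-up discard", key)
    if any(
        t.is_timed and t.trial_index <= design.warmup_discard for t in trials
    ) and not any(t.is_timed for t in kept):
        log.warning("warm-up discard removed every timed trial")
    log.info("warm-up discard: %d of %d trials kept", len(kept), len(trials))
    return kept


def impute_missing(
    trials: Sequence[TrialRecord],
    mode: str = "random",
    seed: int | None = 0,
    design: ExperimentDesign | None = None,
) -> list[TrialRecord]:
    """Resolve missing responses on timed trials.

    mode="random": replace each missing response by a uniformly drawn
    category (seeded), which biases measured accuracy toward chance by the
    known amount m*(1/K - a) at miss rate m and true accuracy a.
    mode="drop": remove missing trials instead.  Non-missing trials are
    returned untouched.
    """
    design = design or ExperimentDesign()
    if mode not in ("random", "drop"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    if mode == "drop":
        out = [t for t in trials if not (t.is_timed and t.missing)]
        log.info("imputation(drop): removed %d missing trials", len(trials) - len(out))
        return out
    rng = np.random.default_rng(seed)
    out: list[TrialRecord] = []
    n_imputed = 0
    for t in trials:
        if t.is_timed and t.missing:
            cat = design.categories[rng.integers(design.n_categories)]
            out.append(replace(t, response_category=cat,
                               response_time_ms=float(t.beep_latency_ms)))
            n_imputed += 1
        else:
            out.append(t)
    log.info("imputation(random): imputed %d missing trials", n_imputed)
    return out


# ---------------------------------------------------------------------------
# Aggregation


def compute_curve(
    trials: Sequence[TrialRecord],
    group: Sequence[str] = ("experiment", "perturbation_kind", "perturbation_level"),
) -> list[SATCurve]:
    """Aggregate timed trials into one SAT curve per group.

    Within each group and beep latency: accuracy is the fraction correct,
    and the standard error is the binomial sqrt(a(1-a)/n).  Trials with
    missing responses must have been imputed or dropped beforehand.  Empty
    groups are omitted with a warning.
    """
    timed = [t for t in trials if t.is_timed]
    if any(t.missing for t in timed):
        raise ValueError("impute or drop missing responses before computing curves")
    if not timed:
        log.warning("no timed trials: no curves computed")
        return []
    df = trials_to_frame(timed)
    df["correct"] = (df["response_category"] == df["true_category"]).astype(float)
    group = list(group)
    curves: list[SATCurve] = []
    for key, sub in df.groupby(group, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        agg = (
            sub.groupby("beep_latency_ms")["correct"]
            .agg(["mean", "count"])
            .sort_index()
        )
        acc = agg["mean"].to_numpy()
        n = agg["count"].to_numpy()
        se = np.sqrt(acc * (1.0 - acc) / n)
        curves.append(
            SATCurve(
                label=dict(zip(group, key)),
                times=tuple(float(x) for x in agg.index),
                accuracies=tuple(acc),
                n_trials=tuple(int(x) for x in n),
                se=tuple(se),
            )
        )
    return curves


def untimed_accuracy(
    trials: Sequence[TrialRecord], per_experiment: bool = False
):
    """Fraction correct on the untimed training trials.

    This is the normalization baseline for SAT curves.  With
    ``per_experiment=True`` a dict {experiment: accuracy} is returned.
    """
    training = [t for t in trials if t.phase == "training" and not t.missing]
    if not training:
        raise ValueError("no training trials present")
    if per_experiment:
        out: dict[str, float] = {}
        for exp in sorted({t.experiment for t in training}):
            sub = [t for t in training if t.experiment == exp]
            out[exp] = sum(t.correct for t in sub) / len(sub)
        return out
    return sum(t.correct for t in training) / len(training)


def normalize_curve(curve: SATCurve, baseline: float) -> SATCurve:
    """Express a curve as a fraction of the untimed baseline accuracy."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    se = None if curve.se is None else tuple(s / baseline for s in curve.se)
    return replace(
        curve,
        accuracies=tuple(a / baseline for a in curve.accuracies),
        se=se,
        normalized=True,
        baseline=baseline,
    )


# ---------------------------------------------------------------------------
# Model observers


def model_curves(
    preds: Sequence[ModelPrediction],
    group: Sequence[str] = ("perturbation_kind", "perturbation_level"),
) -> list[SATCurve]:
    """Per-timestep accuracy curves from a model prediction table."""
    if not preds:
        return []
    df = predictions_to_frame(preds)
    df["correct"] = (df["predicted_category"] == df["true_category"]).astype(float)
    group = list(group)
    curves: list[SATCurve] = []
    for key, sub in df.groupby(group, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        agg = sub.groupby("timestep")["correct"].agg(["mean", "count"]).sort_index()
        acc = agg["mean"].to_numpy()
        n = agg["count"].to_numpy()
        curves.append(
            SATCurve(
                label=dict(zip(group, key)),
                times=tuple(float(x) for x in agg.index),
                accuracies=tuple(acc),
                n_trials=tuple(int(x) for x in n),
                se=tuple(np.sqrt(acc * (1 - acc) / n)),
            )
        )
    return curves


def map_timesteps(
    model_curve: SATCurve,
    design: ExperimentDesign,
    mode: str = "index",
    reference: SATCurve | None = None,
) -> SATCurve:
    """Place a model observer's timesteps on the human reaction-time axis.

    mode="index": timestep i receives the i-th beep latency (the model must
    have exactly one point per timed block).  mode="affine": times become
    a*i + b with a > 0, chosen to minimize the squared error between the
    model accuracies and the reference human curve linearly interpolated at
    the mapped times — speed *and* delay freedom, absorbing fixed motor and
    retinal delays.  A flat reference leaves the mapping unidentified; the
    index mapping is used with a warning.
    """
    if model_curve.anchored:
        raise ValueError("map timesteps before attaching the chance anchor")
    steps = np.asarray(model_curve.times)
    acc = np.asarray(model_curve.accuracies)
    if mode == "index":
        if len(steps) != design.n_timed_blocks:
            raise ValueError(
                f"{len(steps)} timesteps cannot be index-mapped onto "
                f"{design.n_timed_blocks} beep latencies"
            )
        return replace(model_curve, times=tuple(float(x) for x in design.beep_latencies_ms))
    if mode != "affine":
        raise ValueError(f"unknown mapping mode {mode!r}")
    if reference is None:
        raise ValueError("affine mapping requires a reference curve")
    ref_t, ref_a = reference.metric_points()
    if float(np.ptp(ref_a)) < 1e-9:
        log.warning("flat reference curve: affine mapping unidentified, "
                    "falling back to index mode")
        return map_timesteps(model_curve, design, mode="index")

    def resid(x):
        a_slope, b = x
        mapped = a_slope * steps + b
        return np.interp(mapped, ref_t, ref_a) - acc

    # start from the least-squares line through (timestep, latency)
    lat = np.asarray(design.beep_latencies_ms, dtype=float)
    k = min(len(steps), len(lat))
    a0, b0 = np.polyfit(steps[:k], lat[:k], 1)
    sol = least_squares(resid, [max(a0, 1.0), b0],
                        bounds=([1e-9, -np.inf], [np.inf, np.inf]))
    a_slope, b = sol.x
    times = a_slope * steps + b
    return replace(model_curve, times=tuple(float(x) for x in times))


def add_chance_anchor(curve: SATCurve, design: ExperimentDesign) -> SATCurve:
    """Prepend the chance-accuracy point at time 0 (display only).

    The anchor is 1/n_categories in raw units, divided by the baseline when
    the curve is normalized.  Every metric operation skips it.
    """
    if curve.anchored:
        raise ValueError("curve is already anchored")
    if curve.times and curve.times[0] <= 0:
        raise ValueError("curve already has a point at or before time 0")
    chance = design.chance_accuracy
    if curve.normalized:
        if curve.baseline is None:
            raise ValueError("normalized curve lacks its baseline")
        chance = chance / curve.baseline
    return replace(
        curve,
        times=(0.0,) + curve.times,
        accuracies=(chance,) + curve.accuracies,
        n_trials=None if curve.n_trials is None else (0,) + curve.n_trials,
        se=None if curve.se is None else (0.0,) + curve.se,
        anchored=True,
    )


def to_family(curves: Iterable[SATCurve]) -> CurveFamily:
    """Stack per-level curves into the N_p x N_t matrix the fit error uses.

    All curves must share one time axis and carry distinct perturbation
    levels; the unperturbed level-0 condition must be present, since the
    family includes the zero-noise / zero-blur baseline.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to stack")
    rows: dict[float, np.ndarray] = {}
    times0 = None
    for cv in curves:
        t, a = cv.metric_points()
        if times0 is None:
            times0 = t
        elif t.shape != times0.shape or not np.allclose(t, times0):
            raise ValueError("curves have mismatched time axes")
        level = float(cv.label.get("perturbation_level", 0.0))
        if level in rows:
            raise ValueError(f"duplicate perturbation level {level}")
        rows[level] = a
    if 0.0 not in rows:
        raise ValueError("missing level-0 (unperturbed) curve")
    levels = sorted(rows)
    c = np.vstack([rows[p] for p in levels])
    return CurveFamily(perturbation_levels=tuple(levels),
                       times=tuple(float(x) for x in times0), c=c)
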