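"""Human-model comparison metrics for SAT curves.

Three metrics quantify how well a model observer reproduces the human
speed-accuracy tradeoff:

* curve-fit error ``e_RMSE`` — RMSE across time, averaged across the
  perturbation curves of a family;
* category-wise Spearman correlation — per-category SAT curves flattened
  into one vector per side and rank-correlated;
* steepness — the mean curvature of the fitted cumulative-Weibull curve,
  measuring how abruptly accuracy rises with time (humans are gradual,
  early-exit networks tend to be steep).

Degenerate metric values (zero-variance vectors, flat curves) are reported
as NaN and counted, never coerced to a number or silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curves import CurveFamily, SATCurve
from .psychometric import WeibullParams, fit_weibull, weibull_accuracy

log = logging.getLogger(__name__)

__all__ = [
    "rmse_fit_error",
    "categorywise_correlation",
    "per_category_correlation",
    "mean_curvature",
    "steepness",
    "curve_steepness",
    "timestep_flop_correlation",
    "ObserverCurves",
    "MetricReport",
    "benchmark",
]


def rmse_fit_error(c1: CurveFamily, c2: CurveFamily) -> float:
    """Curve-fit error between two accuracy families of identical shape.

    e_RMSE = (1/N_p) * sum_p sqrt( (1/N_t) * sum_t (c1[p,t] - c2[p,t])^2 ):
    the root-mean-squared error across time, averaged across perturbation
    curves.  Symmetric, nonnegative, zero iff the families are equal.
    """
    if c1.shape != c2.shape:
        raise ValueError(f"family shapes differ: {c1.shape} vs {c2.shape}")
    if c1.perturbation_levels != c2.perturbation_levels or c1.times != c2.times:
        raise ValueError("families must share level and time axes")
    per_level = np.sqrt(np.mean((c1.c - c2.c) ** 2, axis=1))
    return float(np.mean(per_level))


def _flatten_by_category(curves: Mapping[str, SATCurve]) -> np.ndarray:
    parts = []
    for cat in sorted(curves):
        _, a = curves[cat].metric_points()
        parts.append(a)
    return np.concatenate(parts)


def categorywise_correlation(
    model: Mapping[str, SATCurve], human: Mapping[str, SATCurve]
) -> float:
    """Spearman rank correlation of flattened per-category SAT curves.

    Both sides are flattened in a fixed order — categories alphabetically,
    then time ascending — so the vectors always align.  Ties receive
    average ranks.  A zero-variance vector makes the correlation
    undefined: NaN is returned as the degenerate flag.
    """
    if set(model) != set(human):
        raise ValueError(
            f"category sets differ: {sorted(set(model) ^ set(human))}"
        )
    for cat in model:
        tm, _ = model[cat].metric_points()
        th, _ = human[cat].metric_points()
        if tm.shape != th.shape or not np.allclose(tm, th):
            raise ValueError(f"time axes differ for category {cat!r}")
    x = _flatten_by_category(model)
    y = _flatten_by_category(human)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def per_category_correlation(model: SATCurve, human: SATCurve) -> float:
    """Spearman correlation between one category's model and human curves.

    Negative values are preserved (any clipping is a display decision, not
    part of the metric); a constant curve yields NaN.
    """
    tm, am = model.metric_points()
    th, ah = human.metric_points()
    if tm.shape != th.shape or not np.allclose(tm, th):
        raise ValueError("curves have mismatched time axes")
    if np.ptp(am) == 0 or np.ptp(ah) == 0:
        return float("nan")
    return float(stats.spearmanr(am, ah).statistic)


# ---------------------------------------------------------------------------
# Steepness


def mean_curvature(x, y) -> float:
    """Mean plane-curve curvature of sampled y(x) on a uniform grid.

    kappa = |y''| / (1 + y'^2)^(3/2), evaluated at interior grid points by
    central differences, then averaged.  Zero for an exactly linear curve.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 equally spaced points")
    h = np.diff(x)
    if not np.allclose(h, h[0]):
        raise ValueError("grid must be uniform")
    h = h[0]
    d1 = (y[2:] - y[:-2]) / (2 * h)
    d2 = (y[2:] - 2 * y[1:-1] + y[:-2]) / h**2
    kappa = np.abs(d2) / (1 + d1**2) ** 1.5
    return float(np.mean(kappa))


def steepness(
    params: WeibullParams,
    t_range: tuple[float, float],
    grid_n: int = 101,
    scale: str = "loglog",
) -> float:
    """Mean curvature of the fitted SAT curve over an evaluation grid.

    With ``scale="loglog"`` (default) the curve is evaluated on a grid
    uniform in log10(time) and curvature is taken of log10(accuracy) vs
    log10(time); the statistic is then invariant to rescaling the time unit
    (a log shift) provided tau is rescaled with it.  ``scale="linear"``
    evaluates accuracy vs time directly.
    """
    t_min, t_max = t_range
    if not t_min < t_max:
        raise ValueError("t_min must be < t_max")
    if scale == "loglog":
        if t_min <= 0:
            raise ValueError("log-log steepness requires positive times")
        x = np.linspace(np.log10(t_min), np.log10(t_max), grid_n)
        y = np.log10(weibull_accuracy(10**x, params))
    elif scale == "linear":
        x = np.linspace(t_min, t_max, grid_n)
        y = weibull_accuracy(x, params)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return mean_curvature(x, y)


def curve_steepness(
    curve: SATCurve,
    grid_n: int = 101,
    scale: str = "loglog",
    fix_gamma: bool = True,
    gamma: float = 1.0 / 16.0,
) -> float:
    """Fit the cumulative Weibull to a curve, then take its steepness.

    Returns NaN (degenerate) for flat curves, where the Weibull shape is
    unidentifiable.  The evaluation grid spans the curve's own time range.
    """
    t, a = curve.metric_points()
    fit = fit_weibull(t, a, fix_gamma=fix_gamma, gamma=gamma)
    if fit.degenerate:
        return float("nan")
    return steepness(fit.params, (float(t.min()), float(t.max())),
                     grid_n=grid_n, scale=scale)


def timestep_flop_correlation(flops: Sequence[float], T: int | None = None) -> float:
    """Pearson correlation of timestep index 1..T with per-output FLOPs.

    Validates that a network's ordinal time analog (exit index, recurrent
    cycle, cascade output) tracks actual computational cost.  Constant
    FLOPs yield NaN (degenerate).
    """
    f = np.asarray(flops, dtype=float)
    T = len(f) if T is None else T
    if len(f) != T or T < 3:
        raise ValueError("need at least 3 per-output FLOP values")
    if np.any(f <= 0):
        raise ValueError("FLOPs must be positive")
    if np.ptp(f) == 0:
        return float("nan")
    return float(stats.pearsonr(np.arange(1, T + 1), f).statistic)


# ---------------------------------------------------------------------------
# Benchmark assembly


@dataclass(frozen=True)
class ObserverCurves:
    """One observer's (human or model) curves, ready for the metrics.

    ``family`` holds the per-perturbation-level curves stacked into the
    N_p x N_t matrix; ``by_category`` optionally holds per-category curves
    for the rank-correlation metric.
    """

    family: CurveFamily
    by_category: Mapping[str, SATCurve] | None = None


@dataclass
class Summary:
    metric: str
    model_id: str
    n: int
    n_degenerate: int
    median: float
    q1: float
    q3: float
    outliers: list[float]


@dataclass
class MetricReport:
    """All pairwise comparisons plus distribution summaries.

    ``comparisons`` rows are (model_id, observer_id, metric, value); the
    "human" model_id rows compare the average human curve to each observer
    (the attainable-error baseline).  Summaries give median, quartiles and
    the points beyond 1.5 IQR, excluding degenerate (NaN) values, whose
    count is reported instead.
    """

    comparisons: list[tuple[str, str, str, float]] = field(default_factory=list)
    summaries: list[Summary] = field(default_factory=list)
    steepness_table: dict[tuple[str, float], float] = field(default_factory=dict)

    def recompute_summaries(self) -> list[Summary]:
        groups: dict[tuple[str, str], list[float]] = {}
        for model_id, _obs, metric, value in self.comparisons:
            groups.setdefault((metric, model_id), []).append(value)
        out = []
        for (metric, model_id), values in sorted(groups.items()):
            v = np.asarray(values, dtype=float)
            finite = v[np.isfinite(v)]
            n_deg = int(v.size - finite.size)
            if finite.size == 0:
                out.append(Summary(metric, model_id, int(v.size), n_deg,
                                   float("nan"), float("nan"), float("nan"), []))
                continue
            q1, med, q3 = np.percentile(finite, [25, 50, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            outliers = sorted(float(x) for x in finite[(finite < lo) | (finite > hi)])
            out.append(Summary(metric, model_id, int(v.size), n_deg,
                               float(med), float(q1), float(q3), outliers))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.comparisons, columns=["model_id", "observer_id", "metric", "value"]
        )

    def summaries_dict(self) -> list[dict]:
        return [asdict(s) for s in self.summaries]

    def to_json(self, path) -> None:
        payload = {
            "summaries": self.summaries_dict(),
            "steepness": [
                {"curve_id": cid, "perturbation_level": lvl, "steepness": val}
                for (cid, lvl), val in sorted(self.steepness_table.items())
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _mean_family(families: Sequence[CurveFamily]) -> CurveFamily:
    f0 = families[0]
    for f in families[1:]:
        if f.perturbation_levels != f0.perturbation_levels or f.times != f0.times:
            raise ValueError("observer families have mismatched axes")
    return CurveFamily(
        perturbation_levels=f0.perturbation_levels,
        times=f0.times,
        c=np.mean([f.c for f in families], axis=0),
    )


def _mean_category_curves(
    sets: Sequence[Mapping[str, SATCurve]]
) -> dict[str, SATCurve]:
    cats = set(sets[0])
    for s in sets[1:]:
        if set(s) != cats:
            raise ValueError("observers have mismatched category sets")
    out: dict[str, SATCurve] = {}
    for cat in sorted(cats):
        t0, _ = sets[0][cat].metric_points()
        acc = np.mean([s[cat].metric_points()[1] for s in sets], axis=0)
        out[cat] = SATCurve(label={"category": cat, "observer_id": "average_human"},
                            times=tuple(t0), accuracies=tuple(acc),
                            normalized=sets[0][cat].normalized,
                            baseline=sets[0][cat].baseline)
    return out


def benchmark(
    models: Mapping[str, ObserverCurves],
    humans: Mapping[str, ObserverCurves],
    steepness_grid_n: int = 101,
    steepness_scale: str = "loglog",
    chance: float = 1.0 / 16.0,
) -> MetricReport:
    """Compare every model observer to every human observer.

    For each (model, human) pair the curve-fit error over the perturbation
    family and, when per-category curves are present, the category-wise
    rank correlation are recorded.  The "human" baseline rows compare the
    average human curve to each individual observer.  Steepness is computed
    per entity and perturbation level from the entity's own or the average
    human family.  Deterministic given its inputs.
    """
    if not models or not humans:
        raise ValueError("need at least one model and one human observer")
    report = MetricReport()
    human_ids = sorted(humans)
    avg_family = _mean_family([humans[h].family for h in human_ids])
    have_cats = all(humans[h].by_category is not None for h in human_ids)
    avg_cats = (
        _mean_category_curves([humans[h].by_category for h in human_ids])
        if have_cats
        else None
    )

    entities: dict[str, tuple[CurveFamily, Mapping[str, SATCurve] | None]] = {
        mid: (mc.family, mc.by_category) for mid, mc in models.items()
    }
    entities["human"] = (avg_family, avg_cats)

    for mid in sorted(entities):
        family, cats = entities[mid]
        for hid in human_ids:
            report.comparisons.append(
                (mid, hid, "rmse", rmse_fit_error(family, humans[hid].family))
            )
            if cats is not None and humans[hid].by_category is not None:
                report.comparisons.append(
                    (mid, hid, "categorywise_spearman",
                     categorywise_correlation(cats, humans[hid].by_category))
                )
        for i, level in enumerate(family.perturbation_levels):
            cv = SATCurve(label={"perturbation_level": level},
                          times=family.times, accuracies=tuple(family.c[i]),
                          normalized=True, baseline=1.0)
            report.steepness_table[(mid, level)] = curve_steepness(
                cv, grid_n=steepness_grid_n, scale=steepness_scale, gamma=chance
            )
    report.summaries = report.recompute_summaries()
    n_deg = sum(s.n_degenerate for s in report.summaries)
    if n_deg:
        log.info("benchmark: %d degenerate metric values flagged", n_deg)
    return report
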