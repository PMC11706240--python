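"""Synthetic human observers and dynamic-network model observers.

The generator reproduces the statistical structure the analysis assumes:
16-way categorization across five beep-latency blocks, Weibull-shaped
accuracy growth with allowed reaction time, response-timing jitter around
the beep, latency-dependent missing responses, and per-timestep model
prediction tables with prescribed accuracy profiles.  It does not emulate
images, sequential learning effects, or trial-to-trial dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from .design import CATEGORIES, ExperimentDesign
from .io import ModelPrediction, TrialRecord
from .psychometric import WeibullParams, weibull_accuracy

__all__ = [
    "ObserverSpec",
    "ModelObserverSpec",
    "simulate_observer",
    "simulate_model_observer",
    "condition_accuracy",
    "default_perturbation_effects",
    "sample_observer_specs",
    "DEFAULT_CONDITIONS",
    "MODEL_PROFILES",
]

#: Perturbation conditions per experiment: (kind, level) pairs, level 0 being
#: the unperturbed baseline (gray at low contrast for noise, color for blur).
DEFAULT_CONDITIONS: dict[str, tuple[tuple[str, float], ...]] = {
    "color_gray": (("color", 0.0), ("gray", 0.0)),
    "gray_noise": (("noise", 0.0), ("noise", 0.04), ("noise", 0.08), ("noise", 0.16)),
    "color_blur": (("blur", 0.0), ("blur", 1.5), ("blur", 3.0)),
}


@dataclass(frozen=True)
class ObserverSpec:
    """Generative parameters of one synthetic human observer.

    ``perturbation_effects`` maps a (kind, level) condition to a pair
    (asymptote scale in (0, 1], tau multiplier >= 1): degraded images lower
    the reachable accuracy and slow its growth.  ``miss_prob`` gives the
    per-trial probability of failing to respond at each beep latency; it is
    highest at the shortest latency, where the response window is tight.
    """

    observer_id: str = "obs0"
    experiment: str = "gray_noise"
    base_params: WeibullParams = field(
        default_factory=lambda: WeibullParams(gamma=1 / 16, lam=0.22, tau=1150.0, beta=3.5)
    )
    category_tau_multipliers: Mapping[str, float] = field(default_factory=dict)
    perturbation_effects: Mapping[tuple[str, float], tuple[float, float]] = field(
        default_factory=dict
    )
    rt_jitter_sd_ms: float = 60.0
    miss_prob: Mapping[int, float] = field(
        default_factory=lambda: {500: 0.15, 900: 0.05, 1100: 0.03, 1300: 0.02, 1500: 0.02}
    )
    block_order: str | None = None  # "ascending" | "descending" | None = random
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in DEFAULT_CONDITIONS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if any(m <= 0 for m in self.category_tau_multipliers.values()):
            raise ValueError("category tau multipliers must be positive")
        for (kind, level), (scale, mult) in self.perturbation_effects.items():
            if not 0 < scale <= 1:
                raise ValueError(f"asymptote scale for {(kind, level)} must be in (0, 1]")
            if mult < 1:
                raise ValueError(f"tau multiplier for {(kind, level)} must be >= 1")
        if any(not 0 <= p <= 1 for p in self.miss_prob.values()):
            raise ValueError("miss probabilities must lie in [0, 1]")
        if self.rt_jitter_sd_ms < 0:
            raise ValueError("rt_jitter_sd_ms must be nonnegative")
        if self.block_order not in (None, "ascending", "descending"):
            raise ValueError("block_order must be ascending, descending or None")

    @property
    def conditions(self) -> tuple[tuple[str, float], ...]:
        base = DEFAULT_CONDITIONS[self.experiment]
        extra = tuple(k for k in self.perturbation_effects if k not in base)
        return base + extra


def condition_accuracy(
    t_ms: float, spec: ObserverSpec, condition: tuple[str, float], category: str | None = None
) -> float:
    """True P(correct) at time t under a condition (and optional category).

    The perturbation scales the rise above chance by its asymptote scale and
    stretches the time axis by its tau multiplier; a category multiplier
    stretches the time axis further for hard categories.
    """
    p = spec.base_params
    scale, tau_mult = spec.perturbation_effects.get(tuple(condition), (1.0, 1.0))
    if category is not None:
        tau_mult = tau_mult * spec.category_tau_multipliers.get(category, 1.0)
    rise = 1.0 - np.exp(-((t_ms / (p.tau * tau_mult)) ** p.beta)) if t_ms > 0 else 0.0
    return p.gamma + (1.0 - p.gamma - p.lam) * scale * rise


def _asymptote(spec: ObserverSpec, condition: tuple[str, float]) -> float:
    p = spec.base_params
    scale, _ = spec.perturbation_effects.get(tuple(condition), (1.0, 1.0))
    return p.gamma + (1.0 - p.gamma - p.lam) * scale


def _balanced_categories(n: int, categories: Sequence[str], rng: np.random.Generator) -> list[str]:
    """As-equal-as-possible category counts: floor allocation, random remainder."""
    k = len(categories)
    base, rem = divmod(n, k)
    counts = np.full(k, base)
    counts[rng.choice(k, size=rem, replace=False)] += 1
    out = [c for c, m in zip(categories, counts) for _ in range(m)]
    rng.shuffle(out)
    return out


def _wrong_category(true: str, categories: Sequence[str], rng: np.random.Generator) -> str:
    wrong = [c for c in categories if c != true]
    return wrong[rng.integers(len(wrong))]


def simulate_observer(
    spec: ObserverSpec, design: ExperimentDesign | None = None
) -> list[TrialRecord]:
    """Simulate one full session of the timed-beep paradigm.

    The session is a training block followed by the timed blocks in the
    spec's order (drawn with equal probability when unspecified).  Each
    timed trial first draws whether the observer misses (no response within
    beep + grace); otherwise it is correct with the condition- and
    category-adjusted Weibull probability, errors are uniform over the 15
    wrong categories, and the response time is the beep latency plus
    truncated-normal jitter confined to [0, latency + grace].  Identical
    (spec, design) inputs yield identical trial lists.
    """
    design = design or ExperimentDesign()
    rng = np.random.default_rng(spec.seed)
    cats = design.categories
    conditions = spec.conditions
    trials: list[TrialRecord] = []

    def draw_condition(i: int) -> tuple[str, float]:
        return conditions[i % len(conditions)]

    # training block: untimed, governed by the asymptotic accuracy
    train_cats = _balanced_categories(design.n_training_trials, cats, rng)
    for i, cat in enumerate(train_cats, start=1):
        cond = draw_condition(i)
        asym = min(_asymptote(spec, cond), 1.0)
        if rng.random() < asym:
            resp = cat
        else:
            resp = _wrong_category(cat, cats, rng)
        rt = float(max(200.0, rng.normal(1200.0, 300.0)))
        trials.append(
            TrialRecord(
                observer_id=spec.observer_id,
                experiment=spec.experiment,
                phase="training",
                block_index=0,
                beep_latency_ms=None,
                perturbation_kind=cond[0],
                perturbation_level=cond[1],
                true_category=cat,
                response_category=resp,
                response_time_ms=rt,
                trial_index=i,
                image_id=f"train_{i:03d}",
            )
        )

    if spec.block_order is None:
        order = "ascending" if rng.random() < 0.5 else "descending"
    else:
        order = spec.block_order
    latencies = list(design.beep_latencies_ms)
    if order == "descending":
        latencies = latencies[::-1]

    for bi, latency in enumerate(latencies, start=1):
        block_index = design.beep_latencies_ms.index(latency) + 1
        block_cats = _balanced_categories(design.trials_per_block, cats, rng)
        p_miss = float(spec.miss_prob.get(latency, 0.0))
        for i, cat in enumerate(block_cats, start=1):
            cond = draw_condition(i)
            if rng.random() < p_miss:
                resp, rt = None, None
            else:
                a = min(condition_accuracy(latency, spec, cond, cat), 1.0)
                resp = cat if rng.random() < a else _wrong_category(cat, cats, rng)
                if spec.rt_jitter_sd_ms > 0:
                    lo = (0.0 - latency) / spec.rt_jitter_sd_ms
                    hi = (design.grace_ms) / spec.rt_jitter_sd_ms
                    rt = latency + spec.rt_jitter_sd_ms * float(
                        truncnorm.rvs(lo, hi, random_state=rng)
                    )
                else:
                    rt = float(latency)
            trials.append(
                TrialRecord(
                    observer_id=spec.observer_id,
                    experiment=spec.experiment,
                    phase="timed",
                    block_index=block_index,
                    beep_latency_ms=latency,
                    perturbation_kind=cond[0],
                    perturbation_level=cond[1],
                    true_category=cat,
                    response_category=resp,
                    response_time_ms=rt,
                    trial_index=i,
                    image_id=f"b{block_index}_{i:03d}",
                )
            )
    return trials


def default_perturbation_effects(
    experiment: str,
) -> dict[tuple[str, float], tuple[float, float]]:
    """Plausible (asymptote scale, tau multiplier) per condition.

    Stronger noise or blur depresses the reachable accuracy and slows its
    growth; the unperturbed level-0 condition is unaffected.  These are the
    generator's nominal task-difficulty settings, not fitted to any dataset.
    """
    effects = {
        "color_gray": {("color", 0.0): (1.0, 1.0), ("gray", 0.0): (0.9, 1.1)},
        "gray_noise": {
            ("noise", 0.0): (1.0, 1.0),
            ("noise", 0.04): (0.8, 1.2),
            ("noise", 0.08): (0.6, 1.4),
            ("noise", 0.16): (0.4, 1.7),
        },
        "color_blur": {
            ("blur", 0.0): (1.0, 1.0),
            ("blur", 1.5): (0.7, 1.3),
            ("blur", 3.0): (0.5, 1.6),
        },
    }
    if experiment not in effects:
        raise ValueError(f"unknown experiment {experiment!r}")
    return effects[experiment]


def sample_observer_specs(
    n_observers: int,
    experiment: str = "gray_noise",
    seed: int = 0,
    base_params: WeibullParams | None = None,
    rt_jitter_sd_ms: float = 60.0,
    miss_prob: Mapping[int, float] | None = None,
) -> list[ObserverSpec]:
    """Draw a population of synthetic observers with individual differences.

    Each observer's time scale and lapse rate are jittered around the base
    parameters (lognormal tau with 10% spread, lapse within +/-0.05) and a
    lognormal per-category difficulty multiplier (15% spread) is drawn, so
    curves differ across observers and categories the way group data do.
    Observer seeds are derived from ``seed`` so sessions are reproducible.
    """
    base = base_params or WeibullParams(gamma=1 / 16, lam=0.22, tau=1150.0, beta=3.5)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_observers)]
    specs = []
    for i in range(n_observers):
        tau = float(base.tau * rng.lognormal(0.0, 0.10))
        lam = float(np.clip(base.lam + rng.uniform(-0.05, 0.05), 0.0, 0.45))
        beta = float(base.beta * rng.lognormal(0.0, 0.10))
        cat_mult = {c: float(rng.lognormal(0.0, 0.15)) for c in CATEGORIES}
        kwargs = {} if miss_prob is None else {"miss_prob": dict(miss_prob)}
        specs.append(
            ObserverSpec(
                observer_id=f"obs{i:03d}",
                experiment=experiment,
                base_params=WeibullParams(gamma=base.gamma, lam=lam, tau=tau, beta=beta),
                category_tau_multipliers=cat_mult,
                perturbation_effects=default_perturbation_effects(experiment),
                rt_jitter_sd_ms=rt_jitter_sd_ms,
                seed=child_seeds[i],
                **kwargs,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Model observers

#: Qualitative per-timestep accuracy profiles over t = 1..5, expressed as the
#: fraction of the (lo, hi) accuracy range reached at each timestep.
#: gradual_wide rises smoothly over the full range (cascaded-network-like);
#: steep_saturating jumps to its ceiling immediately after the first step
#: (early-exit-network-like); shallow_low_range creeps over a narrow band.
MODEL_PROFILES: dict[str, tuple[float, ...]] = {
    "gradual_wide": (0.0, 0.30, 0.58, 0.82, 1.0),
    "steep_saturating": (0.0, 0.97, 1.0, 1.0, 1.0),
    "shallow_low_range": (0.0, 0.25, 0.50, 0.75, 1.0),
}


@dataclass(frozen=True)
class ModelObserverSpec:
    """Generative parameters of one synthetic dynamic-network observer.

    ``accuracy`` maps each (kind, level) condition to the per-timestep true
    accuracy a[t], t = 1..n_timesteps, each value in [1/16, 1].  Use
    :meth:`from_profile` to build the table from a named qualitative shape.
    """

    model_id: str = "model0"
    accuracy: Mapping[tuple[str, float], tuple[float, ...]] = field(default_factory=dict)
    n_images: int = 200
    n_timesteps: int = 5
    seed: int = 0
    profile: str = "custom"

    def __post_init__(self) -> None:
        if not self.accuracy:
            raise ValueError("accuracy table must not be empty")
        for cond, a in self.accuracy.items():
            if len(a) != self.n_timesteps:
                raise ValueError(
                    f"accuracy for {cond} must have {self.n_timesteps} timesteps"
                )
            if any(not 1 / 16 <= x <= 1 for x in a):
                raise ValueError(f"accuracy for {cond} outside [1/16, 1]")
        if self.n_images < 1:
            raise ValueError("n_images must be positive")

    @classmethod
    def from_profile(
        cls,
        profile: str,
        conditions: Sequence[tuple[str, float]],
        lo: float = 0.10,
        hi: float = 0.85,
        level_asymptote_scale: Mapping[tuple[str, float], float] | None = None,
        model_id: str | None = None,
        n_images: int = 200,
        seed: int = 0,
    ) -> "ModelObserverSpec":
        """Build the accuracy table from a named qualitative shape.

        The profile fixes the fraction of the (lo, hi) range reached at each
        timestep; a per-condition asymptote scale shrinks the range toward
        ``lo`` for degraded conditions, mirroring how even mild noise or
        blur sharply depresses peak network accuracy.  When no scales are
        given, conditions ranked by perturbation level receive the default
        schedule 1.0, 0.5, 0.35, 0.25, ... (floor 0.25).
        """
        if profile not in MODEL_PROFILES:
            raise ValueError(f"unknown profile {profile!r}")
        if profile == "shallow_low_range":
            lo, hi = 0.20, 0.38  # narrow, low band by construction
        frac = np.asarray(MODEL_PROFILES[profile])
        if level_asymptote_scale is None:
            schedule = (1.0, 0.5, 0.35, 0.25)
            ranked = sorted(conditions, key=lambda c: c[1])
            level_asymptote_scale = {
                tuple(c): schedule[min(r, len(schedule) - 1)]
                for r, c in enumerate(ranked)
            }
        table: dict[tuple[str, float], tuple[float, ...]] = {}
        for cond in conditions:
            scale = level_asymptote_scale.get(tuple(cond), 1.0)
            a = lo + (hi - lo) * scale * frac
            table[tuple(cond)] = tuple(float(np.clip(x, 1 / 16, 1.0)) for x in a)
        return cls(
            model_id=model_id or profile,
            accuracy=table,
            n_images=n_images,
            seed=seed,
            profile=profile,
        )


def simulate_model_observer(
    spec: ModelObserverSpec, categories: Sequence[str] = CATEGORIES
) -> list[ModelPrediction]:
    """Generate the per-timestep prediction table of a model observer.

    For every condition and timestep, ``n_images`` predictions are drawn
    correct with probability a[t]; errors are uniform over the wrong
    categories.  The same image set (ids and true categories) is evaluated
    at every timestep, as a dynamic network would.  Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    preds: list[ModelPrediction] = []
    for ci, (cond, acc) in enumerate(sorted(spec.accuracy.items())):
        kind, level = cond
        true_cats = _balanced_categories(spec.n_images, list(categories), rng)
        image_ids = [f"{kind}{level:g}_im{i:04d}" for i in range(spec.n_images)]
        for t in range(1, spec.n_timesteps + 1):
            a = acc[t - 1]
            for img, cat in zip(image_ids, true_cats):
                if rng.random() < a:
                    pred = cat
                else:
                    pred = _wrong_category(cat, categories, rng)
                preds.append(
                    ModelPrediction(
                        timestep=t,
                        perturbation_kind=kind,
                        perturbation_level=level,
                        image_id=img,
                        true_category=cat,
                        predicted_category=pred,
                    )
                )
    return preds
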