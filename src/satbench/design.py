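"""Experiment-design constants for the timed-beep categorization paradigm.

The paradigm fixes reaction time per block: the observer must click their
category response at an auditory beep played at a fixed latency after
stimulus onset.  A session consists of one untimed training block followed
by several timed blocks, each with its own beep latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

#: The 16 higher-level object categories, lowercase, alphabetical.
CATEGORIES: tuple[str, ...] = (
    "airplane", "bear", "bicycle", "bird", "boat", "bottle", "car", "cat",
    "chair", "clock", "dog", "elephant", "keyboard", "knife", "oven", "truck",
)

#: Sentinel token used in CSV files for a missing response / reaction time.
MISSING = "NA"

EXPERIMENTS: tuple[str, ...] = ("color_gray", "gray_noise", "color_blur")
PHASES: tuple[str, ...] = ("training", "timed")
PERTURBATION_KINDS: tuple[str, ...] = ("color", "gray", "noise", "blur")


class DesignError(ValueError):
    """Raised when an ExperimentDesign violates its invariants."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Block structure, beep latencies and QC thresholds of one experiment.

    Parameters
    ----------
    n_training_trials : int
        Untimed trials at the start of a session (observer familiarization).
    n_timed_blocks : int
        Number of timed blocks; each uses one beep latency.
    trials_per_block : int
        Trials in each timed block, including the warm-up trials.
    warmup_discard : int
        Leading trials of each timed block dropped before analysis (the
        observer is adapting to the block's beep timing).
    beep_latencies_ms : tuple of int
        Stimulus-onset-to-beep latency for each timed block, strictly
        increasing, milliseconds.
    grace_ms : int
        Extra time after the beep during which a response is still recorded.
    acceptance_window_ms : int
        Half-width of the response-timing window around the beep used for
        observer-level quality control.
    exclusion_outside_fraction : float
        An observer is excluded when at least this fraction of their timed
        responses falls outside the acceptance window (missing responses
        count as outside).
    n_categories : int
        Number of response alternatives; chance accuracy is its reciprocal.
    """

    n_training_trials: int = 50
    n_timed_blocks: int = 5
    trials_per_block: int = 210
    warmup_discard: int = 10
    beep_latencies_ms: tuple[int, ...] = (500, 900, 1100, 1300, 1500)
    grace_ms: int = 200
    acceptance_window_ms: int = 100
    exclusion_outside_fraction: float = 0.5
    n_categories: int = 16
    categories: tuple[str, ...] = field(default=CATEGORIES)

    def __post_init__(self) -> None:
        lat = tuple(int(x) for x in self.beep_latencies_ms)
        object.__setattr__(self, "beep_latencies_ms", lat)
        object.__setattr__(self, "categories", tuple(self.categories))
        if len(lat) != self.n_timed_blocks:
            raise DesignError(
                f"{len(lat)} beep latencies for {self.n_timed_blocks} timed blocks"
            )
        if any(b <= a for a, b in zip(lat, lat[1:])):
            raise DesignError("beep_latencies_ms must be strictly increasing")
        if any(x <= 0 for x in lat):
            raise DesignError("beep latencies must be positive")
        if not 0 <= self.warmup_discard < self.trials_per_block:
            raise DesignError("warmup_discard must lie in [0, trials_per_block)")
        if not 0 < self.exclusion_outside_fraction <= 1:
            raise DesignError("exclusion_outside_fraction must lie in (0, 1]")
        if self.acceptance_window_ms <= 0 or self.grace_ms < 0:
            raise DesignError("invalid acceptance window or grace period")
        if len(self.categories) != self.n_categories:
            raise DesignError(
                f"{len(self.categories)} category labels for n_categories="
                f"{self.n_categories}"
            )

    @property
    def trials_per_session(self) -> int:
        return self.n_training_trials + self.n_timed_blocks * self.trials_per_block

    @property
    def chance_accuracy(self) -> float:
        """Accuracy of uniform guessing over the category set."""
        return 1.0 / self.n_categories

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["beep_latencies_ms"] = list(self.beep_latencies_ms)
        d["categories"] = list(self.categories)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentDesign":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "beep_latencies_ms" in d:
            d["beep_latencies_ms"] = tuple(d["beep_latencies_ms"])
        if "categories" in d:
            d["categories"] = tuple(d["categories"])
        return cls(**d)


DEFAULT_DESIGN = ExperimentDesign()
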