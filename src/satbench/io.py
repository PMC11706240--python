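"""Reading, validating and writing trial and model-prediction tables.

Both tables are comma-separated UTF-8 text with a header row.  Missing
responses and reaction times are encoded by the explicit sentinel ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .design import (
    EXPERIMENTS,
    MISSING,
    PERTURBATION_KINDS,
    PHASES,
    ExperimentDesign,
)

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """A table row violates a schema invariant; the message names the row."""


@dataclass
class TrialRecord:
    """One behavioral (or simulated) trial.

    ``response_category`` and ``response_time_ms`` are ``None`` exactly when
    the observer produced no response before the post-beep grace period
    expired; training trials have no beep, so ``beep_latency_ms`` is ``None``
    and ``block_index`` is 0 for them.
    """

    observer_id: str
    experiment: str
    phase: str
    block_index: int
    beep_latency_ms: int | None
    perturbation_kind: str
    perturbation_level: float
    true_category: str
    response_category: str | None
    response_time_ms: float | None
    trial_index: int
    image_id: str

    @property
    def is_timed(self) -> bool:
        return self.phase == "timed"

    @property
    def missing(self) -> bool:
        return self.response_category is None

    @property
    def correct(self) -> bool:
        return self.response_category == self.true_category


TRIAL_COLUMNS = [f.name for f in fields(TrialRecord)]


@dataclass
class ModelPrediction:
    """One model-observer prediction at one timestep for one image."""

    timestep: int
    perturbation_kind: str
    perturbation_level: float
    image_id: str
    true_category: str
    predicted_category: str

    @property
    def correct(self) -> bool:
        return self.predicted_category == self.true_category


PREDICTION_COLUMNS = [f.name for f in fields(ModelPrediction)]


def validate_trial(rec: TrialRecord, design: ExperimentDesign, row: int | None = None) -> None:
    """Check every TrialRecord invariant; raise ValidationError naming the row."""
    where = f"row {row}: " if row is not None else ""
    if rec.experiment not in EXPERIMENTS:
        raise ValidationError(f"{where}unknown experiment {rec.experiment!r}")
    if rec.phase not in PHASES:
        raise ValidationError(f"{where}unknown phase {rec.phase!r}")
    if rec.perturbation_kind not in PERTURBATION_KINDS:
        raise ValidationError(f"{where}unknown perturbation kind {rec.perturbation_kind!r}")
    if rec.perturbation_level < 0:
        raise ValidationError(f"{where}negative perturbation level")
    if rec.true_category not in design.categories:
        raise ValidationError(f"{where}unknown category label {rec.true_category!r}")
    if rec.response_category is not None and rec.response_category not in design.categories:
        raise ValidationError(f"{where}unknown category label {rec.response_category!r}")
    if (rec.response_category is None) != (rec.response_time_ms is None):
        raise ValidationError(
            f"{where}response_category and response_time_ms must be missing together"
        )
    if rec.response_time_ms is not None and rec.response_time_ms < 0:
        raise ValidationError(f"{where}negative response time")
    if rec.trial_index < 1:
        raise ValidationError(f"{where}trial_index must be >= 1")
    if rec.phase == "timed":
        if rec.beep_latency_ms not in design.beep_latencies_ms:
            raise ValidationError(
                f"{where}beep latency {rec.beep_latency_ms} not in design "
                f"{design.beep_latencies_ms}"
            )
        if not 1 <= rec.block_index <= design.n_timed_blocks:
            raise ValidationError(f"{where}block_index {rec.block_index} out of range")
    else:
        if rec.beep_latency_ms is not None:
            raise ValidationError(f"{where}training trial carries a beep latency")
        if rec.block_index != 0:
            raise ValidationError(f"{where}training trials must have block_index 0")


def _opt(value: str, conv):
    return None if value == MISSING else conv(value)


def read_trials(
    path,
    design: ExperimentDesign,
    column_map: Mapping[str, str] | None = None,
) -> list[TrialRecord]:
    """Read and validate a trial table.

    ``column_map`` maps the on-disk column names onto the canonical schema
    (``{"canonical": "file_column", ...}``), for tables exported with other
    headers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing_cols = set(TRIAL_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"missing columns: {sorted(missing_cols)}")
    records: list[TrialRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = dict(zip(df.columns, row))
        try:
            rec = TrialRecord(
                observer_id=d["observer_id"],
                experiment=d["experiment"],
                phase=d["phase"],
                block_index=int(d["block_index"]),
                beep_latency_ms=_opt(d["beep_latency_ms"], lambda s: int(float(s))),
                perturbation_kind=d["perturbation_kind"],
                perturbation_level=float(d["perturbation_level"]),
                true_category=d["true_category"],
                response_category=_opt(d["response_category"], str),
                response_time_ms=_opt(d["response_time_ms"], float),
                trial_index=int(d["trial_index"]),
                image_id=d["image_id"],
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {i}: malformed value ({exc})") from exc
        validate_trial(rec, design, row=i)
        records.append(rec)
    if not records:
        log.warning("empty trial table: %s", path)
    return records


def write_trials(trials: Iterable[TrialRecord], path) -> None:
    """Write a trial table; ``read_trials`` inverts it exactly."""
    rows = []
    for t in trials:
        rows.append(
            {
                "observer_id": t.observer_id,
                "experiment": t.experiment,
                "phase": t.phase,
                "block_index": t.block_index,
                "beep_latency_ms": MISSING if t.beep_latency_ms is None else t.beep_latency_ms,
                "perturbation_kind": t.perturbation_kind,
                "perturbation_level": t.perturbation_level,
                "true_category": t.true_category,
                "response_category": MISSING if t.response_category is None else t.response_category,
                "response_time_ms": MISSING if t.response_time_ms is None else repr(float(t.response_time_ms)),
                "trial_index": t.trial_index,
                "image_id": t.image_id,
            }
        )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_model_predictions(path) -> list[ModelPrediction]:
    """Read a per-timestep prediction table.

    Timesteps must form a contiguous range starting at 1 and each
    (timestep, image) pair may occur only once.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"missing columns: {sorted(missing_cols)}")
    records: list[ModelPrediction] = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = dict(zip(df.columns, row))
        try:
            rec = ModelPrediction(
                timestep=int(d["timestep"]),
                perturbation_kind=d["perturbation_kind"],
                perturbation_level=float(d["perturbation_level"]),
                image_id=d["image_id"],
                true_category=d["true_category"],
                predicted_category=d["predicted_category"],
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {i}: malformed value ({exc})") from exc
        records.append(rec)
    if not records:
        log.warning("empty prediction table: %s", path)
        return records
    steps = sorted({r.timestep for r in records})
    if steps != list(range(1, len(steps) + 1)):
        raise ValidationError(f"non-contiguous timesteps: {steps}")
    seen: set[tuple[int, str]] = set()
    for i, r in enumerate(records):
        key = (r.timestep, r.image_id)
        if key in seen:
            raise ValidationError(f"row {i}: duplicate (timestep, image_id) {key}")
        seen.add(key)
    return records


def write_model_predictions(preds: Iterable[ModelPrediction], path) -> None:
    rows = [
        {
            "timestep": p.timestep,
            "perturbation_kind": p.perturbation_kind,
            "perturbation_level": p.perturbation_level,
            "image_id": p.image_id,
            "true_category": p.true_category,
            "predicted_category": p.predicted_category,
        }
        for p in preds
    ]
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, index=False)


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial records as a DataFrame with ``None`` for missing responses."""
    return pd.DataFrame([vars(t) for t in trials], columns=TRIAL_COLUMNS)


def predictions_to_frame(preds: Sequence[ModelPrediction]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in preds], columns=PREDICTION_COLUMNS)
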