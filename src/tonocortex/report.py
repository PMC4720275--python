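"""End-to-end subject runs and the per-subject assessment report.

``run_subject`` chains preprocessing (or direct synthesis), N100 detection
for all 12 stimulus conditions, and the four-classifier decoding suite, and
serializes everything to a JSON report that is bit-identically regenerable
from the same configuration and seed.  ``render_table`` lays a cohort of
reports out as the per-subject accuracy / p-value table (column blocks
right / left / binaural x [All, 250, 500, 1000, 2000]), flagging p-values
below the 1% significance level.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import protocol as proto
from .classify import ClassificationOutcome, CVConfig, run_classification_suite
from .preprocess import ContinuousRecording, EpochSet, PipelineConfig, preprocess_pipeline
from .protocol import StimulusProtocol, generate_protocol
from .synthetic import SimConfig, simulate_epochs
from .tcwt import N100Detection, detect_all_conditions

logger = logging.getLogger("tonocortex")

SIGNIFICANCE_LEVEL = 0.01


@dataclasses.dataclass
class Profile:
    """Bundle of sizes: the full acquisition protocol vs a fast test profile."""

    name: str
    n_channels: int
    trials_per_type: int
    n_repetitions: int
    n_permutations: int


PAPER_PROFILE = Profile("paper", n_channels=63, trials_per_type=200,
                        n_repetitions=1000, n_permutations=1000)
TEST_PROFILE = Profile("test", n_channels=16, trials_per_type=80,
                       n_repetitions=50, n_permutations=200)
PROFILES = {p.name: p for p in (PAPER_PROFILE, TEST_PROFILE)}


@dataclasses.dataclass
class SubjectReport:
    """Joint result of detection and decoding for one subject/session."""

    subject_id: str
    detections: dict                    # condition str -> detection dict
    classification: dict                # task -> ClassificationOutcome dict
    artifact_summary: dict
    config: dict
    seed: int
    errors: dict

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "SubjectReport":
        return cls(**json.loads(text))


def _detection_section(ep: EpochSet, errors: dict) -> dict:
    try:
        dets = detect_all_conditions(ep)
        return {str(cond): det.to_dict() for cond, det in dets.items()}
    except Exception as exc:            # noqa: BLE001 - recorded, report continues
        logger.warning("N100 detection failed: %s", exc)
        errors["detection"] = str(exc)
        return {}


def _classification_section(ep: EpochSet, cfg: CVConfig, errors: dict) -> dict:
    try:
        outcomes = run_classification_suite(ep, cfg)
    except Exception as exc:            # noqa: BLE001
        logger.warning("classification suite failed: %s", exc)
        errors["classification"] = str(exc)
        return {}
    section = {}
    for name, oc in outcomes.items():
        d = oc.to_dict()
        d.pop("null_accuracies")        # keep the report compact and stable
        section[name] = d
        if oc.error:
            errors[f"classification:{name}"] = oc.error
    return section


def run_subject(subject_id: str,
                source: ContinuousRecording | EpochSet | SimConfig,
                cv_config: CVConfig | None = None,
                pipeline_config: PipelineConfig | None = None,
                protocol: StimulusProtocol | None = None,
                seed: int = 0) -> SubjectReport:
    """Full assessment of one subject from a recording, epochs, or simulator.

    Per-stage failures are recorded under ``errors`` and leave the affected
    report section empty rather than aborting the run.
    """
    errors: dict = {}
    config_snapshot: dict = {"seed": seed}

    if isinstance(source, SimConfig):
        protocol = protocol or generate_protocol(
            n_per_type=source.trials_per_condition, seed=seed)
        dataset = simulate_epochs(source, protocol)
        ep = dataset.epochs
        config_snapshot["simulation"] = source.to_dict()
        artifact_summary = {"synthetic": True, "n_trials": ep.n_trials}
    elif isinstance(source, ContinuousRecording):
        ep, art = preprocess_pipeline(source, pipeline_config)
        artifact_summary = art.summary()
    elif isinstance(source, EpochSet):
        ep = source
        artifact_summary = {"precomputed_epochs": True, "n_trials": ep.n_trials,
                            "rejected_trials": list(ep.rejected_trials)}
    else:
        raise TypeError("source must be a SimConfig, ContinuousRecording or EpochSet")

    cv = cv_config or CVConfig(seed=seed)
    config_snapshot["cv"] = dataclasses.asdict(cv)

    detections = _detection_section(ep, errors)
    classification = _classification_section(ep, cv, errors)

    return SubjectReport(subject_id=subject_id, detections=detections,
                         classification=classification,
                         artifact_summary=artifact_summary,
                         config=config_snapshot, seed=seed, errors=errors)


# ---------------------------------------------------------------------------
# cohort table

_TABLE_MODALITIES = ("right", "left", "binaural")
_TABLE_COLUMNS = ("All", "250", "500", "1000", "2000")


def _task_cells(classification: dict, modality: str) -> list[tuple[float, float]]:
    """(accuracy, p) for the All + four per-frequency columns of one block."""
    task = classification.get(f"frequency:{modality}")
    cells: list[tuple[float, float]] = []
    if not task or task.get("error"):
        return [(float("nan"), float("nan"))] * len(_TABLE_COLUMNS)
    cells.append((task["global_accuracy"], task["p_global"]))
    for f in _TABLE_COLUMNS[1:]:
        acc = task["per_class_accuracy"].get(f, float("nan"))
        p = task["p_per_class"].get(f, float("nan"))
        cells.append((acc, p))
    return cells


def render_table(reports: list[SubjectReport],
                 alpha: float = SIGNIFICANCE_LEVEL) -> pd.DataFrame:
    """Cohort results table: rows = subjects, 30 value columns.

    Column index is a (modality, frequency, measure) MultiIndex; use
    :func:`table_to_markdown` for a human-readable rendering in which
    p-values below ``alpha`` are flagged in bold.
    """
    if not reports:
        raise ValueError("need at least one report")
    columns = pd.MultiIndex.from_tuples(
        [(m, c, meas) for m in _TABLE_MODALITIES for c in _TABLE_COLUMNS
         for meas in ("accuracy", "p")])
    rows = []
    for rep in reports:
        row: list[float] = []
        for m in _TABLE_MODALITIES:
            for acc, p in _task_cells(rep.classification, m):
                row.extend([acc, p])
        rows.append(row)
    return pd.DataFrame(rows, index=[r.subject_id for r in reports],
                        columns=columns)


def table_to_markdown(table: pd.DataFrame,
                      alpha: float = SIGNIFICANCE_LEVEL) -> str:
    """Markdown rendering; significant p-values (p < alpha) are bolded."""
    lines = ["| subject | " + " | ".join(
        f"{m}/{c} acc (p)" for m in _TABLE_MODALITIES for c in _TABLE_COLUMNS) + " |"]
    lines.append("|" + "---|" * (1 + len(_TABLE_MODALITIES) * len(_TABLE_COLUMNS)))
    for subject, row in table.iterrows():
        cells = [str(subject)]
        for m in _TABLE_MODALITIES:
            for c in _TABLE_COLUMNS:
                acc, p = row[(m, c, "accuracy")], row[(m, c, "p")]
                if np.isnan(acc):
                    cells.append("—")
                    continue
                p_str = f"**{p:g}**" if p < alpha else f"{p:g}"
                cells.append(f"{acc:.3f} ({p_str})")
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def table_to_csv(table: pd.DataFrame, path: str | Path) -> None:
    flat = table.copy()
    flat.columns = [f"{m}_{c}_{meas}" for m, c, meas in table.columns]
    flat.rename_axis("subject").to_csv(path)


def table_from_csv(path: str | Path) -> pd.DataFrame:
    flat = pd.read_csv(path, index_col="subject")
    tuples = [tuple(c.rsplit("_", 2)) for c in flat.columns]
    flat.columns = pd.MultiIndex.from_tuples(tuples)
    return flat
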