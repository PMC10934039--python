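"""Three-behavioural-state paradigm: segmentation, skip-rule averaging and features.

The screening protocol records roughly five minutes of ECG across three
contiguous states - Rest (~60 s), a 100-s mental task (random number
generation) and a 60-s rest After the task. Each HRV index is averaged from
30 s after a state's onset to its end, so frames whose 30-s analysis window
reaches back into the previous state are excluded, and autonomic
responsiveness is expressed as Task/Rest and After/Rest ratios. The twelve
quantities {HF, LF, LF/HF, HR} x {Rest, Task/Rest, After/Rest} form the
feature vector of the linear discriminant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CoverageError,
    DivisionGuardError,
    InsufficientDataError,
    ValidationError,
)
from .hrv_spectral import HRVTrend

logger = logging.getLogger(__name__)

STATES = ("Rest", "Task", "After")
INDICES = ("hf", "lf", "lfhf", "hr")

# column order of the discriminant's feature vector: HF triplet, LF triplet,
# LF/HF triplet, HR triplet; within each: Rest level, Task/Rest, After/Rest
FEATURE_NAMES = (
    "hf_rest", "hf_task_rest", "hf_after_rest",
    "lf_rest", "lf_task_rest", "lf_after_rest",
    "lfhf_rest", "lfhf_task_rest", "lfhf_after_rest",
    "hr_rest", "hr_task_rest", "hr_after_rest",
)

EPDS_CUTOFF = 9
RESPIRATION_BAND_PER_MIN = (9.0, 24.0)
SKIP_S = 30.0


@dataclass
class StatePlan:
    """Timing of the contiguous Rest -> Task -> After states, in seconds."""

    rest_dur: float = 60.0
    task_dur: float = 100.0
    after_dur: float = 60.0
    start: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rest_dur", "task_dur", "after_dur"):
            if getattr(self, name) <= SKIP_S:
                raise ValidationError(
                    f"{name} must exceed the {SKIP_S:g}-s skip so the averaging "
                    f"window is non-empty; got {getattr(self, name)}"
                )

    @property
    def rest_start(self) -> float:
        return self.start

    @property
    def task_start(self) -> float:
        return self.start + self.rest_dur

    @property
    def after_start(self) -> float:
        return self.task_start + self.task_dur

    @property
    def end(self) -> float:
        return self.after_start + self.after_dur

    def bounds(self, state: str) -> tuple[float, float]:
        return {
            "Rest": (self.rest_start, self.task_start),
            "Task": (self.task_start, self.after_start),
            "After": (self.after_start, self.end),
        }[state]

    @classmethod
    def from_annotations(cls, annotations: list[tuple[str, float]]) -> "StatePlan":
        """Build a plan from (label, time_s) marks rest_start/task_start/after_start/end."""
        marks = {label: t for label, t in annotations}
        needed = ("rest_start", "task_start", "after_start", "end")
        missing = [m for m in needed if m not in marks]
        if missing:
            raise ValidationError(f"annotations missing marks: {missing}")
        return cls(
            rest_dur=marks["task_start"] - marks["rest_start"],
            task_dur=marks["after_start"] - marks["task_start"],
            after_dur=marks["end"] - marks["after_start"],
            start=marks["rest_start"],
        )

    @classmethod
    def from_yaml(cls, path) -> "StatePlan":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if "annotations" in cfg:
            return cls.from_annotations(
                [(a["label"], float(a["time_s"])) for a in cfg["annotations"]]
            )
        return cls(
            rest_dur=float(cfg.get("rest_dur", 60.0)),
            task_dur=float(cfg.get("task_dur", 100.0)),
            after_dur=float(cfg.get("after_dur", 60.0)),
            start=float(cfg.get("start", 0.0)),
        )


@dataclass
class StateAverages:
    """Per-state means of the four indices over the skip-rule averaging window."""

    values: dict[str, dict[str, float]]

    def __getitem__(self, state: str) -> dict[str, float]:
        return self.values[state]


@dataclass
class FeatureVector:
    """The 12 discriminant inputs, in the fixed equation order (see FEATURE_NAMES)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != 12:
            raise ValidationError(f"feature vector must have 12 entries, got {self.values.size}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values.tolist()))


@dataclass
class SubjectRecord:
    """A screened subject: identity, diagnosis label, EPDS score and obstetric metadata."""

    id: str
    group: str = "unlabeled"
    epds: int = 0
    metadata: dict = field(default_factory=dict)
    respiration_rate: float | None = None
    features: FeatureVector | None = None

    KNOWN_GROUPS = ("control", "PPD", "AJD", "unlabeled")

    def __post_init__(self) -> None:
        if not (0 <= self.epds <= 30):
            raise ValidationError(f"EPDS score {self.epds} outside [0, 30]")


def segment_states(trend: HRVTrend, plan: StatePlan) -> dict[str, HRVTrend]:
    """Slice the trend into Rest/Task/After; a frame on a boundary joins the later state."""
    if trend.t.size == 0 or trend.t[-1] < plan.end - 1e-9:
        have = trend.t[-1] if trend.t.size else float("nan")
        raise CoverageError(
            f"trend ends at {have:.1f} s but the plan requires {plan.end:.1f} s"
        )
    out = {}
    for state in STATES:
        lo, hi = plan.bounds(state)
        mask = (trend.t >= lo) & (trend.t < hi)
        if state == "After":  # closed at the protocol end
            mask = (trend.t >= lo) & (trend.t <= hi + 1e-9)
        out[state] = trend.slice(mask)
    return out


def state_average(
    trend: HRVTrend, state_start: float, state_end: float, skip_s: float = SKIP_S
) -> dict[str, float]:
    """Mean of each index over frames with t in (state_start + skip, state_end].

    Frames are timestamped by their window END, and a frame at t summarises
    data in (t - 30, t]; requiring t > state_start + 30 therefore guarantees
    the average contains no data from the preceding state. LF/HF is averaged
    over the frames where it is defined.
    """
    if state_end - state_start <= skip_s:
        raise ValidationError("state shorter than the skip interval")
    mask = (trend.t > state_start + skip_s + 1e-9) & (trend.t <= state_end + 1e-9)
    if not np.any(mask):
        raise InsufficientDataError(
            f"no trend frames in averaging window ({state_start + skip_s:g}, {state_end:g}] s"
        )
    out = {
        "lf": float(np.mean(trend.lf[mask])),
        "hf": float(np.mean(trend.hf[mask])),
        "hr": float(np.mean(trend.hr[mask])),
    }
    lfhf = trend.lfhf[mask]
    defined = ~np.isnan(lfhf)
    if not np.any(defined):
        logger.warning("LF/HF undefined in every frame of the averaging window")
        out["lfhf"] = float("nan")
    else:
        out["lfhf"] = float(np.mean(lfhf[defined]))
    return out


def state_averages(trend: HRVTrend, plan: StatePlan) -> StateAverages:
    """Skip-rule averages for all three states of the plan."""
    vals = {}
    for state in STATES:
        lo, hi = plan.bounds(state)
        vals[state] = state_average(trend, lo, hi)
    return StateAverages(values=vals)


def response_ratios(avg: StateAverages) -> dict[str, dict[str, float]]:
    """Task/Rest and After/Rest ratio of each index (responsiveness to task load)."""
    rest = avg["Rest"]
    out = {"Task/Rest": {}, "After/Rest": {}}
    for idx in INDICES:
        if not rest[idx] > 0:
            raise DivisionGuardError(
                f"Rest average of {idx!r} is {rest[idx]!r}; response ratio undefined"
            )
        out["Task/Rest"][idx] = avg["Task"][idx] / rest[idx]
        out["After/Rest"][idx] = avg["After"][idx] / rest[idx]
    return out


def build_features(avg: StateAverages, ratios: dict[str, dict[str, float]]) -> FeatureVector:
    """Assemble the 12-entry discriminant input in the fixed equation order."""
    missing = [s for s in STATES if s not in avg.values]
    missing += [r for r in ("Task/Rest", "After/Rest") if r not in ratios]
    if missing:
        raise ValidationError(f"missing components for feature vector: {missing}")
    vals = []
    for idx in ("hf", "lf", "lfhf", "hr"):
        vals.extend([avg["Rest"][idx], ratios["Task/Rest"][idx], ratios["After/Rest"][idx]])
    return FeatureVector(values=np.array(vals))


def features_from_trend(trend: HRVTrend, plan: StatePlan) -> FeatureVector:
    """Convenience composition: state averages -> ratios -> feature vector."""
    avg = state_averages(trend, plan)
    return build_features(avg, response_ratios(avg))


def check_respiration(rate_per_min: float) -> str:
    """'valid' iff the breathing rate lies in the 9-24 /min (0.15-0.4 Hz) HF band.

    Outside that band the HF power no longer reflects respiratory
    parasympathetic modulation; a warning is emitted and the protocol calls
    for paced breathing and re-measurement.
    """
    if rate_per_min <= 0:
        raise ValidationError(f"respiration rate must be positive, got {rate_per_min}")
    lo, hi = RESPIRATION_BAND_PER_MIN
    if lo <= rate_per_min <= hi:
        return "valid"
    warnings.warn(
        f"respiration rate {rate_per_min:g}/min outside {lo:g}-{hi:g}/min: "
        "HF may not reflect respiratory parasympathetic power",
        stacklevel=2,
    )
    return "out_of_band"


def epds_screen(score: int, cutoff: int = EPDS_CUTOFF) -> str:
    """EPDS screening decision: 'positive' iff score >= cutoff (default 9)."""
    if not (0 <= score <= 30):
        raise ValidationError(f"EPDS score {score} outside [0, 30]")
    return "positive" if score >= cutoff else "negative"


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding, as used for reported percentages."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cohort_summary(
    subjects: list[SubjectRecord],
    n_screened: int | None = None,
    cutoff: int = EPDS_CUTOFF,
) -> dict:
    """Cohort accounting and per-group feature statistics.

    Returns group sizes, each labelled patient group's percentage of the
    EPDS-positive enrolled subset, the enrolled share of the screened total
    (when ``n_screened`` is given), and mean +/- s.d. of every feature column
    per group. Percentages are half-up rounded to one decimal.
    """
    if not subjects:
        raise ValidationError("empty cohort")
    for s in subjects:
        if s.group not in SubjectRecord.KNOWN_GROUPS:
            raise ValidationError(f"unknown group label {s.group!r} for subject {s.id}")
    counts = {g: sum(1 for s in subjects if s.group == g) for g in SubjectRecord.KNOWN_GROUPS}
    n_positive = sum(1 for s in subjects if epds_screen(s.epds, cutoff) == "positive")
    out: dict = {
        "n": len(subjects),
        "group_counts": {g: c for g, c in counts.items() if c > 0},
        "n_epds_positive": n_positive,
    }
    if n_screened is not None:
        out["enrolled_pct_of_screened"] = round_half_up(100.0 * n_positive / n_screened)
    if n_positive > 0:
        out["pct_of_epds_positive"] = {
            g: round_half_up(100.0 * counts[g] / n_positive)
            for g in ("PPD", "AJD")
            if counts[g] > 0
        }
    rows = [s for s in subjects if s.features is not None]
    if rows:
        df = pd.DataFrame(
            [dict(group=s.group, **s.features.as_dict()) for s in rows]
        )
        stats = df.groupby("group").agg(["mean", "std"])
        out["feature_stats"] = {
            g: {
                col: (float(stats.loc[g, (col, "mean")]), float(stats.loc[g, (col, "std")]))
                for col in FEATURE_NAMES
            }
            for g in stats.index
        }
    return out


def feature_table(subjects: list[SubjectRecord]) -> pd.DataFrame:
    """Long-format feature table: id, group, epds and the 12 named feature columns."""
    rows = []
    for s in subjects:
        if s.features is None:
            continue
        rows.append({"id": s.id, "group": s.group, "epds": s.epds, **s.features.as_dict()})
    return pd.DataFrame(rows)
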