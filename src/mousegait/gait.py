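"""Gait-parameter extraction from classified footfalls.

A paw's footfall track is segmented into steps — maximal runs of frames in
contact, bridging gaps of up to ``gap_tolerance`` frames left by isolated
missed detections.  For step j with first/mean/last frames t_f, t_m, t_l:

    run duration    RD   = (t_last - t_first) / fps  over all labelled paws
    cadence         Cad  = S / RD                     (S = number of steps)
    stride length   L_j  = ||C(t_m^j) - C(t_m^{j+1})||
    stance          R_j  = (t_l^j - t_f^j) / fps
    swing           D_j  = (t_f^{j+1} - t_l^j) / fps
    duty cycle      DC   = sum(R) / (sum(R) + sum(D))

Averages of the consecutive-pair quantities (stride, swing) divide by the
number of values actually present (S - 1), not S.  Paw supports count, per
frame, how many paws are simultaneously in contact: diagonal dual support is
time with either diagonal pair (LF+RR or RF+LR) down together, three- and
four-point supports use at-least-k semantics, which makes four-point <=
three-point a structural invariant.  Durations are shared frames / fps and
are also reported as fractions of the run duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import GaitConfig
from .classify import (
    DIAGONAL_PAIRS,
    PAW_LABELS,
    ClassifiedFootfall,
    PawLabel,
)
from .detect import PawCluster

__all__ = [
    "Step",
    "StanceSwing",
    "SupportSummary",
    "PawStats",
    "GaitSummary",
    "segment_steps",
    "run_duration",
    "cadence",
    "stride_lengths",
    "swing_and_stance",
    "paw_support",
    "paw_area_intensity",
    "summarize_gait",
    "paw_position_table",
    "steps_table",
]


@dataclass(frozen=True)
class Step:
    """One contact phase of one paw."""

    label: PawLabel
    t_f: int
    t_m: int
    t_l: int
    centroid_at_mean: tuple[float, float]
    frames: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a step needs at least one member frame")
        if not self.t_f <= self.t_m <= self.t_l:
            raise ValueError("step frames must satisfy t_f <= t_m <= t_l")


@dataclass(frozen=True)
class StanceSwing:
    stances_s: tuple[float, ...]
    swings_s: tuple[float, ...]
    avg_stance_s: float
    avg_swing_s: float  # nan when no swing observed
    duty_cycle: float


@dataclass(frozen=True)
class SupportSummary:
    diagonal_dual_s: float
    three_point_s: float
    four_point_s: float
    diagonal_dual_frac: float
    three_point_frac: float
    four_point_frac: float


@dataclass(frozen=True)
class PawStats:
    step_count: int
    cadence_steps_per_s: float
    stride_lengths_px: tuple[float, ...]
    avg_stride_length_px: float  # nan with < 2 steps
    avg_swing_duration_s: float  # nan with < 2 steps
    avg_stance_s: float
    duty_cycle: float
    avg_area_px: float
    avg_intensity: float
    avg_stride_length_mm: Optional[float] = None


@dataclass(frozen=True)
class GaitSummary:
    run_duration_s: float
    per_paw: dict[str, PawStats]
    supports: SupportSummary
    total_step_count: int
    total_cadence_steps_per_s: float

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, float) and math.isnan(x):
                return None
            return x

        d = asdict(self)

        def walk(obj):
            if isinstance(obj, dict):
                return {k: walk(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [walk(v) for v in obj]
            return clean(obj)

        return walk(d)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, s in self.per_paw.items():
            rows.append(
                {
                    "paw": label,
                    "step_count": s.step_count,
                    "cadence_steps_per_s": s.cadence_steps_per_s,
                    "avg_stride_length_px": s.avg_stride_length_px,
                    "avg_swing_duration_s": s.avg_swing_duration_s,
                    "avg_stance_s": s.avg_stance_s,
                    "duty_cycle": s.duty_cycle,
                    "avg_area_px": s.avg_area_px,
                    "avg_intensity": s.avg_intensity,
                }
            )
        return pd.DataFrame(rows)


def segment_steps(
    footfalls: Sequence[ClassifiedFootfall], gap_tolerance: int = 2
) -> list[Step]:
    """Segment one paw's footfalls into contact phases.

    Footfalls must all carry the same label; gaps of up to ``gap_tolerance``
    missing frames are bridged into the surrounding step.  The mean frame is
    floor((t_f + t_l) / 2) snapped to the nearest member frame (ties to the
    earlier frame); the step centroid is that frame's cluster centroid.
    """
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    if not footfalls:
        return []
    labels = {f.label for f in footfalls}
    if len(labels) != 1:
        raise ValueError(f"footfalls of a single paw expected, got labels {labels}")
    label = labels.pop()
    by_frame: dict[int, ClassifiedFootfall] = {}
    for f in footfalls:
        by_frame.setdefault(f.frame_index, f)
    frames = sorted(by_frame)
    groups: list[list[int]] = [[frames[0]]]
    for fr in frames[1:]:
        if fr - groups[-1][-1] <= gap_tolerance + 1:
            groups[-1].append(fr)
        else:
            groups.append([fr])
    steps = []
    for member in groups:
        t_f, t_l = member[0], member[-1]
        target = (t_f + t_l) // 2
        t_m = min(member, key=lambda fr: (abs(fr - target), fr))
        steps.append(
            Step(
                label=label,
                t_f=t_f,
                t_m=t_m,
                t_l=t_l,
                centroid_at_mean=by_frame[t_m].cluster.centroid,
                frames=tuple(member),
            )
        )
    return steps


def run_duration(frames_with_detection: Iterable[int], fps: float = 60.0) -> float:
    """RD = (t_last - t_first) / fps over frames with >= 1 detected paw."""
    frames = list(frames_with_detection)
    if not frames:
        raise ValueError("run duration undefined without any detected paw")
    return (max(frames) - min(frames)) / fps


def cadence(step_count: int, run_duration_s: float) -> float:
    """Cad = S / RD; 0 steps give 0, RD = 0 is reported as nan."""
    if step_count == 0:
        return 0.0
    if run_duration_s <= 0:
        return math.nan
    return step_count / run_duration_s


def stride_lengths(steps: Sequence[Step]) -> tuple[list[float], float]:
    """Per-step stride lengths and their average.

    L_j is the Euclidean distance between the mean-frame centroids of
    consecutive steps; with fewer than two steps the list is empty and the
    average nan.
    """
    values = []
    for a, b in zip(steps, steps[1:]):
        ax, ay = a.centroid_at_mean
        bx, by = b.centroid_at_mean
        values.append(math.hypot(bx - ax, by - ay))
    avg = float(np.mean(values)) if values else math.nan
    return values, avg


def swing_and_stance(steps: Sequence[Step], fps: float = 60.0) -> StanceSwing:
    """Per-step stances/swings, averages, and the duty cycle.

    A single step has a defined stance, no swing, and DC = 1 by convention
    (no airborne time observed).
    """
    if not steps:
        raise ValueError("swing/stance undefined without steps")
    stances = [(s.t_l - s.t_f) / fps for s in steps]
    swings = [(b.t_f - a.t_l) / fps for a, b in zip(steps, steps[1:])]
    sum_r, sum_d = sum(stances), sum(swings)
    if sum_r + sum_d <= 0:
        dc = 1.0
    else:
        dc = sum_r / (sum_r + sum_d)
    return StanceSwing(
        stances_s=tuple(stances),
        swings_s=tuple(swings),
        avg_stance_s=float(np.mean(stances)),
        avg_swing_s=float(np.mean(swings)) if swings else math.nan,
        duty_cycle=dc,
    )


def _contact_frames(steps: Sequence[Step]) -> set[int]:
    out: set[int] = set()
    for s in steps:
        out.update(range(s.t_f, s.t_l + 1))
    return out


def paw_support(
    steps_by_label: Mapping[PawLabel, Sequence[Step]],
    run_duration_s: float,
    fps: float = 60.0,
) -> SupportSummary:
    """Simultaneous-contact durations from shared step frames.

    A step's contact interval is [t_f, t_l] inclusive (bridged gap frames
    count as contact).  Durations are shared frames / fps; fractions divide
    by the run duration.
    """
    contact = {lab: _contact_frames(steps_by_label.get(lab, ())) for lab in PAW_LABELS}
    all_frames = set().union(*contact.values()) if contact else set()
    diag = three = four = 0
    for fr in all_frames:
        down = [lab for lab in PAW_LABELS if fr in contact[lab]]
        n = len(down)
        if any(a in down and b in down for a, b in DIAGONAL_PAIRS):
            diag += 1
        if n >= 3:
            three += 1
        if n == 4:
            four += 1

    def frac(seconds: float) -> float:
        return seconds / run_duration_s if run_duration_s > 0 else math.nan

    return SupportSummary(
        diagonal_dual_s=diag / fps,
        three_point_s=three / fps,
        four_point_s=four / fps,
        diagonal_dual_frac=frac(diag / fps),
        three_point_frac=frac(three / fps),
        four_point_frac=frac(four / fps),
    )


def paw_area_intensity(clusters: Sequence[PawCluster]) -> tuple[float, float]:
    """Average contact area (pixels) and intensity of one paw's clusters.

    The intensity of a cluster is the mean of its green pixel values; the
    paw's average intensity is the mean of those per-cluster means.
    """
    if not clusters:
        raise ValueError("area/intensity undefined without clusters")
    avg_area = float(np.mean([c.size for c in clusters]))
    avg_intensity = float(np.mean([c.mean_g for c in clusters]))
    return avg_area, avg_intensity


def summarize_gait(
    footfalls: Sequence[ClassifiedFootfall], cfg: GaitConfig | None = None
) -> GaitSummary:
    """Assemble the full per-run and per-paw gait summary.

    Unclassified footfalls are excluded.  A paw with no footfalls simply has
    no entry in ``per_paw``; the run duration and the other paws' statistics
    are still computed.  Raises ValueError when no labelled footfall exists.
    """
    cfg = cfg or GaitConfig()
    cfg.validate()
    labelled = [f for f in footfalls if f.label in PAW_LABELS]
    if not labelled:
        raise ValueError("no classified footfalls; cannot summarise gait")
    rd = run_duration((f.frame_index for f in labelled), cfg.fps)

    per_paw: dict[str, PawStats] = {}
    steps_by_label: dict[PawLabel, list[Step]] = {}
    total_steps = 0
    for lab in PAW_LABELS:
        mine = [f for f in labelled if f.label is lab]
        if not mine:
            continue
        steps = segment_steps(mine, cfg.gap_tolerance)
        steps_by_label[lab] = steps
        total_steps += len(steps)
        strides, avg_stride = stride_lengths(steps)
        ss = swing_and_stance(steps, cfg.fps)
        area, intensity = paw_area_intensity([f.cluster for f in mine])
        per_paw[lab.value] = PawStats(
            step_count=len(steps),
            cadence_steps_per_s=cadence(len(steps), rd),
            stride_lengths_px=tuple(strides),
            avg_stride_length_px=avg_stride,
            avg_swing_duration_s=ss.avg_swing_s,
            avg_stance_s=ss.avg_stance_s,
            duty_cycle=ss.duty_cycle,
            avg_area_px=area,
            avg_intensity=intensity,
            avg_stride_length_mm=(
                avg_stride / cfg.px_per_mm if cfg.px_per_mm else None
            ),
        )

    supports = paw_support(steps_by_label, rd, cfg.fps)
    return GaitSummary(
        run_duration_s=rd,
        per_paw=per_paw,
        supports=supports,
        total_step_count=total_steps,
        total_cadence_steps_per_s=cadence(total_steps, rd),
    )


def paw_position_table(footfalls: Sequence[ClassifiedFootfall]) -> pd.DataFrame:
    """Per-frame centroid positions of each labelled paw, for
    distance-versus-time plots."""
    rows = [
        {
            "frame_index": f.frame_index,
            "paw": f.label.value,
            "x": f.cluster.centroid[0],
            "y": f.cluster.centroid[1],
        }
        for f in footfalls
        if f.label in PAW_LABELS
    ]
    return pd.DataFrame(rows, columns=["frame_index", "paw", "x", "y"])


def steps_table(
    footfalls: Sequence[ClassifiedFootfall], cfg: GaitConfig | None = None
) -> pd.DataFrame:
    """Per-step table with stride, stance, swing and the derived swing speed
    (stride / swing) as a convenience column."""
    cfg = cfg or GaitConfig()
    rows = []
    for lab in PAW_LABELS:
        mine = [f for f in footfalls if f.label is lab]
        if not mine:
            continue
        steps = segment_steps(mine, cfg.gap_tolerance)
        strides, _ = stride_lengths(steps)
        ss = swing_and_stance(steps, cfg.fps)
        for j, step in enumerate(steps):
            stride = strides[j] if j < len(strides) else math.nan
            swing = ss.swings_s[j] if j < len(ss.swings_s) else math.nan
            rows.append(
                {
                    "paw": lab.value,
                    "step": j,
                    "t_f": step.t_f,
                    "t_m": step.t_m,
                    "t_l": step.t_l,
                    "x_at_mean": step.centroid_at_mean[0],
                    "y_at_mean": step.centroid_at_mean[1],
                    "stance_s": ss.stances_s[j],
                    "swing_s": swing,
                    "stride_px": stride,
                    "swing_speed_px_per_s": (
                        stride / swing if swing and not math.isnan(swing) and swing > 0 else math.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
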