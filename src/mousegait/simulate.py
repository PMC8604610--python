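"""Synthetic trackway runs with exact ground truth.

The generator renders what the real apparatus images: a dark red-tinted
glass band across which bright-green contact blobs appear wherever a paw
presses the glass, with the mouse moving left to right.  The gait model is a
trot — the diagonal pairs (Left-Front + Right-Rear, Right-Front + Left-Rear)
move in phase, the two pairs half a cycle apart.  Every run opens with a
lead-in standing phase in which all four paws are down (the offset pair's
lead-in stance extends by the half-cycle before its first lift), so frames
with exactly four clusters — the anchor the classifier needs — always exist
and every subsequent swing gap is exactly ``swing_frames`` long.  During a
stance the paw is fixed in world coordinates; each landing advances it by
one stride.

A footfall is a filled palm disk plus ``digit_count`` small digit disks just
ahead of it — disjoint from the palm but within the proximity-clustering
distance, mimicking the real toe prints.  Optional distractors reproduce the
documented failure modes: sub-threshold background shimmer, small bright
specks (below the minimum cluster size), a tail streak (above the maximum),
and paw-sized nose touches ahead of the animal.

Everything the pipeline should recover is a closed-form function of the
config: :func:`analytic_parameters` derives the expected gait summary from
the contact schedule alone, without rendering or detection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .classify import DIAGONAL_PAIRS, PAW_LABELS, PawLabel
from .config import ConfigError
from .evaluate import GroundTruthBox, GroundTruthFrame
from .frames import FrameImage
from .gait import GaitSummary, PawStats, SupportSummary, cadence

__all__ = [
    "SyntheticGaitConfig",
    "ContactPhase",
    "SyntheticRun",
    "contact_schedule",
    "paw_template",
    "generate_run",
    "analytic_parameters",
    "write_run",
    "make_separable_testset",
]


@dataclass(frozen=True)
class SyntheticGaitConfig:
    """Study conditions for one rendered run.

    Defaults give a reduced-canvas (480x120) trackway with a 70-row analysis
    band, a 3-stride trot at 60 fps with an 18-frame stance and a 12-frame
    swing (duty cycle 0.6), 24 px strides, and footfalls around 100 px —
    inside the 65..510 size window of the default detector.  The full-scale
    1920x1080 canvas is just a different width/height/geometry choice.
    """

    fps: float = 60.0
    width: int = 480
    height: int = 120
    enclosure_y_top: int = 25
    enclosure_y_bottom: int = 95
    n_strides: int = 3
    stance_frames: int = 18
    swing_frames: int = 12
    stride_px: int = 24
    lead_in_frames: int = 10
    tail_pad_frames: int = 3
    front_x0: int = 280
    rear_x0: int = 200
    y_right: int = 40
    y_left: int = 80
    palm_radius: float = 5.0
    digit_count: int = 4
    digit_radius: float = 1.0
    digit_gap: float = 2.0
    paw_g: int = 240
    paw_g_jitter: int = 10
    background_rgb: tuple[int, int, int] = (60, 40, 30)
    background_g_noise: int = 10
    noise_speck_rate: float = 0.0
    speck_radius_range: tuple[int, int] = (0, 1)
    tail_streak: bool = False
    nose_touch_frames: tuple[int, ...] = ()
    distractor_g: int = 230
    rng_seed: int = 0

    def validate(self) -> None:
        if self.stance_frames < 1:
            raise ConfigError("stance_frames must be >= 1")
        if self.swing_frames < 1:
            raise ConfigError("swing_frames must be >= 1")
        if self.n_strides < 1 or self.lead_in_frames < 1:
            raise ConfigError("n_strides and lead_in_frames must be >= 1")
        if not (0 <= self.enclosure_y_top < self.enclosure_y_bottom <= self.height):
            raise ConfigError("enclosure band must lie inside the canvas")
        if self.paw_g - self.paw_g_jitter <= self.background_rgb[1] + self.background_g_noise:
            raise ConfigError("paw G must exceed the noisy background G")
        extent = int(math.ceil(self.palm_radius + self.digit_gap + 2 * self.digit_radius)) + 1
        for y in (self.y_right, self.y_left):
            if not (self.enclosure_y_top + extent <= y <= self.enclosure_y_bottom - 1 - extent):
                raise ConfigError("paw track y outside the enclosure band")
        final_x = self.front_x0 + self.n_strides * self.stride_px
        if final_x + extent >= self.width:
            raise ConfigError("paw blob overruns the right edge of the canvas")
        if self.rear_x0 - extent < 0:
            raise ConfigError("paw blob overruns the left edge of the canvas")

    @property
    def cycle_frames(self) -> int:
        return self.stance_frames + self.swing_frames

    @property
    def band(self) -> tuple[int, int]:
        return (self.enclosure_y_top, self.enclosure_y_bottom)


class ContactPhase(NamedTuple):
    start: int  # first contact frame
    end: int  # last contact frame (inclusive)
    x: int
    y: int


@dataclass(frozen=True)
class SyntheticRun:
    config: SyntheticGaitConfig
    frames: tuple[FrameImage, ...]
    truth: tuple[GroundTruthFrame, ...]
    expected: GaitSummary


def _phase_offsets(cfg: SyntheticGaitConfig) -> dict[PawLabel, int]:
    half = cfg.cycle_frames // 2
    return {
        PawLabel.LEFT_FRONT: 0,
        PawLabel.RIGHT_REAR: 0,
        PawLabel.RIGHT_FRONT: half,
        PawLabel.LEFT_REAR: half,
    }


def _base_position(cfg: SyntheticGaitConfig, label: PawLabel) -> tuple[int, int]:
    x = cfg.front_x0 if label in (PawLabel.LEFT_FRONT, PawLabel.RIGHT_FRONT) else cfg.rear_x0
    y = cfg.y_right if label in (PawLabel.RIGHT_FRONT, PawLabel.RIGHT_REAR) else cfg.y_left
    return x, y


def contact_schedule(cfg: SyntheticGaitConfig) -> dict[PawLabel, list[ContactPhase]]:
    """Every paw's contact phases: (first frame, last frame, world x, y).

    Phase 0 is the lead-in stance [0, lead_in + offset - 1]; stride k then
    lands at base_x + k * stride after exactly ``swing_frames`` airborne
    frames.
    """
    cfg.validate()
    offsets = _phase_offsets(cfg)
    schedule: dict[PawLabel, list[ContactPhase]] = {}
    for label in PAW_LABELS:
        x0, y = _base_position(cfg, label)
        phi = offsets[label]
        phases = [ContactPhase(0, cfg.lead_in_frames + phi - 1, x0, y)]
        for k in range(1, cfg.n_strides + 1):
            start = cfg.lead_in_frames + phi + (k - 1) * cfg.cycle_frames + cfg.swing_frames
            phases.append(
                ContactPhase(start, start + cfg.stance_frames - 1, x0 + k * cfg.stride_px, y)
            )
        schedule[label] = phases
    return schedule


def total_frames(cfg: SyntheticGaitConfig) -> int:
    schedule = contact_schedule(cfg)
    last = max(p.end for phases in schedule.values() for p in phases)
    return last + 1 + cfg.tail_pad_frames


def _disk(radius: float) -> np.ndarray:
    r = int(math.floor(radius))
    pts = [
        (dx, dy)
        for dx in range(-r, r + 1)
        for dy in range(-r, r + 1)
        if dx * dx + dy * dy <= radius * radius
    ]
    return np.array(pts, dtype=np.int64)


def paw_template(cfg: SyntheticGaitConfig) -> np.ndarray:
    """Pixel offsets (dx, dy) of one footfall: palm disk + digit disks.

    Digits sit ahead of the palm (+x), disjoint from it but within the
    clustering distance, spread over +-40 degrees.
    """
    palm = _disk(cfg.palm_radius)
    pts = {(int(dx), int(dy)) for dx, dy in palm}
    centre_r = cfg.palm_radius + cfg.digit_gap
    angles = (
        np.linspace(-40, 40, cfg.digit_count) if cfg.digit_count > 1 else np.array([0.0])
    )
    for a in np.deg2rad(angles[: cfg.digit_count]):
        cx = int(round(centre_r * math.cos(a)))
        cy = int(round(centre_r * math.sin(a)))
        for dx, dy in _disk(cfg.digit_radius):
            pts.add((cx + int(dx), cy + int(dy)))
    return np.array(sorted(pts), dtype=np.int64)


def _contacts_by_frame(
    schedule: dict[PawLabel, list[ContactPhase]], n_frames: int
) -> list[list[tuple[PawLabel, int, int]]]:
    table: list[list[tuple[PawLabel, int, int]]] = [[] for _ in range(n_frames)]
    for label in PAW_LABELS:
        for phase in schedule[label]:
            for t in range(phase.start, phase.end + 1):
                table[t].append((label, phase.x, phase.y))
    return table


def _paint(
    canvas: np.ndarray,
    offsets: np.ndarray,
    x: int,
    y: int,
    g_values: np.ndarray,
    rgb_base: tuple[int, int] = (80, 60),
) -> tuple[int, int, int, int]:
    xs = offsets[:, 0] + x
    ys = offsets[:, 1] + y
    canvas[ys, xs, 0] = rgb_base[0]
    canvas[ys, xs, 1] = g_values
    canvas[ys, xs, 2] = rgb_base[1]
    return (int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max()))


def _nose_position(cfg: SyntheticGaitConfig, schedule) -> tuple[int, int]:
    max_x = max(p.x for phases in schedule.values() for p in phases)
    x = max_x + 40
    extent = int(math.ceil(cfg.palm_radius + cfg.digit_gap + 2 * cfg.digit_radius)) + 1
    if x + extent >= cfg.width:
        raise ConfigError("no room for a nose-touch distractor ahead of the run")
    return x, (cfg.y_right + cfg.y_left) // 2


def _tail_region(cfg: SyntheticGaitConfig) -> tuple[slice, slice]:
    # 4 rows x 140 columns = 560 px, above the maximum cluster size (510)
    y_mid = (cfg.y_right + cfg.y_left) // 2
    x_hi = cfg.rear_x0 - 21
    x_lo = max(4, x_hi - 140)
    return slice(y_mid - 2, y_mid + 2), slice(x_lo, x_hi)


def generate_run(cfg: SyntheticGaitConfig) -> SyntheticRun:
    """Render a full synthetic run: frames, per-frame truth boxes, and the
    analytic gait summary.  Bit-identical for a fixed rng_seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    schedule = contact_schedule(cfg)
    n_frames = total_frames(cfg)
    contacts = _contacts_by_frame(schedule, n_frames)
    offsets = paw_template(cfg)
    n_blob = offsets.shape[0]
    bg_r, bg_g, bg_b = cfg.background_rgb
    nose = _nose_position(cfg, schedule) if cfg.nose_touch_frames else None
    if nose is not None:
        bad = [t for t in cfg.nose_touch_frames if not 0 <= t < n_frames]
        if bad:
            raise ConfigError(f"nose_touch_frames outside the run: {bad}")
    tail_ys, tail_xs = _tail_region(cfg) if cfg.tail_streak else (None, None)

    frames: list[FrameImage] = []
    truth: list[GroundTruthFrame] = []
    for t in range(n_frames):
        canvas = np.empty((cfg.height, cfg.width, 3), dtype=np.uint8)
        canvas[:, :, 0] = bg_r
        canvas[:, :, 2] = bg_b
        noise = rng.integers(
            bg_g - cfg.background_g_noise,
            bg_g + cfg.background_g_noise + 1,
            size=(cfg.height, cfg.width),
        )
        canvas[:, :, 1] = np.clip(noise, 0, 255).astype(np.uint8)

        if cfg.tail_streak:
            canvas[tail_ys, tail_xs, 0] = 80
            canvas[tail_ys, tail_xs, 1] = cfg.distractor_g
            canvas[tail_ys, tail_xs, 2] = 60

        keep_away: list[tuple[int, int]] = []
        boxes = []
        for label, x, y in contacts[t]:
            if cfg.paw_g_jitter > 0:
                g = rng.integers(cfg.paw_g - cfg.paw_g_jitter, cfg.paw_g + 1, size=n_blob)
            else:
                g = np.full(n_blob, cfg.paw_g)
            bbox = _paint(canvas, offsets, x, y, g.astype(np.uint8))
            boxes.append(GroundTruthBox(label.value, *bbox))
            keep_away.append((x, y))

        if nose is not None and t in cfg.nose_touch_frames:
            if cfg.paw_g_jitter > 0:
                g = rng.integers(cfg.paw_g - cfg.paw_g_jitter, cfg.paw_g + 1, size=n_blob)
            else:
                g = np.full(n_blob, cfg.paw_g)
            _paint(canvas, offsets, nose[0], nose[1], g.astype(np.uint8))
            keep_away.append(nose)

        if cfg.noise_speck_rate > 0:
            n_specks = int(rng.poisson(cfg.noise_speck_rate))
            y_mid = (cfg.y_right + cfg.y_left) // 2
            for _ in range(n_specks):
                for _attempt in range(20):
                    sx = int(rng.integers(6, cfg.width - 6))
                    sy = int(rng.integers(cfg.enclosure_y_top + 3, cfg.enclosure_y_bottom - 3))
                    if cfg.tail_streak and abs(sy - y_mid) < 7:
                        continue
                    if all(math.hypot(sx - px, sy - py) >= 16 for px, py in keep_away):
                        r = int(rng.integers(cfg.speck_radius_range[0], cfg.speck_radius_range[1] + 1))
                        spots = _disk(r)
                        _paint(canvas, spots, sx, sy, np.full(spots.shape[0], cfg.distractor_g, dtype=np.uint8))
                        keep_away.append((sx, sy))
                        break

        frames.append(FrameImage(canvas, t))
        truth.append(GroundTruthFrame(t, tuple(boxes)))

    expected = analytic_parameters(cfg)
    return SyntheticRun(cfg, tuple(frames), tuple(truth), expected)


def analytic_parameters(cfg: SyntheticGaitConfig) -> GaitSummary:
    """Closed-form expected gait summary, derived from the contact schedule
    only (no rendering, no detection).

    Stance durations are contact-frame counts / fps, swings are airborne
    frame counts / fps, strides are exactly ``stride_px``, and supports come
    from the frame-by-frame contact table of the schedule.  The expected
    intensity is the mean of the uniform jitter, paw_g - jitter/2.
    """
    cfg.validate()
    schedule = contact_schedule(cfg)
    fps = cfg.fps
    first = min(p.start for ph in schedule.values() for p in ph)
    last = max(p.end for ph in schedule.values() for p in ph)
    rd = (last - first) / fps
    area = float(paw_template(cfg).shape[0])
    intensity = cfg.paw_g - cfg.paw_g_jitter / 2.0

    per_paw: dict[str, PawStats] = {}
    total_steps = 0
    for label in PAW_LABELS:
        phases = schedule[label]
        s = len(phases)
        total_steps += s
        stances = [(p.end - p.start + 1) / fps for p in phases]
        swings = [(b.start - a.end - 1) / fps for a, b in zip(phases, phases[1:])]
        strides = [
            math.hypot(b.x - a.x, b.y - a.y) for a, b in zip(phases, phases[1:])
        ]
        sum_r, sum_d = sum(stances), sum(swings)
        per_paw[label.value] = PawStats(
            step_count=s,
            cadence_steps_per_s=cadence(s, rd),
            stride_lengths_px=tuple(strides),
            avg_stride_length_px=float(np.mean(strides)) if strides else math.nan,
            avg_swing_duration_s=float(np.mean(swings)) if swings else math.nan,
            avg_stance_s=float(np.mean(stances)),
            duty_cycle=sum_r / (sum_r + sum_d) if (sum_r + sum_d) > 0 else 1.0,
            avg_area_px=area,
            avg_intensity=intensity,
        )

    n_frames = last + 1
    contacts = _contacts_by_frame(schedule, n_frames)
    diag = three = four = 0
    for entry in contacts:
        down = {label for label, _x, _y in entry}
        if any(a in down and b in down for a, b in DIAGONAL_PAIRS):
            diag += 1
        if len(down) >= 3:
            three += 1
        if len(down) == 4:
            four += 1
    supports = SupportSummary(
        diagonal_dual_s=diag / fps,
        three_point_s=three / fps,
        four_point_s=four / fps,
        diagonal_dual_frac=diag / fps / rd if rd > 0 else math.nan,
        three_point_frac=three / fps / rd if rd > 0 else math.nan,
        four_point_frac=four / fps / rd if rd > 0 else math.nan,
    )
    return GaitSummary(
        run_duration_s=rd,
        per_paw=per_paw,
        supports=supports,
        total_step_count=total_steps,
        total_cadence_steps_per_s=cadence(total_steps, rd),
    )


def write_run(run: SyntheticRun, out_dir: str | Path) -> dict[str, list[Path]]:
    """Write a run to disk: zero-padded PNG frames, one annotation XML per
    frame, and the expected summary as JSON."""
    from . import io as mgio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame_paths = mgio.write_frames(run.frames, out)
    xml_paths = []
    for frame, gt in zip(run.frames, run.truth):
        p = out / f"frame_{frame.frame_index:05d}.xml"
        mgio.write_voc(gt, p, image_size=(frame.width, frame.height))
        xml_paths.append(p)
    expected_path = out / "expected_gait.json"
    expected_path.write_text(json.dumps(run.expected.to_dict(), indent=2, sort_keys=True))
    return {"frames": frame_paths, "annotations": xml_paths, "expected": [expected_path]}


def make_separable_testset(
    seed: int = 0,
    n_frames: int = 6,
    paw_g: int = 230,
    distractor_g: int = 180,
) -> tuple[list[FrameImage], list[GroundTruthFrame], tuple[int, int]]:
    """A small test set where paws and distractors are perfectly separable
    by green intensity: paw blobs at G = ``paw_g`` (annotated), paw-sized
    distractor blobs at G = ``distractor_g`` (not annotated).

    Frames alternate between four-paw and two-paw scenes, mirroring the
    varied scenarios of a real test set.  Returns (frames, truth, band).
    """
    cfg = SyntheticGaitConfig(paw_g=paw_g, paw_g_jitter=0, rng_seed=seed)
    offsets = paw_template(cfg)
    n_blob = offsets.shape[0]
    band = cfg.band
    frames: list[FrameImage] = []
    truth: list[GroundTruthFrame] = []
    rng = np.random.default_rng(seed)
    paw_spots = [
        (cfg.front_x0, cfg.y_left, PawLabel.LEFT_FRONT),
        (cfg.front_x0 + 10, cfg.y_right, PawLabel.RIGHT_FRONT),
        (cfg.rear_x0, cfg.y_left, PawLabel.LEFT_REAR),
        (cfg.rear_x0 + 10, cfg.y_right, PawLabel.RIGHT_REAR),
    ]
    distractor_spots = [(80, 60), (400, 55)]
    for t in range(n_frames):
        canvas = np.empty((cfg.height, cfg.width, 3), dtype=np.uint8)
        canvas[:, :, 0] = cfg.background_rgb[0]
        canvas[:, :, 2] = cfg.background_rgb[2]
        noise = rng.integers(
            cfg.background_rgb[1] - cfg.background_g_noise,
            cfg.background_rgb[1] + cfg.background_g_noise + 1,
            size=(cfg.height, cfg.width),
        )
        canvas[:, :, 1] = noise.astype(np.uint8)
        spots = paw_spots if t % 2 == 0 else paw_spots[:2]
        boxes = []
        for x, y, label in spots:
            bbox = _paint(canvas, offsets, x, y, np.full(n_blob, paw_g, dtype=np.uint8))
            boxes.append(GroundTruthBox(label.value, *bbox))
        for x, y in distractor_spots:
            _paint(canvas, offsets, x, y, np.full(n_blob, distractor_g, dtype=np.uint8))
        frames.append(FrameImage(canvas, t))
        truth.append(GroundTruthFrame(t, tuple(boxes)))
    return frames, truth, band
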