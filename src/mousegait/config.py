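"""Configuration dataclasses for the gait-analysis pipeline.

All tunable parameters of the pipeline live here.  The detection defaults are
the thresholds that performed best in the validation study of the original
trackway system (green threshold 205, proximity threshold 2 px, cluster size
bounds 65..510 px); the frame rate default matches the 60 fps acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


class ConfigError(ValueError):
    """Raised when a configuration value is invalid."""


@dataclass
class PreprocessConfig:
    """Geometric corrections applied to every frame before detection.

    ``distortion_k1`` is the single radial (barrel) coefficient; 0 disables
    undistortion.  ``rotation_deg`` rotates counter-clockwise (as displayed)
    to level the trackway.  ``crop_y_top``/``crop_y_bottom`` are the rows of
    the trackway walls; the frame is cropped to [top, bottom).  The enclosure
    rows delimit the analysis band *within the cropped frame* and are the
    row range handed to detection.
    """

    distortion_k1: float = 0.0
    rotation_deg: float = 0.0
    crop_y_top: int = 0
    crop_y_bottom: Optional[int] = None  # None = full height
    enclosure_y_top: int = 0
    enclosure_y_bottom: Optional[int] = None

    def validate(self, height: Optional[int] = None) -> None:
        import math

        if not math.isfinite(self.distortion_k1):
            raise ConfigError("distortion_k1 must be finite")
        if not math.isfinite(self.rotation_deg):
            raise ConfigError("rotation_deg must be finite")
        bottom = self.crop_y_bottom
        if self.crop_y_top < 0:
            raise ConfigError("crop_y_top must be >= 0")
        if bottom is not None and bottom <= self.crop_y_top:
            raise ConfigError("crop_y_bottom must exceed crop_y_top")
        if height is not None and bottom is not None and bottom > height:
            raise ConfigError(f"crop band [{self.crop_y_top}, {bottom}) outside image of height {height}")
        eb = self.enclosure_y_bottom
        if self.enclosure_y_top < 0 or (eb is not None and eb <= self.enclosure_y_top):
            raise ConfigError("enclosure rows must satisfy 0 <= top < bottom")
        if bottom is not None and eb is not None and eb > bottom - self.crop_y_top:
            raise ConfigError("enclosure band must lie within the cropped frame")

    def resolved_band(self, cropped_height: int) -> tuple[int, int]:
        """The (y_top, y_bottom) analysis band inside a cropped frame."""
        top = self.enclosure_y_top
        bottom = self.enclosure_y_bottom if self.enclosure_y_bottom is not None else cropped_height
        if not (0 <= top < bottom <= cropped_height):
            raise ConfigError(f"enclosure band [{top}, {bottom}) outside cropped height {cropped_height}")
        return top, bottom


@dataclass
class DetectionThresholds:
    """Thresholds for footfall detection (threshold -> cluster -> size filter).

    Comparisons are inclusive: pixels with G >= green_threshold are kept, and
    clusters with min_cluster_size <= N <= max_cluster_size survive.
    """

    green_threshold: int = 205
    proximity_threshold: float = 2.0
    min_cluster_size: int = 65
    max_cluster_size: int = 510

    def validate(self) -> None:
        if not 0 <= self.green_threshold <= 255:
            raise ConfigError("green_threshold must be in [0, 255]")
        if not self.proximity_threshold > 0:
            raise ConfigError("proximity_threshold must be > 0")
        if not 0 < self.min_cluster_size <= self.max_cluster_size:
            raise ConfigError("cluster size bounds must satisfy 0 < min <= max")


@dataclass
class ClassificationConfig:
    """Parameters for four-paw labelling and label propagation.

    ``propagation_distance`` is the maximum centroid displacement (px) for a
    label to spread between clusters, ``frame_window`` how many frames away a
    single propagation hop may reach.  ``right_to_left`` flips the front/rear
    and left/right rules for runs in the opposite direction.
    """

    propagation_distance: float = 20.0
    frame_window: int = 1
    right_to_left: bool = False

    def validate(self) -> None:
        if not self.propagation_distance > 0:
            raise ConfigError("propagation_distance must be > 0")
        if not self.frame_window > 0:
            raise ConfigError("frame_window must be > 0")


@dataclass
class GaitConfig:
    """Temporal/metric parameters for gait-parameter extraction."""

    fps: float = 60.0
    gap_tolerance: int = 2  # bridged missed-detection frames within one step
    px_per_mm: Optional[float] = None

    def validate(self) -> None:
        if not self.fps > 0:
            raise ConfigError("fps must be > 0")
        if self.gap_tolerance < 0:
            raise ConfigError("gap_tolerance must be >= 0")
        if self.px_per_mm is not None and not self.px_per_mm > 0:
            raise ConfigError("px_per_mm must be > 0")


@dataclass
class RunConfig:
    """Full pipeline configuration."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detect: DetectionThresholds = field(default_factory=DetectionThresholds)
    classify: ClassificationConfig = field(default_factory=ClassificationConfig)
    gait: GaitConfig = field(default_factory=GaitConfig)

    def validate(self) -> None:
        self.preprocess.validate()
        self.detect.validate()
        self.classify.validate()
        self.gait.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(klass, key):
            sub = data.get(key) or {}
            known = {f for f in klass.__dataclass_fields__}
            extra = set(sub) - known
            if extra:
                raise ConfigError(f"unknown {key} config keys: {sorted(extra)}")
            return klass(**sub)

        cfg = cls(
            preprocess=build(PreprocessConfig, "preprocess"),
            detect=build(DetectionThresholds, "detect"),
            classify=build(ClassificationConfig, "classify"),
            gait=build(GaitConfig, "gait"),
        )
        cfg.validate()
        return cfg
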