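"""End-to-end pipeline: preprocess -> detect -> classify -> summarise.

Fully deterministic: no stage consumes randomness, so reruns on the same
input and config produce byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as mgio
from .classify import ClassifiedFootfall, classify_paws, group_by_frame
from .config import RunConfig
from .detect import PawCluster, detect_paws
from .frames import FrameImage
from .gait import GaitSummary, paw_position_table, steps_table, summarize_gait
from .preprocess import preprocess_frame

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    detections: pd.DataFrame
    footfalls: list[ClassifiedFootfall]
    summary: GaitSummary
    output_files: dict[str, Path]


def _stage(name: str, fn):
    try:
        return fn()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc


def run_pipeline(
    frames: Sequence[FrameImage],
    cfg: RunConfig,
    out_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run detection, classification and gait summarisation over a run.

    Config validation happens before any processing.  When ``out_dir`` is
    given, detections, classified footfalls, the gait summary and the
    per-frame paw positions are written there as CSV/JSON.
    """
    cfg.validate()
    if not frames:
        raise PipelineError("stage 'input' failed: no frames to process")

    pre = _stage("preprocess", lambda: [preprocess_frame(f, cfg.preprocess) for f in frames])
    band = cfg.preprocess.resolved_band(pre[0].height)
    logger.info("preprocessed %d frames; analysis band rows [%d, %d)", len(pre), *band)

    clusters: list[PawCluster] = _stage(
        "detect", lambda: [c for f in pre for c in detect_paws(f, cfg.detect, band)]
    )
    logger.info("detected %d clusters across %d frames", len(clusters), len(pre))

    footfalls = _stage(
        "classify", lambda: classify_paws(group_by_frame(clusters), cfg.classify)
    )
    n_labelled = sum(not f.excluded for f in footfalls)
    logger.info("classified %d/%d clusters", n_labelled, len(footfalls))

    summary = _stage("gait", lambda: summarize_gait(footfalls, cfg.gait))
    logger.info(
        "run duration %.3f s, %d steps in total",
        summary.run_duration_s,
        summary.total_step_count,
    )

    outputs: dict[str, Path] = {}
    detections_df = mgio.detections_to_dataframe(clusters)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        det_path = out / "detections.csv"
        detections_df.to_csv(det_path, index=False)
        ff_path = out / "footfalls.csv"
        mgio.footfalls_to_dataframe(footfalls).to_csv(ff_path, index=False)
        pos_path = out / "paw_positions.csv"
        paw_position_table(footfalls).to_csv(pos_path, index=False)
        steps_path = out / "steps.csv"
        steps_table(footfalls, cfg.gait).to_csv(steps_path, index=False)
        outputs = {
            "detections": det_path,
            "footfalls": ff_path,
            "paw_positions": pos_path,
            "steps": steps_path,
        }
        outputs.update(mgio.write_gait_summary(summary, out))

    return PipelineResult(detections_df, footfalls, summary, outputs)
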