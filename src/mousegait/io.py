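"""File formats: frame sequences, PascalVOC-style annotations, CSV/JSON/YAML.

Frames are read from a directory of PNG/JPEG images (lexicographic order) or
from a video container when a decoder is available.  Ground truth uses the
LabelImg dialect of PascalVOC XML (``<annotation><object><name>...
<bndbox>``).  Analysis outputs are plain CSV and JSON.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .classify import ClassifiedFootfall, PawLabel
from .config import RunConfig
from .detect import PawCluster
from .evaluate import GroundTruthBox, GroundTruthFrame
from .frames import FrameImage
from .gait import GaitSummary

__all__ = [
    "IMAGE_EXTENSIONS",
    "read_frames",
    "write_frames",
    "read_voc",
    "read_voc_dir",
    "write_voc",
    "detections_to_dataframe",
    "footfalls_to_dataframe",
    "dataframe_to_footfalls",
    "write_gait_summary",
    "load_run_config",
    "save_run_config",
]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


def _as_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return np.ascontiguousarray(arr[:, :, :3])


def read_frames(path: str | Path) -> list[FrameImage]:
    """Load a frame sequence in temporal order with 0-based indices.

    ``path`` may be a directory of images (ordered lexicographically by file
    name; only recognised image extensions are loaded) or a video file.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS),
            key=lambda p: p.name,
        )
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        frames = []
        for i, p in enumerate(files):
            try:
                arr = iio.imread(p)
            except Exception as exc:  # noqa: BLE001 - surface the file name
                raise OSError(f"could not read frame {p}: {exc}") from exc
            frames.append(FrameImage(_as_rgb(np.asarray(arr)), i))
        return frames
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return [
            FrameImage(_as_rgb(np.asarray(arr)), i)
            for i, arr in enumerate(iio.imiter(path))
        ]
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"could not decode video {path}: {exc}") from exc


def write_frames(
    frames: Sequence[FrameImage], out_dir: str | Path, prefix: str = "frame"
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for f in frames:
        p = out / f"{prefix}_{f.frame_index:05d}.png"
        iio.imwrite(p, f.pixels)
        paths.append(p)
    return paths


def write_voc(
    gt: GroundTruthFrame,
    path: str | Path,
    image_size: tuple[int, int] | None = None,
    filename: str | None = None,
) -> Path:
    """Write one frame's boxes as LabelImg-style PascalVOC XML."""
    path = Path(path)
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = path.parent.name
    ET.SubElement(root, "filename").text = filename or f"frame_{gt.frame_index:05d}.png"
    if image_size is not None:
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "width").text = str(image_size[0])
        ET.SubElement(size, "height").text = str(image_size[1])
        ET.SubElement(size, "depth").text = "3"
    for box in gt.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = box.label
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(int(round(box.x_min)))
        ET.SubElement(bnd, "ymin").text = str(int(round(box.y_min)))
        ET.SubElement(bnd, "xmax").text = str(int(round(box.x_max)))
        ET.SubElement(bnd, "ymax").text = str(int(round(box.y_max)))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")
    return path


def _frame_index_from_name(name: str) -> int:
    digits = ""
    for ch in reversed(Path(name).stem):
        if ch.isdigit():
            digits = ch + digits
        elif digits:
            break
    if not digits:
        raise ValueError(f"cannot infer a frame index from {name!r}")
    return int(digits)


def read_voc(path: str | Path) -> GroundTruthFrame:
    """Read one PascalVOC XML annotation file.

    The frame index is taken from the trailing digits of the ``<filename>``
    entry (falling back to the XML file's own name).
    """
    path = Path(path)
    root = ET.parse(path).getroot()
    fn_el = root.find("filename")
    source_name = fn_el.text if fn_el is not None and fn_el.text else path.name
    try:
        frame_index = _frame_index_from_name(source_name)
    except ValueError:
        frame_index = _frame_index_from_name(path.name)
    boxes = []
    for obj in root.findall("object"):
        name = obj.findtext("name", default="")
        bnd = obj.find("bndbox")
        if bnd is None:
            continue
        boxes.append(
            GroundTruthBox(
                label=name,
                x_min=float(bnd.findtext("xmin")),
                y_min=float(bnd.findtext("ymin")),
                x_max=float(bnd.findtext("xmax")),
                y_max=float(bnd.findtext("ymax")),
            )
        )
    return GroundTruthFrame(frame_index, tuple(boxes))


def read_voc_dir(path: str | Path) -> list[GroundTruthFrame]:
    files = sorted(Path(path).glob("*.xml"), key=lambda p: p.name)
    if not files:
        raise FileNotFoundError(f"no annotation XML files in {path}")
    return [read_voc(p) for p in files]


def detections_to_dataframe(clusters: Sequence[PawCluster]) -> pd.DataFrame:
    rows = []
    counters: dict[int, int] = {}
    for c in clusters:
        cid = counters.get(c.frame_index, 0)
        counters[c.frame_index] = cid + 1
        x_min, y_min, x_max, y_max = c.bounding_box
        rows.append(
            {
                "frame_index": c.frame_index,
                "cluster_id": cid,
                "x_centroid": c.centroid[0],
                "y_centroid": c.centroid[1],
                "size": c.size,
                "g_mean": c.mean_g,
                "x_min": x_min,
                "y_min": y_min,
                "x_max": x_max,
                "y_max": y_max,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "frame_index", "cluster_id", "x_centroid", "y_centroid",
            "size", "g_mean", "x_min", "y_min", "x_max", "y_max",
        ],
    )


def footfalls_to_dataframe(footfalls: Sequence[ClassifiedFootfall]) -> pd.DataFrame:
    df = detections_to_dataframe([f.cluster for f in footfalls])
    df["label"] = [f.label.value for f in footfalls]
    df["excluded"] = [f.excluded for f in footfalls]
    return df


def dataframe_to_footfalls(df: pd.DataFrame) -> list[ClassifiedFootfall]:
    """Rebuild footfalls from a footfalls CSV (centroid-level round-trip:
    each row becomes a single-pixel cluster at the rounded centroid carrying
    the stored size via repetition is not attempted — downstream gait code
    only needs frame, label and centroid)."""
    out = []
    for row in df.itertuples(index=False):
        coords = np.array([[round(row.x_centroid), round(row.y_centroid)]], dtype=np.int64)
        g = np.array([round(row.g_mean)], dtype=np.int64)
        cluster = PawCluster(int(row.frame_index), coords, g)
        out.append(ClassifiedFootfall(cluster, PawLabel(row.label)))
    return out


def write_gait_summary(summary: GaitSummary, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "gait_summary.json"
    json_path.write_text(json.dumps(summary.to_dict(), indent=2, sort_keys=True))
    csv_path = out / "gait_summary.csv"
    summary.to_frame().to_csv(csv_path, index=False)
    return {"json": json_path, "csv": csv_path}


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_run_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    return path
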