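"""Configuration, image I/O and the end-to-end pipeline driver.

The pipeline configuration is a strict schema (unknown keys are rejected)
covering channel semantics, seed thresholds, the fusion hyperparameter,
border widths, tracking, augmentation probabilities and training
hyperparameters.  Acquisition times are always taken from the dataset
manifest, never inferred from file names — the acquisition schedule is
irregular (5-min steps for the first hour, 10-min steps afterwards).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .synthetic import MultiChannelFrame, read_dataset
from .dual_unet import load_checkpoint
from .fusion import triple_predict, fuse
from .quantify import select_tracked_cells, quantify_timelapse

logger = logging.getLogger(__name__)

#: default mapping of plane index to channel role for multi-plane TIFFs
DEFAULT_CHANNEL_MAP = {"nuclei": 0, "evs": 1, "merge": 2}
#: RGB convention: red carries the EV dye, green the membrane stain (merge),
#: blue the DNA stain (nuclei)
RGB_CHANNEL_MAP = {"nuclei": 2, "evs": 0, "merge": 1}


class TrainingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    depth: int = 2
    base_features: int = 16
    epochs: int = 50
    lr: float = 1e-3
    batch_size: int = 2
    loss_weights: tuple[float, float] = (1.0, 1.0)
    cls_loss: str = "dice"


class AugmentSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_flip: float = Field(0.3, ge=0, le=1)
    p_contrast: float = Field(0.25, ge=0, le=1)
    p_scale: float = Field(0.25, ge=0, le=1)
    p_blur: float = Field(0.28, ge=0, le=1)
    p_noise: float = Field(0.28, ge=0, le=1)


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    channel_map: dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    seed_thresholds: dict[str, float] = Field(
        default_factory=lambda: {"cells": 0.5, "nuclei": 0.5, "evs": 0.3})
    fusion_tau: float = Field(0.5, ge=0, le=1)
    border_widths: dict[str, int] = Field(
        default_factory=lambda: {"cells": 2, "nuclei": 2, "evs": 1})
    n_tracked_cells: int = 3
    match_radius: float = 15.0
    augment: AugmentSection = Field(default_factory=AugmentSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True)


def read_frame(path: str | Path, channel_map: dict[str, int] | None = None,
               time: float = 0.0) -> MultiChannelFrame:
    """Read a multi-plane TIFF or an RGB image as a MultiChannelFrame.

    TIFF stacks need >= 3 planes (mapped per ``channel_map``, default plane
    0 = nuclei, 1 = EVs, 2 = merge).  RGB images follow the staining
    convention R -> EVs, G -> merge, B -> nuclei.  Grayscale images are
    rejected: the pipeline needs all three channels.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from imageio.v3 import imread
        arr = imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        raise ValueError(f"{path.name}: grayscale image; three channels are required")
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
        arr = np.moveaxis(arr[..., :3], -1, 0)
        cmap = channel_map or RGB_CHANNEL_MAP
    else:
        if arr.shape[0] < 3:
            raise ValueError(f"{path.name}: {arr.shape[0]} planes; need >= 3 "
                             "or an explicit channel mapping")
        cmap = channel_map or DEFAULT_CHANNEL_MAP
    planes = arr.astype(np.float64)
    return MultiChannelFrame(nuclei_plane=planes[cmap["nuclei"]],
                             ev_plane=planes[cmap["evs"]],
                             merge_plane=planes[cmap["merge"]],
                             time=time)


def run_pipeline(config: PipelineConfig, image_dir: str | Path,
                 checkpoint: str | Path, out_dir: str | Path) -> Path:
    """Full Fig-3-style pipeline: triple prediction, fusion, quantification.

    Reads the dataset manifest in ``image_dir``, segments every frame with
    the trained model, writes 16-bit label TIFFs and a fusion log, selects
    the tracked cells and writes the uptake table.  Returns the path of the
    uptake CSV.
    """
    image_dir = Path(image_dir)
    out_dir = Path(out_dir)
    checkpoint = Path(checkpoint)
    if not checkpoint.with_suffix(".npz").exists():
        raise FileNotFoundError(f"checkpoint not found: {checkpoint}")
    if not (image_dir / "manifest.json").exists():
        raise FileNotFoundError(f"manifest not found in {image_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)

    run = load_checkpoint(checkpoint)
    frames, _, manifest = read_dataset(image_dir)
    schedule = [float(t) for t in manifest["times_min"]]

    results = []
    fusion_log = []
    for i, frame in enumerate(frames):
        cells, nuclei, evs = triple_predict(run.model, frame, config.seed_thresholds)
        res = fuse(cells, nuclei, evs, tau=config.fusion_tau)
        results.append(res)
        for kind, lab in (("cells", res.cells), ("nuclei", res.nuclei), ("evs", res.evs)):
            tifffile.imwrite(out_dir / f"seg_{i:03d}_{kind}.tif", lab.astype(np.uint16))
        fusion_log.append({"frame": i, "time_min": schedule[i], **res.report})
        logger.info("frame %d (t=%s min): %s", i, schedule[i], res.report)

    tracks = select_tracked_cells(results, config.n_tracked_cells, config.match_radius)
    table = quantify_timelapse(results, tracks, schedule)
    csv_path = out_dir / "uptake.csv"
    table.to_csv(csv_path, index=False)

    with open(out_dir / "fusion_log.json", "w") as fh:
        json.dump(fusion_log, fh, indent=2)
    with open(out_dir / "run_info.json", "w") as fh:
        json.dump({"config": config.model_dump(), "config_hash": config.config_hash(),
                   "seed": config.seed, "n_frames": len(frames),
                   "tracked_cells": tracks.track_ids}, fh, indent=2)
    return csv_path
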