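"""File-format helpers: 16-bit TIFF rasters, CSV manifests, YAML configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ImageField, LabelMask
from .errors import InvalidParameterError
from .quantify import QCParams, SpotParams
from .segmentation import SegmentationParams
from .synthetic import FieldConfig

MASK_KINDS = ("nuclei", "cells", "cytoplasm", "droplets")


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image))


def load_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_field(row: pd.Series, images_dir) -> ImageField:
    """Rebuild an ImageField from one manifest row and its TIFF files."""
    images_dir = Path(images_dir)
    channels = {}
    for col in row.index:
        if col.startswith("file_") and isinstance(row[col], str):
            channels[col[len("file_") :]] = read_image(images_dir / row[col])
    if not channels:
        raise InvalidParameterError("manifest row has no file_<channel> columns")
    meta = {
        k: row[k]
        for k in ("field_id", "dose_nM", "time_h", "treatment", "seed")
        if k in row.index
    }
    return ImageField(channels=channels, metadata=meta)


def write_masks(mask_dir, field_id: str, masks: dict) -> None:
    """Persist a field's label masks as 16-bit TIFFs plus a parent map CSV."""
    mask_dir = Path(mask_dir)
    mask_dir.mkdir(parents=True, exist_ok=True)
    for kind in MASK_KINDS:
        labels = masks[kind].labels
        if labels.max() > 65535:
            raise InvalidParameterError("too many objects for a 16-bit mask")
        write_image(mask_dir / f"{field_id}_{kind}.tif", labels.astype(np.uint16))
    parents = pd.DataFrame(
        [
            {"droplet_label": k, "parent_cell_label": v if v is not None else ""}
            for k, v in sorted(masks["parent_of"].items())
        ]
    )
    parents.to_csv(mask_dir / f"{field_id}_parents.csv", index=False)


def read_masks(mask_dir, field_id: str) -> dict:
    mask_dir = Path(mask_dir)
    out: dict = {}
    for kind in MASK_KINDS:
        arr = read_image(mask_dir / f"{field_id}_{kind}.tif").astype(np.int32)
        out[kind] = LabelMask(arr, kind)
    parents = pd.read_csv(mask_dir / f"{field_id}_parents.csv")
    parent_of = {}
    for _, row in parents.iterrows():
        v = row["parent_cell_label"]
        parent_of[int(row["droplet_label"])] = int(v) if pd.notna(v) and v != "" else None
    out["parent_of"] = parent_of
    return out


# --------------------------------------------------------------------------
# parameter (de)serialization
# --------------------------------------------------------------------------


def params_to_yaml(path, *, field_config=None, seg_params=None, qc_params=None, spot_params=None):
    from dataclasses import asdict

    doc = {}
    if field_config is not None:
        doc["field_config"] = field_config.to_dict()
    if seg_params is not None:
        doc["seg_params"] = asdict(seg_params)
    if qc_params is not None:
        doc["qc_params"] = asdict(qc_params)
    if spot_params is not None:
        doc["spot_params"] = asdict(spot_params)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def params_from_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out: dict = {}
    if "field_config" in doc:
        out["field_config"] = FieldConfig.from_dict(doc["field_config"])
    if "seg_params" in doc:
        sp = dict(doc["seg_params"])
        for key in ("nucleus_area_px", "droplet_area_px"):
            if key in sp and isinstance(sp[key], list):
                sp[key] = tuple(sp[key])
        out["seg_params"] = SegmentationParams(**sp)
    if "qc_params" in doc:
        out["qc_params"] = QCParams(**doc["qc_params"])
    if "spot_params" in doc:
        out["spot_params"] = SpotParams(**doc["spot_params"])
    return out
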