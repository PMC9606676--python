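"""Image, table, and position-list I/O with acquisition metadata.

The pipeline moves data between staining rounds as multi-channel 16-bit
images annotated with the acquisition metadata needed to convert between
image and microscope-stage coordinates: pixel size (um/px), the stage
position of the top-left pixel, a magnification tag, and the staining
round.  Images are written as OME-TIFF; the handful of fields OME has no
standard home for (round id, stage axis orientation) travel in a YAML
sidecar next to the file.  The cell database is a plain CSV with a JSON
manifest describing which columns belong to which channel; position lists
are JSON (canonical, explicit um units) with a CSV export.

All round-trips are lossless for pixels and for the declared metadata.
"""

from __future__ import annotations

import csv
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml


class MetadataError(ValueError):
    """An image file is missing required acquisition metadata."""


class SchemaError(ValueError):
    """Records do not share a single measurement schema."""


# --------------------------------------------------------------------------
# core containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AxisConvention:
    """Orientation of the stage axes relative to the camera image.

    ``x_sign``/``y_sign`` give the sign of the stage increment per positive
    pixel step along image columns/rows; ``transpose`` swaps the roles of
    rows and columns.  Stage handedness is vendor specific, so the
    convention is explicit data rather than an assumption.
    """

    x_sign: int = 1
    y_sign: int = 1
    transpose: bool = False

    def to_dict(self) -> dict:
        return {"x_sign": self.x_sign, "y_sign": self.y_sign,
                "transpose": self.transpose}

    @classmethod
    def from_dict(cls, d: Mapping) -> "AxisConvention":
        return cls(int(d.get("x_sign", 1)), int(d.get("y_sign", 1)),
                   bool(d.get("transpose", False)))


@dataclass
class MultichannelImage:
    """A set of co-registered 2D channels plus acquisition metadata.

    Every stage of the pipeline consumes and produces this unit.  Pixel
    data are 16-bit unsigned (the camera's detection scale); metadata
    carries what is needed to place the image on the microscope stage.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    stage_origin_um: tuple[float, float] = (0.0, 0.0)
    magnification_tag: str = ""
    round_id: int = 0
    axis_convention: AxisConvention = field(default_factory=AxisConvention)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("image must contain at least one channel")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        self.stage_origin_um = (float(self.stage_origin_um[0]),
                                float(self.stage_origin_um[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def get(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; available: {self.channel_names}"
            ) from None

    def with_channels(self, channels: dict[str, np.ndarray]) -> "MultichannelImage":
        return replace(self, channels=channels)


# --------------------------------------------------------------------------
# OME-TIFF image I/O
# --------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.parent / (path.name + ".meta.yaml")


def write_image(image: MultichannelImage, path: str | Path) -> Path:
    """Write an image as OME-TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    names = image.channel_names
    stack = np.stack([np.asarray(image.channels[n]) for n in names])
    ox, oy = image.stage_origin_um
    meta = {
        "axes": "CYX",
        "Channel": {"Name": names},
        "PhysicalSizeX": image.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": image.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
        "Plane": {
            "PositionX": [ox] * len(names),
            "PositionY": [oy] * len(names),
            "PositionXUnit": ["µm"] * len(names),
            "PositionYUnit": ["µm"] * len(names),
        },
    }
    tifffile.imwrite(path, stack, ome=True, metadata=meta)
    sidecar = {
        "pixel_size_um": float(image.pixel_size_um),
        "stage_origin_um": [ox, oy],
        "magnification_tag": image.magnification_tag,
        "round_id": int(image.round_id),
        "axis_convention": image.axis_convention.to_dict(),
        "channel_names": names,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def _parse_ome(xml_text: str) -> dict:
    """Pull pixel size, channel names and stage position out of OME-XML."""
    out: dict = {}
    root = ET.fromstring(xml_text)
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    pixels = root.find(f".//{ns}Pixels")
    if pixels is None:
        return out
    if "PhysicalSizeX" in pixels.attrib:
        out["pixel_size_um"] = float(pixels.attrib["PhysicalSizeX"])
    names = []
    for ch in pixels.findall(f"{ns}Channel"):
        names.append(ch.attrib.get("Name", f"C{len(names)}"))
    if names:
        out["channel_names"] = names
    plane = pixels.find(f"{ns}Plane")
    if plane is not None and "PositionX" in plane.attrib:
        out["stage_origin_um"] = (float(plane.attrib["PositionX"]),
                                  float(plane.attrib["PositionY"]))
    return out


def read_image(path: str | Path) -> MultichannelImage:
    """Read an OME-TIFF written by :func:`write_image` (or compatible).

    Pixel size is taken from the YAML sidecar if present, else from the
    OME-XML header.  A file carrying neither raises :class:`MetadataError`
    naming the missing field — there is no silent default.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        ome = _parse_ome(tf.ome_metadata) if tf.ome_metadata else {}
    meta: dict = dict(ome)
    sc = _sidecar_path(path)
    if sc.exists():
        meta.update(yaml.safe_load(sc.read_text()))
    if "pixel_size_um" not in meta:
        raise MetadataError(
            f"{path}: missing required metadata field 'pixel_size_um' "
            "(no OME PhysicalSizeX and no sidecar)"
        )
    if data.ndim == 2:
        data = data[None]
    names = meta.get("channel_names") or [f"C{i}" for i in range(data.shape[0])]
    origin = meta.get("stage_origin_um", (0.0, 0.0))
    return MultichannelImage(
        channels={n: data[i] for i, n in enumerate(names)},
        pixel_size_um=float(meta["pixel_size_um"]),
        stage_origin_um=(float(origin[0]), float(origin[1])),
        magnification_tag=str(meta.get("magnification_tag", "")),
        round_id=int(meta.get("round_id", 0)),
        axis_convention=AxisConvention.from_dict(meta.get("axis_convention", {})),
    )


def write_label_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write an integer label mask as a plain TIFF (16/32-bit)."""
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise TypeError("label mask must have an integer dtype")
    if mask.max(initial=0) <= np.iinfo(np.uint16).max and mask.min(initial=0) >= 0:
        mask = mask.astype(np.uint16)
    path = Path(path)
    tifffile.imwrite(path, mask)
    return path


def read_label_mask(path: str | Path) -> np.ndarray:
    mask = tifffile.imread(path)
    return mask.astype(np.int32)


# --------------------------------------------------------------------------
# cell database
# --------------------------------------------------------------------------

def write_cell_database(records, path: str | Path,
                        channel_columns: Mapping[str, Sequence[str]] | None = None,
                        ) -> Path:
    """Write the per-cell measurement database as CSV + JSON manifest.

    ``records`` is either a DataFrame (one row per cell) or a list of
    mappings sharing an identical key set.  Duplicate cell ids and
    mismatched schemas are errors.  The manifest records column order and,
    when given, the channel -> column mapping, so the CSV remains
    self-describing.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        table = records.copy()
    else:
        records = list(records)
        if not records:
            table = pd.DataFrame()
        else:
            keys = set(records[0])
            for r in records[1:]:
                if set(r) != keys:
                    raise SchemaError(
                        "records do not share the same measurement schema: "
                        f"{sorted(keys ^ set(r))} differ"
                    )
            table = pd.DataFrame(records)
    if "cell_id" in table.columns and table["cell_id"].duplicated().any():
        dup = table.loc[table["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell ids: {dup}")
    table.to_csv(path, index=False)
    manifest = {
        "columns": list(table.columns),
        "n_rows": int(len(table)),
        "channel_columns": {k: list(v) for k, v in (channel_columns or {}).items()},
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=1))
    return path


def read_cell_database(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# --------------------------------------------------------------------------
# position lists
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Position:
    label: str
    x_um: float
    y_um: float
    z_um: float | None = None


@dataclass
class PositionList:
    """An ordered list of labeled stage positions (um units)."""

    positions: list[Position]

    def __post_init__(self) -> None:
        labels = [p.label for p in self.positions]
        if len(labels) != len(set(labels)):
            raise ValueError("position labels must be unique")

    def __len__(self) -> int:
        return len(self.positions)

    def sorted(self) -> "PositionList":
        """Row-major acquisition order: by stage y, then x, then label."""
        return PositionList(sorted(self.positions,
                                   key=lambda p: (p.y_um, p.x_um, p.label)))

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        doc = {"units": "um",
               "positions": [{"label": p.label, "x_um": p.x_um, "y_um": p.y_um,
                              "z_um": p.z_um} for p in self.positions]}
        path.write_text(json.dumps(doc, indent=1))
        return path

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "x_um", "y_um", "z_um"])
            for p in self.positions:
                w.writerow([p.label, repr(p.x_um), repr(p.y_um),
                            "" if p.z_um is None else repr(p.z_um)])
        return path

    @classmethod
    def read_json(cls, path: str | Path) -> "PositionList":
        doc = json.loads(Path(path).read_text())
        return cls([Position(d["label"], float(d["x_um"]), float(d["y_um"]),
                             None if d.get("z_um") is None else float(d["z_um"]))
                    for d in doc["positions"]])


# --------------------------------------------------------------------------
# display scaling
# --------------------------------------------------------------------------

def convert_to_8bit(channel: np.ndarray, fixed_min: float, fixed_max: float
                    ) -> np.ndarray:
    """Linearly map 16-bit data to 8 bits under a fixed intensity scaling.

    Values <= ``fixed_min`` map to 0 and >= ``fixed_max`` to 255; between
    the bounds the map is linear, rounded half-away-from-zero (so the exact
    midpoint maps to 128).  Because the bounds are fixed — not derived from
    the image — equal 16-bit pixels map to equal 8-bit pixels across
    images, which is what makes side-by-side visual comparison meaningful.
    """
    if not fixed_min < fixed_max:
        raise ValueError(f"fixed_min ({fixed_min}) must be < fixed_max ({fixed_max})")
    x = np.asarray(channel, dtype=np.float64)
    scaled = (x - fixed_min) * 255.0 / (fixed_max - fixed_min)
    scaled = np.clip(scaled, 0.0, 255.0)
    return np.floor(scaled + 0.5).astype(np.uint8)  # half away from zero (values >= 0)
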