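"""File I/O: TPS landmark files, binary mask images, metadata tables, run configs.

Conventions fixed here once for the whole toolkit:

* internal geometry is in mathematical axes (x rightward, y upward); image
  pixels are flipped from row-major order on load, so a scale photographed
  "anterior leftwards, dorsal upwards" reads the same way internally;
* coordinates are divided by the per-scale ``pixels_per_mm`` calibration at
  load, so centroid sizes are in millimetres and comparable across
  magnifications.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "ScaleRecord",
    "BinaryMask",
    "LandmarkFileRecord",
    "read_tps",
    "write_tps",
    "read_mask",
    "write_mask",
    "read_metadata",
    "write_metadata",
    "load_run_config",
]

BODY_AREAS = frozenset({"C", "D", "E", "H"})


@dataclass(frozen=True)
class ScaleRecord:
    """One scale's metadata row: identity, provenance and calibration."""

    scale_id: str
    species: str
    specimen_id: str = ""
    body_area: str | None = None
    group: str | None = None
    pixels_per_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.pixels_per_mm <= 0:
            raise ValueError(f"{self.scale_id}: pixels_per_mm must be positive")
        if self.body_area is not None and self.body_area not in BODY_AREAS:
            raise ValueError(
                f"{self.scale_id}: body_area {self.body_area!r} not in {sorted(BODY_AREAS)}"
            )


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} pixel grid holding exactly one 4-connected foreground object.

    Produced by :func:`read_mask`, which enforces single-component foreground
    and border padding; ``pixels`` is row-major (row 0 at the image top).
    """

    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask pixels must be 0 or 1")
        object.__setattr__(self, "pixels", px.astype(np.uint8))
        self.pixels.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class LandmarkFileRecord:
    """One LM= block of a TPS file: an ordered point chain plus its id."""

    shape_id: str
    points: np.ndarray = field(repr=False)
    image: str | None = None
    scale_factor: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (k, 2)")
        object.__setattr__(self, "points", pts)
        self.points.setflags(write=False)


class TPSParseError(ValueError):
    pass


def read_tps(path, *, flip_y: bool = False, apply_scale: bool = True) -> list[LandmarkFileRecord]:
    """Parse a TPS landmark file into one record per ``LM=`` block.

    Honors the LM/ID/IMAGE/SCALE keys of the classic dialect. ``SCALE=``
    multiplies the coordinates when ``apply_scale`` (converting digitizer
    units to physical units). TPS files do not declare their y-axis
    convention; pass ``flip_y=True`` for digitizers that measured y downward
    (applied as y -> -y). CURVES/POINTS blocks (digitized semilandmarks) are
    rejected: semilandmark positions are constructed, never digitized.
    """
    text = Path(path).read_text(encoding="utf-8")
    records: list[LandmarkFileRecord] = []
    lines = [ln.strip() for ln in text.splitlines()]
    i = 0
    block = 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        key = line.split("=", 1)[0].upper()
        if key in ("CURVES", "POINTS"):
            raise TPSParseError(
                f"{path}: {key}= blocks are not supported; "
                "semilandmarks are constructed from the outline, not digitized"
            )
        if key != "LM":
            raise TPSParseError(f"{path}: unexpected line {line!r} outside an LM block")
        block += 1
        try:
            declared = int(line.split("=", 1)[1])
        except (IndexError, ValueError) as exc:
            raise TPSParseError(f"{path}: record {block}: bad LM count {line!r}") from exc
        i += 1
        pts = []
        while i < len(lines) and len(pts) < declared:
            row = lines[i]
            if not row:
                i += 1
                continue
            parts = row.split()
            if len(parts) != 2:
                break
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except ValueError:
                break
            i += 1
        if len(pts) != declared:
            raise TPSParseError(
                f"{path}: record {block}: LM={declared} but {len(pts)} coordinate lines"
            )
        shape_id, image, scale_factor = f"record_{block}", None, None
        while i < len(lines):
            row = lines[i]
            if not row:
                i += 1
                continue
            rkey = row.split("=", 1)[0].upper()
            if rkey == "ID":
                shape_id = row.split("=", 1)[1].strip()
            elif rkey == "IMAGE":
                image = row.split("=", 1)[1].strip()
            elif rkey == "SCALE":
                scale_factor = float(row.split("=", 1)[1])
            elif rkey in ("CURVES", "POINTS"):
                raise TPSParseError(f"{path}: {rkey}= blocks are not supported")
            else:
                break
            i += 1
        points = np.asarray(pts, dtype=float)
        if apply_scale and scale_factor is not None:
            points = points * scale_factor
        if flip_y:
            points = points * np.array([1.0, -1.0])
        records.append(
            LandmarkFileRecord(shape_id=shape_id, points=points, image=image,
                               scale_factor=scale_factor)
        )
    return records


def write_tps(records, path) -> None:
    """Write landmark records as a TPS file (LM/ID keys, full precision)."""
    out = []
    for rec in records:
        out.append(f"LM={len(rec.points)}")
        for x, y in rec.points:
            out.append(f"{x:.12g} {y:.12g}")
        out.append(f"ID={rec.shape_id}")
        if rec.image:
            out.append(f"IMAGE={rec.image}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def read_mask(path, *, pad: int = 1, max_discard_fraction: float = 0.5) -> BinaryMask:
    """Load an image file as a single-object binary mask.

    The image is thresholded at the midpoint of its value range; polarity is
    auto-detected so that the border-dominant color becomes background. Only
    the largest 4-connected foreground component is kept (smaller ones are
    discarded with a warning); the result is padded by ``pad`` background
    pixels so the object never touches the border.
    """
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    img = img.astype(float)
    lo, hi = float(img.min()), float(img.max())
    if lo == hi:
        raise ValueError(f"{path}: no foreground object (uniform image)")
    fg = img > (lo + hi) / 2.0
    border = np.concatenate((fg[0], fg[-1], fg[:, 0], fg[:, -1]))
    if border.mean() > 0.5:  # bright border: dark pixels are the object
        fg = ~fg
    if not fg.any():
        raise ValueError(f"{path}: no foreground object")
    labels, n_comp = ndimage.label(fg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n_comp > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n_comp + 1))
        keep = int(np.argmax(sizes)) + 1
        discarded = float(sizes.sum() - sizes[keep - 1])
        frac = discarded / float(sizes.sum())
        msg = (f"{path}: discarded {n_comp - 1} extra foreground component(s), "
               f"{discarded:.0f} px ({100 * frac:.1f}% of foreground)")
        if frac > max_discard_fraction:
            warnings.warn(msg + " — exceeds max_discard_fraction", stacklevel=2)
        logger.warning(msg)
        fg = labels == keep
    fg = np.pad(fg, max(int(pad), 1))
    # trim excess all-background margin but keep `pad` rows/cols
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    p = max(int(pad), 1)
    fg = fg[max(rows[0] - p, 0):rows[-1] + p + 1, max(cols[0] - p, 0):cols[-1] + p + 1]
    return BinaryMask(fg.astype(np.uint8))


def write_mask(mask: BinaryMask, path) -> None:
    """Write as an 8-bit image, black object on white (the silhouette style)."""
    img = np.where(np.asarray(mask.pixels, bool), 0, 255).astype(np.uint8)
    iio.imwrite(path, img)


_REQUIRED_COLS = ("scale_id", "species")
_OPTIONAL_COLS = ("specimen_id", "body_area", "group", "pixels_per_mm")


def read_metadata(path) -> list[ScaleRecord]:
    """Read a comma-delimited metadata table into validated records.

    Requires columns ``scale_id`` and ``species``; ``specimen_id``,
    ``body_area``, ``group`` and ``pixels_per_mm`` (default 1.0, i.e. pixel
    units) are optional. Duplicate scale_id rows are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    dupes = df.loc[df["scale_id"].duplicated(), "scale_id"].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate scale_id(s): {', '.join(sorted(set(dupes)))}")
    records = []
    for _, row in df.iterrows():
        def get(col, default=None):
            val = row.get(col)
            return default if val is None or (isinstance(val, float) and np.isnan(val)) else val

        records.append(ScaleRecord(
            scale_id=str(row["scale_id"]),
            species=str(row["species"]),
            specimen_id=str(get("specimen_id", "")),
            body_area=get("body_area"),
            group=get("group"),
            pixels_per_mm=float(get("pixels_per_mm", 1.0)),
        ))
    return records


def write_metadata(records, path) -> None:
    rows = [{
        "scale_id": r.scale_id, "species": r.species, "specimen_id": r.specimen_id,
        "body_area": r.body_area, "group": r.group, "pixels_per_mm": r.pixels_per_mm,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_run_config(path) -> dict:
    """Load a YAML run configuration as a plain dict (flags override it)."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a YAML mapping")
    return cfg
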