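"""Domain types and file I/O for two-channel stimulated Raman scattering imagery.

An SRS dataset carries exactly two channels: a lipid channel acquired at the
CH2 stretch (2850 cm^-1) and a protein channel at the CH3 stretch
(2930 cm^-1).  Everything downstream (flat-field correction, stitching,
unmixing, rendering) assumes the canonical in-memory channel order
``(lipid, protein)``; readers enforce it regardless of on-disk order.

Conventions
-----------
* pixel indices are 0-based, row-major; y increases downward;
* stage coordinates are in micrometres and refer to the centre of a tile's
  top-left pixel;
* intensities are stored on disk as 16-bit unsigned integers with a floating
  scale factor (recorded in the TIFF description) and handled in memory as
  float64.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import FormatError, ManifestError

LIPID_SHIFT_CM1 = 2850.0
PROTEIN_SHIFT_CM1 = 2930.0

#: CSV columns of a tile manifest, in order.
MANIFEST_COLUMNS = ["path", "channel_order", "row", "col", "stage_x_um", "stage_y_um"]


@dataclass(frozen=True)
class ChannelSpec:
    """One acquisition channel: a name and its Raman shift in cm^-1."""

    name: str
    raman_shift: float

    def __post_init__(self):
        expected = {"lipid": LIPID_SHIFT_CM1, "protein": PROTEIN_SHIFT_CM1}
        if self.name not in expected:
            raise ValueError(f"channel name must be 'lipid' or 'protein', got {self.name!r}")
        if self.raman_shift != expected[self.name]:
            raise ValueError(
                f"channel {self.name!r} must be at {expected[self.name]} cm^-1, "
                f"got {self.raman_shift}"
            )


#: The canonical channel pair, in canonical order.
CANONICAL_CHANNELS = (
    ChannelSpec("lipid", LIPID_SHIFT_CM1),
    ChannelSpec("protein", PROTEIN_SHIFT_CM1),
)


def _check_two_channel(pixels: np.ndarray, what: str) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 3 or pixels.shape[0] != 2:
        raise ValueError(f"{what} must have shape (2, H, W), got {pixels.shape}")
    if not np.isfinite(pixels).all():
        raise ValueError(f"{what} contains non-finite intensities")
    if (pixels < 0).any():
        raise ValueError(f"{what} contains negative intensities")
    return pixels


@dataclass
class SRSTile:
    """A single two-channel frame with its position on the stage.

    Parameters
    ----------
    pixels
        Array of shape ``(2, H, W)``: channel 0 lipid, channel 1 protein.
    row_index, col_index
        0-based grid coordinates within the acquisition raster.
    stage_x, stage_y
        Stage position (um) of the centre of pixel (0, 0).
    pixel_size
        Physical pixel pitch in um.
    field_of_view
        Side length of the square frame in um; must agree with
        ``pixel_size * side`` within 0.5 %.
    """

    pixels: np.ndarray
    row_index: int
    col_index: int
    stage_x: float
    stage_y: float
    pixel_size: float
    field_of_view: float

    def __post_init__(self):
        self.pixels = _check_two_channel(self.pixels, "tile pixels")
        h, w = self.pixels.shape[1:]
        if h != w:
            raise ValueError(f"tiles are square frames, got {h}x{w}")
        if self.pixel_size <= 0 or self.field_of_view <= 0:
            raise ValueError("pixel_size and field_of_view must be positive")
        if abs(self.pixel_size * w - self.field_of_view) > 0.005 * self.field_of_view:
            raise ValueError(
                f"pixel_size * side = {self.pixel_size * w:.3f} um disagrees with "
                f"field_of_view = {self.field_of_view} um by more than 0.5%"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    @property
    def lipid(self) -> np.ndarray:
        return self.pixels[0]

    @property
    def protein(self) -> np.ndarray:
        return self.pixels[1]


@dataclass
class ManifestEntry:
    path: str | None
    channel_order: tuple[str, str]
    row: int
    col: int
    stage_x_um: float
    stage_y_um: float

    def __post_init__(self):
        order = tuple(self.channel_order)
        if sorted(order) != ["lipid", "protein"]:
            raise ManifestError(f"channel_order must name lipid and protein once, got {order}")
        self.channel_order = order


@dataclass
class TileManifest:
    """Plain-text description of a tile set: file paths, channel order, grid layout."""

    entries: list[ManifestEntry]
    grid_rows: int
    grid_cols: int
    overlap_fraction: float = 0.10

    def __post_init__(self):
        if not (0 <= self.overlap_fraction < 0.5):
            raise ManifestError(f"overlap_fraction must be in [0, 0.5), got {self.overlap_fraction}")
        coords = [(e.row, e.col) for e in self.entries]
        if len(set(coords)) != len(coords):
            dupes = sorted({c for c in coords if coords.count(c) > 1})
            raise ManifestError(f"duplicate grid coordinates in manifest: {dupes}")
        expected = {(r, c) for r in range(self.grid_rows) for c in range(self.grid_cols)}
        if set(coords) != expected:
            missing = sorted(expected - set(coords))
            extra = sorted(set(coords) - expected)
            raise ManifestError(
                f"manifest does not cover a dense {self.grid_rows}x{self.grid_cols} grid; "
                f"missing {missing}, unexpected {extra}"
            )
        self._check_monotone_stages()

    def _check_monotone_stages(self):
        by_coord = {(e.row, e.col): e for e in self.entries}
        for r in range(self.grid_rows):
            xs = [by_coord[(r, c)].stage_x_um for c in range(self.grid_cols)]
            if any(b <= a for a, b in zip(xs, xs[1:])):
                raise ManifestError(f"stage_x not increasing along row {r}")
        for c in range(self.grid_cols):
            ys = [by_coord[(r, c)].stage_y_um for r in range(self.grid_rows)]
            if any(b <= a for a, b in zip(ys, ys[1:])):
                raise ManifestError(f"stage_y not increasing along column {c}")


def write_manifest(manifest: TileManifest, path: str | os.PathLike) -> None:
    rows = [
        {
            "path": e.path,
            "channel_order": "|".join(e.channel_order),
            "row": e.row,
            "col": e.col,
            "stage_x_um": e.stage_x_um,
            "stage_y_um": e.stage_y_um,
        }
        for e in manifest.entries
    ]
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# grid_rows={manifest.grid_rows} grid_cols={manifest.grid_cols} "
                 f"overlap_fraction={manifest.overlap_fraction}\n")
        df.to_csv(fh, index=False)


def read_manifest(path: str | os.PathLike) -> TileManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("#"):
            for token in first[1:].split():
                k, _, v = token.partition("=")
                meta[k] = v
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    entries = [
        ManifestEntry(
            path=str(r.path),
            channel_order=tuple(str(r.channel_order).split("|")),
            row=int(r.row),
            col=int(r.col),
            stage_x_um=float(r.stage_x_um),
            stage_y_um=float(r.stage_y_um),
        )
        for r in df.itertuples()
    ]
    grid_rows = int(meta.get("grid_rows", max(e.row for e in entries) + 1))
    grid_cols = int(meta.get("grid_cols", max(e.col for e in entries) + 1))
    overlap = float(meta.get("overlap_fraction", 0.10))
    return TileManifest(entries, grid_rows, grid_cols, overlap)


@dataclass
class Mosaic:
    """Stitched whole-specimen two-channel image on one physical coordinate frame."""

    pixels: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = _check_two_channel(self.pixels, "mosaic pixels")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    @property
    def lipid(self) -> np.ndarray:
        return self.pixels[0]

    @property
    def protein(self) -> np.ndarray:
        return self.pixels[1]

    @property
    def extent_um(self) -> tuple[float, float]:
        h, w = self.shape
        return (h * self.pixel_size, w * self.pixel_size)


@dataclass
class RGBRendering:
    """8-bit three-channel visualization of a chemical map."""

    pixels: np.ndarray
    mode: str
    pixel_size: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"rendering must have shape (H, W, 3), got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("rendering values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.mode not in ("pseudo_he", "two_color"):
            raise ValueError(f"mode must be 'pseudo_he' or 'two_color', got {self.mode!r}")


# ---------------------------------------------------------------------------
# Tile / mosaic TIFF I/O


def write_tile(tile: SRSTile, path: str | os.PathLike) -> None:
    """Write a tile as a two-plane 16-bit TIFF with a stored intensity scale."""
    peak = float(tile.pixels.max())
    scale = peak / 65535.0 if peak > 0 else 1.0
    data = np.round(tile.pixels / scale).astype(np.uint16)
    desc = {
        "pixel_size_um": tile.pixel_size,
        "field_of_view_um": tile.field_of_view,
        "intensity_scale": scale,
        "channels": ["lipid", "protein"],
    }
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        description=json.dumps(desc),
        resolution=(1e4 / tile.pixel_size, 1e4 / tile.pixel_size),
        resolutionunit="CENTIMETER",
    )


def _read_tile_planes(path: Path) -> tuple[np.ndarray, dict]:
    if not path.exists():
        raise FileNotFoundError(f"tile image not found: {path}")
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if data.ndim == 3 and data.shape[2] == 2 and data.shape[0] != 2:
        data = np.moveaxis(data, 2, 0)
    if data.ndim != 3 or data.shape[0] != 2:
        n = data.shape[0] if data.ndim == 3 else 1
        raise FormatError(f"{path}: expected 2 image planes, found {n}")
    scale = float(meta.get("intensity_scale", 1.0))
    return data.astype(float) * scale, meta


def read_tile_stack(
    manifest: TileManifest,
    base_dir: str | os.PathLike | None = None,
    pixel_size_um: float | None = None,
) -> list[SRSTile]:
    """Load every tile named in a manifest, reordered into canonical channels.

    Channel 0 of each returned tile is always the lipid channel (2850 cm^-1),
    whatever the on-disk plane order declared in the manifest.  Intensities
    are rescaled back to their acquisition values via the stored scale factor
    but are otherwise untouched.

    Parameters
    ----------
    manifest
        Tile manifest; every entry must name a readable two-plane image.
    base_dir
        Directory that relative manifest paths are resolved against.
    pixel_size_um
        Fallback pixel pitch when a file carries no metadata of its own.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    tiles = []
    for entry in manifest.entries:
        if entry.path is None:
            raise ManifestError(f"manifest entry ({entry.row},{entry.col}) has no file path")
        p = Path(entry.path)
        if not p.is_absolute():
            p = base / p
        data, meta = _read_tile_planes(p)
        if entry.channel_order != ("lipid", "protein"):
            data = data[::-1]
        psz = meta.get("pixel_size_um", pixel_size_um)
        if psz is None:
            raise FormatError(f"{p}: no pixel size in metadata and none supplied")
        fov = meta.get("field_of_view_um", float(psz) * data.shape[2])
        tiles.append(
            SRSTile(
                pixels=data,
                row_index=entry.row,
                col_index=entry.col,
                stage_x=entry.stage_x_um,
                stage_y=entry.stage_y_um,
                pixel_size=float(psz),
                field_of_view=float(fov),
            )
        )
    return tiles


def write_mosaic(mosaic: Mosaic, path: str | os.PathLike) -> None:
    desc = {
        "pixel_size_um": mosaic.pixel_size,
        "origin_um": list(mosaic.origin),
        "channels": ["lipid", "protein"],
        "provenance": _jsonable(mosaic.provenance),
    }
    tifffile.imwrite(
        path,
        mosaic.pixels.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(desc),
        resolution=(1e4 / mosaic.pixel_size, 1e4 / mosaic.pixel_size),
        resolutionunit="CENTIMETER",
    )


def read_mosaic(path: str | os.PathLike) -> Mosaic:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mosaic file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray().astype(float)
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {}
    return Mosaic(
        pixels=data,
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        origin=tuple(meta.get("origin_um", (0.0, 0.0))),
        provenance=meta.get("provenance", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


# ---------------------------------------------------------------------------
# Rendering I/O


def write_rendering(rendering: RGBRendering, path: str | os.PathLike) -> None:
    """Write a rendering losslessly (PNG or TIFF by extension), with resolution metadata."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            rendering.pixels,
            photometric="rgb",
            description=json.dumps({"mode": rendering.mode, "pixel_size_um": rendering.pixel_size}),
            resolution=(1e4 / rendering.pixel_size, 1e4 / rendering.pixel_size),
            resolutionunit="CENTIMETER",
        )
    elif suffix == ".png":
        img = Image.fromarray(rendering.pixels, mode="RGB")
        dpi = 25400.0 / rendering.pixel_size  # um/px -> dots per inch
        img.save(path, format="PNG", dpi=(dpi, dpi))
    else:
        raise ValueError(f"unsupported rendering format {suffix!r}; use .png or .tif")


def read_rendering(path: str | os.PathLike, mode: str = "pseudo_he") -> RGBRendering:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"rendering file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        meta = json.loads(desc) if desc else {}
        return RGBRendering(data, meta.get("mode", mode), float(meta.get("pixel_size_um", 1.0)))
    img = Image.open(path)
    dpi = img.info.get("dpi", (25400.0, 25400.0))[0]
    pixel_size = 25400.0 / dpi if dpi else 1.0
    return RGBRendering(np.asarray(img.convert("RGB")), mode, pixel_size)
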