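"""GeoTIFF raster input/output for scenes, labels and plot maps.

Rasters are stored as TIFF with genuine GeoTIFF georeference tags
(ModelPixelScale 33550, ModelTiepoint 33922) written through ``tifffile``,
plus a JSON ImageDescription carrying the CRS string, band roles and the
nodata value.  Band stacks are written band-major (C, H, W) and exposed
in-memory as H×W×C float arrays.

The ten canonical band roles follow the Sentinel-2 feature design:
blue, green, red, three vegetation red-edge bands, NIR, a fourth red-edge
band, and two SWIR bands.  Labels use −1 as the ignore/unlabeled value;
class ids are corn=0, rice=1, soybean=2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Canonical band-role order (Sentinel-2 bands 2..8, 8a, 11, 12).
BAND_ROLES = (
    "blue",        # band 2
    "green",       # band 3
    "red",         # band 4
    "red_edge1",   # band 5
    "red_edge2",   # band 6
    "red_edge3",   # band 7
    "nir",         # band 8
    "red_edge4",   # band 8a
    "swir1",       # band 11
    "swir2",       # band 12
)

#: Sentinel-2 band names in the same order.
BAND_NAMES = (
    "band2", "band3", "band4", "band5", "band6", "band7",
    "band8", "band8a", "band11", "band12",
)

IGNORE_LABEL = -1
CLASS_NAMES = ("corn", "rice", "soybean")

DEFAULT_TRANSFORM = (0.0, 0.0, 10.0, 10.0)  # x0, y0, xres, yres (metres)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922


class RasterFormatError(ValueError):
    """Raised when an on-disk raster does not match the expected format."""


class RasterAlignmentError(ValueError):
    """Raised when rasters of one scene disagree in shape."""


@dataclass
class SceneBundle:
    """Aligned band stack, label raster and plot-id raster for one scene.

    ``bands`` is H×W×10 float reflectance in canonical band-role order,
    ``labels`` is H×W int with −1 for unlabeled pixels, ``plots`` is H×W
    int plot ids with 0 meaning no plot.  ``transform`` is
    (x0, y0, xres, yres); ``crs`` an opaque string carried through.
    """

    bands: np.ndarray
    labels: np.ndarray
    plots: np.ndarray
    transform: tuple[float, float, float, float] = DEFAULT_TRANSFORM
    crs: str | None = None
    band_roles: tuple[str, ...] = BAND_ROLES

    def __post_init__(self):
        h, w = self.bands.shape[:2]
        if self.bands.ndim != 3 or self.bands.shape[2] != len(self.band_roles):
            raise RasterFormatError(
                f"band stack must be H×W×{len(self.band_roles)}, got {self.bands.shape}"
            )
        for name, r in (("labels", self.labels), ("plots", self.plots)):
            if r.shape != (h, w):
                raise RasterAlignmentError(
                    f"{name} shape {r.shape} does not match bands {(h, w)}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[:2]

    def band(self, role: str) -> np.ndarray:
        """Single band plane by role name (e.g. 'nir')."""
        try:
            i = self.band_roles.index(role)
        except ValueError:
            raise KeyError(f"unknown band role {role!r}") from None
        return self.bands[:, :, i]


def _geo_extratags(transform) -> list:
    x0, y0, xres, yres = transform
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (float(xres), float(yres), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(y0), 0.0)),
    ]


def _read_geo(tif: tifffile.TiffFile):
    page = tif.pages[0]
    transform = DEFAULT_TRANSFORM
    meta: dict = {}
    if _TAG_PIXEL_SCALE in page.tags and _TAG_TIEPOINT in page.tags:
        sx, sy, _ = page.tags[_TAG_PIXEL_SCALE].value
        tp = page.tags[_TAG_TIEPOINT].value
        transform = (float(tp[3]), float(tp[4]), float(sx), float(sy))
    if 270 in page.tags:
        try:
            meta = json.loads(page.tags[270].value)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    return transform, meta


def write_bands(
    bands: np.ndarray,
    path: str | Path,
    transform=DEFAULT_TRANSFORM,
    crs: str | None = None,
    band_roles: tuple[str, ...] = BAND_ROLES,
) -> None:
    """Write an H×W×C float band stack as a band-major GeoTIFF."""
    data = np.ascontiguousarray(np.moveaxis(bands.astype(np.float32), 2, 0))
    desc = {"crs": crs, "band_roles": list(band_roles), "kind": "bands"}
    tifffile.imwrite(
        str(path), data, photometric="minisblack",
        description=json.dumps(desc), extratags=_geo_extratags(transform),
    )


def write_int_raster(
    raster: np.ndarray,
    path: str | Path,
    transform=DEFAULT_TRANSFORM,
    crs: str | None = None,
    kind: str = "labels",
    nodata: int = IGNORE_LABEL,
) -> None:
    desc = {"crs": crs, "kind": kind, "nodata": int(nodata)}
    tifffile.imwrite(
        str(path), raster.astype(np.int32), photometric="minisblack",
        description=json.dumps(desc), extratags=_geo_extratags(transform),
    )


def _read_raster(path: str | Path):
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        transform, meta = _read_geo(tif)
    return data, transform, meta


def read_scene(
    band_path: str | Path,
    label_path: str | Path | None = None,
    plot_path: str | Path | None = None,
    band_order: list[str] | None = None,
) -> SceneBundle:
    """Read a scene from GeoTIFF files.

    ``band_order`` maps the on-disk band order to canonical roles: it lists
    the role of each stored band, in storage order.  Without it the file
    must hold >= 10 bands already in canonical order (extra bands are
    dropped).  Missing label/plot files yield all-ignore / all-zero
    rasters.
    """
    data, transform, meta = _read_raster(band_path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise RasterFormatError(f"band file has unsupported shape {data.shape}")
    bands = np.moveaxis(data, 0, 2).astype(np.float32)  # H, W, C

    order = band_order or meta.get("band_roles")
    if order is not None:
        if set(BAND_ROLES) - set(order):
            missing = sorted(set(BAND_ROLES) - set(order))
            raise RasterFormatError(f"band mapping missing roles: {missing}")
        if len(order) != bands.shape[2]:
            raise RasterFormatError(
                f"band mapping lists {len(order)} roles but file has "
                f"{bands.shape[2]} bands"
            )
        idx = [order.index(role) for role in BAND_ROLES]
        bands = bands[:, :, idx]
    elif bands.shape[2] < len(BAND_ROLES):
        raise RasterFormatError(
            f"band file has {bands.shape[2]} bands; need {len(BAND_ROLES)} "
            "or an explicit band-role mapping"
        )
    else:
        bands = bands[:, :, : len(BAND_ROLES)]

    h, w = bands.shape[:2]
    crs = meta.get("crs")

    if label_path is not None:
        labels, ltrans, _ = _read_raster(label_path)
        labels = labels.astype(np.int64)
        if labels.shape != (h, w):
            raise RasterAlignmentError(
                f"label raster {labels.shape} does not match bands {(h, w)}"
            )
    else:
        labels = np.full((h, w), IGNORE_LABEL, dtype=np.int64)

    if plot_path is not None:
        plots, _, _ = _read_raster(plot_path)
        plots = plots.astype(np.int64)
        if plots.shape != (h, w):
            raise RasterAlignmentError(
                f"plot raster {plots.shape} does not match bands {(h, w)}"
            )
    else:
        plots = np.zeros((h, w), dtype=np.int64)

    return SceneBundle(bands=bands, labels=labels, plots=plots,
                       transform=transform, crs=crs)


def write_scene(
    scene: SceneBundle,
    band_path: str | Path,
    label_path: str | Path | None = None,
    plot_path: str | Path | None = None,
) -> None:
    write_bands(scene.bands, band_path, scene.transform, scene.crs, scene.band_roles)
    if label_path is not None:
        write_int_raster(scene.labels, label_path, scene.transform, scene.crs, "labels")
    if plot_path is not None:
        write_int_raster(scene.plots, plot_path, scene.transform, scene.crs,
                         "plots", nodata=0)


#: Default rendering palette, class id -> RGB.
DEFAULT_PALETTE = {0: (230, 180, 40), 1: (60, 150, 220), 2: (90, 190, 90)}


def write_labels(
    labels: np.ndarray,
    path: str | Path,
    palette: dict[int, tuple[int, int, int]] | None = None,
    transform=DEFAULT_TRANSFORM,
    crs: str | None = None,
    png_path: str | Path | None = None,
) -> None:
    """Write a label raster as GeoTIFF and optionally a color-rendered PNG.

    Ignore pixels (−1) render fully transparent in the PNG.
    """
    palette = palette if palette is not None else DEFAULT_PALETTE
    present = set(np.unique(labels)) - {IGNORE_LABEL}
    missing = sorted(present - set(palette))
    if missing:
        raise ValueError(f"palette missing classes: {missing}")
    write_int_raster(labels, path, transform, crs, "labels")
    if png_path is not None:
        from PIL import Image

        h, w = labels.shape
        rgba = np.zeros((h, w, 4), dtype=np.uint8)
        for cls, rgb in palette.items():
            m = labels == cls
            rgba[m, :3] = rgb
            rgba[m, 3] = 255
        Image.fromarray(rgba, "RGBA").save(str(png_path))


def read_labels(path: str | Path) -> np.ndarray:
    data, _, _ = _read_raster(path)
    return data.astype(np.int64)


def write_metrics_json(report, path: str | Path) -> None:
    """Serialize a MetricsReport (or plain dict) to JSON."""
    obj = report.to_dict() if hasattr(report, "to_dict") else report
    Path(path).write_text(json.dumps(obj, indent=2))
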