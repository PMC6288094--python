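"""Patch extraction from percent tree-cover rasters.

A landscape enters the pipeline as a grid of percent tree cover (0-100, one
grid per region per year, MODIS-VCF style).  A forest definition is a cover
threshold; thresholding yields a binary forest map, and maximal sets of
forest cells connected under the Moore rule (8 neighbours, orthogonal +
diagonal) are the *patches*.  The multiset of patch sizes for one
region/year/threshold is the :class:`PatchCensus`, the basic observation fed
to the distribution fitting and largest-patch dynamics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "CoverRaster",
    "BinaryLandscape",
    "PatchCensus",
    "DEFAULT_THRESHOLDS",
    "binarize",
    "label_patches",
    "census_sweep",
    "read_ascii_grid",
    "read_geotiff",
    "read_cover",
    "write_patch_sizes",
    "read_patch_sizes",
    "patch_file_name",
    "parse_patch_file_name",
]

#: Forest-definition thresholds (percent cover), 20-40% in 5% steps.
DEFAULT_THRESHOLDS: tuple[float, ...] = (20.0, 25.0, 30.0, 35.0, 40.0)

#: 8-connectivity structuring element (Moore neighbourhood).
_MOORE = np.ones((3, 3), dtype=bool)

#: Area of a 231-m MODIS VCF cell in km^2.
MODIS_CELL_KM2 = 0.0534


@dataclass(frozen=True)
class CoverRaster:
    """Percent tree-cover grid for one region and year.

    Parameters
    ----------
    values
        2D array of percent cover in [0, 100].  Missing cells (water,
        fill) are NaN.
    cell_area
        Area per cell.  ``None`` means sizes are reported in cells.
    region_id, year
        Provenance labels carried through the pipeline.
    """

    values: np.ndarray
    cell_area: float | None = None
    region_id: str = "region"
    year: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("cover raster must be a non-empty 2D grid")
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("percent cover values must lie in [0, 100]")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BinaryLandscape:
    """Forest / non-forest mask produced by thresholding a cover raster."""

    mask: np.ndarray
    threshold: float = float("nan")
    region_id: str = "region"
    year: int = 0
    cell_area: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or m.size == 0:
            raise ValueError("landscape mask must be a non-empty 2D grid")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class PatchCensus:
    """Multiset of Moore-neighbourhood patch sizes for one landscape.

    ``sizes`` are in cells unless the source raster carried a ``cell_area``,
    in which case they are areas.  ``rs_max`` is the largest patch divided by
    total forest area, the fragmentation-state indicator; it is NaN for an
    empty landscape.
    """

    sizes: np.ndarray
    threshold: float = float("nan")
    region_id: str = "region"
    year: int = 0

    def __post_init__(self) -> None:
        s = np.sort(np.asarray(self.sizes, dtype=float))[::-1]
        if s.size and s.min() <= 0:
            raise ValueError("patch sizes must be positive")
        object.__setattr__(self, "sizes", s)

    @property
    def n_patches(self) -> int:
        return int(self.sizes.size)

    @property
    def s_max(self) -> float:
        return float(self.sizes[0]) if self.sizes.size else 0.0

    @property
    def total_forest(self) -> float:
        return float(self.sizes.sum())

    @property
    def rs_max(self) -> float:
        """Largest-patch proportion S_max / sum(S_i); NaN when empty."""
        if not self.sizes.size:
            return float("nan")
        return self.s_max / self.total_forest

    @property
    def is_empty(self) -> bool:
        return self.sizes.size == 0


def binarize(cover: CoverRaster, threshold: float) -> BinaryLandscape:
    """Threshold percent cover into a forest/non-forest mask.

    A cell is forest iff its cover is >= ``threshold``; missing (NaN) cells
    are non-forest.
    """
    if not 0 < threshold <= 100:
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    vals = cover.values
    mask = np.where(np.isfinite(vals), vals >= threshold, False)
    return BinaryLandscape(
        mask=mask,
        threshold=float(threshold),
        region_id=cover.region_id,
        year=cover.year,
        cell_area=cover.cell_area,
    )


def label_patches(land: BinaryLandscape) -> PatchCensus:
    """Extract the patch-size census by 8-connected component labelling."""
    labels, n = ndimage.label(land.mask, structure=_MOORE)
    if n == 0:
        sizes = np.empty(0)
    else:
        sizes = np.bincount(labels.ravel())[1:].astype(float)
    if land.cell_area is not None:
        sizes = sizes * land.cell_area
    return PatchCensus(
        sizes=sizes,
        threshold=land.threshold,
        region_id=land.region_id,
        year=land.year,
    )


def census_sweep(
    cover: CoverRaster,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[PatchCensus]:
    """One patch census per forest-definition threshold."""
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    return [label_patches(binarize(cover, t)) for t in thresholds]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(
    path: str | Path,
    nodata: float | None = None,
    region_id: str | None = None,
    year: int = 0,
    cell_area: float | None = None,
) -> CoverRaster:
    """Read a whitespace-separated ASCII grid of percent cover.

    Lines starting with ``#`` are comments.  An optional ESRI-style header
    (``ncols/nrows/.../NODATA_value``) is honoured; ``nodata`` overrides any
    header sentinel.  Sentinel cells become NaN (treated as non-forest).
    """
    path = Path(path)
    header_nodata = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0][0].isalpha():  # ESRI ascii-grid header line
                if parts[0].lower() == "nodata_value":
                    header_nodata = float(parts[1])
                continue
            rows.append([float(v) for v in parts])
    if not rows:
        raise ValueError(f"no grid data found in {path}")
    arr = np.asarray(rows, dtype=float)
    sentinel = nodata if nodata is not None else header_nodata
    if sentinel is not None:
        arr[arr == sentinel] = np.nan
    return CoverRaster(
        values=arr,
        cell_area=cell_area,
        region_id=region_id or path.stem,
        year=year,
    )


def read_geotiff(
    path: str | Path,
    nodata: float | None = None,
    region_id: str | None = None,
    year: int = 0,
    cell_area: float | None = None,
) -> CoverRaster:
    """Read a single-band (Geo)TIFF of integer percent cover."""
    import tifffile

    path = Path(path)
    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(f"expected a single-band raster, got shape {arr.shape}")
    if nodata is not None:
        arr[arr == nodata] = np.nan
    arr[arr > 100] = np.nan  # MODIS fill values (e.g. 200 = water)
    return CoverRaster(
        values=arr,
        cell_area=cell_area,
        region_id=region_id or path.stem,
        year=year,
    )


def read_cover(path: str | Path, **kwargs) -> CoverRaster:
    """Dispatch on extension: .tif/.tiff -> GeoTIFF, else ASCII grid."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return read_geotiff(path, **kwargs)
    return read_ascii_grid(path, **kwargs)


def patch_file_name(region_id: str, year: int, threshold: float) -> str:
    """``<region>_<year>_<threshold>.csv`` — the deposited-archive layout."""
    t = int(threshold) if float(threshold).is_integer() else threshold
    return f"{region_id}_{year}_{t}.csv"


_PATCH_FILE_RE = re.compile(r"^(?P<region>.+)_(?P<year>\d{4})_(?P<thr>\d+(?:\.\d+)?)$")


def parse_patch_file_name(path: str | Path) -> tuple[str, int, float]:
    """Recover (region, year, threshold) from a patch-size file name."""
    m = _PATCH_FILE_RE.match(Path(path).stem)
    if m is None:
        raise ValueError(f"cannot parse patch file name {path!r}")
    return m["region"], int(m["year"]), float(m["thr"])


def write_patch_sizes(census: PatchCensus, out_dir: str | Path) -> Path:
    """Write one patch size per line, mirroring the archive layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / patch_file_name(census.region_id, census.year, census.threshold)
    sizes = census.sizes
    if sizes.size and np.allclose(sizes, np.round(sizes)):
        lines = "\n".join(str(int(s)) for s in sizes)
    else:
        lines = "\n".join(repr(float(s)) for s in sizes)
    path.write_text(lines + ("\n" if lines else ""))
    return path


def read_patch_sizes(path: str | Path) -> PatchCensus:
    """Read a one-size-per-line patch file (deposited-archive dialect)."""
    path = Path(path)
    sizes = [
        float(line)
        for line in path.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    try:
        region, year, thr = parse_patch_file_name(path)
    except ValueError:
        region, year, thr = path.stem, 0, float("nan")
    return PatchCensus(sizes=np.asarray(sizes), threshold=thr, region_id=region, year=year)
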