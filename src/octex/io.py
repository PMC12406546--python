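"""Reading and writing of OCT volumes, layer boundaries and cohort manifests.

Volumes are stored as non-compressed multipage greyscale TIFF stacks, one
page per B-scan.  Within a page the axis convention is configurable; by
default columns are A-scans and rows are axial depth samples, i.e. a page of
shape ``(depth, n_ascans)``.  Layer boundaries produced by a segmentation
stage are exchanged as plain CSV tables with one row per
``(interface_index, bscan, ascan)`` cell, and a cohort is described by a
YAML/JSON manifest listing per-scan file paths plus animal metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import N_INTERFACES, BoundarySet

__all__ = [
    "AnimalMeta",
    "OCTVolume",
    "ScanRecord",
    "CohortManifest",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_boundaries",
    "write_boundaries",
    "read_manifest",
    "write_manifest",
]

log = logging.getLogger(__name__)

GROUPS = ("control", "T2D")
WEEKS = (0, 4, 8, 12)

BOUNDARY_COLUMNS = ["interface_index", "bscan", "ascan", "depth_px"]


class FormatError(ValueError):
    """Raised when an on-disk artefact violates the declared file contract."""


@dataclass(frozen=True)
class AnimalMeta:
    """Identity of one imaging session: animal, study group, week, eye."""

    animal_id: str
    group: str = "control"
    week: int = 0
    eye: str = "OD"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.week not in WEEKS:
            raise ValueError(f"week must be one of {WEEKS}, got {self.week!r}")


@dataclass
class OCTVolume:
    """A volumetric OCT scan: a stack of B-scans with acquisition metadata.

    ``intensities`` is indexed ``(bscan, ascan, depth)`` with the depth axis
    increasing from the inner (vitreal) side towards the outer retina.
    ``axial_scale`` converts depth pixels to micrometres; the default of 1.0
    leaves thickness reported in pixels.
    """

    intensities: np.ndarray
    axial_scale: float = 1.0
    meta: AnimalMeta | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError(f"intensities must be 3D, got shape {arr.shape}")
        if any(s < 1 for s in arr.shape):
            raise ValueError(f"all dimensions must be >= 1, got {arr.shape}")
        if np.issubdtype(arr.dtype, np.floating) and not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if arr.min() < 0:
            raise ValueError("intensities must be non-negative")
        self.intensities = arr

    @property
    def n_bscans(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.intensities.shape[1]

    @property
    def depth(self) -> int:
        return self.intensities.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


def _page_to_ascan_depth(page: np.ndarray, rows_are_depth: bool) -> np.ndarray:
    # pages are (depth, ascan) under the default convention; internally the
    # volume is (bscan, ascan, depth) so each page is transposed on read
    return page.T if rows_are_depth else page


def read_volume(
    path: str | Path,
    meta: AnimalMeta | None = None,
    axial_scale: float = 1.0,
    rows_are_depth: bool = True,
) -> OCTVolume:
    """Read a volume from a multipage TIFF or a directory of per-B-scan TIFFs.

    Parameters
    ----------
    path
        A multipage TIFF file, or a directory whose ``*.tif``/``*.tiff``
        files (sorted by name) are the individual B-scans.
    rows_are_depth
        Axis convention within a page: if True (default) page rows are axial
        depth samples and columns are A-scans; if False the page is already
        ``(ascan, depth)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"directory {path} contains no TIFF files")
        pages = [tifffile.imread(f) for f in files]
    else:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
        if not pages:
            raise FormatError(f"{path} contains no image pages")

    shapes = {p.shape for p in pages}
    for p in pages:
        if p.ndim != 2:
            raise FormatError(f"non-greyscale page of shape {p.shape} in {path}")
    if len(shapes) != 1:
        raise FormatError(f"mixed page dimensions {sorted(shapes)} in {path}")

    stack = np.stack([_page_to_ascan_depth(p, rows_are_depth) for p in pages])
    log.info(
        "read %s: %d B-scans x %d A-scans x %d depth px (rows_are_depth=%s)",
        path, stack.shape[0], stack.shape[1], stack.shape[2], rows_are_depth,
    )
    return OCTVolume(stack, axial_scale=axial_scale, meta=meta)


def write_volume(
    volume: OCTVolume,
    path: str | Path,
    rows_are_depth: bool = True,
    rescale: bool = False,
) -> Path:
    """Write a volume as a non-compressed multipage TIFF (inverse of read).

    Integer inputs are written with their dtype preserved (8- or 16-bit);
    float inputs must already lie in ``[0, 2**16)`` and are rounded to
    uint16, unless ``rescale`` is set, in which case they are min-max
    rescaled to the full 16-bit range.
    """
    path = Path(path)
    arr = volume.intensities
    if np.issubdtype(arr.dtype, np.floating):
        if rescale:
            lo, hi = float(arr.min()), float(arr.max())
            arr = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo) * 65535.0
        elif arr.max() >= 2**16:
            raise ValueError(
                "float intensities exceed the 16-bit range; pass rescale=True"
            )
        arr = np.round(arr).astype(np.uint16)
    pages = arr.transpose(0, 2, 1) if rows_are_depth else arr
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, pages, compression=None, photometric="minisblack")
    return path


def read_boundaries(path: str | Path, shape: tuple[int, int] | None = None) -> BoundarySet:
    """Read a boundary CSV into a :class:`BoundarySet`.

    The table must contain the columns ``interface_index`` (0..6), ``bscan``,
    ``ascan`` and ``depth_px``, with complete coverage of the en-face grid
    for all 7 interfaces.
    """
    df = pd.read_csv(path)
    missing = set(BOUNDARY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"boundary table missing columns {sorted(missing)}")
    interfaces = np.sort(df["interface_index"].unique())
    if not np.array_equal(interfaces, np.arange(N_INTERFACES)):
        raise FormatError(
            f"expected interfaces 0..{N_INTERFACES - 1}, found {interfaces.tolist()}"
        )
    nb = int(df["bscan"].max()) + 1
    na = int(df["ascan"].max()) + 1
    if shape is not None and (nb, na) != tuple(shape):
        raise FormatError(f"boundary grid {(nb, na)} does not match expected {shape}")
    if len(df) != N_INTERFACES * nb * na:
        raise FormatError(
            f"incomplete boundary table: {len(df)} rows for a "
            f"{N_INTERFACES}x{nb}x{na} grid"
        )
    depths = np.full((N_INTERFACES, nb, na), np.nan)
    depths[
        df["interface_index"].to_numpy(),
        df["bscan"].to_numpy(),
        df["ascan"].to_numpy(),
    ] = df["depth_px"].to_numpy(float)
    if np.isnan(depths).any():
        raise FormatError("boundary table has missing (interface, bscan, ascan) cells")
    return BoundarySet(depths)


def write_boundaries(bset: BoundarySet, path: str | Path) -> Path:
    path = Path(path)
    k, b, a = np.meshgrid(
        np.arange(N_INTERFACES),
        np.arange(bset.n_bscans),
        np.arange(bset.n_ascans),
        indexing="ij",
    )
    df = pd.DataFrame(
        {
            "interface_index": k.ravel(),
            "bscan": b.ravel(),
            "ascan": a.ravel(),
            "depth_px": bset.depths.ravel(),
        }
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


@dataclass
class ScanRecord:
    """One manifest entry: metadata plus volume / boundary file paths."""

    meta: AnimalMeta
    volume_path: str
    boundaries_path: str


@dataclass
class CohortManifest:
    """Sidecar description of a cohort: scans, paths and acquisition scale."""

    scans: list[ScanRecord] = field(default_factory=list)
    axial_scale: float = 1.0
    name: str = "cohort"

    def __post_init__(self) -> None:
        seen = set()
        for s in self.scans:
            key = (s.meta.animal_id, s.meta.week)
            if key in seen:
                raise ValueError(f"duplicate (animal_id, week) in manifest: {key}")
            seen.add(key)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "axial_scale": self.axial_scale,
            "scans": [
                {
                    "animal_id": s.meta.animal_id,
                    "group": s.meta.group,
                    "week": s.meta.week,
                    "eye": s.meta.eye,
                    "volume": s.volume_path,
                    "boundaries": s.boundaries_path,
                }
                for s in self.scans
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortManifest":
        scans = [
            ScanRecord(
                meta=AnimalMeta(
                    animal_id=str(e["animal_id"]),
                    group=e["group"],
                    week=int(e["week"]),
                    eye=e.get("eye", "OD"),
                ),
                volume_path=e["volume"],
                boundaries_path=e["boundaries"],
            )
            for e in d.get("scans", [])
        ]
        return cls(
            scans=scans,
            axial_scale=float(d.get("axial_scale", 1.0)),
            name=d.get("name", "cohort"),
        )


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = manifest.to_dict()
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(d, fh, indent=2)
        else:
            yaml.safe_dump(d, fh, sort_keys=False)
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    with open(path) as fh:
        d = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return CohortManifest.from_dict(d)
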