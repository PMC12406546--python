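"""Mean-value fundus (MVF) projection.

An MVF image collapses a 3D OCT volume to one en-face 2D image per retinal
layer: each pixel is the mean of the A-scan intensity samples lying between
the layer's two bounding interfaces, mimicking a fundus photograph of just
that layer.  The axial samples included at en-face position ``(b, a)`` are
the half-open integer interval ``[ceil(upper), ceil(lower))``, so adjacent
layers partition every A-scan and the rule is bit-reproducible for
sub-pixel boundaries.  Pixels whose layer contributes fewer than
``min_samples`` samples are masked out rather than zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .geometry import BoundarySet

__all__ = ["MVFImage", "project_mvf", "write_mvf"]


@dataclass
class MVFImage:
    """En-face mean-intensity projection of one layer with a validity mask."""

    values: np.ndarray
    mask: np.ndarray
    layer: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if v.shape != m.shape or v.ndim != 2:
            raise ValueError("values and mask must be 2D arrays of the same shape")
        if not np.all(np.isfinite(v[m])):
            raise ValueError("values must be finite wherever the mask is true")
        self.values = v
        self.mask = m

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


def project_mvf(
    volume, bset: BoundarySet, layer: str, min_samples: int = 1
) -> MVFImage:
    """Project one layer of a volume onto its mean-value fundus image.

    ``values[b, a]`` is the mean of ``volume.intensities[b, a, z]`` for
    ``z`` in ``[ceil(upper), ceil(lower))`` where ``upper``/``lower`` are
    the layer's bounding interface depths at ``(b, a)``.  ``mask[b, a]`` is
    true when at least ``min_samples`` axial samples contribute.
    """
    arr = np.asarray(volume.intensities, dtype=float)
    if (volume.n_bscans, volume.n_ascans) != (bset.n_bscans, bset.n_ascans):
        raise ValueError(
            f"volume en-face grid {(volume.n_bscans, volume.n_ascans)} does not "
            f"match boundaries {(bset.n_bscans, bset.n_ascans)}"
        )
    k = bset.layer_index(layer)
    nz = arr.shape[2]
    z0 = np.clip(np.ceil(bset.depths[k]).astype(np.int64), 0, nz)
    z1 = np.clip(np.ceil(bset.depths[k + 1]).astype(np.int64), 0, nz)
    n = np.maximum(z1 - z0, 0)

    # sum strictly inside the band so the projection is exactly local:
    # intensities outside [z0, z1) cannot perturb the result even at the
    # level of floating-point rounding
    zgrid = np.arange(nz)
    inside = (zgrid >= z0[..., None]) & (zgrid < z1[..., None])
    sums = np.where(inside, arr, 0.0).sum(axis=2)

    mask = n >= max(int(min_samples), 1)
    values = np.zeros_like(sums)
    np.divide(sums, n, out=values, where=n > 0)
    values[~mask] = np.nan
    return MVFImage(values=values, mask=mask, layer=layer)


def write_mvf(img: MVFImage, path: str | Path) -> Path:
    """Export an MVF image as 16-bit TIFF plus a paired ``*_mask.tiff``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vals = np.where(img.mask, img.values, 0.0)
    tifffile.imwrite(path, np.round(vals).astype(np.uint16), compression=None)
    mask_path = path.with_name(path.stem + "_mask" + path.suffix)
    tifffile.imwrite(mask_path, img.mask.astype(np.uint8), compression=None)
    return path
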