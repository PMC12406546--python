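"""Grey-level co-occurrence matrices and the 20-feature Haralick-type suite.

The texture of a layer's mean-value fundus image is summarised by
second-order statistics of its grey-level co-occurrence matrix (GLCM): the
probability of observing a transition from grey level *i* to grey level *j*
between pixels separated by a fixed offset.  The pipeline quantizes each
masked MVF image to ``n_levels`` grey levels, accumulates co-occurrence
counts over a set of direction offsets at distance ``d`` (only pairs whose
both endpoints are inside the validity mask contribute), symmetrizes and
normalizes, and computes 20 named features:

    angular_second_moment (uniformity/energy), contrast (inertia),
    correlation, sum_of_squares_variance, inverse_difference_moment
    (homogeneity), sum_average, sum_variance, sum_entropy, entropy,
    difference_variance, difference_entropy, imci, imcii (information
    measures of correlation I/II), autocorrelation, maximum_probability,
    cluster_prominence, cluster_shade, inn, idn (inverse difference
    [moment] normalized), dissimilarity.

Grey levels are indexed 1..N_g throughout, logarithms are base 2 (entropies
in bits) with the convention 0·log 0 = 0.  Degenerate single-level images
use correlation := 1 and imci := 0 (both marginal variances / entropies
vanish); the imcii radicand is clamped at 0.  ``sum_variance`` is centred
on ``sum_average`` and ``difference_variance`` is the variance of the
difference histogram about its own mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mvf import MVFImage

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_ALIASES",
    "QuantizedImage",
    "GLCM",
    "GLCMMarginals",
    "TextureFeatures",
    "DEFAULT_DIRECTIONS",
    "quantize",
    "compute_glcm",
    "glcm_marginals",
    "texture_features",
]

FEATURE_NAMES = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imci",
    "imcii",
    "autocorrelation",
    "maximum_probability",
    "cluster_prominence",
    "cluster_shade",
    "inn",
    "idn",
    "dissimilarity",
)

# compound names in common use for the same quantities
FEATURE_ALIASES = {
    "angular_second_moment": ("uniformity", "homogeneity", "energy"),
    "inverse_difference_moment": ("homogeneity", "energy"),
    "contrast": ("inertia",),
    "imci": ("information measure of correlation I",),
    "imcii": ("information measure of correlation II",),
    "inn": ("inverse difference normalized",),
    "idn": ("inverse difference moment normalized",),
    "sum_of_squares_variance": ("sum of squares",),
}

# offsets (drow, dcol) for 0°, 45°, 90°, 135° at unit distance
DEFAULT_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class QuantizedImage:
    """Integer grey levels 1..n_levels under a validity mask."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        m = np.asarray(self.mask, dtype=bool)
        if lv.shape != m.shape or lv.ndim != 2:
            raise ValueError("levels and mask must be 2D arrays of the same shape")
        on = lv[m]
        if on.size and (on.min() < 1 or on.max() > self.n_levels):
            raise ValueError(f"levels must lie in 1..{self.n_levels} on the mask")
        self.levels = lv.astype(np.int64)
        self.mask = m


@dataclass
class GLCM:
    """Normalized grey-level co-occurrence probabilities."""

    p: np.ndarray
    n_pairs: int
    distance: int
    directions: tuple[tuple[int, int], ...]
    symmetric: bool
    n_levels: int

    @property
    def degenerate(self) -> bool:
        return self.n_pairs == 0


@dataclass
class GLCMMarginals:
    """Marginal, sum and difference distributions plus entropies of a GLCM."""

    p_x: np.ndarray
    p_y: np.ndarray
    p_sum: np.ndarray  # index k-2 holds P(i+j = k), k = 2..2*N_g
    p_diff: np.ndarray  # index k holds P(|i-j| = k), k = 0..N_g-1
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    hx: float
    hy: float
    hxy: float
    hxy1: float
    hxy2: float


@dataclass
class TextureFeatures:
    """The 20 named GLCM features for one layer of one eye at one timepoint."""

    values: dict[str, float]
    aliases: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(FEATURE_ALIASES))

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(
                f"feature dict must contain exactly the 20 canonical features; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def defined(self) -> bool:
        return all(math.isfinite(v) for v in self.values.values())


def quantize(
    img: MVFImage,
    n_levels: int = 64,
    range_mode: str = "minmax",
    fixed_range: tuple[float, float] | None = None,
) -> QuantizedImage:
    """Linearly bin masked MVF intensities into grey levels 1..n_levels.

    ``minmax`` maps the masked minimum to level 1 and the masked maximum to
    level ``n_levels`` (a constant image maps entirely to level 1), making
    the result invariant to positive affine intensity transforms.  ``fixed``
    bins the interval ``fixed_range`` instead, clipping values outside it.
    """
    if n_levels < 2:
        raise ValueError(f"n_levels must be >= 2, got {n_levels}")
    vals = img.values
    mask = img.mask
    if range_mode == "minmax":
        on = vals[mask]
        if on.size == 0:
            return QuantizedImage(np.ones(vals.shape, np.int64), mask, n_levels)
        lo, hi = float(on.min()), float(on.max())
    elif range_mode == "fixed":
        if fixed_range is None:
            raise ValueError("range_mode='fixed' requires fixed_range=(lo, hi)")
        lo, hi = map(float, fixed_range)
        if hi <= lo:
            raise ValueError(f"fixed range must satisfy hi > lo, got {(lo, hi)}")
    else:
        raise ValueError(f"unknown range_mode {range_mode!r}")

    levels = np.ones(vals.shape, dtype=np.int64)
    if hi > lo:
        scaled = (np.clip(vals, lo, hi) - lo) / (hi - lo) * n_levels
        with np.errstate(invalid="ignore"):
            lv = np.floor(scaled).astype(np.int64) + 1
        levels = np.clip(lv, 1, n_levels)
    levels[~mask] = 1
    return QuantizedImage(levels, mask, n_levels)


def compute_glcm(
    q: QuantizedImage,
    distance: int = 1,
    directions: tuple[tuple[int, int], ...] = DEFAULT_DIRECTIONS,
    symmetric: bool = True,
) -> GLCM:
    """Accumulate a (masked) co-occurrence matrix over direction offsets.

    For every offset ``(dr, dc)`` scaled by ``distance``, each pixel pair
    with both endpoints inside the mask contributes one directed count.
    With ``symmetric=True`` the transpose is added before normalization.
    ``n_pairs`` records the number of directed pairs counted; a GLCM with
    no valid pair is flagged degenerate.
    """
    ng = q.n_levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    lv = q.levels
    mask = q.mask
    nr, nc = lv.shape
    for dr, dc in directions:
        dr, dc = dr * distance, dc * distance
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = lv[r0:r1, c0:c1]
        b = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    n_pairs = int(counts.sum())
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    p = counts / total if total > 0 else counts.astype(float)
    return GLCM(
        p=p,
        n_pairs=n_pairs,
        distance=distance,
        directions=tuple(tuple(d) for d in directions),
        symmetric=symmetric,
        n_levels=ng,
    )


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits with 0·log 0 = 0."""
    p = np.asarray(p, dtype=float).ravel()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def glcm_marginals(g: GLCM) -> GLCMMarginals:
    """Marginal, sum/difference distributions and entropies of a GLCM."""
    if g.degenerate:
        raise ValueError("cannot compute marginals of a degenerate GLCM (n_pairs=0)")
    p = g.p
    ng = g.n_levels
    i = np.arange(1, ng + 1)
    p_x = p.sum(axis=1)
    p_y = p.sum(axis=0)
    mu_x = float((i * p_x).sum())
    mu_y = float((i * p_y).sum())
    sigma_x = float(np.sqrt(max(((i - mu_x) ** 2 * p_x).sum(), 0.0)))
    sigma_y = float(np.sqrt(max(((i - mu_y) ** 2 * p_y).sum(), 0.0)))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    p_sum = np.zeros(2 * ng - 1)  # k = 2..2*ng
    np.add.at(p_sum, (ii + jj - 2).ravel(), p.ravel())
    p_diff = np.zeros(ng)  # k = 0..ng-1
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())

    pxpy = np.outer(p_x, p_y)
    on = p > 0
    hxy1 = float(-(p[on] * np.log2(pxpy[on])).sum())
    return GLCMMarginals(
        p_x=p_x,
        p_y=p_y,
        p_sum=p_sum,
        p_diff=p_diff,
        mu_x=mu_x,
        mu_y=mu_y,
        sigma_x=sigma_x,
        sigma_y=sigma_y,
        hx=_entropy(p_x),
        hy=_entropy(p_y),
        hxy=_entropy(p),
        hxy1=hxy1,
        hxy2=_entropy(pxpy),
    )


def texture_features(g: GLCM) -> TextureFeatures:
    """Compute the 20-feature suite from a GLCM.

    Degenerate GLCMs (no contributing pixel pair) yield NaN for every
    feature.  Single-level GLCMs use the documented conventions
    correlation = 1 and imci = 0.
    """
    if g.degenerate:
        return TextureFeatures({name: float("nan") for name in FEATURE_NAMES})

    m = glcm_marginals(g)
    p = g.p
    ng = g.n_levels
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj
    absdiff = np.abs(diff)

    asm = float((p**2).sum())
    contrast = float((diff**2 * p).sum())
    autocorr = float((ii * jj * p).sum())
    if m.sigma_x * m.sigma_y > 0:
        correlation = (autocorr - m.mu_x * m.mu_y) / (m.sigma_x * m.sigma_y)
    else:
        correlation = 1.0
    sum_sq = float(((ii - m.mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + diff**2)).sum())

    k_sum = np.arange(2, 2 * ng + 1)
    sum_average = float((k_sum * m.p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * m.p_sum).sum())
    sum_entropy = _entropy(m.p_sum)
    entropy = m.hxy

    k_diff = np.arange(ng)
    mu_diff = float((k_diff * m.p_diff).sum())
    difference_variance = float(((k_diff - mu_diff) ** 2 * m.p_diff).sum())
    difference_entropy = _entropy(m.p_diff)

    hmax = max(m.hx, m.hy)
    imci = (m.hxy - m.hxy1) / hmax if hmax > 0 else 0.0
    imcii = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (m.hxy2 - m.hxy))))

    centered = ii + jj - m.mu_x - m.mu_y
    cluster_prominence = float((centered**4 * p).sum())
    cluster_shade = float((centered**3 * p).sum())
    inn = float((p / (1.0 + absdiff / ng)).sum())
    idn = float((p / (1.0 + diff**2 / ng**2)).sum())
    dissimilarity = float((absdiff * p).sum())

    values = {
        "angular_second_moment": asm,
        "contrast": contrast,
        "correlation": float(correlation),
        "sum_of_squares_variance": sum_sq,
        "inverse_difference_moment": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imci": float(imci),
        "imcii": imcii,
        "autocorrelation": autocorr,
        "maximum_probability": float(p.max()),
        "cluster_prominence": cluster_prominence,
        "cluster_shade": cluster_shade,
        "inn": inn,
        "idn": idn,
        "dissimilarity": dissimilarity,
    }
    return TextureFeatures(values)
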