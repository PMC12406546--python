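"""Synthetic OCT phantoms and longitudinal two-group cohorts.

The phantom emulates the geometry of small-animal volumetric OCT: a stack
of B-scans in which six retinal layers, delimited by seven smooth stacked
interface surfaces, carry layer-specific mean reflectivity and
multiplicative speckle.  Speckle is modelled as a unit-mean gamma field
(contrast = std/mean) low-pass filtered laterally to a configurable
correlation length — the simplest model whose first-order (contrast) and
second-order (spatial correlation) statistics are independently tunable,
which are exactly the axes GLCM features measure.  Axial speckle
correlation is one pixel (independent samples).  No point-spread function,
attenuation, shadowing or vasculature is modelled.

A cohort couples phantoms into the two-group, four-timepoint design used
in longitudinal diabetic-retinopathy studies: control and T2D groups imaged
at weeks 0/4/8/12, with animal-level random effects (thickness,
reflectivity, speckle correlation) persistent across weeks — which is what
makes the week-0 baseline an informative covariate — visit-level
measurement variability, and per-(layer, week) disease effects on the T2D
group: multiplicative thinning factors and texture effects (multipliers on
speckle correlation length and/or contrast).

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import scipy.ndimage as ndi

from .geometry import LAYERS, N_INTERFACES, BoundarySet
from .io import (
    AnimalMeta,
    CohortManifest,
    OCTVolume,
    ScanRecord,
    write_boundaries,
    write_manifest,
    write_volume,
)

__all__ = [
    "LayerSpec",
    "PhantomConfig",
    "LayerEffect",
    "CohortConfig",
    "speckle_field",
    "generate_phantom",
    "iter_cohort",
    "generate_cohort",
    "default_diabetic_effects",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class LayerSpec:
    """Geometry and optical texture of one retinal layer in the phantom."""

    thickness: float  # px
    reflectivity: float  # relative, (0, 1]
    speckle_contrast: float = 0.35
    corr_length: float = 1.5  # lateral, px

    def __post_init__(self) -> None:
        if self.thickness < 1:
            raise ValueError("layer thickness must be >= 1 px")
        if self.reflectivity <= 0:
            raise ValueError("reflectivity must be > 0")
        if self.speckle_contrast < 0 or self.corr_length < 0:
            raise ValueError("speckle contrast and correlation length must be >= 0")


# reflectivities alternate bright/dark as in real retinal OCT (plexiform
# layers bright, nuclear layers dark, IS/OS hyper-reflective)
_DEFAULT_LAYERS = (
    LayerSpec(34.0, 0.85),
    LayerSpec(30.0, 0.55),
    LayerSpec(25.0, 0.30),
    LayerSpec(18.0, 0.62),
    LayerSpec(40.0, 0.22),
    LayerSpec(24.0, 0.90),
)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, per-layer optics and seed of one synthetic volume.

    The default 64x64x256 grid is the test-scale geometry; the acquisition-
    scale 512x512x1024 grid is available by configuration.
    """

    n_bscans: int = 64
    n_ascans: int = 64
    depth: int = 256
    layers: tuple[LayerSpec, ...] = _DEFAULT_LAYERS
    margin_top: float = 30.0
    background_reflectivity: float = 0.04
    undulation_amplitude: float = 4.0  # px, whole-pixel surface undulation
    undulation_smoothness: float = 16.0  # lateral Gaussian sigma, px
    intensity_scale: float = 12000.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layers) != len(LAYERS):
            raise ValueError(f"exactly {len(LAYERS)} layers required")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        total = sum(l.thickness for l in self.layers)
        if self.margin_top - self.undulation_amplitude < 0 or (
            self.margin_top + total + self.undulation_amplitude > self.depth
        ):
            raise ValueError(
                f"thickness budget exceeds depth: margin {self.margin_top} + "
                f"layers {total} + undulation {self.undulation_amplitude} "
                f"must fit in {self.depth} px"
            )


@dataclass(frozen=True)
class LayerEffect:
    """Disease effect on one (layer, week) cell, as multiplicative factors."""

    thickness_factor: float = 1.0
    corr_length_factor: float = 1.0
    contrast_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.thickness_factor, self.corr_length_factor, self.contrast_factor) <= 0:
            raise ValueError("effect factors must be > 0")


@dataclass(frozen=True)
class CohortConfig:
    """Design and variability of a synthetic two-group longitudinal cohort.

    ``effects`` maps ``(layer_name, week)`` to the :class:`LayerEffect`
    applied to the T2D group at that week (week 0 is pre-induction and must
    stay at unit factors); ``control_effects`` optionally models normal
    ageing drift in controls.  Animal-level multipliers (drawn once per
    animal) persist across weeks; visit-level multipliers model session-to-
    session measurement variability.
    """

    n_control: int = 10
    n_t2d: int = 10
    weeks: tuple[int, ...] = (0, 4, 8, 12)
    phantom: PhantomConfig = PhantomConfig()
    effects: dict[tuple[str, int], LayerEffect] = field(default_factory=dict)
    control_effects: dict[tuple[str, int], LayerEffect] = field(default_factory=dict)
    animal_thickness_sd: float = 0.05
    animal_reflectivity_sd: float = 0.05
    animal_corr_length_sd: float = 0.10
    visit_thickness_sd: float = 0.005
    visit_corr_length_sd: float = 0.03
    effect_jitter_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for table in (self.effects, self.control_effects):
            for (layer, week), eff in table.items():
                if layer not in LAYERS:
                    raise ValueError(f"unknown layer {layer!r} in effect spec")
                if week not in self.weeks:
                    raise ValueError(f"week {week} not in cohort weeks {self.weeks}")
                if week == 0 and eff != LayerEffect():
                    raise ValueError("week-0 (baseline) effects must be unit factors")


def speckle_field(
    shape: tuple[int, ...],
    contrast: float,
    corr_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-mean multiplicative speckle with given contrast and lateral
    correlation length.

    An i.i.d. gamma field (shape 1/contrast², unit mean) is smoothed with a
    Gaussian of sigma ``corr_length`` over all axes but the last (the axial
    axis stays uncorrelated), then rescaled to restore the target contrast
    and clipped at a small positive floor.
    """
    if contrast == 0:
        return np.ones(shape)
    k = 1.0 / contrast**2
    f = rng.gamma(shape=k, scale=1.0 / k, size=shape)
    if corr_length > 0 and len(shape) >= 2:
        sigma = (corr_length,) * (len(shape) - 1) + (0.0,)
        f = ndi.gaussian_filter(f, sigma=sigma, mode="wrap")
        sd = f.std()
        if sd > 0:
            f = 1.0 + (f - f.mean()) * (contrast / sd)
    return np.clip(f, 0.02, None)


def _undulation(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency en-face surface offset, rounded to whole pixels
    so the rendered volume matches the reported boundaries exactly."""
    if cfg.undulation_amplitude == 0:
        return np.zeros((cfg.n_bscans, cfg.n_ascans))
    u = rng.standard_normal((cfg.n_bscans, cfg.n_ascans))
    u = ndi.gaussian_filter(u, sigma=cfg.undulation_smoothness, mode="wrap")
    sd = u.std()
    if sd > 0:
        u = u / sd * (cfg.undulation_amplitude / 2.0)
    u = np.clip(u, -cfg.undulation_amplitude, cfg.undulation_amplitude)
    return np.round(u)


def generate_phantom(
    cfg: PhantomConfig, meta: AnimalMeta | None = None
) -> tuple[OCTVolume, BoundarySet]:
    """Render one synthetic volume and its exact ground-truth boundaries.

    Interfaces are the cumulative layer thicknesses below ``margin_top``,
    offset by a shared smooth undulation surface (so layer thicknesses are
    preserved exactly).  Voxels take the layer containing their centre;
    intensity is reflectivity x speckle, scaled and clipped to the
    configured bit depth.  Identical configuration (including seed) yields
    bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    nb, na, nz = cfg.n_bscans, cfg.n_ascans, cfg.depth

    u = _undulation(cfg, rng)
    base = np.concatenate(
        [[cfg.margin_top], cfg.margin_top + np.cumsum([l.thickness for l in cfg.layers])]
    )
    depths = base[:, None, None] + u[None, :, :]

    zc = np.arange(nz) + 0.5
    region = np.zeros((nb, na, nz), dtype=np.int8)
    for k in range(N_INTERFACES):
        region += (zc[None, None, :] >= depths[k][:, :, None]).astype(np.int8)

    vol = cfg.background_reflectivity * speckle_field((nb, na, nz), 0.3, 0.0, rng)
    for k, spec in enumerate(cfg.layers):
        z0 = max(0, int(np.floor(depths[k].min())))
        z1 = min(nz, int(np.ceil(depths[k + 1].max())))
        if z1 <= z0:
            continue
        slab = speckle_field((nb, na, z1 - z0), spec.speckle_contrast, spec.corr_length, rng)
        sel = region[:, :, z0:z1] == k + 1
        sub = vol[:, :, z0:z1]
        sub[sel] = (spec.reflectivity * slab)[sel]

    vmax = 2**cfg.bit_depth - 1
    dtype = np.uint8 if cfg.bit_depth == 8 else np.uint16
    intens = np.clip(np.round(vol * cfg.intensity_scale), 0, vmax).astype(dtype)
    return OCTVolume(intens, meta=meta), BoundarySet(depths)


def default_diabetic_effects() -> dict[tuple[str, int], LayerEffect]:
    """Disease-effect template emulating early diabetic retinopathy in
    rodent OCT: per-layer thinning of a few percent of baseline emerging at
    weeks 8/12 (strongest in INL and IS/OS), plus opposite-signed speckle
    texture shifts in IPL (coarser texture) and IS/OS (finer texture)."""
    eff: dict[tuple[str, int], LayerEffect] = {}
    thinning = {
        "IPL": {8: 0.978, 12: 0.982},
        "INL": {4: 0.981, 8: 0.936, 12: 0.962},
        "OPL": {8: 0.983, 12: 0.988},
        "ONL": {4: 0.990, 8: 0.973, 12: 0.986},
        "IS/OS": {4: 0.943, 8: 0.886, 12: 0.912},
    }
    for layer, by_week in thinning.items():
        for week, f in by_week.items():
            eff[(layer, week)] = LayerEffect(thickness_factor=f)
    for week in (8, 12):
        eff[("IPL", week)] = replace(eff[("IPL", week)], corr_length_factor=1.35)
        eff[("IS/OS", week)] = replace(eff[("IS/OS", week)], corr_length_factor=0.7)
    return eff


def _effective_phantom(
    cfg: CohortConfig,
    animal_t: np.ndarray,
    animal_r: float,
    animal_c: float,
    effect_jitter: dict[tuple[str, int], float],
    group: str,
    week: int,
    rng: np.random.Generator,
    seed: int,
) -> PhantomConfig:
    table = cfg.effects if group == "T2D" else cfg.control_effects
    layers = []
    visit_c = 1.0 + rng.normal(0.0, cfg.visit_corr_length_sd)
    for k, (name, spec) in enumerate(zip(LAYERS, cfg.phantom.layers)):
        eff = table.get((name, week), LayerEffect())
        tf = eff.thickness_factor
        if group == "T2D" and tf != 1.0:
            tf = max(tf + effect_jitter[(name, week)], 0.1)
        visit_t = 1.0 + rng.normal(0.0, cfg.visit_thickness_sd)
        layers.append(
            LayerSpec(
                thickness=max(spec.thickness * animal_t[k] * visit_t * tf, 1.0),
                reflectivity=spec.reflectivity * animal_r,
                speckle_contrast=spec.speckle_contrast * eff.contrast_factor,
                corr_length=max(
                    spec.corr_length * animal_c * visit_c * eff.corr_length_factor, 0.0
                ),
            )
        )
    return replace(cfg.phantom, layers=tuple(layers), seed=seed)


def iter_cohort(
    cfg: CohortConfig,
) -> Iterator[tuple[AnimalMeta, OCTVolume, BoundarySet]]:
    """Yield ``(meta, volume, boundaries)`` for every scan of the cohort.

    Scans are ordered animal-major, week-minor; animal ids are ``C01..`` for
    controls and ``D01..`` for the T2D group.  Fully deterministic under the
    master seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 9021]))
    animals = [("control", f"C{i + 1:02d}") for i in range(cfg.n_control)] + [
        ("T2D", f"D{i + 1:02d}") for i in range(cfg.n_t2d)
    ]
    for group, animal_id in animals:
        animal_t = 1.0 + rng.normal(0.0, cfg.animal_thickness_sd, size=len(LAYERS))
        animal_t = np.clip(animal_t, 0.5, None)
        animal_r = max(1.0 + rng.normal(0.0, cfg.animal_reflectivity_sd), 0.2)
        animal_c = max(1.0 + rng.normal(0.0, cfg.animal_corr_length_sd), 0.1)
        effect_jitter = {
            key: rng.normal(0.0, cfg.effect_jitter_sd) for key in sorted(cfg.effects)
        }
        for week in cfg.weeks:
            seed = int(rng.integers(0, 2**31 - 1))
            pcfg = _effective_phantom(
                cfg, animal_t, animal_r, animal_c, effect_jitter, group, week, rng, seed
            )
            meta = AnimalMeta(animal_id=animal_id, group=group, week=week)
            volume, bset = generate_phantom(pcfg, meta=meta)
            yield meta, volume, bset


def generate_cohort(cfg: CohortConfig, out_dir: str | Path) -> CohortManifest:
    """Write a full cohort (TIFF volumes, boundary CSVs, YAML manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scans = []
    for meta, volume, bset in iter_cohort(cfg):
        stem = f"{meta.animal_id}_wk{meta.week:02d}"
        vol_path = out_dir / f"{stem}.tiff"
        bnd_path = out_dir / f"{stem}_boundaries.csv"
        write_volume(volume, vol_path)
        write_boundaries(bset, bnd_path)
        scans.append(
            ScanRecord(meta=meta, volume_path=vol_path.name, boundaries_path=bnd_path.name)
        )
    manifest = CohortManifest(scans=scans, axial_scale=1.0, name="synthetic-cohort")
    write_manifest(manifest, out_dir / "manifest.yaml")
    return manifest


def make_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Write the small deterministic fixtures used across the test suite.

    Contents: a constant 4x4x8 volume, an axial-ramp 4x4x64 volume, a
    2-level checkerboard image, a flat 7-interface boundary table, and a
    JSON manifest of the written files.  Regenerates bit-identically.
    """
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    const = OCTVolume(np.full((4, 4, 8), 7, dtype=np.uint8))
    files["constant_volume"] = write_volume(const, out_dir / "constant_volume.tiff")

    ramp = OCTVolume(
        np.broadcast_to(np.arange(64, dtype=np.uint16), (4, 4, 64)).copy()
    )
    files["ramp_volume"] = write_volume(ramp, out_dir / "ramp_volume.tiff")

    checker = ((np.indices((8, 8)).sum(axis=0) % 2) * 255).astype(np.uint8)
    import tifffile

    checker_path = out_dir / "checkerboard.tiff"
    tifffile.imwrite(checker_path, checker, compression=None)
    files["checkerboard"] = checker_path

    flat = BoundarySet(
        np.tile(np.arange(10.0, 80.0, 10.0)[:, None, None], (1, 4, 4))
    )
    files["flat_boundaries"] = write_boundaries(flat, out_dir / "flat_boundaries.csv")

    manifest_path = out_dir / "fixtures.json"
    with open(manifest_path, "w") as fh:
        json.dump({k: p.name for k, p in files.items()}, fh, indent=2, sort_keys=True)
    files["manifest"] = manifest_path
    return files
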