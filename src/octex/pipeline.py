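"""End-to-end orchestration: manifest → MVF → features/thickness → statistics.

``run_pipeline`` drives the full analysis of a cohort on disk: each scan's
volume and boundary segmentation are loaded, every retinal layer is
projected to its mean-value fundus image, quantized, summarised by the
20-feature GLCM suite, and measured for mean thickness; the per-scan tables
are then pooled into a long-format cohort table on which the longitudinal
statistics run (baseline-covariate ANCOVA per texture feature,
normality-gated two-sample tests on percent-of-baseline thickness).  All
outputs are plain CSV plus a run-metadata JSON; a rerun on identical inputs
reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import LAYERS, BoundarySet, mean_thickness, percent_of_baseline, thickness_map, validate_boundaries
from .io import AnimalMeta, CohortManifest, OCTVolume, read_boundaries, read_manifest, read_volume
from .mvf import project_mvf
from .stats import EndpointSpec, StatResult, run_full_comparison, summarize
from .texture import DEFAULT_DIRECTIONS, FEATURE_NAMES, compute_glcm, quantize, texture_features

__all__ = ["GLCMSettings", "StatsSettings", "RunConfig", "PipelineError",
           "scan_features", "analyze_scans", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage and scan that caused it."""


@dataclass(frozen=True)
class GLCMSettings:
    n_levels: int = 64
    distance: int = 1
    directions: tuple[tuple[int, int], ...] = DEFAULT_DIRECTIONS
    range_mode: str = "minmax"
    symmetric: bool = True
    min_samples: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["directions"] = [list(x) for x in self.directions]
        return d


@dataclass(frozen=True)
class StatsSettings:
    alpha: float = 0.05
    baseline_week: int = 0
    weeks: tuple[int, ...] = (4, 8, 12)
    fdr: bool = False


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    manifest: str
    out_dir: str
    layers: tuple[str, ...] = LAYERS
    glcm: GLCMSettings = GLCMSettings()
    stats: StatsSettings = StatsSettings()
    strict: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        glcm = d.get("glcm", {})
        if "directions" in glcm:
            glcm["directions"] = tuple(tuple(x) for x in glcm["directions"])
        stats = d.get("stats", {})
        if "weeks" in stats:
            stats["weeks"] = tuple(stats["weeks"])
        return cls(
            manifest=d["manifest"],
            out_dir=d["out_dir"],
            layers=tuple(d.get("layers", LAYERS)),
            glcm=GLCMSettings(**glcm),
            stats=StatsSettings(**stats),
            strict=bool(d.get("strict", False)),
            log_level=d.get("log_level", "INFO"),
        )


def scan_features(
    volume: OCTVolume,
    bset: BoundarySet,
    layers: tuple[str, ...] = LAYERS,
    glcm: GLCMSettings = GLCMSettings(),
) -> dict[str, dict[str, float]]:
    """The 20 GLCM features of every requested layer of one scan."""
    out: dict[str, dict[str, float]] = {}
    for layer in layers:
        img = project_mvf(volume, bset, layer, min_samples=glcm.min_samples)
        q = quantize(img, n_levels=glcm.n_levels, range_mode=glcm.range_mode)
        g = compute_glcm(
            q, distance=glcm.distance, directions=glcm.directions, symmetric=glcm.symmetric
        )
        out[layer] = texture_features(g).values
    return out


def analyze_scans(
    scans,
    axial_scale: float = 1.0,
    layers: tuple[str, ...] = LAYERS,
    glcm: GLCMSettings = GLCMSettings(),
    strict: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, int]:
    """Measure every scan and pool the results.

    ``scans`` yields ``(meta, volume, boundaries)`` triples (for example
    :func:`octex.synthetic.iter_cohort`).  Returns the wide feature table,
    the thickness table, the long-format cohort table feeding the
    statistics stage, and the number of scans skipped on error.
    """
    feat_rows, thick_rows, n_failed = [], [], 0
    for meta, volume, bset in scans:
        tag = f"{meta.animal_id} wk{meta.week}"
        try:
            report = validate_boundaries(bset, volume_depth=volume.depth)
            if not report.ok:
                raise PipelineError(
                    f"[geometry] invalid boundaries for {tag}: {len(report)} violations"
                )
            feats = scan_features(volume, bset, layers=layers, glcm=glcm)
        except Exception as exc:  # noqa: BLE001 - per-scan robustness
            if strict:
                raise PipelineError(f"[features] {tag}: {exc}") from exc
            log.warning("skipping %s: %s", tag, exc)
            n_failed += 1
            continue
        for layer in layers:
            feat_rows.append(
                {
                    "animal_id": meta.animal_id,
                    "group": meta.group,
                    "week": meta.week,
                    "layer": layer,
                    **feats[layer],
                }
            )
        for layer in list(layers) + ["total"]:
            tmap = thickness_map(bset, layer)
            thick_rows.append(
                {
                    "animal_id": meta.animal_id,
                    "group": meta.group,
                    "week": meta.week,
                    "layer": layer,
                    "mean_thickness_px": mean_thickness(tmap),
                    "mean_thickness_um": mean_thickness(tmap) * axial_scale,
                }
            )
        log.info("analyzed %s: %d layers", tag, len(layers))

    features = pd.DataFrame(feat_rows)
    thickness = pd.DataFrame(thick_rows)
    if not thickness.empty:
        base = thickness[thickness["week"] == 0].set_index(["animal_id", "layer"])[
            "mean_thickness_px"
        ]

        def _pct(row):
            key = (row["animal_id"], row["layer"])
            if key in base.index and base.loc[key] > 0:
                return percent_of_baseline(row["mean_thickness_px"], base.loc[key])
            return np.nan

        thickness["pct_of_baseline"] = thickness.apply(_pct, axis=1)

    long_rows = []
    for _, r in features.iterrows():
        for name in FEATURE_NAMES:
            long_rows.append(
                {
                    "animal_id": r["animal_id"],
                    "group": r["group"],
                    "week": r["week"],
                    "layer": r["layer"],
                    "measure": name,
                    "value": r[name],
                }
            )
    for _, r in thickness.iterrows():
        long_rows.append(
            {
                "animal_id": r["animal_id"],
                "group": r["group"],
                "week": r["week"],
                "layer": r["layer"],
                "measure": "thickness",
                "value": r["mean_thickness_px"],
            }
        )
    cohort = pd.DataFrame(long_rows)
    return features, thickness, cohort, n_failed


def default_endpoints() -> list[EndpointSpec]:
    """Texture features via baseline-covariate ANCOVA; thickness via the
    normality-gated two-sample test on percent of baseline."""
    eps = [EndpointSpec(measure=name, test="ancova") for name in FEATURE_NAMES]
    eps.append(
        EndpointSpec(measure="thickness", test="gated", as_percent_of_baseline=True)
    )
    return eps


def _results_frame(results: list[StatResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "measure": r.measure,
                "layer": r.layer,
                "week": r.week,
                "test_name": r.test_name,
                "estimate": r.estimate,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "significant": r.significant,
                "n_control": r.n_control,
                "n_t2d": r.n_t2d,
            }
            for r in results
        ]
    )


def _write_csv_with_header(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full cohort analysis described by ``cfg``.

    Writes ``features.csv``, ``thickness.csv``, ``stat_results.csv``,
    ``summary.csv`` and ``run_metadata.json`` into ``cfg.out_dir`` and
    returns the metadata dictionary.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(cfg.manifest)
    root = Path(cfg.manifest).parent

    def scan_iter():
        for s in manifest.scans:
            volume = read_volume(
                root / s.volume_path, meta=s.meta, axial_scale=manifest.axial_scale
            )
            bset = read_boundaries(root / s.boundaries_path)
            yield s.meta, volume, bset

    features, thickness, cohort, n_failed = analyze_scans(
        scan_iter(),
        axial_scale=manifest.axial_scale,
        layers=cfg.layers,
        glcm=cfg.glcm,
        strict=cfg.strict,
    )
    if features.empty:
        raise PipelineError("[stats] no scan was analyzed successfully")

    present = set(cohort["week"].unique())
    weeks = tuple(w for w in cfg.stats.weeks if w in present)
    results = run_full_comparison(
        cohort,
        default_endpoints(),
        weeks=weeks,
        baseline_week=cfg.stats.baseline_week,
        alpha=cfg.stats.alpha,
        fdr=cfg.stats.fdr,
        on_error="raise" if cfg.strict else "skip",
    )
    summaries = []
    for (measure, layer, group, week), _ in cohort.groupby(
        ["measure", "layer", "group", "week"]
    ):
        s = summarize(cohort, measure, layer, group, week)
        summaries.append(dataclasses.asdict(s))

    glcm_header = [f"{k}={v}" for k, v in cfg.glcm.to_dict().items()]
    _write_csv_with_header(features, out_dir / "features.csv", glcm_header)
    thickness.to_csv(out_dir / "thickness.csv", index=False)
    _results_frame(results).to_csv(out_dir / "stat_results.csv", index=False)
    pd.DataFrame(summaries).to_csv(out_dir / "summary.csv", index=False)

    metadata = {
        "version": __version__,
        "config": {
            "manifest": str(cfg.manifest),
            "out_dir": str(cfg.out_dir),
            "layers": list(cfg.layers),
            "glcm": cfg.glcm.to_dict(),
            "stats": dataclasses.asdict(cfg.stats),
            "strict": cfg.strict,
        },
        "counts": {
            "scans": len(manifest.scans),
            "scans_failed": n_failed,
            "feature_rows": len(features),
            "thickness_rows": len(thickness),
            "stat_results": len(results),
        },
        "complete": n_failed == 0,
    }
    with open(out_dir / "run_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
    return metadata
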