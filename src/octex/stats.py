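"""Longitudinal two-group statistics for layer-resolved endpoints.

Two families of tests are provided, matching common practice in preclinical
longitudinal imaging studies:

* **ANCOVA with baseline covariate** — for texture-style endpoints: at each
  follow-up week, ``value_t ~ group + value_baseline`` is fitted by
  ordinary least squares (group coded control=0, T2D=1) and the group
  coefficient is the baseline-adjusted group difference, tested with its
  F (= t²) statistic.  One model per (measure, layer, week); complete-case.
* **Normality-gated two-sample test** — for thickness-style endpoints,
  usually expressed as percent of baseline: Shapiro–Wilk is applied to each
  group; if both pass, a two-sided Student's t-test (pooled variance) is
  used, otherwise a two-sided Mann–Whitney U test (exact enumeration for
  small tie-free samples, normal approximation with tie correction
  otherwise).

Significance is declared at α = 0.05 (two-sided) and no multiplicity
correction is applied by default; Benjamini–Hochberg FDR is available
behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .geometry import percent_of_baseline

__all__ = [
    "COHORT_COLUMNS",
    "StatResult",
    "SummaryStats",
    "EndpointSpec",
    "InsufficientDataError",
    "DegenerateModelError",
    "validate_cohort_table",
    "ancova_group_effect",
    "gated_two_sample_test",
    "summarize",
    "run_full_comparison",
]

log = logging.getLogger(__name__)

COHORT_COLUMNS = ["animal_id", "group", "week", "layer", "measure", "value"]


class InsufficientDataError(ValueError):
    """Fewer complete-case animals than the test requires."""


class DegenerateModelError(ValueError):
    """The response has no variance; the model cannot be fitted."""


@dataclass
class StatResult:
    """One group contrast at one (measure, layer, week)."""

    measure: str
    layer: str
    week: int
    test_name: str  # "ancova", "t_test" or "mann_whitney"
    estimate: float
    statistic: float
    p_value: float
    n_control: int
    n_t2d: int
    alpha: float = 0.05
    normality_p: tuple[float, float] | None = None
    n_dropped: int = 0

    @property
    def significant(self) -> bool:
        return bool(self.p_value <= self.alpha)


@dataclass
class SummaryStats:
    """Mean ± SEM plus the five-number box-plot summary for one cell."""

    group: str
    week: int
    layer: str
    measure: str
    mean: float
    sem: float
    median: float
    q25: float
    q75: float
    min: float
    max: float
    n: int


@dataclass
class EndpointSpec:
    """How one measure is analysed by :func:`run_full_comparison`.

    ``test="ancova"`` uses the raw follow-up values with the week-0 value
    as covariate; ``test="gated"`` uses the normality-gated two-sample test,
    optionally after converting each animal's value to percent of its own
    baseline (the usual presentation for thickness endpoints).
    """

    measure: str
    test: str = "ancova"
    as_percent_of_baseline: bool = False

    def __post_init__(self) -> None:
        if self.test not in ("ancova", "gated"):
            raise ValueError(f"unknown test {self.test!r}")


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format cohort table contract and return it unchanged."""
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    bad_weeks = set(table["week"].unique()) - {0, 4, 8, 12}
    if bad_weeks:
        raise ValueError(f"unexpected weeks {sorted(bad_weeks)}")
    dup = table.duplicated(subset=["animal_id", "week", "layer", "measure"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (animal, week, layer, measure) rows")
    return table


def _paired_values(
    table: pd.DataFrame, measure: str, layer: str, week_t: int, baseline_week: int
) -> pd.DataFrame:
    sub = table[(table["measure"] == measure) & (table["layer"] == layer)]
    base = sub[sub["week"] == baseline_week][["animal_id", "group", "value"]]
    foll = sub[sub["week"] == week_t][["animal_id", "value"]]
    merged = base.merge(foll, on="animal_id", suffixes=("_0", "_t"))
    n_total = sub[sub["week"].isin([baseline_week, week_t])]["animal_id"].nunique()
    merged.attrs["n_dropped"] = n_total - len(merged)
    return merged


def ancova_group_effect(
    table: pd.DataFrame,
    measure: str,
    layer: str,
    week_t: int,
    baseline_week: int = 0,
    alpha: float = 0.05,
) -> StatResult:
    """Baseline-adjusted group difference at one follow-up week.

    Fits ``value_t = b0 + b1*group + b2*value_baseline + e`` by OLS over
    complete cases (animals with both timepoints) and returns ``b1`` with
    its F statistic and two-sided p-value.  Requires at least 3 complete
    animals per group.
    """
    if week_t == baseline_week:
        raise ValueError("follow-up week must differ from the baseline week")
    merged = _paired_values(table, measure, layer, week_t, baseline_week)
    n_dropped = merged.attrs["n_dropped"]
    if n_dropped:
        log.info(
            "ancova %s/%s wk%d: dropped %d incomplete animals",
            measure, layer, week_t, n_dropped,
        )
    n_c = int((merged["group"] == "control").sum())
    n_d = int((merged["group"] == "T2D").sum())
    if n_c < 3 or n_d < 3:
        raise InsufficientDataError(
            f"need >=3 complete animals per group, got control={n_c}, T2D={n_d} "
            f"for {measure}/{layer} week {week_t}"
        )
    y = merged["value_t"].to_numpy(float)
    if np.ptp(y) == 0:
        raise DegenerateModelError(
            f"zero variance in follow-up values for {measure}/{layer} week {week_t}"
        )
    group = (merged["group"] == "T2D").astype(float).to_numpy()
    x0 = merged["value_0"].to_numpy(float)
    X = sm.add_constant(np.column_stack([group, x0]), has_constant="add")
    fit = sm.OLS(y, X).fit()
    beta1 = float(fit.params[1])
    t = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    if not math.isfinite(p):  # perfect fit: zero residual variance
        p = 0.0 if beta1 != 0 else 1.0
    return StatResult(
        measure=measure,
        layer=layer,
        week=week_t,
        test_name="ancova",
        estimate=beta1,
        statistic=t * t,
        p_value=p,
        n_control=n_c,
        n_t2d=n_d,
        alpha=alpha,
        n_dropped=n_dropped,
    )


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U: exact for small tie-free samples, else
    normal approximation with tie correction."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 20 and len(y) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def gated_two_sample_test(
    x,
    y,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    measure: str = "",
    layer: str = "",
    week: int = 0,
) -> StatResult:
    """Two-sample comparison routed by a Shapiro–Wilk normality gate.

    ``x`` are control values, ``y`` T2D values.  If both groups pass
    Shapiro–Wilk (p > ``normality_alpha``), a two-sided pooled-variance
    t-test is used; otherwise (including constant samples, for which
    Shapiro–Wilk is undefined) a two-sided Mann–Whitney U test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise InsufficientDataError(
            f"need n >= 3 per group, got {len(x)} and {len(y)}"
        )
    normality_p: tuple[float, float] | None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant sample: Shapiro-Wilk undefined, routing to Mann-Whitney")
        normality_p = None
        normal = False
    else:
        px = float(sps.shapiro(x).pvalue)
        py = float(sps.shapiro(y).pvalue)
        normality_p = (px, py)
        normal = px > normality_alpha and py > normality_alpha
    estimate = float(y.mean() - x.mean())
    if normal:
        res = sps.ttest_ind(x, y, equal_var=True)
        stat, p, name = float(res.statistic), float(res.pvalue), "t_test"
    else:
        stat, p = _mann_whitney(x, y)
        name = "mann_whitney"
    return StatResult(
        measure=measure,
        layer=layer,
        week=week,
        test_name=name,
        estimate=estimate,
        statistic=stat,
        p_value=p,
        n_control=len(x),
        n_t2d=len(y),
        alpha=alpha,
        normality_p=normality_p,
    )


def summarize(
    table: pd.DataFrame, measure: str, layer: str, group: str, week: int
) -> SummaryStats:
    """Mean ± SEM and box-plot five-number summary for one cohort cell.

    Quartiles use linear interpolation; SEM is sd/√n with sd the sample
    standard deviation (ddof=1), NaN for a single value.
    """
    sub = table[
        (table["measure"] == measure)
        & (table["layer"] == layer)
        & (table["group"] == group)
        & (table["week"] == week)
    ]["value"].to_numpy(float)
    if sub.size == 0:
        raise InsufficientDataError(
            f"no values for {measure}/{layer}/{group}/week {week}"
        )
    n = sub.size
    sem = float(sub.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    q25, med, q75 = np.percentile(sub, [25, 50, 75])
    return SummaryStats(
        group=group,
        week=week,
        layer=layer,
        measure=measure,
        mean=float(sub.mean()),
        sem=sem,
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        min=float(sub.min()),
        max=float(sub.max()),
        n=int(n),
    )


def _percent_table(table: pd.DataFrame, measure: str, baseline_week: int) -> pd.DataFrame:
    """Per-animal percent-of-baseline transform of one measure."""
    sub = table[table["measure"] == measure]
    base = sub[sub["week"] == baseline_week]
    base_map = base.set_index(["animal_id", "layer"])["value"]
    rows = []
    for _, r in sub[sub["week"] != baseline_week].iterrows():
        key = (r["animal_id"], r["layer"])
        if key not in base_map.index:
            continue
        rows.append(
            {
                "animal_id": r["animal_id"],
                "group": r["group"],
                "week": r["week"],
                "layer": r["layer"],
                "measure": measure,
                "value": percent_of_baseline(r["value"], base_map.loc[key]),
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def run_full_comparison(
    table: pd.DataFrame,
    endpoints: list[EndpointSpec],
    weeks: tuple[int, ...] = (4, 8, 12),
    baseline_week: int = 0,
    alpha: float = 0.05,
    fdr: bool = False,
    on_error: str = "raise",
) -> list[StatResult]:
    """One StatResult per (measure, layer, follow-up week).

    Texture-style endpoints go through the baseline-covariate ANCOVA;
    thickness-style endpoints through the normality-gated two-sample test,
    optionally on percent-of-baseline values.  No multiplicity correction
    by default; ``fdr=True`` replaces p-values by Benjamini–Hochberg
    adjusted values across all results.  ``on_error="skip"`` logs and drops
    cells with insufficient or degenerate data instead of raising.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip', got {on_error!r}")
    validate_cohort_table(table)
    results: list[StatResult] = []
    for spec in endpoints:
        sub = table[table["measure"] == spec.measure]
        layers = sorted(sub["layer"].unique())
        gated_table = (
            _percent_table(table, spec.measure, baseline_week)
            if spec.test == "gated" and spec.as_percent_of_baseline
            else table
        )
        for layer in layers:
            for week in weeks:
                try:
                    if spec.test == "ancova":
                        results.append(
                            ancova_group_effect(
                                table, spec.measure, layer, week,
                                baseline_week=baseline_week, alpha=alpha,
                            )
                        )
                    else:
                        cell = gated_table[
                            (gated_table["measure"] == spec.measure)
                            & (gated_table["layer"] == layer)
                            & (gated_table["week"] == week)
                        ]
                        x = cell[cell["group"] == "control"]["value"].to_numpy(float)
                        y = cell[cell["group"] == "T2D"]["value"].to_numpy(float)
                        results.append(
                            gated_two_sample_test(
                                x, y, alpha=alpha,
                                measure=spec.measure, layer=layer, week=week,
                            )
                        )
                except (InsufficientDataError, DegenerateModelError) as exc:
                    if on_error == "raise":
                        raise
                    log.warning(
                        "skipping %s/%s week %d: %s", spec.measure, layer, week, exc
                    )
    if fdr and results:
        adjusted = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, p_adj in zip(results, adjusted):
            r.p_value = float(p_adj)
    return results
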