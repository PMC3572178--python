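"""Aggregation-based accuracy assessment of gridded population maps.

The protocol: take census counts at a fine admin level, sum them to the next
coarser level, rebuild the gridded map from the coarse counts only, then sum
the modelled cells back within each fine unit and compare with the held-back
fine counts.  Per method this yields paired (observed, estimated) unit
totals scored with

    RMSE  = sqrt(mean (est - obs)^2)
    %RMSE = 100 * RMSE / mean(obs)
    MAE   = mean |est - obs|

plus Pearson's correlation of estimates against observations (both r and r^2
are reported, since published accuracy tables are not always explicit about
which they print).  Method error distributions are compared with the
Kruskal-Wallis rank test and the Siegel-Castellan critical-difference
post-hoc on mean ranks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geodata import (
    NODATA_FLOAT,
    AdminUnitSet,
    CategoricalRaster,
    ValueRaster,
)
from .gridding import CensusTable

logger = logging.getLogger("popweave")


@dataclass
class EvaluationPairs:
    """Observed vs estimated population per fine unit for one method.

    ``frame`` columns: unit_id, observed, estimated, method.  ``n_excluded``
    counts fine units that rasterized to zero cells and were dropped.
    """

    frame: pd.DataFrame
    n_excluded: int = 0

    def errors(self) -> np.ndarray:
        return (self.frame["estimated"] - self.frame["observed"]).to_numpy(float)

    def abs_errors(self) -> np.ndarray:
        return np.abs(self.errors())


@dataclass
class MethodMetrics:
    method: str
    n_units: int
    rmse: float
    mae: float
    pct_rmse: float | None       # None when mean(observed) == 0
    pearson_r: float | None      # None when either side is constant
    r_squared: float | None


@dataclass
class PairwiseComparison:
    method_a: str
    method_b: str
    mean_rank_diff: float
    critical_difference: float
    significant: bool


@dataclass
class AccuracyReport:
    """Per-method error metrics plus the rank-based method comparison."""

    metrics: list[MethodMetrics]
    kruskal_h: float | None = None
    kruskal_p: float | None = None
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    alpha: float = 0.05
    n_excluded: int = 0

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.metrics])

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self.pairwise])

    def to_csv(self, path) -> None:
        self.metrics_frame().to_csv(path, index=False)

    def summary(self) -> str:
        lines = ["method accuracy (fine-unit observed vs estimated totals)", ""]
        for m in self.metrics:
            pct = f"{m.pct_rmse:.2f}%" if m.pct_rmse is not None else "undefined"
            r = f"{m.pearson_r:.3f}" if m.pearson_r is not None else "undefined"
            lines.append(
                f"  {m.method:>10s}: RMSE={m.rmse:.2f}  %RMSE={pct}  "
                f"MAE={m.mae:.2f}  r={r}  (n={m.n_units})"
            )
        if self.kruskal_h is not None:
            lines.append("")
            lines.append(
                f"Kruskal-Wallis on absolute errors: H={self.kruskal_h:.4f}, "
                f"p={self.kruskal_p:.3g}"
            )
            for p in self.pairwise:
                verdict = "differ" if p.significant else "no significant difference"
                lines.append(
                    f"  {p.method_a} vs {p.method_b}: |mean-rank diff|="
                    f"{p.mean_rank_diff:.2f} vs critical {p.critical_difference:.2f} "
                    f"-> {verdict} (alpha={self.alpha})"
                )
        if self.n_excluded:
            lines.append(f"\n{self.n_excluded} unit(s) excluded (zero cells).")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# protocol steps
# ---------------------------------------------------------------------------

def aggregate_units(
    fine_census: CensusTable, units: AdminUnitSet
) -> tuple[CensusTable, AdminUnitSet]:
    """Sum fine-level census counts to their parent units.

    Returns the coarse census table together with the coarse AdminUnitSet
    (unioned child geometries).  Fine units without a resolvable parent are a
    hard error.
    """
    fine_level = max(units.levels())
    fine_units = {u.unit_id: u for u in units.at_level(fine_level)}
    df = fine_census.frame
    rows = {}
    for r in df.itertuples():
        u = fine_units.get(r.unit_id)
        if u is None:
            raise ValueError(f"census unit {r.unit_id!r} not in the fine unit set")
        if u.parent_id is None:
            raise ValueError(f"fine unit {r.unit_id!r} has no parent")
        agg = rows.setdefault(
            u.parent_id,
            {"unit_id": u.parent_id, "population": 0.0,
             "reference_year": r.reference_year, "country": r.country},
        )
        agg["population"] += float(r.population)
    coarse_census = CensusTable(pd.DataFrame(sorted(rows.values(), key=lambda d: d["unit_id"])))
    coarse_units = units.aggregate_to_parents(fine_level)
    return coarse_census, coarse_units


def evaluate(
    pop: ValueRaster,
    fine_zones: CategoricalRaster,
    fine_census: CensusTable,
    method: str,
) -> EvaluationPairs:
    """Sum modelled cells within each fine unit and pair with observed counts.

    Fine units that cover no raster cells are excluded from the pairs and
    counted in ``n_excluded``.
    """
    from .geodata import assert_same_grid

    assert_same_grid(pop, fine_zones)
    vals = np.where(pop.nodata_mask(), 0.0, pop.values)
    id_to_code = {uid: code for code, uid in fine_zones.legend.items()}
    rows = []
    excluded = 0
    for r in fine_census.frame.itertuples():
        code = id_to_code.get(r.unit_id)
        cells = fine_zones.values == code if code is not None else None
        if cells is None or not cells.any():
            excluded += 1
            continue
        rows.append(
            {"unit_id": r.unit_id, "observed": float(r.population),
             "estimated": float(vals[cells].sum()), "method": method}
        )
    if excluded:
        logger.warning("evaluate: %d fine unit(s) with zero cells excluded", excluded)
    return EvaluationPairs(pd.DataFrame(rows), n_excluded=excluded)


def error_metrics(pairs: EvaluationPairs) -> MethodMetrics:
    """RMSE / %RMSE / MAE / Pearson r for one method's evaluation pairs."""
    df = pairs.frame
    if len(df) < 2:
        raise ValueError("need at least 2 (observed, estimated) pairs")
    obs = df["observed"].to_numpy(float)
    est = df["estimated"].to_numpy(float)
    err = est - obs
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    mean_obs = float(np.mean(obs))
    pct = 100.0 * rmse / mean_obs if mean_obs > 0 else None
    if np.ptp(obs) == 0 or np.ptp(est) == 0:
        r = None  # correlation undefined for a constant series
    else:
        r = float(stats.pearsonr(obs, est).statistic)
    method = df["method"].iloc[0] if "method" in df.columns and len(df) else ""
    return MethodMetrics(
        method=str(method),
        n_units=len(df),
        rmse=rmse,
        mae=mae,
        pct_rmse=pct,
        pearson_r=r,
        r_squared=(r * r if r is not None else None),
    )


def compare_methods(
    errors_by_method: dict[str, np.ndarray | list], alpha: float = 0.05
) -> tuple[float, float, list[PairwiseComparison]]:
    """Kruskal-Wallis test across methods plus Siegel-Castellan post-hoc.

    ``errors_by_method`` maps method label -> per-unit absolute errors.  The
    H statistic uses the standard tie correction with a chi-square p-value on
    k-1 degrees of freedom.  Pairwise significance follows the
    multiple-comparison-of-mean-ranks rule: methods a and b differ when

        |Rbar_a - Rbar_b| >= z_{1 - alpha/(k(k-1))} *
                             sqrt(N(N+1)/12 * (1/n_a + 1/n_b))

    If every value across all groups is identical, H = 0, p = 1 and no pair
    is significant.
    """
    methods = list(errors_by_method)
    groups = [np.asarray(errors_by_method[m], dtype=float) for m in methods]
    if len(groups) < 2:
        raise ValueError("need at least two methods to compare")
    if any(g.size < 2 for g in groups):
        raise ValueError("each method needs at least two observations")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
        h, p = float(h), float(p)
    # mean ranks for the post-hoc
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(float(ranks[start:start + n].mean()))
        start += n
    n_total = pooled.size
    k = len(groups)
    z = stats.norm.ppf(1.0 - alpha / (k * (k - 1)))
    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(mean_ranks[i] - mean_ranks[j])
            crit = z * math.sqrt(
                n_total * (n_total + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            significant = bool(diff >= crit) and np.ptp(pooled) != 0
            pairwise.append(
                PairwiseComparison(methods[i], methods[j], diff, float(crit), significant)
            )
    return h, p, pairwise


def error_raster(pairs: EvaluationPairs, fine_zones: CategoricalRaster) -> ValueRaster:
    """Map per-unit signed error (estimated - observed) onto the fine units.

    Every cell of a unit carries the unit's error; cells outside all units
    are nodata.  A rasterized unit missing from the pairs is a hard error.
    """
    err = dict(
        zip(pairs.frame["unit_id"], (pairs.frame["estimated"] - pairs.frame["observed"]))
    )
    out = np.full(fine_zones.grid.shape, NODATA_FLOAT, dtype=np.float64)
    for code in fine_zones.codes_present():
        uid = fine_zones.legend.get(code, str(code))
        if uid not in err:
            raise ValueError(f"unit {uid!r} is rasterized but missing from pairs")
        out[fine_zones.values == code] = err[uid]
    return ValueRaster(fine_zones.grid, out)


def build_report(
    pairs_by_method: dict[str, EvaluationPairs], alpha: float = 0.05
) -> AccuracyReport:
    """Convenience: metrics per method plus the cross-method rank comparison."""
    metrics = [error_metrics(p) for p in pairs_by_method.values()]
    h = p_val = None
    pairwise: list[PairwiseComparison] = []
    if len(pairs_by_method) >= 2:
        h, p_val, pairwise = compare_methods(
            {m: pr.abs_errors() for m, pr in pairs_by_method.items()}, alpha=alpha
        )
    n_excluded = sum(p.n_excluded for p in pairs_by_method.values())
    return AccuracyReport(metrics, h, p_val, pairwise, alpha, n_excluded)
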