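"""CASP-convention z-scores, composite ranking scores, and baselines.

The ranking machinery standardises each metric within the pool of model-1
submissions for one target (two-pass: z-score, drop outliers below a
threshold, recompute the statistics on the survivors, re-assign z to every
submission, floor), combines per-metric z-scores into composite ranking
scores, and sums them over targets.  A "naive predictor" that resubmits the
starting model unchanged provides the baseline every group must beat; it is
z-scored against the statistics of the real predictions without entering the
pool that defines them.

Composite presets
-----------------
``casp12``    0.46 z_RMS_CA + 0.17 z_GDT_HA + 0.20 z_SG + 0.15 z_QCS + 0.02 z_MP
``tbm``       1/3 z_GDT_HA + 1/9 (z_lDDT + z_CADaa + z_SG) + 1/3 z_ASE
``tbm_prime`` 1/2 z_GDT_HA + 1/6 (z_lDDT + z_CADaa + z_SG)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "KEY_COLUMNS",
    "NATIVE_METRICS",
    "INGESTED_METRICS",
    "DEFAULT_ORIENTATION",
    "MetricTable",
    "ZScoreConfig",
    "RankingWeights",
    "PRESET_WEIGHTS",
    "RankingResult",
    "BaselineResult",
    "pool_statistics",
    "casp_zscores",
    "zscore_frame",
    "composite_score",
    "composite_frame",
    "rank_groups",
    "naive_baseline",
    "fraction_improved",
    "best_vs_start",
]

logger = logging.getLogger("refeval")

KEY_COLUMNS = ("target_id", "group_id", "model_index")
NATIVE_METRICS = ("rms_ca", "gdt_ts", "gdt_ha", "sg", "lddt", "ase", "s_torsion")
INGESTED_METRICS = ("qcs", "mp", "cadaa", "llg")

# +1: higher is better; -1: lower is better.
DEFAULT_ORIENTATION: dict[str, int] = {
    "rms_ca": -1,
    "gdt_ts": +1,
    "gdt_ha": +1,
    "sg": +1,
    "lddt": +1,
    "ase": +1,
    "s_torsion": +1,
    "qcs": +1,
    "mp": -1,
    "cadaa": +1,
    "llg": +1,
}


@dataclass
class MetricTable:
    """Per (target, group, model) metric values with column provenance."""

    frame: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in KEY_COLUMNS:
            if col not in self.frame.columns:
                raise ValueError(f"metric table missing key column {col!r}")
        if self.frame.duplicated(subset=list(KEY_COLUMNS)).any():
            raise ValueError("duplicate (target_id, group_id, model_index) keys")
        for col in self.metric_columns:
            self.provenance.setdefault(
                col, "computed" if col in NATIVE_METRICS else "ingested"
            )

    @property
    def metric_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in KEY_COLUMNS]

    def model1(self) -> pd.DataFrame:
        return self.frame[self.frame["model_index"] == 1]

    @classmethod
    def from_rows(cls, rows: list[dict], provenance: dict | None = None) -> "MetricTable":
        return cls(pd.DataFrame(rows), provenance or {})

    @classmethod
    def from_csv(cls, path: str | Path) -> "MetricTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass
class ZScoreConfig:
    """The "usual CASP conventions" for standardising a metric pool."""

    orientation: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ORIENTATION))
    outlier_threshold: float = -2.0  # drop z below this before recomputing
    floor: float = -2.0  # minimum assigned z
    sd_mode: Literal["population", "sample"] = "population"

    def __post_init__(self) -> None:
        if self.floor > 0:
            raise ValueError("floor must be <= 0")
        if any(o not in (-1, +1) for o in self.orientation.values()):
            raise ValueError("orientations must be +1 or -1")


@dataclass(frozen=True)
class RankingWeights:
    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if not np.isclose(sum(self.weights.values()), 1.0):
            raise ValueError(f"{self.name}: weights must sum to 1")


PRESET_WEIGHTS: dict[str, RankingWeights] = {
    "casp12": RankingWeights(
        "casp12", {"rms_ca": 0.46, "gdt_ha": 0.17, "sg": 0.20, "qcs": 0.15, "mp": 0.02}
    ),
    "tbm": RankingWeights(
        "tbm",
        {"gdt_ha": 1 / 3, "lddt": 1 / 9, "cadaa": 1 / 9, "sg": 1 / 9, "ase": 1 / 3},
    ),
    "tbm_prime": RankingWeights(
        "tbm_prime", {"gdt_ha": 1 / 2, "lddt": 1 / 6, "cadaa": 1 / 6, "sg": 1 / 6}
    ),
}


@dataclass
class RankingResult:
    table: pd.DataFrame  # per group: total, rank; sorted by rank
    per_target: pd.DataFrame  # groups x targets composite scores
    mode: str

    def rank_of(self, group_id: str) -> int:
        return int(self.table.loc[self.table["group_id"] == group_id, "rank"].iloc[0])


@dataclass
class BaselineResult:
    baseline_total: float
    baseline_per_target: pd.Series
    group_flags: pd.DataFrame  # per group: total, beats_baseline
    n_beating: int


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------

def _sd(x: np.ndarray, mode: str) -> float:
    if mode == "sample":
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    else:
        sd = float(np.std(x))
    # a numerically-zero spread (identical values up to rounding) is degenerate
    if sd <= 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        return 0.0
    return sd


def pool_statistics(values: np.ndarray, config: ZScoreConfig) -> tuple[float, float]:
    """Two-pass (outlier-rejected) mean and SD of an oriented value pool."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ValueError("pool must hold at least 2 values")
    mean, sd = float(np.mean(x)), _sd(x, config.sd_mode)
    if sd == 0:
        return mean, 0.0
    z0 = (x - mean) / sd
    keep = x[z0 >= config.outlier_threshold]
    if len(keep) >= 2:
        dropped = len(x) - len(keep)
        if dropped:
            logger.debug("outlier pass dropped %d of %d values", dropped, len(x))
        mean, sd = float(np.mean(keep)), _sd(keep, config.sd_mode)
    return mean, sd


def _zscore_values(values: np.ndarray, config: ZScoreConfig) -> np.ndarray:
    mean, sd = pool_statistics(values, config)
    if sd == 0:
        return np.where(np.isnan(values), np.nan, 0.0)
    z = (values - mean) / sd
    return np.maximum(z, config.floor)


def casp_zscores(
    table: MetricTable,
    metric: str,
    config: ZScoreConfig | None = None,
    pool: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-row z-scores of one metric, standardised per target over the
    model-1 pool (two-pass with outlier rejection, floored)."""
    config = config or ZScoreConfig()
    orient = config.orientation.get(metric)
    if orient is None:
        raise ValueError(f"no orientation defined for metric {metric!r}")
    rows = table.model1() if pool is None else pool
    out = pd.Series(np.nan, index=rows.index, dtype=float)
    for target_id, grp in rows.groupby("target_id"):
        vals = orient * grp[metric].to_numpy(dtype=float)
        n_valid = np.sum(~np.isnan(vals))
        if n_valid < 2:
            raise ValueError(f"{target_id}: pool of size {n_valid} for {metric!r}")
        logger.debug("%s/%s: pool size %d", target_id, metric, n_valid)
        out.loc[grp.index] = _zscore_values(vals, config)
    return out


def zscore_frame(
    table: MetricTable,
    metrics: list[str] | None = None,
    config: ZScoreConfig | None = None,
) -> pd.DataFrame:
    """Model-1 rows with each metric replaced by its per-target z-score."""
    config = config or ZScoreConfig()
    rows = table.model1()
    metrics = metrics or [m for m in table.metric_columns if m in config.orientation]
    zf = rows[list(KEY_COLUMNS)].copy()
    for m in metrics:
        zf[m] = casp_zscores(table, m, config)
    return zf


# ---------------------------------------------------------------------------
# composite scores
# ---------------------------------------------------------------------------

MissingPolicy = Literal["strict", "renormalize", "pool_min"]


def composite_score(
    z: Mapping[str, float],
    weights: RankingWeights,
    missing: MissingPolicy = "strict",
    pool_min: Mapping[str, float] | None = None,
) -> float:
    """Weighted sum of per-metric z-scores.

    Missing-component policy: ``strict`` raises; ``renormalize`` reweights
    over the available components; ``pool_min`` substitutes the pool-minimum
    z for the missing component (so groups without ASE estimates score below
    average on that component, rather than being excluded).
    """
    total, wsum = 0.0, 0.0
    for metric, w in weights.weights.items():
        v = z.get(metric)
        v = np.nan if v is None else float(v)
        if np.isnan(v):
            if missing == "strict":
                raise ValueError(f"missing z-score for weighted metric {metric!r}")
            if missing == "pool_min":
                if pool_min is None or metric not in pool_min:
                    raise ValueError(f"pool_min policy needs a pool minimum for {metric!r}")
                v = float(pool_min[metric])
            else:  # renormalize
                continue
        total += w * v
        wsum += w
    if wsum == 0:
        raise ValueError("no available components in composite score")
    if missing == "renormalize":
        return total / wsum
    return total


def composite_frame(
    zf: pd.DataFrame,
    weights: RankingWeights,
    missing: MissingPolicy = "strict",
) -> pd.DataFrame:
    """Per (target, group) composite scores from a z-score frame."""
    pool_min = None
    if missing == "pool_min":
        pool_min_frame = zf.groupby("target_id").min(numeric_only=True)
    rows = []
    for row in zf.itertuples(index=False):
        zvec = {m: getattr(row, m) for m in weights.weights if m in zf.columns}
        if missing == "pool_min":
            pool_min = {
                m: pool_min_frame.loc[row.target_id, m]
                for m in weights.weights
                if m in pool_min_frame.columns
            }
        rows.append(
            {
                "target_id": row.target_id,
                "group_id": row.group_id,
                "score": composite_score(zvec, weights, missing, pool_min),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group ranking and baselines
# ---------------------------------------------------------------------------

def _aggregate(scores: pd.DataFrame, mode: str) -> pd.Series:
    if mode == "sum_positive":
        return scores.groupby("group_id")["score"].apply(lambda s: s.clip(lower=0).sum())
    if mode == "mean":
        return scores.groupby("group_id")["score"].mean()
    raise ValueError(f"unknown aggregation mode {mode!r}")


def rank_groups(
    table: MetricTable,
    weights: RankingWeights,
    config: ZScoreConfig | None = None,
    mode: str = "sum_positive",
    missing: MissingPolicy = "strict",
) -> RankingResult:
    """Order groups by their aggregated composite score over targets.

    ``sum_positive`` sums max(score, 0) per target (the group-ranking
    convention); ``mean`` averages raw scores.  Ties break lexicographically
    by group id.
    """
    config = config or ZScoreConfig()
    rows = table.model1()
    if rows["group_id"].nunique() < 2:
        raise ValueError("need model-1 rows for at least 2 groups")
    metrics = [m for m in weights.weights if m in table.metric_columns]
    missing_metrics = set(weights.weights) - set(metrics)
    if missing_metrics and missing == "strict":
        raise ValueError(f"metric table lacks weighted columns: {sorted(missing_metrics)}")
    zf = zscore_frame(table, metrics, config)
    scores = composite_frame(zf, weights, missing)
    totals = _aggregate(scores, mode)
    result = (
        totals.rename("total")
        .reset_index()
        .sort_values(["total", "group_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    result["rank"] = np.arange(1, len(result) + 1)
    per_target = scores.pivot(index="group_id", columns="target_id", values="score")
    return RankingResult(table=result, per_target=per_target, mode=mode)


def _baseline_zvec(
    table: MetricTable,
    start_rows: pd.DataFrame,
    metrics: list[str],
    config: ZScoreConfig,
) -> pd.DataFrame:
    """z-scores of the starting model against the real-prediction pools."""
    rows = table.model1()
    out = []
    for srow in start_rows.itertuples(index=False):
        target_id = srow.target_id
        pool = rows[rows["target_id"] == target_id]
        if pool.empty:
            raise ValueError(f"no predictions for start-model target {target_id}")
        zvec: dict[str, float] = {"target_id": target_id}
        for m in metrics:
            orient = config.orientation[m]
            vals = orient * pool[m].to_numpy(dtype=float)
            start_val = float(getattr(srow, m))
            if np.isnan(start_val):
                zvec[m] = np.nan
                continue
            mean, sd = pool_statistics(vals, config)
            z = 0.0 if sd == 0 else (orient * start_val - mean) / sd
            zvec[m] = max(z, config.floor)
        out.append(zvec)
    return pd.DataFrame(out)


def naive_baseline(
    table: MetricTable,
    start_rows: pd.DataFrame,
    weights: RankingWeights,
    config: ZScoreConfig | None = None,
    mode: str = "sum_positive",
    missing: MissingPolicy = "strict",
) -> BaselineResult:
    """Score a naive predictor that resubmits the starting model.

    ``start_rows`` holds one row per target with the starting model's metric
    values.  The baseline is z-scored against the statistics of the real
    predictions (it never enters the pool that defines mean/SD), then
    aggregated under the same mode as the groups.
    """
    config = config or ZScoreConfig()
    targets = set(table.model1()["target_id"])
    missing_targets = targets - set(start_rows["target_id"])
    if missing_targets:
        raise ValueError(f"start rows missing for targets: {sorted(missing_targets)}")
    metrics = [m for m in weights.weights if m in table.metric_columns and m in start_rows.columns]
    if missing == "strict" and set(metrics) != set(weights.weights):
        raise ValueError("start rows or table lack weighted metric columns")
    bz = _baseline_zvec(table, start_rows, metrics, config)
    base_scores = composite_frame(
        bz.assign(group_id="__naive__"), weights, missing
    ).set_index("target_id")["score"]
    if mode == "sum_positive":
        baseline_total = float(base_scores.clip(lower=0).sum())
    else:
        baseline_total = float(base_scores.mean())
    ranking = rank_groups(table, weights, config, mode, missing)
    flags = ranking.table[["group_id", "total"]].copy()
    flags["beats_baseline"] = flags["total"] > baseline_total
    return BaselineResult(
        baseline_total=baseline_total,
        baseline_per_target=base_scores,
        group_flags=flags,
        n_beating=int(flags["beats_baseline"].sum()),
    )


def fraction_improved(
    table: MetricTable,
    start_rows: pd.DataFrame,
    score_spec: "str | RankingWeights" = None,
    config: ZScoreConfig | None = None,
    missing: MissingPolicy = "strict",
) -> pd.Series:
    """Per-group fraction of targets where model 1 strictly beats the start.

    ``score_spec`` is either a single metric name (compared with its
    orientation) or a RankingWeights composite (compared via z-scores, with
    the start z-scored against the prediction pool).  Ties count as not
    improved.
    """
    config = config or ZScoreConfig()
    if score_spec is None:
        score_spec = PRESET_WEIGHTS["casp12"]
    rows = table.model1()
    start = start_rows.set_index("target_id")
    if isinstance(score_spec, str):
        orient = config.orientation[score_spec]

        def improved(row) -> bool:
            s = float(start.loc[row.target_id, score_spec])
            return orient * float(getattr(row, score_spec)) > orient * s

        flags = pd.DataFrame(
            {
                "group_id": rows["group_id"].to_numpy(),
                "better": [improved(r) for r in rows.itertuples(index=False)],
            }
        )
    else:
        metrics = [m for m in score_spec.weights if m in table.metric_columns]
        zf = zscore_frame(table, metrics, config)
        scores = composite_frame(zf, score_spec, missing)
        bz = _baseline_zvec(table, start_rows, metrics, config)
        base_scores = composite_frame(
            bz.assign(group_id="__naive__"), score_spec, missing
        ).set_index("target_id")["score"]
        flags = pd.DataFrame(
            {
                "group_id": scores["group_id"].to_numpy(),
                "better": [
                    row.score > float(base_scores.loc[row.target_id])
                    for row in scores.itertuples(index=False)
                ],
            }
        )
    return flags.groupby("group_id")["better"].mean()


def best_vs_start(
    table: MetricTable,
    start_rows: pd.DataFrame,
    initial_table: MetricTable,
    metric: str,
    config: ZScoreConfig | None = None,
) -> pd.DataFrame:
    """Per-target comparison of the start value, the best initial model-1
    value, and the best refined model-1 value of one oriented metric.

    Flags the exception targets where the best refined submission fails to
    beat the best initial one."""
    config = config or ZScoreConfig()
    orient = config.orientation[metric]
    refined = table.model1()
    initial = initial_table.model1()
    start = start_rows.set_index("target_id")
    targets = sorted(set(refined["target_id"]) & set(initial["target_id"]))
    if not targets:
        raise ValueError("refinement and initial tables share no targets")

    def best(frame: pd.DataFrame, tid: str) -> float:
        vals = frame.loc[frame["target_id"] == tid, metric].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        return float(np.max(orient * vals) * orient)

    out = []
    for tid in targets:
        b_init = best(initial, tid)
        b_ref = best(refined, tid)
        out.append(
            {
                "target_id": tid,
                "start": float(start.loc[tid, metric]),
                "best_initial": b_init,
                "best_refined": b_ref,
                "refined_better": orient * b_ref > orient * b_init,
            }
        )
    return pd.DataFrame(out)
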