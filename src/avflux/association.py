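"""Feature selection, hierarchical clustering and outcome correlation.

Covers the descriptive end of the pipeline: selecting metabolic features
with a postprandial response (any time point different from fasting after
BH-FDR across features), Ward/Euclidean hierarchical clustering of
auto-scaled condition means, and Pearson correlation of each metabolite's
postprandial |exchange AUC| (pooled over both study days) against clinical
outcomes (HOMA-IR, body weight), with the sign-switch exclusion rule:
metabolites whose day-mean AUC flips between uptake and release across days
are excluded, because |AUC| would not reflect their change in exchange.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .chemometrics import bh_fdr
from .data_model import MetaboliteTable, OutcomeTable, ValidationError
from .exchange import ExchangeError, _paired_t, cohort_arrays

logger = logging.getLogger("avflux")

OUTCOME_COLUMNS = {"HOMA_IR": "homa_ir", "BW": "body_weight"}


# ---------------------------------------------------------------------------
# Postprandial feature selection
# ---------------------------------------------------------------------------

def select_postprandial_features(
    met_table: MetaboliteTable, alpha: float = 0.05, method: str = "paired_t"
) -> pd.DataFrame:
    """Flag features with ≥1 postprandial point different from fasting.

    For each (feature, vessel, day) and each postprandial time, the values
    are compared to T0 by a paired t-test across animals; p-values are
    BH-adjusted across features within each (vessel, day, time) stratum, and
    a feature is selected if any adjusted p falls below ``alpha``. The
    ``method='kw'`` alternative runs a Kruskal–Wallis test across the five
    time points per (feature, vessel, day) with BH across features.

    Returns one row per (feature, vessel, day) with ``selected`` and the
    minimum adjusted p over times.
    """
    arrays = cohort_arrays(met_table)
    if arrays.times[0] != 0:
        raise ExchangeError("fasting (T0) samples are required for selection")
    conc = arrays.conc  # (v, a, d, t, m)
    n_v, n_a, n_d, n_t, n_m = conc.shape
    vessels = ("ART", "PV", "HV")
    rows = []
    for vi, vessel in enumerate(vessels):
        for di, day in enumerate(arrays.days):
            block = conc[vi, :, di, :, :]  # (a, t, m)
            if np.all(np.isnan(block)):
                continue
            if method == "paired_t":
                q_by_time = []
                for ti in range(1, n_t):
                    _, p = _paired_t(block[:, ti, :] - block[:, 0, :], axis=0)  # (m,)
                    q_by_time.append(bh_fdr(np.nan_to_num(p, nan=1.0)))
                min_q = np.min(np.column_stack(q_by_time), axis=1)
            elif method == "kw":
                p = np.ones(n_m)
                for mi in range(n_m):
                    groups = [block[:, ti, mi][~np.isnan(block[:, ti, mi])] for ti in range(n_t)]
                    if any(len(g) == 0 for g in groups):
                        continue
                    col = np.concatenate(groups)
                    if np.all(col == col[0]):
                        continue
                    _, p[mi] = stats.kruskal(*groups)
                min_q = bh_fdr(p)
            else:
                raise ValueError(f"unknown method {method!r}")
            for mi, met in enumerate(arrays.metabolites):
                rows.append((met, vessel, day, float(min_q[mi]), bool(min_q[mi] < alpha)))
    return pd.DataFrame(rows, columns=["feature", "vessel", "day", "min_q", "selected"])


def condition_means(met_table: MetaboliteTable) -> pd.DataFrame:
    """Features × condition matrix: mean over animals per (vessel, day, time)."""
    arrays = cohort_arrays(met_table)
    cols = {}
    for vi, vessel in enumerate(("ART", "PV", "HV")):
        for di, day in enumerate(arrays.days):
            for ti, t in enumerate(arrays.times):
                block = arrays.conc[vi, :, di, ti, :]  # (a, m)
                if np.all(np.isnan(block)):
                    continue
                cols[f"{vessel}_{day}_t{int(t)}"] = np.nanmean(block, axis=0)
    return pd.DataFrame(cols, index=arrays.metabolites)


# ---------------------------------------------------------------------------
# Hierarchical clustering (Ward / Euclidean)
# ---------------------------------------------------------------------------

@dataclass
class HCAResult:
    """Ward-linkage dendrogram summary: merges, heights, leaves, cuts."""

    labels: list[str]
    merges: np.ndarray  # (n-1, 2) merged cluster indices, scipy convention
    heights: np.ndarray
    leaf_order: np.ndarray
    assignments: dict[int, np.ndarray]  # k -> cluster label per leaf

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "merges": self.merges.tolist(),
            "heights": self.heights.tolist(),
            "leaf_order": self.leaf_order.tolist(),
            "assignments": {str(k): v.tolist() for k, v in self.assignments.items()},
        }


def _ward(X: np.ndarray, labels: list[str]) -> HCAResult:
    Z = linkage(X, method="ward", metric="euclidean")
    n = X.shape[0]
    assignments = {
        k: fcluster(Z, t=k, criterion="maxclust") for k in range(2, min(6, n) + 1)
    }
    return HCAResult(
        labels=labels,
        merges=Z[:, :2].astype(int),
        heights=Z[:, 2],
        leaf_order=leaves_list(Z),
        assignments=assignments,
    )


def hca_heatmap(X: pd.DataFrame, scale_rows: bool = True) -> tuple[HCAResult, HCAResult]:
    """Cluster rows (features) and columns (conditions) of a mean matrix.

    Features are auto-scaled (zero mean, unit SD across conditions) first,
    so rows cluster by response *pattern* and columns by condition profile;
    constant rows are dropped since they carry no clustering information.
    ``scale_rows=False`` clusters raw values. Ward linkage on Euclidean
    distances (ward.D2 convention), deterministic for fixed input. Returns
    (row_result, column_result).
    """
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("HCA needs at least 2 rows and 2 columns")
    vals = X.to_numpy(dtype=float)
    keep = np.ones(len(vals), dtype=bool)
    if scale_rows:
        sd = vals.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.info("HCA: dropping %d constant feature row(s)", int((~keep).sum()))
        vals = vals[keep]
    labels = [str(l) for l, k in zip(X.index, keep) if k]
    if vals.shape[0] < 2:
        raise ValidationError("fewer than 2 non-constant features; cannot cluster")
    scaled = vals
    if scale_rows:
        scaled = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
    rows = _ward(scaled, labels)
    cols = _ward(scaled.T, [str(c) for c in X.columns])
    return rows, cols


# ---------------------------------------------------------------------------
# Outcome correlation
# ---------------------------------------------------------------------------

def correlate_outcomes(
    per_animal_auc: pd.DataFrame,
    outcomes: OutcomeTable,
    outcome: str = "HOMA_IR",
    per_animal_sign_rule: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of per-metabolite |exchange AUC| with an outcome.

    Points are pooled over animals and both days (n = animals × 2). The
    absolute AUC is used so that uptake (positive AUC) and release (negative
    AUC) contribute alike; metabolites whose day-mean AUC switches sign
    between D0 and D60 are excluded with reason ``sign_switch`` (per-animal
    strictness optional). Constant |AUC| vectors are excluded as
    ``constant_auc``.

    ``per_animal_auc`` is the frame produced by
    :func:`avflux.exchange.per_animal_auc_exchange`.
    """
    col = OUTCOME_COLUMNS.get(outcome)
    if col is None:
        raise ValueError(f"unknown outcome {outcome!r}; expected {sorted(OUTCOME_COLUMNS)}")
    merged = per_animal_auc.merge(
        outcomes.records[["animal_id", "day", col]],
        left_on=["animal", "day"],
        right_on=["animal_id", "day"],
        how="inner",
    )
    rows = []
    for (organ, met), g in merged.groupby(["organ", "metabolite"], sort=True):
        day_means = g.groupby("day")["auc_induction_pct"].mean()
        excluded, reason = False, ""
        if len(day_means) < 2:
            excluded, reason = True, "missing_day"
        elif day_means.iloc[0] * day_means.iloc[1] < 0:
            excluded, reason = True, "sign_switch"
        elif per_animal_sign_rule:
            prod = g.pivot_table(index="animal", columns="day", values="auc_induction_pct")
            if (prod.iloc[:, 0] * prod.iloc[:, 1] < 0).any():
                excluded, reason = True, "sign_switch"
        x = np.abs(g["auc_induction_pct"].to_numpy(dtype=float))
        yv = g[col].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(yv))
        x, yv = x[ok], yv[ok]
        r = p = np.nan
        if not excluded:
            if len(x) < 3:
                excluded, reason = True, "too_few_points"
            elif np.ptp(x) == 0 or np.ptp(yv) == 0:
                excluded, reason = True, "constant_auc"
            else:
                r, p = stats.pearsonr(x, yv)
        rows.append((met, organ, outcome, float(r), float(p), int(len(x)), excluded, reason))
    return pd.DataFrame(
        rows, columns=["metabolite", "organ", "outcome", "r", "p", "n", "excluded", "reason"]
    )


def top_k_report(report: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k metabolites by |r| per (organ, outcome), excluded ones removed.

    Ties in |r| break alphabetically by metabolite name; ``significant``
    flags p < 0.05.
    """
    if k <= 0:
        raise ValueError("k must be ≥ 1")
    if report.empty:
        raise ValueError("empty correlation report")
    usable = report.loc[~report["excluded"]].copy()
    usable["abs_r"] = usable["r"].abs()
    usable = usable.sort_values(
        ["organ", "outcome", "abs_r", "metabolite"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    out = usable.groupby(["organ", "outcome"], sort=True).head(k).copy()
    out["rank"] = out.groupby(["organ", "outcome"]).cumcount() + 1
    out["significant"] = out["p"] < 0.05
    return out.drop(columns=["abs_r"]).reset_index(drop=True)
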