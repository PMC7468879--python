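"""Arteriovenous exchange statistics across the intestine and the liver.

The exchange statistic is the percent induction from the steady state
(inflow/outflow = 1):

* intestine:  ``(Art/PV − 1) × 100``
* liver:      ``((0.2·Art + 0.8·PV)/HV − 1) × 100``

where the hepatic inflow is the flow-weighted composite of arterial (20%)
and portal (80%) blood. Positive values mean net uptake by the organ,
negative values net release.

Postprandial summaries per metabolite × day follow the same logic applied
to whole-period quantities: trapezoid AUCs of the inflow and outflow
concentration curves (the hepatic composite is formed pointwise in time
before integration), the time-averaged induction (AUC of the induction
curve divided by the 510-min window) compared against the fasting (T0)
induction, and the signed maximum excursion of induction from fasting.
All significance tests are two-sided paired t-tests across animals;
all-zero difference vectors return p = 1 by convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DAYS, VESSELS, MetaboliteTable, ValidationError
from .synthetic import HEPATIC_WEIGHTS

logger = logging.getLogger("avflux")

ORGANS = ("intestine", "liver")


class ExchangeError(ValueError):
    """Invalid input to an exchange computation."""


# ---------------------------------------------------------------------------
# Elementary induction formulas
# ---------------------------------------------------------------------------

def induction_intestine(art, pv):
    """Intestinal % induction: (Art/PV − 1)·100. Positive = uptake."""
    art = np.asarray(art, dtype=float)
    pv = np.asarray(pv, dtype=float)
    if np.any(np.nan_to_num(pv, nan=1.0) <= 0):
        raise ExchangeError("portal-vein concentration must be positive")
    return (art / pv - 1.0) * 100.0


def induction_liver(art, pv, hv, weights=HEPATIC_WEIGHTS):
    """Hepatic % induction: ((w_a·Art + w_p·PV)/HV − 1)·100 with flow
    weights (0.2, 0.8) by default."""
    art = np.asarray(art, dtype=float)
    pv = np.asarray(pv, dtype=float)
    hv = np.asarray(hv, dtype=float)
    if np.any(np.nan_to_num(hv, nan=1.0) <= 0):
        raise ExchangeError("hepatic-vein concentration must be positive")
    w_art, w_pv = weights
    return ((w_art * art + w_pv * pv) / hv - 1.0) * 100.0


def trapezoid_auc(times, values) -> float:
    """Trapezoid-rule area under a time course (value·min)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or len(times) != len(values):
        raise ExchangeError("times and values must be 1-D of equal length")
    if len(times) < 2:
        raise ExchangeError("AUC needs at least two time points")
    if np.any(np.diff(times) <= 0):
        raise ExchangeError("times must be strictly increasing")
    return float(np.trapezoid(values, times))


def _paired_t(diffs: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided paired t on difference arrays; all-zero diffs give p = 1.

    NaN differences drop the pair; fewer than 3 complete pairs gives NaN.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = np.sum(~np.isnan(diffs), axis=axis)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(diffs, axis=axis)
        sd = np.nanstd(diffs, axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    zero = (sd == 0) & (mean == 0)
    exact = (sd == 0) & (mean != 0)
    t = np.where(zero, 0.0, t)
    p = np.where(zero, 1.0, p)
    p = np.where(exact, 0.0, p)
    p = np.where(n < 3, np.nan, p)
    t = np.where(n < 3, np.nan, t)
    return t, p


def test_exchange_at_time(inflow_values, outflow_values) -> tuple[float, float]:
    """Paired t-test of inflow vs outflow across animals at one time point."""
    inflow = np.asarray(inflow_values, dtype=float)
    outflow = np.asarray(outflow_values, dtype=float)
    if inflow.shape != outflow.shape or inflow.ndim != 1:
        raise ExchangeError("paired vectors must be 1-D of equal length")
    if np.sum(~np.isnan(inflow - outflow)) < 3:
        raise ExchangeError("paired t-test needs at least 3 complete pairs")
    t, p = _paired_t(inflow - outflow)
    return float(t), float(p)


test_exchange_at_time.__test__ = False  # statistical test, not a pytest case


def compare_days(delta_d0, delta_d60) -> tuple[float, float]:
    """Paired t-test of per-animal deltas between D0 and D60."""
    return test_exchange_at_time(np.asarray(delta_d0, float), np.asarray(delta_d60, float))


def max_delta(induction_curve, fasting_index: int = 0) -> float:
    """Signed maximum excursion of induction from the fasting value.

    Finds the postprandial time maximizing |induction(t) − induction(0)| and
    returns the signed difference at that time.
    """
    v = np.asarray(induction_curve, dtype=float)
    post = np.delete(v, fasting_index)
    post = post[~np.isnan(post)]
    if post.size == 0 or np.isnan(v[fasting_index]):
        raise ExchangeError("max_delta needs the fasting point and ≥1 postprandial point")
    d = post - v[fasting_index]
    return float(d[np.argmax(np.abs(d))])


# ---------------------------------------------------------------------------
# Cohort-level arrays
# ---------------------------------------------------------------------------

@dataclass
class ExchangeSeries:
    """One metabolite × animal × day induction time course for one organ."""

    metabolite: str
    animal: str
    day: str
    organ: str
    induction_pct: np.ndarray
    time_grid: np.ndarray


@dataclass
class CohortArrays:
    """Dense (vessel, animal, day, time, metabolite) view of a cohort.

    Missing design cells are NaN; the helper functions propagate them as
    recorded gaps rather than silent zeros.
    """

    conc: np.ndarray
    animals: list[str]
    days: list[str]
    times: np.ndarray
    metabolites: list[str]


def cohort_arrays(met_table: MetaboliteTable) -> CohortArrays:
    ann = met_table.annotations
    animals = sorted(ann["animal_id"].unique())
    days = [d for d in DAYS if d in set(ann["day"])]
    times = np.sort(ann["time_min"].unique())
    mets = met_table.metabolite_names
    conc = np.full((3, len(animals), len(days), len(times), len(mets)), np.nan)
    a_ix = {a: i for i, a in enumerate(animals)}
    d_ix = {d: i for i, d in enumerate(days)}
    t_ix = {int(t): i for i, t in enumerate(times)}
    v_ix = {v: i for i, v in enumerate(VESSELS)}
    rows = ann.itertuples()
    for r, row in zip(rows, met_table.values):
        conc[v_ix[r.vessel], a_ix[r.animal_id], d_ix[r.day], t_ix[int(r.time_min)], :] = row
    return CohortArrays(conc=conc, animals=animals, days=days, times=times, metabolites=list(mets))


def _flows(arrays: CohortArrays, organ: str, weights=HEPATIC_WEIGHTS):
    """(inflow, outflow) concentration arrays of shape (a, d, t, m)."""
    art, pv, hv = arrays.conc[0], arrays.conc[1], arrays.conc[2]
    if organ == "intestine":
        return art, pv
    if organ == "liver":
        w_art, w_pv = weights
        return w_art * art + w_pv * pv, hv
    raise ExchangeError(f"unknown organ {organ!r}; expected one of {ORGANS}")


def induction_array(arrays: CohortArrays, organ: str, weights=HEPATIC_WEIGHTS) -> np.ndarray:
    """% induction per (animal, day, time, metabolite); NaN marks gaps."""
    inflow, outflow = _flows(arrays, organ, weights)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (inflow / outflow - 1.0) * 100.0


def exchange_series(met_table: MetaboliteTable, organ: str, weights=HEPATIC_WEIGHTS) -> list[ExchangeSeries]:
    """One induction series per metabolite × animal × day.

    Missing vessel tuples appear as NaN gaps; a series with no complete time
    point at all is omitted with a log entry.
    """
    arrays = cohort_arrays(met_table)
    ind = induction_array(arrays, organ, weights)
    out = []
    for mi, met in enumerate(arrays.metabolites):
        for ai, a in enumerate(arrays.animals):
            for di, d in enumerate(arrays.days):
                curve = ind[ai, di, :, mi]
                if np.all(np.isnan(curve)):
                    logger.info("omitting series %s/%s/%s/%s: no complete vessel tuple",
                                organ, met, a, d)
                    continue
                out.append(ExchangeSeries(met, a, d, organ, curve, arrays.times.astype(float)))
    return out


def per_animal_auc_exchange(
    met_table: MetaboliteTable, organ: str, weights=HEPATIC_WEIGHTS
) -> pd.DataFrame:
    """AUC-based % induction per metabolite × animal × day.

    AUCs are taken of the inflow and outflow concentration curves (hepatic
    composite formed pointwise before integration) and the induction formula
    is applied to the AUC pair.
    """
    arrays = cohort_arrays(met_table)
    inflow, outflow = _flows(arrays, organ, weights)
    t = arrays.times.astype(float)
    auc_in = np.trapezoid(inflow, t, axis=2)  # (a, d, m)
    auc_out = np.trapezoid(outflow, t, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ind = (auc_in / auc_out - 1.0) * 100.0
    rows = []
    for mi, met in enumerate(arrays.metabolites):
        for ai, a in enumerate(arrays.animals):
            for di, d in enumerate(arrays.days):
                rows.append((organ, met, a, d, ind[ai, di, mi],
                             auc_in[ai, di, mi], auc_out[ai, di, mi]))
    return pd.DataFrame(
        rows, columns=["organ", "metabolite", "animal", "day",
                       "auc_induction_pct", "auc_inflow", "auc_outflow"]
    )


def summarize_exchange(
    met_table: MetaboliteTable,
    organ: str,
    alpha: float = 0.05,
    weights=HEPATIC_WEIGHTS,
) -> pd.DataFrame:
    """Full postprandial exchange summary, one row per metabolite × day.

    Columns per time point t: ``mean_t{t}``, ``sem_t{t}``, ``p_t{t}``
    (paired inflow-vs-outflow test, the per-time asterisks). Whole-period
    columns: AUC-based induction and its paired test, the AUC/510
    fasting comparison ("$" flag), the signed max delta, and D0-vs-D60
    paired comparisons of the fasting induction, the AUC exchange and the
    delta ("#" flags).
    """
    arrays = cohort_arrays(met_table)
    inflow, outflow = _flows(arrays, organ, weights)  # (a, d, t, m)
    ind = induction_array(arrays, organ, weights)
    t = arrays.times.astype(float)
    n_a, n_d, n_t, n_m = ind.shape
    span = t[-1] - t[0]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(ind, axis=0)  # (d, t, m)
        n_obs = np.sum(~np.isnan(ind), axis=0)
        sem = np.nanstd(ind, axis=0, ddof=1) / np.sqrt(np.maximum(n_obs, 1))
    _, p_time = _paired_t(inflow - outflow, axis=0)  # (d, t, m)

    auc_in = np.trapezoid(inflow, t, axis=2)  # (a, d, m)
    auc_out = np.trapezoid(outflow, t, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        auc_ind = (auc_in / auc_out - 1.0) * 100.0  # (a, d, m)
    _, p_auc = _paired_t(auc_in - auc_out, axis=0)  # (d, m)

    # time-averaged induction vs fasting induction
    avg_ind = np.trapezoid(ind, t, axis=2) / span  # (a, d, m)
    fasting = ind[:, :, 0, :]  # (a, d, m)
    _, p_fasting = _paired_t(avg_ind - fasting, axis=0)  # (d, m)

    # signed max excursion from fasting, per animal
    deltas = ind[:, :, 1:, :] - ind[:, :, :1, :]  # (a, d, t-1, m)
    with np.errstate(invalid="ignore"):
        arg = np.nanargmax(np.where(np.isnan(deltas), -np.inf, np.abs(deltas)), axis=2)
    delta = np.take_along_axis(deltas, arg[:, :, None, :], axis=2)[:, :, 0, :]  # (a, d, m)

    # D0-vs-D60 comparisons (need both days)
    if n_d == 2:
        _, p_day_fast = _paired_t(fasting[:, 0, :] - fasting[:, 1, :], axis=0)  # (m,)
        _, p_day_auc = _paired_t(auc_ind[:, 0, :] - auc_ind[:, 1, :], axis=0)
        _, p_day_delta = _paired_t(delta[:, 0, :] - delta[:, 1, :], axis=0)
    else:
        p_day_fast = p_day_auc = p_day_delta = np.full(n_m, np.nan)

    rows = []
    for mi, met in enumerate(arrays.metabolites):
        for di, d in enumerate(arrays.days):
            row = {"organ": organ, "metabolite": met, "day": d}
            for ti, tt in enumerate(arrays.times):
                row[f"mean_t{int(tt)}"] = mean[di, ti, mi]
                row[f"sem_t{int(tt)}"] = sem[di, ti, mi]
                row[f"p_t{int(tt)}"] = p_time[di, ti, mi]
                row[f"sig_t{int(tt)}"] = bool(p_time[di, ti, mi] < alpha)
            row["auc_induction_pct"] = float(np.nanmean(auc_ind[:, di, mi]))
            row["auc_p"] = p_auc[di, mi]
            row["sig_auc"] = bool(p_auc[di, mi] < alpha)
            row["fasting_comparison_p"] = p_fasting[di, mi]
            row["sig_fasting"] = bool(p_fasting[di, mi] < alpha)
            row["max_delta"] = float(np.nanmean(delta[:, di, mi]))
            row["fasting_day_p"] = p_day_fast[mi]
            row["auc_day_p"] = p_day_auc[mi]
            row["delta_day_p"] = p_day_delta[mi]
            row["sig_day"] = bool(p_day_auc[mi] < alpha)
            rows.append(row)
    return pd.DataFrame(rows)


def count_differential(
    summaries: pd.DataFrame, mode: str, alpha: float = 0.05
) -> dict[str, int]:
    """Count metabolites whose D0-vs-D60 exchange comparison is significant.

    ``mode='fasting'`` compares the T0 induction between days;
    ``mode='postprandial_auc'`` compares the whole-period AUC exchange.
    Returns counts per organ.
    """
    col = {"fasting": "fasting_day_p", "postprandial_auc": "auc_day_p"}.get(mode)
    if col is None:
        raise ExchangeError(f"unknown mode {mode!r}")
    if set(summaries["day"]) != set(DAYS):
        raise ExchangeError("both D0 and D60 summaries are required")
    per_met = summaries.groupby(["organ", "metabolite"])[col].first()
    counts = {}
    for organ in summaries["organ"].unique():
        p = per_met.loc[organ]
        counts[organ] = int(np.sum(p < alpha))
    return counts
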