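"""Cohort-level statistics over AID markers (value + risk-contribution pairs).

Marker importance (MI) summarizes how much of the network's decision mass a
marker carries: the sum of absolute risk contributions divided by the number
of patients in whom the marker was observed.  For subcohorts, risk
contributions are first centered by the full-cohort per-marker mean so that
the subcohort MI measures deviation from the cohort-typical attribution.

The linearized view of an AID marker is the OLS slope of RC on the
standardized marker value; agreement of these slopes with univariate Cox
log hazard ratios across markers is the package's internal consistency check
between the network's attribution and classical survival modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .cohort import SurvivalOutcome
from .lrp import RelevanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class MarkerImportanceTable:
    """Per-marker MI = sum |RC| / n_present, for a pan-cohort or subcohort scope."""

    table: pd.DataFrame  # columns: mi, n_present, total_abs_rc
    scope: str = "pan"

    def ranked(self) -> pd.DataFrame:
        return self.table.dropna(subset=["mi"]).sort_values("mi", ascending=False)


def marker_importance(rc: RelevanceMatrix | pd.DataFrame, mask: pd.DataFrame,
                      scope_idx=None, scope: str = "pan",
                      center: pd.Series | None = None) -> MarkerImportanceTable:
    """Marker importance over the cohort or a subcohort.

    ``mask`` is True where the marker is missing for the patient.  For a
    subcohort (``scope_idx`` a boolean or positional selector), RCs are first
    centered by the full-cohort per-marker mean (computed over patients with
    the marker present, or supplied via ``center``).  Markers absent in every
    scoped patient get MI = NaN and are excluded from rankings.
    """
    rc_df = rc.rc if isinstance(rc, RelevanceMatrix) else rc
    mask = mask.loc[rc_df.index, rc_df.columns]
    present = ~mask
    if scope_idx is not None:
        centered = rc_df - (center if center is not None else rc_df[present].mean())
        rc_scoped = centered.loc[rc_df.index[np.asarray(scope_idx)]]
        present = present.loc[rc_scoped.index]
    else:
        rc_scoped = rc_df
    abs_rc = rc_scoped.abs().where(present, 0.0)
    n_present = present.sum()
    total = abs_rc.sum()
    mi = total / n_present.replace(0, np.nan)
    return MarkerImportanceTable(
        table=pd.DataFrame({"mi": mi, "n_present": n_present, "total_abs_rc": total}),
        scope=scope,
    )


@dataclass
class SlopeRecord:
    marker: str
    slope: float
    intercept: float
    r: float
    p: float
    stderr: float
    n: int
    log_hr: float | None = None


def rc_slope(values, rcs, marker: str = "", standardize: bool = True) -> SlopeRecord:
    """OLS slope of RC on (standardized) marker value, with Pearson r.

    Pairs with a missing value or RC are dropped; needs >= 3 pairs and
    non-constant values.
    """
    v = np.asarray(values, dtype=float)
    r = np.asarray(rcs, dtype=float)
    keep = ~(np.isnan(v) | np.isnan(r))
    v, r = v[keep], r[keep]
    if len(v) < 3:
        raise ValueError(f"marker {marker!r}: need >= 3 paired points, got {len(v)}")
    if np.std(v) == 0:
        raise ValueError(f"marker {marker!r}: zero variance in values, slope undefined")
    if standardize:
        v = (v - v.mean()) / v.std()
    fit = stats.linregress(v, r)
    return SlopeRecord(marker=marker, slope=float(fit.slope), intercept=float(fit.intercept),
                       r=float(fit.rvalue), p=float(fit.pvalue), stderr=float(fit.stderr), n=len(v))


def cox_univariate(values, outcome: SurvivalOutcome, standardize: bool = True) -> float:
    """Univariate Cox log hazard ratio of one marker (Breslow ties).

    Fitted on patients with the marker present; the marker is standardized so
    log-HRs are comparable to RC slopes on standardized values.  Raises on
    non-convergence or when the fit does not beat the null model.
    """
    v = np.asarray(values, dtype=float)
    keep = ~np.isnan(v)
    if outcome.event[keep].sum() < 2:
        raise ValueError("need >= 2 events among non-missing values")
    v = v[keep]
    if np.std(v) == 0:
        raise ValueError("constant marker, hazard ratio undefined")
    if standardize:
        v = (v - v.mean()) / v.std()
    df = pd.DataFrame({"x": v, "time": outcome.time[keep], "event": outcome.event[keep].astype(int)})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise ValueError(f"univariate Cox fit did not converge: {err}") from err
    if cph.log_likelihood_ < _null_cox_loglik(df):
        raise ValueError("Cox fit worse than its baseline model; discarded")
    return float(cph.params_["x"])


def _null_cox_loglik(df: pd.DataFrame) -> float:
    # Breslow partial log-likelihood of the null (no-covariate) model
    t = df["time"].to_numpy()
    e = df["event"].to_numpy().astype(bool)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = len(t)
    at_risk = n - np.arange(n)
    first = np.ones(n, dtype=bool)
    first[1:] = t[1:] != t[:-1]
    gidx = np.cumsum(first) - 1
    risk_at_group = at_risk[first][gidx]
    return float(-(np.log(risk_at_group)[e]).sum())


def slope_table(values: pd.DataFrame, rc: RelevanceMatrix,
                outcome: SurvivalOutcome | None = None) -> pd.DataFrame:
    """RC slopes (and optionally univariate Cox log-HRs) for every marker."""
    rows = []
    for m in rc.markers:
        if m not in values.columns:
            continue
        v = values[m].to_numpy(dtype=float)
        r = rc.rc[m].to_numpy(dtype=float)
        r = np.where(np.isnan(v), np.nan, r)
        try:
            rec = rc_slope(v, r, marker=m)
        except ValueError as err:
            logger.info("slope skipped: %s", err)
            continue
        if outcome is not None:
            try:
                rec.log_hr = cox_univariate(v, outcome)
            except ValueError as err:
                logger.info("univariate Cox skipped for %s: %s", m, err)
        rows.append(rec.__dict__)
    return pd.DataFrame(rows).set_index("marker") if rows else pd.DataFrame()


def slope_hr_agreement(slopes, log_hrs) -> tuple[float, float]:
    """Pearson correlation across markers between RC slopes and Cox log-HRs."""
    s = np.asarray(slopes, dtype=float)
    h = np.asarray(log_hrs, dtype=float)
    keep = ~(np.isnan(s) | np.isnan(h))
    if keep.sum() < 3:
        raise ValueError("need >= 3 markers with both a slope and a log-HR")
    r, p = stats.pearsonr(s[keep], h[keep])
    return float(r), float(p)


def cumulative_importance(mi: MarkerImportanceTable) -> pd.DataFrame:
    """Cumulative fraction of total absolute relevance carried by the top-k markers.

    Markers are ranked by their total absolute relevance mass (sum |RC|, not
    the per-patient-normalized MI); the curve is nondecreasing and ends at 1.
    """
    t = mi.table.dropna(subset=["mi"]).sort_values("total_abs_rc", ascending=False)
    total = t["total_abs_rc"].sum()
    if total == 0:
        frac = np.ones(len(t))
    else:
        frac = t["total_abs_rc"].cumsum().to_numpy() / total
    return pd.DataFrame({"marker": t.index, "k": np.arange(1, len(t) + 1),
                         "cum_fraction": frac}).set_index("k")


def markers_for_fraction(curve: pd.DataFrame, threshold: float = 0.9) -> int:
    """Minimal number of top markers whose relevance mass reaches ``threshold``."""
    hit = curve.index[curve["cum_fraction"] >= threshold - 1e-12]
    return int(hit[0]) if len(hit) else int(curve.index[-1])
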