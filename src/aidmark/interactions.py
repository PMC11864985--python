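"""Decile-conditioned mixed-effects screen for pairwise marker interactions.

The network may assign a different risk contribution (RC) to the same value of
a 'primary' marker depending on the patient's other markers.  The screen makes
this measurable: for each ordered pair (primary, secondary), patients are
conditioned on the secondary marker being high (top 10%) or low (bottom 10%),
and the linear relationship RC_primary ~ value_primary is compared between the
two condition classes with a likelihood-ratio test of

    full:     RC = b0 + b1*x + b2*x*1[high] + u_class   (class-specific slope)
    baseline: RC = b0 + b1*x + u_class                  (common slope)

where u_class is a random intercept over the two condition classes.  Holm's
step-down correction controls the family-wise error over all tested pairs.
A proportional-hazards validation refits the class-specific effect of the
primary marker against survival directly (class-stratified Cox model) and
compares the sign of the effect difference with the RC-based slope difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .cohort import EXCLUDED_MODALITIES, MarkerSpec, SurvivalOutcome
from .lrp import RelevanceMatrix

logger = logging.getLogger(__name__)

MIN_PAIR_N = 100          # pairs observed in fewer samples are discarded
MIN_CLASS_FRACTION = 0.10  # each condition class must hold >= 10% of samples


class DiscardError(ValueError):
    """A pair cannot be tested; carries the reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class ConditionSplit:
    """High/low condition classes over the cohort (boolean masks)."""

    high: np.ndarray
    low: np.ndarray
    secondary: str = ""

    @property
    def either(self) -> np.ndarray:
        return self.high | self.low


def condition_split(values, spec: MarkerSpec, secondary: str = "") -> ConditionSplit:
    """Split patients on a secondary marker being high or low.

    Continuous markers use the empirical top/bottom decile (boundary ties fall
    on the extreme side).  Ordinal and binary markers grow extreme levels
    until each side holds at least 10% of the non-missing samples; if the two
    sides would overlap, the pair is discarded.
    """
    v = np.asarray(values, dtype=float)
    obs = ~np.isnan(v)
    if obs.sum() == 0:
        raise DiscardError("secondary entirely missing")
    vo = v[obs]
    if np.nanmin(vo) == np.nanmax(vo):
        raise DiscardError("secondary is constant")
    if spec.kind == "continuous":
        q10, q90 = np.quantile(vo, [MIN_CLASS_FRACTION, 1 - MIN_CLASS_FRACTION])
        if q10 == q90:
            raise DiscardError("degenerate deciles")
        high = obs & (v >= q90)
        low = obs & (v <= q10)
    else:
        levels = np.sort(np.unique(vo))
        n = obs.sum()
        hi_levels, lo_levels = [], []
        i = len(levels) - 1
        while i >= 0:
            hi_levels.append(levels[i])
            if (obs & np.isin(v, hi_levels)).sum() >= MIN_CLASS_FRACTION * n:
                break
            i -= 1
        j = 0
        while j < len(levels):
            lo_levels.append(levels[j])
            if (obs & np.isin(v, lo_levels)).sum() >= MIN_CLASS_FRACTION * n:
                break
            j += 1
        if set(hi_levels) & set(lo_levels):
            raise DiscardError("high and low classes overlap")
        high = obs & np.isin(v, hi_levels)
        low = obs & np.isin(v, lo_levels)
    if high.sum() == 0 or low.sum() == 0:
        raise DiscardError("empty condition class")
    return ConditionSplit(high=high, low=low, secondary=secondary)


@dataclass
class InteractionRecord:
    primary: str
    secondary: str
    n: int = 0
    delta_slope: float = np.nan
    slope_low: float = np.nan
    p_lrt: float = np.nan
    p_holm: float = np.nan
    cox_delta: float = np.nan
    status: str = "tested"
    reason: str = ""

    def discarded(self) -> bool:
        return self.status != "tested"


def _loglik_pair(endog, exog_base, exog_full, groups) -> tuple[float, float, float]:
    """ML log-likelihoods of the baseline and full mixed models, plus the
    full-model interaction coefficient.

    A two-level random intercept frequently sits on the variance boundary;
    when the mixed fit degenerates (non-finite likelihood) both models are
    refitted by OLS, which is the mixed model at that boundary.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        fit_base = sm.MixedLM(endog, exog_base, groups=groups).fit(
            reml=False, method="lbfgs", maxiter=200)
        fit_full = sm.MixedLM(endog, exog_full, groups=groups).fit(
            reml=False, method="lbfgs", maxiter=200)
        if np.isfinite(fit_base.llf) and np.isfinite(fit_full.llf):
            return float(fit_base.llf), float(fit_full.llf), np.asarray(fit_full.fe_params)
        ols_base = sm.OLS(endog, exog_base).fit()
        ols_full = sm.OLS(endog, exog_full).fit()
        return float(ols_base.llf), float(ols_full.llf), np.asarray(ols_full.params)


def test_pair(primary_values, rcs, split: ConditionSplit, primary: str = "",
              min_n: int = MIN_PAIR_N) -> InteractionRecord:
    """Likelihood-ratio test for a class-specific RC slope of the primary marker."""
    rec = InteractionRecord(primary=primary, secondary=split.secondary)
    v = np.asarray(primary_values, dtype=float)
    r = np.asarray(rcs, dtype=float)
    rows = split.either & ~np.isnan(v) & ~np.isnan(r)
    rec.n = int(rows.sum())
    if rec.n < min_n:
        rec.status, rec.reason = "discarded", "min_n"
        return rec
    x = v[rows]
    y = r[rows]
    is_high = split.high[rows].astype(float)
    if np.std(x) == 0:
        rec.status, rec.reason = "discarded", "constant primary"
        return rec
    exog_base = np.column_stack([np.ones_like(x), x])
    exog_full = np.column_stack([np.ones_like(x), x, x * is_high])
    groups = np.where(is_high > 0, "high", "low")
    try:
        llf_base, llf_full, fe = _loglik_pair(y, exog_base, exog_full, groups)
    except (np.linalg.LinAlgError, ValueError) as err:
        rec.status, rec.reason = "discarded", f"singular fit: {err}"
        return rec
    lr = max(2.0 * (llf_full - llf_base), 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    if not np.isfinite(p) or not np.all(np.isfinite(fe)):
        rec.status, rec.reason = "discarded", "singular fit"
        return rec
    rec.p_lrt = p
    rec.slope_low = float(fe[1])
    rec.delta_slope = float(fe[2])  # slope(high) - slope(low)
    return rec


def screen_all(values: pd.DataFrame, rc: RelevanceMatrix, schema: dict[str, MarkerSpec],
               excluded_modalities=EXCLUDED_MODALITIES, pairs=None,
               min_n: int = MIN_PAIR_N) -> list[InteractionRecord]:
    """Test all eligible ordered (primary, secondary) pairs; Holm-adjust p-values.

    Markers of excluded modalities (medications, diagnosis/procedure codes,
    cancer types) never enter the screen.  The Holm family is the set of pairs
    actually tested (discarded pairs yield no p-value).
    """
    eligible = [m for m in values.columns
                if m in rc.markers and schema[m].modality not in excluded_modalities]
    if pairs is None:
        pairs = [(p, s) for p in eligible for s in eligible if p != s]
    else:
        bad = [(p, s) for p, s in pairs if p not in eligible or s not in eligible]
        if bad:
            raise ValueError(f"pairs include ineligible markers: {bad}")

    records: list[InteractionRecord] = []
    splits: dict[str, ConditionSplit | DiscardError] = {}
    for p, s in pairs:
        if s not in splits:
            try:
                splits[s] = condition_split(values[s].to_numpy(), schema[s], secondary=s)
            except DiscardError as err:
                splits[s] = err
        sp = splits[s]
        if isinstance(sp, DiscardError):
            records.append(InteractionRecord(primary=p, secondary=s, status="discarded",
                                             reason=sp.reason))
            continue
        prim = values[p].to_numpy(dtype=float)
        rcs = np.where(np.isnan(prim), np.nan, rc.rc[p].to_numpy(dtype=float))
        records.append(test_pair(prim, rcs, sp, primary=p, min_n=min_n))

    tested = [r for r in records if not r.discarded()]
    if tested:
        adj = multipletests([r.p_lrt for r in tested], method="holm")[1]
        for r, a in zip(tested, adj):
            r.p_holm = float(a)
    return records


def records_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def cox_validate(record: InteractionRecord, primary_values, outcome: SurvivalOutcome,
                 split: ConditionSplit) -> InteractionRecord:
    """Survival-side check of a tested pair.

    Fits a Cox model on the high/low patients with a class-stratified baseline
    hazard (the proportional-hazards analogue of a per-class intercept) and a
    class-specific effect of the primary marker.  ``cox_delta`` is the
    difference in log-hazard effect (high minus low); a fit whose partial
    log-likelihood falls below the common-slope baseline is discarded.
    """
    if record.discarded():
        return record
    v = np.asarray(primary_values, dtype=float)
    rows = split.either & ~np.isnan(v)
    df = pd.DataFrame({
        "x": v[rows],
        "x_high": v[rows] * split.high[rows],
        "cls": np.where(split.high[rows], "high", "low"),
        "time": outcome.time[rows],
        "event": outcome.event[rows].astype(int),
    })
    if df["event"].sum() < 2 or df["x"].std() == 0:
        record.reason = "cox: degenerate data"
        return record
    full, base = CoxPHFitter(), CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full.fit(df, duration_col="time", event_col="event", strata=["cls"])
            base.fit(df[["x", "cls", "time", "event"]], duration_col="time",
                     event_col="event", strata=["cls"])
    except (ConvergenceError, ValueError) as err:
        record.reason = f"cox: {err}"
        return record
    if full.log_likelihood_ < base.log_likelihood_:
        record.reason = "cox: fit below baseline"
        return record
    record.cox_delta = float(full.params_["x_high"])
    return record


@dataclass
class ScreenSummary:
    n_tested: int
    n_discarded: int
    n_significant: int
    alpha: float = 0.05
    significant: list[tuple[str, str]] = field(default_factory=list)


def summarize(records: list[InteractionRecord], alpha: float = 0.05) -> ScreenSummary:
    tested = [r for r in records if not r.discarded()]
    sig = [r for r in tested if r.p_holm < alpha]
    return ScreenSummary(
        n_tested=len(tested),
        n_discarded=len(records) - len(tested),
        n_significant=len(sig),
        alpha=alpha,
        significant=[(r.primary, r.secondary) for r in sig],
    )
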