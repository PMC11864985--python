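"""Simplicity baselines for the risk network and paired model comparisons.

The parsimonious baseline mirrors a deployable bedside model: an elastic-net
penalized Cox path (mixing 0.9 toward the lasso) selects the ten most
informative variables, then an unpenalized linear Cox model is refitted on
the active set.  Single clinical scores (ordinal stage-like variables) can be
benchmarked directly as bare risk predictors via their concordance on the
same test splits.  Contenders are compared with a two-sided Wilcoxon
signed-rank test over paired per-split concordances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .cohort import SurvivalOutcome
from .coxnn import concordance

logger = logging.getLogger(__name__)


@dataclass
class ParsimoniousCox:
    """Selected markers and the refitted linear Cox model."""

    selected: list[str]
    fitter: CoxPHFitter
    penalty: float
    target_k: int

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        lp = X[self.selected].fillna(0.0) @ self.fitter.params_.reindex(self.selected)
        return lp.to_numpy()


def _active_set(X: np.ndarray, y, alpha: float, l1_ratio: float) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=[alpha], fit_baseline_model=False)
        model.fit(X, y)
    return np.flatnonzero(np.abs(model.coef_[:, 0]) > 1e-12)


def select_parsimonious(X: pd.DataFrame, outcome: SurvivalOutcome, k: int = 10,
                        l1_ratio: float = 0.9, max_iter: int = 50) -> ParsimoniousCox:
    """Penalized-Cox variable selection targeting an active set of size k.

    The penalty is bisected until exactly k coefficients are nonzero; if the
    path jumps over k, the nearest achievable active set of size <= k is used
    (logged).  With fewer than k candidate markers, all are retained.
    Missing values enter the selector as 0 (the mean of standardized markers).
    """
    markers = list(X.columns)
    Xf = X.fillna(0.0).to_numpy(dtype=float)
    y = Surv.from_arrays(event=outcome.event, time=outcome.time)
    if len(markers) <= k:
        logger.warning("only %d candidate markers for target %d; retaining all", len(markers), k)
        sel, alpha = np.arange(len(markers)), 0.0
    else:
        lo, hi = 1e-6, 10.0
        while len(_active_set(Xf, y, hi, l1_ratio)) > 0:
            hi *= 4
            if hi > 1e6:  # pragma: no cover
                break
        best_alpha, best_sel = hi, np.array([], dtype=int)
        for _ in range(max_iter):
            mid = np.sqrt(lo * hi)
            active = _active_set(Xf, y, mid, l1_ratio)
            if len(active) == k:
                best_alpha, best_sel = mid, active
                break
            if len(active) > k:
                lo = mid
            else:
                hi = mid
            if len(active) <= k and len(active) > len(best_sel):
                best_alpha, best_sel = mid, active
        sel, alpha = best_sel, best_alpha
        if len(sel) != k:
            logger.warning("exact active set of %d unattainable; using %d markers", k, len(sel))

    selected = [markers[i] for i in sel]
    df = X[selected].fillna(0.0).copy()
    df["time"], df["event"] = outcome.time, outcome.event.astype(int)
    fitter = CoxPHFitter(penalizer=1e-6)
    fitter.fit(df, duration_col="time", event_col="event")
    return ParsimoniousCox(selected=selected, fitter=fitter, penalty=float(alpha), target_k=k)


def score_cindex(score, outcome: SurvivalOutcome, splits: list[np.ndarray]) -> list[float]:
    """Concordance of a bare clinical score on each test split.

    Restricted to patients with the score present; a degenerate (constant)
    score scores 0.5 by the tie convention.
    """
    score = np.asarray(score, dtype=float)
    out = []
    for idx in splits:
        idx = np.asarray(idx)
        present = ~np.isnan(score[idx])
        sub = idx[present]
        if len(sub) == 0 or np.nanstd(score[sub]) == 0:
            out.append(0.5)
            continue
        try:
            out.append(concordance(score[sub], outcome.subset(sub)))
        except ValueError:
            out.append(0.5)
    return out


def compare_models(cindex_a, cindex_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired concordance lists.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 pairs, a continuity-corrected normal approximation above.  All
    differences zero gives (0, 1) by convention.
    """
    a = np.asarray(cindex_a, dtype=float)
    b = np.asarray(cindex_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    if len(a) < 5:
        raise ValueError("need >= 5 paired values")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0
    mode = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", mode=mode, correction=(mode == "approx"))
    return float(res.statistic), float(res.pvalue)


@dataclass
class BenchmarkResult:
    """Per-split concordances of two contenders plus the paired test."""

    table: pd.DataFrame  # columns: split, model, cindex
    statistic: float
    pvalue: float

    def mean_cindex(self, model: str) -> float:
        return float(self.table.loc[self.table["model"] == model, "cindex"].mean())


def benchmark_pair(cindex_a: list[float], cindex_b: list[float],
                   name_a: str = "xai", name_b: str = "baseline") -> BenchmarkResult:
    stat, p = compare_models(cindex_a, cindex_b)
    rows = [{"split": i, "model": name_a, "cindex": c} for i, c in enumerate(cindex_a)]
    rows += [{"split": i, "model": name_b, "cindex": c} for i, c in enumerate(cindex_b)]
    return BenchmarkResult(table=pd.DataFrame(rows), statistic=stat, pvalue=p)
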