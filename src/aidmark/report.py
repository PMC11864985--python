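"""Survival reporting: Kaplan-Meier curves, risk groups, explainable KM
timelines and the per-patient clinician's guide.

All report objects are data first (tables that tests can assert on); the
matplotlib helpers render those tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import CohortTable, SurvivalOutcome
from .lrp import RelevanceMatrix, RiskGroups, stratify_risk


@dataclass
class KMCurve:
    """Product-limit survival estimate: S(0)=1, nonincreasing, piecewise constant."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        """First time with S(t) <= 0.5; inf if never reached (beyond follow-up)."""
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else np.inf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk, "label": self.label})


def km_estimate(outcome: SurvivalOutcome, label: str = "") -> KMCurve:
    if len(outcome.time) < 1:
        raise ValueError("empty outcome")
    kmf = KaplanMeierFitter()
    kmf.fit(outcome.time, outcome.event)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float)
    return KMCurve(times=times, survival=surv, at_risk=at_risk, label=label)


def risk_group_km(risks, outcome: SurvivalOutcome, k: int = 5) -> tuple[list[KMCurve], RiskGroups]:
    """One KM curve per predicted-risk quantile group (group 1 = lowest risk)."""
    groups = stratify_risk(risks, k=k)
    curves = []
    for g in range(1, k + 1):
        sel = groups.group == g
        sub = SurvivalOutcome.__new__(SurvivalOutcome)  # allow all-censored groups
        sub.time = outcome.time[sel]
        sub.event = outcome.event[sel]
        sub.endpoint = outcome.endpoint
        sub.index = None
        curves.append(km_estimate(sub, label=f"risk group {g}"))
    return curves, groups


def explainable_km(
    rc: RelevanceMatrix,
    outcome: SurvivalOutcome,
    markers: list[str] | None = None,
    mask: pd.DataFrame | None = None,
    min_patients: int = 40,
    measurement_age: pd.DataFrame | None = None,
    max_measurement_age: float = 730.0,
    bandwidth_fraction: float = 0.10,
) -> pd.DataFrame:
    """Marker-importance timelines along deceased patients ordered by survival.

    Only deceased patients enter.  They are ordered by observed survival time
    (the pseudo-timeline); each marker's local importance is a Gaussian-kernel
    weighted moving average of |RC| over this ordering (bandwidth = 10% of the
    deceased count), then min-max scaled to [0, 1] (a constant profile maps to
    0 by convention).  Markers measured in fewer than ``min_patients``
    deceased patients, or outside the measurement-recency window, are dropped.
    Returns a long DataFrame (marker, rank, time, mi_scaled) plus the pooled
    KM curve rows (marker == "__km__", mi_scaled = S(t)).
    """
    dead = np.asarray(outcome.event, dtype=bool)
    if not dead.any():
        raise ValueError("no deceased patients")
    markers = markers if markers is not None else rc.markers
    order = np.argsort(outcome.time[dead], kind="stable")
    dead_pos = np.flatnonzero(dead)[order]
    times = outcome.time[dead_pos]
    n = len(dead_pos)
    bw = max(bandwidth_fraction * n, 1.0)
    ranks = np.arange(n)
    weights = np.exp(-0.5 * ((ranks[:, None] - ranks[None, :]) / bw) ** 2)

    frames = []
    for m in markers:
        vals = np.abs(rc.rc[m].to_numpy(dtype=float)[dead_pos])
        present = np.ones(n, dtype=bool)
        if mask is not None:
            present &= ~mask[m].to_numpy()[dead_pos]
        if measurement_age is not None:
            present &= measurement_age[m].to_numpy(dtype=float)[dead_pos] <= max_measurement_age
        if present.sum() < min_patients:
            continue
        w = weights * present[None, :]
        denom = w.sum(axis=1)
        local = np.divide((w * vals[None, :]).sum(axis=1), denom,
                          out=np.zeros(n), where=denom > 0)
        span = local.max() - local.min()
        if span <= 1e-12 * max(1.0, np.abs(local).max()):
            scaled = np.zeros(n)  # constant profile maps to 0 by convention
        else:
            scaled = (local - local.min()) / span
        frames.append(pd.DataFrame({"marker": m, "rank": ranks, "time": times,
                                    "mi_scaled": scaled}))

    km = km_estimate(outcome.subset(dead_pos), label="deceased")
    frames.append(pd.DataFrame({"marker": "__km__",
                                "rank": np.arange(len(km.times)),
                                "time": km.times, "mi_scaled": km.survival}))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["marker", "rank", "time", "mi_scaled"])


@dataclass
class ClinicianGuide:
    """Per-patient marker profile: values with their risk contributions.

    ``profile`` lists the patient's present markers sorted by RC (most
    adverse first); ``median_survival_similar`` is the KM median overall
    survival of the ``n_similar`` patients with the closest predicted risk.
    """

    patient: object
    risk: float
    profile: pd.DataFrame
    bias_absorbed: float
    median_survival_similar: float
    n_similar: int

    def to_frame(self) -> pd.DataFrame:
        return self.profile.assign(patient=self.patient, risk=self.risk)


def clinician_guide(patient, cohort: CohortTable, rc: RelevanceMatrix, risks,
                    outcome: SurvivalOutcome, n_similar: int = 100) -> ClinicianGuide:
    """Build the single-patient report used at the bedside.

    The similar-risk reference set is the ``n_similar`` nearest neighbours in
    predicted risk (absolute difference, ties broken by patient order,
    always containing the patient); in cohorts smaller than ``n_similar`` all
    patients are used.
    """
    risks = np.asarray(risks, dtype=float)
    pos = rc.rc.index.get_loc(patient)
    values = cohort.values.loc[patient]
    rc_row = rc.rc.loc[patient]
    present = ~values.isna()
    profile = pd.DataFrame({
        "value": values[present],
        "rc": rc_row[present],
    }).sort_values("rc", ascending=False, kind="stable")

    n = len(risks)
    take = min(n_similar, n)
    order = np.argsort(np.abs(risks - risks[pos]), kind="stable")[:take]
    med = km_estimate(outcome.subset(order)).median
    return ClinicianGuide(
        patient=patient,
        risk=float(risks[pos]),
        profile=profile,
        bias_absorbed=float(rc.bias_absorbed.loc[patient]),
        median_survival_similar=med,
        n_similar=take,
    )


# ---------------------------------------------------------------------------
# plotting (thin wrappers over the data tables)


def plot_km_curves(curves: list[KMCurve], path=None, title: str = ""):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        ax.step(c.times, c.survival, where="post", label=c.label or None)
    ax.set_xlabel("time")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    if any(c.label for c in curves):
        ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_clinician_guide(guide: ClinicianGuide, path=None, top: int = 15):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prof = guide.profile
    show = pd.concat([prof.head(top // 2 + top % 2), prof.tail(top // 2)]).drop_duplicates()
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(show) + 1.5))
    colors = ["firebrick" if v > 0 else "steelblue" for v in show["rc"]]
    ax.barh(np.arange(len(show))[::-1], show["rc"], color=colors)
    ax.set_yticks(np.arange(len(show))[::-1])
    ax.set_yticklabels([f"{m} = {v:.2g}" for m, v in zip(show.index, show["value"])], fontsize=8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("risk contribution")
    med = guide.median_survival_similar
    med_txt = f"{med:.0f}" if np.isfinite(med) else ">max follow-up"
    ax.set_title(f"risk {guide.risk:.2f}; median survival of {guide.n_similar} "
                 f"similar-risk patients: {med_txt}", fontsize=9)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
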