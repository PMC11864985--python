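"""Synthetic multimodal survival cohorts with known ground-truth hazard.

The generator emulates a pan-cancer real-world cohort at reduced scale:
mixed marker kinds across modalities (continuous labs, ordinal clinical
scores, binary indicators), cancer-entity labels that shift marker means,
right-censored outcomes with a configurable censoring fraction (default 45%,
the order of magnitude seen in large treatment-outcome registries), and
missing-at-random gaps.  Event times follow a Weibull-baseline proportional
hazards model

    h(t | x) = h0(t) * exp(beta' x + sum_ij gamma_ij x_i x_j)

so that every downstream stage (training, attribution, interaction screening)
can be validated against a known linear predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, MarkerSpec, SurvivalOutcome

#: ordinal markers use this many levels (0 .. N_ORDINAL_LEVELS-1), the range
#: of common clinical scores such as ECOG performance status (0-4).
N_ORDINAL_LEVELS = 5


@dataclass
class GeneratorConfig:
    n_patients: int = 2000
    n_continuous: int = 12
    n_ordinal: int = 4
    n_binary: int = 4
    n_entities: int = 4
    beta: np.ndarray | None = None  # default: evenly spaced in [-0.8, 0.8]
    interactions: list[tuple[str, str, float]] = field(default_factory=list)
    baseline_shape: float = 1.3
    baseline_scale: float = 365.0  # days
    censor_rate: float = 0.45
    missing_rate: float | dict = 0.2
    missing_mode: str = "mcar"  # or "mar" (probability rises with value)
    endpoint: str = "OS"
    entity_shift_sd: float = 0.3
    seed: int = 0

    @property
    def n_markers(self) -> int:
        return self.n_continuous + self.n_ordinal + self.n_binary

    def marker_names(self) -> list[str]:
        return (
            [f"lab_{i}" for i in range(self.n_continuous)]
            + [f"score_{i}" for i in range(self.n_ordinal)]
            + [f"flag_{i}" for i in range(self.n_binary)]
        )

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_markers <= 0:
            raise ValueError("empty cohort or marker set requested")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        rates = self.missing_rate.values() if isinstance(self.missing_rate, dict) else [self.missing_rate]
        if any(not 0 <= r < 1 for r in rates):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_entities <= 0:
            raise ValueError("need at least one entity")
        names = set(self.marker_names())
        for a, b, _ in self.interactions:
            if a == b or a not in names or b not in names:
                raise ValueError(f"interaction ({a}, {b}) must name two distinct existing markers")
        if self.endpoint not in ("OS", "TTNT"):
            raise ValueError("endpoint must be OS or TTNT")


@dataclass
class TruthRecord:
    """Generating truth: coefficients and each patient's linear predictor."""

    beta: pd.Series
    interactions: list[tuple[str, str, float]]
    linear_predictor: pd.Series
    pre_missing: pd.DataFrame  # marker values before missingness was applied

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "interactions": [[a, b, float(g)] for a, b, g in self.interactions],
            "linear_predictor": self.linear_predictor.tolist(),
        }


def _default_beta(names: list[str]) -> pd.Series:
    m = len(names)
    return pd.Series(np.linspace(-0.8, 0.8, m), index=names)


def _draw_markers(config: GeneratorConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.Series]:
    n = config.n_patients
    entity = pd.Series(
        rng.integers(0, config.n_entities, size=n), name="entity"
    ).map(lambda i: f"entity_{i}")
    cols = {}
    names = config.marker_names()
    # entity-specific mean shifts so entity-balanced CV splitting is exercised
    shifts = rng.normal(0.0, config.entity_shift_sd, size=(config.n_entities, config.n_continuous))
    ent_idx = entity.str.removeprefix("entity_").astype(int).to_numpy()
    for j in range(config.n_continuous):
        z = rng.normal(size=n) + shifts[ent_idx, j]
        z = (z - z.mean()) / z.std()  # marginally ~(0, 1) despite entity shifts
        cols[names[j]] = z
    # ordinal scores: binned latent normal, levels 0..4
    edges = [-1.0, -0.3, 0.3, 1.0]
    for j in range(config.n_ordinal):
        cols[names[config.n_continuous + j]] = np.digitize(rng.normal(size=n), edges).astype(float)
    for j in range(config.n_binary):
        cols[names[config.n_continuous + config.n_ordinal + j]] = rng.binomial(1, 0.3, size=n).astype(float)
    return pd.DataFrame(cols, index=pd.RangeIndex(n, name="patient_id")), entity


def _linear_predictor(values: pd.DataFrame, beta: pd.Series, interactions) -> np.ndarray:
    eta = values.to_numpy() @ beta.reindex(values.columns).to_numpy()
    for a, b, g in interactions:
        eta = eta + g * values[a].to_numpy() * values[b].to_numpy()
    return eta


def _tune_censoring(event_times: np.ndarray, u_censor: np.ndarray, target: float) -> np.ndarray:
    """Exponential censoring times with rate bisected to hit the target fraction."""
    if target == 0:
        return np.full_like(event_times, np.inf)

    def frac_censored(log_rate: float) -> float:
        c = -np.log(u_censor) / np.exp(log_rate)
        return float((c < event_times).mean())

    lo, hi = np.log(1e-8), np.log(1e4)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac_censored(mid) < target:
            lo = mid
        else:
            hi = mid
    return -np.log(u_censor) / np.exp(0.5 * (lo + hi))


def _apply_missingness(values: pd.DataFrame, schema, config: GeneratorConfig, rng) -> pd.DataFrame:
    out = values.copy()
    for name in values.columns:
        rate = (
            config.missing_rate.get(name, 0.0)
            if isinstance(config.missing_rate, dict)
            else config.missing_rate
        )
        if rate <= 0:
            continue
        x = values[name].to_numpy()
        if config.missing_mode == "mar":
            # probability rises with the (standardized) value; mean kept at `rate`
            z = (x - x.mean()) / (x.std() + 1e-12)
            p = 1.0 / (1.0 + np.exp(-(z - 0.0)))
            p = p * rate / p.mean()
            p = np.clip(p, 0.0, 0.95)
        else:
            p = np.full(len(x), rate)
        mask = rng.random(len(x)) < p
        out.loc[mask, name] = np.nan
    return out


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTable, SurvivalOutcome, TruthRecord]:
    """Draw a cohort, its survival outcome and the generating truth.

    Event times are sampled from the Weibull-baseline proportional-hazards
    model by inverse transform, censoring times are independent exponentials
    with the rate tuned by bisection so the realized censored fraction matches
    ``config.censor_rate``, and missingness is applied only after outcomes are
    generated.  Identical seeds yield identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    values, entity = _draw_markers(config, rng)

    names = config.marker_names()
    beta = (
        pd.Series(np.asarray(config.beta, dtype=float), index=names)
        if config.beta is not None
        else _default_beta(names)
    )
    eta = _linear_predictor(values, beta, config.interactions)

    # T = scale * (-log U / exp(eta))^(1/shape); TTNT runs on a shorter clock
    scale = config.baseline_scale * (0.5 if config.endpoint == "TTNT" else 1.0)
    u = rng.uniform(size=config.n_patients)
    event_times = scale * (-np.log(u) / np.exp(eta)) ** (1.0 / config.baseline_shape)

    u_censor = rng.uniform(size=config.n_patients)
    censor_times = _tune_censoring(event_times, u_censor, config.censor_rate)
    time = np.minimum(event_times, censor_times)
    event = event_times <= censor_times
    if not event.any():
        raise ValueError("generated cohort has no events; lower censor_rate")

    schema: dict[str, MarkerSpec] = {}
    for i, name in enumerate(names):
        if i < config.n_continuous:
            schema[name] = MarkerSpec("continuous", "lab")
        elif i < config.n_continuous + config.n_ordinal:
            schema[name] = MarkerSpec("ordinal", "clinical_score", n_levels=N_ORDINAL_LEVELS)
        else:
            # half the binary block is an excluded modality (comorbidity codes)
            mod = "biomarker" if (i - config.n_continuous - config.n_ordinal) % 2 == 0 else "icd"
            schema[name] = MarkerSpec("binary", mod)

    observed = _apply_missingness(values, schema, config, rng)
    age = pd.DataFrame(
        rng.integers(0, 1095, size=values.shape), index=values.index, columns=values.columns
    )

    cohort = CohortTable(values=observed, schema=schema, entity=entity, measurement_age=age)
    outcome = SurvivalOutcome(time, event, config.endpoint, index=values.index)
    truth = TruthRecord(
        beta=beta,
        interactions=list(config.interactions),
        linear_predictor=pd.Series(eta, index=values.index),
        pre_missing=values,
    )
    return cohort, outcome, truth


def true_attribution(cohort: CohortTable, truth: TruthRecord, noise_sd: float = 0.0,
                     seed: int = 0) -> pd.DataFrame:
    """Ground-truth per-marker risk contributions, optionally with noise.

    The additive decomposition of the true log-hazard assigns beta_j * x_j to
    marker j plus half of every planted product term it participates in (the
    symmetric split between the two partners), using pre-missingness values;
    markers missing in the observed table contribute exactly 0.  Gaussian
    noise of sd ``noise_sd`` emulates attribution scatter.  This is the
    independent oracle against which LRP-derived contributions are judged.
    """
    rng = np.random.default_rng(seed)
    vals = truth.pre_missing
    rc = vals * truth.beta.reindex(vals.columns)
    for a, b, g in truth.interactions:
        half = 0.5 * g * vals[a] * vals[b]
        rc[a] = rc[a] + half
        rc[b] = rc[b] + half
    if noise_sd > 0:
        rc = rc + rng.normal(0.0, noise_sd, size=rc.shape)
    return rc.where(~cohort.values.isna(), 0.0)


def true_risk(cohort: CohortTable, truth: TruthRecord) -> np.ndarray:
    """Ground-truth log-hazard score beta'x + sum gamma_ij x_i x_j (pre-missingness values)."""
    if list(truth.pre_missing.columns) != cohort.markers or len(truth.pre_missing) != cohort.n_patients:
        raise ValueError("truth record does not match cohort dimensions")
    return _linear_predictor(truth.pre_missing, truth.beta, truth.interactions)
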