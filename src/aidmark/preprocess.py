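"""Preprocessing: outlier removal, standardization, encodings, feature expansion.

Continuous markers are cleaned with a single-pass 3-standard-deviation outlier
rule (flagged values become missing, the patient stays in the cohort) and then
standardized to zero mean and unit variance over the non-missing entries.
Ordinal scores pass through as integer levels, binary indicators as {0,1}.

To keep missingness explainable, every marker that has at least one missing
value is *feature expanded*: its value x becomes the tuple (x, 1-x), and a
missing entry becomes (0, 0) -- distinguishable from any observed value, for
which the two slots always sum to one.  Markers without missing values keep a
single column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, MarkerSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StandardizationParams:
    mean: float
    sd: float
    lo: float  # raw-value outlier cutoffs from the first pass
    hi: float
    degenerate: bool = False  # sd was 0; divided by 1


def clean_continuous(values: np.ndarray) -> tuple[np.ndarray, StandardizationParams]:
    """Single-pass 3-sd outlier removal then standardization of one marker.

    Entries more than three standard deviations from the mean (both computed
    over the non-missing entries of the raw vector, in one pass) are set to
    missing; the survivors are standardized with the post-removal mean and sd.
    Returns the cleaned standardized vector and the parameters needed to apply
    the identical transform to new data.
    """
    x = np.asarray(values, dtype=float).copy()
    obs = ~np.isnan(x)
    if obs.sum() == 0:
        return x, StandardizationParams(0.0, 1.0, -np.inf, np.inf, degenerate=True)
    mu0 = float(x[obs].mean())
    sd0 = float(x[obs].std(ddof=1)) if obs.sum() > 1 else 0.0  # sample sd
    if sd0 == 0.0:
        if obs.sum() > 1:
            logger.warning("constant marker: sd=0, standardization divides by 1")
        params = StandardizationParams(mu0, 1.0, -np.inf, np.inf, degenerate=True)
        return apply_standardization(x, params), params
    lo, hi = mu0 - 3.0 * sd0, mu0 + 3.0 * sd0
    x[obs & ((x < lo) | (x > hi))] = np.nan
    obs = ~np.isnan(x)
    mu = float(x[obs].mean()) if obs.any() else 0.0
    sd = float(x[obs].std(ddof=1)) if obs.sum() > 1 else 1.0
    if sd == 0.0:
        logger.warning("marker constant after outlier removal; dividing by 1")
        sd, degenerate = 1.0, True
    else:
        degenerate = False
    params = StandardizationParams(mu, sd, lo, hi, degenerate)
    return apply_standardization(x, params), params


def apply_standardization(values: np.ndarray, params: StandardizationParams) -> np.ndarray:
    x = np.asarray(values, dtype=float).copy()
    obs = ~np.isnan(x)
    x[obs & ((x < params.lo) | (x > params.hi))] = np.nan
    obs = ~np.isnan(x)
    x[obs] = (x[obs] - params.mean) / params.sd
    return x


@dataclass
class ExpandedMatrix:
    """Feature-expanded design matrix with its column map.

    ``colmap`` lists, per expanded column, the pair (marker, slot) where slot
    is ``"x"``, ``"1-x"`` or ``"plain"`` (marker was not expanded).
    """

    matrix: np.ndarray
    colmap: list[tuple[str, str]]
    expanded_flags: dict[str, bool]
    index: pd.Index | None = None

    @property
    def markers(self) -> list[str]:
        seen: list[str] = []
        for m, _ in self.colmap:
            if m not in seen:
                seen.append(m)
        return seen

    def columns_of(self, marker: str) -> list[int]:
        return [i for i, (m, _) in enumerate(self.colmap) if m == marker]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{m}|{slot}" if slot != "plain" else m for m, slot in self.colmap]
        return pd.DataFrame(self.matrix, columns=cols, index=self.index)


def encode(cohort: CohortTable, params: dict[str, StandardizationParams] | None = None):
    """Encode a cohort: clean/standardize continuous, pass through ordinal/binary.

    Returns (encoded DataFrame, params dict).  Supplying ``params`` applies a
    previously fitted transform instead of refitting (leakage-free reuse).
    """
    fitted: dict[str, StandardizationParams] = {}
    out = {}
    for name in cohort.markers:
        spec = cohort.schema[name]
        col = cohort.values[name].to_numpy(dtype=float)
        if spec.kind == "continuous":
            if params is not None and name in params:
                out[name] = apply_standardization(col, params[name])
                fitted[name] = params[name]
            else:
                out[name], fitted[name] = clean_continuous(col)
        elif spec.kind in ("ordinal", "binary"):
            out[name] = col
        else:  # pragma: no cover - schema validation rejects other kinds
            raise ValueError(f"unknown marker kind {spec.kind!r}")
    encoded = pd.DataFrame(out, index=cohort.values.index)
    return encoded, fitted


def expand_features(encoded: pd.DataFrame, schema: dict[str, MarkerSpec] | None = None,
                    expand: dict[str, bool] | None = None) -> ExpandedMatrix:
    """Expand each marker with missing values to the (x, 1-x) pair.

    Missing entries become (0, 0).  Markers with no missing values keep one
    column.  ``expand`` forces the expansion decision per marker (used to
    apply a fitted layout to new data); by default a marker is expanded iff it
    has at least one missing value.
    """
    cols: list[np.ndarray] = []
    colmap: list[tuple[str, str]] = []
    flags: dict[str, bool] = {}
    for name in encoded.columns:
        x = encoded[name].to_numpy(dtype=float)
        do_expand = expand[name] if expand is not None else bool(np.isnan(x).any())
        flags[name] = do_expand
        if do_expand:
            miss = np.isnan(x)
            a = np.where(miss, 0.0, x)
            b = np.where(miss, 0.0, 1.0 - x)
            cols += [a, b]
            colmap += [(name, "x"), (name, "1-x")]
        else:
            cols.append(np.nan_to_num(x, nan=0.0))
            colmap.append((name, "plain"))
    return ExpandedMatrix(np.column_stack(cols), colmap, flags, index=encoded.index)


def collapse_to_encoded(expanded: ExpandedMatrix) -> pd.DataFrame:
    """Inverse of :func:`expand_features` on non-missing entries (takes slot x)."""
    out = {}
    for name in expanded.markers:
        idx = expanded.columns_of(name)
        slots = [expanded.colmap[i][1] for i in idx]
        if slots == ["plain"]:
            out[name] = expanded.matrix[:, idx[0]]
        else:
            x = expanded.matrix[:, idx[slots.index("x")]]
            one_minus = expanded.matrix[:, idx[slots.index("1-x")]]
            miss = (x == 0) & (one_minus == 0)
            out[name] = np.where(miss, np.nan, x)
    return pd.DataFrame(out, index=expanded.index)


@dataclass
class Preprocessor:
    """Fitted preprocessing pipeline: encode + expand with stored parameters."""

    params: dict[str, StandardizationParams] = field(default_factory=dict)
    expand_flags: dict[str, bool] = field(default_factory=dict)
    fitted: bool = False

    def fit_transform(self, cohort: CohortTable) -> ExpandedMatrix:
        encoded, self.params = encode(cohort)
        expanded = expand_features(encoded, cohort.schema)
        self.expand_flags = expanded.expanded_flags
        self.fitted = True
        return expanded

    def transform(self, cohort: CohortTable) -> ExpandedMatrix:
        if not self.fitted:
            raise RuntimeError("Preprocessor not fitted")
        encoded, _ = encode(cohort, params=self.params)
        return expand_features(encoded, cohort.schema, expand=self.expand_flags)
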