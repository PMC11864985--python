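"""Core data containers: patient-by-marker tables and right-censored outcomes.

A cohort is a patients x markers table of mixed-type clinical variables
(continuous laboratory values, ordinal clinical scores, binary presence
indicators), a schema describing each marker, and a per-patient cancer-entity
label.  Missing entries are NaN.  Survival outcomes are (time, event) pairs
for a named endpoint -- overall survival (OS) or time to next treatment
(TTNT) -- with event=1 meaning the event was observed and event=0 right
censoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MARKER_KINDS = ("continuous", "ordinal", "binary")

#: modalities excluded from the pairwise interaction screen because their
#: levels are too unbalanced to condition on (presence indicators that are
#: almost always zero, and the cancer-type one-hot block).
EXCLUDED_MODALITIES = frozenset({"medication", "icd", "ops", "cancer_type"})


@dataclass(frozen=True)
class MarkerSpec:
    """Schema entry for one marker."""

    kind: str
    modality: str = "lab"
    n_levels: int | None = None  # for ordinal markers

    def __post_init__(self):
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"unknown marker kind {self.kind!r}")


@dataclass
class CohortTable:
    """Patients x markers values with schema and entity labels.

    ``values`` holds the raw marker values with NaN for missing entries;
    ``schema`` maps marker name -> :class:`MarkerSpec`; ``entity`` is a
    per-patient categorical cancer-entity label aligned to ``values.index``.
    ``measurement_age`` optionally records, per cell, how many days before
    baseline the measurement was taken (used by report-level recency filters).
    """

    values: pd.DataFrame
    schema: dict[str, MarkerSpec]
    entity: pd.Series
    measurement_age: pd.DataFrame | None = None

    def __post_init__(self):
        missing_spec = [m for m in self.values.columns if m not in self.schema]
        if missing_spec:
            raise ValueError(f"markers without schema entry: {missing_spec}")
        if len(self.entity) != len(self.values):
            raise ValueError("entity labels not aligned to values")
        self.validate()

    def validate(self) -> None:
        for name, spec in self.schema.items():
            if name not in self.values.columns:
                continue
            col = self.values[name].dropna()
            if spec.kind == "binary" and not col.isin([0, 1]).all():
                raise ValueError(f"binary marker {name!r} has values outside {{0,1}}")
            if spec.kind == "ordinal" and not np.allclose(col, np.round(col)):
                raise ValueError(f"ordinal marker {name!r} has non-integer levels")

    @property
    def n_patients(self) -> int:
        return len(self.values)

    @property
    def markers(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """True where a value is missing."""
        return self.values.isna()

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(outdir / "cohort.csv", index_label="patient_id")
        self.entity.rename("entity").to_csv(outdir / "entity.csv", index_label="patient_id")
        schema = {
            m: {"kind": s.kind, "modality": s.modality, "n_levels": s.n_levels}
            for m, s in self.schema.items()
        }
        (outdir / "schema.json").write_text(json.dumps(schema, indent=1))
        if self.measurement_age is not None:
            self.measurement_age.to_csv(outdir / "measurement_age.csv", index_label="patient_id")

    @classmethod
    def read(cls, outdir: str | Path) -> "CohortTable":
        outdir = Path(outdir)
        values = pd.read_csv(outdir / "cohort.csv", index_col="patient_id")
        entity = pd.read_csv(outdir / "entity.csv", index_col="patient_id")["entity"]
        raw = json.loads((outdir / "schema.json").read_text())
        schema = {m: MarkerSpec(d["kind"], d["modality"], d.get("n_levels")) for m, d in raw.items()}
        age_path = outdir / "measurement_age.csv"
        age = pd.read_csv(age_path, index_col="patient_id") if age_path.exists() else None
        return cls(values=values, schema=schema, entity=entity, measurement_age=age)


@dataclass
class SurvivalOutcome:
    """Right-censored survival outcome for one endpoint (OS or TTNT)."""

    time: np.ndarray
    event: np.ndarray
    endpoint: str = "OS"
    index: pd.Index | None = field(default=None, repr=False)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event).astype(bool)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must be aligned")
        if np.any(self.time < 0):
            raise ValueError("negative survival time")
        if not self.event.any():
            raise ValueError("cohort contains no events")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def event_fraction(self) -> float:
        return float(self.event.mean())

    def subset(self, idx) -> "SurvivalOutcome":
        sub_index = self.index[idx] if self.index is not None else None
        return SurvivalOutcome(self.time[idx], self.event[idx], self.endpoint, sub_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event.astype(int), "endpoint": self.endpoint},
            index=self.index if self.index is not None else pd.RangeIndex(len(self.time)),
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="patient_id")

    @classmethod
    def read(cls, path: str | Path) -> "SurvivalOutcome":
        df = pd.read_csv(path, index_col="patient_id")
        endpoint = str(df["endpoint"].iloc[0]) if "endpoint" in df else "OS"
        return cls(df["time"].to_numpy(), df["event"].to_numpy(), endpoint, df.index)
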