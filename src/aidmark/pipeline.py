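"""End-to-end pipeline: simulate -> preprocess -> train -> explain -> stats.

Every stage writes plain-text artifacts (CSV/JSON) so that two runs with the
same configuration and seed are byte-identical, which is the reproducibility
contract of the whole package.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import aidstats
from .coxnn import CoxRiskNet, TrainConfig
from .preprocess import Preprocessor, collapse_to_encoded
from .simulate import GeneratorConfig, generate_cohort


def _fmt(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format="%.10g", **kw)


def run_pipeline(gen_config: GeneratorConfig, outdir: str | Path,
                 train_config: TrainConfig | None = None, gamma: float = 0.01) -> dict:
    """Run the full chain on a synthetic cohort and write all artifacts.

    Returns a dict of the in-memory objects for further use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    train_config = train_config or TrainConfig(seed=gen_config.seed)

    cohort, outcome, truth = generate_cohort(gen_config)
    cohort.write(outdir)
    outcome.write(outdir / "outcome.csv")
    (outdir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))

    pp = Preprocessor()
    expanded = pp.fit_transform(cohort)
    _fmt(expanded.to_frame(), outdir / "expanded.csv", index_label="patient_id")
    (outdir / "colmap.json").write_text(json.dumps(expanded.colmap))

    model = CoxRiskNet(expanded, outcome)
    results = model.fit(train_config)
    results.net.to_json(outdir / "model.json")
    risks = results.predict_risk()
    _fmt(pd.Series(risks, index=expanded.index, name="risk").to_frame(),
         outdir / "risks.csv", index_label="patient_id")

    rel = results.explain(gamma=gamma)
    rc_out = rel.rc.copy()
    rc_out["bias_absorbed"] = rel.bias_absorbed
    _fmt(rc_out, outdir / "rc.csv", index_label="patient_id")

    mi = aidstats.marker_importance(rel, collapse_to_encoded(expanded).isna())
    _fmt(mi.table, outdir / "mi.csv", index_label="marker")
    encoded = collapse_to_encoded(expanded)  # the cleaned values the network saw
    slopes = aidstats.slope_table(encoded, rel, outcome=outcome)
    _fmt(slopes, outdir / "slopes.csv")

    return {"cohort": cohort, "outcome": outcome, "truth": truth, "expanded": expanded,
            "results": results, "rc": rel, "mi": mi, "slopes": slopes, "risks": risks}
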