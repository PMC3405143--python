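"""Score the pipeline against the generator's ground truth.

Sensitivity over the planted (probe, population) effects and the false
discovery rate of the recovered pairs (a pair counts as false only if the
true mixture-model beta difference versus whole blood is below 0.01 —
mixture spillover is a genuine difference, not an error).
"""

import json
from pathlib import Path

import pandas as pd

from bloodmeth.datamodel import read_intensity_tables
from bloodmeth.pipeline import AnalysisConfig, recovery_metrics, run_reference_analysis
from bloodmeth.synthetic import CellMixtureTruth

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"

truth = CellMixtureTruth.from_json(DATA / "truth.json")
dataset = read_intensity_tables(
    DATA / "meth.tsv", DATA / "unmeth.tsv", DATA / "samplesheet.csv", DATA / "channel.tsv"
)
result = run_reference_analysis(dataset, AnalysisConfig(), do_structure=False)

metrics = recovery_metrics(result, truth)
per_pop = (
    truth.planted_dm.assign(
        recovered=[
            probe in set(result.filtered[pop]["probe_id"])
            for probe, pop in zip(truth.planted_dm["probe_id"], truth.planted_dm["population"])
        ]
    )
    .groupby("population")["recovered"]
    .mean()
    .round(3)
)

out = {k: (round(v, 4) if isinstance(v, float) else v) for k, v in metrics.items()}
out["per_population_sensitivity"] = per_pop.to_dict()
(ROOT / "results" / "recovery.json").write_text(json.dumps(out, indent=2) + "\n")
print(json.dumps(out, indent=2))
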