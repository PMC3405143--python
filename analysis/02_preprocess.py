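"""Preprocess raw two-channel intensities into normalized M-values.

Background subtraction (5% quantile, floor 1), red-channel quantile mapping
onto the green distribution, quantile normalization of the stacked
intensity matrix, then M = log2((meth+100)/(unmeth+100)).  The M-value
matrix (large) goes to scratch/; a small distribution summary to results/.
"""

import json
from pathlib import Path

import numpy as np

from bloodmeth.datamodel import read_intensity_tables
from bloodmeth.preprocess import PreprocessConfig, preprocess_pipeline

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"

dataset = read_intensity_tables(
    DATA / "meth.tsv", DATA / "unmeth.tsv", DATA / "samplesheet.csv", DATA / "channel.tsv"
)
config = PreprocessConfig()
m = preprocess_pipeline(dataset, config)

with open(ROOT / "scratch" / "mvalues.tsv", "w") as fh:
    m.to_frame().to_csv(fh, sep="\t", index_label="probe_id", float_format="%.17g")

summary = {
    "m_offset": config.m_offset,
    "background_quantile": config.background_quantile,
    "color_reference": config.color_reference,
    "m_range": [round(float(m.values.min()), 2), round(float(m.values.max()), 2)],
    "m_quartiles": [round(float(q), 2) for q in np.percentile(m.values, [25, 50, 75])],
}
(ROOT / "results" / "preprocess_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
print(json.dumps(summary, indent=2))
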