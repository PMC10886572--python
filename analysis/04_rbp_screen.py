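#!/usr/bin/env python
"""RNA-binding-protein enrichment among the secretory miRNAs.

Builds per-RBP 2x2 contingency tables (secretory vs background miRNAs of
the detected universe), applies the chi-squared screen with BH adjustment,
and reports the top-10 RBPs by observed/expected interaction ratio along
with how many of the planted sorting RBPs they include.
"""

import json
from pathlib import Path

import pandas as pd

from sevmir.pipeline import RunConfig, stage_rbp

cfg = RunConfig(workdir="results/run", seed=1)
run = Path(cfg.workdir)
if not (run / "results" / "differential.tsv").exists():
    raise SystemExit("differential table missing: run analysis/02 first")

stage_rbp(cfg, run / "inputs", run / "results")
table = pd.read_csv(run / "results" / "rbp_enrichment_secretory.tsv", sep="\t", index_col=0)
truth = json.loads((run / "inputs" / "truth.json").read_text())

top10 = table[table["top"].fillna(False)]
print("top RBPs for the secretory compartment (obs/exp ratio):")
print(top10[["a", "c", "obs_exp_ratio", "p_adjusted"]].to_string())
planted = set(truth["enriched_rbp_ids"])
print(f"planted RBPs recovered in top 10: {len(planted & set(top10.index))}/{len(planted)}")
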