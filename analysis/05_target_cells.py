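#!/usr/bin/env python
"""Candidate target cell types of the secretory miRNAs.

Pools the target mRNAs of the secretory miRNAs, tests each cell-type
marker set by the one-sided hypergeometric test, exports the bipartite
miRNA-target subnetwork of each significant type, and reports the
headline (most significant) cell type.
"""

import json
from pathlib import Path

import pandas as pd

from sevmir.pipeline import RunConfig, stage_celltypes

cfg = RunConfig(workdir="results/run", seed=1)
run = Path(cfg.workdir)
if not (run / "results" / "differential.tsv").exists():
    raise SystemExit("differential table missing: run analysis/02 first")

written = stage_celltypes(cfg, run / "inputs", run / "results")
table = pd.read_csv(run / "results" / "celltype_enrichment.tsv", sep="\t", index_col=0)
truth = json.loads((run / "inputs" / "truth.json").read_text())

print("cell-type over-representation (sorted by p):")
print(table[["overlap", "set_size", "pool_size", "p", "p_adjusted"]].head(5).to_string())
print(f"headline cell type: {table.index[0]} (planted: {truth['true_cell_type']})")
subnets = [p for p in written if p.suffix == ".sif"]
print(f"exported {len(subnets)} significant-type subnetwork(s)")
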