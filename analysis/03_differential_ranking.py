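#!/usr/bin/env python
"""Per-cohort compositional differential ranking of all OGUs.

Fits the penalized multinomial log-contrast model within each dataset
(no prevalence prefiltering), writes the CLR-centered differentials in
long format, and scores rank recovery against the planted ground truth.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from ecoresp.core_io import read_ogu_table, read_sample_metadata, spearman
from ecoresp.diffrank import differentials_long, fit_differentials

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
parser.add_argument("--reg", type=float, default=1.0)
args = parser.parse_args()

datadir = args.outdir / "data"
table = read_ogu_table(datadir / "ogu_table.tsv", "biom_triplet")
smeta = read_sample_metadata(datadir / "sample_metadata.tsv")
truth = json.loads((datadir / "sim_truth.json").read_text())["result"]
planted = np.asarray(truth["planted_effect"])

diff = fit_differentials(table, smeta, reg_strength=args.reg)
differentials_long(diff).to_csv(args.outdir / "differentials.tsv", sep="\t",
                                index=False)

print(f"fitted {len(diff.fitted_datasets())} of {len(diff.dataset_ids)} datasets "
      f"(reg_strength {args.reg})")
rhos = []
for ds in diff.fitted_datasets():
    col = diff.coef[ds].dropna()
    idx = [int(o[3:]) for o in col.index]
    rho, _ = spearman(col.values, planted[idx])
    rhos.append(rho)
    print(f"  {ds}: {len(col)} OGUs present, "
          f"rank recovery rho = {rho:.3f}, "
          f"{'converged' if diff.converged[ds] else 'NOT converged'}")
print(f"mean per-dataset recovery rho = {np.mean(rhos):.3f} "
      "(attenuated at survey-scale sparsity: most taxa are detected in only "
      "a handful of samples per cohort)")
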