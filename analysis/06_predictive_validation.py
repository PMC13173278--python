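#!/usr/bin/env python
"""Leave-one-cohort-out and cross-cancer validation of the biomarker.

Builds the three per-sample predictors (marker log ratio, Shannon index,
Proteobacteria relative abundance), runs LOGO cross-validation for each
predictor and the combined model, and transfers between melanoma and
non-melanoma cohorts in both directions.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from ecoresp.core_io import (
    read_ogu_metadata,
    read_ogu_table,
    read_sample_metadata,
    result_to_json,
    tss_normalize,
)
from ecoresp.diffrank import fit_differentials
from ecoresp.markers import MarkerSet, compute_log_ratio, select_markers
from ecoresp.validate import build_predictors, logo_cv, transfer_validation

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

datadir = args.outdir / "data"
table = read_ogu_table(datadir / "ogu_table.tsv", "biom_triplet")
smeta = read_sample_metadata(datadir / "sample_metadata.tsv")
ometa = read_ogu_metadata(datadir / "ogu_metadata.tsv")
rel = tss_normalize(table)

markers_path = args.outdir / "markers_logratio.json"
if markers_path.exists():
    payload = json.loads(markers_path.read_text())["result"]["markers"]
    mset = MarkerSet(set(payload["r_markers"]), set(payload["nr_markers"]),
                     payload["selection_params"], {})
else:
    diff = fit_differentials(table, smeta)
    cancer_map = {m.dataset_id: m.cancer_type for m in smeta.values()}
    mset = select_markers(diff, require_nonmelanoma=True,
                          dataset_cancer_map=cancer_map)

lr = compute_log_ratio(rel, mset)
preds = build_predictors(rel, lr, ometa)
labels = np.array([1 if smeta[s].response == "R" else 0 for s in preds.index])
groups = np.array([smeta[s].dataset_id for s in preds.index], dtype=object)
cancer = np.array([smeta[s].cancer_type for s in preds.index])

results = {}
print("LOGO cross-validation (one cohort held out per fold):")
for name, cols in [
    ("log_ratio", ("log_ratio",)),
    ("shannon", ("shannon",)),
    ("proteobacteria", ("proteobacteria_relabund",)),
    ("combined", ("log_ratio", "shannon", "proteobacteria_relabund")),
]:
    cv = logo_cv(preds, labels, groups, predictors_used=cols, seed=args.seed)
    results[f"logo_{name}"] = cv
    print(f"  {name:15s} mean AUC = {cv.mean_auc:.2f} +/- {cv.sd_auc:.2f}")

mel = cancer == "melanoma"
for name, train, test in [
    ("melanoma_to_other", mel, ~mel),
    ("other_to_melanoma", ~mel, mel),
]:
    tr = transfer_validation(preds, labels, train, test, seed=args.seed)
    results[f"transfer_{name}"] = tr
    fold = tr.folds[0]
    print(f"transfer {name}: AUC = {tr.mean_auc:.2f}, "
          f"accuracy = {fold.accuracy:.2f}, sens = {fold.sensitivity:.2f}, "
          f"spec = {fold.specificity:.2f}")

result_to_json(results, args.outdir / "validation.json")
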