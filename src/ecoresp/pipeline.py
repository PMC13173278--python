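"""End-to-end pipeline driver: simulate -> diversity -> differential ranking
-> markers -> log ratio -> association -> validation -> enrichment.

The run is configured by a single YAML/dict config with one block per
stage; a global seed is deterministically expanded into per-stage
substreams, every stage logs to stderr, and a machine-readable run report
(per-stage status, parameters, output digests, wall clock, seeds) is
written alongside the outputs.  Re-running an identical config reproduces
all outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import exogenous_burden, fit_lmm, prevalence_association
from .core_io import (
    SCHEMA_VERSION,
    compute_prevalence,
    read_ogu_metadata,
    read_ogu_table,
    read_sample_metadata,
    result_to_json,
    tss_normalize,
    write_ogu_metadata,
    write_ogu_table,
    write_sample_metadata,
)
from .diffrank import differentials_long, fit_differentials
from .diversity import bray_curtis, permanova_stratified, permdisp, shannon
from .enrich import gsea_preranked, make_ranked_list
from .markers import compute_log_ratio, per_dataset_wilcoxon, select_markers
from .simulate import SimConfig, simulate_cohorts
from .validate import build_predictors, logo_cv, transfer_validation

_STAGE_ORDER = (
    "simulate",
    "diversity",
    "diffrank",
    "markers",
    "logratio",
    "assoc",
    "validate",
    "enrich",
)

_STAGE_DEPS = {
    "diversity": (),
    "diffrank": (),
    "markers": ("diffrank",),
    "logratio": ("markers",),
    "assoc": ("diffrank", "logratio"),
    "validate": ("logratio",),
    "enrich": ("diffrank", "markers"),
}

_ALLOWED_TOP = {"seed", "outdir", "stages", "inputs"} | set(_STAGE_ORDER)


class ConfigError(ValueError):
    pass


class DependencyError(RuntimeError):
    pass


@dataclass
class StageRecord:
    name: str
    status: str
    parameters: dict
    outputs: dict[str, str]  # path -> sha256 digest
    wall_seconds: float
    seed: int | None


@dataclass
class RunReport:
    stages: list[StageRecord]
    global_seed: int
    package_version: str
    schema_version: str = SCHEMA_VERSION

    def digests(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for s in self.stages:
            out.update(s.outputs)
        return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(msg: str) -> None:
    print(f"[ecoresp] {msg}", file=sys.stderr)


def validate_config(config: dict) -> dict:
    """Schema-check the run config before any stage executes."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - _ALLOWED_TOP
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in config:
        raise ConfigError("config requires a global 'seed'")
    stages = config.get("stages", list(_STAGE_ORDER))
    bad = [s for s in stages if s not in _STAGE_ORDER]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    if "simulate" not in stages and "inputs" not in config:
        raise ConfigError("either a simulate stage or an 'inputs' block is required")
    for s in stages:
        for dep in _STAGE_DEPS.get(s, ()):
            if dep not in stages:
                raise DependencyError(f"stage {s!r} requires stage {dep!r}")
        blk = config.get(s, {})
        if blk is not None and not isinstance(blk, dict):
            raise ConfigError(f"stage block {s!r} must be a mapping")
    return config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def run_pipeline(config: dict, outdir: str | Path | None = None) -> RunReport:
    """Run the configured stages in dependency order; halt on failure."""
    config = validate_config(config)
    outdir = Path(outdir or config.get("outdir", "ecoresp_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in _STAGE_ORDER if s in config.get("stages", list(_STAGE_ORDER))]
    seed = int(config["seed"])
    stage_seeds = {
        s: int(np.random.SeedSequence(seed).spawn(len(_STAGE_ORDER))[i].generate_state(1)[0] % (2**31))
        for i, s in enumerate(_STAGE_ORDER)
    }

    report = RunReport(stages=[], global_seed=seed, package_version=__version__)
    state: dict[str, Any] = {}

    def record(name: str, params: dict, outputs: dict[str, Path], t0: float) -> None:
        report.stages.append(
            StageRecord(
                name=name,
                status="ok",
                parameters=params,
                outputs={str(p): _digest(p) for p in outputs.values()},
                wall_seconds=round(time.perf_counter() - t0, 3),
                seed=stage_seeds.get(name),
            )
        )

    try:
        if "simulate" in stages:
            t0 = time.perf_counter()
            blk = dict(config.get("simulate") or {})
            blk.setdefault("seed", stage_seeds["simulate"])
            sim_cfg = SimConfig(**blk)
            table, smeta, ometa, truth = simulate_cohorts(sim_cfg)
            paths = {
                "table": outdir / "ogu_table.tsv",
                "sample_meta": outdir / "sample_metadata.tsv",
                "ogu_meta": outdir / "ogu_metadata.tsv",
                "truth": outdir / "sim_truth.json",
            }
            write_ogu_table(table, paths["table"])
            write_sample_metadata(smeta, paths["sample_meta"])
            write_ogu_metadata(ometa, paths["ogu_meta"])
            result_to_json(truth, paths["truth"])
            state.update(table=table, smeta=smeta, ometa=ometa, truth=truth)
            record("simulate", blk, paths, t0)
            _log(f"simulate: {table.n_samples} samples x {table.n_ogus} OGUs")
        else:
            inputs = config["inputs"]
            state["table"] = read_ogu_table(
                inputs["table"], inputs.get("dialect", "tsv_dense")
            )
            state["smeta"] = read_sample_metadata(inputs["sample_metadata"])
            state["ometa"] = read_ogu_metadata(inputs["ogu_metadata"])
            _log("inputs loaded from files")

        table, smeta, ometa = state["table"], state["smeta"], state["ometa"]
        rel = tss_normalize(table)
        responses = [smeta[s].response for s in table.sample_ids]
        datasets = [smeta[s].dataset_id for s in table.sample_ids]

        if "diversity" in stages:
            t0 = time.perf_counter()
            blk = dict(config.get("diversity") or {})
            dm = bray_curtis(rel)
            perm = permanova_stratified(
                dm, responses, datasets,
                n_perm=blk.get("n_perm", 999), seed=stage_seeds["diversity"],
            )
            disp = permdisp(
                dm, responses,
                n_perm=blk.get("n_perm_disp", 999), seed=stage_seeds["diversity"],
            )
            sh = pd.Series(
                [shannon(rel.values[i]) for i in range(rel.n_samples)],
                index=rel.sample_ids, name="shannon",
            )
            paths = {
                "permanova": outdir / "permanova.json",
                "shannon": outdir / "shannon.tsv",
            }
            result_to_json({"permanova": perm, "permdisp": disp}, paths["permanova"])
            sh.to_csv(paths["shannon"], sep="\t")
            state["shannon"] = sh
            record("diversity", blk, paths, t0)
            _log(f"diversity: PERMANOVA F={perm.statistic:.3f} p={perm.p_value:.4f}")

        if "diffrank" in stages:
            t0 = time.perf_counter()
            blk = dict(config.get("diffrank") or {})
            diff = fit_differentials(
                table, smeta,
                reg_strength=blk.get("reg_strength", 1.0),
                seed=stage_seeds["diffrank"],
            )
            paths = {"diff": outdir / "differentials.tsv"}
            differentials_long(diff).to_csv(paths["diff"], sep="\t", index=False)
            state["diff"] = diff
            record("diffrank", blk, paths, t0)
            _log(f"diffrank: fitted {len(diff.fitted_datasets())} datasets")

        if "markers" in stages:
            t0 = time.perf_counter()
            blk = dict(config.get("markers") or {})
            cancer_map = {
                smeta[s].dataset_id: smeta[s].cancer_type for s in table.sample_ids
            }
            mset = select_markers(
                state["diff"],
                threshold=blk.get("threshold", 0.3),
                exclusion_mode=blk.get("exclusion_mode", "opposite_above_threshold"),
                require_nonmelanoma=blk.get("require_nonmelanoma", False),
                dataset_cancer_map=cancer_map,
            )
            paths = {"markers": outdir / "markers.json"}
            result_to_json(mset, paths["markers"])
            state["markers"] = mset
            record("markers", blk, paths, t0)
            _log(f"markers: {len(mset.r_markers)} R / {len(mset.nr_markers)} NR")

        if "logratio" in stages:
            t0 = time.perf_counter()
            blk = dict(config.get("logratio") or {})
            lr = compute_log_ratio(
                rel, state["markers"],
                zero_policy=blk.get("zero_policy", "exclude_sample"),
            )
            wil = per_dataset_wilcoxon(lr, smeta, alpha=blk.get("alpha", 0.05))
            paths = {"logratio": outdir / "log_ratios.tsv",
                     "wilcoxon": outdir / "logratio_wilcoxon.json"}
            pd.DataFrame(
                [dataclasses.asdict(v) for v in lr.values()]
            ).to_csv(paths["logratio"], sep="\t", index=False)
            result_to_json(wil, paths["wilcoxon"])
            state["logratio"] = lr
            record("logratio", blk, paths, t0)
            n_valid = sum(1 for v in lr.values() if v.valid)
            _log(f"logratio: {n_valid}/{len(lr)} samples valid")

        if "assoc" in stages:
            t0 = time.perf_counter()
            blk = dict(config.get("assoc") or {})
            lr = state["logratio"]
            valid = [s for s in table.sample_ids if lr[s].valid]
            y = [lr[s].value for s in valid]
            x = pd.DataFrame(
                {"response": [1.0 if smeta[s].response == "R" else 0.0 for s in valid]}
            )
            g = [smeta[s].dataset_id for s in valid]
            lmm = fit_lmm(y, x, g)
            profiles = compute_prevalence(table, smeta)
            prev = prevalence_association(
                state["diff"], profiles,
                n_perm=blk.get("n_perm", 0), seed=stage_seeds["assoc"],
                counts=table, meta=smeta,
            )
            burden = exogenous_burden(rel, ometa)
            xb = pd.DataFrame(
                {"response": [1.0 if smeta[s].response == "R" else 0.0
                              for s in table.sample_ids]}
            )
            lmm_burden = fit_lmm(burden.values, xb, datasets)
            paths = {"assoc": outdir / "association.json"}
            result_to_json(
                {"logratio_lmm": lmm, "prevalence": prev, "burden_lmm": lmm_burden},
                paths["assoc"],
            )
            state["assoc"] = {"lmm": lmm, "prev": prev}
            record("assoc", blk, paths, t0)
            _log(
                "assoc: logratio beta="
                f"{lmm.fixed_effects['response'].estimate:.3f}, "
                f"prevalence rho={prev.rho:.3f}"
            )

        if "validate" in stages:
            t0 = time.perf_counter()
            blk = dict(config.get("validate") or {})
            preds = build_predictors(rel, state["logratio"], ometa)
            labels = [1 if smeta[s].response == "R" else 0 for s in preds.index]
            grp = [smeta[s].dataset_id for s in preds.index]
            cv = logo_cv(
                preds, labels, grp,
                predictors_used=blk.get("predictors", ("log_ratio",)),
                seed=stage_seeds["validate"],
            )
            cancer = np.asarray([smeta[s].cancer_type for s in preds.index])
            paths = {"cv": outdir / "validation.json"}
            results = {"logo": cv}
            if (cancer == "melanoma").any() and (cancer != "melanoma").any():
                results["transfer_mel_to_other"] = transfer_validation(
                    preds, labels, cancer == "melanoma", cancer != "melanoma",
                    predictors_used=blk.get("predictors", ("log_ratio",)),
                    seed=stage_seeds["validate"],
                )
            result_to_json(results, paths["cv"])
            state["cv"] = cv
            record("validate", blk, paths, t0)
            _log(f"validate: LOGO mean AUC={cv.mean_auc:.3f} +/- {cv.sd_auc:.3f}")

        if "enrich" in stages:
            t0 = time.perf_counter()
            blk = dict(config.get("enrich") or {})
            diff = state["diff"]
            fitted = diff.fitted_datasets()
            mean_coef = diff.coef[fitted].mean(axis=1, skipna=True).dropna()
            # per-OGU rank-sum screen of relative abundance, R vs NR, feeds
            # the signed-significance ranking metric
            from .core_io import rank_sum_test

            resp_arr = np.asarray(responses, dtype=object)
            oi = rel.ogu_index()
            screen_p = np.array(
                [
                    rank_sum_test(
                        rel.values[resp_arr == "R", oi[o]],
                        rel.values[resp_arr == "NR", oi[o]],
                    )[1]
                    for o in mean_coef.index
                ]
            )
            ranked = make_ranked_list(
                list(mean_coef.index), mean_coef.values, screen_p,
                metric=blk.get("metric", "signed_neglog10p"),
            )
            sets: dict[str, list[str]] = {}
            for ogu, m in ometa.items():
                for f in m.source_flags:
                    sets.setdefault(f"source:{f}", []).append(ogu)
                ph = m.phylum()
                if ph:
                    sets.setdefault(f"phylum:{ph}", []).append(ogu)
            res = gsea_preranked(
                ranked, sets,
                n_perm=blk.get("n_perm", 1000), seed=stage_seeds["enrich"],
            )
            paths = {"enrich": outdir / "enrichment.json"}
            result_to_json(res, paths["enrich"])
            record("enrich", blk, paths, t0)
            _log(f"enrich: {len(res)} sets tested")

    except Exception as exc:
        report.stages.append(
            StageRecord(
                name="error", status=f"failed: {exc}", parameters={}, outputs={},
                wall_seconds=0.0, seed=None,
            )
        )
        _write_report(report, outdir)
        raise

    _write_report(report, outdir)
    return report


def _write_report(report: RunReport, outdir: Path) -> None:
    path = Path(outdir) / "run_report.json"
    payload = {
        "schema_version": report.schema_version,
        "package_version": report.package_version,
        "global_seed": report.global_seed,
        "stages": [dataclasses.asdict(s) for s in report.stages],
    }
    path.write_text(json.dumps(payload, indent=2))
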