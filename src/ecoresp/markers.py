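"""Cross-dataset marker selection and the per-sample log-ratio biomarker.

An OGU becomes a responder (R) marker when its differential exceeds the
threshold in at least one fitted dataset, no dataset contradicts it in the
non-responder (NR) direction (two exclusion modes, see below), and — when
the multicancer rule is on — the supporting evidence is not confined to
melanoma datasets.  The NR rule is symmetric.  The per-sample biomarker is
the natural-log ratio of summed R-marker abundance to summed NR-marker
abundance, which is scale-free and hence invariant to TSS normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core_io import OguCountTable, SampleMetadata, rank_sum_test
from .diffrank import DifferentialTable

EXCLUSION_MODES = ("opposite_above_threshold", "any_opposite_sign")
ZERO_POLICIES = ("exclude_sample", "pseudocount")


@dataclass
class MarkerSet:
    r_markers: set[str]
    nr_markers: set[str]
    selection_params: dict
    per_marker_evidence: dict[str, list[tuple[str, float]]]

    def __post_init__(self) -> None:
        overlap = self.r_markers & self.nr_markers
        if overlap:
            raise ValueError(f"marker sets overlap: {sorted(overlap)[:5]}")


@dataclass
class LogRatioResult:
    sample_id: str
    value: float | None
    valid: bool
    n_numerator_detected: int
    n_denominator_detected: int
    policy: dict


def _passes(
    coefs: dict[str, float],
    threshold: float,
    exclusion_mode: str,
    sign: int,
    require_nonmelanoma: bool,
    cancer_of: Mapping[str, str] | None,
    require_all_datasets: bool,
) -> bool:
    above = {ds for ds, c in coefs.items() if sign * c > threshold}
    if require_all_datasets:
        if len(above) < len(coefs) or not above:
            return False
    elif not above:
        return False
    for ds, c in coefs.items():
        opp = -sign * c
        if exclusion_mode == "any_opposite_sign":
            if opp > 0:
                return False
        else:
            if opp > threshold:
                return False
    if require_nonmelanoma:
        if not any(cancer_of[ds] != "melanoma" for ds in above):
            return False
    return True


def select_markers(
    diff: DifferentialTable,
    threshold: float = 0.3,
    exclusion_mode: str = "opposite_above_threshold",
    require_nonmelanoma: bool = False,
    dataset_cancer_map: Mapping[str, str] | None = None,
    require_all_datasets: bool = False,
) -> MarkerSet:
    """Consistency-based selection of R- and NR-associated OGUs.

    Default exclusion mode requires an opposite-direction differential to
    itself exceed the threshold before it disqualifies a candidate;
    ``any_opposite_sign`` implements the strict literal rule.  With
    ``require_all_datasets`` the threshold must be met in every dataset the
    OGU is present in, instead of at least one.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if exclusion_mode not in EXCLUSION_MODES:
        raise ValueError(f"exclusion_mode must be one of {EXCLUSION_MODES}")
    fitted = diff.fitted_datasets()
    if not fitted:
        raise ValueError("no fitted dataset in the differential table")
    if require_nonmelanoma:
        if dataset_cancer_map is None:
            raise ValueError("require_nonmelanoma needs a dataset_cancer_map")
        missing = [d for d in fitted if d not in dataset_cancer_map]
        if missing:
            raise ValueError(f"dataset_cancer_map missing fitted datasets: {missing}")

    r_markers: set[str] = set()
    nr_markers: set[str] = set()
    evidence: dict[str, list[tuple[str, float]]] = {}
    for ogu in diff.ogu_ids:
        coefs = {
            ds: float(diff.coef.at[ogu, ds])
            for ds in fitted
            if not math.isnan(diff.coef.at[ogu, ds])
        }
        if not coefs:
            continue
        kwargs = dict(
            threshold=threshold,
            exclusion_mode=exclusion_mode,
            require_nonmelanoma=require_nonmelanoma,
            cancer_of=dataset_cancer_map,
            require_all_datasets=require_all_datasets,
        )
        if _passes(coefs, sign=+1, **kwargs):
            r_markers.add(ogu)
            evidence[ogu] = sorted(coefs.items())
        elif _passes(coefs, sign=-1, **kwargs):
            nr_markers.add(ogu)
            evidence[ogu] = sorted(coefs.items())
    params = {
        "threshold": threshold,
        "exclusion_mode": exclusion_mode,
        "require_nonmelanoma": require_nonmelanoma,
        "require_all_datasets": require_all_datasets,
    }
    return MarkerSet(r_markers, nr_markers, params, evidence)


def compute_log_ratio(
    table: OguCountTable,
    markers: MarkerSet,
    zero_policy: str = "exclude_sample",
    pseudocount: float = 1e-6,
) -> dict[str, LogRatioResult]:
    """Per-sample ln(sum R-marker abundance / sum NR-marker abundance).

    Under ``exclude_sample`` a zero numerator or denominator marks the
    sample invalid with no value; under ``pseudocount`` the constant is
    added to both sums.  The ratio is scale-free, so raw counts and TSS
    abundances give identical values.
    """
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"zero_policy must be one of {ZERO_POLICIES}")
    if not markers.r_markers or not markers.nr_markers:
        raise ValueError("both marker sets must be nonempty")
    oi = table.ogu_index()
    num_idx = [oi[o] for o in sorted(markers.r_markers) if o in oi]
    den_idx = [oi[o] for o in sorted(markers.nr_markers) if o in oi]
    if not num_idx or not den_idx:
        raise ValueError("marker sets have no OGUs in common with the table")
    policy = {"zero_policy": zero_policy, "pseudocount": pseudocount}
    out: dict[str, LogRatioResult] = {}
    num = table.values[:, num_idx]
    den = table.values[:, den_idx]
    num_sum = num.sum(axis=1)
    den_sum = den.sum(axis=1)
    n_num_det = (num > 0).sum(axis=1)
    n_den_det = (den > 0).sum(axis=1)
    for i, sid in enumerate(table.sample_ids):
        ns, ds = num_sum[i], den_sum[i]
        if zero_policy == "pseudocount":
            value = float(np.log((ns + pseudocount) / (ds + pseudocount)))
            valid = True
        elif ns > 0 and ds > 0:
            value = float(np.log(ns / ds))
            valid = True
        else:
            value, valid = None, False
        out[sid] = LogRatioResult(
            sample_id=sid,
            value=value,
            valid=valid,
            n_numerator_detected=int(n_num_det[i]),
            n_denominator_detected=int(n_den_det[i]),
            policy=policy,
        )
    return out


@dataclass
class DatasetWilcoxon:
    dataset_id: str
    statistic: float | None
    p_value: float | None
    passed: bool
    testable: bool
    n_r: int
    n_nr: int


def per_dataset_wilcoxon(
    logratios: Mapping[str, LogRatioResult],
    meta: Mapping[str, SampleMetadata],
    alpha: float = 0.05,
) -> dict[str, DatasetWilcoxon]:
    """Two-sided rank-sum test of valid log-ratio values, R vs NR, per dataset.

    Datasets with fewer than two valid samples in either group are reported
    untestable rather than raising.
    """
    by_ds: dict[str, dict[str, list[float]]] = {}
    for sid, lr in logratios.items():
        if not lr.valid:
            continue
        m = meta[sid]
        by_ds.setdefault(m.dataset_id, {"R": [], "NR": []})[m.response].append(lr.value)
    out: dict[str, DatasetWilcoxon] = {}
    for ds, groups in sorted(by_ds.items()):
        r, nr = groups["R"], groups["NR"]
        if len(r) < 2 or len(nr) < 2:
            out[ds] = DatasetWilcoxon(ds, None, None, False, False, len(r), len(nr))
            continue
        stat, p = rank_sum_test(r, nr)
        out[ds] = DatasetWilcoxon(ds, stat, p, p < alpha, True, len(r), len(nr))
    return out
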