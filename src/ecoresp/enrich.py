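"""Preranked set enrichment and gene-family contingency statistics.

The GSEA-style statistic is the weighted Kolmogorov-Smirnov running sum:
walking down the ranked list, a set member increments proportionally to
|metric|^weight (normalized over members), a non-member decrements by
1/(N - |S|); the enrichment score (ES) is the signed extremum.  The null is
built by permuting item labels (the preranked convention — phenotypes are
not re-fitted at this stage), NES divides ES by the mean |null ES| of
matching sign, and the p-value is one-sided by sign with the +1 convention.

The default ranking metric is sign(coef) * -log10(p): ranking by the raw
signed p-value would place the most significant items nearest zero, which
contradicts how a preranked enrichment is meant to read; the literal
``signed_one_minus_p`` variant is provided as a mode.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .core_io import bh_adjust, rank_sum_test

RANK_METRICS = ("signed_one_minus_p", "signed_neglog10p", "coef_only")


@dataclass
class RankedList:
    item_ids: list[str]
    metric: np.ndarray  # aligned with item_ids, descending
    metric_definition: str


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    p_value: float
    adj_p: float
    leading_edge: list[str]
    n_members: int


def make_ranked_list(
    item_ids: Sequence[str],
    coefs: Sequence[float],
    p_values: Sequence[float],
    metric: str = "signed_neglog10p",
) -> RankedList:
    """Rank items by a signed significance metric, descending.

    Ties break by larger coefficient first, then by item id.  p = 0 is
    clamped to the smallest positive float with a warning.
    """
    if metric not in RANK_METRICS:
        raise ValueError(f"metric must be one of {RANK_METRICS}")
    ids = [str(i) for i in item_ids]
    c = np.asarray(coefs, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if not (len(ids) == c.size == p.size):
        raise ValueError("item_ids, coefs and p_values must align")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p = 0 clamped to the machine minimum", stacklevel=2)
        p = np.maximum(p, sys.float_info.min)
    sign = np.sign(c)
    sign[sign == 0] = 1.0
    if metric == "signed_one_minus_p":
        m = sign * (1.0 - p)
    elif metric == "signed_neglog10p":
        m = sign * (-np.log10(p))
    else:
        m = c.copy()
    order = sorted(range(len(ids)), key=lambda i: (-m[i], -c[i], ids[i]))
    return RankedList([ids[i] for i in order], m[order], metric)


def _running_sum(metric: np.ndarray, member: np.ndarray, weight: float) -> np.ndarray:
    n = metric.size
    k = int(member.sum())
    if k == 0 or k == n:
        raise ValueError("set must have between 1 and N-1 members in the ranking")
    w = np.abs(metric) ** weight
    hit_total = w[member].sum()
    if hit_total <= 0:  # all member metrics zero: fall back to equal steps
        steps_hit = member / k
    else:
        steps_hit = np.where(member, w / hit_total, 0.0)
    steps = steps_hit - (~member) / (n - k)
    return np.cumsum(steps)


def _es(metric: np.ndarray, member: np.ndarray, weight: float) -> tuple[float, int]:
    rs = _running_sum(metric, member, weight)
    i = int(np.argmax(np.abs(rs)))
    return float(rs[i]), i


def gsea_preranked(
    ranked: RankedList,
    sets: Mapping[str, Sequence[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict[str, EnrichmentResult]:
    """Weighted KS enrichment of each set against the ranked list.

    Sets with fewer than 2 members present in the ranking, or covering the
    whole ranking, are skipped with a warning.  BH adjustment is applied
    across the sets actually tested.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ids = ranked.item_ids
    pos = {item: i for i, item in enumerate(ids)}
    n = len(ids)
    rng = np.random.default_rng(seed)

    tested: list[tuple[str, float, int, np.ndarray]] = []
    for set_id, members in sets.items():
        mask = np.zeros(n, dtype=bool)
        present = [m for m in set(members) if m in pos]
        for m in present:
            mask[pos[m]] = True
        k = mask.sum()
        if k < 2:
            warnings.warn(f"set {set_id!r} has < 2 members in the ranking; skipped",
                          stacklevel=2)
            continue
        if k == n:
            warnings.warn(f"set {set_id!r} covers the whole ranking; skipped",
                          stacklevel=2)
            continue
        es, i_ext = _es(ranked.metric, mask, weight)
        tested.append((set_id, es, i_ext, mask))

    # one shared null per set size
    null_cache: dict[int, np.ndarray] = {}

    def null_for(k: int) -> np.ndarray:
        if k not in null_cache:
            out = np.empty(n_perm)
            for b in range(n_perm):
                mask = np.zeros(n, dtype=bool)
                mask[rng.choice(n, size=k, replace=False)] = True
                out[b], _ = _es(ranked.metric, mask, weight)
            null_cache[k] = out
        return null_cache[k]

    results: dict[str, EnrichmentResult] = {}
    raw_ps: list[float] = []
    order: list[str] = []
    for set_id, es, i_ext, mask in tested:
        null = null_for(int(mask.sum()))
        if es >= 0:
            same = null[null >= 0]
            ge = int((same >= es - 1e-12).sum())
        else:
            same = null[null < 0]
            ge = int((same <= es + 1e-12).sum())
        p = (1 + ge) / (1 + same.size)
        denom = np.abs(same).mean() if same.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        member_idx = np.flatnonzero(mask)
        if es >= 0:
            leading = [ids[j] for j in member_idx if j <= i_ext]
        else:
            leading = [ids[j] for j in member_idx if j >= i_ext]
        results[set_id] = EnrichmentResult(
            set_id, es, float(nes), p, np.nan, leading, int(mask.sum())
        )
        raw_ps.append(p)
        order.append(set_id)
    if raw_ps:
        adj = bh_adjust(raw_ps)
        for set_id, a in zip(order, adj):
            results[set_id].adj_p = float(a)
    return results


@dataclass
class FamilyEnrichment:
    family: str
    table: tuple[int, int, int, int]  # (a_with, a_without, b_with, b_without)
    p_value: float
    adj_p: float
    log_fc: float
    passed: bool


def fisher_family_enrichment(
    gene_presence: Mapping[str, Sequence[str] | frozenset[str]],
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    logfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> dict[str, FamilyEnrichment]:
    """Per-family 2x2 Fisher exact enrichment between two genome sets.

    logFC = log2 of carriage frequencies with a per-group continuity
    constant 0.5/n (so swapping the groups negates logFC exactly and
    preserves p).  ``passed`` requires BH-adjusted p < alpha AND
    |logFC| > logfc_threshold.  Families absent from every genome are
    skipped.
    """
    a_ids = list(group_a_ids)
    b_ids = list(group_b_ids)
    if not a_ids or not b_ids:
        raise ValueError("both groups must be nonempty")
    if set(a_ids) & set(b_ids):
        raise ValueError("groups must be disjoint")
    families = sorted({f for g in (a_ids + b_ids) for f in gene_presence.get(g, ())})
    na, nb = len(a_ids), len(b_ids)
    rows: list[tuple[str, int, int]] = []
    for fam in families:
        ka = sum(1 for g in a_ids if fam in gene_presence.get(g, ()))
        kb = sum(1 for g in b_ids if fam in gene_presence.get(g, ()))
        if ka == 0 and kb == 0:
            continue
        rows.append((fam, ka, kb))
    ps = []
    out: dict[str, FamilyEnrichment] = {}
    for fam, ka, kb in rows:
        table = [[ka, na - ka], [kb, nb - kb]]
        _, p = fisher_exact(table, alternative="two-sided")
        log_fc = float(np.log2(((ka + 0.5) / na) / ((kb + 0.5) / nb)))
        out[fam] = FamilyEnrichment(
            fam, (ka, na - ka, kb, nb - kb), float(p), np.nan, log_fc, False
        )
        ps.append(p)
    if ps:
        adj = bh_adjust(ps)
        for (fam, _, _), a in zip(rows, adj):
            out[fam].adj_p = float(a)
            out[fam].passed = bool(
                a < alpha and abs(out[fam].log_fc) > logfc_threshold
            )
    return out


def count_comparison(
    gene_presence: Mapping[str, Sequence[str] | frozenset[str]],
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
) -> tuple[dict[str, int], float]:
    """Per-genome family counts and a two-sided rank-sum p between groups."""
    a_ids = list(group_a_ids)
    b_ids = list(group_b_ids)
    if not a_ids or not b_ids:
        raise ValueError("both groups must be nonempty")
    counts = {g: len(gene_presence.get(g, ())) for g in a_ids + b_ids}
    _, p = rank_sum_test([counts[g] for g in a_ids], [counts[g] for g in b_ids])
    return counts, float(p)
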