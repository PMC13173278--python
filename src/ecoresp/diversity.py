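"""Alpha diversity, Bray-Curtis beta diversity, stratified PERMANOVA, PERMDISP.

PERMANOVA uses the standard partition of squared inter-point distances
(Gower-centered implicitly through the group sum-of-squares identity);
permutations shuffle labels only within strata, matching the design of a
multi-study collection where the dataset is the dominant source of
variation.  Monte-Carlo p-values use the +1 convention, so p > 0 always.

PERMDISP embeds the distance matrix by principal coordinates, keeping
negative eigenvalues as imaginary axes (squared distances to the group
centroid subtract the imaginary part, the usual correction), computes a
one-way ANOVA F on the per-sample centroid distances, and permutes group
labels for the p-value.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core_io import IntegrityError, OguCountTable


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise IntegrityError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise IntegrityError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise IntegrityError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise IntegrityError("distances must be non-negative")


@dataclass
class PermTestResult:
    statistic: float
    r_squared: float
    p_value: float
    n_permutations: int
    strata_used: bool


def shannon(abundances: Sequence[float]) -> float:
    """Shannon index H = -sum p_i ln p_i over positive proportions (natural log)."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero profile")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(table: OguCountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on the table rows as given (counts or TSS)."""
    zero_rows = np.flatnonzero(table.values.sum(axis=1) <= 0)
    if zero_rows.size:
        ids = [table.sample_ids[i] for i in zero_rows]
        raise IntegrityError(f"Bray-Curtis undefined for all-zero samples: {ids}")
    d = squareform(pdist(table.values, metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0 or ss_within <= 0:
        return np.inf, ss_among / ss_total if ss_total > 0 else 0.0
    f = (ss_among / df_among) / (ss_within / df_within)
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2)


def _within_stratum_permutations(codes, strata_codes):
    """All distinct label arrangements obtained by permuting within strata."""
    n = codes.size
    per_stratum: list[list[tuple[int, ...]]] = []
    idx_lists: list[np.ndarray] = []
    for s in np.unique(strata_codes):
        idx = np.flatnonzero(strata_codes == s)
        idx_lists.append(idx)
        per_stratum.append(sorted(set(itertools.permutations(codes[idx]))))
    for combo in itertools.product(*per_stratum):
        perm = np.empty(n, dtype=codes.dtype)
        for idx, labs in zip(idx_lists, combo):
            perm[idx] = labs
        yield perm


def permanova_stratified(
    dist: DistanceMatrix,
    labels: Sequence[str],
    strata: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "monte_carlo",
) -> PermTestResult:
    """PERMANOVA with permutations restricted to strata.

    ``strata=None`` (or a single stratum) reduces to plain PERMANOVA.
    ``method='exact'`` enumerates all distinct within-stratum label
    arrangements instead of sampling (only feasible for small n); the exact
    p is the fraction of arrangements, observed included, with F >= F_obs.
    """
    labels = np.asarray(labels, dtype=object)
    n = len(dist.sample_ids)
    if labels.size != n:
        raise ValueError("labels must cover all samples")
    if strata is None:
        strata_codes = np.zeros(n, dtype=int)
        strata_used = False
    else:
        strata_arr = np.asarray(strata, dtype=object)
        if strata_arr.size != n:
            raise ValueError("strata must cover all samples")
        _, strata_codes = np.unique(strata_arr, return_inverse=True)
        strata_used = True
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least two label levels")

    free = 0
    for s in np.unique(strata_codes):
        levels = np.unique(codes[strata_codes == s])
        if levels.size > 1:
            free += 1
        else:
            warnings.warn(
                f"stratum {s} has a single label level and contributes no "
                "permutation freedom",
                stacklevel=2,
            )
    if free == 0:
        raise ValueError("all strata are degenerate: no permutation freedom")

    d2 = dist.values**2
    f_obs, r2 = _pseudo_f(d2, codes, uniq.size)

    if method == "exact":
        total = 0
        ge = 0
        for perm in _within_stratum_permutations(codes, strata_codes):
            f_p, _ = _pseudo_f(d2, perm, uniq.size)
            total += 1
            if f_p >= f_obs - 1e-12:
                ge += 1
        return PermTestResult(f_obs, r2, ge / total, total, strata_used)

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    ge = 0
    perm = codes.copy()
    stratum_idx = [np.flatnonzero(strata_codes == s) for s in np.unique(strata_codes)]
    for _ in range(n_perm):
        for idx in stratum_idx:
            perm[idx] = codes[idx][rng.permutation(idx.size)]
        f_p, _ = _pseudo_f(d2, perm, uniq.size)
        if f_p >= f_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_perm)
    return PermTestResult(f_obs, r2, p, n_perm, strata_used)


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------


def _pcoa_coords(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding split into real and imaginary axes."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-10 * max(1.0, np.abs(vals).max())
    pos = vals > tol
    neg = vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


def _centroid_distances(real, imag, codes, n_groups) -> np.ndarray:
    out = np.empty(codes.size)
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        cr = real[idx].mean(axis=0)
        ci = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        d2 = ((real[idx] - cr) ** 2).sum(axis=1)
        if imag.size:
            d2 = d2 - ((imag[idx] - ci) ** 2).sum(axis=1)
        out[idx] = np.sqrt(np.clip(d2, 0.0, None))
    return out


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df_b = n_groups - 1
    df_w = values.size - n_groups
    eps = 1e-12 * values.size * max(1.0, float((values**2).max()))
    if ss_within <= eps:
        return np.inf if ss_between > eps else 0.0
    return float((ss_between / df_b) / (ss_within / df_w))


def permdisp(
    dist: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermTestResult:
    """Homogeneity of multivariate dispersions (centroid variant).

    Per permutation the group assignment is shuffled and the distances to
    the (new) group centroids recomputed in the fixed PCoA space.
    """
    groups = np.asarray(groups, dtype=object)
    n = len(dist.sample_ids)
    if groups.size != n:
        raise ValueError("groups must cover all samples")
    uniq, codes = np.unique(groups, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(uniq[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups of size 1 are not allowed: {small}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    real, imag = _pcoa_coords(dist.values)
    d_obs = _centroid_distances(real, imag, codes, uniq.size)
    f_obs = _anova_f(d_obs, codes, uniq.size)

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = codes[rng.permutation(n)]
        d_p = _centroid_distances(real, imag, perm, uniq.size)
        if _anova_f(d_p, perm, uniq.size) >= f_obs - 1e-12:
            ge += 1
    # r_squared repurposed as between-group fraction of dispersion variance
    grand = d_obs.mean()
    ssb = sum(
        (codes == g).sum() * (d_obs[codes == g].mean() - grand) ** 2
        for g in range(uniq.size)
    )
    sst = ((d_obs - grand) ** 2).sum()
    r2 = float(ssb / sst) if sst > 0 else 0.0
    return PermTestResult(f_obs, r2, (1 + ge) / (1 + n_perm), n_perm, False)
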