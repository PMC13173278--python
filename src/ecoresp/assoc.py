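"""Mixed-model association, effect sizes, permutation nulls, prevalence link.

The workhorse is the single-random-intercept linear mixed model
``y ~ X beta + (1 | group)`` fitted by REML.  The public :func:`fit_lmm`
uses statsmodels' MixedLM with normal-approximation Wald p-values (the df
method is recorded in ``fit_method``).  Resampling procedures — the
within-group permutation test and the two-stage case bootstrap — need
tens of thousands of refits, so they run on a profiled 1-D REML solver for
the same model (exact for the single-intercept structure; cross-checked
against MixedLM in the test suite).

The prevalence-association analysis reproduces the two-model
residualization: the differential is regressed on mean relative abundance
with dataset as a *fixed* factor, prevalence is regressed on mean relative
abundance with dataset as a *random* intercept, and the Spearman
correlation plus linear slope of the two residual sets estimate the
prevalence-response link net of abundance and study origin.  The
permutation null shuffles response labels within datasets and propagates
them through re-fitted differentials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.optimize import minimize_scalar

from .core_io import (
    OguCountTable,
    OguMetadata,
    PrevalenceProfile,
    SampleMetadata,
    VALID_SOURCE_FLAGS,
    spearman,
)
from .diffrank import DifferentialTable, fit_differentials


# ---------------------------------------------------------------------------
# fast profiled REML for y ~ X beta + (1 | group)
# ---------------------------------------------------------------------------


class _RemlFit:
    __slots__ = ("beta", "se", "sigma_g2", "sigma_e2", "fitted_fixed", "resid")

    def __init__(self, beta, se, sigma_g2, sigma_e2, fitted_fixed, resid):
        self.beta = beta
        self.se = se
        self.sigma_g2 = sigma_g2
        self.sigma_e2 = sigma_e2
        self.fitted_fixed = fitted_fixed
        self.resid = resid


def _group_blocks(groups: np.ndarray) -> list[np.ndarray]:
    uniq = pd.unique(groups)
    return [np.flatnonzero(groups == g) for g in uniq]


def _reml_random_intercept(
    y: np.ndarray, x: np.ndarray, blocks: Sequence[np.ndarray]
) -> _RemlFit:
    """Profiled REML for a single random intercept.

    For V = sigma_e^2 (I + lam Z Z') the inverse is block diagonal with
    V_g^{-1} = I - lam/(1 + n_g lam) J, so all GLS quantities reduce to
    per-group sums and the REML criterion is a 1-D function of log(lam).
    """
    n, p = x.shape
    ng = np.array([b.size for b in blocks])
    sx = np.stack([x[b].sum(axis=0) for b in blocks])  # (G, p)
    sy = np.array([y[b].sum() for b in blocks])
    xtx = x.T @ x
    xty = x.T @ y
    yty = y @ y

    def criterion(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = lam / (1.0 + ng * lam)
        a = xtx - (sx.T * w) @ sx
        b = xty - sx.T @ (w * sy)
        c = yty - (w * sy * sy).sum()
        try:
            beta = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            return np.inf
        rss = c - b @ beta
        if rss <= 0:
            return np.inf
        sign, logdet_a = np.linalg.slogdet(a)
        if sign <= 0:
            return np.inf
        return (
            np.log1p(ng * lam).sum() + logdet_a + (n - p) * np.log(rss)
        )

    res = minimize_scalar(criterion, bounds=(-12.0, 12.0), method="bounded")
    lam = float(np.exp(res.x))
    if criterion(np.log(max(lam, 1e-300))) > criterion(-30.0):  # boundary: no group var
        lam = 0.0
    w = lam / (1.0 + ng * lam) if lam > 0 else np.zeros(len(blocks))
    a = xtx - (sx.T * w) @ sx
    b = xty - sx.T @ (w * sy)
    c = yty - (w * sy * sy).sum()
    beta = np.linalg.solve(a, b)
    rss = max(c - b @ beta, 1e-300)
    sigma_e2 = rss / (n - p)
    sigma_g2 = lam * sigma_e2
    cov = sigma_e2 * np.linalg.inv(a)
    se = np.sqrt(np.diag(cov))
    fitted = x @ beta
    # conditional residuals: subtract the BLUP of each group intercept
    resid = y - fitted
    if lam > 0:
        for b_idx, w_g in zip(blocks, lam / (1.0 + ng * lam)):
            resid[b_idx] -= w_g * resid[b_idx].sum()
    return _RemlFit(beta, se, float(sigma_g2), float(sigma_e2), fitted, resid)


# ---------------------------------------------------------------------------
# public LMM surface
# ---------------------------------------------------------------------------


@dataclass
class FixedEffect:
    term: str
    estimate: float
    se: float
    p_value: float
    df_method: str


@dataclass
class LmmFit:
    fixed_effects: dict[str, FixedEffect]
    random_intercept_variance: float
    residual_variance: float
    icc: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    fit_method: str


def _as_design(fixed: pd.DataFrame | Mapping[str, Sequence[float]]) -> pd.DataFrame:
    df = pd.DataFrame(fixed).astype(float)
    if df.isna().any().any():
        raise ValueError("fixed-effect design contains missing values")
    return df


def fit_lmm(
    outcome: Sequence[float],
    fixed: pd.DataFrame | Mapping[str, Sequence[float]],
    group: Sequence[str],
) -> LmmFit:
    """REML linear mixed model with a single random intercept.

    ``fixed`` holds named covariate columns (no intercept column; one is
    added).  With a single group the model degenerates and an ordinary
    least-squares fit is returned, flagged in ``fit_method``.  Marginal and
    conditional R^2 follow the variance-partition convention
    var(fixed) / (var(fixed) + var(group) + var(resid)), the conditional
    version adding the group variance to the numerator.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    xdf = _as_design(fixed)
    groups = np.asarray(group, dtype=object)
    if y.size != len(xdf) or y.size != groups.size:
        raise ValueError("outcome, fixed and group must have equal length")
    exog = sm.add_constant(xdf, has_constant="add")
    if np.linalg.matrix_rank(exog.values) < exog.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    n_groups = len(pd.unique(groups))
    terms = [c for c in exog.columns if c != "const"]

    if n_groups < 2:
        ols = sm.OLS(y, exog).fit()
        var_f = float(np.var(exog[terms].values @ ols.params[terms].values)) if terms else 0.0
        var_e = float(ols.mse_resid)
        fx = {
            t: FixedEffect(t, float(ols.params[t]), float(ols.bse[t]),
                           float(ols.pvalues[t]), "t")
            for t in terms
        }
        denom = var_f + var_e
        return LmmFit(
            fixed_effects=fx,
            random_intercept_variance=0.0,
            residual_variance=var_e,
            icc=0.0,
            r2_marginal=var_f / denom if denom > 0 else 0.0,
            r2_conditional=var_f / denom if denom > 0 else 0.0,
            n_obs=int(y.size),
            n_groups=n_groups,
            fit_method="ols_single_group_fallback",
        )

    fit_method = "reml_mixedlm_normal_approx"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=groups)
            fit = model.fit(reml=True, method="lbfgs")
        var_g = float(np.atleast_2d(np.asarray(fit.cov_re))[0, 0])
        var_e = float(fit.scale)
        estimates = {t: float(fit.params[t]) for t in terms}
        ses = {t: float(fit.bse[t]) for t in terms}
        if not all(np.isfinite(v) for v in ses.values()):
            raise np.linalg.LinAlgError("non-finite standard errors")
    except (np.linalg.LinAlgError, ValueError):
        # MixedLM can fail near the variance boundary on small cohorts; the
        # profiled solver handles the boundary exactly
        cols = [c for c in exog.columns]
        x = exog.values
        fast = _reml_random_intercept(y, x, _group_blocks(groups))
        var_g, var_e = fast.sigma_g2, fast.sigma_e2
        estimates = {t: float(fast.beta[cols.index(t)]) for t in terms}
        ses = {t: float(fast.se[cols.index(t)]) for t in terms}
        fit_method = "reml_profiled_normal_approx"
    fx = {}
    for t in terms:
        est, se = estimates[t], ses[t]
        p = float(2 * _sps.norm.sf(abs(est / se))) if se > 0 else np.nan
        fx[t] = FixedEffect(t, est, se, p, "normal_approximation")
    beta_vec = np.array([estimates[t] for t in terms])
    var_f = float(np.var(exog[terms].values @ beta_vec)) if terms else 0.0
    denom = var_f + var_g + var_e
    return LmmFit(
        fixed_effects=fx,
        random_intercept_variance=var_g,
        residual_variance=var_e,
        icc=var_g / (var_g + var_e) if var_g + var_e > 0 else 0.0,
        r2_marginal=var_f / denom if denom > 0 else 0.0,
        r2_conditional=(var_f + var_g) / denom if denom > 0 else 0.0,
        n_obs=int(y.size),
        n_groups=n_groups,
        fit_method=fit_method,
    )


def cohens_d(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float, float]:
    """Pooled-SD Cohen's d of group A minus group B with a normal-approx CI."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    d = (a.mean() - b.mean()) / pooled
    se = np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb)))
    return float(d), float(d - 1.959963984540054 * se), float(d + 1.959963984540054 * se)


def case_bootstrap_ci(
    outcome: Sequence[float],
    fixed: pd.DataFrame | Mapping[str, Sequence[float]],
    group: Sequence[str],
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Two-stage case bootstrap percentile CI for each fixed-effect term.

    Groups are resampled with replacement, then observations within each
    sampled group; the model is refitted per replicate.  Replicates whose
    refit fails are dropped and counted under the ``"_n_failed"`` key.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y = np.asarray(outcome, dtype=float)
    xdf = _as_design(fixed)
    groups = np.asarray(group, dtype=object)
    terms = list(xdf.columns)
    x = np.column_stack([np.ones(y.size), xdf.values])
    blocks = _group_blocks(groups)
    rng = np.random.default_rng(seed)
    draws: list[np.ndarray] = []
    failed = 0
    for _ in range(n_boot):
        picked = rng.integers(0, len(blocks), size=len(blocks))
        rows = []
        new_blocks = []
        offset = 0
        for g in picked:
            b = blocks[g]
            take = b[rng.integers(0, b.size, size=b.size)]
            rows.append(take)
            new_blocks.append(np.arange(offset, offset + b.size))
            offset += b.size
        idx = np.concatenate(rows)
        try:
            fit = _reml_random_intercept(y[idx], x[idx], new_blocks)
            if not np.all(np.isfinite(fit.beta)):
                raise FloatingPointError
            draws.append(fit.beta[1:])
        except (np.linalg.LinAlgError, FloatingPointError):
            failed += 1
    arr = np.asarray(draws)
    lo = (1 - ci_level) / 2 * 100
    out: dict[str, tuple[float, float]] = {
        t: (
            float(np.percentile(arr[:, j], lo)),
            float(np.percentile(arr[:, j], 100 - lo)),
        )
        for j, t in enumerate(terms)
    }
    out["_n_failed"] = (failed, failed)
    return out


def permutation_test_lmm(
    outcome: Sequence[float],
    fixed_of_interest: Sequence[float],
    covariates: pd.DataFrame | Mapping[str, Sequence[float]] | None,
    group: Sequence[str],
    n_perm: int = 200,
    seed: int | None = None,
) -> float:
    """Within-group permutation p for one fixed effect of the mixed model.

    The covariate of interest is shuffled within each group, the model
    refitted, and its coefficient recorded; p = (1 + #{|b_perm| >= |b_obs|})
    / (1 + n_perm).  Groups too small to permute contribute identity
    permutations (warned).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(outcome, dtype=float)
    v = np.asarray(fixed_of_interest, dtype=float)
    groups = np.asarray(group, dtype=object)
    cov = _as_design(covariates) if covariates is not None else None
    cov_mat = cov.values if cov is not None else np.empty((y.size, 0))
    blocks = _group_blocks(groups)
    for b in blocks:
        if b.size < 2:
            warnings.warn(
                "a group has < 2 observations and contributes only identity "
                "permutations",
                stacklevel=2,
            )

    def coef_for(vv: np.ndarray) -> float:
        x = np.column_stack([np.ones(y.size), vv, cov_mat])
        return float(_reml_random_intercept(y, x, blocks).beta[1])

    b_obs = abs(coef_for(v))
    rng = np.random.default_rng(seed)
    ge = 0
    vp = v.copy()
    for _ in range(n_perm):
        for b in blocks:
            if b.size > 1:
                vp[b] = v[b][rng.permutation(b.size)]
        if abs(coef_for(vp)) >= b_obs - 1e-12:
            ge += 1
    return (1 + ge) / (1 + n_perm)


# ---------------------------------------------------------------------------
# prevalence-association analysis
# ---------------------------------------------------------------------------


@dataclass
class ThresholdPoint:
    cutoff: int
    n_taxa: int
    rho: float | None
    p_value: float | None
    stable: bool


@dataclass
class PrevalenceAssoc:
    rho: float
    p_value: float
    estimate: float
    covariates_removed: list[str]
    threshold_curve: list[ThresholdPoint]
    permutation_p: float | None
    n_permutations: int
    mode: str
    n_pairs: int


def _residual_pair(
    coef: np.ndarray,
    prevalence: np.ndarray,
    relabund: np.ndarray,
    dataset: np.ndarray | None,
    completeness: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """The two residual sets of the partial-correlation construction.

    Differential ~ relabund (+ completeness) + dataset-as-fixed-factor (OLS);
    prevalence ~ relabund (+ completeness) + dataset-as-random-intercept
    (REML, conditional residuals).  Without a dataset dimension both models
    are plain OLS.
    """
    extra = [relabund]
    if completeness is not None:
        extra.append(completeness)
    base = np.column_stack([np.ones(coef.size)] + extra)
    if dataset is not None:
        uniq = pd.unique(dataset)
        dummies = np.column_stack(
            [(dataset == d).astype(float) for d in uniq[1:]]
        ) if len(uniq) > 1 else np.empty((coef.size, 0))
        x_fixed = np.column_stack([base, dummies])
        beta, *_ = np.linalg.lstsq(x_fixed, coef, rcond=None)
        res_coef = coef - x_fixed @ beta
        blocks = _group_blocks(dataset)
        res_prev = _reml_random_intercept(
            prevalence.astype(float), base, blocks
        ).resid
    else:
        beta, *_ = np.linalg.lstsq(base, coef, rcond=None)
        res_coef = coef - base @ beta
        beta2, *_ = np.linalg.lstsq(base, prevalence.astype(float), rcond=None)
        res_prev = prevalence - base @ beta2
    return res_coef, res_prev


def _pairs_frame(
    diff: DifferentialTable,
    profiles: Mapping[str, PrevalenceProfile],
    mode: str,
    completeness_of: Mapping[str, float] | None,
) -> pd.DataFrame:
    rows = []
    if mode == "per_pair":
        for ds in diff.fitted_datasets():
            col = diff.coef[ds].dropna()
            for ogu, c in col.items():
                pr = profiles[ogu]
                rows.append(
                    {
                        "ogu_id": ogu,
                        "dataset": ds,
                        "coef": float(c),
                        "prevalence": pr.sample_prevalence,
                        "relabund": pr.mean_relabund,
                    }
                )
    elif mode == "mean":
        means = diff.coef[diff.fitted_datasets()].mean(axis=1, skipna=True).dropna()
        for ogu, c in means.items():
            pr = profiles[ogu]
            rows.append(
                {
                    "ogu_id": ogu,
                    "dataset": None,
                    "coef": float(c),
                    "prevalence": pr.sample_prevalence,
                    "relabund": pr.mean_relabund,
                }
            )
    else:
        raise ValueError("mode must be 'per_pair' or 'mean'")
    df = pd.DataFrame(rows)
    if completeness_of is not None:
        df["completeness"] = df["ogu_id"].map(completeness_of)
    return df


def prevalence_association(
    diff: DifferentialTable,
    profiles: Mapping[str, PrevalenceProfile],
    completeness_of: Mapping[str, float] | None = None,
    mode: str = "per_pair",
    thresholds: Sequence[int] = (1, 2, 3, 4, 5, 10, 20, 30, 40, 50),
    n_perm: int = 0,
    seed: int | None = None,
    counts: OguCountTable | None = None,
    meta: Mapping[str, SampleMetadata] | None = None,
    reg_strength: float = 1.0,
    min_taxa: int = 10,
) -> PrevalenceAssoc:
    """Prevalence-differential association net of abundance and study origin.

    ``mode='per_pair'`` uses one (OGU, dataset) coefficient per fitted
    dataset; ``mode='mean'`` collapses to the mean coefficient per OGU (no
    dataset term in the residualization).  ``completeness_of`` adds genome
    completeness to both residual-extraction models.  The permutation null
    (``n_perm > 0``, requires ``counts`` and ``meta``) shuffles response
    labels within each dataset, refits the differentials, and recomputes
    the residual Spearman rho.
    """
    df = _pairs_frame(diff, profiles, mode, completeness_of)
    if len(df) < min_taxa:
        raise ValueError("too few (OGU, dataset) pairs for a stable estimate")
    thresholds = sorted(set(int(t) for t in thresholds))

    def residual_stats(frame: pd.DataFrame):
        res_c, res_p = _residual_pair(
            frame["coef"].values,
            frame["prevalence"].values.astype(float),
            frame["relabund"].values,
            frame["dataset"].values if mode == "per_pair" else None,
            frame["completeness"].values if "completeness" in frame else None,
        )
        rho, p = spearman(res_p, res_c)
        slope = float(np.polyfit(res_p, res_c, 1)[0])
        return rho, p, slope

    rho, p, slope = residual_stats(df)

    curve: list[ThresholdPoint] = []
    for cut in thresholds:
        sub = df[df["prevalence"] >= cut]
        if sub["ogu_id"].nunique() < min_taxa:
            curve.append(ThresholdPoint(cut, int(sub["ogu_id"].nunique()), None, None, False))
            continue
        r_c, p_c, _ = residual_stats(sub)
        curve.append(ThresholdPoint(cut, int(sub["ogu_id"].nunique()), r_c, p_c, True))

    perm_p = None
    if n_perm > 0:
        if counts is None or meta is None:
            raise ValueError("the permutation null needs counts and meta")
        rng = np.random.default_rng(seed)
        ds_of = np.asarray([meta[s].dataset_id for s in counts.sample_ids], dtype=object)
        resp = np.asarray([meta[s].response for s in counts.sample_ids], dtype=object)
        blocks = _group_blocks(ds_of)
        ge = 0
        for _ in range(n_perm):
            shuffled = resp.copy()
            for b in blocks:
                shuffled[b] = resp[b][rng.permutation(b.size)]
            meta_p = {
                s: SampleMetadata(
                    sample_id=s,
                    dataset_id=meta[s].dataset_id,
                    response=shuffled[i],
                    cancer_type=meta[s].cancer_type,
                )
                for i, s in enumerate(counts.sample_ids)
            }
            diff_p = fit_differentials(counts, meta_p, reg_strength=reg_strength)
            df_p = _pairs_frame(diff_p, profiles, mode, completeness_of)
            rho_p, _, _ = residual_stats(df_p)
            if abs(rho_p) >= abs(rho) - 1e-12:
                ge += 1
        perm_p = (1 + ge) / (1 + n_perm)

    removed = ["mean_relabund"] + (["completeness"] if completeness_of else []) + (
        ["dataset"] if mode == "per_pair" else []
    )
    return PrevalenceAssoc(
        rho=rho,
        p_value=p,
        estimate=slope,
        covariates_removed=removed,
        threshold_curve=curve,
        permutation_p=perm_p,
        n_permutations=n_perm,
        mode=mode,
        n_pairs=len(df),
    )


# ---------------------------------------------------------------------------
# exogenous burden
# ---------------------------------------------------------------------------


def exogenous_burden(
    table: OguCountTable,
    ogu_meta: Mapping[str, OguMetadata],
    flags: Sequence[str] = ("oral", "food"),
) -> pd.Series:
    """Per-sample summed relative abundance of source-flagged OGUs.

    The table must be TSS-normalized; burdens lie in [0, 1] and grow
    monotonically as flags are added.
    """
    flagset = frozenset(flags)
    unknown = flagset - VALID_SOURCE_FLAGS
    if unknown:
        raise ValueError(f"unknown source flags: {sorted(unknown)}")
    if not table.is_relative:
        raise ValueError("exogenous_burden requires a TSS-normalized table")
    idx = [
        j
        for j, o in enumerate(table.ogu_ids)
        if o in ogu_meta and ogu_meta[o].source_flags & flagset
    ]
    burden = (
        table.values[:, idx].sum(axis=1) if idx else np.zeros(table.n_samples)
    )
    return pd.Series(burden, index=table.sample_ids, name="exogenous_burden")
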