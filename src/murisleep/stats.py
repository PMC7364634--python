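"""Longitudinal group statistics.

The repeated-measures model is a cell-means (profile) fit of group x age
with an unstructured within-animal covariance across ages, estimated from
residual cross-products (pairwise-complete over missing weeks). Least-
squares means are the model cell means. Pairwise group contrasts at each age
use Kramer's unequal-n standard error and the studentized-range distribution
with k = number of groups; by default the adjustment additionally applies a
Bonferroni factor across ages so the declared family -- all group pairs at
all ages (42 for 4 groups x 7 ages) -- is jointly controlled. Outcomes
analysed on the log scale are back-transformed to multiplicative ratios.

Terminal measures use classical one-way ANOVA with Tukey(-Kramer) HSD, and
atrophy correlations use Spearman rank correlation either on raw ("actual")
values pooled across groups or on within-group mean-centred ("residual")
values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as st

__all__ = [
    "ModelFit",
    "ContrastResult",
    "AnovaResult",
    "CorrelationResult",
    "fit_repeated_measures",
    "pairwise_contrasts",
    "back_transform",
    "one_way_anova",
    "correlate_with_atrophy",
    "simulate_null_fwer",
]


@dataclass
class ModelFit:
    outcome: str
    scale: str  # "raw" or "log"
    groups: tuple[str, ...]
    ages: tuple[float, ...]
    cell_means: np.ndarray  # (n_groups, n_ages), NaN for empty cells
    cell_n: np.ndarray  # (n_groups, n_ages) ints
    covariance: np.ndarray  # (n_ages, n_ages) pooled within-animal
    df_by_age: np.ndarray  # residual df per age


@dataclass
class ContrastResult:
    group_a: str
    group_b: str
    age_week: float
    estimate: float  # difference (log difference for log-scale outcomes)
    se: float
    p_unadjusted: float
    p_adjusted: float
    significant: bool
    scale: str
    df: float
    n_groups: int
    family_size: int
    alpha: float
    alpha_effective: float


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p: float
    posthoc: dict[tuple[str, str], float]  # pair -> Tukey-adjusted p


@dataclass
class CorrelationResult:
    outcome: str
    mode: str  # "actual" or "residual"
    rs: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# repeated measures


def _fit_wide(
    wide_by_group: Mapping[str, np.ndarray], pairwise_complete: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core cell-means + covariance estimation.

    ``wide_by_group[g]`` is an (n_animals, n_ages) array with NaN for missing
    weeks. Returns (cell_means, cell_n, covariance, df_by_age).
    """
    groups = list(wide_by_group)
    k = len(groups)
    n_ages = next(iter(wide_by_group.values())).shape[1]
    means = np.full((k, n_ages), np.nan)
    ns = np.zeros((k, n_ages), dtype=int)
    resid_blocks = []
    for gi, g in enumerate(groups):
        x = np.asarray(wide_by_group[g], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(x, axis=0)
        n = np.sum(~np.isnan(x), axis=0)
        means[gi] = m
        ns[gi] = n
        resid_blocks.append(x - m[None, :])
    resid = np.vstack(resid_blocks)
    if not pairwise_complete:
        resid = resid[~np.isnan(resid).any(axis=1)]
    cov = np.full((n_ages, n_ages), np.nan)
    for a in range(n_ages):
        for b in range(a, n_ages):
            ok = ~np.isnan(resid[:, a]) & ~np.isnan(resid[:, b])
            n_ok = int(ok.sum())
            denom = n_ok - k
            if denom > 0:
                cov[a, b] = cov[b, a] = float(
                    np.sum(resid[ok, a] * resid[ok, b]) / denom
                )
    df_by_age = ns.sum(axis=0) - (ns > 0).sum(axis=0)
    return means, ns, cov, df_by_age.astype(float)


def fit_repeated_measures(
    table: pd.DataFrame,
    outcome: str,
    log_scale: bool = False,
    *,
    photoperiod: str | None = None,
    pairwise_complete: bool = True,
) -> ModelFit:
    """Fit the group x age cell-means model to one outcome.

    ``table`` is long format with columns animal_id, group, age_week,
    photoperiod (optional), outcome, value. With balanced complete data the
    LS means equal the arithmetic cell means exactly. ``log_scale`` requires
    strictly positive values and analyses natural logs.
    """
    df = table[table["outcome"] == outcome] if "outcome" in table.columns else table
    if photoperiod is not None and "photoperiod" in df.columns:
        df = df[df["photoperiod"] == photoperiod]
    elif "photoperiod" in df.columns and df["photoperiod"].nunique() > 1:
        raise ValueError("table mixes photoperiods; pass photoperiod=...")
    if df.empty:
        raise ValueError(f"no rows for outcome {outcome!r}")
    dup = df.duplicated(subset=["animal_id", "age_week"])
    if dup.any():
        raise ValueError("multiple values per animal x age")
    vals = df["value"].to_numpy(dtype=float)
    if log_scale:
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("log-scale analysis requires strictly positive values")
    groups = tuple(sorted(df["group"].unique()))
    ages = tuple(sorted(df["age_week"].unique()))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    wide_by_group: dict[str, np.ndarray] = {}
    for g in groups:
        sub = df[df["group"] == g]
        animals = sorted(sub["animal_id"].unique())
        x = np.full((len(animals), len(ages)), np.nan)
        amap = {a: i for i, a in enumerate(animals)}
        wmap = {w: i for i, w in enumerate(ages)}
        for _, row in sub.iterrows():
            v = float(row["value"])
            x[amap[row["animal_id"]], wmap[row["age_week"]]] = np.log(v) if log_scale else v
        wide_by_group[g] = x
    means, ns, cov, dfa = _fit_wide(wide_by_group, pairwise_complete)
    return ModelFit(
        outcome=outcome,
        scale="log" if log_scale else "raw",
        groups=groups,
        ages=ages,
        cell_means=means,
        cell_n=ns,
        covariance=cov,
        df_by_age=dfa,
    )


def _contrasts_from_fit(
    fit: ModelFit, alpha: float, family: str
) -> list[ContrastResult]:
    k = len(fit.groups)
    n_ages = len(fit.ages)
    pairs = list(combinations(range(k), 2))
    family_size = len(pairs) * n_ages
    n_families = n_ages if family == "all" else 1
    alpha_eff = alpha / n_families
    diag = np.diag(fit.covariance)
    if np.any(~np.isfinite(diag)) or np.any(diag <= 0):
        # compound-symmetry fallback: common variance and covariance
        warnings.warn("singular covariance estimate; falling back to compound symmetry")
        finite = np.isfinite(fit.covariance)
        var = float(np.nanmean(np.diag(fit.covariance)[np.isfinite(diag)]))
        off = fit.covariance[~np.eye(n_ages, dtype=bool) & finite]
        rho = float(np.mean(off)) if off.size else 0.0
        cov = np.full((n_ages, n_ages), rho)
        np.fill_diagonal(cov, var)
        diag = np.diag(cov)
    out: list[ContrastResult] = []
    for ai, age in enumerate(fit.ages):
        var_a = diag[ai]
        dfr = fit.df_by_age[ai]
        for gi, gj in pairs:
            n1, n2 = fit.cell_n[gi, ai], fit.cell_n[gj, ai]
            m1, m2 = fit.cell_means[gi, ai], fit.cell_means[gj, ai]
            if n1 == 0 or n2 == 0 or not np.isfinite(m1) or not np.isfinite(m2):
                warnings.warn(
                    f"empty cell for {fit.groups[gi]} or {fit.groups[gj]} at week {age}; contrast skipped"
                )
                continue
            se = float(np.sqrt(var_a * (1.0 / n1 + 1.0 / n2)))
            diff = float(m1 - m2)
            if se == 0 or dfr <= 0:
                p_un = p_tukey = np.nan
            else:
                t = abs(diff) / se
                q = t * np.sqrt(2.0)
                p_un = float(2.0 * st.t.sf(t, dfr))
                p_tukey = float(st.studentized_range.sf(q, k, dfr))
            p_adj = min(1.0, p_tukey * n_families) if np.isfinite(p_tukey) else np.nan
            out.append(
                ContrastResult(
                    group_a=fit.groups[gi],
                    group_b=fit.groups[gj],
                    age_week=float(age),
                    estimate=diff,
                    se=se,
                    p_unadjusted=p_un,
                    p_adjusted=p_adj,
                    significant=bool(np.isfinite(p_adj) and p_adj < alpha),
                    scale=fit.scale,
                    df=float(dfr),
                    n_groups=k,
                    family_size=family_size,
                    alpha=alpha,
                    alpha_effective=alpha_eff,
                )
            )
    return out


def pairwise_contrasts(
    fit: ModelFit, alpha: float = 0.05, *, family: str = "all"
) -> list[ContrastResult]:
    """All group pairs at every age (the declared family: pairs x ages).

    ``family="all"`` (default) controls the whole family jointly
    (studentized range within age, Bonferroni across ages); ``family=
    "per_age"`` treats each age as its own nominal-level family.
    """
    if family not in ("all", "per_age"):
        raise ValueError("family must be 'all' or 'per_age'")
    return _contrasts_from_fit(fit, alpha, family)


@dataclass
class BackTransformed:
    ratio: float
    ci_low: float
    ci_high: float


def back_transform(contrast: ContrastResult) -> BackTransformed:
    """Back-transform a log-scale contrast to a multiplicative ratio with a
    simultaneous confidence interval at the contrast's effective level."""
    if contrast.scale != "log":
        raise ValueError("back_transform requires a log-scale contrast")
    if contrast.df > 0 and np.isfinite(contrast.se):
        q = st.studentized_range.ppf(1.0 - contrast.alpha_effective, contrast.n_groups, contrast.df)
        half = q / np.sqrt(2.0) * contrast.se
    else:
        half = np.nan
    return BackTransformed(
        ratio=float(np.exp(contrast.estimate)),
        ci_low=float(np.exp(contrast.estimate - half)),
        ci_high=float(np.exp(contrast.estimate + half)),
    )


# ---------------------------------------------------------------------------
# terminal measures


def one_way_anova(groups: Mapping[str, Sequence[float]], *, posthoc: bool = True) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD post hoc (Kramer for unequal
    group sizes). ``posthoc=False`` skips the pairwise comparisons."""
    names = list(groups)
    samples = [np.asarray(groups[g], dtype=float) for g in names]
    if len(samples) < 2 or any(s.size < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.var(s) == 0 for s in samples):
        raise ValueError("zero within-group variance everywhere; F undefined")
    f, p = st.f_oneway(*samples)
    posthoc_p: dict[tuple[str, str], float] = {}
    if posthoc:
        hsd = st.tukey_hsd(*samples)
        for i, j in combinations(range(len(names)), 2):
            posthoc_p[(names[i], names[j])] = float(hsd.pvalue[i, j])
    n_total = sum(s.size for s in samples)
    return AnovaResult(
        f_statistic=float(f),
        df_between=len(samples) - 1,
        df_within=n_total - len(samples),
        p=float(p),
        posthoc=posthoc_p,
    )


def correlate_with_atrophy(
    last_observations: Sequence[float],
    atrophy: Sequence[float],
    mode: str = "actual",
    *,
    groups: Sequence[str] | None = None,
    outcome: str = "",
    exact_below_n: int = 12,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman correlation of a final-week outcome against terminal
    thickness.

    ``actual`` pools raw pairs across groups; ``residual`` centres both
    variables by their group means first (rank correlation of within-group
    residuals), removing the contribution of group-mean shifts. For
    n < ``exact_below_n`` the p value comes from a permutation null.
    """
    x = np.asarray(last_observations, dtype=float)
    y = np.asarray(atrophy, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D")
    if x.size < 5:
        raise ValueError("need >= 5 paired observations")
    if mode == "residual":
        if groups is None:
            raise ValueError("residual mode requires group labels")
        g = np.asarray(groups)
        xr, yr = x.astype(float).copy(), y.astype(float).copy()
        for gv in np.unique(g):
            sel = g == gv
            xr[sel] -= xr[sel].mean()
            yr[sel] -= yr[sel].mean()
        x, y = xr, yr
    elif mode != "actual":
        raise ValueError("mode must be 'actual' or 'residual'")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in one of the variables; correlation undefined")
    if x.size < exact_below_n:
        res = st.spearmanr(x, y, alternative="two-sided")
        perm = st.permutation_test(
            (x, y),
            lambda a, b: st.spearmanr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=20000,
            rng=np.random.default_rng(seed),
        )
        rs, p = float(res.statistic), float(perm.pvalue)
    else:
        res = st.spearmanr(x, y)
        rs, p = float(res.statistic), float(res.pvalue)
    return CorrelationResult(outcome=outcome, mode=mode, rs=rs, p=p, n=int(x.size))


# ---------------------------------------------------------------------------
# calibration


def simulate_null_fwer(
    n_groups: int = 4,
    n_ages: int = 7,
    n_per_group: int = 12,
    n_reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    *,
    correlation: float = 0.3,
    family: str = "all",
) -> float:
    """Family-wise type-I error under the global null.

    Each replicate draws every animal's age profile from a common
    multivariate normal with heterogeneous variances and AR-like
    correlation, fits the cell-means model and counts a family-wise error
    when any adjusted contrast is significant. Returns the error fraction.
    """
    rng = np.random.default_rng(seed)
    variances = np.linspace(0.8, 1.5, n_ages)
    idx = np.arange(n_ages)
    corr = correlation ** np.abs(idx[:, None] - idx[None, :])
    cov = corr * np.sqrt(np.outer(variances, variances))
    chol = np.linalg.cholesky(cov)
    groups = [f"G{i}" for i in range(n_groups)]
    hits = 0
    for _ in range(n_reps):
        wide = {
            g: rng.standard_normal((n_per_group, n_ages)) @ chol.T for g in groups
        }
        means, ns, est_cov, dfa = _fit_wide(wide)
        fit = ModelFit(
            outcome="null",
            scale="raw",
            groups=tuple(groups),
            ages=tuple(float(a) for a in range(n_ages)),
            cell_means=means,
            cell_n=ns,
            covariance=est_cov,
            df_by_age=dfa,
        )
        res = _contrasts_from_fit(fit, alpha, family)
        if any(c.significant for c in res):
            hits += 1
    return hits / n_reps
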