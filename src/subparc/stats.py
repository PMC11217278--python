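"""Group-level statistical battery.

Per feature: Levene's test (median-centred) gates the route — ANCOVA with
covariate adjustment when variances are homogeneous, Kruskal-Wallis with
Dunn post hocs otherwise. Family-wise control is Bonferroni at a fixed,
explicit family size (default 96) with Benjamini-Hochberg as the liberal
alternative. Group-equivalence evidence uses a BIC-approximated Bayes
factor, and clinical associations use Spearman rank correlation with an
exact permutation p for small n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from subparc.errors import ConfigError, StatsPreconditionError

__all__ = [
    "GroupTestResult",
    "EquivalenceResult",
    "levene_gate",
    "ancova_group",
    "kruskal_dunn",
    "adjust_pvalues",
    "bayes_equivalence",
    "spearman_assoc",
    "run_battery",
    "ancova_f_many",
    "levene_routes",
    "omnibus_pvalues",
]

DEFAULT_FAMILY = 96


@dataclass
class PairwiseResult:
    groups: tuple[str, str]
    statistic: float  # t or Dunn z
    df: float | None
    p: float
    p_adj: float | None = None


@dataclass
class GroupTestResult:
    feature: str
    route: str  # "parametric" | "nonparametric"
    statistic: float  # F or H
    df: tuple[float, float] | tuple[float]
    mse: float | None
    eta_sq_p: float | None
    p: float
    p_adj: float | None
    levene_stat: float
    levene_p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    correction: str | None = None
    family_size: int | None = None


@dataclass
class EquivalenceResult:
    feature: str
    groups: tuple[str, str]
    bf10: float
    method: str = "BIC"


# ---------------------------------------------------------------------------
# Levene gate

def levene_gate(groups: list[np.ndarray], alpha: float = 0.05):
    """Median-centred Levene test; nonparametric route iff p < alpha."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise StatsPreconditionError("need >= 2 groups")
    for g in groups:
        if len(g) < 2:
            raise StatsPreconditionError("each group needs >= 2 observations")
    z = [np.abs(g - np.median(g)) for g in groups]
    if all(np.allclose(zi, 0.0) for zi in z):
        return "parametric", 0.0, 1.0
    stat, p = sps.levene(*groups, center="median")
    if np.isnan(stat):
        stat, p = 0.0, 1.0
    route = "nonparametric" if p < alpha else "parametric"
    return route, float(stat), float(p)


def levene_routes(Y: np.ndarray, group_idx: np.ndarray, alpha: float = 0.05):
    """Vectorised median-centred Levene over feature columns.

    Returns (nonparametric boolean mask, statistics, p-values).
    """
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    k = group_idx.max() + 1
    Z = np.empty_like(Y)
    for g in range(k):
        sel = group_idx == g
        Z[sel] = np.abs(Y[sel] - np.median(Y[sel], axis=0))
    grand = Z.mean(axis=0)
    ss_between = np.zeros(m)
    ss_within = np.zeros(m)
    for g in range(k):
        sel = group_idx == g
        zg = Z[sel]
        mg = zg.mean(axis=0)
        ss_between += sel.sum() * (mg - grand) ** 2
        ss_within += ((zg - mg) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = (n - k) / (k - 1) * ss_between / ss_within
    W = np.where(ss_within <= 0, 0.0, W)
    p = np.where(ss_within <= 0, 1.0, sps.f.sf(W, k - 1, n - k))
    return p < alpha, W, p


# ---------------------------------------------------------------------------
# design matrices

def _encode_covariates(cohort: pd.DataFrame, covariates) -> np.ndarray:
    cols = []
    for c in covariates:
        v = cohort[c]
        if v.dtype.kind in "OUSb" or str(v.dtype) == "category":
            levels = v.value_counts().index.tolist()  # reference = largest level
            for lev in levels[1:]:
                cols.append((v == lev).to_numpy(float))
        else:
            cols.append(v.to_numpy(float))
    n = len(cohort)
    X = np.column_stack([np.ones(n)] + cols) if cols else np.ones((n, 1))
    return X


def _group_dummies(group: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(group.unique())
    G = np.column_stack([(group == lev).to_numpy(float) for lev in levels[1:]])
    return G, levels


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify aliased columns by sequential rank growth
        aliased = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                aliased.append(names[j] if j < len(names) else f"col{j}")
            r = rj
        raise StatsPreconditionError(f"design matrix rank deficient; aliased: {aliased}")


# ---------------------------------------------------------------------------
# ANCOVA

def _sse(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid**2).sum(axis=0)


def ancova_f_many(
    Y: np.ndarray, Xr: np.ndarray, G: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[int, int], np.ndarray, np.ndarray]:
    """Vectorised omnibus Group F over feature columns.

    Returns (F, p, (df1, df2), mse, partial eta squared).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Xf = np.column_stack([Xr, G])
    sse_r = _sse(Xr, Y)
    sse_f = _sse(Xf, Y)
    df1 = G.shape[1]
    df2 = Y.shape[0] - Xf.shape[1]
    ss_group = np.maximum(sse_r - sse_f, 0.0)
    mse = sse_f / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_group / df1) / mse
        eta = ss_group / (ss_group + sse_f)
    F = np.where(mse <= 0, 0.0, F)
    p = np.where(mse <= 0, 1.0, sps.f.sf(F, df1, df2))
    return F, p, (df1, df2), mse, eta


def ancova_group(
    y: np.ndarray,
    group: pd.Series,
    covariates: pd.DataFrame | None = None,
    covariate_names=("age", "sex"),
    feature: str = "",
    contrast_df: str = "pairwise",
) -> GroupTestResult:
    """Omnibus Group ANCOVA by nested model comparison, with pairwise
    covariate-adjusted contrasts.

    ``contrast_df="pairwise"`` reports contrast df as n1+n2-2 (as printed
    in classical outputs); ``"model"`` uses the full-model residual df.
    """
    y = np.asarray(y, dtype=float)
    group = pd.Series(np.asarray(group))
    if covariates is not None:
        use = [c for c in covariate_names if c in covariates.columns]
        Xr = _encode_covariates(covariates, use)
        names = ["intercept"] + list(use)
    else:
        Xr = np.ones((len(y), 1))
        names = ["intercept"]
    G, levels = _group_dummies(group)
    Xf = np.column_stack([Xr, G])
    _check_rank(Xf, names + [f"group[{lev}]" for lev in levels[1:]])

    F, p, (df1, df2), mse, eta = ancova_f_many(y[:, None], Xr, G)
    F, p, mse, eta = float(F[0]), float(p[0]), float(mse[0]), float(eta[0])

    beta, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    xtx_inv = np.linalg.pinv(Xf.T @ Xf)
    k0 = Xr.shape[1]
    pairwise = []
    for i, j in itertools.combinations(range(len(levels)), 2):
        c = np.zeros(Xf.shape[1])
        if i > 0:
            c[k0 + i - 1] = 1.0
        if j > 0:
            c[k0 + j - 1] -= 1.0
        diff = float(c @ beta)
        se = float(np.sqrt(mse * c @ xtx_inv @ c))
        t = diff / se if se > 0 else 0.0
        n_pair = int((group == levels[i]).sum() + (group == levels[j]).sum())
        df_pair = n_pair - 2 if contrast_df == "pairwise" else df2
        p_pair = 2.0 * sps.t.sf(abs(t), df_pair)
        pairwise.append(PairwiseResult((levels[i], levels[j]), t, df_pair, float(p_pair)))
    return GroupTestResult(
        feature=feature,
        route="parametric",
        statistic=F,
        df=(df1, df2),
        mse=mse,
        eta_sq_p=eta,
        p=p,
        p_adj=None,
        levene_stat=np.nan,
        levene_p=np.nan,
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn

def kruskal_dunn(groups: dict[str, np.ndarray], feature: str = "") -> GroupTestResult:
    """Kruskal-Wallis omnibus (tie-corrected) with Dunn pairwise z tests."""
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    if np.all(pooled == pooled[0]):
        H, p_omni = 0.0, 1.0
    else:
        H, p_omni = sps.kruskal(*arrays)
    ranks = sps.rankdata(pooled)
    sizes = [len(a) for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))
    ]
    # tie correction for the Dunn variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairwise = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        pairwise.append(PairwiseResult((names[i], names[j]), float(z), None, float(p)))
    return GroupTestResult(
        feature=feature,
        route="nonparametric",
        statistic=float(H),
        df=(len(arrays) - 1,),
        mse=None,
        eta_sq_p=None,
        p=float(p_omni),
        p_adj=None,
        levene_stat=np.nan,
        levene_p=np.nan,
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# multiplicity

def adjust_pvalues(pvalues, method: str = "bonferroni", family_size: int | None = None):
    """Bonferroni or Benjamini-Hochberg adjustment at an explicit family size.

    ``family_size`` defaults to the length of ``pvalues``; the full feature
    grid uses m = 96.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("p-values must lie in [0, 1]")
    m = family_size if family_size is not None else len(p)
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method in ("benjamini-hochberg", "bh", "fdr_bh"):
        order = np.argsort(p)
        adj = np.empty_like(p)
        ranked = p[order] * m / (np.arange(len(p), 0, -1)[::-1])
        # step-up: enforce monotonicity from the largest p downwards
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj[order] = np.minimum(1.0, ranked)
        return adj
    raise ConfigError(f"unknown correction method {method!r}")


# ---------------------------------------------------------------------------
# Bayesian equivalence (BIC approximation)

def bayes_equivalence(
    y: np.ndarray,
    group: pd.Series,
    covariates: pd.DataFrame | None = None,
    covariate_names=("age", "sex"),
    feature: str = "",
) -> EquivalenceResult:
    """BF10 for a two-group effect via the BIC approximation.

    BF10 = exp((BIC_null - BIC_group) / 2), with covariates in both models.
    Approximates a JZS-prior Bayesian ANCOVA; only the direction of the
    evidence (BF10 below or above 1) should be interpreted.
    """
    y = np.asarray(y, dtype=float)
    group = pd.Series(np.asarray(group))
    levels = sorted(group.unique())
    if len(levels) != 2:
        raise StatsPreconditionError("bayes_equivalence compares exactly two groups")
    if covariates is not None:
        use = [c for c in covariate_names if c in covariates.columns]
        Xr = _encode_covariates(covariates, use)
    else:
        Xr = np.ones((len(y), 1))
    n = len(y)
    if n < Xr.shape[1] + 3:
        raise StatsPreconditionError("too few observations for the covariate model")
    G = (group == levels[1]).to_numpy(float)[:, None]
    Xf = np.column_stack([Xr, G])
    sse0 = float(_sse(Xr, y[:, None])[0])
    sse1 = float(_sse(Xf, y[:, None])[0])
    bic0 = n * np.log(max(sse0, 1e-300) / n) + Xr.shape[1] * np.log(n)
    bic1 = n * np.log(max(sse1, 1e-300) / n) + Xf.shape[1] * np.log(n)
    bf10 = float(np.exp((bic0 - bic1) / 2.0))
    return EquivalenceResult(feature, (levels[0], levels[1]), bf10, "BIC")


# ---------------------------------------------------------------------------
# Spearman

def spearman_assoc(x, y, exact_max_n: int = 9):
    """Spearman rank correlation with average-rank ties.

    Two-sided p by the t approximation; exact permutation enumeration for
    n <= ``exact_max_n``. Returns (r_s, p); (None, None) when n < 4 or a
    variable has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4 or np.all(x == x[0]) or np.all(y == y[0]):
        return None, None
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    r_obs = float(np.corrcoef(rx, ry)[0, 1])
    if abs(r_obs) > 1.0 - 1e-12:  # snap floating-point drift at the extremes
        r_obs = float(np.sign(r_obs))
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(ry)))
        rx_c = rx - rx.mean()
        pc = perms - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (pc**2).sum(axis=1))
        r_all = (pc @ rx_c) / denom
        p = float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))
    else:
        t = r_obs * np.sqrt((n - 2) / max(1e-300, 1.0 - r_obs**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r_obs, p


def omnibus_pvalues(
    Y: np.ndarray,
    cohort: pd.DataFrame,
    covariate_names=("age", "sex"),
    levene_alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast gated omnibus p per feature column (no pairwise contrasts).

    Returns (p, nonparametric-route mask). Used by calibration runs where
    only the omnibus family matters.
    """
    Y = np.asarray(Y, dtype=float)
    group = cohort["group"]
    levels = sorted(group.unique())
    group_idx = group.map({g: i for i, g in enumerate(levels)}).to_numpy()
    nonpar, _, _ = levene_routes(Y, group_idx, alpha=levene_alpha)
    Xr = _encode_covariates(cohort, [c for c in covariate_names if c in cohort])
    G, _ = _group_dummies(group)
    p = np.empty(Y.shape[1])
    par = ~nonpar
    if par.any():
        _, p_par, _, _, _ = ancova_f_many(Y[:, par], Xr, G)
        p[par] = p_par
    for j in np.flatnonzero(nonpar):
        arrays = [Y[group_idx == i, j] for i in range(len(levels))]
        pooled = Y[:, j]
        if np.all(pooled == pooled[0]):
            p[j] = 1.0
        else:
            _, p[j] = sps.kruskal(*arrays)
    return p, nonpar


# ---------------------------------------------------------------------------
# the battery

def run_battery(
    features: pd.DataFrame,
    cohort: pd.DataFrame,
    covariate_names=("age", "sex"),
    correction: str = "bonferroni",
    family_size: int = DEFAULT_FAMILY,
    levene_alpha: float = 0.05,
    contrast_df: str = "pairwise",
) -> pd.DataFrame:
    """Run the Levene-gated battery over every feature column.

    Returns a long-format frame with one row per feature (omnibus) carrying
    route, statistic, p, p_adj and one column per pairwise contrast.
    """
    cohort = cohort.set_index("subject_id").loc[features.index].reset_index()
    group = cohort["group"]
    levels = sorted(group.unique())
    group_idx = group.map({g: i for i, g in enumerate(levels)}).to_numpy()
    cols = [c for c in features.columns if features[c].notna().all()]
    Y = features[cols].to_numpy(float)

    nonpar, lev_W, lev_p = levene_routes(Y, group_idx, alpha=levene_alpha)
    Xr = _encode_covariates(cohort, [c for c in covariate_names if c in cohort])
    G, _ = _group_dummies(group)
    _check_rank(np.column_stack([Xr, G]), ["covariates"] * Xr.shape[1] + ["group"] * G.shape[1])

    rows = []
    par_idx = np.flatnonzero(~nonpar)
    if par_idx.size:
        F, p, dfs, mse, eta = ancova_f_many(Y[:, par_idx], Xr, G)
        for k, j in enumerate(par_idx):
            res = ancova_group(
                Y[:, j], group, cohort, covariate_names, feature=cols[j],
                contrast_df=contrast_df,
            )
            rows.append((j, res, float(p[k])))
    for j in np.flatnonzero(nonpar):
        grouped = {g: Y[group_idx == i, j] for i, g in enumerate(levels)}
        res = kruskal_dunn(grouped, feature=cols[j])
        rows.append((j, res, res.p))

    rows.sort(key=lambda r: r[0])
    omnibus_p = np.array([r[2] for r in rows])
    adj = adjust_pvalues(omnibus_p, method=correction, family_size=family_size)
    records = []
    for (j, res, p_omni), p_adj in zip(rows, adj):
        res.p_adj = float(p_adj)
        res.levene_stat = float(lev_W[j])
        res.levene_p = float(lev_p[j])
        res.correction = correction
        res.family_size = family_size
        rec = {
            "feature": res.feature,
            "route": res.route,
            "statistic": res.statistic,
            "p": p_omni,
            "p_adj": res.p_adj,
            "levene_p": res.levene_p,
            "mse": res.mse,
            "eta_sq_p": res.eta_sq_p,
        }
        pair_p = [pw.p for pw in res.pairwise]
        pair_adj = adjust_pvalues(np.array(pair_p), method=correction, family_size=family_size)
        for pw, pa in zip(res.pairwise, pair_adj):
            pw.p_adj = float(pa)
            tag = f"{pw.groups[0]}_vs_{pw.groups[1]}"
            rec[f"stat[{tag}]"] = pw.statistic
            rec[f"p[{tag}]"] = pw.p
            rec[f"p_adj[{tag}]"] = pw.p_adj
        records.append(rec)
    return pd.DataFrame(records)
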