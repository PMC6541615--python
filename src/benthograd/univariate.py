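"""One-factor GLM comparisons of metrics across disturbance levels.

Count metrics (per-unit abundances over equal areas) are fitted with
quasi-Poisson errors -- Poisson point estimates with a Pearson-based
dispersion phi inflating all standard errors -- and diversity metrics with
Gaussian errors.  The global test is a quasi-F on scaled deviance
differences (classical one-way ANOVA in the Gaussian case).  All pairwise
level contrasts are tested simultaneously with the single-step multivariate-t
("max-|t|") adjustment; eta-squared gives the effect size, and compact letter
displays summarise the significance pattern.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import qmc

__all__ = [
    "GlmFit",
    "PairwiseResult",
    "fit_glm",
    "global_test",
    "pairwise_compare",
    "letter_display",
    "eta_squared",
]


@dataclass
class GlmFit:
    """A fitted saturated one-factor GLM.

    Coefficients are the per-level means on the link scale (one-hot design,
    no intercept), so fitted level means equal observed level means.
    """

    family: str  # "quasipoisson" | "gaussian"
    levels: list  # level labels in model order
    n_per_level: np.ndarray
    means: np.ndarray  # fitted level means, response scale
    ci_low: np.ndarray  # 95% Wald CI on the link scale, back-transformed
    ci_high: np.ndarray
    coef: np.ndarray  # link-scale level means
    cov: np.ndarray  # covariance of coef, scaled by phi
    phi: float  # dispersion (Pearson chi^2 / df_resid)
    deviance: float
    null_deviance: float
    df_model: int
    df_resid: int
    boundary: bool = False  # a level mean sits on the log-link boundary (0)
    values: np.ndarray = field(default=None, repr=False)
    level_of: np.ndarray = field(default=None, repr=False)
    metric: str = ""


def _closed_form(values, level_of, levels, family):
    """Saturated one-way fit without IRLS (used when a level mean is 0)."""
    y = np.asarray(values, dtype=float)
    k = len(levels)
    n = len(y)
    n_g = np.array([(level_of == g).sum() for g in levels])
    mu_g = np.array([y[level_of == g].mean() for g in levels])
    mu = np.repeat(np.nan, n)
    for g, m in zip(levels, mu_g):
        mu[level_of == g] = m
    df_resid = n - k
    if family == "gaussian":
        dev = float(np.sum((y - mu) ** 2))
        null_dev = float(np.sum((y - y.mean()) ** 2))
        phi = dev / df_resid if df_resid else np.nan
        coef = mu_g
        var = phi / n_g
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        dev = float(2 * np.sum(np.where(mu > 0, term - (y - mu), 0.0)))
        ybar = y.mean()
        term0 = np.where(y > 0, y * np.log(y / ybar), 0.0)
        null_dev = float(2 * np.sum(term0 - (y - ybar)))
        with np.errstate(divide="ignore", invalid="ignore"):
            pear = np.where(mu > 0, (y - mu) ** 2 / mu, 0.0)
        phi = float(np.sum(pear)) / df_resid if df_resid else np.nan
        with np.errstate(divide="ignore"):
            coef = np.log(mu_g)
        with np.errstate(divide="ignore"):
            var = np.where(mu_g > 0, phi / (n_g * mu_g), np.inf)
    return mu_g, coef, np.diag(var), phi, dev, null_dev, df_resid


def fit_glm(values, level_of, family: str = "quasipoisson", metric: str = "") -> GlmFit:
    """Fit metric ~ disturbance level by IRLS (statsmodels GLM).

    ``family`` is "quasipoisson" (log link; requires non-negative integer
    counts) or "gaussian".  Requires >= 2 levels with >= 2 replicates each.
    A level of all-zero counts puts the log-link mean on the boundary; the
    fit then falls back to the saturated closed form and is flagged.
    """
    y = np.asarray(values, dtype=float)
    level_of = np.asarray(level_of)
    levels = sorted(pd.unique(level_of))
    if len(levels) < 2:
        raise ValueError("need >= 2 levels")
    n_g = np.array([(level_of == g).sum() for g in levels])
    if np.any(n_g < 2):
        raise ValueError("need >= 2 replicates per level")
    if family == "quasipoisson":
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError("quasi-Poisson family requires non-negative integer counts")
        fam = sm.families.Poisson()
    elif family == "gaussian":
        fam = sm.families.Gaussian()
    else:
        raise ValueError(f"unknown family {family!r}")

    X = np.column_stack([(level_of == g).astype(float) for g in levels])
    boundary = family == "quasipoisson" and any(
        y[level_of == g].sum() == 0 for g in levels
    )
    if boundary or np.var(y) == 0:
        mu_g, coef, cov, phi, dev, null_dev, df_resid = _closed_form(
            y, level_of, levels, family
        )
    else:
        res = sm.GLM(y, X, family=fam).fit(scale="X2", tol=1e-10)
        coef = res.params
        phi = float(res.scale)
        cov = np.asarray(res.cov_params())  # already scaled by phi
        dev = float(res.deviance)
        null_dev = float(res.null_deviance)
        df_resid = int(res.df_resid)
        mu_g = fam.link.inverse(coef)

    tcrit = stats.t.ppf(0.975, df_resid) if df_resid > 0 else np.nan
    se = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", over="ignore"):
        lo, hi = coef - tcrit * se, coef + tcrit * se
        if family == "quasipoisson":
            lo, hi = np.exp(lo), np.exp(hi)
    return GlmFit(
        family=family,
        levels=list(levels),
        n_per_level=n_g,
        means=np.asarray(mu_g, dtype=float),
        ci_low=np.asarray(lo, dtype=float),
        ci_high=np.asarray(hi, dtype=float),
        coef=np.asarray(coef, dtype=float),
        cov=cov,
        phi=phi,
        deviance=dev,
        null_deviance=null_dev,
        df_model=len(levels) - 1,
        df_resid=df_resid,
        boundary=boundary,
        values=y,
        level_of=level_of,
        metric=metric,
    )


def global_test(fit: GlmFit) -> tuple:
    """Quasi-F test of any level effect: ((D0 - D1)/df1)/phi ~ F(df1, df2).

    Reduces to the classical one-way ANOVA F for the Gaussian family.
    Degenerate constant data (phi = 0) is reported as (inf, df1, df2, 0.0).
    """
    df1, df2 = fit.df_model, fit.df_resid
    num = (fit.null_deviance - fit.deviance) / df1
    if fit.phi == 0 or not np.isfinite(fit.phi):
        if num == 0:
            return (0.0, df1, df2, 1.0)
        return (np.inf, df1, df2, 0.0)
    F = num / fit.phi
    p = float(stats.f.sf(F, df1, df2))
    return (float(F), df1, df2, p)


@dataclass
class PairwiseResult:
    pairs: list  # [(level_i, level_j), ...]
    estimates: np.ndarray  # link-scale differences
    se: np.ndarray
    tstats: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    df: int
    alpha: float
    mc_error: float  # integration error estimate of the adjustment
    method: str  # "single-step mvt" | "bonferroni" | "exact t"
    letters: dict = None


def _max_abs_t_tail(t_obs, corr, df, seed, n_scramble=8, m_pow=16):
    """P(max_i |T_i| >= t) for a multivariate t via scrambled-Sobol QMC.

    Returns (p vector, error estimate).  ``corr`` may be singular (contrast
    correlation matrices always are); sampling uses its eigen factor.
    """
    k = corr.shape[0]
    w, V = np.linalg.eigh(corr)
    A = V * np.sqrt(np.clip(w, 0.0, None))
    t_obs = np.abs(np.asarray(t_obs, dtype=float))
    est = np.empty((n_scramble, t_obs.size))
    for s in range(n_scramble):
        eng = qmc.Sobol(d=k + 1, scramble=True, seed=seed + s)
        u = eng.random(2 ** m_pow)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        z = stats.norm.ppf(u[:, :k]) @ A.T
        chi = stats.chi2.ppf(u[:, k], df)
        T = z * np.sqrt(df / chi)[:, None]
        maxabs = np.max(np.abs(T), axis=1)
        est[s] = np.mean(maxabs[:, None] >= t_obs[None, :], axis=0)
    p = est.mean(axis=0)
    err = float(est.std(axis=0, ddof=1).max() / np.sqrt(n_scramble))
    return p, err


def pairwise_compare(fit: GlmFit, alpha: float = 0.05, seed: int = 0) -> PairwiseResult:
    """All pairwise level contrasts with single-step multivariate-t adjustment.

    Contrasts are differences of link-scale level means with model-based
    standard errors (already scaled by phi); each adjusted p-value is the
    probability that the maximum absolute component of a multivariate t with
    the contrast correlation and df_residual exceeds the observed |t|,
    evaluated by quasi-Monte-Carlo integration with a fixed seed.  With two
    levels the single contrast is exact.  A degenerate (zero-variance)
    contrast covariance falls back to Bonferroni.
    """
    k = len(fit.levels)
    pairs = list(itertools.combinations(range(k), 2))
    C = np.zeros((len(pairs), k))
    for r, (i, j) in enumerate(pairs):
        C[r, i], C[r, j] = 1.0, -1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        est = C @ fit.coef
        V = C @ fit.cov @ C.T
        se = np.sqrt(np.diag(V))
        t_obs = est / se
    labels = [(fit.levels[i], fit.levels[j]) for i, j in pairs]
    # contrasts with a boundary (zero-mean) level have infinite link-scale
    # estimates/SEs: their Wald p is undefined and reported as nan
    ok = np.isfinite(t_obs)
    p_raw = np.full(len(pairs), np.nan)
    p_raw[ok] = 2 * stats.t.sf(np.abs(t_obs[ok]), fit.df_resid)
    p_adj = np.full(len(pairs), np.nan)

    if ok.sum() == 0:
        method, err = "undefined", 0.0
    elif ok.sum() == 1:
        p_adj[ok] = p_raw[ok]
        method, err = "exact t", 0.0
    else:
        sub_V = V[np.ix_(ok, ok)]
        sub_se = se[ok]
        corr = sub_V / np.outer(sub_se, sub_se)
        if not np.all(np.isfinite(corr)):
            p_adj[ok] = np.minimum(1.0, p_raw[ok] * int(ok.sum()))
            method, err = "bonferroni", 0.0
        else:
            adj, err = _max_abs_t_tail(t_obs[ok], corr, fit.df_resid, seed)
            p_adj[ok] = np.clip(np.maximum(adj, p_raw[ok]), 0.0, 1.0)
            method = "single-step mvt"
    res = PairwiseResult(
        pairs=labels,
        estimates=est,
        se=se,
        tstats=t_obs,
        p_raw=p_raw,
        p_adj=p_adj,
        df=fit.df_resid,
        alpha=alpha,
        mc_error=err,
        method=method,
    )
    res.letters = letter_display(res, alpha)
    return res


def letter_display(pairwise: PairwiseResult, alpha: float = 0.05) -> dict:
    """Compact letter display by insert-and-absorb.

    Two levels share a letter iff their contrast is *not* significant at
    ``alpha``.  Intransitive patterns are representable (a level may carry
    several letters); never an error.
    """
    levels = sorted({l for pair in pairwise.pairs for l in pair})
    sig = {
        frozenset(pair)
        for pair, p in zip(pairwise.pairs, pairwise.p_adj)
        if p < alpha
    }
    classes = [set(levels)]
    for pair in sig:
        a, b = tuple(pair)
        new = []
        for cls in classes:
            if a in cls and b in cls:
                new.extend([cls - {a}, cls - {b}])
            else:
                new.append(cls)
        # absorb: keep only non-empty maximal sets
        pruned = []
        for cls in sorted(new, key=len, reverse=True):
            if cls and not any(cls <= p for p in pruned):
                pruned.append(cls)
        classes = pruned
    # stable letter order: by smallest member level
    classes.sort(key=lambda cls: [levels.index(l) for l in sorted(cls)])
    letters = {l: "" for l in levels}
    for idx, cls in enumerate(classes):
        ch = chr(ord("a") + idx)
        for l in sorted(cls):
            letters[l] += ch
    return letters


def eta_squared(values, level_of) -> float:
    """Effect size eta^2 = SS_between / SS_total on the response scale.

    Zero total variance yields nan (flagged missing), not 0.
    """
    y = np.asarray(values, dtype=float)
    level_of = np.asarray(level_of)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0:
        return np.nan
    ss_between = float(
        sum(
            (level_of == g).sum() * (y[level_of == g].mean() - y.mean()) ** 2
            for g in pd.unique(level_of)
        )
    )
    return ss_between / ss_total
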