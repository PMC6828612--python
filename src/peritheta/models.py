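"""Mixed-effects and classical inference for peri-error analyses.

The inferential machinery mirrors what performance-monitoring studies
typically run on trial-level reaction-time data:

* :class:`RandomInterceptLM` — a linear mixed model with a single random
  intercept per subject, fitted by maximum likelihood (ML, not REML) so
  that nested models can be compared with likelihood-ratio tests on
  their fixed effects.  The likelihood is profiled: for each value of
  the variance ratio ``psi = var(subject) / var(residual)`` the fixed
  effects and the residual variance have closed-form GLS solutions, so
  the fit reduces to a one-dimensional search over ``log(psi)``.
* :class:`RandomInterceptLogit` — the logistic analogue for trial-wise
  correctness, with the random-intercept integral evaluated by adaptive
  Gauss–Hermite quadrature.
* :func:`lrt` — likelihood-ratio test between two nested ML fits.
* :func:`mixed_anova_2x2` — the 2 (group) x 2 (trial position)
  split-plot ANOVA used as a cross-check of the mixed-model route.
* :func:`two_sample_t`, :func:`ttest_power`, :func:`min_detectable_d` —
  classical group comparisons and the noncentral-t power analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "RandomInterceptLM",
    "RandomInterceptLMResults",
    "RandomInterceptLogit",
    "RandomInterceptLogitResults",
    "LRTResult",
    "PowerResult",
    "lrt",
    "mixed_anova_2x2",
    "two_sample_t",
    "ttest_power",
    "min_detectable_d",
]


# --------------------------------------------------------------------------
# linear mixed model, random intercept, profiled ML
# --------------------------------------------------------------------------

class RandomInterceptLM:
    """Linear mixed model with one random intercept per group, ML fit.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response (e.g. standardized reaction time).
    exog : array-like, shape (n, p) or None
        Fixed-effect design matrix.  ``None`` or a zero-column matrix
        fits the null model containing only the random intercept and
        the residual variance.
    groups : array-like, shape (n,)
        Grouping labels (subject identifiers).
    exog_names : sequence of str, optional
        Column names for the fixed effects.
    """

    def __init__(self, endog, exog, groups, exog_names: Sequence[str] | None = None):
        y = np.asarray(endog, dtype=float).ravel()
        if exog is None:
            X = np.empty((y.size, 0))
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
        if X.shape[0] != y.size:
            raise ValueError("endog and exog have incompatible shapes")
        if not (np.isfinite(y).all() and np.isfinite(X).all()):
            raise ValueError("endog/exog contain non-finite values")
        codes, uniques = pd.factorize(np.asarray(groups))
        if uniques.size < 2:
            raise ValueError("need at least 2 groups for a random intercept")
        p = X.shape[1]
        if p and np.linalg.matrix_rank(X) < p:
            raise ValueError("singular fixed-effect design")
        if exog_names is None:
            exog_names = [f"x{i}" for i in range(p)]
        if len(exog_names) != p:
            raise ValueError("exog_names length mismatch")

        self.endog = y
        self.exog = X
        self.group_codes = codes
        self.group_labels = uniques
        self.exog_names = list(exog_names)
        self.nobs = y.size
        self.n_groups = uniques.size

        # sufficient statistics: totals and per-group sums
        G = self.n_groups
        self._n_i = np.bincount(codes, minlength=G).astype(float)
        self._Sy = np.bincount(codes, weights=y, minlength=G)
        self._Sx = np.zeros((G, p))
        for j in range(p):
            self._Sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=G)
        self._XtX = X.T @ X
        self._Xty = X.T @ y
        self._yty = float(y @ y)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       fixed: Sequence[str] = (), groups: str = "subject",
                       add_intercept: bool = True) -> "RandomInterceptLM":
        """Build the model from tidy trial-level data.

        ``fixed`` names numeric columns of ``data``; categorical terms
        must be coded (dummy/contrast columns) by the caller.
        """
        cols = list(fixed)
        X = data[cols].to_numpy(dtype=float) if cols else np.empty((len(data), 0))
        names = cols
        if add_intercept:
            X = np.column_stack([np.ones(len(data)), X])
            names = ["Intercept"] + cols
        return cls(data[response], X, data[groups], exog_names=names)

    # -- profiled likelihood pieces ---------------------------------------
    def _profile(self, psi: float):
        """GLS solution and profiled ML log-likelihood at a given psi."""
        n_i, Sx, Sy = self._n_i, self._Sx, self._Sy
        c = psi / (1.0 + n_i * psi)                      # shrinkage weights
        XtAX = self._XtX - np.einsum("g,gj,gk->jk", c, Sx, Sx)
        XtAy = self._Xty - Sx.T @ (c * Sy)
        ytAy = self._yty - float(c @ (Sy ** 2))
        p = self.exog.shape[1]
        if p:
            beta = np.linalg.solve(XtAX, XtAy)
            rss = ytAy - float(beta @ XtAy)
        else:
            beta = np.empty(0)
            rss = ytAy
        rss = max(rss, 1e-300)
        N = self.nobs
        sigma2 = rss / N
        ll = -0.5 * N * (np.log(2 * np.pi * sigma2) + 1.0) \
             - 0.5 * float(np.log1p(n_i * psi).sum())
        return ll, beta, sigma2, XtAX

    def fit(self, psi_bounds: tuple[float, float] = (1e-8, 1e4),
            tol: float = 1e-10) -> "RandomInterceptLMResults":
        """Maximise the profiled ML log-likelihood over the variance ratio.

        A coarse grid over ``log(psi)`` locates the mode (the profile
        can be flat near the boundary), followed by a bounded scalar
        refinement; ``psi = 0`` (no subject variance, ordinary
        regression) is always evaluated and kept if it wins.
        """
        lo, hi = np.log(psi_bounds[0]), np.log(psi_bounds[1])
        grid = np.linspace(lo, hi, 61)
        ll_grid = np.array([self._profile(np.exp(t))[0] for t in grid])
        k = int(np.argmax(ll_grid))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            lambda t: -self._profile(np.exp(t))[0],
            bounds=(a, b), method="bounded", options={"xatol": tol})
        psi_hat = float(np.exp(res.x))
        ll_hat = -res.fun

        ll0 = self._profile(0.0)[0]
        boundary = ll0 >= ll_hat - 1e-10
        if boundary:
            psi_hat, ll_hat = 0.0, ll0
        ll, beta, sigma2, XtAX = self._profile(psi_hat)
        cov = sigma2 * np.linalg.inv(XtAX) if beta.size else np.empty((0, 0))
        return RandomInterceptLMResults(
            model=self, params=pd.Series(beta, index=self.exog_names),
            cov_params=cov, sigma2_resid=sigma2,
            sigma2_group=psi_hat * sigma2, psi=psi_hat, llf=ll,
            converged=bool(res.success or boundary), at_boundary=boundary)


@dataclass
class RandomInterceptLMResults:
    """ML fit of a random-intercept linear mixed model."""

    model: RandomInterceptLM
    params: pd.Series
    cov_params: np.ndarray
    sigma2_resid: float
    sigma2_group: float
    psi: float
    llf: float
    converged: bool
    at_boundary: bool = False

    @property
    def k_fe(self) -> int:
        return len(self.params)

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.diag(self.cov_params)) if self.k_fe else np.empty(0)
        return pd.Series(se, index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.params.index)

    def summary(self) -> str:
        tbl = pd.DataFrame({
            "estimate": self.params, "se": self.bse,
            "z": self.zvalues, "p": self.pvalues})
        lines = [
            "Random-intercept linear mixed model (ML)",
            f"  nobs: {self.model.nobs}   groups: {self.model.n_groups}"
            f"   llf: {self.llf:.4f}",
            f"  var(subject): {self.sigma2_group:.6g}"
            f"   var(resid): {self.sigma2_resid:.6g}"
            + ("   [psi at boundary 0]" if self.at_boundary else ""),
            tbl.to_string(float_format=lambda v: f"{v:.4f}") if self.k_fe
            else "  (no fixed effects)",
        ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# logistic mixed model, adaptive Gauss-Hermite quadrature
# --------------------------------------------------------------------------

def _logit_newton(y, X, maxiter=50, ridge=1e-8):
    """Plain logistic regression by Newton's method (starting values)."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        H = X.T @ (X * W[:, None]) + ridge * np.eye(X.shape[1])
        g = X.T @ (y - p)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    return beta


class RandomInterceptLogit:
    """Logistic mixed model for binary trial outcomes, random intercept.

    The marginal likelihood integrates the subject intercept out with
    adaptive Gauss–Hermite quadrature (default 21 nodes): each
    subject's integrand is re-centred at its conditional mode and
    re-scaled by the local curvature before applying the Hermite rule,
    which keeps the rule accurate even for subjects with many trials.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        y = np.asarray(endog, dtype=float).ravel()
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        codes, uniques = pd.factorize(np.asarray(groups))
        p = X.shape[1]
        if p == 0 or np.linalg.matrix_rank(X) < p:
            raise ValueError("fixed-effect design empty or singular")
        if exog_names is None:
            exog_names = [f"x{i}" for i in range(p)]
        self.endog, self.exog = y, X
        self.group_codes, self.group_labels = codes, uniques
        self.exog_names = list(exog_names)
        self.nobs, self.n_groups = y.size, uniques.size
        # pad per-subject data to a (G, max_n) rectangle for vector ops
        order = np.argsort(codes, kind="stable")
        self._n_i = np.bincount(codes, minlength=self.n_groups)
        m = int(self._n_i.max())
        G = self.n_groups
        self._Yp = np.zeros((G, m))
        self._mask = np.zeros((G, m), dtype=bool)
        self._rowpos = np.zeros(y.size, dtype=int)
        pos = np.zeros(G, dtype=int)
        for idx in order:
            g = codes[idx]
            self._rowpos[idx] = pos[g]
            pos[g] += 1
        self._Yp[codes, self._rowpos] = y
        self._mask[codes, self._rowpos] = True
        self._Xrows = X  # linear predictor laid out per call

    @classmethod
    def from_dataframe(cls, data, response, fixed=(), groups="subject",
                       add_intercept=True):
        cols = list(fixed)
        X = data[cols].to_numpy(dtype=float) if cols else np.empty((len(data), 0))
        names = cols
        if add_intercept:
            X = np.column_stack([np.ones(len(data)), X])
            names = ["Intercept"] + cols
        return cls(data[response], X, data[groups], exog_names=names)

    def _loglike(self, beta, tau, z, w):
        """Marginal log-likelihood via adaptive GH with nodes z, weights w."""
        G = self.n_groups
        eta0 = np.zeros_like(self._Yp)
        eta0[self.group_codes, self._rowpos] = self._Xrows @ beta
        Y, M = self._Yp, self._mask
        if tau < 1e-6:  # variance ~ 0: plain logistic likelihood
            e = np.clip(eta0, -30, 30)
            ll = Y * e - np.log1p(np.exp(e))
            return float(ll[M].sum())
        inv_t2 = 1.0 / tau ** 2
        b = np.zeros((G, 1))
        for _ in range(25):  # Newton to each subject's conditional mode
            e = np.clip(eta0 + b, -30, 30)
            pvec = 1.0 / (1.0 + np.exp(-e))
            g1 = ((Y - pvec) * M).sum(1, keepdims=True) - b * inv_t2
            g2 = -(pvec * (1 - pvec) * M).sum(1, keepdims=True) - inv_t2
            step = g1 / g2
            b = b - step
            if np.abs(step).max() < 1e-9:
                break
        e = np.clip(eta0 + b, -30, 30)
        pvec = 1.0 / (1.0 + np.exp(-e))
        curv = (pvec * (1 - pvec) * M).sum(1, keepdims=True) + inv_t2
        shat = 1.0 / np.sqrt(curv)                       # (G,1)
        # evaluate h at transformed nodes: b_k = bhat + sqrt(2)*shat*z_k
        bk = b + np.sqrt(2.0) * shat * z[None, :]        # (G,K)
        ek = np.clip(eta0[:, :, None] + bk[:, None, :], -30, 30)  # (G,m,K)
        llk = (Y[:, :, None] * ek - np.log1p(np.exp(ek))) * M[:, :, None]
        h = llk.sum(1) - 0.5 * bk ** 2 * inv_t2 \
            - np.log(tau) - 0.5 * np.log(2 * np.pi)      # (G,K)
        expo = h + z[None, :] ** 2 + np.log(w)[None, :]
        hmax = expo.max(1, keepdims=True)
        integ = np.log(np.exp(expo - hmax).sum(1)) + hmax.ravel()
        integ = integ + 0.5 * np.log(2.0) + np.log(shat.ravel())
        return float(integ.sum())

    def fit(self, n_quad: int = 21, maxiter: int = 200) -> "RandomInterceptLogitResults":
        z, w = np.polynomial.hermite.hermgauss(n_quad)
        beta0 = _logit_newton(self.endog, self.exog)
        x0 = np.concatenate([beta0, [np.log(0.5)]])

        def neg(theta):
            return -self._loglike(theta[:-1], np.exp(theta[-1]), z, w)

        res = optimize.minimize(neg, x0, method="L-BFGS-B",
                                options={"maxiter": maxiter, "ftol": 1e-12})
        beta = res.x[:-1]
        tau = float(np.exp(res.x[-1]))
        if np.abs(beta).max() > 10:
            warnings.warn("possible separation: large logit coefficients",
                          RuntimeWarning, stacklevel=2)
            beta = np.clip(beta, -15, 15)
        return RandomInterceptLogitResults(
            model=self, params=pd.Series(beta, index=self.exog_names),
            tau=tau, llf=-res.fun, converged=bool(res.success),
            n_quad=n_quad)


@dataclass
class RandomInterceptLogitResults:
    """ML fit of a random-intercept logistic mixed model."""

    model: RandomInterceptLogit
    params: pd.Series
    tau: float        # random-intercept SD on the logit scale
    llf: float
    converged: bool
    n_quad: int

    @property
    def k_fe(self) -> int:
        return len(self.params)

    def summary(self) -> str:
        return (
            "Random-intercept logistic mixed model (ML, adaptive GH "
            f"{self.n_quad} nodes)\n"
            f"  nobs: {self.model.nobs}   groups: {self.model.n_groups}"
            f"   llf: {self.llf:.4f}   sd(subject): {self.tau:.4f}\n"
            + self.params.to_string(float_format=lambda v: f"{v:.4f}")
        )


# --------------------------------------------------------------------------
# likelihood-ratio test
# --------------------------------------------------------------------------

@dataclass
class LRTResult:
    chi2: float
    df: int
    pvalue: float
    llf_full: float
    llf_reduced: float

    def __str__(self):
        return f"chi2({self.df}) = {self.chi2:.2f}, p = {self.pvalue:.4g}"


def lrt(full, reduced) -> LRTResult:
    """Likelihood-ratio test between two nested ML fits.

    Nesting is checked structurally: same model class, same number of
    observations and groups, and the reduced model's fixed-effect names
    a strict subset of the full model's.
    """
    if type(full) is not type(reduced):
        raise ValueError("cannot compare fits of different model classes")
    if full.model.nobs != reduced.model.nobs \
            or full.model.n_groups != reduced.model.n_groups:
        raise ValueError("models fitted to different data")
    f_names, r_names = set(full.params.index), set(reduced.params.index)
    if not (r_names < f_names):
        raise ValueError("reduced model is not nested in the full model")
    df = full.k_fe - reduced.k_fe
    chi2 = 2.0 * (full.llf - reduced.llf)
    if chi2 < -1e-6:
        raise RuntimeError(f"negative LRT statistic ({chi2:.3g}): "
                           "full-model optimisation failed")
    chi2 = max(chi2, 0.0)
    return LRTResult(chi2=chi2, df=df, pvalue=float(stats.chi2.sf(chi2, df)),
                     llf_full=full.llf, llf_reduced=reduced.llf)


# --------------------------------------------------------------------------
# 2x2 split-plot ANOVA (group between, trial position within)
# --------------------------------------------------------------------------

def mixed_anova_2x2(subject_means: pd.DataFrame, dv: str = "value",
                    within: str = "position", between: str = "group",
                    subject: str = "subject") -> pd.DataFrame:
    """Split-plot ANOVA with one between factor and one within factor,
    both at two levels; one value per subject x within cell.

    Returns a table with F, df1, df2 and p for the between main effect,
    the within main effect, and their interaction.  Denominator df is
    n_subjects - 2 for every effect, as in a standard 2x2 mixed design.
    """
    wide = subject_means.pivot_table(index=[subject, between], columns=within,
                                     values=dv)
    if wide.isna().any().any() or wide.shape[1] != 2:
        raise ValueError("need exactly 2 within levels, complete per subject")
    grp = wide.index.get_level_values(between)
    levels = pd.unique(grp)
    if len(levels) != 2:
        raise ValueError("need exactly 2 between-group levels")
    a = wide.iloc[:, 0].to_numpy()
    b = wide.iloc[:, 1].to_numpy()
    g = (grp == levels[1]).astype(bool)
    n = len(wide)
    n0, n1 = int((~g).sum()), int(g.sum())
    df2 = n - 2

    def _pooled(v):
        m0, m1 = v[~g].mean(), v[g].mean()
        sse = ((v[~g] - m0) ** 2).sum() + ((v[g] - m1) ** 2).sum()
        return m0, m1, sse / df2

    def _ratio(num, den):
        if den == 0:
            return 0.0 if num == 0 else np.inf
        return num / den

    s = 0.5 * (a + b)            # subject average  -> between-subject part
    d = b - a                    # within difference -> within-subject part
    ms0, ms1, s2_s = _pooled(s)
    md0, md1, s2_d = _pooled(d)
    inv = 1 / n0 + 1 / n1
    F_between = _ratio((ms1 - ms0) ** 2, s2_s * inv)
    F_within = _ratio(n * d.mean() ** 2, s2_d)      # weighted grand mean
    F_inter = _ratio((md1 - md0) ** 2, s2_d * inv)
    out = pd.DataFrame({
        "effect": [between, within, f"{between}*{within}"],
        "F": [F_between, F_within, F_inter],
        "df1": [1, 1, 1],
        "df2": [df2, df2, df2],
    })
    out["p"] = stats.f.sf(out["F"], out["df1"], out["df2"])
    return out


# --------------------------------------------------------------------------
# t-tests and power
# --------------------------------------------------------------------------

def two_sample_t(x, y, paired: bool = False):
    """Student t-test (pooled variance if unpaired); returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test needs equal-length samples")
        if x.size < 2:
            raise ValueError("need n >= 2")
        t, p = stats.ttest_rel(x, y)
        df = x.size - 1
    else:
        if x.size < 2 or y.size < 2:
            raise ValueError("need n >= 2 per group")
        t, p = stats.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
    return float(t), int(df), float(p)


@dataclass
class PowerResult:
    d: float
    n1: int
    n2: int
    alpha: float
    power: float


def ttest_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> PowerResult:
    """Power of a two-sided two-sample t-test at effect size ``d``.

    Uses the noncentral t distribution with noncentrality
    ``|d| * sqrt(n1*n2/(n1+n2))`` and ``n1+n2-2`` degrees of freedom;
    the two-sided power is symmetric in the sign of ``d``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    ncp = abs(d) * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    power = float(1 - stats.nct.cdf(tcrit, df, ncp)
                  + stats.nct.cdf(-tcrit, df, ncp))
    if np.isnan(power):   # extreme noncentrality: normal limit
        power = float(stats.norm.sf(tcrit - ncp) + stats.norm.cdf(-tcrit - ncp))
    return PowerResult(d=d, n1=n1, n2=n2, alpha=alpha, power=power)


def min_detectable_d(power_target: float, n1: int, n2: int,
                     alpha: float = 0.05, tol: float = 1e-4) -> float:
    """Smallest Cohen's d at which the two-sample t-test reaches the
    target power; bisection to ``tol`` (report to 2 decimals)."""
    if not 0 < power_target < 1:
        raise ValueError("power_target must be in (0, 1)")
    lo, hi = 0.0, 0.5
    while ttest_power(hi, n1, n2, alpha).power < power_target:
        hi *= 2
        if hi > 100:
            raise RuntimeError("power target unreachable")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ttest_power(mid, n1, n2, alpha).power >= power_target:
            hi = mid
        else:
            lo = mid
    return hi
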