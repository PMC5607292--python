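"""Mixed-effects trend models for crypt-level stem-cell dynamics.

Two outcomes, one design: crypt-level observations nested in patients, two
treatment arms, three timepoints.

* methylation-pattern **diversity** (a small right-skewed count) is
  modelled with mixed-effects negative binomial regression: NB2 (variance
  mu + mu^2/theta), log link, fixed effects treatment + time +
  treatment x time, Gaussian random intercept per patient, maximum
  likelihood via adaptive Gauss–Hermite quadrature over the random effect.
* **percent methylation** (approximately Gaussian) is modelled with a
  random-intercept linear mixed model fitted by ML with the variance ratio
  profiled out (one-dimensional optimization; the zero-variance boundary is
  exactly OLS).

Time enters either categorically (per-group means per timepoint) or
continuously in years (per-group rate of change per year; for the NB model
``exp(slope)`` is the multiplicative rate).  Inference is Wald (z) on the
link scale, plus likelihood-ratio tests between nested fits.  Reported NB
group means are conditional on a random intercept of zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats as sps
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

Z95 = sps.norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the final gradient norm and message."""

    def __init__(self, message: str, gradient_norm: float, trace: object = None):
        super().__init__(f"{message} (|grad| = {gradient_norm:.3g})")
        self.gradient_norm = gradient_norm
        self.trace = trace


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _group_levels(table: pd.DataFrame) -> list[str]:
    levels = sorted(table["group"].unique())
    if "placebo" in levels:  # placebo is the conventional reference arm
        levels = ["placebo"] + [g for g in levels if g != "placebo"]
    return levels


def _time_levels(table: pd.DataFrame) -> list[tuple[str, float]]:
    lv = (table[["timepoint_label", "timepoint_years"]]
          .drop_duplicates().sort_values("timepoint_years"))
    return list(lv.itertuples(index=False, name=None))


def build_design(
    table: pd.DataFrame,
    time_coding: str,
    covariates: Sequence[str] = (),
    interaction: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix: intercept, non-reference group
    indicators, time (continuous years or timepoint dummies), their
    interactions (omitted when ``interaction=False``, the reduced model for
    likelihood-ratio testing), then extra covariate columns."""
    groups = _group_levels(table)
    cols: list[np.ndarray] = [np.ones(len(table))]
    names = ["intercept"]
    gdum = {}
    for g in groups[1:]:
        gdum[g] = (table["group"] == g).to_numpy(float)
        cols.append(gdum[g])
        names.append(g)
    if time_coding == "continuous":
        t = table["timepoint_years"].to_numpy(float)
        cols.append(t)
        names.append("years")
        if interaction:
            for g in groups[1:]:
                cols.append(gdum[g] * t)
                names.append(f"{g}:years")
    elif time_coding == "categorical":
        for lab, _ in _time_levels(table)[1:]:
            d = (table["timepoint_label"] == lab).to_numpy(float)
            cols.append(d)
            names.append(lab)
            if interaction:
                for g in groups[1:]:
                    cols.append(gdum[g] * d)
                    names.append(f"{g}:{lab}")
    else:
        raise ValueError(f"unknown time_coding {time_coding!r}")
    for cv in covariates:
        cols.append(table[cv].to_numpy(float))
        names.append(cv)
    return np.column_stack(cols), names


def _cell_contrast(names: list[str], group: str, ref_group: str,
                   time_label: str, ref_label: str, time_coding: str,
                   years: float | None = None) -> np.ndarray:
    """Contrast vector for the linear predictor of one group x time cell."""
    c = np.zeros(len(names))
    c[names.index("intercept")] = 1.0
    if group != ref_group:
        c[names.index(group)] = 1.0
    if time_coding == "categorical":
        if time_label != ref_label:
            c[names.index(time_label)] = 1.0
            if group != ref_group and f"{group}:{time_label}" in names:
                c[names.index(f"{group}:{time_label}")] = 1.0
    else:
        c[names.index("years")] = years
        if group != ref_group and f"{group}:years" in names:
            c[names.index(f"{group}:years")] = years
    return c


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    """Fitted mixed-model summary."""

    model_kind: str            # "nb_mixed" | "linear_mixed"
    time_coding: str           # "categorical" | "continuous"
    params: np.ndarray         # all ML parameters (fixed, then variance terms)
    names: list[str]           # fixed-effect names
    cov: np.ndarray            # covariance of all parameters
    loglik: float
    dispersion: float | None   # NB theta (None for linear)
    random_intercept_variance: float
    residual_variance: float | None
    n_obs: int
    n_groups: int
    fixed_effects: pd.DataFrame = field(repr=False)
    group_means: pd.DataFrame | None = field(default=None, repr=False)
    rates: pd.DataFrame | None = field(default=None, repr=False)
    interaction_terms: list[str] = field(default_factory=list)
    interaction_p: float = float("nan")
    converged: bool = True
    data_shape: tuple = ()

    @property
    def beta(self) -> np.ndarray:
        return self.params[: len(self.names)]

    def wald(self, c: np.ndarray) -> tuple[float, float]:
        """Point estimate and SE of contrast c'beta (link scale)."""
        k = len(self.names)
        est = float(c @ self.beta)
        se = float(np.sqrt(c @ self.cov[:k, :k] @ c))
        return est, se


def _joint_wald(fit: TrendFit, terms: list[str]) -> float:
    if not terms:
        return float("nan")
    k = len(fit.names)
    idx = [fit.names.index(t) for t in terms]
    b = fit.beta[idx]
    V = fit.cov[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        return float("nan")
    return float(sps.chi2.sf(stat, len(idx)))


def _fixed_effects_frame(fit_names, beta, se) -> pd.DataFrame:
    z = beta / se
    return pd.DataFrame({
        "term": fit_names, "coef": beta, "se": se,
        "ci_low": beta - Z95 * se, "ci_high": beta + Z95 * se,
        "z": z, "p": 2 * sps.norm.sf(np.abs(z)),
    })


def _summaries(fit: TrendFit, table: pd.DataFrame, link_exp: bool) -> None:
    """Attach per-group per-timepoint means (categorical) or per-year
    rates/changes (continuous), with Wald CIs and within-group timepoint
    comparisons mirroring the usual trial-report layout."""
    groups = _group_levels(table)
    tls = _time_levels(table)
    ref_g, (ref_t, _) = groups[0], tls[0]
    tf = lambda x: float(np.exp(x)) if link_exp else float(x)

    if fit.time_coding == "categorical":
        rows = []
        for g in groups:
            for i, (lab, yrs) in enumerate(tls):
                c = _cell_contrast(fit.names, g, ref_g, lab, ref_t, "categorical")
                est, se = fit.wald(c)
                row = {"group": g, "timepoint_label": lab, "timepoint_years": yrs,
                       "mean": tf(est), "ci_low": tf(est - Z95 * se),
                       "ci_high": tf(est + Z95 * se)}
                for j, (lab2, _) in enumerate(tls):
                    if j >= i:
                        continue
                    c2 = _cell_contrast(fit.names, g, ref_g, lab2, ref_t, "categorical")
                    d, dse = fit.wald(c - c2)
                    row[f"p_vs_{lab2}"] = 2 * sps.norm.sf(abs(d / dse))
                rows.append(row)
        fit.group_means = pd.DataFrame(rows)
        fit.interaction_terms = [n for n in fit.names if ":" in n]
        fit.interaction_p = _joint_wald(fit, fit.interaction_terms)
    else:
        rows = []
        for g in groups:
            c = np.zeros(len(fit.names))
            c[fit.names.index("years")] = 1.0
            if g != ref_g and f"{g}:years" in fit.names:
                c[fit.names.index(f"{g}:years")] = 1.0
            est, se = fit.wald(c)
            rows.append({
                "group": g,
                "rate_per_year" if link_exp else "change_per_year": tf(est),
                "ci_low": tf(est - Z95 * se), "ci_high": tf(est + Z95 * se),
                "p": 2 * sps.norm.sf(abs(est / se)),
            })
        fit.rates = pd.DataFrame(rows)
        fit.interaction_terms = [n for n in fit.names if n.endswith(":years")]
        fit.interaction_p = _joint_wald(fit, fit.interaction_terms)


# ---------------------------------------------------------------------------
# Negative binomial mixed model
# ---------------------------------------------------------------------------

def _nb_logpmf(y, mu, theta):
    return (gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
            + theta * (np.log(theta) - np.log(theta + mu))
            + y * (np.log(mu) - np.log(theta + mu)))


class _NBMixedData:
    """Per-patient ragged arrays padded to a (G, n_max) grid."""

    def __init__(self, y: np.ndarray, X: np.ndarray, patient: np.ndarray):
        self.levels, codes = np.unique(patient, return_inverse=True)
        G = len(self.levels)
        nmax = int(np.bincount(codes).max())
        p = X.shape[1]
        self.y = np.zeros((G, nmax))
        self.X = np.zeros((G, nmax, p))
        self.mask = np.zeros((G, nmax), dtype=bool)
        fill = np.zeros(G, dtype=int)
        for i, g in enumerate(codes):
            j = fill[g]
            self.y[g, j] = y[i]
            self.X[g, j] = X[i]
            self.mask[g, j] = True
            fill[g] += 1


def _nb_mixed_loglik(params: np.ndarray, data: _NBMixedData, n_nodes: int,
                     sigma_fixed: float | None) -> float:
    p = data.X.shape[2]
    beta = params[:p]
    theta = np.exp(params[p])
    sigma = sigma_fixed if sigma_fixed is not None else np.exp(params[p + 1])
    eta = np.clip(data.X @ beta, -30, 30)

    if sigma is not None and sigma < 1e-8:
        mu = np.exp(eta)
        ll = np.where(data.mask, _nb_logpmf(data.y, mu, theta), 0.0)
        return float(ll.sum())

    # adaptive GH: Newton for the per-patient mode of the joint log-density
    b = np.zeros(data.y.shape[0])
    for _ in range(60):
        mu = np.exp(np.clip(eta + b[:, None], -30, 30))
        w = (data.y + theta) * mu / (theta + mu)
        g1 = np.where(data.mask, data.y - w, 0.0).sum(axis=1) - b / sigma**2
        g2 = -np.where(data.mask, w * theta / (theta + mu), 0.0).sum(axis=1) - 1.0 / sigma**2
        step = np.clip(g1 / g2, -3.0, 3.0)
        b = b - step
        if np.max(np.abs(step)) < 1e-12:
            break
    s = 1.0 / np.sqrt(-g2)

    z, wq = hermgauss(n_nodes)
    bk = b[:, None] + np.sqrt(2.0) * s[:, None] * z[None, :]        # (G, K)
    eta_k = eta[:, None, :] + bk[:, :, None]                        # (G, K, n)
    mu_k = np.exp(np.clip(eta_k, -30, 30))
    ll_obs = np.where(data.mask[:, None, :],
                      _nb_logpmf(data.y[:, None, :], mu_k, theta), 0.0).sum(axis=2)
    h = ll_obs + sps.norm.logpdf(bk, 0.0, sigma)
    li = logsumexp(np.log(wq)[None, :] + z[None, :] ** 2 + h, axis=1)
    li = li + np.log(np.sqrt(2.0) * s)
    return float(li.sum())


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    h = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fit_nb_mixed(
    table: pd.DataFrame,
    time_coding: str = "continuous",
    quadrature_nodes: int = 25,
    outcome: str = "diversity",
    covariates: Sequence[str] = (),
    sigma_fixed: float | None = None,
    interaction: bool = True,
) -> TrendFit:
    """Fit the mixed-effects NB2 regression of a crypt-level count outcome.

    ``sigma_fixed=0`` constrains the random-intercept SD to the boundary,
    which reduces the likelihood exactly to an ordinary NB GLM.
    ``interaction=False`` fits the additive reduced model (for LRTs).
    Raises :class:`ConvergenceError` if the optimizer fails.
    """
    y = table[outcome].to_numpy(float)
    if (y < 0).any():
        raise ValueError("counts must be >= 0")
    if table.groupby("group")["patient_id"].nunique().min() < 2:
        raise ValueError("need >= 2 patients per group for a mixed fit")
    X, names = build_design(table, time_coding, covariates, interaction)
    data = _NBMixedData(y, X, table["patient_id"].to_numpy())

    glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    mu0 = glm.fittedvalues
    excess = max(((y - mu0) ** 2 - mu0).sum(), 1e-6)
    theta0 = float(np.clip((mu0 ** 2).sum() / excess, 0.5, 50.0))
    x0 = list(glm.params) + [np.log(theta0)]
    bounds = [(None, None)] * len(names) + [(-4.0, 10.0)]
    if sigma_fixed is None:
        x0.append(np.log(0.5))
        bounds.append((-8.0, 3.0))
    x0 = np.asarray(x0)

    nll = lambda p: -_nb_mixed_loglik(p, data, quadrature_nodes, sigma_fixed)
    # fd step 1e-5: the default 1e-8 drowns the gradient in cancellation
    # noise when theta is large (Poisson-limit boundary)
    opts = {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8, "eps": 1e-5}
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options=opts)

    def _projected_gnorm(x):
        # stable central-difference gradient; components pushing into an
        # active bound do not count
        g = np.empty(len(x))
        for i in range(len(x)):
            e = np.zeros(len(x))
            e[i] = 1e-5
            g[i] = (nll(x + e) - nll(x - e)) / 2e-5
        for i, (lo, hi) in enumerate(bounds):
            if lo is not None and x[i] <= lo + 1e-8 and g[i] > 0:
                g[i] = 0.0
            if hi is not None and x[i] >= hi - 1e-8 and g[i] < 0:
                g[i] = 0.0
        return float(np.max(np.abs(g)))

    gnorm = _projected_gnorm(res.x)
    if not res.success:
        if gnorm > 1e-2:  # line-search hiccup: polish with a simplex pass
            polish = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                       options={"maxiter": 4000, "fatol": 1e-10,
                                                "xatol": 1e-8})
            if polish.fun <= res.fun:
                res2 = optimize.minimize(nll, polish.x, method="L-BFGS-B",
                                         bounds=bounds,
                                         options=opts)
                if res2.fun <= polish.fun:
                    res = res2
                    gnorm = _projected_gnorm(res.x)
        if gnorm > 5e-2:
            raise ConvergenceError(f"NB mixed fit failed: {res.message}", gnorm, res)
        logger.warning("NB mixed optimizer stopped at a boundary "
                       "(projected |grad| = %.2g); solution accepted", gnorm)

    H = _numeric_hessian(nll, res.x)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        logger.warning("singular Hessian; using pseudo-inverse")
        cov = np.linalg.pinv(H)

    theta = float(np.exp(res.x[len(names)]))
    if sigma_fixed is None:
        sigma = float(np.exp(res.x[len(names) + 1]))
        if sigma < 1e-3:
            logger.warning("random-intercept variance on boundary (~0); "
                           "estimates equivalent to a plain NB GLM")
    else:
        sigma = float(sigma_fixed)

    k = len(names)
    se = np.sqrt(np.clip(np.diag(cov)[:k], 0, None))
    fit = TrendFit(
        model_kind="nb_mixed", time_coding=time_coding,
        params=res.x.copy(), names=names, cov=cov, loglik=-float(res.fun),
        dispersion=theta, random_intercept_variance=sigma ** 2,
        residual_variance=None, n_obs=len(y), n_groups=len(data.levels),
        fixed_effects=_fixed_effects_frame(names, res.x[:k], se),
        converged=bool(res.success), data_shape=(len(y), k),
    )
    _summaries(fit, table, link_exp=True)
    return fit


def nb_mixed_loglik_oracle_ready(table: pd.DataFrame, time_coding: str,
                                 outcome: str = "diversity",
                                 covariates: Sequence[str] = ()):
    """Expose (data, loglik function) so tests can evaluate the marginal
    likelihood at fixed parameters against independent integrators."""
    y = table[outcome].to_numpy(float)
    X, names = build_design(table, time_coding, covariates)
    data = _NBMixedData(y, X, table["patient_id"].to_numpy())
    return data, names, (lambda params, nodes=25:
                         _nb_mixed_loglik(np.asarray(params), data, nodes, None))


# ---------------------------------------------------------------------------
# Linear mixed model (random intercept, ML, profiled variance ratio)
# ---------------------------------------------------------------------------

def _lmm_profile(y, X, codes, G, lam):
    """Profile ML pieces at variance ratio lam = sigma_b^2 / sigma_e^2."""
    n = len(y)
    ni = np.bincount(codes, minlength=G).astype(float)
    ci = lam / (1.0 + ni * lam)
    Sx = np.zeros((G, X.shape[1]))
    Sy = np.zeros(G)
    np.add.at(Sx, codes, X)
    np.add.at(Sy, codes, y)
    A = X.T @ X - (Sx * ci[:, None]).T @ Sx
    bvec = X.T @ y - Sx.T @ (ci * Sy)
    beta = np.linalg.solve(A, bvec)
    yVy = y @ y - ci @ Sy**2
    rss = yVy - beta @ bvec
    sigma2 = rss / n
    ll = (-0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
          - 0.5 * np.sum(np.log1p(ni * lam)))
    return ll, beta, sigma2, A


def fit_linear_mixed(
    table: pd.DataFrame,
    time_coding: str = "continuous",
    outcome: str = "percent_methylation_readweighted",
    covariates: Sequence[str] = (),
    lambda_fixed: float | None = None,
    interaction: bool = True,
) -> TrendFit:
    """ML random-intercept linear regression of a continuous crypt-level
    outcome.  The between/within variance ratio is profiled out and
    maximized on a 1-D log grid + local refinement; the lambda = 0 boundary
    reproduces OLS exactly."""
    y = table[outcome].to_numpy(float)
    if not np.isfinite(y).all():
        raise ValueError("outcome contains non-finite values")
    if table.groupby("group")["patient_id"].nunique().min() < 2:
        raise ValueError("need >= 2 patients per group for a mixed fit")
    X, names = build_design(table, time_coding, covariates, interaction)
    levels, codes = np.unique(table["patient_id"].to_numpy(), return_inverse=True)
    G = len(levels)

    if lambda_fixed is not None:
        lam = float(lambda_fixed)
    else:
        grid = np.concatenate([[0.0], np.exp(np.linspace(-10, 8, 73))])
        lls = [_lmm_profile(y, X, codes, G, l)[0] for l in grid]
        lam = float(grid[int(np.argmax(lls))])
        if lam > 0:
            r = optimize.minimize_scalar(
                lambda u: -_lmm_profile(y, X, codes, G, np.exp(u))[0],
                bounds=(np.log(lam) - 1.5, np.log(lam) + 1.5), method="bounded",
                options={"xatol": 1e-10})
            if -r.fun >= max(lls):
                lam = float(np.exp(r.x))
    ll, beta, sigma2, A = _lmm_profile(y, X, codes, G, lam)
    if lam < 1e-10:
        logger.warning("random-intercept variance on boundary (~0); "
                       "estimates equal OLS")

    k = len(names)
    cov_beta = sigma2 * np.linalg.inv(A)
    cov = np.zeros((k + 2, k + 2))
    cov[:k, :k] = cov_beta
    se = np.sqrt(np.diag(cov_beta))
    fit = TrendFit(
        model_kind="linear_mixed", time_coding=time_coding,
        params=np.concatenate([beta, [sigma2, lam * sigma2]]),
        names=names, cov=cov, loglik=float(ll),
        dispersion=None, random_intercept_variance=float(lam * sigma2),
        residual_variance=float(sigma2), n_obs=len(y), n_groups=G,
        fixed_effects=_fixed_effects_frame(names, beta, se),
        converged=True, data_shape=(len(y), k),
    )
    _summaries(fit, table, link_exp=False)
    return fit


# ---------------------------------------------------------------------------
# Interaction testing, rate projection
# ---------------------------------------------------------------------------

def test_interaction(fit_full: TrendFit, fit_reduced: TrendFit) -> dict:
    """Likelihood-ratio test between nested fits, reported alongside the
    full model's Wald interaction p-value."""
    if fit_full.model_kind != fit_reduced.model_kind:
        raise ValueError("fits are not the same model kind")
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("fits are not on the same data")
    if not set(fit_reduced.names) <= set(fit_full.names):
        raise ValueError("models are not nested")
    df = len(fit_full.names) - len(fit_reduced.names)
    stat = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return {"lrt_statistic": stat, "df": df, "p_lrt": p,
            "p_wald": fit_full.interaction_p}


def project_rate(baseline_mean: float, rate_per_year: float, years: float,
                 decimals: int = 2) -> float:
    """Project a mean count forward under a multiplicative per-year rate:
    baseline x rate^years, reported at 2 decimals by convention.

    A rate of 0.96 applied to a mean of 4.46 gives 4.28 after one year and
    4.11 after two.
    """
    if rate_per_year <= 0:
        raise ValueError("rate_per_year must be > 0")
    return round(float(baseline_mean) * rate_per_year ** years, decimals)


# ---------------------------------------------------------------------------
# Per-patient trends and correlations
# ---------------------------------------------------------------------------

def _patient_count_rate(y: np.ndarray, t: np.ndarray) -> float:
    """Per-patient NB regression of counts on years; returns exp(slope).
    Falls back to a Poisson GLM when the NB MLE does not converge (same
    mean structure)."""
    X = sm.add_constant(t)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            r = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            if np.isfinite(r.params[1]) and r.mle_retvals.get("converged", False):
                return float(np.exp(r.params[1]))
        except Exception:
            pass
        r = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return float(np.exp(r.params[1]))


def per_patient_trends(table: pd.DataFrame, polyps: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per patient: NB rate of diversity change per year, OLS change in
    percent methylation per year, OLS change in polyp count per year; then
    Pearson correlations between the three across patients (groups pooled,
    kept as a label)."""
    rows = []
    pct_col = ("percent_methylation_readweighted"
               if "percent_methylation_readweighted" in table.columns
               else "percent_methylation")
    for pid, sub in table.groupby("patient_id"):
        t = sub["timepoint_years"].to_numpy(float)
        if len(np.unique(t)) < 2:
            logger.warning("patient %s: <2 timepoints; excluded", pid)
            continue
        y = sub["diversity"].to_numpy(float)
        if (y == 0).all():
            logger.warning("patient %s: all-zero counts; rate undefined, excluded", pid)
            rate = float("nan")
        else:
            rate = _patient_count_rate(y, t)
        dpct = float(np.polyfit(t, sub[pct_col].to_numpy(float), 1)[0])
        prow = polyps[polyps["patient_id"] == pid]
        if len(prow) >= 2:
            dpol = float(np.polyfit(prow["timepoint_years"].to_numpy(float),
                                    prow["polyps"].to_numpy(float), 1)[0])
        else:
            dpol = float("nan")
        rows.append({"patient_id": pid, "group": sub["group"].iloc[0],
                     "rate_patterns_per_year": rate,
                     "delta_percent_per_year": dpct,
                     "delta_polyps_per_year": dpol})
    trends = pd.DataFrame(rows)
    correlations = {}
    pairs = [("rate_patterns_per_year", "delta_polyps_per_year"),
             ("delta_percent_per_year", "delta_polyps_per_year"),
             ("rate_patterns_per_year", "delta_percent_per_year")]
    for a, b in pairs:
        sub = trends[[a, b]].dropna()
        if len(sub) >= 3 and sub[a].std() > 0 and sub[b].std() > 0:
            r, p = sps.pearsonr(sub[a], sub[b])
            correlations[f"{a}__vs__{b}"] = {"r": float(r), "p": float(p),
                                             "n": int(len(sub))}
        else:
            correlations[f"{a}__vs__{b}"] = {"r": float("nan"), "p": float("nan"),
                                             "n": int(len(sub))}
    return trends, correlations


def adjust_for_age(
    table: pd.DataFrame,
    ages: pd.DataFrame,
    model: str = "nb",
    time_coding: str = "continuous",
    **kwargs,
) -> dict:
    """Refit a trend model with baseline age (centered) as an extra fixed
    covariate; returns {"unadjusted": fit, "adjusted": fit-or-None}.

    Missing ages refuse adjustment (unadjusted fit returned with a notice);
    a constant age column is dropped as inestimable with a warning.
    """
    fitter = fit_nb_mixed if model == "nb" else fit_linear_mixed
    unadjusted = fitter(table, time_coding=time_coding, **kwargs)
    amap = dict(zip(ages["patient_id"], ages["age"]))
    missing = sorted(set(table["patient_id"]) - set(amap))
    if missing:
        logger.warning("ages missing for patients %s; adjustment refused, "
                       "reporting unadjusted fit", missing)
        return {"unadjusted": unadjusted, "adjusted": None}
    aug = table.copy()
    aug["age_centered"] = aug["patient_id"].map(amap).astype(float)
    if aug["age_centered"].nunique() == 1:
        logger.warning("age constant across patients; covariate inestimable "
                       "and dropped (adjusted fit equals unadjusted)")
        return {"unadjusted": unadjusted, "adjusted": unadjusted}
    aug["age_centered"] -= aug["age_centered"].mean()
    adjusted = fitter(aug, time_coding=time_coding,
                      covariates=["age_centered"], **kwargs)
    return {"unadjusted": unadjusted, "adjusted": adjusted}


# ---------------------------------------------------------------------------
# Generative helper for power / calibration / recovery studies
# ---------------------------------------------------------------------------

def simulate_nb_mixed_table(
    rng: np.random.Generator,
    n_patients_per_group: int = 4,
    n_crypts: int = 10,
    timepoints: Sequence[tuple[str, float]] = (("t0", 0.0), ("t4m", 1 / 3), ("t2y", 2.0)),
    baseline_mean: float = 2.2,
    group_ratio_baseline: float = 1.0,
    rate_placebo: float = 1.3,
    rate_sulindac: float = 1.0,
    theta: float = 8.0,
    sigma_b: float = 0.3,
) -> pd.DataFrame:
    """Draw a crypt-level diversity table from the NB-mixed generative
    model itself (used for parameter-recovery and calibration studies)."""
    rows = []
    for gi, group in enumerate(("placebo", "sulindac")):
        rate = rate_placebo if group == "placebo" else rate_sulindac
        for p in range(n_patients_per_group):
            pid = f"{group[:2].upper()}{p + 1}"
            b = rng.normal(0.0, sigma_b)
            for lab, yrs in timepoints:
                mu = (baseline_mean * (group_ratio_baseline if gi else 1.0)
                      * rate ** yrs * np.exp(b))
                y = rng.negative_binomial(theta, theta / (theta + mu), size=n_crypts)
                for c, yv in enumerate(y):
                    rows.append({"crypt_id": f"{pid}_{lab}_c{c}", "patient_id": pid,
                                 "group": group, "timepoint_label": lab,
                                 "timepoint_years": yrs, "diversity": int(yv)})
    return pd.DataFrame(rows)
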