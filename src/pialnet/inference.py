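"""Poisson mixed-model inference for per-region vascular counts.

The count of PAs, LMAs or offshoot vertices C in region R of animal M is
modelled as Poisson with log link and a known offset log(A) for region
area, so coefficients act on densities:

    log E[C] = γ₁S + α₀Y + α₁(Y·S) + γ₃G + γ₄R + γ₅(S·R) + u₁[M] + log A

with S the deprivation group, Y age (centred), G sex, R the cortical
region, and u₁[M] ~ N(0, σ_u²) a per-animal random intercept capturing
shared between-animal variation in overall vessel counts.

The marginal likelihood — the Poisson likelihood integrated over the
Gaussian random intercept — is maximized directly: the one-dimensional
integral per animal is evaluated by adaptive Gauss–Hermite quadrature
(mode + curvature rescaling; 1 node = Laplace approximation) inside a
quasi-Newton outer optimization.  Factors are tested by drop-one
likelihood-ratio tests; post-hoc region contrasts use a single-step
max-|z| multivariate-normal adjustment (the z-statistic analogue of
Tukey's HSD); Poisson adequacy is checked by a χ² test on the Pearson
residual sum of squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .errors import PialnetError, ValidationError
from .territories import CountTable

#: All fixed-effect terms of the full model, in canonical order.
FULL_TERMS = ("S", "Y", "Y:S", "G", "R", "S:R")

_REF = {"R": "barrels", "S": "sham", "G": "M"}


@dataclass
class ModelSpec:
    """Which fixed effects enter the log-linear count model.

    The offset log(A) and the intercept are always present; the random
    animal intercept is always present unless ``sigma_u`` is fixed at 0.
    Treatment (dummy) coding against barrels / sham / male reference
    levels; age is centred at the cohort mean.
    """

    fixed_terms: tuple = FULL_TERMS
    n_quad: int = 15
    fix_sigma_u: Optional[float] = None   # None = estimate

    def __post_init__(self):
        bad = set(self.fixed_terms) - set(FULL_TERMS)
        if bad:
            raise ValidationError(f"unknown model terms: {sorted(bad)}")
        self.fixed_terms = tuple(t for t in FULL_TERMS if t in self.fixed_terms)

    def reduced(self, drop: str) -> "ModelSpec":
        """The spec with one factor removed (for drop-one LRTs)."""
        if drop not in self.fixed_terms:
            raise ValidationError(f"term {drop!r} not in model")
        return ModelSpec(tuple(t for t in self.fixed_terms if t != drop),
                         self.n_quad, self.fix_sigma_u)


def design_matrix(table: CountTable, spec: ModelSpec):
    """Build (y, X, offset, group_codes, column_names, level info)."""
    df = table.df.reset_index(drop=True)
    y = df["count"].to_numpy(float)
    offset = np.log(df["area_mm2"].to_numpy(float))
    groups, g_levels = pd.factorize(df["animal_id"], sort=True)

    cols = [np.ones(len(df))]
    names = ["intercept"]
    s = (df["group"] == "plucked").to_numpy(float)
    yc = df["age_days"].to_numpy(float)
    yc = yc - yc.mean()
    g = (df["sex"] == "F").to_numpy(float)
    regions = sorted(df["region"].unique())
    nonref = [r for r in regions if r != _REF["R"]]
    rdum = {r: (df["region"] == r).to_numpy(float) for r in nonref}

    for term in spec.fixed_terms:
        if term == "S":
            cols.append(s)
            names.append("S[plucked]")
        elif term == "Y":
            cols.append(yc)
            names.append("Y")
        elif term == "Y:S":
            cols.append(yc * s)
            names.append("Y:S[plucked]")
        elif term == "G":
            cols.append(g)
            names.append("G[F]")
        elif term == "R":
            for r in nonref:
                cols.append(rdum[r])
                names.append(f"R[{r}]")
        elif term == "S:R":
            for r in nonref:
                cols.append(s * rdum[r])
                names.append(f"S[plucked]:R[{r}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValidationError(
            f"rank-deficient design: rank {rank} < {X.shape[1]} columns "
            f"({names}); aliased terms must be dropped")
    return y, X, offset, groups, names, {"regions": regions, "n_groups": len(g_levels)}


@dataclass
class FitResult:
    """A maximized Poisson mixed-model fit."""

    estimates: pd.Series          # fixed-effect coefficients
    se: pd.Series
    sigma_u: float
    loglik: float
    vcov: pd.DataFrame            # fixed-effect covariance
    fitted: np.ndarray            # conditional expected counts per row
    pearson_residuals: np.ndarray
    converged: bool
    n_obs: int
    n_fixed_params: int
    spec: ModelSpec
    u_hat: np.ndarray = field(repr=False, default=None)
    info: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# marginal likelihood

def _group_slices(groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_groups) != 0])
    return order, starts


class _MarginalLoglik:
    """Adaptive Gauss–Hermite marginal log-likelihood for a Poisson model
    with one Gaussian random intercept per animal.

    Per animal i the integrand's log is
        h(u) = T_i u − A_i(β) e^u − u²/(2σ²),
    with T_i = Σ_j y_ij and A_i = Σ_j exp(x_ij'β + offset_ij); h is
    strictly concave, so the mode is found by a few Newton steps and the
    integral rescaled to the mode/curvature before quadrature.
    """

    def __init__(self, y, X, offset, groups, n_quad=15):
        self.order, self.starts = _group_slices(groups)
        self.y = y[self.order]
        self.X = X[self.order]
        self.offset = offset[self.order]
        self.T = np.add.reduceat(self.y, self.starts)
        self.const = float(np.sum(self.y * self.offset - gammaln(self.y + 1.0)))
        z, w = hermgauss(n_quad)
        self.z, self.logw = z, np.log(w)

    def _eta(self, beta):
        return self.X @ beta + self.offset

    def poisson_loglik(self, beta):
        """σ_u = 0 limit: plain Poisson log-likelihood."""
        eta = self._eta(beta)
        return float(np.sum(self.y * eta - np.exp(eta) - gammaln(self.y + 1.0)))

    def __call__(self, beta, sigma):
        if sigma < 1e-8:
            return self.poisson_loglik(beta)
        eta = self._eta(beta)
        A = np.add.reduceat(np.exp(eta), self.starts)
        T = self.T
        # Newton for the per-animal mode of h(u)
        u = np.zeros_like(A)
        inv_s2 = 1.0 / (sigma * sigma)
        for _ in range(50):
            eu = np.exp(np.clip(u, -40, 40))
            grad = T - A * eu - u * inv_s2
            hess = -A * eu - inv_s2
            step = grad / hess
            step = np.clip(step, -5.0, 5.0)
            u -= step
            if np.max(np.abs(step)) < 1e-12:
                break
        eu = np.exp(np.clip(u, -40, 40))
        tau = 1.0 / np.sqrt(A * eu + inv_s2)
        # h at the quadrature abscissae u_k = û + √2 τ z
        uk = u[:, None] + math.sqrt(2.0) * tau[:, None] * self.z[None, :]
        h = (T[:, None] * uk - A[:, None] * np.exp(np.clip(uk, -40, 40))
             - 0.5 * uk * uk * inv_s2)
        log_int = (math.log(math.sqrt(2.0)) + np.log(tau)
                   + logsumexp(self.logw[None, :] + self.z[None, :] ** 2 + h,
                               axis=1))
        # Σ_j y η_j (β part) per animal + normalization
        beta_part = float(np.sum(self.y * (self.X @ beta))) + self.const
        n_groups = len(T)
        return float(beta_part - n_groups * math.log(sigma * math.sqrt(2 * math.pi))
                     + np.sum(log_int))

    def modes(self, beta, sigma):
        """Empirical-Bayes modes û per animal (0 when σ_u = 0)."""
        A = np.add.reduceat(np.exp(self._eta(beta)), self.starts)
        if sigma < 1e-8:
            return np.zeros_like(A)
        u = np.zeros_like(A)
        inv_s2 = 1.0 / (sigma * sigma)
        for _ in range(50):
            eu = np.exp(np.clip(u, -40, 40))
            grad = self.T - A * eu - u * inv_s2
            hess = -A * eu - inv_s2
            step = np.clip(grad / hess, -5.0, 5.0)
            u -= step
            if np.max(np.abs(step)) < 1e-12:
                break
        return u


def _numerical_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H


def fit_poisson_glmm(table: CountTable, spec: Optional[ModelSpec] = None,
                     ) -> FitResult:
    """Maximize the marginal likelihood of the Poisson mixed count model.

    Starting values come from the σ_u = 0 Poisson regression; the outer
    optimization is quasi-Newton (L-BFGS-B) over (β, σ_u) with σ_u ≥ 0,
    converging on relative log-likelihood change below 1e-8.  Standard
    errors derive from the numerically differentiated observed
    information of the marginal likelihood.
    """
    if spec is None:
        spec = ModelSpec()
    if len(table) == 0:
        raise ValidationError("empty count table")
    y, X, offset, groups, names, meta = design_matrix(table, spec)
    ml = _MarginalLoglik(y, X, offset, groups, spec.n_quad)
    p = X.shape[1]

    # σ_u = 0 Poisson GLM warm start
    import statsmodels.api as sm
    glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    try:
        beta0 = glm.fit().params
    except Exception:
        beta0 = np.zeros(p)
        beta0[0] = math.log(max(y.mean(), 0.1)) - offset.mean()

    fixed_sigma = spec.fix_sigma_u
    if fixed_sigma is not None:
        def nll(th):
            return -ml(th, fixed_sigma)
        x0 = beta0
        bounds = [(None, None)] * p
    else:
        def nll(th):
            return -ml(th[:p], th[p])
        x0 = np.r_[beta0, 0.3]
        bounds = [(None, None)] * p + [(0.0, 20.0)]

    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"ftol": 1e-10, "gtol": 1e-8,
                                     "maxiter": 500})
    beta = res.x[:p]
    sigma = fixed_sigma if fixed_sigma is not None else float(res.x[p])
    loglik = -float(res.fun)
    converged = bool(res.success)
    if not converged and res.jac is not None:
        # the line search can stall when the warm start is already the
        # optimum; a vanishing projected gradient is convergence
        converged = bool(np.max(np.abs(res.jac)) < 1e-3 * max(1.0, abs(res.fun)))

    # observed-information covariance of the fixed effects
    if fixed_sigma is not None or sigma < 1e-6:
        H = _numerical_hessian(lambda b: -ml(b, sigma), beta)
        try:
            cov_b = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_b = np.full((p, p), np.nan)
    else:
        H = _numerical_hessian(lambda th: -ml(th[:p], th[p]), np.r_[beta, sigma])
        try:
            cov_all = np.linalg.inv(H)
            cov_b = cov_all[:p, :p]
        except np.linalg.LinAlgError:
            cov_b = np.full((p, p), np.nan)

    u_hat = ml.modes(beta, sigma)
    eta_sorted = ml._eta(beta) + u_hat[
        np.searchsorted(ml.starts, np.arange(len(y)), side="right") - 1]
    fitted_sorted = np.exp(eta_sorted)
    fitted = np.empty_like(fitted_sorted)
    fitted[ml.order] = fitted_sorted
    pearson = (table.df["count"].to_numpy(float) - fitted) / np.sqrt(fitted)

    se = np.sqrt(np.clip(np.diag(cov_b), 0, None))
    return FitResult(
        estimates=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        sigma_u=float(sigma),
        loglik=loglik,
        vcov=pd.DataFrame(cov_b, index=names, columns=names),
        fitted=fitted,
        pearson_residuals=pearson,
        converged=converged,
        n_obs=len(y),
        n_fixed_params=p,
        spec=spec,
        u_hat=u_hat,
        info={"optimizer_message": str(res.message), "regions": meta["regions"]},
    )


# ---------------------------------------------------------------------------
# tests on fits

@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    factor_dropped: str


def likelihood_ratio_test(full: FitResult, reduced: FitResult,
                          factor: str = "") -> LRTResult:
    """Drop-one-factor likelihood-ratio test between nested fits."""
    f_terms, r_terms = set(full.spec.fixed_terms), set(reduced.spec.fixed_terms)
    if not r_terms <= f_terms or full.n_obs != reduced.n_obs:
        raise ValidationError("models are not nested on the same data")
    if not (full.converged and reduced.converged):
        raise PialnetError("refusing LRT on a non-converged fit")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise PialnetError(f"negative LRT statistic {stat:.3g}: "
                           "inner optimization failed")
    stat = max(stat, 0.0)
    df = full.n_fixed_params - reduced.n_fixed_params
    if df <= 0:
        p = 1.0
    else:
        p = float(stats.chi2.sf(stat, df))
    if not factor:
        factor = ",".join(sorted(f_terms - r_terms)) or "(none)"
    return LRTResult(stat, df, p, factor)


@dataclass
class Contrast:
    pair: tuple
    estimate: float
    se: float
    z: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class PosthocResult:
    factor: str
    contrasts: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "level_i": c.pair[0], "level_j": c.pair[1], "estimate": c.estimate,
            "se": c.se, "z": c.z, "p_unadjusted": c.p_unadjusted,
            "p_adjusted": c.p_adjusted} for c in self.contrasts])


def tukey_posthoc(fit: FitResult, factor: str = "R", n_draws: int = 100_000,
                  seed: int = 2024) -> PosthocResult:
    """All pairwise level contrasts with single-step max-|z| adjustment.

    Contrasts are on the link (log-density) scale.  The family-wise
    adjusted p-value of contrast i is P(max_j |Z_j| ≥ |z_i|) under the
    joint normal of all contrast z-statistics, evaluated by seeded
    Monte-Carlo — the z-based analogue of Tukey's HSD appropriate for a
    generalized mixed model.
    """
    if not fit.converged:
        raise PialnetError("refusing post-hoc tests on a non-converged fit")
    if factor != "R":
        raise ValidationError("post-hoc contrasts are implemented for the "
                              "region factor")
    if "R" not in fit.spec.fixed_terms:
        raise ValidationError("factor R not present in the fitted model")
    levels = list(fit.info.get("regions", []))
    if len(levels) < 2:
        raise ValidationError("factor must have at least 2 levels")
    names = list(fit.estimates.index)
    p = len(names)

    def level_vec(level):
        v = np.zeros(p)
        if level != _REF["R"]:
            v[names.index(f"R[{level}]")] = 1.0
        return v

    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    L = np.array([level_vec(a) - level_vec(b) for a, b in pairs])
    est = L @ fit.estimates.to_numpy()
    V = L @ fit.vcov.to_numpy() @ L.T
    se = np.sqrt(np.diag(V))
    z = est / se
    corr = V / np.outer(se, se)
    # draw from the joint null of the contrast z-statistics
    rng = np.random.default_rng(seed)
    jitter = 1e-10 * np.eye(len(pairs))
    chol = np.linalg.cholesky(corr + jitter)
    draws = rng.standard_normal((n_draws, len(pairs))) @ chol.T
    maxabs = np.abs(draws).max(axis=1)
    contrasts = []
    for i, pair in enumerate(pairs):
        p_raw = 2 * float(stats.norm.sf(abs(z[i])))
        p_adj = float(np.mean(maxabs >= abs(z[i])))
        p_adj = min(1.0, max(p_adj, p_raw))
        contrasts.append(Contrast(pair, float(est[i]), float(se[i]),
                                  float(z[i]), p_raw, p_adj))
    return PosthocResult(factor, contrasts)


@dataclass
class DispersionResult:
    statistic: float
    df: int
    ratio: float
    p_over: float
    p_under: float


def dispersion_check(fit: FitResult) -> DispersionResult:
    """χ² check of the Poisson mean–variance relation.

    The Pearson residual sum of squares is referred to χ² with
    n_obs − n_fixed_params degrees of freedom; both one-sided tails are
    reported (overdispersion: variance > mean; underdispersion:
    variance < mean).
    """
    if not fit.converged:
        raise PialnetError("refusing dispersion check on a non-converged fit")
    if fit.n_obs <= fit.n_fixed_params:
        raise ValidationError("no residual degrees of freedom")
    r = fit.pearson_residuals
    if np.all(np.abs(r) < 1e-12):
        raise PialnetError("degenerate residuals: fitted equals observed "
                           "everywhere; dispersion is undefined")
    stat = float(np.sum(r * r))
    df = fit.n_obs - fit.n_fixed_params
    return DispersionResult(
        statistic=stat, df=df, ratio=stat / df,
        p_over=float(stats.chi2.sf(stat, df)),
        p_under=float(stats.chi2.cdf(stat, df)))


# ---------------------------------------------------------------------------
# LMA-vs-PA regression (per-animal totals)

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    t: float
    df: int
    p_value: float
    p_adjusted: float
    k_comparisons: int


def lma_pa_regression(per_animal: Sequence[tuple[float, float]],
                      k_comparisons: int = 1) -> RegressionResult:
    """Least-squares regression of per-animal LMA totals on PA totals,
    with Bonferroni adjustment over ``k_comparisons`` fitted lines."""
    pairs = np.asarray(per_animal, float)
    if pairs.ndim != 2 or pairs.shape[0] < 3:
        raise ValidationError("need at least 3 (PA, LMA) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in PA counts: slope undefined")
    n = len(x)
    if np.ptp(y) == 0:   # flat response: slope 0 exactly, no evidence
        res = stats.linregress(x, y)
        r2, t, p = 0.0, 0.0, 1.0
    else:
        res = stats.linregress(x, y)
        r2 = float(res.rvalue ** 2)
        t = float(res.slope / res.stderr) if res.stderr > 0 else 0.0
        p = float(res.pvalue)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept), r_squared=r2,
        t=t, df=n - 2, p_value=p,
        p_adjusted=min(1.0, k_comparisons * p), k_comparisons=k_comparisons)


# ---------------------------------------------------------------------------
# power

@dataclass
class PowerSpec:
    n1: int = 10
    n2: int = 9
    alpha: float = 0.05
    power: float = 0.8
    tails: int = 1

    def __post_init__(self):
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValidationError("alpha and power must lie in (0, 1)")
        if self.n1 < 2 or self.n2 < 2:
            raise ValidationError("group sizes must be >= 2")
        if self.tails not in (1, 2):
            raise ValidationError("tails must be 1 or 2")


def _t_power(d: float, spec: PowerSpec) -> float:
    df = spec.n1 + spec.n2 - 2
    nc = d * math.sqrt(spec.n1 * spec.n2 / (spec.n1 + spec.n2))
    if spec.tails == 1:
        tcrit = stats.t.ppf(1 - spec.alpha, df)
        return float(stats.nct.sf(tcrit, df, nc))
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def detectable_effect_size(spec: PowerSpec) -> float:
    """Smallest Cohen's d a two-sample t-test detects at the requested
    power and level, from the noncentral-t power function (bisection to
    1e-6)."""
    if _t_power(0.0, spec) >= spec.power:
        warnings.warn("requested power is attained at zero effect size")
        return 0.0
    lo, hi = 0.0, 1.0
    while _t_power(hi, spec) < spec.power:
        hi *= 2.0
        if hi > 1e6:
            raise PialnetError("power target unreachable")
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2.0
        if _t_power(mid, spec) < spec.power:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def normal_approx_effect_size(spec: PowerSpec) -> float:
    """Closed-form normal-approximation oracle:
    (z_{1−α(/tails)} + z_{power}) · √(1/n1 + 1/n2)."""
    alpha = spec.alpha if spec.tails == 1 else spec.alpha / 2
    return float((stats.norm.ppf(1 - alpha) + stats.norm.ppf(spec.power))
                 * math.sqrt(1.0 / spec.n1 + 1.0 / spec.n2))
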