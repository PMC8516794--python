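"""Mixed-model and ANOVA inference for behavior, ERP amplitude and movement.

Three models carry the study's hypotheses, each with a two-level fixed
factor and by-participant random intercepts and slopes:

* reaction time ~ oddball variant, inverse-Gaussian family with inverse
  link (so the response-scale condition mean is 1 / linear predictor);
* miss ~ oddball variant, binomial family with logit link;
* P3 amplitude ~ tone role (standard/target), Gaussian LMM fit per
  condition, with *independent* random intercepts and slopes.

Estimation is maximum likelihood with a Laplace approximation to the
random-effect integrals — exact for the Gaussian LMM and for the
inverse-Gaussian/inverse pair, whose joint log-likelihood is quadratic in
the linear predictor.  Fixed effects are reported on the link scale with
standard errors from the observed information; single-coefficient
hypotheses use the Wald chi-square test ((beta/SE)^2 on 1 df), competing
family/link combinations are compared by log-likelihood with
likelihood-ratio tests for nested pairs, and block-level displacement
means are compared with one-way repeated-measures ANOVA (generalized eta
squared effect size, Bonferroni-corrected paired post hocs).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import optimize
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "GlmmSpec",
    "ModelFit",
    "AnovaResult",
    "fit_glmm",
    "wald_chisq",
    "compare_models",
    "rm_anova",
]

_FAMILY_LINKS = {
    "gaussian": {"identity", "log", "inverse"},
    "binomial": {"logit"},
    "inverse_gaussian": {"inverse", "identity", "log"},
    "gamma": {"inverse", "identity", "log"},
}


@dataclass(frozen=True)
class GlmmSpec:
    """Model formula: response ~ fixed (2-level factor) + (1 + fixed | groups)."""

    response: str
    fixed: str
    family: str = "gaussian"
    link: str = "identity"
    random: str = "independent"  # "independent" | "correlated" | "intercept"
    groups: str = "participant"
    reference: str | None = None  # reference level of the fixed factor

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_LINKS:
            raise ValueError(f"unknown family {self.family!r}")
        if self.link not in _FAMILY_LINKS[self.family]:
            raise ValueError(f"link {self.link!r} not admissible for {self.family}")
        if self.random not in ("independent", "correlated", "intercept"):
            raise ValueError(f"unknown random structure {self.random!r}")


@dataclass
class ModelFit:
    spec: GlmmSpec
    levels: tuple[str, str]  # (reference, other)
    beta_link: np.ndarray  # (intercept, slope)
    se_link: np.ndarray
    loglik: float
    vc: dict  # random-effect SDs (and correlation if modeled)
    dispersion: dict  # family shape/scale parameter
    n_params: int
    n_obs: int
    response_scale_summary: dict
    converged: bool = True
    singular: bool = False
    data_token: str = ""
    coef_names: tuple[str, str] = ("intercept", "slope")

    def coef(self, name: str) -> tuple[float, float]:
        if name not in self.coef_names:
            raise KeyError(f"no coefficient {name!r}; have {self.coef_names}")
        i = self.coef_names.index(name)
        return float(self.beta_link[i]), float(self.se_link[i])


# ---------------------------------------------------------------------------
# family/link log-likelihood terms: l(y; eta), dl/deta, d2l/deta2


def _link_funcs(link: str):
    if link == "identity":
        return (lambda e: e, lambda e: np.ones_like(e), lambda e: np.zeros_like(e))
    if link == "log":
        return (np.exp, np.exp, np.exp)
    if link == "inverse":
        return (lambda e: 1.0 / e, lambda e: -1.0 / e**2, lambda e: 2.0 / e**3)
    raise ValueError(link)


def _ll_terms(family: str, link: str, y: np.ndarray, eta: np.ndarray, disp: float):
    """Per-observation log-likelihood and its first two eta-derivatives.

    Returns (l, dl, d2l, ok) where ok is False if eta leaves the family's
    domain anywhere (caller treats the point as -inf).
    """
    if family == "binomial":  # logit link only
        p = expit(eta)
        l = y * eta - np.logaddexp(0.0, eta)
        return l, y - p, -p * (1.0 - p), True
    if family == "inverse_gaussian" and link == "inverse":
        if np.any(eta <= 0):
            return None, None, None, False
        lam = disp
        r = y * eta - 1.0
        l = 0.5 * np.log(lam / (2 * np.pi * y**3)) - lam * r**2 / (2 * y)
        return l, -lam * r, -lam * y, True
    mu_f, dmu, d2mu = _link_funcs(link)
    mu = mu_f(eta)
    if family == "gaussian":
        sig2 = disp**2
        l = -0.5 * np.log(2 * np.pi * sig2) - (y - mu) ** 2 / (2 * sig2)
        dldmu = (y - mu) / sig2
        d2ldmu = -np.ones_like(mu) / sig2
    elif family == "inverse_gaussian":
        if np.any(mu <= 0):
            return None, None, None, False
        lam = disp
        l = 0.5 * np.log(lam / (2 * np.pi * y**3)) - lam * (y - mu) ** 2 / (
            2 * mu**2 * y
        )
        dldmu = lam * (y - mu) / mu**3
        d2ldmu = -lam * (3 * y - 2 * mu) / mu**4
    elif family == "gamma":
        if np.any(mu <= 0):
            return None, None, None, False
        k = disp
        from scipy.special import gammaln

        l = k * np.log(k) - k * np.log(mu) - gammaln(k) + (k - 1) * np.log(y) - k * y / mu
        dldmu = k * (y - mu) / mu**2
        d2ldmu = k * (mu - 2 * y) / mu**3
    else:  # pragma: no cover
        raise ValueError(family)
    md, md2 = dmu(eta), d2mu(eta)
    return l, dldmu * md, d2ldmu * md**2 + dldmu * md2, True


# ---------------------------------------------------------------------------
# Laplace machinery


def _group_marginal(
    y: np.ndarray,
    z: np.ndarray,  # n x 2 design (shared by fixed and random parts)
    beta: np.ndarray,
    sig_inv: np.ndarray,
    logdet_sig: float,
    family: str,
    link: str,
    disp: float,
) -> float:
    """Laplace-approximate log marginal likelihood of one participant."""
    offset = z @ beta
    b = np.zeros(2)

    def joint(bv):
        terms = _ll_terms(family, link, y, offset + z @ bv, disp)
        if not terms[3]:
            return -np.inf, None, None
        l, dl, d2l = terms[:3]
        h = l.sum() - 0.5 * bv @ sig_inv @ bv
        g = z.T @ dl - sig_inv @ bv
        hess = (z * d2l[:, None]).T @ z - sig_inv
        return h, g, hess

    h, g, hess = joint(b)
    if not np.isfinite(h):
        return -np.inf
    for _ in range(60):
        try:
            step = -np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            step = g * 1e-3
        scale = 1.0
        for _ in range(30):
            h_new, g_new, hess_new = joint(b + scale * step)
            if np.isfinite(h_new) and h_new >= h - 1e-12:
                break
            scale *= 0.5
        else:
            break
        b, h, g, hess = b + scale * step, h_new, g_new, hess_new
        if np.max(np.abs(g)) < 1e-8:
            break
    sign, logdet_negh = np.linalg.slogdet(-hess)
    if sign <= 0:
        return -np.inf
    # + Gaussian prior normalizer and the Laplace volume term (q = 2)
    return h - 0.5 * logdet_sig - np.log(2 * np.pi) + np.log(2 * np.pi) - 0.5 * logdet_negh


_MIN_LOG_SD = np.log(1e-4)


def _unpack(theta: np.ndarray, spec: GlmmSpec, has_disp: bool):
    beta = theta[:2]
    i = 2
    if spec.random == "intercept":
        s0 = np.exp(max(theta[i], _MIN_LOG_SD))
        sig = np.diag([s0**2, 1e-12])
        i += 1
    else:
        s0 = np.exp(max(theta[i], _MIN_LOG_SD))
        s1 = np.exp(max(theta[i + 1], _MIN_LOG_SD))
        i += 2
        if spec.random == "correlated":
            rho = np.tanh(theta[i])
            i += 1
            sig = np.array(
                [[s0**2, rho * s0 * s1], [rho * s0 * s1, s1**2]]
            )
        else:
            sig = np.diag([s0**2, s1**2])
    disp = np.exp(theta[i]) if has_disp else 1.0
    return beta, sig, disp


def _marginal_loglik(
    theta: np.ndarray,
    spec: GlmmSpec,
    groups: list[tuple[np.ndarray, np.ndarray]],
    has_disp: bool,
) -> float:
    beta, sig, disp = _unpack(theta, spec, has_disp)
    sig = sig + np.eye(2) * 1e-10
    try:
        sig_inv = np.linalg.inv(sig)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = np.linalg.slogdet(sig)[1]
    total = 0.0
    for y, z in groups:
        m = _group_marginal(y, z, beta, sig_inv, logdet, spec.family, spec.link, disp)
        if not np.isfinite(m):
            return -np.inf
        total += m
    return total


def _start_values(spec: GlmmSpec, y: np.ndarray, x: np.ndarray, has_disp: bool):
    link_g = {
        "identity": lambda m: m,
        "log": np.log,
        "inverse": lambda m: 1.0 / m,
        "logit": lambda m: np.log(m / (1 - m)),
    }[spec.link]
    m0 = float(np.clip(y[x == 0].mean(), 1e-4, None))
    m1 = float(np.clip(y[x == 1].mean(), 1e-4, None)) if (x == 1).any() else m0
    if spec.family == "binomial":
        m0, m1 = np.clip([m0, m1], 0.01, 0.99)
    b0 = link_g(m0)
    b1 = link_g(m1) - b0
    theta = [b0, b1]
    n_sds = 1 if spec.random == "intercept" else 2
    theta += [np.log(max(0.1 * abs(b0), 1e-3))] * n_sds
    if spec.random == "correlated":
        theta += [0.0]
    if has_disp:
        var = float(y.var()) + 1e-12
        mean = float(y.mean())
        if spec.family == "gaussian":
            theta += [0.5 * np.log(var)]
        elif spec.family == "inverse_gaussian":
            theta += [np.log(max(mean**3 / var, 1e-3))]
        else:  # gamma
            theta += [np.log(max(mean**2 / var, 1e-3))]
    return np.asarray(theta, dtype=float)


def _numeric_hessian(f, theta: np.ndarray, h_rel: float = 1e-3) -> np.ndarray:
    n = len(theta)
    h = h_rel * (1.0 + np.abs(theta))
    hess = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei, ej = np.zeros(n), np.zeros(n)
            ei[i], ej[j] = h[i], h[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def fit_glmm(data: pd.DataFrame, spec: GlmmSpec) -> ModelFit:
    """Fit the two-level mixed model by Laplace maximum likelihood.

    ``data`` is long-format with the response, the two-level fixed factor
    and the grouping column.  Non-convergence or a singular (boundary)
    variance estimate is flagged on the returned fit, never silent.
    """
    cols = [spec.response, spec.fixed, spec.groups]
    d = data[cols].dropna()
    levels = sorted(d[spec.fixed].astype(str).unique())
    if spec.reference is not None:
        if spec.reference not in levels:
            raise ValueError(f"reference {spec.reference!r} not in {levels}")
        levels = [spec.reference] + [l for l in levels if l != spec.reference]
    if len(levels) != 2:
        raise ValueError(f"fixed factor must have 2 levels, found {levels}")
    if d[spec.groups].nunique() < 2:
        raise ValueError("need at least 2 groups (participants)")

    y_all = d[spec.response].to_numpy(dtype=float)
    x_all = (d[spec.fixed].astype(str) == levels[1]).to_numpy(dtype=float)
    has_disp = spec.family != "binomial"

    groups = []
    for _, sub in d.groupby(spec.groups):
        yy = sub[spec.response].to_numpy(dtype=float)
        xx = (sub[spec.fixed].astype(str) == levels[1]).to_numpy(dtype=float)
        groups.append((yy, np.column_stack([np.ones_like(xx), xx])))

    theta0 = _start_values(spec, y_all, x_all, has_disp)
    nll = lambda th: -_marginal_loglik(th, spec, groups, has_disp)
    res = optimize.minimize(
        nll,
        theta0,
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-4, "fatol": 1e-6, "adaptive": True},
    )
    theta = res.x
    loglik = -res.fun
    converged = bool(res.success) and np.isfinite(loglik)

    # Wald SEs from the fixed-effect block of the observed information,
    # variance/dispersion parameters held at their ML estimates (the usual
    # mixed-model Wald convention)
    se = np.full(2, np.nan)
    try:
        nll_beta = lambda b: nll(np.concatenate([b, theta[2:]]))
        hess = _numeric_hessian(nll_beta, theta[:2], h_rel=1e-4)
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.all(diag > 0):
            se = np.sqrt(diag)
        else:
            converged = False
    except np.linalg.LinAlgError:
        converged = False

    beta, sig, disp = _unpack(theta, spec, has_disp)
    sds = np.sqrt(np.diag(sig))
    vc = {"intercept_sd": float(sds[0]), "slope_sd": float(sds[1])}
    if spec.random == "correlated":
        vc["corr"] = float(sig[0, 1] / (sds[0] * sds[1] + 1e-300))
    singular = bool(np.any(sds[: 1 if spec.random == "intercept" else 2] < 2e-4))

    inv_link = {
        "identity": lambda e: e,
        "log": np.exp,
        "inverse": lambda e: 1.0 / e,
        "logit": expit,
    }[spec.link]
    mu_ref = float(inv_link(beta[0]))
    mu_other = float(inv_link(beta[0] + beta[1]))
    summary = {
        f"mean_{levels[0]}": mu_ref,
        f"mean_{levels[1]}": mu_other,
        "difference": mu_other - mu_ref,
    }
    disp_name = {
        "gaussian": "residual_sd",
        "inverse_gaussian": "shape",
        "gamma": "shape",
        "binomial": None,
    }[spec.family]
    token = hashlib.sha1(
        np.ascontiguousarray(np.sort(y_all)).tobytes()
    ).hexdigest()[:16]
    return ModelFit(
        spec=spec,
        levels=(levels[0], levels[1]),
        beta_link=beta.copy(),
        se_link=se,
        loglik=float(loglik),
        vc=vc,
        dispersion={disp_name: float(disp)} if disp_name else {},
        n_params=len(theta),
        n_obs=len(d),
        response_scale_summary=summary,
        converged=converged,
        singular=singular,
        data_token=token,
    )


def wald_chisq(fit: ModelFit, coefficient: str = "slope") -> tuple[float, int, float]:
    """Wald chi-square test of one coefficient: ((beta/SE)^2, 1, p)."""
    beta, se = fit.coef(coefficient)
    if not np.isfinite(se) or se <= 0:
        raise ValueError("no valid standard error for the Wald test")
    chi2 = (beta / se) ** 2
    return float(chi2), 1, float(sps.chi2.sf(chi2, 1))


def _is_nested(a: ModelFit, b: ModelFit) -> bool:
    """Simpler model a nested in b: same family/link, reduced structure."""
    return (
        a.spec.family == b.spec.family
        and a.spec.link == b.spec.link
        and a.n_params < b.n_params
        and a.spec.response == b.spec.response
    )


def compare_models(fits: list[ModelFit]) -> pd.DataFrame:
    """Rank fits by log-likelihood with LR tests against the best fit.

    All fits must be on identical data.  For each fit nested in the
    top-ranked model (same family and link, fewer parameters) the
    likelihood-ratio statistic 2*delta-loglik with df = parameter-count
    difference and its chi-square p-value are reported; non-nested pairs
    carry only the log-likelihood and are flagged.
    """
    if len({f.data_token for f in fits}) > 1 or len({f.n_obs for f in fits}) > 1:
        raise ValueError("model comparison requires fits on identical data")
    ranked = sorted(fits, key=lambda f: f.loglik, reverse=True)
    best = ranked[0]
    rows = []
    for f in ranked:
        nested = f is not best and (_is_nested(f, best) or _is_nested(best, f))
        lr = df = p = np.nan
        if f is best:
            lr, df, p = 0.0, 0, np.nan
        elif nested:
            lr = 2.0 * (best.loglik - f.loglik)
            df = abs(best.n_params - f.n_params)
            p = float(sps.chi2.sf(lr, max(df, 1)))
        rows.append(
            {
                "family": f.spec.family,
                "link": f.spec.link,
                "random": f.spec.random,
                "loglik": f.loglik,
                "n_params": f.n_params,
                "lr_vs_best": lr,
                "lr_df": df,
                "lr_p": p,
                "nested_in_best": bool(nested),
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    F: float
    df: tuple[float, float]
    p: float
    ges: float
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)
    degenerate: bool = False


def rm_anova(
    data: pd.DataFrame,
    *,
    dv: str = "value",
    within: str = "block",
    subject: str = "participant",
    posthoc: bool = True,
) -> AnovaResult:
    """One-way repeated-measures ANOVA with generalized eta squared.

    ``data`` is long-format, one row per subject x within-level cell; a
    missing cell raises (no silent listwise deletion).  Post hoc paired t
    tests over all level pairs are Bonferroni-corrected.
    """
    counts = data.groupby([subject, within])[dv].count().unstack()
    if counts.isna().any().any() or (counts != 1).any().any():
        raise ValueError("incomplete subject x level table for rm_anova")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(
            data=data, dv=dv, within=within, subject=subject, effsize="ng2"
        )
    # zero within- and between-cell variance leaves pingouin without F/p columns
    F = float(aov.loc[0, "F"]) if "F" in aov else np.nan
    ddof1, ddof2 = float(aov.loc[0, "ddof1"]), float(aov.loc[0, "ddof2"])
    p = float(aov.loc[0, "p_unc"]) if "p_unc" in aov else np.nan
    ges = float(aov.loc[0, "ng2"]) if "ng2" in aov else np.nan
    degenerate = not np.isfinite(F)
    if degenerate:
        F, p, ges = np.nan, np.nan, 0.0
    ph = pd.DataFrame()
    if posthoc and not degenerate:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ph = pg.pairwise_tests(
                data=data,
                dv=dv,
                within=within,
                subject=subject,
                padjust="bonf",
            )
    return AnovaResult(F, (ddof1, ddof2), p, ges, ph, degenerate)
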