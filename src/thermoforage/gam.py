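"""Penalized-spline additive models with factor random effects.

The engine fits Gaussian, binomial (logit) and Poisson (log) additive models
by penalized IRLS. Each smooth term carries its own smoothing parameter;
factor random effects enter as ridge-penalized indicator blocks (for a
random intercept) or indicator and indicator-times-covariate blocks with
separate variance parameters (random intercept + slope). Smoothing and
variance parameters are chosen by maximizing a Laplace-approximate
restricted marginal likelihood (exact REML in the Gaussian case),
coordinate-wise with Brent's method on the log scale.

Effective degrees of freedom (EDF) are trace-based: the diagonal of
``(X'WX + S)^{-1} X'WX`` summed over each term's columns. Information
criteria use the total EDF as the model dimension, the only coherent count
for a penalized fit: ``AIC = -2 loglik + 2 EDF`` and
``BIC = -2 loglik + EDF log n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .basis import SmoothBasis, build_basis

LOG_LAMBDA_BOUNDS = (-10.0, 18.0)
_BIG_LAMBDA = 1e12


@dataclass
class SmoothSpec:
    """One penalized smooth term of a model formula."""

    variable: str
    k: int = 5
    penalty_order: int = 2
    cyclic: bool = False
    period: float = 365.25

    def __post_init__(self) -> None:
        if not (3 <= self.k <= 20):
            raise ValueError(f"k must lie in [3, 20], got {self.k}")


@dataclass
class RandomEffectSpec:
    """A factor random effect: intercept, or intercept plus slope."""

    grouping: str
    structure: str = "intercept"
    slope_variable: str | None = None

    def __post_init__(self) -> None:
        if self.structure not in ("intercept", "intercept+slope"):
            raise ValueError(f"unknown random-effect structure {self.structure!r}")
        if self.structure == "intercept+slope" and self.slope_variable is None:
            raise ValueError("intercept+slope random effect needs slope_variable")
        if self.structure == "intercept" and self.slope_variable is not None:
            raise ValueError("slope_variable given but structure is intercept-only")


@dataclass
class TermBlock:
    name: str
    kind: str  # "intercept" | "parametric" | "smooth" | "random"
    sl: slice
    basis: SmoothBasis | None = None
    levels: np.ndarray | None = None
    slope_variable: str | None = None
    penalty_index: int | None = None  # index into the lambda vector


@dataclass
class Design:
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    offset: np.ndarray = field(repr=False)
    terms: list[TermBlock]
    penalties: list[tuple[slice, np.ndarray]] = field(repr=False)
    penalty_ranks: list[int] = field(default_factory=list)
    penalty_logpdets: list[float] = field(default_factory=list)
    n_unpenalized: int = 0
    family: str = "gaussian"

    def s_lambda(self, lam: np.ndarray) -> np.ndarray:
        p = self.X.shape[1]
        S = np.zeros((p, p))
        for lj, (sl, Sj) in zip(lam, self.penalties):
            S[sl, sl] += lj * Sj
        return S

    def log_pdet_s(self, lam: np.ndarray) -> float:
        return float(sum(r * np.log(lj) + lp for lj, r, lp in
                         zip(lam, self.penalty_ranks, self.penalty_logpdets)))


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# families

def _family_funcs(family: str):
    if family == "gaussian":
        def mu_of(eta):
            return eta

        def weights(mu):
            return np.ones_like(mu)

        def dmu(mu):
            return np.ones_like(mu)

        def dev_resid(y, mu):
            return (y - mu) ** 2
    elif family == "binomial":
        def mu_of(eta):
            return special.expit(eta)

        def weights(mu):
            return mu * (1.0 - mu)

        def dmu(mu):
            return mu * (1.0 - mu)

        def dev_resid(y, mu):
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            return 2.0 * (special.xlogy(y, y / mu) + special.xlogy(1 - y, (1 - y) / (1 - mu)))
    elif family == "poisson":
        def mu_of(eta):
            return np.exp(np.clip(eta, -30.0, 30.0))

        def weights(mu):
            return mu

        def dmu(mu):
            return mu

        def dev_resid(y, mu):
            mu = np.maximum(mu, 1e-12)
            return 2.0 * (special.xlogy(y, y / mu) - (y - mu))
    else:
        raise ValueError(f"unknown family {family!r}")
    return mu_of, weights, dmu, dev_resid


def _log_likelihood(family: str, y: np.ndarray, mu: np.ndarray, scale: float) -> float:
    if family == "gaussian":
        n = y.size
        return float(-0.5 * n * (np.log(2 * np.pi * scale) + 1.0)) if scale > 0 else np.inf
    if family == "binomial":
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return float(np.sum(special.xlogy(y, mu) + special.xlogy(1 - y, 1 - mu)))
    if family == "poisson":
        mu = np.maximum(mu, 1e-12)
        return float(np.sum(special.xlogy(y, mu) - mu - special.gammaln(y + 1.0)))
    raise ValueError(family)


def _null_deviance(family: str, y: np.ndarray, offset: np.ndarray) -> float:
    _, _, _, dev_resid = _family_funcs(family)
    if np.allclose(offset, 0.0):
        if family == "gaussian":
            mu0 = np.full_like(y, y.mean())
        elif family == "binomial":
            mu0 = np.full_like(y, np.clip(y.mean(), 1e-10, 1 - 1e-10))
        else:
            mu0 = np.full_like(y, max(y.mean(), 1e-10))
        return float(dev_resid(y, mu0).sum())
    # with an offset the null model still has a free intercept: 1-d fit
    from scipy.optimize import minimize_scalar

    mu_of, _, _, _ = _family_funcs(family)

    def obj(b0):
        return dev_resid(y, mu_of(np.full_like(y, b0) + offset)).sum()

    res = minimize_scalar(obj, bounds=(-20, 20), method="bounded")
    return float(res.fun)


# ---------------------------------------------------------------------------
# design construction

def build_design(data: pd.DataFrame, response: str, smooths=(), parametric=(),
                 random_effect: RandomEffectSpec | None = None,
                 family: str = "gaussian", offset: str | np.ndarray | None = None,
                 ) -> Design:
    n = len(data)
    y = np.asarray(data[response], dtype=float)
    if family == "binomial" and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binomial family requires a 0/1 response")
    if family == "poisson" and (np.any(y < 0) or np.any(y != np.round(y))):
        raise ValueError("poisson family requires non-negative integer response")
    if offset is None:
        off = np.zeros(n)
    elif isinstance(offset, str):
        off = np.asarray(data[offset], dtype=float)
    else:
        off = np.asarray(offset, dtype=float)

    cols: list[np.ndarray] = [np.ones((n, 1))]
    terms: list[TermBlock] = [TermBlock("intercept", "intercept", slice(0, 1))]
    penalties: list[tuple[slice, np.ndarray]] = []
    pos = 1
    for name in parametric:
        cols.append(np.asarray(data[name], dtype=float)[:, None])
        terms.append(TermBlock(name, "parametric", slice(pos, pos + 1)))
        pos += 1
    n_unpen = pos
    for spec in smooths:
        b = build_basis(np.asarray(data[spec.variable], dtype=float), spec.variable,
                        k=spec.k, penalty_order=spec.penalty_order,
                        cyclic=spec.cyclic, period=spec.period)
        Xs = b.design(np.asarray(data[spec.variable], dtype=float))
        sl = slice(pos, pos + Xs.shape[1])
        cols.append(Xs)
        terms.append(TermBlock(f"s({spec.variable})", "smooth", sl, basis=b,
                               penalty_index=len(penalties)))
        penalties.append((sl, b.penalty))
        pos += Xs.shape[1]
    if random_effect is not None:
        levels, codes = np.unique(np.asarray(data[random_effect.grouping]),
                                  return_inverse=True)
        G = levels.size
        Zi = np.zeros((n, G))
        Zi[np.arange(n), codes] = 1.0
        sl = slice(pos, pos + G)
        cols.append(Zi)
        terms.append(TermBlock(f"re({random_effect.grouping})", "random", sl,
                               levels=levels, penalty_index=len(penalties)))
        penalties.append((sl, np.eye(G)))
        pos += G
        if random_effect.structure == "intercept+slope":
            z = np.asarray(data[random_effect.slope_variable], dtype=float)
            Zs = Zi * z[:, None]
            sl = slice(pos, pos + G)
            cols.append(Zs)
            terms.append(TermBlock(
                f"re({random_effect.grouping}|{random_effect.slope_variable})",
                "random", sl, levels=levels,
                slope_variable=random_effect.slope_variable,
                penalty_index=len(penalties)))
            penalties.append((sl, np.eye(G)))
            pos += G

    X = np.hstack(cols)
    ranks, logpdets = [], []
    for _, Sj in penalties:
        ev = np.linalg.eigvalsh(Sj)
        pos_ev = ev[ev > 1e-10 * max(ev.max(), 1.0)]
        ranks.append(int(pos_ev.size))
        logpdets.append(float(np.sum(np.log(pos_ev))))
    return Design(X=X, y=y, offset=off, terms=terms, penalties=penalties,
                  penalty_ranks=ranks, penalty_logpdets=logpdets,
                  n_unpenalized=n_unpen, family=family)


# ---------------------------------------------------------------------------
# penalized IRLS at fixed lambda

def _pirls(design: Design, lam: np.ndarray, beta0: np.ndarray | None = None,
           max_iter: int = 200, tol: float = 1e-8):
    X, y, off, family = design.X, design.y, design.offset, design.family
    n, p = X.shape
    mu_of, wfun, dmu, dev_resid = _family_funcs(family)
    S = design.s_lambda(lam)

    if family == "gaussian":
        A = X.T @ X + S
        b = X.T @ (y - off)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            # zero-variance columns (e.g. a constant covariate) make A
            # singular; the minimum-norm solution sets their coefficients to 0
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
        eta = X @ beta + off
        mu = eta
        dev = float(((y - mu) ** 2).sum())
        return beta, mu, np.ones(n), dev, True, 1, []

    if beta0 is not None and beta0.shape == (p,):
        beta = beta0.copy()
        eta = X @ beta + off
    else:
        beta = np.zeros(p)
        if family == "binomial":
            mu0 = np.clip((y + 0.5) / 2.0, 0.01, 0.99)
            eta = np.log(mu0 / (1 - mu0))
        else:
            mu0 = y + 0.1
            eta = np.log(mu0)
    mu = mu_of(eta)
    dev = float(dev_resid(y, mu).sum())
    pdev = dev + float(beta @ S @ beta)
    notes: list[str] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.maximum(wfun(mu), 1e-10)
        z = (eta - off) + (y - mu) / np.maximum(dmu(mu), 1e-10)
        WX = X * w[:, None]
        A = X.T @ WX + S
        try:
            beta_new = np.linalg.solve(A, WX.T @ z)
        except np.linalg.LinAlgError:
            A += 1e-8 * np.eye(p)
            beta_new = np.linalg.solve(A, WX.T @ z)
        eta_new = X @ beta_new + off
        mu_new = mu_of(eta_new)
        dev_new = float(dev_resid(y, mu_new).sum())
        pdev_new = dev_new + float(beta_new @ S @ beta_new)
        # step halving on the penalized deviance, the PIRLS objective
        step = 1.0
        while not np.isfinite(pdev_new) or pdev_new > pdev * (1 + 1e-6) + 1e-9:
            step /= 2.0
            if step < 1e-4:
                break
            beta_new = beta + step * (beta_new - beta)
            eta_new = X @ beta_new + off
            mu_new = mu_of(eta_new)
            dev_new = float(dev_resid(y, mu_new).sum())
            pdev_new = dev_new + float(beta_new @ S @ beta_new)
        rel = abs(pdev - pdev_new) / (abs(pdev_new) + 0.1)
        beta, eta, mu, dev, pdev = beta_new, eta_new, mu_new, dev_new, pdev_new
        if rel < tol:
            converged = True
            break
    if not converged:
        notes.append(f"IRLS did not converge in {max_iter} iterations (last dev {dev:.6g})")
    if family == "binomial" and np.max(np.abs(eta)) > 12.0:
        notes.append("possible separation: |linear predictor| > 12")
    w = np.maximum(wfun(mu), 1e-10)
    return beta, mu, w, dev, converged, it, notes


def _reml_score(design: Design, lam: np.ndarray, beta0=None):
    """Negative Laplace-approximate REML (exact for Gaussian), to minimize."""
    beta, mu, w, dev, conv, it, notes = _pirls(design, lam, beta0)
    X = design.X
    S = design.s_lambda(lam)
    pen = float(beta @ S @ beta)
    A = X.T @ (X * w[:, None]) + S
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf, beta
    log_pdet_s = design.log_pdet_s(lam)
    n, M = X.shape[0], design.n_unpenalized
    if design.family == "gaussian":
        rss_p = dev + pen
        score = 0.5 * (n - M) * np.log(rss_p) + 0.5 * (logdet_a - log_pdet_s)
    else:
        score = 0.5 * (dev + pen) + 0.5 * (logdet_a - log_pdet_s)
    return float(score), beta


def gaussian_reml_loglik(design: Design, lam: np.ndarray) -> float:
    """Exact restricted log-likelihood of a Gaussian fit at fixed lambda."""
    if design.family != "gaussian":
        raise ValueError("restricted likelihood is computed for Gaussian fits only")
    beta, mu, w, dev, *_ = _pirls(design, lam)
    S = design.s_lambda(lam)
    rss_p = dev + float(beta @ S @ beta)
    A = design.X.T @ design.X + S
    _, logdet_a = np.linalg.slogdet(A)
    n, M = design.X.shape[0], design.n_unpenalized
    nm = n - M
    phi = rss_p / nm
    return float(-0.5 * nm * (np.log(2 * np.pi * phi) + 1.0)
                 + 0.5 * (design.log_pdet_s(lam) - logdet_a))


# ---------------------------------------------------------------------------
# the public fit object

@dataclass
class AdditiveFit:
    family: str
    coefficients: np.ndarray
    smoothing_params: dict[str, float]
    edf_per_term: dict[str, float]
    total_edf: float
    log_likelihood: float
    deviance: float
    null_deviance: float
    deviance_explained: float
    aic: float
    bic: float
    scale: float
    converged: bool
    n_iter: int
    notes: list[str]
    reml: float | None
    design_description: list[str]
    design_: Design = field(repr=False)
    cov_: np.ndarray = field(repr=False)
    fitted_: np.ndarray = field(repr=False)

    @property
    def nobs(self) -> int:
        return self.design_.y.size

    def term(self, name: str) -> TermBlock:
        for t in self.design_.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term named {name!r}; have {[t.name for t in self.design_.terms]}")

    def coef_block(self, name: str) -> np.ndarray:
        return self.coefficients[self.term(name).sl]

    def _newdata_design(self, newdata: pd.DataFrame, re_action: str = "include") -> np.ndarray:
        n = len(newdata)
        X = np.zeros((n, self.design_.X.shape[1]))
        for t in self.design_.terms:
            if t.kind == "intercept":
                X[:, t.sl] = 1.0
            elif t.kind == "parametric":
                X[:, t.sl] = np.asarray(newdata[t.name], dtype=float)[:, None]
            elif t.kind == "smooth":
                x = np.asarray(newdata[t.basis.variable], dtype=float)
                lo, hi = t.basis.training_range
                span = max(hi - lo, 1e-12)
                if x.min() < lo - 0.1 * span or x.max() > hi + 0.1 * span:
                    warnings.warn(
                        f"prediction for {t.basis.variable} extrapolates beyond "
                        f"10% of the training range [{lo:.3g}, {hi:.3g}]",
                        stacklevel=3)
                X[:, t.sl] = t.basis.design(x)
            elif t.kind == "random":
                if re_action == "zero":
                    continue
                group_col = t.name.split("(")[1].split("|")[0].rstrip(")")
                g = np.asarray(newdata[group_col])
                codes = np.searchsorted(t.levels, g)
                known = (codes < t.levels.size) & (t.levels[np.minimum(codes, t.levels.size - 1)] == g)
                Zi = np.zeros((n, t.levels.size))
                Zi[np.where(known)[0], codes[known]] = 1.0
                if t.slope_variable is not None:
                    Zi = Zi * np.asarray(newdata[t.slope_variable], dtype=float)[:, None]
                X[:, t.sl] = Zi
        return X

    def predict(self, newdata: pd.DataFrame, se: bool = False,
                re_action: str = "include", offset: np.ndarray | None = None):
        """Mean response on the inverse-link scale, optionally with SE of the
        linear predictor mapped through the link derivative."""
        X = self._newdata_design(newdata, re_action=re_action)
        eta = X @ self.coefficients
        if offset is not None:
            eta = eta + offset
        mu_of, _, dmu, _ = _family_funcs(self.family)
        mu = mu_of(eta)
        if not np.all(np.isfinite(mu)):
            raise FitError("non-finite predictions")
        if not se:
            return mu
        var_eta = np.einsum("ij,jk,ik->i", X, self.cov_, X)
        se_mu = np.sqrt(np.maximum(var_eta, 0.0)) * np.abs(dmu(mu))
        return mu, se_mu

    def summary_dict(self) -> dict:
        return {
            "family": self.family,
            "n": int(self.nobs),
            "edf_per_term": {k: round(v, 4) for k, v in self.edf_per_term.items()},
            "total_edf": round(self.total_edf, 4),
            "smoothing_params": {k: float(v) for k, v in self.smoothing_params.items()},
            "log_likelihood": self.log_likelihood,
            "deviance_explained": self.deviance_explained,
            "aic": self.aic,
            "bic": self.bic,
            "converged": self.converged,
            "notes": list(self.notes),
        }


def fit_additive(data: pd.DataFrame, response: str, smooths=(), parametric=(),
                 random_effect: RandomEffectSpec | None = None,
                 family: str = "gaussian", offset=None,
                 fixed_lambda: dict[str, float] | float | None = None,
                 max_iter: int = 200, tol: float = 1e-8) -> AdditiveFit:
    """Fit a penalized additive model; smoothing parameters by REML unless fixed.

    ``fixed_lambda`` may be a scalar applied to every penalty or a dict keyed
    by term name (``"s(var)"``, ``"re(group)"``, ``"re(group|slope)"``);
    ``numpy.inf`` collapses a term onto its penalty null space.
    """
    if len(data) < 10:
        raise ValueError("need at least 10 observations")
    design = build_design(data, response, smooths=smooths, parametric=parametric,
                          random_effect=random_effect, family=family, offset=offset)
    n_pen = len(design.penalties)
    pen_names = [t.name for t in design.terms if t.penalty_index is not None]

    if fixed_lambda is not None:
        if np.isscalar(fixed_lambda):
            lam = np.full(n_pen, float(fixed_lambda))
        else:
            lam = np.array([float(fixed_lambda[nm]) for nm in pen_names])
        lam = np.where(np.isinf(lam), _BIG_LAMBDA, np.maximum(lam, 0.0))
        lam_eff = np.where(lam <= 0.0, 1e-10, lam)
    elif n_pen == 0:
        lam_eff = np.zeros(0)
    else:
        rho = np.zeros(n_pen)
        beta_warm = None
        last = np.inf
        for _ in range(5):
            for j in range(n_pen):
                def obj(r, j=j):
                    nonlocal beta_warm
                    trial = rho.copy()
                    trial[j] = r
                    sc, beta_warm = _reml_score(design, np.exp(trial), beta_warm)
                    return sc
                res = optimize.minimize_scalar(
                    obj, bounds=LOG_LAMBDA_BOUNDS, method="bounded",
                    options={"xatol": 1e-2})
                rho[j] = float(res.x)
            score, beta_warm = _reml_score(design, np.exp(rho), beta_warm)
            if abs(last - score) < 1e-4:
                break
            last = score
        lam_eff = np.exp(rho)

    beta, mu, w, dev, conv, it, notes = _pirls(design, lam_eff,
                                               max_iter=max_iter, tol=tol)
    X, y = design.X, design.y
    n = y.size
    S = design.s_lambda(lam_eff) if n_pen else np.zeros((X.shape[1], X.shape[1]))
    H = X.T @ (X * w[:, None])
    A = H + S
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        Ainv = np.linalg.pinv(A)
    Fmat = Ainv @ H
    edf_diag = np.diag(Fmat)
    edf_per_term = {t.name: float(edf_diag[t.sl].sum()) for t in design.terms}
    total_edf = float(edf_diag.sum())

    if family == "gaussian":
        scale = dev / n  # ML scale for the reported likelihood
        cov_scale = dev / max(n - total_edf, 1.0)
    else:
        scale = 1.0
        cov_scale = 1.0
    loglik = _log_likelihood(family, y, mu, scale if family == "gaussian" else 1.0)
    null_dev = _null_deviance(family, y, design.offset)
    dev_expl = float(1.0 - dev / null_dev) if null_dev > 0 else 0.0
    reml = gaussian_reml_loglik(design, lam_eff) if (family == "gaussian" and n_pen) else None

    smoothing = dict(zip(pen_names, lam_eff.tolist()))
    desc = [f"{t.kind}:{t.name}" for t in design.terms]
    return AdditiveFit(
        family=family, coefficients=beta, smoothing_params=smoothing,
        edf_per_term=edf_per_term, total_edf=total_edf,
        log_likelihood=loglik, deviance=float(dev), null_deviance=float(null_dev),
        deviance_explained=dev_expl,
        aic=float(-2 * loglik + 2 * total_edf),
        bic=float(-2 * loglik + total_edf * np.log(n)),
        scale=float(cov_scale), converged=conv, n_iter=it, notes=notes,
        reml=reml, design_description=desc, design_=design,
        cov_=Ainv * cov_scale, fitted_=mu)
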