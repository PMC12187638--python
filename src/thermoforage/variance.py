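"""Among-nest variance: seasonal spline mixed models and simulated RLRTs.

Daily summaries (daytime minimum, daytime range, available hours) are
modeled with a cyclic seasonal smooth of day-of-year under three random
structures for nest identity — none, random intercept, random intercept +
slope on the seasonal index — ranked by BIC. The contribution of a random
effect is then tested with a restricted likelihood ratio test whose null
distribution is built by parametric bootstrap: responses are simulated from
the fitted null model and both models are refitted to every replicate. The
observed statistic is max(0, 2 * (restricted loglik alt - null)); because
the variance component sits on the boundary of its parameter space, a large
share of simulated statistics is exactly zero.

Refitting thousands of Gaussian replicates is made cheap by maximizing the
exact restricted likelihood over a shared grid of log smoothing parameters,
with all replicates solved simultaneously per grid point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .gam import AdditiveFit, RandomEffectSpec, SmoothSpec, fit_additive
from .synthetic import SEASONAL_PEAK_DOY

#: log-lambda grids used by the fast REML refits: smooth terms move both
#: models identically so a coarse grid suffices; random-effect blocks get a
#: finer grid plus a near-infinite boundary value so the no-effect limit is
#: reachable exactly.
SMOOTH_GRID = np.arange(-8.0, 16.1, 2.0)
RE_GRID = np.concatenate([np.arange(-8.0, 16.1, 0.75), [18.0, 24.0]])

MODEL_ORDER = ("none", "intercept", "intercept+slope")


def seasonal_index(dates) -> np.ndarray:
    """Cosine seasonal index: +1 in mid-summer, -1 in mid-winter."""
    doy = pd.DatetimeIndex(dates).dayofyear.to_numpy(dtype=float)
    return np.cos(2.0 * np.pi * (doy - SEASONAL_PEAK_DOY) / 365.25)


@dataclass
class NestedModelSet:
    response: str
    fits: dict[str, AdditiveFit]
    bic: dict[str, float]
    delta_bic: dict[str, float]
    best: str
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"model": m, "bic": self.bic[m], "delta_bic": self.delta_bic[m]}
                for m in MODEL_ORDER if m in self.bic]
        return pd.DataFrame(rows)


def fit_nested_models(daily: pd.DataFrame, response: str = "value",
                      k: int = 8) -> NestedModelSet:
    """Fit the three seasonal spline models and rank them by BIC.

    ``daily`` needs columns nest_id, date and the response. The random slope
    of the third model is on the seasonal index — the natural choice when
    the fixed trend being modulated is itself seasonal.
    """
    df = daily.dropna(subset=[response]).copy()
    n_nests = df["nest_id"].nunique()
    if df["date"].nunique() < 30:
        raise ValueError("need at least 30 distinct days")
    df["doy"] = pd.DatetimeIndex(df["date"]).dayofyear.astype(float)
    df["seasonal_index"] = seasonal_index(df["date"])
    smooths = [SmoothSpec("doy", k=k, cyclic=True, period=365.25)]

    notes: list[str] = []
    fits: dict[str, AdditiveFit] = {}
    fits["none"] = fit_additive(df, response, smooths=smooths, family="gaussian")
    if n_nests >= 2:
        fits["intercept"] = fit_additive(
            df, response, smooths=smooths,
            random_effect=RandomEffectSpec("nest_id"), family="gaussian")
        fits["intercept+slope"] = fit_additive(
            df, response, smooths=smooths,
            random_effect=RandomEffectSpec("nest_id", "intercept+slope",
                                           "seasonal_index"),
            family="gaussian")
    else:
        notes.append("single nest: random-effect models skipped")
    bic = {m: f.bic for m, f in fits.items()}
    lo = min(bic.values())
    delta = {m: b - lo for m, b in bic.items()}
    best = min(bic, key=bic.get)
    return NestedModelSet(response=response, fits=fits, bic=bic,
                          delta_bic=delta, best=best, notes=notes)


@dataclass
class RLRTResult:
    statistic: float
    p_value: float
    n_sim: int
    seed: int
    prop_zero_null: float  # share of simulated statistics exactly at zero

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p_value": self.p_value,
                "n_sim": self.n_sim, "seed": self.seed,
                "prop_zero_null": self.prop_zero_null}


class _RemlGrid:
    """Exact Gaussian restricted likelihood maximized over a lambda grid,
    vectorized across response replicates sharing one design."""

    def __init__(self, fit: AdditiveFit):
        d = fit.design_
        if d.family != "gaussian":
            raise ValueError("RLRT machinery applies to Gaussian fits")
        self.X = d.X
        self.G = d.X.T @ d.X
        self.M = d.n_unpenalized
        self.n = d.X.shape[0]
        self.blocks = d.penalties
        self.ranks = d.penalty_ranks
        self.logpdets = d.penalty_logpdets
        grids = []
        for t in d.terms:
            if t.penalty_index is None:
                continue
            grids.append(RE_GRID if t.kind == "random" else SMOOTH_GRID)
        self.grids = grids

    def max_reml(self, Y: np.ndarray, return_best: bool = False):
        """Max restricted loglik per column of Y over the lambda grid."""
        Y = np.atleast_2d(Y.T).T  # ensure (n, B)
        U = self.X.T @ Y
        q = np.einsum("ij,ij->j", Y, Y)
        B = Y.shape[1]
        nm = self.n - self.M
        best = np.full(B, -np.inf)
        best_idx = np.zeros(B, dtype=int)
        combos = list(itertools.product(*[range(g.size) for g in self.grids]))
        p = self.X.shape[1]
        for ci, combo in enumerate(combos):
            lam = np.array([self.grids[j][cj] for j, cj in enumerate(combo)])
            lam = np.exp(lam)
            A = self.G.copy()
            logpdet_s = 0.0
            for lj, (sl, Sj), r, lp in zip(lam, self.blocks, self.ranks, self.logpdets):
                A[sl, sl] += lj * Sj
                logpdet_s += r * np.log(lj) + lp
            c, low = linalg.cho_factor(A, lower=True, check_finite=False)
            logdet_a = 2.0 * np.sum(np.log(np.diag(c)))
            theta = linalg.cho_solve((c, low), U, check_finite=False)
            rssp = np.maximum(q - np.einsum("ij,ij->j", theta, U), 1e-300)
            lr = (-0.5 * nm * (np.log(2 * np.pi * rssp / nm) + 1.0)
                  + 0.5 * (logpdet_s - logdet_a))
            better = lr > best
            best = np.where(better, lr, best)
            best_idx[better] = ci
        if not return_best:
            return best
        # fitted values and scale at each replicate's best grid point
        fitted = np.empty_like(Y)
        scales = np.empty(B)
        for ci in np.unique(best_idx):
            cols = np.where(best_idx == ci)[0]
            lam = np.exp(np.array([self.grids[j][cj]
                                   for j, cj in enumerate(combos[ci])]))
            A = self.G.copy()
            for lj, (sl, Sj) in zip(lam, self.blocks):
                A[sl, sl] += lj * Sj
            theta = np.linalg.solve(A, U[:, cols])
            fitted[:, cols] = self.X @ theta
            rssp = q[cols] - np.einsum("ij,ij->j", theta, U[:, cols])
            scales[cols] = np.maximum(rssp, 1e-300) / (self.n - self.M)
        return best, fitted, scales


def _check_nested(null_fit: AdditiveFit, alt_fit: AdditiveFit) -> None:
    pn, pa = null_fit.design_.X.shape[1], alt_fit.design_.X.shape[1]
    extra = len(alt_fit.design_.penalties) - len(null_fit.design_.penalties)
    extra_random = ([t for t in alt_fit.design_.terms if t.kind == "random"]
                    [len([t for t in null_fit.design_.terms if t.kind == "random"]):])
    if (extra != 1 or len(extra_random) != 1 or pa <= pn
            or not np.array_equal(null_fit.design_.X, alt_fit.design_.X[:, :pn])):
        raise ValueError("models are not nested by exactly one random-effect block")


def rlrt_simulation(null_fit: AdditiveFit, alt_fit: AdditiveFit,
                    n_sim: int = 10000, seed: int = 0,
                    y: np.ndarray | None = None) -> RLRTResult:
    """Simulation-based restricted likelihood ratio test for one RE block.

    Simulates ``n_sim`` response vectors from the fitted null model, refits
    both models to each (restricted likelihood maximized over the shared
    smoothing-parameter grid), and returns the one-sided p-value with +1
    continuity correction. ``y`` replaces the observed response (the designs
    are reused), which makes repeated-data calibration studies cheap.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    _check_nested(null_fit, alt_fit)
    g_null = _RemlGrid(null_fit)
    g_alt = _RemlGrid(alt_fit)
    y = null_fit.design_.y if y is None else np.asarray(y, dtype=float)

    lr_null, fitted, scale = g_null.max_reml(y[:, None], return_best=True)
    lr_alt = g_alt.max_reml(y[:, None])
    observed = max(0.0, 2.0 * float(lr_alt[0] - lr_null[0]))

    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    sd = float(np.sqrt(scale[0]))
    mu = fitted[:, 0]
    stats = np.empty(n_sim)
    batch = 250
    for start in range(0, n_sim, batch):
        b = min(batch, n_sim - start)
        Ysim = mu[:, None] + rng.normal(0.0, sd, (y.size, b))
        stats[start:start + b] = np.maximum(
            0.0, 2.0 * (g_alt.max_reml(Ysim) - g_null.max_reml(Ysim)))
    p = (1.0 + np.sum(stats >= observed)) / (n_sim + 1.0)
    return RLRTResult(statistic=observed, p_value=float(p), n_sim=n_sim,
                      seed=seed, prop_zero_null=float(np.mean(stats == 0.0)))
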