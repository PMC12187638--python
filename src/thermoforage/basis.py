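"""Spline bases and penalties for the additive-model engine.

Two bases are provided:

* a natural cubic regression spline parameterized by its values at knots
  placed at quantiles of the covariate, with a divided-difference penalty
  (order 2 by default). On an evenly spaced knot grid the penalty quadratic
  form is exactly the sum of squared second differences of the fitted values
  at the knots; on any grid it annihilates linear functions of the covariate.
* a harmonic (Fourier) basis for exactly periodic seasonal smooths, with a
  frequency-weighted ridge penalty so higher harmonics are shrunk first.

Both bases are returned with a sum-to-zero constraint absorbed (the column
space is orthogonal to the intercept over the training sample), so smooths
are identifiable alongside a free intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _quantile_knots(x: np.ndarray, k: int) -> np.ndarray:
    ux = np.unique(x[np.isfinite(x)])
    if ux.size < k:
        raise ValueError(f"need at least k={k} distinct covariate values, got {ux.size}")
    knots = np.quantile(ux, np.linspace(0.0, 1.0, k))
    # quantiles of distinct values can still collide on clumpy data
    knots = np.unique(knots)
    if knots.size < k:
        knots = np.linspace(ux.min(), ux.max(), k)
    return knots


def _crs_f_matrix(knots: np.ndarray) -> np.ndarray:
    """Map from knot values to second derivatives of the natural interpolant."""
    k = knots.size
    h = np.diff(knots)
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
    F = np.zeros((k, k))
    F[1:-1, :] = np.linalg.solve(B, D)
    return F


def crs_design(x: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Evaluate the cardinal natural-spline basis at x (linear beyond knots)."""
    x = np.asarray(x, dtype=float)
    k = knots.size
    n = x.size
    X = np.zeros((n, k))
    h = np.diff(knots)

    inside = (x >= knots[0]) & (x <= knots[-1])
    xi = x[inside]
    j = np.clip(np.searchsorted(knots, xi, side="right") - 1, 0, k - 2)
    hj = h[j]
    xm = knots[j + 1] - xi
    xp = xi - knots[j]
    rows = np.where(inside)[0]
    Xi = np.zeros((xi.size, k))
    Xi[np.arange(xi.size), j] += xm / hj
    Xi[np.arange(xi.size), j + 1] += xp / hj
    cm = (xm**3 / hj - hj * xm) / 6.0
    cp = (xp**3 / hj - hj * xp) / 6.0
    Xi += cm[:, None] * F[j, :] + cp[:, None] * F[j + 1, :]
    X[rows] = Xi

    below = x < knots[0]
    if below.any():
        h0 = h[0]
        deriv = np.zeros(k)
        deriv[0] -= 1.0 / h0
        deriv[1] += 1.0 / h0
        deriv -= (h0 / 3.0) * F[0, :] + (h0 / 6.0) * F[1, :]
        base = np.zeros(k)
        base[0] = 1.0
        X[below] = base[None, :] + (x[below] - knots[0])[:, None] * deriv[None, :]

    above = x > knots[-1]
    if above.any():
        hl = h[-1]
        deriv = np.zeros(k)
        deriv[-2] -= 1.0 / hl
        deriv[-1] += 1.0 / hl
        deriv += (hl / 6.0) * F[-2, :] + (hl / 3.0) * F[-1, :]
        base = np.zeros(k)
        base[-1] = 1.0
        X[above] = base[None, :] + (x[above] - knots[-1])[:, None] * deriv[None, :]
    return X


def crs_penalty(knots: np.ndarray, order: int = 2) -> np.ndarray:
    """Divided-difference penalty on knot values.

    Order 2 penalizes curvature (zero on straight lines); order 1 penalizes
    departures from a constant. Scaled so an even knot grid gives plain
    integer difference coefficients.
    """
    k = knots.size
    h = np.diff(knots)
    hbar = h.mean()
    if order == 1:
        Dp = np.zeros((k - 1, k))
        for i in range(k - 1):
            Dp[i, i] = -hbar / h[i]
            Dp[i, i + 1] = hbar / h[i]
    elif order == 2:
        Dp = np.zeros((k - 2, k))
        for i in range(k - 2):
            c = 2.0 * hbar**2 / (h[i] + h[i + 1])
            Dp[i, i] = c / h[i]
            Dp[i, i + 1] = -c * (1.0 / h[i] + 1.0 / h[i + 1])
            Dp[i, i + 2] = c / h[i + 1]
    else:
        raise ValueError(f"penalty_order must be 1 or 2, got {order}")
    return Dp.T @ Dp


@dataclass
class SmoothBasis:
    """A constrained smooth basis, reusable at prediction time."""

    variable: str
    kind: str  # "crs" | "cyclic"
    k: int
    penalty: np.ndarray = field(repr=False)  # constrained, (k-1)x(k-1)
    Z: np.ndarray = field(repr=False)  # k x (k-1) constraint null-space map
    knots: np.ndarray | None = None
    F: np.ndarray | None = field(default=None, repr=False)
    period: float = 365.25
    training_range: tuple[float, float] = (0.0, 0.0)
    center_offset: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_cols(self) -> int:
        return self.Z.shape[1]

    def _raw_design(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "crs":
            return crs_design(x, self.knots, self.F)
        return harmonic_design(x, self.k, self.period)

    def design(self, x: np.ndarray) -> np.ndarray:
        raw = self._raw_design(np.asarray(x, dtype=float))
        if self.center_offset is not None:
            raw = raw - self.center_offset
        return raw @ self.Z


def harmonic_design(x: np.ndarray, k: int, period: float) -> np.ndarray:
    """sin/cos pairs for harmonics 1..k//2 of the given period."""
    x = np.asarray(x, dtype=float)
    m = k // 2
    if m < 1:
        raise ValueError("cyclic basis needs k >= 2")
    cols = []
    for j in range(1, m + 1):
        w = 2.0 * np.pi * j * x / period
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols)


def harmonic_penalty(k: int) -> np.ndarray:
    m = k // 2
    w = np.repeat(np.arange(1, m + 1, dtype=float) ** 4, 2)
    return np.diag(w)


def _sum_to_zero(raw: np.ndarray) -> np.ndarray:
    """Null-space transform Z making column sums of raw @ Z zero."""
    c = raw.sum(axis=0)
    norm = np.linalg.norm(c)
    p = raw.shape[1]
    Q, _ = np.linalg.qr(np.column_stack([c / norm, np.eye(p)]))
    return Q[:, 1:p]


def build_basis(x: np.ndarray, variable: str, k: int = 5, penalty_order: int = 2,
                cyclic: bool = False, period: float = 365.25) -> SmoothBasis:
    """Construct a constrained smooth basis and its penalty.

    Returns the basis object; its ``design(x)`` gives the n x (k-1)
    sum-to-zero design and ``penalty`` the matching positive semidefinite
    penalty matrix.
    """
    x = np.asarray(x, dtype=float)
    if not (3 <= k <= 20):
        raise ValueError(f"basis dimension k must lie in [3, 20], got {k}")
    if cyclic:
        raw = harmonic_design(x, k, period)
        pen = harmonic_penalty(k)
        # harmonic columns are already near-orthogonal to the intercept, so a
        # coefficient-space constraint is ill-conditioned; column-center the
        # design instead, which enforces sum-to-zero fitted values directly
        return SmoothBasis(variable=variable, kind="cyclic", k=k,
                           penalty=pen, Z=np.eye(raw.shape[1]), period=period,
                           training_range=(float(x.min()), float(x.max())),
                           center_offset=raw.mean(axis=0))
    knots = _quantile_knots(x, k)
    F = _crs_f_matrix(knots)
    raw = crs_design(x, knots, F)
    pen = crs_penalty(knots, penalty_order)
    Z = _sum_to_zero(raw)
    return SmoothBasis(variable=variable, kind="crs", k=k, penalty=Z.T @ pen @ Z,
                       Z=Z, knots=knots, F=F,
                       training_range=(float(x.min()), float(x.max())))
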