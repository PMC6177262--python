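"""Extended background-selection model with a mutation–recombination
power law.

The classic approximation predicts the relative diversity reduction at a
focal neutral site as B = π/π₀ ≈ exp(-u_d / r), with u_d the local
deleterious mutation rate and r the local per-bp recombination rate.
Allowing u_d to follow a power law of recombination, u_d(r) = u₀ r^b
(log-log linear, b = 0 recovering a constant mutation rate), gives

    B(r) = exp(-u₀ · r^(b-1)).

Both variants are fitted to (r, B) points by non-linear least squares and
compared by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

#: 1 cM/Mb expressed per bp per generation
CM_PER_MB_TO_PER_BP = 1e-8


def cmmb_to_per_bp(rate_cmmb: float | np.ndarray) -> float | np.ndarray:
    """Convert a recombination rate from cM/Mb to per-bp per-generation."""
    return np.asarray(rate_cmmb, dtype=float) * CM_PER_MB_TO_PER_BP


def predict_B(r, u0: float, b: float):
    """B(r) = exp(-u0 * r^(b-1)) for per-bp recombination rate(s) r > 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("recombination rate must be positive")
    if u0 < 0:
        raise ValueError("u0 must be non-negative")
    out = np.exp(-u0 * r ** (b - 1.0))
    return float(out) if out.ndim == 0 else out


@dataclass
class BgsModelFit:
    u0: float
    b: float
    rss: float
    n_points: int
    k_free: int
    fix_b_zero: bool

    @property
    def aic(self) -> float:
        """Gaussian concentrated-likelihood AIC: n ln(rss/n) + 2k.

        Additive constants dropped — only AIC differences are meaningful.
        rss = 0 maps to -inf (a perfect fit dominates any penalty).
        """
        if self.rss <= 0:
            return float("-inf")
        return self.n_points * np.log(self.rss / self.n_points) + 2 * self.k_free

    def predict(self, r):
        return predict_B(r, self.u0, self.b)


def _residuals(theta, r, B_obs, fix_b_zero):
    log_u0 = np.clip(theta[0], -700.0, 700.0)   # keep exp() finite
    b = 0.0 if fix_b_zero else theta[1]
    with np.errstate(over="ignore", under="ignore"):
        expo = -np.exp(log_u0) * r ** (b - 1.0)
        return np.exp(np.clip(expo, -745.0, 0.0)) - B_obs


def fit_bgs_model(points, fix_b_zero: bool = False, init=None,
                  tol: float = 1e-12, n_starts: int = 5,
                  seed: int = 0) -> BgsModelFit:
    """Least-squares fit of B(r) = exp(-u0 r^(b-1)) to (r, B) points.

    ``points``: sequence of (r per-bp, B_obs in (0,1]).  Optimization runs
    over (log u0, b) for positivity and conditioning, with ``n_starts``
    multi-starts around a moment-based initial guess to avoid local minima.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (r, B) pairs")
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    r, B = pts[:, 0], pts[:, 1]
    if np.any(r <= 0):
        raise ValueError("recombination rates must be positive")
    if np.any((B <= 0) | (B > 1)):
        raise ValueError("B values must lie in (0, 1]")

    # moment start: -ln B = u0 r^(b-1) is log-log linear in r
    y = -np.log(np.clip(B, 1e-12, 1.0))
    pos = y > 0
    if pos.sum() >= 2 and not fix_b_zero:
        slope, intercept = np.polyfit(np.log(r[pos]), np.log(y[pos]), 1)
        b0, log_u0 = slope + 1.0, intercept
    else:
        b0 = 0.0
        log_u0 = float(np.log(np.median(y[pos] * r[pos])) if pos.any()
                       else np.log(np.median(r)))
    rng = np.random.default_rng(seed)
    starts = [(log_u0, b0)]
    for _ in range(n_starts - 1):
        starts.append((log_u0 + rng.normal(scale=2.0),
                       b0 + rng.normal(scale=0.5)))

    best = None
    for s0 in starts:
        theta0 = np.array([s0[0]] if fix_b_zero else list(s0))
        try:
            res = least_squares(_residuals, theta0, args=(r, B, fix_b_zero),
                                xtol=tol, ftol=tol, gtol=tol, method="lm")
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, res.x)
    if best is None:
        raise RuntimeError("non-linear least squares did not converge "
                           f"from any of {n_starts} starts")
    rss, theta = best
    u0 = float(np.exp(theta[0]))
    b = 0.0 if fix_b_zero else float(theta[1])
    return BgsModelFit(u0, b, rss, len(pts), 1 if fix_b_zero else 2,
                       fix_b_zero)


def compare_models(fit_free: BgsModelFit, fit_fixed: BgsModelFit):
    """ΔAIC = AIC(fixed) − AIC(free); the free-b model is preferred iff
    ΔAIC > 0."""
    if fit_free.n_points != fit_fixed.n_points:
        raise ValueError("fits must use the same points")
    delta = fit_fixed.aic - fit_free.aic
    return delta, ("free" if delta > 0 else "fixed")
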