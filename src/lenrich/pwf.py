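"""Probability weighting function: P(called DE) as a monotone function of a
bias covariate.

The fit is a least-squares cubic regression spline on log10(covariate) with a
monotonicity constraint, applied to the per-gene binary DE indicators.  Knots
sit at equally spaced quantiles of the log covariate.  Monotonicity is
enforced by reparameterising the B-spline coefficients as cumulative sums of
sign-constrained increments (nondecreasing coefficients give a nondecreasing
cubic B-spline); both directions are fitted and the lower residual sum of
squares wins, because non-statistical DE callers can produce decreasing
trends.  Fitted values are clamped to [eps, 1] — a weight of exactly 0 would
make a gene unsampleable under the resampling null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import lsq_linear

from lenrich.errors import DegenerateFitError, ValidationError

logger = logging.getLogger(__name__)

#: lower clamp for fitted weights
EPS = 1e-8

_DEGREE = 3

#: covariate winsorisation quantile — extreme outliers are pinned to this
#: quantile before the basis is built, otherwise a lone DE gene at the
#: covariate extreme can pull the boundary coefficient arbitrarily far at
#: negligible residual cost
_WINSOR = 0.02

#: second-difference penalty per observation (P-spline smoothing)
_PENALTY_PER_OBS = 0.01


@dataclass
class PWF:
    """A fitted monotone probability weighting function."""

    covariate_kind: str
    knots: np.ndarray          # full knot vector (with repeated boundaries)
    coefficients: np.ndarray   # monotone B-spline coefficients
    direction: str             # 'increasing' or 'decreasing'
    x_min: float               # training range on the log10 scale
    x_max: float
    floor: float = EPS

    def evaluate(self, covariate) -> np.ndarray:
        """Evaluate at positive covariate values; constant beyond the range."""
        x = np.asarray(covariate, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        if np.any(x <= 0):
            raise ValidationError("covariate values must be strictly positive")
        lx = np.clip(np.log10(x), self.x_min, self.x_max)
        spline = BSpline(self.knots, self.coefficients, _DEGREE, extrapolate=False)
        vals = np.clip(spline(lx), self.floor, 1.0)
        return float(vals[0]) if scalar else vals

    __call__ = evaluate


def fit_pwf(
    covariate,
    de_flags,
    n_knots: int = 6,
    covariate_kind: str = "length",
) -> PWF:
    """Fit the PWF to binary DE flags against a positive bias covariate.

    ``n_knots`` interior knots are placed at equally spaced quantiles of the
    log10 covariate.  Raises :class:`DegenerateFitError` when all flags are
    identical (a constant PWF should be used instead); reduces the knot count
    with a warning when there are fewer distinct covariate values than knots.
    """
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(de_flags, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("covariate and de_flags must be equal-length vectors")
    if np.any(x <= 0):
        raise ValidationError("covariate values must be strictly positive")
    if not np.all((y == 0) | (y == 1)):
        raise ValidationError("de_flags must be binary")
    n_de = int(y.sum())
    if n_de == 0 or n_de == y.size:
        raise DegenerateFitError(
            "all DE flags identical; fit a constant PWF equal to the DE "
            "fraction instead"
        )
    if n_knots < 1:
        raise ValidationError("n_knots must be >= 1")

    lx = np.log10(x)
    lo = float(np.quantile(lx, _WINSOR))
    hi = float(np.quantile(lx, 1 - _WINSOR))
    if lo == hi:
        lo, hi = float(lx.min()), float(lx.max())
    lx = np.clip(lx, lo, hi)
    n_distinct = np.unique(lx).size
    if n_distinct < 2:
        raise DegenerateFitError("covariate has a single distinct value")
    if n_distinct <= n_knots:
        new_knots = max(1, n_distinct - 1)
        warnings.warn(
            f"only {n_distinct} distinct covariate values; reducing knots "
            f"{n_knots} -> {new_knots}",
            stacklevel=2,
        )
        n_knots = new_knots

    knots = _knot_vector(lx, n_knots)
    design = BSpline.design_matrix(lx, knots, _DEGREE).toarray()
    penalty = _PENALTY_PER_OBS * y.size

    inc_coef, inc_rss = _constrained_fit(design, y, increasing=True, penalty=penalty)
    dec_coef, dec_rss = _constrained_fit(design, y, increasing=False, penalty=penalty)
    if inc_rss <= dec_rss:
        coef, direction = inc_coef, "increasing"
    else:
        coef, direction = dec_coef, "decreasing"
    logger.info(
        "PWF fit: %s direction, %d knots, RSS %.6g", direction, n_knots,
        min(inc_rss, dec_rss),
    )
    return PWF(
        covariate_kind=covariate_kind,
        knots=knots,
        coefficients=coef,
        direction=direction,
        x_min=float(lx.min()),
        x_max=float(lx.max()),
    )


def _knot_vector(lx: np.ndarray, n_interior: int) -> np.ndarray:
    """Clamped cubic knot vector with interior knots at log-covariate quantiles."""
    lo, hi = float(lx.min()), float(lx.max())
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(lx, qs)
    # keep interior knots strictly inside the boundary
    interior = interior[(interior > lo) & (interior < hi)]
    interior = np.unique(interior)
    return np.concatenate(
        [np.repeat(lo, _DEGREE + 1), interior, np.repeat(hi, _DEGREE + 1)]
    )

def _constrained_fit(
    design: np.ndarray, y: np.ndarray, increasing: bool, penalty: float = 0.0
):
    """Penalized least squares with monotone B-spline coefficients.

    Coefficients are written c_i = c_0 + sum_{j<=i} d_j with d_j >= 0
    (increasing) or d_j <= 0 (decreasing); the base level c_0 is free.  A
    second-difference penalty on the coefficients smooths the fit.
    """
    m = design.shape[1]
    # column i of the transformed design = sum of B-spline columns j >= i
    cum = np.cumsum(design[:, ::-1], axis=1)[:, ::-1]
    target = y
    if penalty > 0 and m > 2:
        d2 = np.diff(np.eye(m), 2, axis=0)
        lower = np.tril(np.ones((m, m)))
        cum = np.vstack([cum, np.sqrt(penalty) * (d2 @ lower)])
        target = np.concatenate([y, np.zeros(m - 2)])
    lb = np.full(m, 0.0 if increasing else -np.inf)
    ub = np.full(m, np.inf if increasing else 0.0)
    lb[0], ub[0] = -np.inf, np.inf  # free base level
    res = lsq_linear(cum, target, bounds=(lb, ub), method="bvls")
    coef = np.cumsum(res.x)
    rss = float(np.sum((design @ coef - y) ** 2))
    return coef, rss


def evaluate_pwf(pwf: PWF, covariate) -> np.ndarray:
    """Functional alias for :meth:`PWF.evaluate`."""
    return pwf.evaluate(covariate)


def bin_de_proportions(covariate, de_flags, bin_size: int = 300):
    """Binned DE-proportion diagnostic.

    Sorts genes by covariate, partitions them into consecutive bins of
    ``bin_size`` (last bin may be smaller) and returns a list of
    (median covariate, DE proportion) per bin — the raw data the PWF is
    fitted through.
    """
    if bin_size < 2:
        raise ValidationError("bin_size must be >= 2")
    x = np.asarray(covariate, dtype=float)
    y = np.asarray(de_flags, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("covariate and de_flags must be equal-length vectors")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    out = []
    for start in range(0, x.size, bin_size):
        xb = xs[start : start + bin_size]
        yb = ys[start : start + bin_size]
        out.append((float(np.median(xb)), float(yb.mean())))
    return out
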