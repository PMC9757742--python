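"""Asymmetric logistic climatic niches.

A species' tolerance to one climate variable (temperature in degC or monthly
precipitation in mm) is described by a bell-shaped *local extinction
probability* curve built from two logistic tails that meet at the niche
optimum ``x_mean``:

    p(x) = 1 - 1/(1 + exp(-c (x - d)))   for x <= x_mean   (cold/dry tail)
    p(x) = 1/(1 + exp(-a (x - b)))       for x >  x_mean   (warm/wet tail)

The four parameters are calibrated so that p equals ``1 - p_thresh`` (0.05 by
default) exactly at the most extreme values ``v_min`` and ``v_max`` recorded
in the calibration samples, and is close to zero at the optimum.  The curve is
thus a progressive bioclimatic envelope: flat-bottomed inside the recorded
range, 5% extinction risk at the range edges, and saturating to certain local
extinction far outside them.

Calibration follows a slope-escalation scheme: the tail slope starts at
0.0001 and is incremented by 0.01 per step, with the intercept re-derived at
every step from the closed form that pins the edge condition, until the tail
evaluated at the optimum drops below a small stopping tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "NicheAxis",
    "fit_axis",
    "fit_axis_from_bounds",
    "axis_extinction_prob",
    "combined_extinction_prob",
    "shift_niche",
    "params_array",
    "ext_prob_params",
    "combined_ext_params",
]

DEFAULT_P_THRESH = 0.95
#: stopping tolerance for the warm tail evaluated at the optimum
RIGHT_STOP = 0.001
#: stopping tolerance for the cold tail at the optimum (the ">= 0.9998" rule)
LEFT_STOP = 0.0002
SLOPE_INIT = 0.0001
SLOPE_STEP = 0.01
#: hard cap on slope increments; reaching it raises instead of looping forever
MAX_STEPS = 1_000_000
#: slope assigned to a zero-width (degenerate) axis
DEGENERATE_SLOPE = 1e4


@dataclass
class NicheAxis:
    """Fitted tolerance curve for one climate variable.

    ``degenerate`` flags a zero-width axis (all calibration samples equal):
    the closed forms still give extinction probability ``1 - p_thresh`` at the
    single recorded value, with near-step tails on either side.
    """

    x_mean: float
    v_min: float
    v_max: float
    a: float
    b: float
    c: float
    d: float
    p_thresh: float = DEFAULT_P_THRESH
    degenerate: bool = False


def _right_intercept(a: float, v_max: float, p_thresh: float) -> float:
    """b such that the warm tail equals 1 - p_thresh at v_max."""
    return (math.log(p_thresh / (1.0 - p_thresh)) + a * v_max) / a


def _left_intercept(c: float, v_min: float, p_thresh: float) -> float:
    """d such that the cold tail equals 1 - p_thresh at v_min."""
    return (math.log((1.0 - p_thresh) / p_thresh) + c * v_min) / c


def _logistic(z: float) -> float:
    # overflow-safe scalar logistic
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def fit_axis_from_bounds(
    x_mean: float,
    v_min: float,
    v_max: float,
    p_thresh: float = DEFAULT_P_THRESH,
) -> NicheAxis:
    """Calibrate tail parameters for given optimum and tolerance edges.

    Used both when fitting from raw samples and when re-deriving the curve
    after an adaptation shift rigidly translates (x_mean, v_min, v_max).
    """
    if not (0.5 < p_thresh < 1.0):
        raise ValueError(f"p_thresh must lie in (0.5, 1), got {p_thresh}")
    if not (v_min <= x_mean <= v_max):
        raise ValueError("require v_min <= x_mean <= v_max")

    if v_min == v_max:
        a = c = DEGENERATE_SLOPE
        return NicheAxis(
            x_mean=x_mean,
            v_min=v_min,
            v_max=v_max,
            a=a,
            b=_right_intercept(a, v_max, p_thresh),
            c=c,
            d=_left_intercept(c, v_min, p_thresh),
            p_thresh=p_thresh,
            degenerate=True,
        )

    # warm/wet tail: escalate a until the tail at the optimum is <= RIGHT_STOP
    a = SLOPE_INIT
    b = _right_intercept(a, v_max, p_thresh)
    steps = 0
    while _logistic(a * (x_mean - b)) > RIGHT_STOP:
        a += SLOPE_STEP
        b = _right_intercept(a, v_max, p_thresh)
        steps += 1
        if steps > MAX_STEPS:
            raise RuntimeError(
                "right-tail calibration did not converge "
                f"(x_mean={x_mean}, v_max={v_max})"
            )

    # cold/dry tail: escalate c until 1/(1+exp(-c(x_mean-d))) >= 1 - LEFT_STOP
    c = SLOPE_INIT
    d = _left_intercept(c, v_min, p_thresh)
    steps = 0
    while _logistic(c * (x_mean - d)) < 1.0 - LEFT_STOP:
        c += SLOPE_STEP
        d = _left_intercept(c, v_min, p_thresh)
        steps += 1
        if steps > MAX_STEPS:
            raise RuntimeError(
                "left-tail calibration did not converge "
                f"(x_mean={x_mean}, v_min={v_min})"
            )

    return NicheAxis(x_mean, v_min, v_max, a, b, c, d, p_thresh)


def fit_axis(samples, p_thresh: float = DEFAULT_P_THRESH) -> NicheAxis:
    """Fit a niche axis to monthly climate samples.

    ``x_mean`` is the arithmetic mean of the samples, ``v_min``/``v_max``
    their extremes.  Non-finite samples are rejected; identical samples yield
    a degenerate zero-width axis.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("samples must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("samples contain non-finite values")
    return fit_axis_from_bounds(
        float(arr.mean()), float(arr.min()), float(arr.max()), p_thresh
    )


def axis_extinction_prob(axis: NicheAxis, x) -> float | np.ndarray:
    """Local extinction probability at climate value ``x``.

    Extrapolation beyond [v_min, v_max] is allowed; the probability saturates
    towards 1 far outside the tolerance range.
    """
    x = np.asarray(x, dtype=float)
    left = 1.0 - _vlogistic(axis.c * (x - axis.d))
    right = _vlogistic(axis.a * (x - axis.b))
    p = np.where(x <= axis.x_mean, left, right)
    out = np.clip(p, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _vlogistic(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def combined_extinction_prob(species, temperature, precipitation):
    """Bidimensional niche rule: survival is the *minimum* survival over the
    two variables, i.e. extinction is the maximum of the two tail values."""
    pt = axis_extinction_prob(species.niche_T, temperature)
    pp = axis_extinction_prob(species.niche_P, precipitation)
    return np.maximum(pt, pp)


def shift_niche(
    niche_T: NicheAxis,
    niche_P: NicheAxis,
    local_mean_T: float,
    local_mean_P: float,
    C_adp: float,
    A: float,
    std_T: float,
    std_P: float,
) -> tuple[NicheAxis, NicheAxis]:
    """Adaptive niche shift toward local mean conditions.

    The niche center, treated as a point in standardized (T, P) space, moves
    along the segment toward the local means by length ``C_adp * A * d_N``
    where ``d_N`` is the standardized Euclidean distance between the two
    points.  Each axis (optimum and both tolerance edges) is translated
    rigidly and its tail parameters re-derived.  Standardization uses the
    grid-wide standard deviation of each variable so that degC and mm
    contribute comparably to ``d_N``.
    """
    if C_adp < 0:
        raise ValueError("C_adp must be >= 0")
    if not (0.0 <= A <= 1.0):
        raise ValueError("adaptive capacity A must lie in [0, 1]")
    std_T = std_T if std_T > 0 else 1.0
    std_P = std_P if std_P > 0 else 1.0

    zt = (local_mean_T - niche_T.x_mean) / std_T
    zp = (local_mean_P - niche_P.x_mean) / std_P
    d_n = math.hypot(zt, zp)
    frac = C_adp * A
    if d_n == 0.0 or frac == 0.0:
        return niche_T, niche_P
    frac = min(frac, 1.0)  # never overshoot the target

    delta_T = frac * (local_mean_T - niche_T.x_mean)
    delta_P = frac * (local_mean_P - niche_P.x_mean)
    new_T = fit_axis_from_bounds(
        niche_T.x_mean + delta_T,
        niche_T.v_min + delta_T,
        niche_T.v_max + delta_T,
        niche_T.p_thresh,
    )
    new_P = fit_axis_from_bounds(
        niche_P.x_mean + delta_P,
        niche_P.v_min + delta_P,
        niche_P.v_max + delta_P,
        niche_P.p_thresh,
    )
    return new_T, new_P


# ---------------------------------------------------------------------------
# packed-array form used in the simulation hot path
# ---------------------------------------------------------------------------

#: column layout of a packed axis-parameter array
PARAM_COLS = ("x_mean", "v_min", "v_max", "a", "b", "c", "d")
X_MEAN, V_MIN, V_MAX, P_A, P_B, P_C, P_D = range(7)


def params_array(axes) -> np.ndarray:
    """Pack a sequence of NicheAxis into an (n, 7) float array."""
    out = np.empty((len(axes), 7), dtype=float)
    for i, ax in enumerate(axes):
        out[i] = (ax.x_mean, ax.v_min, ax.v_max, ax.a, ax.b, ax.c, ax.d)
    return out


def axis_from_params(row: np.ndarray, p_thresh: float = DEFAULT_P_THRESH) -> NicheAxis:
    return NicheAxis(*map(float, row[:7]), p_thresh=p_thresh)


def ext_prob_params(params: np.ndarray, x) -> np.ndarray:
    """Vectorized extinction probability for an (n, 7) parameter array at
    climate value(s) x (scalar or length-n)."""
    x = np.broadcast_to(np.asarray(x, dtype=float), (params.shape[0],))
    left = 1.0 - _vlogistic(params[:, P_C] * (x - params[:, P_D]))
    right = _vlogistic(params[:, P_A] * (x - params[:, P_B]))
    return np.clip(np.where(x <= params[:, X_MEAN], left, right), 0.0, 1.0)


def combined_ext_params(params_T: np.ndarray, params_P: np.ndarray, t, p) -> np.ndarray:
    return np.maximum(ext_prob_params(params_T, t), ext_prob_params(params_P, p))
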