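"""Multi-step regression estimation of autocorrelation coefficients r_k.

For each time lag ``k`` the coefficient ``r_k`` is the slope of the linear
regression of the activity shifted by ``k`` bins onto the unshifted
activity.  For a (fully sampled, stationary) first-order autoregressive
process ``r_k = m**k``, and under spatial subsampling only the amplitude of
``r_k`` is scaled while the exponential decay rate -- the intrinsic
timescale -- is untouched.

Two estimators that exploit the trial structure are provided:

``trialseparated``
    Regress within each trial separately, then average the per-trial
    slopes.  Robust to trial-to-trial changes of the mean activity, but
    biased when trials are short compared to the timescale.

``stationarymean``
    Pool all trials around common, lag-dependent means.  Assumes the
    activity is stationary across trials and in return compensates the
    short-trial bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_io import TrialArray, input_handler
from .exceptions import DegenerateDataError, ValidationError

__all__ = [
    "CoefficientResult",
    "rk_naive",
    "rk_trialseparated",
    "rk_stationarymean",
    "coefficients",
]

_METHODS = {
    "ts": "trialseparated",
    "trialseparated": "trialseparated",
    "sm": "stationarymean",
    "stationarymean": "stationarymean",
}


@dataclass
class CoefficientResult:
    """Estimated correlation coefficients with their time metadata.

    ``trial_coefficients`` (the per-trial matrix ``r_{i,k}``) is only
    populated by the trialseparated method.  ``bootstrap_samples`` and
    ``stderrs`` are attached when bootstrapping was requested.
    """

    steps: np.ndarray
    coefficients: np.ndarray
    method: str
    dt: float = 1.0
    dtunit: str = "steps"
    trial_coefficients: Optional[np.ndarray] = None
    stderrs: Optional[np.ndarray] = None
    bootstrap_samples: Optional[np.ndarray] = None
    num_trials: int = 0
    trial_length: int = 0
    # per-trial sufficient statistics kept for stationarymean resampling
    _sm_stats: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self):
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.steps.size != self.coefficients.size:
            raise ValidationError("steps and coefficients must have equal length")

    @property
    def lags(self) -> np.ndarray:
        """Physical lags ``k * dt`` in dtunits."""
        return self.steps * self.dt


def rk_naive(trial, k: int) -> float:
    """Lag-``k`` regression slope of a single activity vector (the naive
    single-time-series estimator).

    With ``x`` the first ``T-k`` samples and ``y`` the samples shifted by
    ``k``, returns ``sum((x - xbar)(y - ybar)) / sum((x - xbar)**2)`` where
    the means are taken over the respective ``T-k`` samples.
    """
    trial = np.asarray(trial, dtype=float).ravel()
    k = int(k)
    if k < 1:
        raise ValidationError(f"lag k must be >= 1, got {k}")
    if trial.size <= k + 1:
        raise ValidationError(
            f"trial of length {trial.size} too short for lag k={k}"
        )
    x = trial[:-k]
    y = trial[k:]
    xc = x - x.mean()
    den = np.dot(xc, xc)
    if den == 0.0:
        raise DegenerateDataError(
            f"zero variance over the first {x.size} samples at lag k={k}"
        )
    return float(np.dot(xc, y - y.mean()) / den)


def rk_trialseparated(trials, k: int):
    """Per-trial lag-``k`` slopes and their arithmetic mean.

    Returns ``(r_k, r_ik)`` where ``r_ik[i]`` is the naive estimate on
    trial ``i`` and ``r_k`` is the mean over trials.
    """
    values = trials.values if isinstance(trials, TrialArray) else np.atleast_2d(np.asarray(trials, dtype=float))
    k = int(k)
    if k < 1 or values.shape[1] <= k + 1:
        raise ValidationError(f"lag k={k} out of range for trial length {values.shape[1]}")
    x = values[:, :-k]
    y = values[:, k:]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    den = np.einsum("it,it->i", xc, xc)
    bad = np.nonzero(den == 0.0)[0]
    if bad.size:
        raise DegenerateDataError(
            f"trial {bad[0]} has zero variance over the first "
            f"{x.shape[1]} samples at lag k={k}"
        )
    r_ik = np.einsum("it,it->i", xc, yc) / den
    return float(r_ik.mean()), r_ik


def _sm_from_stats(sx, sy, sxy, sfull, sfull2, n, tk, t):
    """Evaluate the pooled (stationarymean) estimator from per-trial sums.

    All inputs may carry leading batch axes; the trial axis is the last.
    """
    xbar = sx.sum(axis=-1) / (n * tk)
    ybar = sy.sum(axis=-1) / (n * tk)
    num = (
        sxy.sum(axis=-1)
        - xbar * sy.sum(axis=-1)
        - ybar * sx.sum(axis=-1)
        + n * tk * xbar * ybar
    ) / tk
    den = (sfull2.sum(axis=-1) - 2 * xbar * sfull.sum(axis=-1) + n * t * xbar**2) / t
    return num, den


def rk_stationarymean(trials, k: int) -> float:
    """Pooled lag-``k`` slope across all trials.

    Deviations are taken from the lag-dependent pooled means
    ``xbar = (1/(N(T-k))) sum_i sum_{t<T-k} a_{i,t}`` (and the analogous
    shifted mean); the variance normalisation sums the squared deviations of
    every sample ``t = 1..T`` with weight ``1/T``.
    """
    values = trials.values if isinstance(trials, TrialArray) else np.atleast_2d(np.asarray(trials, dtype=float))
    n, t = values.shape
    k = int(k)
    if k < 1 or t <= k + 1:
        raise ValidationError(f"lag k={k} out of range for trial length {t}")
    x = values[:, :-k]
    y = values[:, k:]
    num, den = _sm_from_stats(
        sx=x.sum(axis=1),
        sy=y.sum(axis=1),
        sxy=np.einsum("it,it->i", x, y),
        sfull=values.sum(axis=1),
        sfull2=np.einsum("it,it->i", values, values),
        n=n,
        tk=t - k,
        t=t,
    )
    if den == 0.0:
        raise DegenerateDataError(f"pooled variance is zero at lag k={k}")
    return float(num / den)


def _resolve_steps(steps, trial_length: int) -> np.ndarray:
    kmax_allowed = trial_length - 2
    if kmax_allowed < 1:
        raise ValidationError(f"trials of length {trial_length} are too short")
    if steps is None:
        steps = (1, min(1000, kmax_allowed))
    steps_arr = np.asarray(steps)
    if steps_arr.ndim == 1 and steps_arr.size == 2 and isinstance(steps, tuple):
        kmin, kmax = int(steps[0]), int(steps[1])
        if kmin < 1 or kmax < kmin:
            raise ValidationError(f"invalid step range ({kmin}, {kmax})")
        if kmax > kmax_allowed:
            warnings.warn(
                f"kmax={kmax} exceeds the largest usable lag {kmax_allowed} "
                f"(trial length {trial_length}); clipping",
                stacklevel=3,
            )
            kmax = kmax_allowed
        if kmin > kmax_allowed:
            raise ValidationError(f"no usable lags remain in ({kmin}, {kmax})")
        return np.arange(kmin, kmax + 1, dtype=np.int64)
    steps_arr = np.unique(steps_arr.astype(np.int64).ravel())
    if steps_arr.size == 0 or steps_arr[0] < 1:
        raise ValidationError("explicit steps must be positive integers")
    keep = steps_arr <= kmax_allowed
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} step(s) beyond the largest usable "
            f"lag {kmax_allowed}",
            stacklevel=3,
        )
        steps_arr = steps_arr[keep]
    if steps_arr.size == 0:
        raise ValidationError("no usable lags remain after clipping")
    return steps_arr


def coefficients(
    data,
    method: str,
    steps=None,
    dt: Optional[float] = None,
    dtunit: Optional[str] = None,
    numboot: int = 0,
    seed: Optional[int] = None,
) -> CoefficientResult:
    """Estimate correlation coefficients ``r_k`` from trial-structured data.

    Parameters
    ----------
    data :
        Anything acceptable to :func:`mrtau.data_io.input_handler`.
    method :
        ``"trialseparated"``/``"ts"`` or ``"stationarymean"``/``"sm"``.
    steps :
        Either a ``(kmin, kmax)`` tuple (inclusive range) or an explicit
        array of lags; lags beyond ``T - 2`` are clipped with a warning.
        Defaults to ``(1, min(1000, T - 2))``.
    numboot :
        Number of trial-level bootstrap resamples used to attach standard
        errors and bootstrap samples (requires at least 2 trials;
        ``numboot=0`` disables resampling).
    seed :
        Seed for the bootstrap resampling stream.
    """
    if method not in _METHODS:
        raise ValidationError(
            f"unknown method '{method}'; choose from {sorted(set(_METHODS))}"
        )
    method = _METHODS[method]
    trials = input_handler(
        data, dt=1.0 if dt is None else dt, dtunit=dtunit or "steps"
    )
    # explicit arguments win; otherwise inherit the input's time metadata
    if dt is None:
        dt = trials.dt
    if dtunit is None:
        dtunit = trials.dtunit
    values = trials.values
    n, t = values.shape
    steps_arr = _resolve_steps(steps, t)
    nsteps = steps_arr.size

    rks = np.empty(nsteps)
    trial_coeffs = None
    sm_stats = None
    if method == "trialseparated":
        trial_coeffs = np.empty((n, nsteps))
        for j, k in enumerate(steps_arr):
            rks[j], trial_coeffs[:, j] = rk_trialseparated(trials, int(k))
    else:
        sfull = values.sum(axis=1)
        sfull2 = np.einsum("it,it->i", values, values)
        sx = np.empty((n, nsteps))
        sy = np.empty((n, nsteps))
        sxy = np.empty((n, nsteps))
        for j, k in enumerate(steps_arr):
            x = values[:, :-k]
            y = values[:, k:]
            sx[:, j] = x.sum(axis=1)
            sy[:, j] = y.sum(axis=1)
            sxy[:, j] = np.einsum("it,it->i", x, y)
            num, den = _sm_from_stats(
                sx[:, j], sy[:, j], sxy[:, j], sfull, sfull2, n, t - k, t
            )
            if den == 0.0:
                raise DegenerateDataError(f"pooled variance is zero at lag k={k}")
            rks[j] = num / den
        sm_stats = dict(sx=sx, sy=sy, sxy=sxy, sfull=sfull, sfull2=sfull2)

    result = CoefficientResult(
        steps=steps_arr,
        coefficients=rks,
        method=method,
        dt=dt,
        dtunit=dtunit,
        trial_coefficients=trial_coeffs,
        num_trials=n,
        trial_length=t,
        _sm_stats=sm_stats,
    )
    if numboot and numboot > 0 and n >= 2:
        samples = _bootstrap_coefficients(result, int(numboot), seed)
        result.bootstrap_samples = samples
        result.stderrs = samples.std(axis=0, ddof=1)
    return result


def _bootstrap_coefficients(result: CoefficientResult, numboot: int, seed) -> np.ndarray:
    """Trial-level bootstrap replicates of the full r_k curve.

    Each replicate draws ``N`` trials with replacement; for trialseparated
    the replicate is the mean of the resampled per-trial slopes, for
    stationarymean the pooled estimator is re-evaluated from per-trial
    sufficient statistics of the resampled trials.
    """
    rng = np.random.default_rng(seed)
    n = result.num_trials
    idx = rng.integers(0, n, size=(numboot, n))
    if result.method == "trialseparated":
        return result.trial_coefficients[idx].mean(axis=1)
    s = result._sm_stats
    t = result.trial_length
    tk = (t - result.steps).astype(float)  # (K,)
    # gather per-replicate sums; shapes (numboot, n, K) -> reduce trial axis
    num, den = _sm_from_stats(
        sx=np.swapaxes(s["sx"][idx], 1, 2),
        sy=np.swapaxes(s["sy"][idx], 1, 2),
        sxy=np.swapaxes(s["sxy"][idx], 1, 2),
        sfull=s["sfull"][idx][:, None, :],
        sfull2=s["sfull2"][idx][:, None, :],
        n=n,
        tk=tk[None, :],
        t=t,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den
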