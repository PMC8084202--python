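"""Analytic autocorrelation models and nonlinear least-squares fitting.

The intrinsic timescale ``tau`` is obtained by fitting an exponentially
decaying model to the estimated coefficients ``r_k`` as a function of the
physical lag ``k*dt``.  Because spatial subsampling only scales the
amplitude of ``r_k`` -- not its decay -- the amplitude is a free parameter
and the fitted ``tau`` is subsampling-invariant.  The fitted timescale maps
onto the branching parameter through ``m = exp(-dt/tau)``.

Three models are built in (lag ``t = k*dt`` in dtunits):

``exponential``          ``A * exp(-t/tau)``
``exponential_offset``   ``A * exp(-t/tau) + O``
``complex``              ``D*exp(-t/tau) + E*exp(-(t/tau_osc)**gamma) * cos(2*pi*nu*t)
                         + F*exp(-(t/tau_gauss)**2) + O``

The complex model augments the exponential with a stretched-exponentially
damped cosine (network oscillations, frequency ``nu`` in 1/dtunit), a
Gaussian term (single-neuron refractoriness) and an offset (slow
non-stationarities).  Its canonical parameter order is
``(tau, D, O, tau_osc, E, gamma, nu, tau_gauss, F)``.

Fits are unweighted least squares with a multi-start strategy (log-spaced
timescale grid, oscillation frequency seeded from the data); the start with
the smallest residual sum of squares wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .coefficients import CoefficientResult
from .exceptions import FitFailureError, ValidationError
from .uncertainty import percentile_ci

__all__ = [
    "FitFunctionSpec",
    "FitResult",
    "tau_from_m",
    "m_from_tau",
    "evaluate_fitfunc",
    "get_fitfunc",
    "fit",
]


# ---------------------------------------------------------------------------
# timescale <-> branching parameter


def tau_from_m(m: float, dt: float = 1.0) -> float:
    """Intrinsic timescale tau = -dt/ln(m) of a subcritical process."""
    if not (0 < m < 1):
        raise ValidationError(
            f"tau is only defined for 0 < m < 1 (subcritical), got m={m}"
        )
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    return float(-dt / np.log(m))


def m_from_tau(tau: float, dt: float = 1.0) -> float:
    """Branching parameter m = exp(-dt/tau); exact inverse of tau_from_m."""
    if tau <= 0:
        raise ValidationError(f"tau must be positive, got {tau}")
    if dt <= 0:
        raise ValidationError(f"dt must be positive, got {dt}")
    return float(np.exp(-dt / tau))


# ---------------------------------------------------------------------------
# model definitions


def _f_exponential(t, tau, A):
    return A * np.exp(-t / tau)


def _f_exponential_offset(t, tau, A, O):
    return A * np.exp(-t / tau) + O


def _f_complex(t, tau, D, O, tau_osc, E, gamma, nu, tau_gauss, F):
    return (
        D * np.exp(-t / tau)
        + E * np.exp(-((t / tau_osc) ** gamma)) * np.cos(2 * np.pi * nu * t)
        + F * np.exp(-((t / tau_gauss) ** 2))
        + O
    )


@dataclass(frozen=True)
class FitFunctionSpec:
    """An analytic autocorrelation model: callable, parameter names, and
    data-driven defaults for bounds and initial guesses."""

    name: str
    params: tuple
    fn: Callable = field(repr=False)
    bounds: Callable = field(repr=False)  # (lags, coeffs) -> (lower, upper)
    guesses: Callable = field(repr=False)  # (lags, coeffs) -> list of x0

    @property
    def nparams(self) -> int:
        return len(self.params)


def _tau_grid(lags, npoints=6):
    return np.geomspace(max(lags[0], 1e-6), lags[-1], npoints)


def _tail_offset(coeffs):
    ntail = max(1, coeffs.size // 10)
    return float(np.mean(coeffs[-ntail:]))


def _bounds_exponential(lags, coeffs):
    return (np.array([1e-4 * lags[0], 0.0]), np.array([10.0 * lags[-1], np.inf]))


def _guesses_exponential(lags, coeffs):
    a0 = max(float(coeffs[0]), 1e-3)
    return [np.array([tau0, a0]) for tau0 in _tau_grid(lags)]


def _bounds_exponential_offset(lags, coeffs):
    return (
        np.array([1e-4 * lags[0], 0.0, -np.inf]),
        np.array([10.0 * lags[-1], np.inf, np.inf]),
    )


def _guesses_exponential_offset(lags, coeffs):
    o0 = _tail_offset(coeffs)
    a0 = max(float(coeffs[0]) - o0, 1e-3)
    return [np.array([tau0, a0, o0]) for tau0 in _tau_grid(lags)]


def _frequency_candidates(lags, coeffs):
    """Plausible oscillation frequencies, from the spectrum of the
    detrended coefficients and from their zero-crossing rate."""
    cands = []
    resid = coeffs - np.convolve(coeffs, np.ones(5) / 5.0, mode="same")
    span = lags[-1] - lags[0]
    if span > 0 and resid.size > 8:
        dt_eff = span / (resid.size - 1)
        spec = np.abs(np.fft.rfft(resid))
        freqs = np.fft.rfftfreq(resid.size, d=dt_eff)
        if spec[1:].size:
            cands.append(float(freqs[1:][np.argmax(spec[1:])]))
    centered = coeffs - np.mean(coeffs)
    crossings = np.count_nonzero(np.diff(np.signbit(centered)))
    if span > 0 and crossings > 0:
        cands.append(crossings / (2.0 * span))
    nyquist = 0.5 / (lags[1] - lags[0]) if lags.size > 1 else 0.5
    cands = [nu for nu in cands if 0 < nu <= nyquist]
    return cands or [0.25 * nyquist]


def _bounds_complex(lags, coeffs):
    nyquist = 0.5 / (lags[1] - lags[0]) if lags.size > 1 else 0.5
    tmax = 10.0 * lags[-1]
    lower = np.array([1e-4 * lags[0], 0.0, -np.inf, 1e-4 * lags[0], 0.0, 1e-3, 0.0, 1e-4 * lags[0], 0.0])
    upper = np.array([tmax, np.inf, np.inf, tmax, np.inf, 5.0, nyquist, tmax, np.inf])
    return lower, upper


def _guesses_complex(lags, coeffs):
    o0 = _tail_offset(coeffs)
    amp = max(float(coeffs[0]) - o0, 1e-3)
    nus = _frequency_candidates(lags, coeffs)[:2]
    guesses = []
    for tau0 in _tau_grid(lags, npoints=4):
        for nu0 in nus:
            # amplitude split evenly between the three decaying terms
            guesses.append(
                np.array([tau0, amp / 3, o0, tau0, amp / 3, 1.0, nu0, tau0 / 2, amp / 3])
            )
            # exponential-dominated start
            guesses.append(
                np.array([tau0, amp, o0, 2 * tau0, amp / 10, 1.0, nu0, tau0 / 2, amp / 10])
            )
    return guesses


_FITFUNCS = {}


def _register(spec: FitFunctionSpec, *aliases: str):
    for key in (spec.name, *aliases):
        _FITFUNCS[key] = spec


_register(
    FitFunctionSpec(
        "exponential",
        ("tau", "A"),
        _f_exponential,
        _bounds_exponential,
        _guesses_exponential,
    ),
    "e",
    "exp",
)
_register(
    FitFunctionSpec(
        "exponential_offset",
        ("tau", "A", "O"),
        _f_exponential_offset,
        _bounds_exponential_offset,
        _guesses_exponential_offset,
    ),
    "eo",
    "exp_offset",
    "exp_off",
    "offset",
)
_register(
    FitFunctionSpec(
        "complex",
        ("tau", "D", "O", "tau_osc", "E", "gamma", "nu", "tau_gauss", "F"),
        _f_complex,
        _bounds_complex,
        _guesses_complex,
    ),
    "c",
    "cplx",
)


def get_fitfunc(label) -> FitFunctionSpec:
    """Resolve a model label or abbreviation to its spec."""
    if isinstance(label, FitFunctionSpec):
        return label
    try:
        return _FITFUNCS[str(label).lower()]
    except KeyError:
        raise ValidationError(
            f"unknown fit function '{label}'; known labels: "
            f"{sorted(set(_FITFUNCS))}"
        ) from None


def evaluate_fitfunc(spec, lag, params):
    """Evaluate a model at the given physical lag(s)."""
    spec = get_fitfunc(spec)
    params = np.asarray(params, dtype=float).ravel()
    if params.size != spec.nparams:
        raise ValidationError(
            f"{spec.name} takes {spec.nparams} parameters, got {params.size}"
        )
    return spec.fn(np.asarray(lag, dtype=float), *params)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Outcome of fitting one autocorrelation model."""

    fitfunc: str
    tau: float
    mre: float
    params: dict
    popt: np.ndarray
    ssres: float
    fitrange: np.ndarray
    dt: float
    dtunit: str
    ci: Optional[dict] = None
    ci_level: Optional[float] = None
    bootstrap_params: Optional[np.ndarray] = None
    warnings: list = field(default_factory=list)

    def model_values(self, lags) -> np.ndarray:
        return evaluate_fitfunc(self.fitfunc, lags, self.popt)


def _detect_supercritical(lags, coeffs) -> Optional[float]:
    """Log-slope diagnostic: growing coefficients imply m > 1.

    Returns the implied per-step growth factor when the coefficients are
    overwhelmingly positive with a clearly positive log-slope, else None.
    """
    positive = coeffs > 0
    if positive.mean() < 0.9 or positive.sum() < 4:
        return None
    x = lags[positive]
    y = np.log(coeffs[positive])
    slope = np.polyfit(x, y, 1)[0]
    # require clear growth: second half above first half, positive slope
    half = coeffs.size // 2
    if slope > 0 and np.mean(coeffs[half:]) > np.mean(coeffs[:half]):
        return float(slope)
    return None


def _run_least_squares(spec, lags, coeffs, x0, bounds):
    def residual(p):
        return spec.fn(lags, *p) - coeffs

    x0 = np.clip(x0, bounds[0], bounds[1])
    # keep strictly inside where bounds are open
    x0 = np.where(x0 <= bounds[0], bounds[0] + 1e-12, x0)
    return least_squares(
        residual, x0, bounds=bounds, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-12,
        max_nfev=2000,
    )


def _fit_once(spec, lags, coeffs, extra_starts=()):
    bounds = spec.bounds(lags, coeffs)
    best = None
    failures = []
    starts = list(extra_starts) + list(spec.guesses(lags, coeffs))
    for x0 in starts:
        try:
            sol = _run_least_squares(spec, lags, coeffs, x0, bounds)
        except Exception as exc:  # optimizer blow-up on one start is not fatal
            failures.append(str(exc))
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        ssres = float(np.sum(sol.fun**2))
        if best is None or ssres < best[1]:
            best = (sol, ssres)
    if best is None:
        raise FitFailureError(
            f"{spec.name} fit failed from all {len(starts)} initial guesses",
            diagnostics={"failures": failures},
        )
    return best[0], best[1], bounds


def fit(
    coeffs: CoefficientResult,
    fitfunc="exponential_offset",
    fitrange=None,
    numboot: int = 0,
    seed: Optional[int] = None,
    ci_level: float = 0.75,
) -> FitResult:
    """Fit an autocorrelation model to estimated coefficients.

    Parameters
    ----------
    coeffs :
        A :class:`CoefficientResult`.
    fitfunc :
        Model label (full name or abbreviation).
    fitrange :
        Optional ``(kmin, kmax)`` tuple or explicit array restricting the
        steps used for fitting; defaults to all available steps.
    numboot, seed :
        When the coefficient result carries bootstrap samples those are
        refitted to yield parameter confidence intervals; otherwise, if
        ``numboot > 0`` and per-trial coefficients exist, trial-level
        replicates are generated here with ``seed``.
    ci_level :
        Confidence level of the percentile intervals (default 0.75).

    Returns a :class:`FitResult` with the fitted timescale ``tau`` (in
    dtunits) and the derived branching parameter ``mre = exp(-dt/tau)``.
    """
    spec = get_fitfunc(fitfunc)
    steps = coeffs.steps
    rk = coeffs.coefficients
    if fitrange is not None:
        fr = np.asarray(fitrange)
        if fr.size == 2 and isinstance(fitrange, tuple):
            mask = (steps >= fr[0]) & (steps <= fr[1])
        else:
            mask = np.isin(steps, fr)
        if not mask.any():
            raise ValidationError("fitrange selects no available steps")
        steps, rk = steps[mask], rk[mask]
    else:
        mask = np.ones(coeffs.steps.size, dtype=bool)
    if steps.size < spec.nparams + 1:
        raise ValidationError(
            f"need at least {spec.nparams + 1} coefficients to fit "
            f"{spec.name}, got {steps.size}"
        )
    lags = steps * coeffs.dt

    warn_list = []
    growth = _detect_supercritical(lags, rk)
    if growth is not None:
        mhat = float(np.exp(growth * coeffs.dt))
        warnings.warn(
            f"coefficients grow with the lag: the process looks supercritical "
            f"(log-slope implies m = {mhat:.4f} > 1); no decay time exists and "
            "the exponential fit is not attempted",
            stacklevel=2,
        )
        return FitResult(
            fitfunc=spec.name,
            tau=float("nan"),
            mre=mhat,
            params={},
            popt=np.full(spec.nparams, np.nan),
            ssres=float("nan"),
            fitrange=steps,
            dt=coeffs.dt,
            dtunit=coeffs.dtunit,
            warnings=["supercritical"],
        )

    sol, ssres, bounds = _fit_once(spec, lags, rk)
    popt = sol.x
    tau = float(popt[0])
    if tau >= 0.99 * bounds[1][0]:
        warn_list.append("tau_at_bound")
        warnings.warn(
            f"fitted tau = {tau:.3g} {coeffs.dtunit} is pinned at the upper "
            "bound; consider extending the step range",
            stacklevel=2,
        )
    mre = m_from_tau(tau, coeffs.dt)

    result = FitResult(
        fitfunc=spec.name,
        tau=tau,
        mre=mre,
        params=dict(zip(spec.params, popt)),
        popt=popt,
        ssres=ssres,
        fitrange=steps,
        dt=coeffs.dt,
        dtunit=coeffs.dtunit,
        warnings=warn_list,
    )

    replicates = None
    if coeffs.bootstrap_samples is not None and len(coeffs.bootstrap_samples):
        replicates = np.asarray(coeffs.bootstrap_samples)[:, mask]
    elif numboot and numboot > 0 and coeffs.trial_coefficients is not None:
        tc = coeffs.trial_coefficients[:, mask]
        n = tc.shape[0]
        if n >= 2:
            rng = np.random.default_rng(seed)
            idx = rng.integers(0, n, size=(int(numboot), n))
            replicates = tc[idx].mean(axis=1)

    if replicates is not None:
        boot = _refit_replicates(spec, lags, replicates, popt, bounds)
        if boot is not None and boot.shape[0] >= 2:
            result.bootstrap_params = boot
            ci = {
                name: percentile_ci(boot[:, j], ci_level)
                for j, name in enumerate(spec.params)
            }
            taus = boot[:, 0]
            good = np.isfinite(taus) & (taus > 0)
            ci["tau"] = percentile_ci(taus[good], ci_level) if good.sum() >= 2 else ci["tau"]
            if good.sum() >= 2:
                ci["mre"] = percentile_ci(np.exp(-coeffs.dt / taus[good]), ci_level)
            result.ci = ci
            result.ci_level = ci_level
    return result


def _refit_replicates(spec, lags, replicates, popt, bounds):
    """Refit each bootstrap replicate of the coefficient curve, starting
    from the point estimate (fast polish; the global search already ran)."""
    out = []
    for rk_b in replicates:
        if not np.all(np.isfinite(rk_b)):
            continue
        try:
            sol = _run_least_squares(spec, lags, rk_b, popt.copy(), bounds)
        except Exception:
            continue
        if np.all(np.isfinite(sol.x)):
            out.append(sol.x)
    return np.asarray(out) if out else None
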