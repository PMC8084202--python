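"""Closed-form expectations for the short-trial bias of the estimator.

When a single trial is not much longer than the intrinsic timescale, the
sample means entering the lag-``k`` regression are themselves biased, which
pushes the estimated coefficients (and hence the timescale) systematically
downward.  For the one-step coefficient of a stationary first-order
autoregressive process with true parameter ``m`` and trial length ``T``
(in steps), the expectation of the biased estimate is, to leading order in
``1/T``,

    E[m_hat] = m * (1 - (1/T) * (3 + 1/m))

Propagating this through ``tau = -dt / ln(m)`` gives the expected ratio of
the estimated to the true timescale,

    tau_hat / tau = 1 / (1 + (tau/(T*dt)) * (3 + exp(dt/tau)))

and, for ``tau >> dt``, the leading-order universal curve in the normalised
trial length ``x = T*dt/tau``:

    y = 1 / (1 + 4/x)

These formulas describe the trialseparated estimator (each trial's means
are estimated within that trial); the stationarymean estimator pools trials
and compensates the bias when activity is stationary across trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "BiasPrediction",
    "expected_mhat",
    "expected_tau_ratio",
    "tau_ratio_leading_order",
]


@dataclass(frozen=True)
class BiasPrediction:
    """Expected short-trial bias at one trial length."""

    m_hat_expected: float
    tau_ratio: float
    trial_length: int
    x: float  # normalised trial length T*dt/tau


def expected_mhat(m: float, T: int) -> float:
    """Expectation of the biased one-step coefficient for trial length T.

    Always below the true ``m``: the bias is downward.
    """
    if not (0 < m < 1):
        raise ValidationError(f"m must be in (0, 1), got {m}")
    if T < 2:
        raise ValidationError(f"trial length T must be >= 2, got {T}")
    return m * (1.0 - (3.0 + 1.0 / m) / T)


def expected_tau_ratio(tau: float, T: int, dt: float = 1.0) -> float:
    """Expected ratio tau_hat / tau of the trialseparated estimate (full,
    non-leading-order form)."""
    if tau <= 0 or T <= 0 or dt <= 0:
        raise ValidationError("tau, T and dt must all be positive")
    return 1.0 / (1.0 + (tau / (T * dt)) * (3.0 + np.exp(dt / tau)))


def tau_ratio_leading_order(x) -> float:
    """Leading-order bias curve y = 1/(1 + 4/x) in x = T*dt/tau.

    Monotone increasing, approaching 1 for long trials.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("normalised trial length x must be positive")
    out = 1.0 / (1.0 + 4.0 / x)
    return float(out) if out.ndim == 0 else out


def predict(m: float, T: int, dt: float = 1.0) -> BiasPrediction:
    """Bundle the bias expectations for one (m, T) condition."""
    tau = -dt / np.log(m)
    return BiasPrediction(
        m_hat_expected=expected_mhat(m, T),
        tau_ratio=expected_tau_ratio(tau, T, dt),
        trial_length=int(T),
        x=T * dt / tau,
    )
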