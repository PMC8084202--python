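"""Driven branching-process simulator with binomial subsampling.

The model is the mean-field (fully-connected) driven branching process: at
every discrete time step each of the ``A_t`` active units triggers on
average ``m`` units in the next step, and an external Poisson drive adds on
average ``h*dt`` events.  Conditioned on the present activity, the next
activity therefore satisfies

    <A_{t+1} | A_t> = m * A_t + h * dt

For ``m < 1`` the process is stationary with mean ``<A> = h*dt / (1 - m)``
and its autocorrelation decays as ``r_k = m**k``, i.e. with intrinsic
timescale ``tau = -dt / ln(m)``.  Offspring and drive are drawn jointly as
``A_{t+1} ~ Poisson(m*A_t + h*dt)`` (a sum of independent Poisson offspring
per unit plus Poisson drive is itself Poisson with that mean, which keeps
the conditional-mean contract exact).

Subsampling emulates the experimental constraint of observing only a
fraction ``alpha`` of the system: each recorded count ``a_t`` is a binomial
draw with ``A_t`` attempts and success probability ``alpha``, independently
per time bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_io import TrialArray
from .exceptions import ValidationError

__all__ = ["BranchingConfig", "simulate_branching", "simulate_subsampling"]


@dataclass(frozen=True)
class BranchingConfig:
    """Parameters of a simulated driven branching process.

    Parameters
    ----------
    m :
        Branching parameter (mean offspring per event per step), >= 0.
    h :
        External drive rate in events per dtunit; the drive contributes
        ``h*dt`` events per bin on average.  May be omitted when
        ``target_activity`` is given and ``m < 1``.
    target_activity :
        Desired stationary mean activity ``a`` in events per bin.  For
        ``m < 1`` the drive is set to ``h = a*(1-m)/dt`` so that the
        stationary mean ``h*dt/(1-m)`` equals ``a``.
    dt :
        Bin size in dtunits.
    length :
        Time steps per trial, >= 2.
    numtrials :
        Number of independent trials.
    subp :
        Sampling fraction ``alpha`` in (0, 1]; values below 1 return the
        binomially subsampled activity.
    seed :
        Master seed; each trial uses an independently derived substream, so
        enlarging ``numtrials`` does not perturb earlier trials.
    burnin :
        Steps simulated and discarded before recording (default 0: the
        process starts at its stationary mean and is stationary from t=0
        for the linear statistics used here).
    """

    m: float
    h: Optional[float] = None
    target_activity: Optional[float] = None
    dt: float = 1.0
    length: int = 10000
    numtrials: int = 1
    subp: float = 1.0
    seed: Optional[int] = None
    burnin: int = 0

    def __post_init__(self):
        if self.m < 0:
            raise ValidationError(f"branching parameter m must be >= 0, got {self.m}")
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        if int(self.length) < 2:
            raise ValidationError(f"length must be >= 2, got {self.length}")
        if int(self.numtrials) < 1:
            raise ValidationError(f"numtrials must be >= 1, got {self.numtrials}")
        if not (0 < self.subp <= 1):
            raise ValidationError(f"subp must be in (0, 1], got {self.subp}")
        if self.burnin < 0:
            raise ValidationError(f"burnin must be >= 0, got {self.burnin}")
        if self.h is None and self.target_activity is None:
            raise ValidationError("one of h or target_activity must be given")
        if self.h is not None and self.h < 0:
            raise ValidationError(f"drive h must be >= 0, got {self.h}")
        if self.target_activity is not None and self.target_activity <= 0:
            raise ValidationError(
                f"target_activity must be positive, got {self.target_activity}"
            )
        if self.h is None and self.m >= 1:
            raise ValidationError(
                "m >= 1 has no finite stationary mean: the drive h must be "
                "given explicitly"
            )

    @property
    def drive(self) -> float:
        """Effective external drive rate h (events per dtunit)."""
        if self.h is not None:
            return self.h
        return self.target_activity * (1.0 - self.m) / self.dt

    @property
    def initial_activity(self) -> int:
        """Deterministic starting activity A_0."""
        if self.target_activity is not None:
            return max(int(round(self.target_activity)), 0)
        if self.m < 1:
            return max(int(round(self.drive * self.dt / (1.0 - self.m))), 0)
        return max(int(round(self.drive * self.dt)), 0)


def _simulate_trial(rng: np.random.Generator, config: BranchingConfig) -> np.ndarray:
    hdt = config.drive * config.dt
    m = config.m
    total = config.burnin + int(config.length)
    out = np.empty(total, dtype=np.int64)
    a = config.initial_activity
    out[0] = a
    for t in range(1, total):
        a = rng.poisson(m * a + hdt)
        out[t] = a
    return out[config.burnin :]


def simulate_branching(config: BranchingConfig, return_full: bool = False):
    """Simulate a driven branching process.

    Returns a :class:`TrialArray` of shape ``(numtrials, length)`` with
    non-negative integer counts.  When ``config.subp < 1`` the returned
    array is the binomially subsampled activity; pass ``return_full=True``
    to additionally obtain the fully sampled array as
    ``(subsampled, full)``.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(int(config.numtrials) + 1)
    values = np.empty((config.numtrials, config.length), dtype=np.int64)
    for i in range(config.numtrials):
        values[i] = _simulate_trial(np.random.Generator(np.random.PCG64(children[i])), config)
    full = TrialArray(values, dt=config.dt, dtunit="steps")
    if config.subp >= 1.0:
        return (full, full) if return_full else full
    sub_rng = np.random.Generator(np.random.PCG64(children[-1]))
    sub = _binomial_thin(full, config.subp, sub_rng)
    return (sub, full) if return_full else sub


def _binomial_thin(trials: TrialArray, prob: float, rng: np.random.Generator) -> TrialArray:
    counts = trials.values
    ints = np.rint(counts)
    if np.any(np.abs(counts - ints) > 1e-9) or np.any(counts < 0):
        raise ValidationError("subsampling requires non-negative integer counts")
    thinned = rng.binomial(ints.astype(np.int64), prob)
    return trials.with_values(thinned)


def simulate_subsampling(trials, prob: float, seed: Optional[int] = None) -> TrialArray:
    """Binomially subsample activity counts.

    Each count ``A_t`` is replaced by a draw from ``Binomial(A_t, prob)``,
    independently per time bin; shape and time metadata are preserved and
    ``a_t <= A_t`` holds elementwise.  ``prob = 1`` returns an identical
    copy.
    """
    if not (0 < prob <= 1):
        raise ValidationError(f"sampling fraction must be in (0, 1], got {prob}")
    if not isinstance(trials, TrialArray):
        trials = TrialArray(np.asarray(trials, dtype=float).reshape(1, -1) if np.ndim(trials) == 1 else np.asarray(trials, dtype=float))
    if prob == 1.0:
        return trials.with_values(trials.values.copy())
    rng = np.random.default_rng(seed)
    return _binomial_thin(trials, prob, rng)
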