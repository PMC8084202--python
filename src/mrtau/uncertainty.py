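"""Trial-level bootstrap resampling and percentile confidence intervals.

Every trial is treated as one exchangeable unit ("bin"): a bootstrap sample
draws ``N`` trials with replacement and re-evaluates the statistic of
interest on them.  Confidence intervals are empirical percentile intervals
(linear-interpolation quantiles) at a default level of 75%.  A single trial
carries no resampling information; long single recordings should first be
cut into artificial trials with :func:`mrtau.data_io.chunk_into_trials`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .data_io import TrialArray
from .exceptions import SingleTrialError, ValidationError

__all__ = ["BootstrapSpec", "bootstrap_trials", "percentile_ci"]


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap configuration: sample count, seed and confidence level."""

    numboot: int = 100
    seed: Optional[int] = None
    level: float = 0.75

    def __post_init__(self):
        if self.numboot < 0:
            raise ValidationError(f"numboot must be >= 0, got {self.numboot}")
        if not (0 < self.level < 1):
            raise ValidationError(f"confidence level must be in (0, 1), got {self.level}")


def bootstrap_trials(data, statistic: Callable, spec: BootstrapSpec) -> np.ndarray:
    """Draw ``spec.numboot`` bootstrap values of ``statistic``.

    ``data`` is either a :class:`TrialArray` (the statistic receives a
    resampled TrialArray) or a 1-D/2-D array whose first axis indexes
    trials (the statistic receives the resampled rows).  Identical seeds
    yield identical samples.
    """
    if isinstance(data, TrialArray):
        n = data.numtrials
        take = lambda idx: data.with_values(data.values[idx])  # noqa: E731
    else:
        arr = np.asarray(data)
        n = arr.shape[0]
        take = lambda idx: arr[idx]  # noqa: E731
    if n < 2:
        raise SingleTrialError(
            "bootstrap needs at least 2 trials; cut long recordings into "
            "artificial trials first (see mrtau.data_io.chunk_into_trials)"
        )
    rng = np.random.default_rng(spec.seed)
    samples = []
    for b in range(spec.numboot):
        idx = rng.integers(0, n, size=n)
        try:
            samples.append(statistic(take(idx)))
        except Exception as exc:
            raise type(exc)(f"statistic failed on bootstrap resample {b}: {exc}") from exc
    return np.asarray(samples)


def percentile_ci(samples, level: float = 0.75):
    """Empirical percentile confidence interval.

    Returns the ``(1-level)/2`` and ``1-(1-level)/2`` linear-interpolation
    quantiles of the samples, e.g. the 12.5% and 87.5% quantiles for the
    default 75% level.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    samples = samples[np.isfinite(samples)]
    if samples.size < 2:
        raise ValidationError("need at least 2 finite samples for a confidence interval")
    if not (0 < level < 1):
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    lo = (1.0 - level) / 2.0
    lower, upper = np.quantile(samples, [lo, 1.0 - lo])
    return float(lower), float(upper)
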