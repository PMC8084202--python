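"""Trial-structured data container and converters for real-world inputs.

The universal exchange format of this package is the :class:`TrialArray`: a
two-dimensional matrix whose first index labels the trial and whose second
index labels the time bin, together with the bin size ``dt`` and a free-text
unit label ``dtunit``.  All trials must have the same length and the same
``dt``.  The helpers in this module convert common raw inputs -- nested
lists, flat sequences, whitespace/comma-delimited text files (optionally via
wildcards), spike time-stamp lists and single long recordings -- into that
format.
"""

from __future__ import annotations

import glob as _glob
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import FormatError, ValidationError

__all__ = [
    "TrialArray",
    "SpikeTimes",
    "input_handler",
    "bin_spike_times",
    "chunk_into_trials",
    "write_trials",
]


@dataclass
class TrialArray:
    """Trial-structured activity: ``values[i, t]`` is the activity in time
    bin ``t`` of trial ``i``.

    Parameters
    ----------
    values :
        Two-dimensional numeric matrix of shape ``(numtrials, length)``.
    dt :
        Size of one time bin, in units of ``dtunit``.
    dtunit :
        Free-text label for the time unit (e.g. ``"ms"``, ``"steps"``).
    """

    values: np.ndarray
    dt: float = 1.0
    dtunit: str = "steps"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise FormatError(
                f"trial data must be two-dimensional (trials x time), "
                f"got ndim={values.ndim}"
            )
        if not np.all(np.isfinite(values)):
            raise FormatError("trial data contains non-finite entries")
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        self.values = values

    @property
    def numtrials(self) -> int:
        return self.values.shape[0]

    @property
    def triallength(self) -> int:
        return self.values.shape[1]

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def with_values(self, values: np.ndarray) -> "TrialArray":
        """Return a new TrialArray with the same time metadata."""
        return TrialArray(values=values, dt=self.dt, dtunit=self.dtunit)


@dataclass
class SpikeTimes:
    """A sorted, non-negative sequence of event time stamps."""

    timestamps: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float).ravel()
        if ts.size == 0:
            raise ValidationError("spike-time list is empty")
        if np.any(ts < 0):
            raise ValidationError("spike times must be non-negative")
        if np.any(np.diff(ts) < 0):
            ts = np.sort(ts)
        self.timestamps = ts


def _load_text_matrix(path: str) -> np.ndarray:
    """Load one whitespace- or comma-delimited numeric text file.

    Lines starting with '#' are treated as comments.
    """
    try:
        return np.loadtxt(path, comments="#", ndmin=1)
    except ValueError:
        pass
    try:
        return np.loadtxt(path, comments="#", delimiter=",", ndmin=1)
    except ValueError as exc:
        raise FormatError(f"could not parse numeric content of '{path}': {exc}") from exc


def _columns_as_trials(arr: np.ndarray, usecols) -> list[np.ndarray]:
    """Interpret a loaded file: one column = one trial."""
    if arr.ndim == 1:
        cols = [arr]
    else:
        cols = [arr[:, j] for j in range(arr.shape[1])]
    if usecols is not None:
        try:
            cols = [cols[j] for j in usecols]
        except IndexError as exc:
            raise ValidationError(
                f"usecols={tuple(usecols)} out of range for {len(cols)} column(s)"
            ) from exc
    return cols


def input_handler(source, usecols=None, dt: float = 1.0, dtunit: str = "steps") -> TrialArray:
    """Coerce ``source`` into a :class:`TrialArray`.

    Accepted sources:

    * an existing :class:`TrialArray` (returned unchanged; ``dt``/``dtunit``
      arguments are ignored in that case),
    * a flat 1-D sequence -> a single trial,
    * a 2-D structure or nested lists of equal length -> trials x time,
    * one or more file paths (wildcards are expanded); each column of each
      file becomes one trial; ``usecols`` selects columns.
    """
    if isinstance(source, TrialArray):
        return source

    if isinstance(source, (str, os.PathLike)) or (
        isinstance(source, (list, tuple))
        and len(source) > 0
        and all(isinstance(s, (str, os.PathLike)) for s in source)
    ):
        patterns = [source] if isinstance(source, (str, os.PathLike)) else list(source)
        paths: list[str] = []
        for pat in patterns:
            pat = os.fspath(pat)
            matches = sorted(_glob.glob(os.path.expanduser(pat)))
            if not matches:
                raise FileNotFoundError(f"no file matches '{pat}'")
            paths.extend(matches)
        trials: list[np.ndarray] = []
        for path in paths:
            trials.extend(_columns_as_trials(_load_text_matrix(path), usecols))
        lengths = {len(t) for t in trials}
        if len(lengths) > 1:
            bad = next(i for i, t in enumerate(trials) if len(t) != len(trials[0]))
            raise FormatError(
                f"trials have unequal lengths {sorted(lengths)}; "
                f"first offending trial index {bad}"
            )
        return TrialArray(np.vstack(trials), dt=dt, dtunit=dtunit)

    arr = np.asarray(source, dtype=object)
    if arr.dtype == object:
        # ragged nested lists end up as object arrays
        try:
            arr = np.asarray(source, dtype=float)
        except (ValueError, TypeError):
            lengths = [len(row) for row in source]
            bad = next(i for i, n in enumerate(lengths) if n != lengths[0])
            raise FormatError(
                f"trial {bad} has length {lengths[bad]}, expected {lengths[0]}: "
                "all trials need the same length"
            ) from None
    else:
        arr = arr.astype(float)

    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.ndim != 2:
        raise FormatError(f"cannot interpret {arr.ndim}-dimensional input as trials x time")
    return TrialArray(arr, dt=dt, dtunit=dtunit)


def bin_spike_times(spikes, bin_size: float) -> np.ndarray:
    """Convert spike time stamps into an activity vector.

    The vector has ``ceil(last_timestamp / bin_size)`` bins and each spike
    increments bin ``floor(timestamp / bin_size)``.  A time stamp falling
    exactly on the upper edge of the final bin is clamped into the last bin
    so that the total spike count is conserved.
    """
    if bin_size <= 0:
        raise ValidationError(f"bin_size must be positive, got {bin_size}")
    if not isinstance(spikes, SpikeTimes):
        spikes = SpikeTimes(np.asarray(spikes, dtype=float))
    ts = spikes.timestamps
    num_bins = int(np.ceil(ts[-1] / bin_size))
    num_bins = max(num_bins, 1)
    idx = np.floor(ts / bin_size).astype(np.int64)
    idx = np.minimum(idx, num_bins - 1)  # clamp the exact-edge spike
    out = np.bincount(idx, minlength=num_bins)
    return out.astype(np.int64)


def chunk_into_trials(series, numtrials: int, dt: float = 1.0, dtunit: str = "steps") -> TrialArray:
    """Cut one long recording into ``numtrials`` artificial trials.

    Trial ``i`` holds samples ``[i*len, (i+1)*len)`` with
    ``len = floor(L / numtrials)``; trailing remainder samples are dropped.
    """
    series = np.asarray(series, dtype=float).ravel()
    if numtrials < 1:
        raise ValidationError(f"numtrials must be >= 1, got {numtrials}")
    if numtrials > series.size:
        raise ValidationError(
            f"cannot cut a series of length {series.size} into {numtrials} trials"
        )
    triallen = series.size // numtrials
    values = series[: numtrials * triallen].reshape(numtrials, triallen)
    return TrialArray(values, dt=dt, dtunit=dtunit)


def write_trials(trials: TrialArray, path, header_lines: Iterable[str] = ()) -> None:
    """Write a TrialArray as delimited text, one column per trial.

    '#'-prefixed header lines carry metadata and are ignored by
    :func:`input_handler` on re-read; values are written at full precision
    so the round trip is exact.
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# dt = {trials.dt!r}\n")
        fh.write(f"# dtunit = {trials.dtunit}\n")
        fh.write("# one column per trial\n")
        np.savetxt(fh, trials.values.T, fmt="%.17g", delimiter="\t")
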