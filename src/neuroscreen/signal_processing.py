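"""Raw six-axis inertial signal conditioning.

Converts tri-axial accelerometer/gyroscope streams into a clean,
gravity-free scalar movement signal:

1. :func:`compute_norm` — per-sample Euclidean magnitude of an axis
   triplet, which is invariant under sensor orientation.
2. :func:`fill_gaps` — local degree-2 polynomial interpolation of short
   interior gaps caused by streaming loss.
3. :func:`remove_gravity` — zero-phase Butterworth high-pass filtering
   (default cut-off 0.1 Hz) that strips the constant 1 g gravity
   component while leaving voluntary-movement frequencies untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps


class SignalError(ValueError):
    """Raised when a signal violates a processing precondition."""


@dataclass
class ImuSeries:
    """Uniformly sampled six-axis inertial time series from one sensor.

    Acceleration axes (``ax, ay, az``) are in units of g; angular-velocity
    axes (``gx, gy, gz``) in deg/s. ``gap_mask`` flags samples lost during
    streaming; gap samples hold NaN.
    """

    sample_rate: float
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    gap_mask: np.ndarray = None  # type: ignore[assignment]

    AXES = ("ax", "ay", "az", "gx", "gy", "gz")

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise SignalError(f"sample_rate must be positive, got {self.sample_rate}")
        arrays = {name: np.asarray(getattr(self, name), dtype=float) for name in ("t",) + self.AXES}
        n = arrays["t"].size
        if n == 0:
            raise SignalError("empty series: no samples")
        for name, arr in arrays.items():
            if arr.size != n:
                raise SignalError(f"channel {name!r} has length {arr.size}, expected {n}")
            setattr(self, name, arr)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(n, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.size != n:
                raise SignalError("gap_mask length does not match signal length")
        if n > 1:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise SignalError("time grid must be strictly increasing")
            if not np.allclose(steps, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-9):
                raise SignalError("time grid step does not match 1/sample_rate")
        valid = ~self.gap_mask
        for name in self.AXES:
            if not np.all(np.isfinite(getattr(self, name)[valid])):
                raise SignalError(f"non-finite value in channel {name!r} outside gaps")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class ScalarSignal:
    """A single uniformly sampled scalar channel with a units tag."""

    sample_rate: float
    values: np.ndarray
    units: str = "g"
    gap_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise SignalError(f"sample_rate must be positive, got {self.sample_rate}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise SignalError("empty signal: no samples")
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.values.size, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.size != self.values.size:
                raise SignalError("gap_mask length does not match signal length")
        if not np.all(np.isfinite(self.values[~self.gap_mask])):
            raise SignalError("non-finite value outside gaps")

    def __len__(self) -> int:
        return self.values.size


def compute_norm(series: ImuSeries, source: str = "accel") -> ScalarSignal:
    """Per-sample Euclidean magnitude ``sqrt(x² + y² + z²)`` of an axis triplet.

    The norm is invariant under any fixed rotation of the sensor, which is
    why downstream features are computed on it rather than on raw axes.
    Gap samples stay gaps.

    Parameters
    ----------
    series:
        Input six-axis series.
    source:
        ``"accel"`` (g) or ``"gyro"`` (deg/s).
    """
    if source == "accel":
        x, y, z = series.ax, series.ay, series.az
        units = "g"
    elif source == "gyro":
        x, y, z = series.gx, series.gy, series.gz
        units = "deg/s"
    else:
        raise ValueError(f"source must be 'accel' or 'gyro', got {source!r}")
    values = np.sqrt(x * x + y * y + z * z)
    values = np.where(series.gap_mask, np.nan, values)
    return ScalarSignal(series.sample_rate, values, units=units, gap_mask=series.gap_mask.copy())


def _gap_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) half-open index pairs."""
    runs = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        runs.append((int(start), int(stop)))
    return runs


# Valid samples taken from each side of a gap for the quadratic fit.
_FIT_SUPPORT = 3


def _fill_channel(values: np.ndarray, mask: np.ndarray, max_gap_samples: int) -> np.ndarray:
    out = values.copy()
    n = values.size
    for start, stop in _gap_runs(mask):
        if start == 0 or stop == n:
            continue  # leading/trailing gaps handled by trimming, not here
        length = stop - start
        if length > max_gap_samples:
            raise SignalError(
                f"gap of {length} samples at [{start}, {stop}) exceeds max_gap_samples={max_gap_samples}"
            )
        left = [i for i in range(start - 1, -1, -1) if not mask[i]][:_FIT_SUPPORT]
        right = [i for i in range(stop, n) if not mask[i]][:_FIT_SUPPORT]
        support = np.array(sorted(left + right))
        if support.size < 3:
            raise SignalError(f"gap at [{start}, {stop}) has fewer than 3 valid neighbours")
        # least-squares degree-2 polynomial on up to 3 valid samples per side
        coeff = np.polynomial.polynomial.polyfit(support.astype(float), values[support], deg=2)
        out[start:stop] = np.polynomial.polynomial.polyval(
            np.arange(start, stop, dtype=float), coeff
        )
    return out


def fill_gaps(signal, max_gap_samples: int = 10):
    """Interpolate short interior gaps with a local degree-2 polynomial.

    The polynomial is least-squares fitted to the 3 nearest valid samples
    on each side of the gap. Leading/trailing gaps are trimmed rather than
    extrapolated. Non-gap samples are returned bit-identical.

    Accepts a :class:`ScalarSignal` or an :class:`ImuSeries` (each channel
    interpolated independently); returns the same type, gap-free.
    """
    if isinstance(signal, ScalarSignal):
        mask = signal.gap_mask
        values, mask2 = _trim_edges(signal.values, mask)
        filled = _fill_channel(values, mask2, max_gap_samples)
        return ScalarSignal(signal.sample_rate, filled, units=signal.units)
    if isinstance(signal, ImuSeries):
        mask = signal.gap_mask
        keep = _edge_keep_slice(mask)
        mask2 = mask[keep]
        channels = {
            name: _fill_channel(getattr(signal, name)[keep], mask2, max_gap_samples)
            for name in ImuSeries.AXES
        }
        return ImuSeries(signal.sample_rate, signal.t[keep], **channels)
    raise TypeError(f"unsupported signal type {type(signal).__name__}")


def _edge_keep_slice(mask: np.ndarray) -> slice:
    valid = np.flatnonzero(~mask)
    if valid.size == 0:
        raise SignalError("signal is entirely gaps")
    return slice(int(valid[0]), int(valid[-1]) + 1)


def _trim_edges(values: np.ndarray, mask: np.ndarray):
    keep = _edge_keep_slice(mask)
    return values[keep], mask[keep]


def design_highpass(sample_rate: float, cutoff_hz: float = 0.1, order: int = 4) -> np.ndarray:
    """Butterworth high-pass in second-order sections."""
    if sample_rate <= 2 * cutoff_hz:
        raise SignalError(
            f"sample_rate {sample_rate} Hz too low for cutoff {cutoff_hz} Hz"
        )
    return sps.butter(order, cutoff_hz, btype="highpass", fs=sample_rate, output="sos")


def remove_gravity(signal: ScalarSignal, cutoff_hz: float = 0.1, order: int = 4) -> ScalarSignal:
    """Remove the quasi-static gravity component by high-pass filtering.

    A Butterworth high-pass (default cut-off 0.1 Hz, order 4) is applied
    forward-backward, so the filter is zero-phase and exercise events are
    not shifted in time. The constant 1 g offset of a resting sensor maps
    to ~0.
    """
    if np.any(signal.gap_mask):
        raise SignalError("remove_gravity requires a gap-free signal; run fill_gaps first")
    sos = design_highpass(signal.sample_rate, cutoff_hz, order)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(signal) <= padlen:
        raise SignalError(
            f"signal of {len(signal)} samples shorter than filter warm-up ({padlen + 1} samples)"
        )
    filtered = sps.sosfiltfilt(sos, signal.values)
    return ScalarSignal(signal.sample_rate, filtered, units=signal.units)


def highpass_gain(sample_rate: float, freq_hz: float, cutoff_hz: float = 0.1, order: int = 4) -> float:
    """Magnitude response of the zero-phase high-pass at one frequency.

    Forward-backward filtering squares the single-pass magnitude.
    """
    sos = design_highpass(sample_rate, cutoff_hz, order)
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=sample_rate)
    return float(np.abs(h[0]) ** 2)
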