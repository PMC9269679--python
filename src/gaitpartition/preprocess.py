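"""Signal conditioning applied before segmentation and template matching.

Three families of filters:

* **Kolmogorov–Zurbenko (KZ)**: ``k`` iterated applications of a centered
  length-``m`` moving average — the iterated-boxcar smoother whose effective
  kernel converges to a Gaussian.  Implemented directly (it is a spec-level
  primitive here), with reflect padding so the endpoints do not droop and bias
  the first/last gait-event estimates.
* **FFT low-pass smoothing**: hard zeroing of frequency components above a
  cutoff.  Gait content in foot accelerometry lives below ~10 Hz, so the
  default cutoff for accelerometer channels is 15 Hz.
* **EMG conditioning**: 20–450 Hz fourth-order Butterworth band-pass, then
  full-wave rectification and a 10 Hz fourth-order low-pass to form the linear
  envelope.  All IIR filtering is zero-phase (forward–backward), because the
  downstream comparison is *event timing* against ground truth and phase lag
  would bias it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_model import SignalTrace, ValidationError

__all__ = [
    "FilterSpec",
    "kz_filter",
    "fft_smooth",
    "emg_bandpass",
    "emg_envelope",
    "condition_accelerometer",
]

log = logging.getLogger("gaitpartition.preprocess")


@dataclass(frozen=True)
class FilterSpec:
    """Default conditioning parameters.

    kz_window_samples/kz_iterations suit 100 Hz accelerometer channels: a
    5-sample window iterated 3 times smooths sample noise while leaving the
    ~0.4 s swing-phase transients intact.
    """

    kz_window_samples: int = 5
    kz_iterations: int = 3
    fft_cutoff_hz: float = 15.0
    emg_band_hz: tuple = (20.0, 450.0)
    emg_order: int = 4
    envelope_cutoff_hz: float = 10.0
    apply_fft: bool = True
    apply_kz: bool = True

    def __post_init__(self) -> None:
        if self.kz_window_samples < 1 or self.kz_window_samples % 2 == 0:
            raise ValidationError("kz_window_samples must be a positive odd integer")
        if self.kz_iterations < 1:
            raise ValidationError("kz_iterations must be >= 1")
        lo, hi = self.emg_band_hz
        if not (0 < lo < hi):
            raise ValidationError("emg_band_hz must satisfy 0 < low < high")


def kz_filter(x: SignalTrace, m: int = 5, k: int = 3) -> SignalTrace:
    """Kolmogorov–Zurbenko filter: k-fold centered moving average of window m.

    Edge policy: the input is reflect-padded before each pass, so the output
    has the input's length and the endpoints are not pulled toward zero.
    A constant input is returned unchanged for any (m, k).
    """
    if m < 1 or m % 2 == 0:
        raise ValidationError(f"KZ window m must be a positive odd integer, got {m}")
    if m > len(x.values):
        raise ValidationError(f"KZ window m={m} exceeds trace length {len(x.values)}")
    y = x.values
    kernel = np.full(m, 1.0 / m)
    half = m // 2
    for _ in range(k):
        if half:
            padded = np.pad(y, half, mode="reflect")
        else:
            padded = y
        y = np.convolve(padded, kernel, mode="valid")
    return x.with_values(y)


def fft_smooth(x: SignalTrace, cutoff_hz: float = 15.0) -> SignalTrace:
    """Low-pass by zeroing rFFT bins strictly above ``cutoff_hz``.

    Idempotent: a second application with the same cutoff is a no-op.
    """
    nyq = x.rate_hz / 2.0
    if not (0 < cutoff_hz < nyq):
        raise ValidationError(
            f"fft_smooth cutoff {cutoff_hz} Hz out of range (0, {nyq}) for "
            f"rate {x.rate_hz} Hz"
        )
    n = len(x.values)
    if n == 0:
        return x
    spec = np.fft.rfft(x.values)
    freqs = np.fft.rfftfreq(n, d=1.0 / x.rate_hz)
    spec[freqs > cutoff_hz] = 0.0
    return x.with_values(np.fft.irfft(spec, n=n))


def _sos_filtfilt(values: np.ndarray, sos: np.ndarray) -> np.ndarray:
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(values) <= padlen:
        raise ValidationError(
            f"trace of {len(values)} samples is shorter than the filter "
            f"warm-up length ({padlen + 1} samples)"
        )
    return sps.sosfiltfilt(sos, values)


def emg_bandpass(x: SignalTrace, spec: FilterSpec = FilterSpec()) -> SignalTrace:
    """Band-pass raw EMG (default 20–450 Hz, 4th-order Butterworth, zero-phase).

    If the sampling rate cannot hold the upper band edge (e.g. 500 Hz EMG),
    the edge is clipped to 0.45 * rate with a warning.
    """
    lo, hi = spec.emg_band_hz
    nyq = x.rate_hz / 2.0
    if hi >= nyq:
        clipped = 0.45 * x.rate_hz
        log.warning(
            "EMG band edge %.0f Hz >= Nyquist for %s (%.0f Hz rate); clipping to %.0f Hz",
            hi, x.name, x.rate_hz, clipped,
        )
        hi = clipped
    if not (0 < lo < hi < nyq):
        raise ValidationError(f"EMG band ({lo}, {hi}) Hz invalid for rate {x.rate_hz} Hz")
    sos = sps.butter(spec.emg_order, [lo, hi], btype="bandpass", fs=x.rate_hz, output="sos")
    return x.with_values(_sos_filtfilt(x.values, sos))


def emg_envelope(x: SignalTrace, spec: FilterSpec = FilterSpec()) -> SignalTrace:
    """Linear envelope of band-passed EMG: rectify, then 10 Hz low-pass.

    The envelope of a constant-amplitude sinusoidal burst settles at the
    rectified mean, 2A/pi for amplitude A.
    """
    sos = sps.butter(
        spec.emg_order, spec.envelope_cutoff_hz, btype="lowpass", fs=x.rate_hz, output="sos"
    )
    return x.with_values(_sos_filtfilt(np.abs(x.values), sos))


def condition_accelerometer(x: SignalTrace, spec: FilterSpec = FilterSpec()) -> SignalTrace:
    """Standard accelerometer conditioning: FFT smoothing, then KZ.

    Either stage can be disabled via the spec's ``apply_fft`` / ``apply_kz``
    flags.
    """
    y = x
    if spec.apply_fft and 0 < spec.fft_cutoff_hz < x.rate_hz / 2:
        y = fft_smooth(y, spec.fft_cutoff_hz)
    if spec.apply_kz and spec.kz_window_samples <= len(y.values):
        y = kz_filter(y, spec.kz_window_samples, spec.kz_iterations)
    return y
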