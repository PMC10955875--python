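"""Trace-level signal processing for electroacoustic RF data.

Covers the processing chain applied to recorded channel data before image
formation: zero-phase low-pass filtering, discrete-wavelet-transform
denoising with the universal (sqtwolog) threshold, SNR measurement,
Hilbert envelope extraction, time-of-flight picking, sound-speed
regression, and adjacent-frame averaging of frame stacks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pywt
import scipy.signal as sps

__all__ = [
    "DenoiseSpec",
    "FrameStack",
    "lowpass",
    "wavelet_denoise",
    "compute_snr",
    "snr_vs_reference",
    "envelope",
    "estimate_tof",
    "fit_sound_speed",
    "frame_average",
]


@dataclass
class DenoiseSpec:
    """Wavelet shrinkage configuration.

    The universal ("sqtwolog") threshold is ``sigma_j * sqrt(2 ln N)`` per
    detail level, with ``sigma_j`` the level's noise scale estimated from
    the median absolute deviation (MAD / 0.6745).
    """

    wavelet: str = "coif3"
    levels: int = None           # None -> maximum usable depth
    threshold_rule: str = "sqtwolog"
    mode: str = "hard"
    shifts: int = 8              # cycle-spinning translations (1 = none)

    def __post_init__(self):
        if self.threshold_rule != "sqtwolog":
            raise ValueError("only the universal 'sqtwolog' rule is supported")
        if self.mode not in ("soft", "hard"):
            raise ValueError("thresholding mode must be 'soft' or 'hard'")
        if self.levels is not None and self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.shifts < 1:
            raise ValueError("shifts must be >= 1")


@dataclass
class FrameStack:
    """Repeated acquisitions: ``frames`` is (n_frames, elements, samples)."""

    frames: np.ndarray
    frame_interval: float        # seconds
    sampling_rate: float = 40e6
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (n_frames, elements, samples)")
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self):
        return self.frames.shape[0]


def lowpass(trace, cutoff, sampling_rate, order=8):
    """Zero-phase Butterworth low-pass along the last axis."""
    if cutoff >= sampling_rate / 2:
        raise ValueError("cutoff must be below Nyquist")
    trace = np.asarray(trace, dtype=float)
    sos = sps.butter(order, cutoff, btype="low", fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, trace, axis=-1)


def wavelet_denoise(trace, spec=None):
    """Denoise a trace by thresholding its DWT detail coefficients.

    Per level the universal threshold is ``sigma_j sqrt(2 ln N)`` with
    ``sigma_j`` from the level's MAD, so a noise-free trace passes through
    essentially unchanged.  The default hard thresholding is averaged over
    ``spec.shifts`` circular translations (cycle spinning), which removes
    the pseudo-Gibbs ringing of a single decimated transform.  Works on
    1-D traces or (elements, samples) arrays (each row independently).
    """
    if spec is None:
        spec = DenoiseSpec()
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    if trace.ndim == 2:
        return np.stack([wavelet_denoise(row, spec) for row in trace])
    n = trace.shape[-1]
    max_lev = pywt.dwt_max_level(n, pywt.Wavelet(spec.wavelet).dec_len)
    levels = min(spec.levels, max_lev) if spec.levels else max_lev
    if levels < 1:
        raise ValueError("trace too short for one decomposition level")
    acc = np.zeros(n)
    for sh in range(spec.shifts):
        shifted = np.roll(trace, sh)
        coeffs = pywt.wavedec(shifted, spec.wavelet, level=levels)
        out = [coeffs[0]]
        for detail in coeffs[1:]:
            sigma = np.median(np.abs(detail)) / 0.6745
            thr = sigma * np.sqrt(2 * np.log(n))
            out.append(pywt.threshold(detail, thr, mode=spec.mode)
                       if thr > 0 else detail)
        acc += np.roll(pywt.waverec(out, spec.wavelet)[:n], -sh)
    return acc / spec.shifts


def compute_snr(trace, signal_window, noise_window):
    """SNR in dB: ``20 log10(peak |signal window| / std(noise window))``.

    Windows are ``(start, stop)`` sample index pairs and must be disjoint
    and non-empty.
    """
    trace = np.asarray(trace, dtype=float)
    s0, s1 = signal_window
    n0, n1 = noise_window
    if s1 <= s0 or n1 <= n0:
        raise ValueError("windows must be non-empty")
    if not (s1 <= n0 or n1 <= s0):
        raise ValueError("signal and noise windows must be disjoint")
    peak = np.abs(trace[..., s0:s1]).max()
    noise_std = np.std(trace[..., n0:n1])
    if noise_std == 0:
        raise ValueError("noise window has zero standard deviation")
    return 20 * np.log10(peak / noise_std)


def snr_vs_reference(clean, estimate):
    """SNR of an estimate against a known clean reference, dB.

    ``20 log10(peak |clean| / std(estimate - clean))``, the same
    peak-over-noise-std convention as :func:`compute_snr`.
    """
    clean = np.asarray(clean, dtype=float)
    err = np.asarray(estimate, dtype=float) - clean
    resid = np.std(err)
    if resid == 0:
        return np.inf
    return 20 * np.log10(np.abs(clean).max() / resid)


def envelope(trace):
    """Magnitude of the analytic signal (Hilbert envelope), last axis."""
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    return np.abs(sps.hilbert(trace, axis=-1))


def estimate_tof(trace, sampling_rate, t0=0.0, method="peak",
                 threshold=None, detection_level=0.0):
    """Arrival-time pick from a single trace, in absolute seconds.

    ``method="peak"`` (default) returns the time of the envelope maximum;
    ``method="threshold"`` returns the first crossing of
    ``threshold * max(envelope)``.  Returns None ("no arrival") when the
    trace never exceeds ``detection_level``.
    """
    trace = np.asarray(trace, dtype=float)
    if np.abs(trace).max() <= detection_level:
        return None
    env = envelope(trace)
    if method == "peak":
        idx = int(np.argmax(env))
    elif method == "threshold":
        thr = (threshold if threshold is not None else 0.5) * env.max()
        above = np.nonzero(env >= thr)[0]
        idx = int(above[0])
    else:
        raise ValueError("method must be 'peak' or 'threshold'")
    return t0 + idx / sampling_rate


def fit_sound_speed(distances, tofs):
    """Ordinary least squares of distance on time of flight.

    Returns ``(speed, intercept)`` where ``speed`` is the slope in m/s and
    ``intercept`` the time-axis offset in seconds (distance = speed *
    (tof - intercept)).
    """
    d = np.asarray(distances, dtype=float)
    t = np.asarray(tofs, dtype=float)
    if d.size < 2 or d.size != t.size:
        raise ValueError("need >= 2 paired (distance, tof) points")
    if np.ptp(t) == 0:
        raise ValueError("degenerate fit: all TOFs equal")
    slope, offset = np.polyfit(t, d, 1)
    return float(slope), float(-offset / slope)


def frame_average(stack, k):
    """Average non-overlapping blocks of ``k`` adjacent frames.

    A trailing remainder (when ``n_frames`` is not divisible by ``k``) is
    truncated with a warning.  The output frame interval is ``k`` times
    the input interval.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    k = int(k)
    n = stack.n_frames
    n_out = n // k
    if n_out == 0:
        raise ValueError(f"fewer than k={k} frames to average")
    if n % k:
        warnings.warn(f"truncating {n % k} trailing frame(s) "
                      f"not filling a block of {k}")
    blocks = stack.frames[: n_out * k].reshape(n_out, k, *stack.frames.shape[1:])
    return FrameStack(frames=blocks.mean(axis=1),
                      frame_interval=stack.frame_interval * k,
                      sampling_rate=stack.sampling_rate,
                      meta={**stack.meta, "averaged_k": k})
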