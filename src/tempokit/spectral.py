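"""PSDs, coherence, wavelet spectrograms, band envelopes and
event-triggered averaging.

Coherence magnitude is magnitude-squared coherence (Welch averaged);
phase comes from the cross-spectral density on the same segmentation.
The wavelet transform uses an analytic Morlet calibrated so a unit
sinusoid at an on-grid frequency yields unit ridge magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from tempokit.preprocess import bandpass

__all__ = [
    "CoherenceResult",
    "Spectrogram",
    "coherence",
    "wavelet_spectrogram",
    "band_envelope",
    "event_triggered_average",
    "event_related_spectrogram",
]


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    magnitude: np.ndarray  # magnitude-squared coherence in [0, 1]
    phase: np.ndarray      # cross-spectral phase, radians in (-pi, pi]
    n_segments: int
    window_len: float
    overlap: float

    @property
    def magnitude_sqrt(self) -> np.ndarray:
        """Square-root (non-squared) coherence view."""
        return np.sqrt(self.magnitude)


@dataclass
class Spectrogram:
    times: np.ndarray
    freqs: np.ndarray
    values: np.ndarray  # (freq, time) magnitude or power, non-negative
    kind: str = "wavelet"
    coi: np.ndarray | None = None  # boolean validity mask, same shape
    meta: dict = field(default_factory=dict)


def coherence(x, y, fs, window_len=1.0, overlap=0.8) -> CoherenceResult:
    """Welch magnitude-squared coherence and cross-spectral phase.

    ``window_len`` and ``overlap`` are in seconds (defaults: 1-s segments
    overlapping by 0.8 s).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("x and y must share a length")
    nperseg = int(round(window_len * fs))
    noverlap = int(round(overlap * fs))
    if noverlap >= nperseg:
        raise ValueError("overlap must be shorter than the window")
    hop = nperseg - noverlap
    n_seg = 1 + max(0, (len(x) - nperseg)) // hop
    if len(x) < nperseg or n_seg < 5:
        raise ValueError(f"need >= 5 segments, got {n_seg}")
    freqs, mag = signal.coherence(x, y, fs=fs, nperseg=nperseg, noverlap=noverlap)
    _, pxy = signal.csd(x, y, fs=fs, nperseg=nperseg, noverlap=noverlap)
    return CoherenceResult(
        freqs=freqs, magnitude=np.clip(mag, 0.0, 1.0), phase=np.angle(pxy),
        n_segments=n_seg, window_len=window_len, overlap=overlap,
    )


def _morlet_kernel(f, fs, n_cycles):
    """Analytic Morlet kernel normalized so a unit-amplitude real tone at
    frequency f produces unit response magnitude."""
    sigma_t = n_cycles / (2 * np.pi * f)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    kern = gauss * np.exp(2j * np.pi * f * t)
    # response to exp(i 2 pi f t) is sum(gauss); a real tone carries half
    # its amplitude at +f, so scale by 2 / sum(gauss)
    return kern * (2.0 / gauss.sum()), half


def wavelet_spectrogram(trace, fs, freq_range=(1.0, 120.0),
                        voices_per_octave=10, n_cycles=7.0) -> Spectrogram:
    """Analytic-Morlet transform magnitude on a log-spaced frequency grid.

    The cone-of-influence mask marks samples farther than 2 temporal
    sigmas of the wavelet from either edge.
    """
    x = np.asarray(trace, dtype=np.float64)
    lo, hi = freq_range
    if not (0 < lo < hi < fs / 2):
        raise ValueError("freq_range outside (0, Nyquist)")
    n_oct = np.log2(hi / lo)
    n_freqs = max(2, int(np.ceil(n_oct * voices_per_octave)) + 1)
    freqs = lo * 2 ** (np.linspace(0, n_oct, n_freqs))
    vals = np.empty((n_freqs, len(x)))
    coi = np.zeros((n_freqs, len(x)), dtype=bool)
    for i, f in enumerate(freqs):
        kern, half = _morlet_kernel(f, fs, n_cycles)
        resp = signal.fftconvolve(x, kern, mode="same")
        vals[i] = np.abs(resp)
        edge = min(half // 2, len(x))
        coi[i, edge:len(x) - edge if edge else len(x)] = True
    times = np.arange(len(x)) / fs
    return Spectrogram(times=times, freqs=freqs, values=vals, kind="wavelet",
                       coi=coi, meta={"n_cycles": n_cycles})


def band_envelope(trace, fs, band, method="wavelet", **kw):
    """Amplitude envelope of a band.

    "wavelet": mean wavelet-spectrogram magnitude across rows in the band.
    "hilbert": magnitude of the analytic signal of the band-passed trace.
    """
    lo, hi = band
    if method == "hilbert":
        xb = bandpass(trace, fs, lo, hi, order=kw.pop("order", 3))
        return np.abs(signal.hilbert(xb))
    if method == "wavelet":
        spec = wavelet_spectrogram(trace, fs, freq_range=band, **kw)
        return spec.values.mean(axis=0)
    raise ValueError(f"unknown envelope method {method!r}")


def event_triggered_average(trace, fs, event_times, window=(-0.5, 0.5),
                            ci="bootstrap", n_boot=1000, seed=0):
    """Stack per-event windows of ``trace`` and average.

    Returns a dict with keys ``t`` (window time axis), ``mean``, ``lo``,
    ``hi`` (95% band), ``n_used`` and ``n_dropped`` (edge-clipped events).
    """
    x = np.asarray(trace, dtype=np.float64)
    i0 = int(np.floor(window[0] * fs))
    i1 = int(np.ceil(window[1] * fs))
    rows, dropped = [], 0
    for et in np.atleast_1d(event_times):
        c = int(round(et * fs))
        if c + i0 < 0 or c + i1 >= len(x):
            dropped += 1
            continue
        rows.append(x[c + i0: c + i1 + 1])
    if not rows:
        raise ValueError("no usable events inside the recording")
    stack = np.stack(rows)
    mean = stack.mean(axis=0)
    n = len(rows)
    if n == 1:
        lo = hi = mean.copy()
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = stack[idx].mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    else:  # normal approximation
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
        lo, hi = mean - 1.96 * sem, mean + 1.96 * sem
    t = np.arange(i0, i1 + 1) / fs
    return {"t": t, "mean": mean, "lo": lo, "hi": hi,
            "n_used": n, "n_dropped": dropped}


def event_related_spectrogram(trace, fs, event_times, window=(-0.5, 1.0),
                              freq_range=(1.0, 120.0), **kw) -> Spectrogram:
    """Wavelet spectrogram of the full trace averaged over event windows."""
    spec = wavelet_spectrogram(trace, fs, freq_range=freq_range, **kw)
    i0 = int(np.floor(window[0] * fs))
    i1 = int(np.ceil(window[1] * fs))
    rows, used = [], 0
    for et in np.atleast_1d(event_times):
        c = int(round(et * fs))
        if c + i0 < 0 or c + i1 >= spec.values.shape[1]:
            continue
        rows.append(spec.values[:, c + i0: c + i1 + 1])
        used += 1
    if not rows:
        raise ValueError("no usable events inside the recording")
    mean = np.mean(rows, axis=0)
    t = np.arange(i0, i1 + 1) / fs
    return Spectrogram(times=t, freqs=spec.freqs, values=mean,
                       kind="wavelet", meta={"n_events": used})
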