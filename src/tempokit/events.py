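"""Discrete-event detection: sharp-wave ripples (normalized-squared-signal
method), ictal spikes, locomotor-state segmentation, and movie-level wave
event windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from tempokit.preprocess import bandpass, highpass

__all__ = [
    "PeakCriteria",
    "RippleEvent",
    "find_peaks",
    "nss",
    "detect_ripples",
    "detect_ictal_spikes",
    "segment_locomotor_state",
    "detect_wave_events",
]


@dataclass(frozen=True)
class PeakCriteria:
    """Peak filtering thresholds; distances/widths are in seconds."""

    min_prominence: float = 0.1
    min_distance: float = 0.010
    min_width: float = 0.010
    max_width: float = 0.200

    def __post_init__(self):
        if not self.min_width < self.max_width:
            raise ValueError("min_width must be < max_width")


@dataclass
class RippleEvent:
    peak_time: float      # s
    window: tuple         # 300-ms (start, end) interval, s
    prominence: float     # normalized units (NSS is rescaled to [0, 1])
    width: float          # s, at half prominence
    clipped: bool = False # window extends past a recording edge


def find_peaks(sig, fs, criteria: PeakCriteria):
    """Local maxima filtered by prominence, minimum separation (greedy,
    larger peak kept) and half-prominence width within [min, max].

    Returns a dict of arrays: ``indices``, ``times``, ``heights``,
    ``prominences``, ``widths`` (seconds).
    """
    sig = np.asarray(sig, dtype=np.float64)
    if not np.all(np.isfinite(sig)):
        raise ValueError("signal must be finite")
    idx, props = signal.find_peaks(
        sig,
        prominence=criteria.min_prominence,
        distance=max(1, int(round(criteria.min_distance * fs))),
        width=(criteria.min_width * fs, criteria.max_width * fs),
        rel_height=0.5,
    )
    return {
        "indices": idx,
        "times": idx / fs,
        "heights": sig[idx],
        "prominences": props["prominences"],
        "widths": props["widths"] / fs,
    }


def nss(lfp, fs, band=(120.0, 200.0), smooth_window=0.020):
    """Normalized squared signal: band-pass (3rd-order, zero phase),
    square, 20-ms moving maximum, 20-ms moving average, min-max rescale
    to [0, 1] over the whole recording."""
    xb = bandpass(lfp, fs, band[0], band[1], order=3)
    sq = xb ** 2
    w = max(1, int(round(smooth_window * fs)))
    mx = ndimage.maximum_filter1d(sq, size=w, mode="nearest")
    sm = ndimage.uniform_filter1d(mx, size=w, mode="nearest")
    lo, hi = float(sm.min()), float(sm.max())
    if hi == lo:
        return np.zeros_like(sm)
    return (sm - lo) / (hi - lo)


def detect_ripples(lfp, fs, band=(120.0, 200.0),
                   criteria: PeakCriteria | None = None,
                   window_s: float = 0.300):
    """Detect sharp-wave ripples on an NSS trace.

    Returns (events, nss_trace).  Events whose 300-ms window extends past
    a recording edge are kept but flagged ``clipped``.
    """
    lfp = np.asarray(lfp, dtype=np.float64)
    if fs < 500:
        raise ValueError("ripple detection requires fs >= 500 Hz")
    if len(lfp) < fs:
        raise ValueError("recording shorter than 1 s")
    criteria = criteria or PeakCriteria()
    trace = nss(lfp, fs, band=band)
    pk = find_peaks(trace, fs, criteria)
    half = window_s / 2.0
    events = []
    t_end = len(lfp) / fs
    for t, prom, wid in zip(pk["times"], pk["prominences"], pk["widths"]):
        clipped = (t - half < 0) or (t + half > t_end)
        events.append(RippleEvent(
            peak_time=float(t),
            window=(float(t - half), float(t + half)),
            prominence=float(prom), width=float(wid), clipped=clipped,
        ))
    return events, trace


def detect_ictal_spikes(lfp, fs, units=None):
    """Detect ictal (epileptiform) spikes.

    ``units`` must be "V" or "uV".  The trace is zero-phase high-passed at
    25 Hz (6th-order Butterworth) and peaks kept with width in [2, 20] ms
    and prominence >= 1000 uV.  Returns spike times in seconds.
    """
    if units not in ("V", "uV"):
        raise ValueError('units must be declared as "V" or "uV"')
    x = np.asarray(lfp, dtype=np.float64)
    if units == "V":
        x = x * 1e6
    xf = highpass(x, fs, 25.0, order=6)
    pk = find_peaks(xf, fs, PeakCriteria(
        min_prominence=1000.0, min_distance=1.0 / fs,
        min_width=0.002, max_width=0.020,
    ))
    return pk["times"]


def segment_locomotor_state(lfp, fs, theta_band=(5.0, 9.0), threshold=0.5,
                            mode="quantile", smooth_s=1.0, min_bout_s=0.5):
    """Binary run/rest mask from theta-band power (locomotor proxy).

    The theta envelope is smoothed over ``smooth_s``; the mask is
    ``envelope > threshold`` with the threshold taken as an absolute value
    (``mode="absolute"``) or an envelope quantile (``mode="quantile"``).
    Bouts shorter than ``min_bout_s`` are merged into their surroundings.
    """
    x = np.asarray(lfp, dtype=np.float64)
    if len(x) < 30 * fs:
        raise ValueError("recording must be >= 30 s")
    xb = bandpass(x, fs, theta_band[0], theta_band[1], order=3)
    env = np.abs(signal.hilbert(xb))
    env = ndimage.uniform_filter1d(env, size=max(1, int(round(smooth_s * fs))))
    thr = float(np.quantile(env, threshold)) if mode == "quantile" else float(threshold)
    mask = env > thr
    min_n = int(round(min_bout_s * fs))
    if min_n > 1:
        mask = _merge_short_bouts(mask, min_n)
    return mask


def _merge_short_bouts(mask, min_n):
    out = mask.copy()
    edges = np.flatnonzero(np.diff(out.astype(int))) + 1
    bounds = np.concatenate([[0], edges, [len(out)]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < min_n:
            out[a:b] = ~out[a] if a > 0 else out[b] if b < len(out) else out[a]
    return out


def detect_wave_events(movie, k_sd=3.0, pad=0, fs=None):
    """Wave-event windows from a voltage movie: intervals where the
    field-of-view-mean trace exceeds mean + k_sd * s.d. of the whole
    trace.

    Each supra-threshold run is padded by ``pad`` samples on both sides;
    overlapping padded windows are merged.  Returns (start, end) pairs in
    samples, or in seconds when ``fs`` is given.
    """
    movie = np.asarray(movie)
    trace = movie.mean(axis=(1, 2)).astype(np.float64)
    thr = trace.mean() + k_sd * trace.std()
    above = trace > thr
    runs = []
    in_run = False
    for i, flag in enumerate(above):
        if flag and not in_run:
            a = i
            in_run = True
        elif not flag and in_run:
            runs.append((a, i))
            in_run = False
    if in_run:
        runs.append((a, len(above)))
    if pad > 0 and runs:
        padded = [(max(0, a - pad), min(len(trace), b + pad)) for a, b in runs]
        merged = [padded[0]]
        for a, b in padded[1:]:
            if a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        runs = merged
    if fs is None:
        return runs
    return [(a / fs, b / fs) for a, b in runs]
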