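"""Phase-amplitude cross-frequency coupling.

Phase convention: 0 degrees is the trough of the carrier oscillation
(greatest hyperpolarization for depolarization-positive traces), so the
carrier peak sits at 180 degrees.  Profiles are averaged over single
carrier cycles (delimited by phase resets) and tiled over two cycles
[0, 720) for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from tempokit.preprocess import bandpass
from tempokit.spectral import band_envelope

__all__ = ["CFCProfile", "carrier_phase", "cfc_profile", "amplitude_peak_offsets"]


@dataclass
class CFCProfile:
    phase_bins: np.ndarray  # bin centers, degrees over [0, 720)
    amplitude: np.ndarray   # mean high-band envelope per bin
    carrier_band: tuple
    amp_band: tuple
    n_cycles: int
    preferred_phase: float  # degrees in [0, 360)
    phase_convention: str = "0 deg = carrier trough"


def carrier_phase(trace, fs, band, power_floor=1e-12):
    """Instantaneous carrier phase in degrees, trough-referenced.

    The trace is zero-phase band-passed, the Hilbert analytic phase taken,
    and shifted so a trough maps to 0 degrees (a pure ``-cos`` has phase 0
    at t=0).  Output wraps in [0, 360).
    """
    xb = bandpass(trace, fs, band[0], band[1], order=3)
    if float(np.var(xb)) < power_floor:
        raise ValueError("carrier band power below floor")
    ana = signal.hilbert(xb)
    # analytic angle of -cos at its trough is pi; shift so trough -> 0
    return (np.degrees(np.angle(ana)) - 180.0) % 360.0


def cfc_profile(trace, fs, carrier_band, amp_band, n_bins=36,
                envelope_method="wavelet", phase_source=None) -> CFCProfile:
    """Phase-conditioned amplitude profile over two carrier cycles.

    The high-band envelope is binned against the carrier phase within
    every complete cycle (cycles delimited at phase resets, i.e. the
    360 -> 0 wrap of the trough-referenced phase), averaged per bin over
    cycles, and tiled to 720 degrees.  ``phase_source`` optionally
    provides a different trace (e.g. an LFP) for phase extraction.
    """
    x = np.asarray(trace, dtype=np.float64)
    ph = carrier_phase(phase_source if phase_source is not None else x,
                       fs, carrier_band)
    env = band_envelope(x, fs, amp_band, method=envelope_method)

    resets = np.flatnonzero(np.diff(ph) < -180.0) + 1
    if len(resets) < 2:
        raise ValueError("too few carrier cycles")
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    n_cycles = 0
    for a, b in zip(resets[:-1], resets[1:]):
        bins = np.minimum((ph[a:b] / 360.0 * n_bins).astype(int), n_bins - 1)
        np.add.at(sums, bins, env[a:b])
        np.add.at(counts, bins, 1)
        n_cycles += 1
    if n_cycles < 20:
        raise ValueError(f"need >= 20 carrier cycles, got {n_cycles}")
    amp = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    centers = (np.arange(n_bins) + 0.5) * 360.0 / n_bins
    preferred = float(centers[np.argmax(amp)])
    return CFCProfile(
        phase_bins=np.concatenate([centers, centers + 360.0]),
        amplitude=np.concatenate([amp, amp]),
        carrier_band=tuple(carrier_band), amp_band=tuple(amp_band),
        n_cycles=n_cycles, preferred_phase=preferred,
    )


def amplitude_peak_offsets(trace, fs, carrier_band, amp_band, events,
                           envelope_method="hilbert"):
    """Per-event timing of the high-band envelope peak relative to the
    carrier depolarization peak.

    ``events`` is a sequence of (start_s, end_s) windows.  Offsets are
    envelope-peak time minus carrier-peak time (negative: envelope leads).
    Returns a dict with ``offsets_ms``, ``mean_ms``, ``sem_ms``,
    ``p_value`` (two-sided Wilcoxon signed-rank vs 0; None for a single
    event) and ``n_dropped``.
    """
    x = np.asarray(trace, dtype=np.float64)
    carrier = bandpass(x, fs, carrier_band[0], carrier_band[1], order=3)
    env = band_envelope(x, fs, amp_band, method=envelope_method)
    offsets = []
    dropped = 0
    for t0, t1 in events:
        a, b = int(round(t0 * fs)), int(round(t1 * fs))
        a, b = max(a, 0), min(b, len(x))
        if b - a < 3 or np.ptp(carrier[a:b]) == 0:
            dropped += 1
            continue
        t_car = (a + int(np.argmax(carrier[a:b]))) / fs
        t_env = (a + int(np.argmax(env[a:b]))) / fs
        offsets.append((t_env - t_car) * 1000.0)
    if len(offsets) == 0:
        raise ValueError("no usable events")
    offsets = np.asarray(offsets)
    n = len(offsets)
    out = {
        "offsets_ms": offsets,
        "mean_ms": float(np.mean(offsets)),
        "sem_ms": float(np.std(offsets, ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "p_value": None,
        "n_dropped": dropped,
    }
    if n > 1:
        if np.all(offsets == 0):
            out["p_value"] = 1.0
        else:
            out["p_value"] = float(stats.wilcoxon(offsets).pvalue)
    return out
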