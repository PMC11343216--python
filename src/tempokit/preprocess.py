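"""Notch/band filtering, photobleach detrending (dF/F) and decrosstalking.

All recursive filters are applied forward-backward through second-order
sections (zero phase); quoted orders refer to the single-pass design, so a
"3rd-order" bandpass is ``butter(3, ...)`` applied twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

__all__ = [
    "BaselineFit",
    "notch_filter",
    "bandpass",
    "highpass",
    "estimate_baseline",
    "detrend",
    "decrosstalk_fiber",
    "decrosstalk_movie",
]

# movie decrosstalk defaults per indicator (fraction of green bleeding red)
CROSSTALK_DEFAULTS = {"asap3": 0.07, "ace-mneon1": 0.095}


def _impulse_len(sos, decay=1e-9):
    """Samples until the slowest pole decays below ``decay``."""
    poles = np.concatenate([np.roots(sec[3:]) for sec in sos])
    r = float(np.max(np.abs(poles))) if len(poles) else 0.0
    if r <= 0 or r >= 1:
        return 200
    return int(np.log(decay) / np.log(r)) + 1


def _sosfiltfilt(sos, x):
    x = np.asarray(x, dtype=np.float64)
    # reflection padding sized from the impulse-response decay (sosfiltfilt's
    # default padlen is far too short for narrow-band / low-frequency filters)
    padlen = min(len(x) - 1, 3 * _impulse_len(sos))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def notch_filter(trace, fs, center, halfwidth=1.0, order=8):
    """Zero-phase band-stop around ``center +/- halfwidth`` Hz.

    ``order`` is the overall single-pass stop-band order (default 8, i.e.
    a 4th-order low/high prototype pair).
    """
    lo, hi = center - halfwidth, center + halfwidth
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"stop band ({lo}, {hi}) outside (0, Nyquist)")
    sos = signal.butter(order // 2, [lo, hi], btype="bandstop", fs=fs, output="sos")
    return _sosfiltfilt(sos, trace)


def bandpass(trace, fs, lo, hi, order=3, zero_phase=True):
    """Butterworth band-pass; zero-phase (forward-backward) when flagged."""
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist)")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        return _sosfiltfilt(sos, trace)
    return signal.sosfilt(sos, np.asarray(trace, dtype=np.float64))


def highpass(trace, fs, cutoff, order=6, zero_phase=True):
    if not 0 < cutoff < fs / 2:
        raise ValueError("cutoff outside (0, Nyquist)")
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    if zero_phase:
        return _sosfiltfilt(sos, trace)
    return signal.sosfilt(sos, np.asarray(trace, dtype=np.float64))


@dataclass
class BaselineFit:
    """Time-varying baseline F0(t) with the method that produced it.

    For exponential methods ``params`` holds fitted amplitudes ``a`` (one
    per component plus offset ``c``) and time constants ``tau`` in
    seconds; ``half_life`` is the time at which the fitted decay reaches
    half of its initial value (``inf`` when it never does).
    """

    method: str
    baseline: np.ndarray
    params: dict = field(default_factory=dict)
    half_life: float = float("inf")


class FitConvergenceError(RuntimeError):
    def __init__(self, msg, best_residual=None):
        super().__init__(msg)
        self.best_residual = best_residual


def _exp_model(t, a, tau, c):
    return np.sum(a[:, None] * np.exp(-t[None, :] / tau[:, None]), axis=0) + c


def _fit_multiexp(t, y, n_exp, n_starts=6, seed=0):
    rng = np.random.default_rng(seed)
    span = max(t[-1] - t[0], 1e-9)
    amp0 = max(y[0] - y[-1], 1e-12)
    best = None
    # log-spaced time-constant initializations across the record span
    for s in range(n_starts):
        taus0 = np.logspace(
            np.log10(span / 200), np.log10(span * 2), n_exp
        ) * np.exp(rng.uniform(-0.3, 0.3, n_exp) if s else np.zeros(n_exp))
        p0 = np.concatenate([np.full(n_exp, amp0 / n_exp), taus0, [y[-1]]])
        lb = np.concatenate([np.zeros(n_exp), np.full(n_exp, 1e-6), [-np.inf]])
        ub = np.full(2 * n_exp + 1, np.inf)

        def model(tt, *p):
            return _exp_model(tt, np.array(p[:n_exp]), np.array(p[n_exp:2 * n_exp]), p[-1])

        try:
            popt, _ = optimize.curve_fit(
                model, t, y, p0=p0, bounds=(lb, ub), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        resid = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise FitConvergenceError(f"{n_exp}-exponential fit did not converge")
    popt, resid = best
    a = np.array(popt[:n_exp])
    tau = np.array(popt[n_exp:2 * n_exp])
    order = np.argsort(tau)
    return a[order], tau[order], float(popt[-1]), resid


def _half_life(a, tau, c, t_max):
    f0 = float(np.sum(a) + c)
    target = f0 / 2.0

    def g(t):
        return float(np.sum(a * np.exp(-t / tau)) + c - target)

    hi = t_max
    if g(hi) > 0:  # decay never reaches half within a generous horizon
        return float("inf")
    return float(optimize.brentq(g, 0.0, hi))


def estimate_baseline(trace, fs, method="lowpass", cutoff=0.5, seed=0):
    """Estimate the baseline fluorescence F0(t).

    method "lowpass": zero-phase 4th-order Butterworth low-pass at
    ``cutoff`` Hz.  Methods "exp1"/"exp2"/"exp3": nonlinear least-squares
    fit of ``sum_i a_i exp(-t/tau_i) + c`` with positive time constants,
    multi-start initialized.
    """
    y = np.asarray(trace, dtype=np.float64)
    t = np.arange(len(y)) / fs
    if method == "lowpass":
        if len(y) < 10 * fs / cutoff:
            raise ValueError("trace too short for low-pass baseline estimation")
        sos = signal.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
        return BaselineFit(method="lowpass", baseline=_sosfiltfilt(sos, y))
    if method in ("exp1", "exp2", "exp3"):
        if np.any(y <= 0):
            raise ValueError("exponential baseline fits require a positive trace")
        n_exp = int(method[3])
        if np.ptp(y) < 1e-12 * abs(y[0]):  # constant trace: degenerate fit
            return BaselineFit(
                method=method, baseline=np.full_like(y, y.mean()),
                params={"a": np.zeros(n_exp), "tau": np.full(n_exp, np.inf),
                        "c": float(y.mean())},
                half_life=float("inf"),
            )
        a, tau, c, resid = _fit_multiexp(t, y, n_exp, seed=seed)
        hl = _half_life(a, tau, c, t_max=1e4 * max(tau.max(), t[-1]))
        return BaselineFit(
            method=method, baseline=_exp_model(t, a, tau, c),
            params={"a": a, "tau": tau, "c": c, "residual": resid},
            half_life=hl,
        )
    raise ValueError(f"unknown baseline method {method!r}")


def detrend(trace, baseline: BaselineFit, highpass_hz: float | None = None,
            fs: float | None = None):
    """dF/F normalization: trace / F0(t), optional zero-phase FIR high-pass.

    ``highpass_hz`` of 0.5 (anesthetized) or 1.5 (awake) are the usual
    choices; requires ``fs`` when set.
    """
    y = np.asarray(trace, dtype=np.float64)
    f0 = np.asarray(baseline.baseline, dtype=np.float64)
    if len(f0) != len(y):
        raise ValueError("baseline length does not match trace")
    if np.any(f0 <= 0):
        raise ValueError("baseline must be strictly positive for dF/F")
    out = y / f0
    if highpass_hz is not None:
        if fs is None:
            raise ValueError("fs required for the post-detrend high-pass")
        numtaps = int(4 * fs / highpass_hz) | 1  # odd, ~4 cycles long
        numtaps = min(numtaps, (len(out) - 1) // 3 * 2 + 1)
        taps = signal.firwin(numtaps, highpass_hz, pass_zero=False, fs=fs)
        out = signal.filtfilt(taps, [1.0], out, padlen=min(len(out) - 1, 3 * numtaps))
    return out


def decrosstalk_fiber(reference_trace, donor_gevi_trace, fs, band=(3.0, 7.0)):
    """Remove GEVI bleed-through from a fiber reference trace.

    The two traces are band-passed (3rd-order zero-phase Butterworth over
    ``band``), the OLS slope of reference on donor is taken as the
    crosstalk coefficient, and ``coefficient * donor`` is subtracted from
    the *unfiltered* reference.

    Returns (corrected_reference, coefficient).
    """
    r = np.asarray(reference_trace, dtype=np.float64)
    d = np.asarray(donor_gevi_trace, dtype=np.float64)
    if len(r) != len(d):
        raise ValueError("traces must share a length")
    rb = bandpass(r, fs, *band, order=3)
    db = bandpass(d, fs, *band, order=3)
    denom = float(np.dot(db, db))
    if denom < 1e-30 * len(db):
        raise ValueError("band-passed donor trace has (near) zero variance")
    coeff = float(np.dot(db, rb) / denom)
    return r - coeff * d, coeff


def decrosstalk_movie(red_movie, green_movie, coefficient):
    """Frame-wise ``red - coefficient * green`` bleed-through correction.

    ``coefficient`` may be a float or an indicator name with a calibrated
    default ("asap3" -> 0.07, "ace-mneon1" -> 0.095).
    """
    if isinstance(coefficient, str):
        coefficient = CROSSTALK_DEFAULTS[coefficient.lower()]
    if not 0 <= coefficient < 1:
        raise ValueError("coefficient must be in [0, 1)")
    red = np.asarray(red_movie)
    green = np.asarray(green_movie)
    if red.shape != green.shape:
        raise ValueError("movie shapes differ")
    return (red.astype(np.float64) - coefficient * green.astype(np.float64)).astype(
        red.dtype if red.dtype.kind == "f" else np.float32
    )
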