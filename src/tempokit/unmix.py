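"""Frequency-dependent convolutional (Wiener) unmixing of reference-channel
artifacts from voltage-indicator traces and movies.

The filter is estimated as a per-frequency complex regression between
windowed, overlapping segments of the two channels:

    f(w) = <g_k conj(r_k)>_k / <r_k conj(r_k)>_k

with the amplitude clipped at ``alpha * |f(w0)|`` relative to the
heartbeat fundamental ``w0`` (phase preserved), inverse-transformed to a
two-sided time-domain kernel centered at zero lag, and applied by linear
convolution.  A frequency-independent OLS regression is provided as the
comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from tempokit.core_io import DualChannelMovie

__all__ = [
    "WienerParams",
    "WienerFilter",
    "UnmixResult",
    "HeartbeatError",
    "estimate_heartbeat",
    "estimate_wiener_filter",
    "unmix_trace",
    "scalar_regression_unmix",
    "unmix_movie",
    "select_params",
]


class HeartbeatError(RuntimeError):
    """No unambiguous spectral peak in the heartbeat search band; pass a
    manual ``omega0`` via WienerParams."""


@dataclass(frozen=True)
class WienerParams:
    """Estimation parameters for the convolutional unmixing filter.

    segment_len : segment duration tau in seconds (typical 0.5-2).
    overlap : fractional overlap of successive segments in [0, 1).
    window : taper name understood by scipy.signal.get_window.
    alpha : relative spectral amplitude limit (>= 0; typical 1.0-1.3).
    heartbeat_band : Hz band searched for the heartbeat fundamental w0.
    omega0 : optional manual override of the heartbeat fundamental, Hz.
    demean : subtract each segment's mean before tapering.
    min_segments : minimum number of segments required for estimation.
    """

    segment_len: float = 1.0
    overlap: float = 0.75
    window: str = "hann"
    alpha: float = 1.1
    heartbeat_band: tuple = (8.0, 14.0)
    omega0: float | None = None
    demean: bool = True
    min_segments: int = 4

    def __post_init__(self):
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    def n_samples(self, fs: float) -> int:
        n = int(round(self.segment_len * fs))
        if n < 8:
            raise ValueError("segment_len * fs must be >= 8 samples")
        return n


@dataclass
class WienerFilter:
    """Frequency-domain transfer estimate plus its time-domain kernel.

    ``f_raw`` holds the pre-clipping coefficients, ``f`` the clipped ones;
    ``kernel`` is the real two-sided impulse response of length
    ``segment_len * fs`` with zero lag at index ``len(kernel) // 2``.
    """

    freqs: np.ndarray
    f: np.ndarray
    f_raw: np.ndarray
    omega0: float
    kernel: np.ndarray
    fs: float
    params: WienerParams
    n_segments: int
    n_zero_power_bins: int = 0

    @property
    def zero_lag_index(self) -> int:
        return len(self.kernel) // 2

    def apply(self, reference: np.ndarray) -> np.ndarray:
        """Linear (non-circular) convolution of the reference trace with
        the two-sided kernel, reflection-padded and truncated to input
        length so zero lag stays aligned."""
        r = np.asarray(reference, dtype=np.float64)
        p = self.zero_lag_index
        if p > 0:
            rp = np.pad(r, p, mode="reflect") if len(r) > 1 else np.repeat(r, 2 * p + 1)
        else:
            rp = r
        full = signal.fftconvolve(rp, self.kernel)
        return full[2 * p: 2 * p + len(r)]


@dataclass
class UnmixResult:
    """Unmixed voltage V(t) plus artifact estimate H(t), with V + H = G."""

    voltage: np.ndarray
    artifact: np.ndarray
    filter: WienerFilter | None
    diagnostics: dict = field(default_factory=dict)


def estimate_heartbeat(reference, fs, band=(8.0, 14.0), min_ratio=10.0):
    """Locate the heartbeat fundamental: the frequency of maximum Welch
    PSD of the reference trace within ``band``.

    Raises HeartbeatError when the in-band peak is less than ``min_ratio``
    times the in-band median (flat spectrum).
    """
    r = np.asarray(reference, dtype=np.float64)
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError("heartbeat band outside (0, Nyquist)")
    nperseg = int(min(len(r), round(4 * fs)))
    freqs, psd = signal.welch(r, fs=fs, nperseg=nperseg)
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 3:
        raise ValueError("heartbeat band too narrow for the spectral grid")
    pk = float(np.max(psd[mask]))
    med = float(np.median(psd[mask]))
    if med <= 0 or pk < min_ratio * med:
        raise HeartbeatError(
            f"no clear spectral peak in {band} Hz (peak/median="
            f"{pk / med if med > 0 else np.inf:.2f} < {min_ratio}); "
            "set omega0 manually"
        )
    return float(freqs[mask][np.argmax(psd[mask])])


def _segment_spectra(x, n, hop, window, demean):
    x = np.asarray(x, dtype=np.float64)
    n_seg = 1 + (len(x) - n) // hop
    idx = np.arange(n)[None, :] + hop * np.arange(n_seg)[:, None]
    segs = x[idx]
    if demean:
        segs = segs - segs.mean(axis=1, keepdims=True)
    return np.fft.rfft(segs * window[None, :], axis=1), n_seg


def estimate_wiener_filter(G, R, fs, params: WienerParams | None = None) -> WienerFilter:
    """Estimate the unmixing filter between a GEVI trace G and reference R.

    Bins where the reference carries no power get a zero coefficient
    (counted in ``n_zero_power_bins``) rather than aborting the run.
    """
    params = params or WienerParams()
    G = np.asarray(G, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    if len(G) != len(R):
        raise ValueError("G and R must share a length")
    n = params.n_samples(fs)
    if len(G) < n:
        raise ValueError("trace shorter than one segment")
    hop = max(1, int(round(n * (1 - params.overlap))))
    window = signal.get_window(params.window, n, fftbins=True)

    g, n_seg = _segment_spectra(G, n, hop, window, params.demean)
    r, _ = _segment_spectra(R, n, hop, window, params.demean)
    if n_seg < params.min_segments:
        raise ValueError(
            f"only {n_seg} segments available; need >= {params.min_segments}"
        )

    cross = np.mean(g * np.conj(r), axis=0)
    auto = np.mean(np.abs(r) ** 2, axis=0)
    floor = np.max(auto) * 1e-15 if np.max(auto) > 0 else 0.0
    dead = auto <= floor
    f_raw = np.zeros_like(cross)
    np.divide(cross, auto, out=f_raw, where=~dead)

    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    omega0 = params.omega0
    if omega0 is None:
        omega0 = estimate_heartbeat(R, fs, params.heartbeat_band)
    i0 = int(np.argmin(np.abs(freqs - omega0)))
    limit = params.alpha * np.abs(f_raw[i0])

    f_clip = f_raw.copy()
    over = np.abs(f_raw) > limit
    f_clip[over] = limit * np.exp(1j * np.angle(f_raw[over]))

    kernel = np.roll(np.fft.irfft(f_clip, n), n // 2)
    return WienerFilter(
        freqs=freqs, f=f_clip, f_raw=f_raw, omega0=omega0, kernel=kernel,
        fs=fs, params=params, n_segments=n_seg,
        n_zero_power_bins=int(np.sum(dead)),
    )


def unmix_trace(G, R, fs, params: WienerParams | None = None,
                filt: WienerFilter | None = None) -> UnmixResult:
    """Unmix a trace pair: H = F * R (linear convolution), V = G - H.

    A pre-estimated filter may be supplied via ``filt``; otherwise one is
    estimated from (G, R).  Samples within half a kernel length of either
    edge are flagged in ``diagnostics['edge_samples']``.
    """
    G = np.asarray(G, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    if filt is None:
        filt = estimate_wiener_filter(G, R, fs, params)
    H = filt.apply(R)
    V = G - H
    half = filt.zero_lag_index
    return UnmixResult(
        voltage=V, artifact=H, filter=filt,
        diagnostics={
            "residual_variance": float(np.var(V)),
            "edge_samples": min(half, len(G)),
            "n_zero_power_bins": filt.n_zero_power_bins,
        },
    )


def scalar_regression_unmix(G, R) -> UnmixResult:
    """Frequency-independent baseline: V = G - beta R with beta the OLS
    slope of G on R."""
    G = np.asarray(G, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    if len(G) != len(R):
        raise ValueError("G and R must share a length")
    rc = R - R.mean()
    denom = float(np.dot(rc, rc))
    if denom < 1e-30 * max(len(R), 1):
        raise ValueError("reference has zero variance")
    beta = float(np.dot(rc, G - G.mean()) / denom)
    H = beta * R
    V = G - H
    return UnmixResult(
        voltage=V, artifact=H, filter=None,
        diagnostics={"beta": beta, "residual_variance": float(np.var(V))},
    )


# ---------------------------------------------------------------------------
# movies


def _block_slices(size, width):
    edges = list(range(0, size, width))
    return [slice(e, min(e + width, size)) for e in edges]


def unmix_movie(movie: DualChannelMovie, params: WienerParams | None = None,
                prefilter_scale: float = 1.0, per_pixel: bool = True):
    """Two-pass unmixing of a (detrended) dual-channel movie.

    Pass 1 estimates the artifact from a spatially averaged reference over
    tiles of width ``prefilter_scale`` mm (the whole field when smaller)
    and subtracts it from every pixel of the tile.  Pass 2 (optional)
    re-unmixes each pixel's residual against its own reference trace.
    Pixels whose reference carries no variance keep the pass-1 result.

    Returns (voltage_movie, diagnostics).
    """
    params = params or WienerParams()
    T, H_, W_ = movie.shape
    G = movie.gevi.astype(np.float64)
    R = movie.reference.astype(np.float64)
    V = np.empty_like(G)
    diags = {"pass1_tiles": 0, "pass2_pixels": 0, "skipped_pixels": 0}

    r_global = R.mean(axis=(1, 2))
    if np.var(r_global) < 1e-30:
        # degenerate reference: nothing to unmix
        return movie.gevi.copy(), {**diags, "note": "zero-variance reference"}

    omega0 = params.omega0
    if omega0 is None:
        omega0 = estimate_heartbeat(r_global, movie.fs, params.heartbeat_band)
    p = replace(params, omega0=omega0)

    width = max(1, int(round(prefilter_scale / movie.pixel_pitch)))
    for rs in _block_slices(H_, width):
        for cs in _block_slices(W_, width):
            g_tile = G[:, rs, cs]
            r_avg = R[:, rs, cs].mean(axis=(1, 2))
            g_avg = g_tile.mean(axis=(1, 2))
            if np.var(r_avg) < 1e-30:
                V[:, rs, cs] = g_tile
                continue
            filt = estimate_wiener_filter(g_avg, r_avg, movie.fs, p)
            h_avg = filt.apply(r_avg)
            V[:, rs, cs] = g_tile - h_avg[:, None, None]
            diags["pass1_tiles"] += 1

    if per_pixel:
        for i in range(H_):
            for j in range(W_):
                r_px = R[:, i, j]
                if np.var(r_px) < 1e-30:
                    diags["skipped_pixels"] += 1
                    continue
                filt = estimate_wiener_filter(V[:, i, j], r_px, movie.fs, p)
                V[:, i, j] = V[:, i, j] - filt.apply(r_px)
                diags["pass2_pixels"] += 1

    return V.astype(np.float32), diags


# ---------------------------------------------------------------------------
# data-driven parameter selection


def select_params(G, R, fs, tau_grid, alpha_grid, params: WienerParams | None = None):
    """Choose (tau, alpha) by half-split validation.

    For every grid cell the filter is estimated on the first half of the
    recording and applied to the second half; the objective is the
    variance of the unmixed test trace.  Ties break toward smaller tau
    then smaller alpha.

    Returns (tau_star, alpha_star, table) where ``table`` maps
    (tau, alpha) -> objective (NaN for failed cells).
    """
    tau_grid = sorted(tau_grid)
    alpha_grid = sorted(alpha_grid)
    if not tau_grid or not alpha_grid:
        raise ValueError("parameter grids must be nonempty")
    G = np.asarray(G, dtype=np.float64)
    R = np.asarray(R, dtype=np.float64)
    if len(G) < 4 * max(tau_grid) * fs:
        raise ValueError("recording too short for the requested tau grid")
    base = params or WienerParams()
    half = len(G) // 2
    G1, R1 = G[:half], R[:half]
    G2, R2 = G[half:], R[half:]

    omega0 = base.omega0
    if omega0 is None:
        omega0 = estimate_heartbeat(R, fs, base.heartbeat_band)

    table = {}
    best = None
    for tau in tau_grid:
        for alpha in alpha_grid:
            p = replace(base, segment_len=tau, alpha=alpha, omega0=omega0)
            try:
                filt = estimate_wiener_filter(G1, R1, fs, p)
                obj = float(np.var(G2 - filt.apply(R2)))
            except (ValueError, HeartbeatError):
                table[(tau, alpha)] = float("nan")
                continue
            table[(tau, alpha)] = obj
            if best is None or obj < best[0]:
                best = (obj, tau, alpha)
    if best is None:
        raise RuntimeError("every (tau, alpha) cell failed")
    return best[1], best[2], table
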