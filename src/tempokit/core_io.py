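"""Data model, file I/O, stream alignment and spatial binning.

Fluorescence payloads are promoted to float32 on ingestion; computations
downstream may promote to float64 internally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "DualChannelTrace",
    "DualChannelMovie",
    "ElectricalTrace",
    "AlignmentError",
    "align_streams",
    "spatial_bin",
    "read_trace",
    "write_trace",
    "read_movie",
    "write_movie",
    "read_electrical",
    "write_electrical",
    "read_movie_tiff",
]

DTYPE = np.float32


class AlignmentError(RuntimeError):
    """Raised when the sync cross-correlation peak is too weak to trust."""


def _as_float32(x) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(x), dtype=DTYPE)


@dataclass
class DualChannelTrace:
    """Paired indicator/reference time series on a uniform time grid.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, uniformly spaced.
    gevi : array of float
        Voltage-indicator fluorescence (arbitrary units or dF/F).
    reference : array of float
        Reference-fluor fluorescence, same convention.
    fs : float
        Sampling rate in Hz; must match the median time step.
    labels : tuple of str
        Channel names, ``(gevi_label, reference_label)``.
    meta : dict
        Free-form key/value metadata.
    """

    time: np.ndarray
    gevi: np.ndarray
    reference: np.ndarray
    fs: float
    labels: tuple = ("gevi", "reference")
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=np.float64)
        self.gevi = _as_float32(self.gevi)
        self.reference = _as_float32(self.reference)
        if self.gevi.ndim != 1 or self.reference.ndim != 1:
            raise ValueError("gevi and reference must be 1-D")
        if not (len(self.time) == len(self.gevi) == len(self.reference)):
            raise ValueError("time, gevi and reference must share a length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.time) > 1:
            dt = float(np.median(np.diff(self.time)))
            if abs(dt - 1.0 / self.fs) > 1e-6 / self.fs:
                raise ValueError(
                    f"fs={self.fs} inconsistent with median time step {dt}"
                )

    def __len__(self) -> int:
        return len(self.time)

    @classmethod
    def from_arrays(cls, gevi, reference, fs, t0=0.0, **kw) -> "DualChannelTrace":
        n = len(np.asarray(gevi))
        time = t0 + np.arange(n) / float(fs)
        return cls(time=time, gevi=gevi, reference=reference, fs=float(fs), **kw)


@dataclass
class DualChannelMovie:
    """Paired T x H x W stacks with frame rate and pixel pitch (mm/pixel)."""

    gevi: np.ndarray
    reference: np.ndarray
    fs: float
    pixel_pitch: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gevi = _as_float32(self.gevi)
        self.reference = _as_float32(self.reference)
        if self.gevi.ndim != 3 or self.reference.ndim != 3:
            raise ValueError("movie stacks must be T x H x W")
        if self.gevi.shape != self.reference.shape:
            raise ValueError("gevi and reference stacks must share a shape")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @property
    def shape(self):
        return self.gevi.shape


@dataclass
class ElectricalTrace:
    """Electrode trace in volts, optionally carrying a binary sync waveform."""

    signal: np.ndarray
    fs: float
    sync: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.sync is not None:
            self.sync = np.asarray(self.sync, dtype=np.float64)
            if len(self.sync) != len(self.signal):
                raise ValueError("sync must match signal length")
            levels = np.unique(self.sync)
            if len(levels) > 2:
                raise ValueError("sync must be binary (at most two levels)")

    def __len__(self) -> int:
        return len(self.signal)


# ---------------------------------------------------------------------------
# alignment


def _norm_xcorr_lag(a: np.ndarray, b: np.ndarray, max_lag: int):
    """Lag (in samples of ``a``'s grid) maximizing the normalized
    cross-correlation of ``a`` against ``b``; positive lag means ``b``
    is delayed relative to ``a``.  Returns (lag, peak_value)."""
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        return 0, 0.0
    n = len(a) + len(b) - 1
    nfft = 1 << int(np.ceil(np.log2(n)))
    corr = np.fft.irfft(np.fft.rfft(a, nfft) * np.conj(np.fft.rfft(b, nfft)), nfft)
    # lag k: sum a[t] b[t-k]; negative lags wrap around
    lags = np.concatenate([np.arange(0, max_lag + 1), np.arange(-max_lag, 0)])
    vals = np.concatenate([corr[: max_lag + 1], corr[-max_lag:]])
    i = int(np.argmax(vals))
    return int(lags[i]), float(vals[i] / denom)


def align_streams(
    optical: DualChannelTrace,
    electrical: ElectricalTrace,
    max_lag: float = 10.0,
    min_peak: float = 0.9,
) -> tuple[DualChannelTrace, ElectricalTrace]:
    """Align an electrode stream to the optical time base via a shared
    randomized square-wave sync signal.

    The electrical sync is first resampled (nearest-neighbor) onto the
    optical rate, the lag of the normalized cross-correlation peak between
    the two sync waveforms is found within ``+/- max_lag`` seconds, and the
    continuous electrode signal is spline-interpolated onto the shifted
    optical grid (nearest-neighbor for the binary sync).  Time origin is
    t=0 at the first optical sample.

    Raises
    ------
    AlignmentError
        If the sync correlation peak is below ``min_peak``.
    """
    opt_sync = optical.meta.get("sync")
    if opt_sync is None or electrical.sync is None:
        raise ValueError("both streams must carry a sync waveform")
    opt_sync = np.asarray(opt_sync, float)
    fs = optical.fs

    t_el = np.arange(len(electrical)) / electrical.fs
    t_opt_rel = np.arange(len(optical)) / fs
    # nearest-neighbor resample of the electrical sync onto the optical rate
    idx = np.clip(np.round(t_opt_rel * electrical.fs).astype(int), 0, len(electrical) - 1)
    el_sync_rs = electrical.sync[idx]

    max_lag_n = max(1, int(round(max_lag * fs)))
    max_lag_n = min(max_lag_n, len(opt_sync) - 2)
    lag, peak = _norm_xcorr_lag(opt_sync, el_sync_rs, max_lag_n)
    if peak < min_peak:
        raise AlignmentError(
            f"sync cross-correlation peak {peak:.3f} below confidence {min_peak}"
        )
    shift_s = lag / fs  # electrical stream starts shift_s before optical t=0

    # optical output: same samples, time origin at first sample
    t_out = np.arange(len(optical)) / fs
    opt_out = dataclasses.replace(optical, time=t_out)

    # electrical stream resampled onto the optical grid
    t_query = t_out - shift_s
    spline = CubicSpline(t_el, electrical.signal, extrapolate=False)
    sig = spline(t_query)
    sig = np.where(np.isnan(sig), 0.0, sig)
    idx_q = np.clip(np.round(t_query * electrical.fs).astype(int), 0, len(electrical) - 1)
    sync_rs = electrical.sync[idx_q]
    el_out = ElectricalTrace(
        signal=sig, fs=fs, sync=sync_rs,
        meta={**electrical.meta, "shift_s": shift_s, "sync_peak": peak},
    )
    return opt_out, el_out


# ---------------------------------------------------------------------------
# spatial binning


def spatial_bin(movie: DualChannelMovie, factor: int) -> DualChannelMovie:
    """Block-average each channel over ``factor x factor`` pixel blocks.

    Trailing rows/columns not filling a block are dropped; pixel pitch is
    multiplied by ``factor``.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    t, h, w = movie.shape
    if factor > h or factor > w:
        raise ValueError(f"factor {factor} exceeds spatial dimensions {(h, w)}")
    if factor == 1:
        return movie

    def _bin(stack):
        hh, ww = (h // factor) * factor, (w // factor) * factor
        s = stack[:, :hh, :ww].astype(np.float64)
        s = s.reshape(t, hh // factor, factor, ww // factor, factor)
        return s.mean(axis=(2, 4)).astype(DTYPE)

    return DualChannelMovie(
        gevi=_bin(movie.gevi),
        reference=_bin(movie.reference),
        fs=movie.fs,
        pixel_pitch=movie.pixel_pitch * factor,
        meta=dict(movie.meta),
    )


# ---------------------------------------------------------------------------
# file I/O


def write_trace(path, trace: DualChannelTrace) -> None:
    """Write a trace as CSV (columns time,gevi,reference) or HDF5 by suffix."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame(
            {"time": trace.time, "gevi": trace.gevi, "reference": trace.reference}
        ).to_csv(path, index=False, float_format="%.17g")
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=trace.time)
            f.create_dataset("gevi", data=trace.gevi)
            f.create_dataset("reference", data=trace.reference)
            f.attrs["fs"] = trace.fs
            f.attrs["labels"] = list(trace.labels)


def read_trace(path, fs: float | None = None) -> DualChannelTrace:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        time = df["time"].to_numpy()
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(time)))
        return DualChannelTrace(
            time=time, gevi=df["gevi"].to_numpy(),
            reference=df["reference"].to_numpy(), fs=fs,
        )
    with h5py.File(path, "r") as f:
        labels = tuple(
            s.decode() if isinstance(s, bytes) else str(s)
            for s in f.attrs.get("labels", ["gevi", "reference"])
        )
        return DualChannelTrace(
            time=f["time"][:], gevi=f["gevi"][:], reference=f["reference"][:],
            fs=float(f.attrs["fs"]), labels=labels,
        )


def write_movie(path, movie: DualChannelMovie) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gevi", data=movie.gevi)
        f.create_dataset("reference", data=movie.reference)
        f.attrs["fs"] = movie.fs
        f.attrs["pixel_pitch"] = movie.pixel_pitch


def read_movie(path) -> DualChannelMovie:
    with h5py.File(path, "r") as f:
        return DualChannelMovie(
            gevi=f["gevi"][:], reference=f["reference"][:],
            fs=float(f.attrs["fs"]), pixel_pitch=float(f.attrs["pixel_pitch"]),
        )


def read_movie_tiff(gevi_path, reference_path, fs: float, pixel_pitch: float) -> DualChannelMovie:
    """Import a channel pair from multi-page TIFF stacks."""
    import tifffile

    return DualChannelMovie(
        gevi=tifffile.imread(gevi_path),
        reference=tifffile.imread(reference_path),
        fs=fs, pixel_pitch=pixel_pitch,
    )


def write_electrical(path, trace: ElectricalTrace) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        cols = {"signal": trace.signal}
        if trace.sync is not None:
            cols["sync"] = trace.sync
        df = pd.DataFrame(cols)
        with open(path, "w") as fh:
            fh.write(f"# fs={trace.fs}\n")
            df.to_csv(fh, index=False, float_format="%.17g")
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=trace.signal)
            if trace.sync is not None:
                f.create_dataset("sync", data=trace.sync)
            f.attrs["fs"] = trace.fs


def read_electrical(path, fs: float | None = None) -> ElectricalTrace:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# fs="):
                fs = float(first.strip().split("=", 1)[1])
                df = pd.read_csv(fh, float_precision="round_trip")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, float_precision="round_trip")
        if fs is None:
            raise ValueError("fs must be given for headerless CSV electrode files")
        sync = df["sync"].to_numpy() if "sync" in df else None
        return ElectricalTrace(signal=df["signal"].to_numpy(), fs=fs, sync=sync)
    with h5py.File(path, "r") as f:
        sync = f["sync"][:] if "sync" in f else None
        return ElectricalTrace(signal=f["signal"][:], fs=float(f.attrs["fs"]), sync=sync)
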