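"""Synthetic dual-channel recordings with known ground truth.

Every generator is a pure function of its spec plus seed.  Artifacts
enter multiplicatively on the photobleaching baseline (small-signal
regime), so after detrending they appear additively in dF/F units; the
implied GEVI<->reference transfer h(w) = g_gevi(w) / g_ref(w) is recorded
in the ground truth at every heartbeat harmonic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from tempokit.core_io import DualChannelMovie, DualChannelTrace
from tempokit.delays import DelayObservation

__all__ = [
    "HeartbeatSpec",
    "CFCSpec",
    "RippleSpec",
    "DriftSpec",
    "TraceSynthSpec",
    "WaveSpec",
    "MovieSynthSpec",
    "OpticalDesignParams",
    "gen_trace_pair",
    "gen_movie_pair",
    "gen_delay_experiments",
    "snr_bound",
]


@dataclass(frozen=True)
class HeartbeatSpec:
    """Heartbeat fundamental f0 with per-harmonic complex channel gains.

    ``gevi_gains[m]`` and ``ref_gains[m]`` are the complex amplitudes of
    harmonic (m+1) in each channel; magnitude sets dF/F amplitude, angle
    the phase lead relative to a shared random harmonic phase.
    """

    f0: float
    gevi_gains: tuple = (0.005,)
    ref_gains: tuple = (0.01,)

    @property
    def n_harmonics(self):
        return max(len(self.gevi_gains), len(self.ref_gains))


@dataclass(frozen=True)
class CFCSpec:
    carrier_hz: float = 2.0
    amp_hz: float = 40.0
    carrier_amp: float = 0.01
    amp_amp: float = 0.002
    m: float = 0.5            # modulation depth in [0, 1]
    phi0_deg: float = 0.0     # preferred carrier phase (trough convention)


@dataclass(frozen=True)
class RippleSpec:
    rate_per_min: float = 6.0
    duration_ms: float = 60.0
    center_hz: float = 150.0
    amplitude: float = 1.0


@dataclass(frozen=True)
class DriftSpec:
    """Shared band-limited hemodynamic drift, per-channel real gains."""

    cutoff_hz: float = 1.0
    gevi_gain: float = 0.002
    ref_gain: float = 0.004


@dataclass(frozen=True)
class TraceSynthSpec:
    duration: float = 60.0
    fs: float = 500.0
    oscillations: tuple = ()          # (freq_hz, amplitude_dff) pairs
    cfc: CFCSpec | None = None
    ripples: RippleSpec | None = None
    heartbeat: HeartbeatSpec | None = None
    drift: DriftSpec | None = None
    bleach: tuple = ()                # (amplitude, tau_s) components, + 1 offset
    noise_gevi: float = 0.0
    noise_ref: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.heartbeat is not None and not 0 < self.heartbeat.f0 < self.fs / 2:
            raise ValueError("heartbeat f0 outside (0, Nyquist)")
        for f, a in self.oscillations:
            if a < 0:
                raise ValueError("oscillation amplitudes must be >= 0")


@dataclass
class TraceGroundTruth:
    voltage: np.ndarray           # clean voltage dF/F
    artifact_gevi: np.ndarray     # clean artifact dF/F in the GEVI channel
    artifact_ref: np.ndarray
    transfer: dict                # harmonic freq (Hz) -> complex h(w)
    ripple_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    bleach_gevi: np.ndarray | None = None
    bleach_ref: np.ndarray | None = None


def _bleach_curve(t, components):
    if not components:
        return np.ones_like(t)
    out = np.zeros_like(t)
    for a, tau in components:
        out += a * np.exp(-t / tau)
    return out + 1.0  # unit offset keeps the baseline positive


def gen_trace_pair(spec: TraceSynthSpec):
    """Generate a dual-channel trace pair and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs

    voltage = np.zeros(n)
    for f, a in spec.oscillations:
        voltage += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))

    if spec.cfc is not None:
        c = spec.cfc
        # trough-referenced carrier phase: -cos carrier has trough at t=0
        carrier = -c.carrier_amp * np.cos(2 * np.pi * c.carrier_hz * t)
        phase = 2 * np.pi * c.carrier_hz * t  # trough-ref phase, radians
        envelope = c.amp_amp * (1 + c.m * np.cos(phase - np.deg2rad(c.phi0_deg)))
        voltage += carrier + envelope * np.sin(2 * np.pi * c.amp_hz * t)

    ripple_times = np.empty(0)
    if spec.ripples is not None:
        rp = spec.ripples
        n_events = max(0, int(round(rp.rate_per_min * spec.duration / 60.0)))
        dur_n = max(3, int(round(rp.duration_ms / 1000.0 * spec.fs)))
        margin = dur_n
        centers = np.sort(rng.uniform(margin / spec.fs,
                                      spec.duration - margin / spec.fs, n_events))
        env = signal.windows.hann(dur_n)
        for c0 in centers:
            i0 = int(round(c0 * spec.fs)) - dur_n // 2
            tt = np.arange(dur_n) / spec.fs
            voltage[i0:i0 + dur_n] += rp.amplitude * env * np.sin(
                2 * np.pi * rp.center_hz * tt)
        ripple_times = centers

    art_g = np.zeros(n)
    art_r = np.zeros(n)
    transfer = {}
    if spec.heartbeat is not None:
        hb = spec.heartbeat
        for m in range(hb.n_harmonics):
            fm = hb.f0 * (m + 1)
            gg = complex(hb.gevi_gains[m]) if m < len(hb.gevi_gains) else 0j
            gr = complex(hb.ref_gains[m]) if m < len(hb.ref_gains) else 0j
            ph = rng.uniform(0, 2 * np.pi)
            theta = 2 * np.pi * fm * t + ph
            art_g += np.abs(gg) * np.cos(theta + np.angle(gg))
            art_r += np.abs(gr) * np.cos(theta + np.angle(gr))
            if gr != 0:
                transfer[fm] = gg / gr

    if spec.drift is not None:
        d = spec.drift
        white = rng.standard_normal(n)
        sos = signal.butter(3, d.cutoff_hz, btype="lowpass", fs=spec.fs, output="sos")
        slow = signal.sosfiltfilt(sos, white)
        slow /= max(np.std(slow), 1e-12)
        art_g += d.gevi_gain * slow
        art_r += d.ref_gain * slow

    bleach_g = _bleach_curve(t, spec.bleach)
    bleach_r = _bleach_curve(t, spec.bleach)
    gevi = bleach_g * (1.0 + voltage + art_g) + spec.noise_gevi * rng.standard_normal(n)
    ref = bleach_r * (1.0 + art_r) + spec.noise_ref * rng.standard_normal(n)

    trace = DualChannelTrace.from_arrays(gevi, ref, spec.fs)
    truth = TraceGroundTruth(
        voltage=voltage, artifact_gevi=art_g, artifact_ref=art_r,
        transfer=transfer, ripple_times=ripple_times,
        bleach_gevi=bleach_g, bleach_ref=bleach_r,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# movies


@dataclass(frozen=True)
class WaveSpec:
    """One traveling plane-wave event.

    The crest reaches position x (mm) at ``t0 + slowness . x``; speed is
    1/|slowness| mm/s and propagation direction atan2(sy, sx).
    """

    slowness: tuple = (0.02, 0.0)  # (sx, sy) s/mm
    freq: float = 4.0              # temporal frequency, Hz
    amplitude: float = 0.01
    t0: float = 0.5                # event (crest at origin) time, s
    n_cycles: float = 1.0          # Gaussian envelope width in carrier cycles


@dataclass(frozen=True)
class MovieSynthSpec:
    shape: tuple = (300, 32, 32)   # (T, H, W)
    fs: float = 100.0
    pixel_pitch: float = 0.05      # mm/pixel
    waves: tuple = ()
    heartbeat: HeartbeatSpec | None = None
    artifact_pattern: str = "uniform"   # "uniform" | "two_region"
    artifact_phase_lag: float = 0.0     # extra GEVI phase lag in region 2, rad
    background_rank: int = 0
    background_amp: float = 0.0
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for wv in self.waves:
            if wv.freq >= self.fs / 2:
                raise ValueError("wave temporal frequency must be < Nyquist")


@dataclass
class MovieGroundTruth:
    wave_speeds: np.ndarray       # mm/s per wave event
    wave_directions: np.ndarray   # degrees per wave event
    wave_times: np.ndarray
    artifact_gevi: np.ndarray | None = None
    artifact_ref: np.ndarray | None = None


def gen_movie_pair(spec: MovieSynthSpec):
    """Generate a dual-channel movie and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    T, H, W = spec.shape
    t = np.arange(T) / spec.fs
    x = np.arange(W) * spec.pixel_pitch
    y = np.arange(H) * spec.pixel_pitch
    xx, yy = np.meshgrid(x, y)  # (H, W)

    volt = np.zeros((T, H, W))
    speeds, dirs, times = [], [], []
    for wv in spec.waves:
        sx, sy = wv.slowness
        tau = sx * xx + sy * yy  # crest arrival offset per pixel, s
        sigma = wv.n_cycles / (2.0 * wv.freq)
        arg = t[:, None, None] - wv.t0 - tau[None, :, :]
        volt += wv.amplitude * np.cos(2 * np.pi * wv.freq * arg) * np.exp(
            -(arg ** 2) / (2 * sigma ** 2))
        mag = np.hypot(sx, sy)
        speeds.append(1.0 / mag if mag > 0 else np.inf)
        dirs.append(np.degrees(np.arctan2(sy, sx)))
        times.append(wv.t0)

    art_g = np.zeros((T, H, W))
    art_r = np.zeros((T, H, W))
    if spec.heartbeat is not None:
        hb = spec.heartbeat
        region2 = xx >= x[-1] / 2 if spec.artifact_pattern == "two_region" else \
            np.zeros_like(xx, dtype=bool)
        for m in range(hb.n_harmonics):
            fm = hb.f0 * (m + 1)
            gg = complex(hb.gevi_gains[m]) if m < len(hb.gevi_gains) else 0j
            gr = complex(hb.ref_gains[m]) if m < len(hb.ref_gains) else 0j
            ph = rng.uniform(0, 2 * np.pi)
            theta = 2 * np.pi * fm * t[:, None, None] + ph
            lag_map = np.where(region2, spec.artifact_phase_lag, 0.0)[None, :, :]
            art_g += np.abs(gg) * np.cos(theta + np.angle(gg) + lag_map)
            art_r += np.abs(gr) * np.cos(theta + np.angle(gr) + lag_map)

    bg = np.zeros((T, H, W))
    if spec.background_rank > 0 and spec.background_amp > 0:
        for _ in range(spec.background_rank):
            sp = rng.standard_normal((H, W))
            sp = signal.fftconvolve(sp, np.ones((5, 5)) / 25.0, mode="same")
            tm = rng.standard_normal(T)
            sos = signal.butter(2, min(2.0, spec.fs / 4), fs=spec.fs, output="sos")
            tm = signal.sosfiltfilt(sos, tm)
            bg += spec.background_amp * tm[:, None, None] * sp[None, :, :]

    gevi = 1.0 + volt + art_g + bg + spec.noise * rng.standard_normal((T, H, W))
    ref = 1.0 + art_r + spec.noise * rng.standard_normal((T, H, W))
    movie = DualChannelMovie(gevi=gevi, reference=ref, fs=spec.fs,
                             pixel_pitch=spec.pixel_pitch)
    truth = MovieGroundTruth(
        wave_speeds=np.asarray(speeds), wave_directions=np.asarray(dirs),
        wave_times=np.asarray(times), artifact_gevi=art_g, artifact_ref=art_r,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# delay-model experiment designs


STANDARD_ASSIGNMENTS = (
    ("indA", "indB"), ("indB", "indA"), ("indA", "indC"),
    ("indC", "indA"), ("indB", "indC"), ("indC", "indB"),
    ("indA", "indB"),  # the repeat
)


def gen_delay_experiments(d_phys, delta, sds=0.2, n_events=100, seed=0,
                          assignments=STANDARD_ASSIGNMENTS, noise=True):
    """Synthetic ancillary-experiment designs for the delay model.

    ``delta`` maps (indicator, class) -> induced delay in ms; missing
    pairs default to 0.  ``sds`` is a scalar or per-experiment sequence of
    event-level s.d. (ms).  Observed means are drawn as
    Normal(pred, sd/sqrt(n_events)) when ``noise`` is set.

    Returns (observations, truth) with truth = {"d": ..., "delta": {...}}.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(sds):
        sds = [float(sds)] * len(assignments)
    obs = []
    for e, ((i1, i2), sd) in enumerate(zip(assignments, sds)):
        pred = d_phys + delta.get((i1, "class1"), 0.0) - delta.get((i2, "class2"), 0.0)
        mean = pred + (rng.normal(0.0, sd / np.sqrt(n_events)) if noise else 0.0)
        obs.append(DelayObservation(
            experiment_id=f"exp{e}", indicator_on_class1=i1,
            indicator_on_class2=i2, mean_delay=float(mean),
            sd_delay=float(sd), n_events=n_events,
        ))
    return obs, {"d": d_phys, "delta": dict(delta)}


# ---------------------------------------------------------------------------
# mesoscope design bound


@dataclass(frozen=True)
class OpticalDesignParams:
    """Parameters of the shot-noise SNR bound for wave detection."""

    dFF: float          # fluorescence wave amplitude, dimensionless
    M: float            # optical magnification
    lambda_gamma: float # wave spatial wavelength, mm
    n_f: float          # frames averaged
    W_C: float          # pixel well capacity, electrons
    l_px: float         # camera pixel pitch, mm

    def __post_init__(self):
        for name in ("dFF", "M", "lambda_gamma", "n_f", "W_C", "l_px"):
            if getattr(self, name) < 0 or (name != "dFF" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")


def snr_bound(params: OpticalDesignParams):
    """Shot-noise-limited SNR upper bound for single-trial wave detection.

    Returns a dict with ``snr`` = dFF * (M * Lambda / (2 l_px)) *
    sqrt(n_f * W_C) and ``n_max`` = (M * Lambda / (2 l_px))^2 * n_f * W_C,
    the maximum photoelectron count over half a wavelength.
    """
    half_width_px = params.M * params.lambda_gamma / (2.0 * params.l_px)
    n_max = half_width_px ** 2 * params.n_f * params.W_C
    snr = params.dFF * half_width_px * np.sqrt(params.n_f * params.W_C)
    return {"snr": float(snr), "n_max": float(n_max)}
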