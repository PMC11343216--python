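"""Traveling-wave velocimetry.

Two routes are implemented: (A) seed-pixel normalized cross-correlation
delay maps with least-squares plane fits of the delay surface, and (B)
space-time projection with robust (bisquare IRLS) regression of per-
position crest times on position, yielding a slowness vector.

Velocity conventions for the plane fit: the "reciprocal" convention reports
v = (1/A, 1/B) from the fitted delay plane tau = A x + B y + C (a common
reporting convention), while the "gradient" convention reports
v = (A, B) / (A^2 + B^2), which is the kinematically consistent
plane-wave velocity.  Both are stored; gradient is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DelayMap",
    "PlaneFit",
    "SlownessFit",
    "WaveEvent",
    "delay_map",
    "plane_fit_velocity",
    "flow_map",
    "spacetime_project",
    "fit_slowness",
    "velocity_distributions",
]


@dataclass
class DelayMap:
    peak_corr: np.ndarray  # per-pixel max normalized cross-correlation
    delay: np.ndarray      # per-pixel lag of the peak, s (NaN below x_min)
    seed: tuple            # (row, col)
    x_min: float
    pixel_pitch: float


@dataclass
class PlaneFit:
    A: float  # s/mm
    B: float  # s/mm
    C: float  # s
    r2: float
    n_pixels: int
    velocity_gradient: tuple  # mm/s, (A,B)/(A^2+B^2)
    velocity_reciprocal: tuple     # mm/s, (1/A, 1/B)
    convention: str = "gradient"

    @property
    def velocity(self):
        return self.velocity_gradient if self.convention == "gradient" else self.velocity_reciprocal

    @property
    def speed(self):
        vx, vy = self.velocity
        return float(np.hypot(vx, vy))

    @property
    def direction(self):
        vx, vy = self.velocity
        return float(np.degrees(np.arctan2(vy, vx)))


@dataclass
class SlownessFit:
    alpha_x: float  # s/mm
    alpha_y: float  # s/mm
    se_x: float
    se_y: float
    p_x: float
    p_y: float
    n_pixels: int

    @property
    def speed(self):
        mag = np.hypot(self.alpha_x, self.alpha_y)
        return float(1.0 / mag) if mag > 0 else float("inf")

    @property
    def direction(self):
        d = float(np.degrees(np.arctan2(self.alpha_y, self.alpha_x)))
        return d if d > -180.0 else 180.0

    def p_joint(self):
        """Wald test that the slowness vector is nonzero (chi-squared,
        2 dof, axes treated as independent)."""
        if self.se_x == 0 and self.se_y == 0:
            return 1.0 if (self.alpha_x == 0 and self.alpha_y == 0) else 0.0
        w = 0.0
        for a, se in ((self.alpha_x, self.se_x), (self.alpha_y, self.se_y)):
            if se > 0:
                w += (a / se) ** 2
        return float(stats.chi2.sf(w, df=2))

    def accepted(self, p_thresh=0.01, strict=False):
        """Significance gate: joint |alpha| test by default; ``strict``
        requires each Cartesian component individually significant."""
        if strict:
            return self.p_x < p_thresh and self.p_y < p_thresh
        return self.p_joint() < p_thresh


@dataclass
class WaveEvent:
    window: tuple
    method: str
    fit: object
    accepted: bool
    reason: str = ""


# ---------------------------------------------------------------------------
# route A: seed-pixel cross-correlation + plane fit


def _xcorr_peak(seed, px, max_lag):
    """Normalized cross-correlation of px against seed over +/- max_lag
    samples, with 3-point parabolic sub-sample refinement.

    Positive lag means the pixel lags the seed."""
    a = seed - seed.mean()
    b = px - px.mean()
    denom = np.sqrt(np.dot(a, a) * np.dot(b, b))
    if denom == 0:
        return 0.0, 0.0
    full = np.correlate(b, a, mode="full")  # index n-1+k = sum b[t+k] a[t]...
    n = len(a)
    lags = np.arange(-max_lag, max_lag + 1)
    vals = full[n - 1 + lags[0]: n + lags[-1]] / denom
    i = int(np.argmax(vals))
    lag = float(lags[i])
    if 0 < i < len(vals) - 1:
        y0, y1, y2 = vals[i - 1], vals[i], vals[i + 1]
        d = y0 - 2 * y1 + y2
        if d < 0:
            lag += 0.5 * (y0 - y2) / d
    return float(vals[i]), lag


def delay_map(movie, seed, window=None, x_min=0.75, max_lag=0.25,
              fs=1.0, pixel_pitch=1.0) -> DelayMap:
    """Per-pixel peak correlation and delay relative to a seed pixel.

    ``movie`` is T x H x W (voltage); ``window`` an optional (start, end)
    frame slice; ``max_lag`` in seconds.  Delay is defined (non-NaN) only
    where peak correlation >= ``x_min``.
    """
    m = np.asarray(movie, dtype=np.float64)
    if window is not None:
        m = m[slice(*window)]
    t, h, w = m.shape
    r0, c0 = seed
    seed_tr = m[:, r0, c0]
    if np.var(seed_tr) == 0:
        raise ValueError("seed pixel has zero variance")
    max_lag_n = max(1, min(int(round(max_lag * fs)), t - 2))
    peak = np.empty((h, w))
    delay = np.full((h, w), np.nan)
    for i in range(h):
        for j in range(w):
            v, lag = _xcorr_peak(seed_tr, m[:, i, j], max_lag_n)
            peak[i, j] = v
            if v >= x_min:
                delay[i, j] = lag / fs
    return DelayMap(peak_corr=peak, delay=delay, seed=(r0, c0),
                    x_min=x_min, pixel_pitch=pixel_pitch)


def plane_fit_velocity(dmap: DelayMap, region=None, spatial_binning=1,
                       convention="gradient") -> PlaneFit:
    """Least-squares fit tau(x, y) = A x + B y + C over masked delays.

    ``region`` is an optional (row_slice, col_slice); ``spatial_binning``
    block-averages the delay surface first.  Coordinates are in mm
    (column -> x, row -> y).
    """
    delay = dmap.delay
    pitch = dmap.pixel_pitch
    if region is not None:
        delay = delay[region]
    if spatial_binning > 1:
        b = spatial_binning
        h, w = delay.shape
        hh, ww = (h // b) * b, (w // b) * b
        blocks = delay[:hh, :ww].reshape(hh // b, b, ww // b, b)
        with np.errstate(invalid="ignore"):
            delay = np.nanmean(blocks, axis=(1, 3))
        pitch = pitch * b
    rows, cols = np.nonzero(np.isfinite(delay))
    if len(rows) < 10:
        raise ValueError(f"only {len(rows)} masked pixels; need >= 10")
    x = cols * pitch
    y = rows * pitch
    tau = delay[rows, cols]
    X = np.column_stack([x, y, np.ones_like(x)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design (degenerate pixel geometry)")
    coef, _, _, _ = np.linalg.lstsq(X, tau, rcond=None)
    A, B, C = (float(c) for c in coef)
    pred = X @ coef
    ss_res = float(np.sum((tau - pred) ** 2))
    ss_tot = float(np.sum((tau - tau.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    g2 = A * A + B * B
    v_grad = (A / g2, B / g2) if g2 > 0 else (float("nan"), float("nan"))
    v_recip = (1.0 / A if A != 0 else float("inf"),
               1.0 / B if B != 0 else float("inf"))
    return PlaneFit(A=A, B=B, C=C, r2=r2, n_pixels=len(rows),
                    velocity_gradient=v_grad, velocity_reciprocal=v_recip,
                    convention=convention)


def flow_map(movie, event_window=None, tile_size=16, fs=1.0, pixel_pitch=1.0,
             x_min=0.75, max_lag=0.25, min_r2=0.5, convention="gradient"):
    """Per-tile velocity field over an event window.

    Each ``tile_size``-pixel tile gets a local delay map (seed at the tile
    center) and a plane fit; tiles failing the fit (or with r^2 below
    ``min_r2``) are dropped and counted.  Returns a dict with the tile
    grid of unit direction vectors, raw speeds/directions and the drop
    count.
    """
    m = np.asarray(movie, dtype=np.float64)
    if event_window is not None:
        m = m[slice(*event_window)]
    t, h, w = m.shape
    ny, nx = h // tile_size, w // tile_size
    u = np.full((ny, nx), np.nan)
    v = np.full((ny, nx), np.nan)
    speeds, dirs = [], []
    dropped = 0
    for ti in range(ny):
        for tj in range(nx):
            rs = slice(ti * tile_size, (ti + 1) * tile_size)
            cs = slice(tj * tile_size, (tj + 1) * tile_size)
            tile = m[:, rs, cs]
            seed = (tile_size // 2, tile_size // 2)
            try:
                dm = delay_map(tile, seed, x_min=x_min, max_lag=max_lag,
                               fs=fs, pixel_pitch=pixel_pitch)
                fit = plane_fit_velocity(dm, convention=convention)
            except ValueError:
                dropped += 1
                continue
            if fit.r2 < min_r2 or not np.isfinite(fit.speed) or fit.speed == 0:
                dropped += 1
                continue
            vx, vy = fit.velocity
            norm = np.hypot(vx, vy)
            u[ti, tj], v[ti, tj] = vx / norm, vy / norm
            speeds.append(fit.speed)
            dirs.append(fit.direction)
    return {"u": u, "v": v, "speeds": np.asarray(speeds),
            "directions": np.asarray(dirs), "n_dropped": dropped}


# ---------------------------------------------------------------------------
# route B: space-time projection + robust slowness regression


def spacetime_project(movie, event_window=None, pixel_pitch=1.0):
    """Project a movie onto its row and column axes.

    Returns (row_proj, col_proj, coords) where row_proj is time x rows
    (mean over columns), col_proj is time x columns (mean over rows) and
    ``coords`` holds the physical axes in mm.
    """
    m = np.asarray(movie, dtype=np.float64)
    if event_window is not None:
        m = m[slice(*event_window)]
    row_proj = m.mean(axis=2)  # (T, H)
    col_proj = m.mean(axis=1)  # (T, W)
    coords = {
        "rows_mm": np.arange(m.shape[1]) * pixel_pitch,
        "cols_mm": np.arange(m.shape[2]) * pixel_pitch,
    }
    return row_proj, col_proj, coords


def _robust_slope(pos_mm, t_peak_s):
    """IRLS bisquare regression of peak time on position; returns
    (slope, se, p)."""
    if np.ptp(t_peak_s) == 0:
        return 0.0, 0.0, 1.0
    X = sm.add_constant(pos_mm)
    fit = sm.RLM(t_peak_s, X, M=sm.robust.norms.TukeyBiweight()).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(2 * stats.norm.sf(abs(slope) / se)) if se > 0 else (
        1.0 if slope == 0 else 0.0)
    return slope, se, p


def _crest_times(proj, fs):
    """Per-position time of maximum, with 3-point parabolic sub-sample
    refinement (first maximum on plateaus)."""
    idx = np.argmax(proj, axis=0)
    t = idx.astype(np.float64)
    for j, i in enumerate(idx):
        if 0 < i < proj.shape[0] - 1:
            y0, y1, y2 = proj[i - 1, j], proj[i, j], proj[i + 1, j]
            d = y0 - 2 * y1 + y2
            if d < 0:
                t[j] += 0.5 * (y0 - y2) / d
    return t / fs


def fit_slowness(row_proj, col_proj, fs=1.0, pixel_pitch=1.0,
                 event_window=None, smooth_hz=None) -> SlownessFit:
    """Slowness vector from crest times of the two 1-D projections.

    For every position the time of maximum signal within the event window
    is found (parabolic sub-sample refinement; first maximum on plateaus)
    and robust-regressed on position; the column-axis slope is alpha_x and
    the row-axis slope is alpha_y (s/mm).  ``smooth_hz`` optionally
    low-passes the projections in time first (useful on noisy movies that
    have not been through the low-rank denoiser).
    """
    rp = np.asarray(row_proj, dtype=np.float64)
    cp = np.asarray(col_proj, dtype=np.float64)
    if event_window is not None:
        rp = rp[slice(*event_window)]
        cp = cp[slice(*event_window)]
    if rp.shape[1] < 8 or cp.shape[1] < 8:
        raise ValueError("each projection needs >= 8 positions")
    if smooth_hz is not None:
        from scipy import signal as _sig
        sos = _sig.butter(3, smooth_hz, btype="lowpass", fs=fs, output="sos")
        rp = _sig.sosfiltfilt(sos, rp, axis=0)
        cp = _sig.sosfiltfilt(sos, cp, axis=0)
    t_row = _crest_times(rp, fs)
    t_col = _crest_times(cp, fs)
    y_mm = np.arange(rp.shape[1]) * pixel_pitch
    x_mm = np.arange(cp.shape[1]) * pixel_pitch
    ax, sex, px = _robust_slope(x_mm, t_col)
    ay, sey, py = _robust_slope(y_mm, t_row)
    return SlownessFit(alpha_x=ax, alpha_y=ay, se_x=sex, se_y=sey,
                       p_x=px, p_y=py, n_pixels=rp.shape[1] + cp.shape[1])


def analyze_wave_event(movie, event_window, fs, pixel_pitch,
                       p_thresh=0.01, strict=False) -> WaveEvent:
    """Run the space-time route on one event window (frame indices)."""
    rp, cp, _ = spacetime_project(movie, event_window, pixel_pitch)
    fit = fit_slowness(rp, cp, fs=fs, pixel_pitch=pixel_pitch)
    ok = fit.accepted(p_thresh=p_thresh, strict=strict)
    return WaveEvent(window=tuple(event_window), method="spacetime_regression",
                     fit=fit, accepted=ok,
                     reason="" if ok else "slowness not significantly nonzero")


# ---------------------------------------------------------------------------
# distribution summaries


def velocity_distributions(events, speed_bins=20, direction_bins=18,
                           n_boot=1000, seed=0, compare_modes=None):
    """Speed and direction histograms over accepted events with
    bootstrap s.e.m. of the median speed.

    ``compare_modes`` optionally provides two boolean masks selecting
    event subsets; a two-sided rank-sum test on their speeds is reported.
    """
    accepted = [e for e in events if getattr(e, "accepted", True)]
    if not accepted:
        raise ValueError("no accepted events")
    speeds = np.array([e.fit.speed for e in accepted])
    dirs = np.array([e.fit.direction for e in accepted])
    if np.ptp(speeds) < 1e-9 * max(abs(speeds.max()), 1.0):
        # degenerate (single-valued) speeds: pad the histogram range
        pad = max(abs(speeds[0]) * 0.01, 1e-9)
        s_hist, s_edges = np.histogram(
            speeds, bins=speed_bins, range=(speeds[0] - pad, speeds[0] + pad))
    else:
        s_hist, s_edges = np.histogram(speeds, bins=speed_bins)
    d_hist, d_edges = np.histogram(dirs, bins=direction_bins, range=(-180, 180))
    rng = np.random.default_rng(seed)
    med = float(np.median(speeds))
    if len(speeds) > 1:
        boots = np.median(
            speeds[rng.integers(0, len(speeds), size=(n_boot, len(speeds)))], axis=1
        )
        sem = float(np.std(boots, ddof=1))
    else:
        sem = float("nan")
    out = {
        "speeds": speeds, "directions": dirs,
        "speed_hist": (s_hist, s_edges), "direction_hist": (d_hist, d_edges),
        "median_speed": med, "median_speed_sem": sem,
        "n_events": len(accepted),
    }
    if compare_modes is not None:
        m1, m2 = compare_modes
        a, b = speeds[np.asarray(m1)], speeds[np.asarray(m2)]
        if len(a) and len(b):
            out["ranksum_p"] = float(stats.ranksums(a, b).pvalue)
    return out
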