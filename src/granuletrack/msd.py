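"""Mean-squared-displacement analysis and anomalous-exponent fitting.

Per-track MSD uses the overlapping-pair estimator: MSD(n*dt) is the
mean of |r(i+n) - r(i)|^2 over all ordered pairs at frame lag n, for
lags up to half the track length.  The log-log curve is fitted by
ordinary least squares with the power-law model

    <r^2> = Gamma * t^alpha,   log <r^2> = log Gamma + alpha log t,

over the first 50% of available lags; fits with R^2 < 0.8 are flagged
as not accepted.  alpha ~ 1 indicates free diffusion, alpha > 1
directed transport, alpha < 1 constrained motion.  Additional views:
per-axis alpha after rotating the track so its start-to-end vector
lies along +x (x = back-and-forth along the transport axis, y =
perpendicular), a sliding 8-frame local alpha, and a pair-count
weighted ensemble MSD whose first half is fitted with MSD = 4*D*t for
the 2-D diffusion coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R2_ACCEPT = 0.8
FIT_FRACTION = 0.5


@dataclass
class MSDCurve:
    """MSD versus time lag for one track."""

    lag_s: np.ndarray
    msd: np.ndarray       # µm²
    n_pairs: np.ndarray

    def __len__(self) -> int:
        return int(self.lag_s.size)


@dataclass
class AlphaFit:
    """Power-law fit <r²> = Γ t^α of a log-log MSD curve."""

    alpha: float
    log_prefactor: float   # ln Γ, Γ in µm²/sᵅ
    r_squared: float
    accepted: bool
    n_points: int = 0


@dataclass
class EnsembleMSD:
    """Pair-count weighted ensemble MSD with its diffusion coefficient."""

    lag_s: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    total_pairs: np.ndarray
    diffusion_coeff: float   # µm²/s, from MSD = 4 D t on the first 50% of lags


def _pair_msd(frames: np.ndarray, values: np.ndarray,
              max_lag: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Overlapping-pair MSD over frame lags 1..max_lag; ``values`` is
    (n, d).  Handles gapped tracks by pairing existing frames only."""
    lags, msds, counts = [], [], []
    frame_to_idx = {int(f): i for i, f in enumerate(frames)}
    for n in range(1, max_lag + 1):
        sq = [np.sum((values[frame_to_idx[f + n]] - values[i]) ** 2)
              for i, f in enumerate(frames) if int(f) + n in frame_to_idx]
        if sq:
            lags.append(n)
            msds.append(float(np.mean(sq)))
            counts.append(len(sq))
    return (np.array(lags, dtype=int), np.array(msds),
            np.array(counts, dtype=int))


def msd(track, frame_interval_s: float = 20.0,
        max_lag: int | None = None) -> MSDCurve:
    """Per-track MSD curve (overlapping-pair estimator).

    Lags default to floor(N/2) frames for a track of N spots.  Raises
    ValueError for tracks with fewer than 3 spots.
    """
    pos = np.atleast_2d(np.asarray(track.positions_um, dtype=float))
    frames = np.asarray(track.frames, dtype=int)
    n = len(frames)
    if n < 3:
        raise ValueError("MSD needs at least 3 spots")
    if max_lag is None:
        max_lag = n // 2
    lags, msds, counts = _pair_msd(frames, pos, max_lag)
    return MSDCurve(lag_s=lags * frame_interval_s, msd=msds, n_pairs=counts)


def fit_alpha(curve: MSDCurve, fit_fraction: float = FIT_FRACTION,
              min_points: int = 5) -> AlphaFit:
    """OLS fit of log(MSD) on log(lag) over the first ``fit_fraction``
    of lags.  Zero-MSD points are excluded; fewer than ``min_points``
    usable points yields an undefined, not-accepted fit."""
    k = max(int(np.ceil(fit_fraction * len(curve))), 1)
    lag = curve.lag_s[:k]
    val = curve.msd[:k]
    ok = val > 0
    lag, val = lag[ok], val[ok]
    if lag.size < min_points:
        return AlphaFit(float("nan"), float("nan"), float("nan"), False,
                        int(lag.size))
    x = np.log(lag)
    y = np.log(val)
    alpha, intercept = np.polyfit(x, y, 1)
    resid = y - (alpha * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res < 1e-20 else 1.0 - ss_res / ss_tot \
        if ss_tot > 0 else 0.0
    return AlphaFit(float(alpha), float(intercept), float(r2),
                    bool(r2 >= R2_ACCEPT), int(lag.size))


def axis_msd(track, frame_interval_s: float = 20.0,
             max_lag: int | None = None) -> tuple[AlphaFit, AlphaFit]:
    """Per-axis alpha after rotating the start->end vector onto +x.

    x displacements then reflect back-and-forth motion along the
    transport axis, y displacements motion perpendicular to it.
    Raises ValueError if start and end coincide (rotation undefined).
    """
    pos = np.asarray(track.positions_um, dtype=float)
    frames = np.asarray(track.frames, dtype=int)
    d = pos[-1] - pos[0]
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("axis_msd: track start and end coincide")
    u = d / norm
    rel = pos - pos[0]
    x = rel @ u
    y = rel @ np.array([-u[1], u[0]])
    if max_lag is None:
        max_lag = len(frames) // 2
    fits = []
    for comp in (x, y):
        lags, msds, counts = _pair_msd(frames, comp[:, None], max_lag)
        curve = MSDCurve(lags * frame_interval_s, msds, counts)
        fits.append(fit_alpha(curve))
    return fits[0], fits[1]


def sliding_alpha(track, frame_interval_s: float = 20.0,
                  window: int = 8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local alpha over a gliding window of ``window`` spots.

    Within each full window the MSD is computed over lags
    1..window-1 and fitted as usual but without the R² acceptance
    gate (the R² is reported alongside).  Values attach to the central
    time point of the window.  Returns (frames, alpha, r_squared);
    empty arrays for tracks shorter than the window.
    """
    pos = np.asarray(track.positions_um, dtype=float)
    frames = np.asarray(track.frames, dtype=int)
    n = len(frames)
    if n < window:
        return (np.empty(0, dtype=int), np.empty(0), np.empty(0))
    back = (window - 1) // 2
    centres = np.arange(back, n - (window - 1 - back))
    out_f, out_a, out_r = [], [], []
    for i in centres:
        lo = i - back
        w_frames = frames[lo:lo + window]
        w_pos = pos[lo:lo + window]
        lags, msds, counts = _pair_msd(w_frames - w_frames[0], w_pos,
                                       int(w_frames[-1] - w_frames[0]))
        fit = fit_alpha(MSDCurve(lags * frame_interval_s, msds, counts),
                        fit_fraction=1.0, min_points=5)
        out_f.append(frames[i])
        out_a.append(fit.alpha)
        out_r.append(fit.r_squared)
    return np.array(out_f, dtype=int), np.array(out_a), np.array(out_r)


def ensemble_msd(curves: list[MSDCurve],
                 fit_fraction: float = FIT_FRACTION) -> EnsembleMSD:
    """Pair-count weighted mean and SD across MSD curves, plus the
    diffusion coefficient from a through-origin fit MSD = 4 D t over
    the first ``fit_fraction`` of the mean curve's lags."""
    if not curves:
        raise ValueError("ensemble_msd needs at least one curve")
    acc: dict[float, list[tuple[float, int]]] = {}
    for c in curves:
        for lag, m, w in zip(c.lag_s, c.msd, c.n_pairs):
            acc.setdefault(float(lag), []).append((float(m), int(w)))
    lags = np.array(sorted(acc))
    mean = np.empty_like(lags)
    sd = np.empty_like(lags)
    tot = np.empty(lags.size, dtype=int)
    for i, lag in enumerate(lags):
        vals = np.array([v for v, _ in acc[lag]])
        wts = np.array([w for _, w in acc[lag]], dtype=float)
        mu = float(np.average(vals, weights=wts))
        mean[i] = mu
        sd[i] = float(np.sqrt(np.average((vals - mu) ** 2, weights=wts)))
        tot[i] = int(wts.sum())
    k = max(int(np.ceil(fit_fraction * lags.size)), 1)
    t = lags[:k]
    m = mean[:k]
    denom = float(np.sum(t * t))
    d_coeff = float(np.sum(t * m) / (4.0 * denom)) if denom > 0 else float("nan")
    return EnsembleMSD(lags, mean, sd, tot, max(d_coeff, 0.0))
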