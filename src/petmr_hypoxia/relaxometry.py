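"""Voxelwise T2* estimation from multi-echo gradient-echo magnitude data.

The signal model is mono-exponential decay, S(TE) = S0 * exp(-TE / T2*).
Because magnitude images carry a Rician noise floor, echoes whose signal
has fallen below ``multiplier`` times the channel noise level are censored
before fitting: the fit keeps only the leading contiguous run of echoes at
or above the floor, so once one echo drops under it, that echo and all
later ones are discarded. The default fit is a weighted log-linear least
squares (weights S^2, the delta-method variance stabilization for ln S),
which is exact on noise-free data; a nonlinear least-squares refinement of
the exponential model, initialized at the log-linear solution, is optional.

"Noise level" here means the Gaussian channel sigma, estimated from the
mean background magnitude via the Rayleigh mean E|n| = sigma*sqrt(pi/2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .geometry import GridGeometry
from .images import MultiEchoSeries, RoiMask

log = logging.getLogger(__name__)

#: Fewest surviving echoes that still allow a fit with a residual check.
MIN_ECHOES = 3
#: T2* outside (0, T2STAR_CAP_MS] is physically implausible in neck tissue at 3 T.
T2STAR_CAP_MS = 500.0
#: Rayleigh mean factor: E|complex Gaussian noise| = sigma * sqrt(pi/2).
RAYLEIGH_MEAN = float(np.sqrt(np.pi / 2.0))

#: The default acquisition: 12 echoes, TE_k = 4.83 + k * 2.55 ms.
def default_echo_times(n_echoes: int = 12, first_te_ms: float = 4.83,
                       delta_te_ms: float = 2.55) -> np.ndarray:
    return first_te_ms + delta_te_ms * np.arange(n_echoes)


@dataclass
class T2StarMap:
    """Voxelwise T2*/S0 estimates with validity bookkeeping.

    ``t2star`` and ``s0`` are NaN wherever the fit was not attempted or
    rejected; ``valid`` is True exactly where ``t2star`` is finite.
    """

    t2star: np.ndarray
    s0: np.ndarray
    n_echoes_used: np.ndarray
    valid: np.ndarray
    noise_level: float
    geometry: GridGeometry

    def __post_init__(self) -> None:
        if not np.array_equal(self.valid, np.isfinite(self.t2star)):
            raise ValueError("valid must be exactly where t2star is finite")


def estimate_noise_level(series: MultiEchoSeries, background_mask: RoiMask) -> float:
    """Gaussian channel sigma from background magnitude (Rayleigh-corrected).

    In signal-free voxels the magnitude is Rayleigh distributed with mean
    sigma*sqrt(pi/2); averaging over all echoes of all background voxels and
    dividing by that factor recovers sigma.
    """
    series.geometry.require_compatible(background_mask.geometry, "series vs background mask")
    if background_mask.is_empty:
        raise ValueError("background mask is empty; cannot estimate noise level")
    bg = series.signal[background_mask.mask, :]
    mean_mag = float(np.mean(bg))
    sigma = mean_mag / RAYLEIGH_MEAN
    # Pure noise is flat across echoes; tissue decays with TE. A clearly
    # decaying background mean betrays tissue inside the mask.
    first, last = float(np.mean(bg[:, 0])), float(np.mean(bg[:, -1]))
    if last > 0 and first > 1.5 * last:
        warnings.warn(
            f"background signal decays across echoes (first-echo mean {first:.3g} "
            f"vs last {last:.3g}); the mask may contain tissue",
            stacklevel=2)
    return sigma


def censor_echoes(signal_train: np.ndarray, echo_times: np.ndarray,
                  noise_level: float, multiplier: float = 5.0,
                  contiguous: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Drop late echoes below the noise floor.

    With ``contiguous=True`` (the default), the leading run of echoes with
    signal >= multiplier * noise_level is kept; the first sub-floor echo and
    everything after it are discarded. ``contiguous=False`` drops sub-floor
    echoes individually instead.
    """
    if multiplier < 0:
        raise ValueError("multiplier must be >= 0")
    signal_train = np.asarray(signal_train, dtype=float)
    echo_times = np.asarray(echo_times, dtype=float)
    floor = multiplier * noise_level
    above = signal_train >= floor
    if contiguous:
        below_idx = np.flatnonzero(~above)
        n_keep = below_idx[0] if below_idx.size else signal_train.size
        keep = np.zeros(signal_train.size, dtype=bool)
        keep[:n_keep] = True
    else:
        keep = above
    return echo_times[keep], signal_train[keep]


def _loglinear_fit(te: np.ndarray, signal: np.ndarray) -> tuple[float, float]:
    """Weighted OLS of ln S on TE (weights S^2). Returns (S0, T2* in ms)."""
    w = signal**2
    y = np.log(signal)
    sw = w.sum()
    mx = (w * te).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (te - mx) ** 2).sum()
    if sxx == 0:
        return np.nan, np.nan
    slope = (w * (te - mx) * (y - my)).sum() / sxx
    intercept = my - slope * mx
    if slope >= 0 or not np.isfinite(slope):
        return np.nan, np.nan
    return float(np.exp(intercept)), float(-1.0 / slope)


def fit_monoexponential(echo_times: np.ndarray, signal: np.ndarray,
                        method: str = "log-linear") -> tuple[float, float]:
    """Fit S(TE) = S0 exp(-TE/T2*) to one voxel's censored echo train.

    Returns ``(S0, T2*_ms)``; either may be NaN for degenerate trains
    (zero slope, too short after checks are done upstream). Raises on
    contract violations: fewer than :data:`MIN_ECHOES` echoes or
    non-positive signals among the kept echoes.
    """
    echo_times = np.asarray(echo_times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if echo_times.size < MIN_ECHOES:
        raise ValueError(
            f"need >= {MIN_ECHOES} echoes to fit, got {echo_times.size}")
    if np.any(signal <= 0):
        raise ValueError("kept echo signals must be strictly positive")
    s0, t2 = _loglinear_fit(echo_times, signal)
    if method == "log-linear" or not np.isfinite(t2):
        return s0, t2
    if method != "nonlinear":
        raise ValueError(f"unknown method {method!r}")

    def model(te, s0_, t2_):
        return s0_ * np.exp(-te / t2_)

    try:
        popt, _ = curve_fit(model, echo_times, signal, p0=[s0, t2], maxfev=2000)
    except RuntimeError:
        return s0, t2
    s0n, t2n = float(popt[0]), float(popt[1])
    if t2n <= 0 or not np.isfinite(t2n):
        return np.nan, np.nan
    return s0n, t2n


def compute_t2star_map(series: MultiEchoSeries, noise_level: float,
                       roi_mask: RoiMask | None = None,
                       multiplier: float = 5.0,
                       method: str = "log-linear",
                       contiguous_censoring: bool = True) -> T2StarMap:
    """Apply echo censoring and the mono-exponential fit at every voxel.

    Voxels with fewer than :data:`MIN_ECHOES` surviving echoes, a
    non-positive kept signal, a non-negative decay slope, or a T2* outside
    (0, 500] ms are marked invalid (NaN).
    """
    if roi_mask is not None:
        series.geometry.require_compatible(roi_mask.geometry, "series vs ROI mask")
    shape = series.geometry.shape
    n_echo = series.n_echoes
    sig = series.signal.reshape(-1, n_echo)
    te = series.echo_times

    fit_here = np.ones(sig.shape[0], dtype=bool)
    if roi_mask is not None:
        fit_here = roi_mask.mask.reshape(-1).copy()

    floor = multiplier * noise_level
    above = sig >= floor
    if contiguous_censoring:
        any_below = ~above
        first_below = np.where(any_below.any(axis=1),
                               any_below.argmax(axis=1), n_echo)
        keep = np.arange(n_echo)[None, :] < first_below[:, None]
    else:
        keep = above
    n_used = keep.sum(axis=1)

    ok = fit_here & (n_used >= MIN_ECHOES)
    # a kept echo with zero signal cannot enter the log fit
    ok &= ~np.any(keep & (sig <= 0), axis=1)

    # weighted log-linear, vectorized over voxels via masked sums
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(keep & (sig > 0), np.log(np.where(sig > 0, sig, 1.0)), 0.0)
    w = np.where(keep, sig**2, 0.0)
    sw = w.sum(axis=1)
    sw = np.where(sw > 0, sw, np.nan)
    mx = (w * te[None, :]).sum(axis=1) / sw
    my = (w * y).sum(axis=1) / sw
    dx = te[None, :] - mx[:, None]
    sxx = (w * dx**2).sum(axis=1)
    sxy = (w * dx * (y - my[:, None])).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
    intercept = my - slope * mx
    t2 = np.where(slope < 0, -1.0 / slope, np.nan)
    s0 = np.exp(intercept)

    valid = ok & np.isfinite(t2) & (t2 > 0) & (t2 <= T2STAR_CAP_MS)
    n_capped = int(np.count_nonzero(ok & np.isfinite(t2) & (t2 > T2STAR_CAP_MS)))
    if n_capped:
        log.info("T2* cap %.0f ms invalidated %d voxels", T2STAR_CAP_MS, n_capped)

    t2 = np.where(valid, t2, np.nan)
    s0 = np.where(valid, s0, np.nan)

    if method == "nonlinear":
        for idx in np.flatnonzero(valid):
            te_k = te[keep[idx]]
            sg_k = sig[idx, keep[idx]]
            s0[idx], t2[idx] = fit_monoexponential(te_k, sg_k, method="nonlinear")
        valid = valid & np.isfinite(t2)
    elif method != "log-linear":
        raise ValueError(f"unknown method {method!r}")

    return T2StarMap(
        t2star=t2.reshape(shape),
        s0=s0.reshape(shape),
        n_echoes_used=np.where(fit_here, n_used, 0).reshape(shape).astype(np.int32),
        valid=np.isfinite(t2).reshape(shape),
        noise_level=float(noise_level),
        geometry=series.geometry,
    )
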