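"""Mean-squared displacement, diffusive-regime validation and diffusion.

MSD is averaged over every time origin (the FFT autocorrelation identity
makes this O(T log T) per particle) and over the selected entities.  The
local log-log slope beta(tau) = d ln MSD / d ln tau validates the regime:
beta = 1 is diffusive, beta = 2 ballistic; the diffusive window is the
longest contiguous stretch with |beta - 1| within tolerance, and must span
a minimum fraction of the lags to count.  The Einstein relation
D = slope(MSD vs tau) / 6 then yields the self-diffusion coefficient.

Wrapped-only trajectories are unwrapped by accumulating minimum-image
inter-frame steps, valid while no particle moves more than half a box edge
between stored frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .shape import make_whole
from .trajectory import Trajectory, minimum_image

__all__ = [
    "MsdResult",
    "unwrap_trajectory",
    "msd",
    "beta_exponent",
    "diffusion_coefficient",
    "relative_error",
    "D_SI_FACTOR",
]

D_SI_FACTOR = 1e5  # nm^2/ps -> 10^-11 m^2/s

BETA_TOL = 0.1          # |beta - 1| tolerance for the diffusive window
MIN_WINDOW_FRACTION = 0.2  # window must span >= 20% of available lags


@dataclass
class MsdResult:
    lags: np.ndarray          # ps, starting at 0
    msd: np.ndarray           # nm^2
    n_entities: int

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)


def unwrap_trajectory(traj: Trajectory) -> np.ndarray:
    """(n_frames, n_atoms, 3) unwrapped coordinates.

    Uses the stored unwrapped channel when present; otherwise accumulates
    minimum-image displacements between consecutive frames.
    """
    if traj.unwrapped is not None:
        return traj.unwrapped
    n_f, n_a = traj.n_frames, traj.n_atoms
    out = np.empty((n_f, n_a, 3))
    out[0] = traj.frames[0].coords
    for k in range(1, n_f):
        step = minimum_image(traj.frames[k - 1].coords, traj.frames[k].coords,
                             traj.frames[k].box)
        half = traj.frames[k].box / 2.0
        if np.any(np.abs(step) >= half - 1e-9):
            raise ValueError(
                f"cannot unwrap: a displacement between frames {k - 1} and {k} "
                "reaches half the box edge; store unwrapped coordinates or "
                "save frames more often"
            )
        out[k] = out[k - 1] + step
    return out


def _msd_fft_single(x: np.ndarray) -> np.ndarray:
    """All-origin MSD of one (T, 3) path via the FFT autocorrelation identity."""
    T = x.shape[0]
    s2 = np.zeros(T)
    nfft = 1 << (2 * T - 1).bit_length()
    for dim in range(3):
        f = np.fft.rfft(x[:, dim], nfft)
        acf = np.fft.irfft(f * np.conjugate(f), nfft)[:T]
        s2 += acf
    d = np.einsum("ij,ij->i", x, x)
    s1 = np.empty(T)
    acc = 2.0 * d.sum()
    s1[0] = acc
    for m in range(1, T):
        acc -= d[m - 1] + d[T - m]
        s1[m] = acc
    n_origins = T - np.arange(T)
    return s1 / n_origins - 2.0 * s2 / n_origins


def msd(traj: Trajectory, selection: Optional[Sequence[int]] = None,
        mode: str = "per_particle", max_lag_fraction: float = 0.5) -> MsdResult:
    """Multiple-time-origin MSD of a selection.

    ``mode='per_particle'`` averages single-atom MSDs over the selection;
    ``mode='com'`` first reduces the selection to its mass-weighted centre
    (made PBC-whole per frame before unwrapping).  Lags run up to
    ``max_lag_fraction`` of the trajectory length.
    """
    if traj.n_frames < 10:
        raise ValueError("MSD needs at least 10 frames")
    times = traj.times
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("MSD requires uniformly spaced frames")
    if selection is None:
        selection = np.arange(traj.n_atoms)
    selection = np.asarray(selection, dtype=int)
    coords = unwrap_trajectory(traj)[:, selection, :].copy()
    if mode == "com":
        if traj.unwrapped is None:
            # re-join a molecule split by wrapping at frame 0: each atom's
            # whole path shifts by a constant box multiple, invisible to MSD
            whole0 = make_whole(traj.frames[0].coords[selection], traj.frames[0].box)
            coords += (whole0 - coords[0])[None, :, :]
        w = traj.masses(selection)
        coords = np.average(coords, axis=1, weights=w)[:, None, :]
    elif mode != "per_particle":
        raise ValueError(f"mode must be 'per_particle' or 'com', got {mode!r}")
    n_lag = max(2, int(np.floor(traj.n_frames * max_lag_fraction)))
    acc = np.zeros(traj.n_frames)
    for p in range(coords.shape[1]):
        acc += _msd_fft_single(np.ascontiguousarray(coords[:, p, :]))
    series = acc[:n_lag] / coords.shape[1]
    series[0] = 0.0
    return MsdResult(lags=np.arange(n_lag) * dts[0], msd=series,
                     n_entities=coords.shape[1])


@dataclass
class BetaResult:
    lags: np.ndarray          # positive lags only, ps
    beta: np.ndarray          # local log-log slope
    window: Optional[tuple[int, int]]   # [start, stop) into ``lags``; None if none
    diffusive: bool

    def window_lags(self) -> Optional[tuple[float, float]]:
        if self.window is None:
            return None
        return float(self.lags[self.window[0]]), float(self.lags[self.window[1] - 1])


def beta_exponent(result: MsdResult, tolerance: float = BETA_TOL,
                  min_fraction: float = MIN_WINDOW_FRACTION) -> BetaResult:
    """beta(tau) by centred log-log finite differences, plus the diffusive window."""
    pos = result.lags > 0
    lags, series = result.lags[pos], result.msd[pos]
    if len(lags) < 5:
        raise ValueError("beta needs at least 5 positive-lag points")
    if np.any(series <= 0):
        raise ValueError("MSD must be positive at positive lags for the log-log slope")
    lt, lm = np.log(lags), np.log(series)
    beta = np.gradient(lm, lt)
    ok = np.abs(beta - 1.0) <= tolerance
    best: Optional[tuple[int, int]] = None
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if best is None or i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    diffusive = best is not None and (best[1] - best[0]) >= min_fraction * len(lags)
    return BetaResult(lags=lags, beta=beta, window=best, diffusive=diffusive)


def diffusion_coefficient(result: MsdResult,
                          window: Optional[tuple[int, int]] = None) -> tuple[float, float]:
    """Einstein-relation D = slope/6 over a lag window; returns (D, fit SE) in nm^2/ps.

    ``window`` is a [start, stop) index pair into the positive-lag series
    (e.g. from :func:`beta_exponent`); default fits the second half of the
    lags.  Any additive MSD offset is absorbed by the intercept.
    """
    pos = result.lags > 0
    lags, series = result.lags[pos], result.msd[pos]
    if window is None:
        window = (len(lags) // 2, len(lags))
    i0, i1 = window
    if i1 - i0 < 3:
        raise ValueError("fit window must contain at least 3 points")
    fit = stats.linregress(lags[i0:i1], series[i0:i1])
    return float(fit.slope / 6.0), float((fit.stderr or 0.0) / 6.0)


def relative_error(x_exp: float, x_sim: float) -> float:
    """|X_exp - X_sim| / X_exp * 100, the percent deviation from experiment."""
    if x_exp == 0:
        raise ValueError("experimental reference must be nonzero")
    return abs(x_exp - x_sim) / abs(x_exp) * 100.0
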