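"""Centroid mean-square displacement and the ballistic/diffusive crossover.

The time-averaged MSD of a persistent random walker grows as (v dT)^2 at
lags below the persistence time and linearly at long lags.  Two lines are
fitted in log-log space — slope 2 over the short-lag window and slope 1 over
the long-lag window (free intercepts) — and their intersection defines the
persistence time tau0; X0 = sqrt(MSD(tau0)) in units of the mean cell
length is the persistence length.  A free-slope fit over the short-lag
window is also reported (the ballistic-regime exponent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MSDResult", "time_averaged_msd", "msd_persistence"]


@dataclass
class MSDResult:
    lags: np.ndarray          # s
    msd: np.ndarray           # (cell lengths)^2 if normalized, else um^2
    tau0: float | None        # s; None when unresolved within the lag range
    x0: float | None          # sqrt(MSD at tau0), same length unit as msd
    short_slope: float        # free-slope log-log fit over the short window
    long_slope: float         # free-slope log-log fit over the long window
    short_intercept: float    # intercept of the fixed slope-2 line
    long_intercept: float     # intercept of the fixed slope-1 line
    cell_length: float        # normalization length (1.0 if not normalized)

    @property
    def resolved(self) -> bool:
        return self.tau0 is not None


def time_averaged_msd(track: np.ndarray, frame_interval: float,
                      max_lag_fraction: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD over all start times, lags up to a fraction of the
    track duration (longer lags are too noisy to average)."""
    track = np.asarray(track, dtype=float)
    n = len(track)
    max_lag = max(2, int(n * max_lag_fraction))
    lags = np.arange(1, max_lag + 1)
    msd = np.array([((track[k:] - track[:-k]) ** 2).sum(axis=1).mean() for k in lags])
    return lags * frame_interval, msd


def _loglog_intercept(lags: np.ndarray, msd: np.ndarray, slope: float) -> float:
    return float(np.mean(np.log(msd) - slope * np.log(lags)))


def msd_persistence(
    track: np.ndarray,
    frame_interval: float,
    cell_length: float = 1.0,
    short_fraction: float = 0.2,
    long_fraction: float = 0.5,
    max_lag_fraction: float = 0.25,
) -> MSDResult:
    """MSD crossover analysis of a centroid track.

    track : (n, 2) positions in um, n >= 50.
    cell_length : mean cell length along the moving direction (um); MSD is
        reported in squared cell lengths.
    short_fraction / long_fraction : the short-window covers lags up to
        ``short_fraction`` of the maximum lag, the long-window lags beyond
        ``long_fraction``.
    """
    track = np.asarray(track, dtype=float)
    if len(track) < 50:
        raise ValueError("MSD persistence analysis needs at least 50 frames")
    if cell_length <= 0:
        raise ValueError("cell_length must be positive")
    lags, msd = time_averaged_msd(track, frame_interval, max_lag_fraction)
    msd = msd / cell_length**2
    positive = msd > 0
    lags, msd = lags[positive], msd[positive]
    if len(lags) < 4:
        raise ValueError("track is effectively stationary; MSD fit impossible")

    lag_max = lags[-1]
    short = lags <= short_fraction * lag_max
    long = lags >= long_fraction * lag_max
    if short.sum() < 2:
        short = np.zeros_like(lags, bool)
        short[:2] = True
    if long.sum() < 2:
        long = np.zeros_like(lags, bool)
        long[-2:] = True

    # free-slope fits (the ballistic / diffusive exponents of the data)
    short_slope = float(np.polyfit(np.log(lags[short]), np.log(msd[short]), 1)[0])
    long_slope = float(np.polyfit(np.log(lags[long]), np.log(msd[long]), 1)[0])

    b_short = _loglog_intercept(lags[short], msd[short], 2.0)
    b_long = _loglog_intercept(lags[long], msd[long], 1.0)
    # slope-2 and slope-1 lines intersect at log(tau0) = b_long - b_short
    tau0 = float(np.exp(b_long - b_short))
    # a crossover is only meaningful when the two windows actually sit in
    # different regimes: still-ballistic long lags (slope ~2) or
    # never-ballistic short lags (slope ~1) leave tau0 unresolved
    if short_slope >= 1.5 and long_slope <= 1.5 and lags[0] <= tau0 <= lag_max:
        x0 = float(np.sqrt(np.exp(np.interp(np.log(tau0), np.log(lags), np.log(msd)))))
    else:
        tau0, x0 = None, None
    return MSDResult(
        lags=lags, msd=msd, tau0=tau0, x0=x0, short_slope=short_slope,
        long_slope=long_slope, short_intercept=b_short, long_intercept=b_long,
        cell_length=cell_length,
    )
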