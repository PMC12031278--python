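"""Side-motion identification via the global wavelet spectrum.

After fusion, gravity sits on the world Y axis and the skier's lateral
(turning) and fore–aft motions are distributed over the two horizontal
axes X and Z.  Turning produces a strong periodicity at the turn
cadence, so the horizontal axis whose *global wavelet spectrum*
(time-averaged wavelet power per scale) peaks higher is taken as the
side-motion axis; the other becomes forward.  The assembled Skier
Fixed Reference Frame (SFRF) signal set is (up, side, forward).

The analysing wavelet is the complex Morlet with centre frequency 6
(the standard choice for time-averaged spectra); scales are laid out
logarithmically, 8 voices per octave, over periods 0.5–16 s, which
covers turn cadences from short-radius to long-radius techniques.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .fusion import WorldAccel

logger = logging.getLogger(__name__)

__all__ = [
    "GlobalWaveletSpectrum",
    "SfrfSignals",
    "global_wavelet_spectrum",
    "select_side_axis",
    "to_sfrf",
    "SideMotionTransformer",
]

# complex Morlet, omega0 = 6: pywt 'cmorB-C' with B = 2, C = 6 / (2*pi)
_MORLET_C = 6.0 / (2.0 * np.pi)
_WAVELET = f"cmor2.0-{_MORLET_C:.16f}"


@dataclass
class GlobalWaveletSpectrum:
    """Time-averaged wavelet power per scale.

    ``degenerate`` marks a constant/zero input whose power is all-zero
    and whose peak is undefined.
    """

    periods: np.ndarray
    power: np.ndarray
    peak_period: float
    peak_power: float
    degenerate: bool = False


@dataclass
class SfrfSignals:
    """Skier-Fixed-Reference-Frame acceleration set."""

    t: np.ndarray
    up: np.ndarray
    side: np.ndarray
    forward: np.ndarray
    side_axis_label: str        # "X" or "Z": world axis selected as side
    side_power: float
    forward_power: float


def _period_grid(period_range: tuple[float, float], voices_per_octave: int) -> np.ndarray:
    lo, hi = period_range
    n_oct = np.log2(hi / lo)
    n = int(round(n_oct * voices_per_octave)) + 1
    return lo * 2.0 ** (np.arange(n) / voices_per_octave)


def global_wavelet_spectrum(signal, fs: float,
                            period_range: tuple[float, float] = (0.5, 16.0),
                            voices_per_octave: int = 8) -> GlobalWaveletSpectrum:
    """Continuous-wavelet power averaged over time, per scale.

    The signal is de-meaned internally.  Requires at least 4 s of data
    so the shortest turn cadences are resolvable.
    """
    x = np.asarray(signal, dtype=float)
    if len(x) < 4 * fs:
        raise ValueError("global wavelet spectrum needs at least 4 s of data")
    periods = _period_grid(period_range, voices_per_octave)
    x = x - x.mean()
    if float(np.max(np.abs(x))) == 0.0:
        power = np.zeros_like(periods)
        return GlobalWaveletSpectrum(periods, power, float("nan"), 0.0, degenerate=True)
    scales = periods * _MORLET_C * fs
    coef, _ = pywt.cwt(x, scales, _WAVELET, sampling_period=1.0 / fs, method="fft")
    power = np.mean(np.abs(coef) ** 2, axis=1)
    k = int(np.argmax(power))
    return GlobalWaveletSpectrum(periods, power, float(periods[k]), float(power[k]))


def select_side_axis(x_series, z_series, fs: float, **gws_kwargs):
    """Pick the horizontal axis with the higher global-wavelet-spectrum peak.

    Returns ``(side, forward, label)``; ties break toward X with a
    logged warning.  Raises when both candidates are degenerate
    (no periodic motion present).
    """
    x_series = np.asarray(x_series, dtype=float)
    z_series = np.asarray(z_series, dtype=float)
    if x_series.shape != z_series.shape:
        raise ValueError("candidate series must have equal length")
    gx = global_wavelet_spectrum(x_series, fs, **gws_kwargs)
    gz = global_wavelet_spectrum(z_series, fs, **gws_kwargs)
    if gx.degenerate and gz.degenerate:
        raise ValueError("no periodic motion detected on either horizontal axis")
    if gx.peak_power == gz.peak_power:
        logger.warning("global wavelet spectra tie exactly; side axis broken toward X")
    if gz.peak_power > gx.peak_power:
        return z_series, x_series, "Z"
    return x_series, z_series, "X"


def to_sfrf(world: WorldAccel, fs: float, **gws_kwargs) -> SfrfSignals:
    """Assemble (up, side, forward) from fused world-frame acceleration.

    Up is the world Y series unmodified; side/forward come from the
    wavelet comparison of the X and Z series over the whole run (a
    per-run decision, so the axis cannot flip mid-recording).
    """
    x, y, z = world.accel[:, 0], world.accel[:, 1], world.accel[:, 2]
    gx = global_wavelet_spectrum(x, fs, **gws_kwargs)
    gz = global_wavelet_spectrum(z, fs, **gws_kwargs)
    if gx.degenerate and gz.degenerate:
        raise ValueError("no periodic motion detected on either horizontal axis")
    if gz.peak_power > gx.peak_power:
        side, forward, label = z, x, "Z"
        p_side, p_fwd = gz.peak_power, gx.peak_power
    else:
        if gx.peak_power == gz.peak_power:
            logger.warning("global wavelet spectra tie exactly; side axis broken toward X")
        side, forward, label = x, z, "X"
        p_side, p_fwd = gx.peak_power, gz.peak_power
    return SfrfSignals(t=world.t, up=y, side=side, forward=forward,
                       side_axis_label=label, side_power=p_side, forward_power=p_fwd)


class SideMotionTransformer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer reordering world axes to (up, side, forward).

    Input ``X`` is the ``(n, 3)`` world-frame acceleration from
    :class:`~skiturn.fusion.ComplementaryFilter` (columns x, y, z with
    y up).  ``fit`` runs the wavelet comparison and stores
    ``side_axis_label_``, ``side_power_``, ``forward_power_``;
    ``transform`` returns columns ``[up, side, forward]``.
    """

    def __init__(self, fs: float = 50.0,
                 period_range: tuple[float, float] = (0.5, 16.0),
                 voices_per_octave: int = 8):
        self.fs = fs
        self.period_range = period_range
        self.voices_per_octave = voices_per_octave

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be an (n, 3) world-frame acceleration array")
        kw = dict(period_range=self.period_range, voices_per_octave=self.voices_per_octave)
        _, _, label = select_side_axis(X[:, 0], X[:, 2], self.fs, **kw)
        gx = global_wavelet_spectrum(X[:, 0], self.fs, **kw)
        gz = global_wavelet_spectrum(X[:, 2], self.fs, **kw)
        self.side_axis_label_ = label
        self.side_power_ = gx.peak_power if label == "X" else gz.peak_power
        self.forward_power_ = gz.peak_power if label == "X" else gx.peak_power
        self.n_features_in_ = 3
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "side_axis_label_"):
            raise ValueError("SideMotionTransformer is not fitted yet")
        X = np.asarray(X, dtype=float)
        side_col = 0 if self.side_axis_label_ == "X" else 2
        fwd_col = 2 if self.side_axis_label_ == "X" else 0
        return np.column_stack([X[:, 1], X[:, side_col], X[:, fwd_col]])
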