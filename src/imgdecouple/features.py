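"""Decoupling features computed from processed CG kinematics.

Seven candidate features discriminate coupled from decoupled events; the
final classifier uses four of them:

* f1 — percent of spectral amplitude between 100 and 500 Hz on linear
  acceleration Z (band CDF difference),
* f3 — the same band CDF on angular acceleration Y,
* f4 — 1-based rank (in time order) of the global maximum among the
  post-trigger local maxima of the resultant linear acceleration,
* f7 — time (ms after trigger) of the spectrogram's global maximum on
  angular acceleration Y, from a Hamming-windowed STFT with 12-ms
  segments and 90% overlap.

Optional features f2 (band CDF, angular acceleration X), f5 and f6 (STFT
max times on linear Z and angular X) are available for completeness.

A tightly coupled impact concentrates its energy in a low-frequency pulse
shortly after the trigger; mouthguard decoupling superimposes late
100-500 Hz oscillations, raising the band CDFs, pushing the global peak
later in the peak order and delaying the spectrogram maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import ShortTimeFFT, find_peaks, get_window

from .errors import SignalLengthError, UndefinedFeatureError
from .signals import CgKinematics, ChannelSignal

FINAL_FEATURES = ("f1", "f3", "f4", "f7")
ALL_FEATURES = ("f1", "f2", "f3", "f4", "f5", "f6", "f7")


@dataclass
class FeatureConfig:
    """Spectral-feature settings.

    The FFT is zero-padded to ``fft_pad_factor`` times the signal length;
    the STFT uses ``stft_window_ms`` Hamming windows with
    ``stft_overlap_frac`` overlap.
    """

    band_lo_hz: float = 100.0
    band_hi_hz: float = 500.0
    fft_pad_factor: int = 5
    stft_window_ms: float = 12.0
    stft_overlap_frac: float = 0.90
    stft_window_shape: str = "hamming"
    #: how spectral "content" is cumulated into the CDF: 'power' weights
    #: each bin by squared amplitude (energy distribution; a pure in-band
    #: tone then concentrates >99% in its band), 'amplitude' by |FFT|
    #: directly (rectangular-window leakage then leaves ~10-15% of the
    #: amplitude mass outside the band of even a pure tone)
    spectrum_weight: str = "power"

    def validate(self, sample_rate: float) -> None:
        if not 0 <= self.band_lo_hz < self.band_hi_hz <= sample_rate / 2:
            raise ValueError("need 0 <= band_lo < band_hi <= Nyquist")
        if not 0 <= self.stft_overlap_frac < 1:
            raise ValueError("overlap fraction must be in [0, 1)")
        if self.spectrum_weight not in ("power", "amplitude"):
            raise ValueError("spectrum_weight must be 'power' or 'amplitude'")


@dataclass
class FeatureVector:
    """The four model features plus optional extras for one event."""

    f1: float  # percent
    f3: float  # percent
    f4: int  # global-peak order, >= 1
    f7: float  # ms
    event_id: str = ""
    f2: Optional[float] = None
    f5: Optional[float] = None
    f6: Optional[float] = None

    def as_array(self) -> np.ndarray:
        """Feature values in the model's canonical order (f1, f3, f4, f7)."""
        return np.array([self.f1, self.f3, float(self.f4), self.f7])


def band_cdf_fraction(sig: ChannelSignal, cfg: FeatureConfig = FeatureConfig()) -> float:
    """Percent of one-sided spectral content between the band edges.

    The signal is zero-padded (appended zeros) to ``fft_pad_factor`` times
    its length; the one-sided spectrum ``|FFT| * 2 / N`` is truncated at
    Nyquist and weighted per ``cfg.spectrum_weight`` (power by default).
    The returned value is ``CDF(band_hi) - CDF(band_lo)`` of the normalised
    spectral-content distribution, i.e. the percent of total content whose
    frequency lies inside [band_lo, band_hi].  Scale-invariant by
    construction; the full band (0, Nyquist) gives exactly 100%.
    """
    cfg.validate(sig.sample_rate)
    x = sig.samples
    if not np.any(x):
        raise UndefinedFeatureError("band CDF undefined for an all-zero signal")
    n = len(x)
    n_fft = n * cfg.fft_pad_factor
    spec = np.abs(np.fft.rfft(x, n=n_fft)) * 2.0 / n
    if cfg.spectrum_weight == "power":
        spec = spec ** 2
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sig.sample_rate)
    keep = freqs <= sig.sample_rate / 2
    spec, freqs = spec[keep], freqs[keep]
    band = (freqs >= cfg.band_lo_hz) & (freqs <= cfg.band_hi_hz)
    return float(spec[band].sum() / spec.sum() * 100.0)


def global_peak_order(res: ChannelSignal) -> int:
    """Rank of the global maximum among post-trigger local maxima.

    Local maxima are strict-neighbour peaks (plateaus collapse to their
    first sample, no prominence threshold); any peak before t = 0 is
    discarded as a pre-trigger artifact.  Returns the 1-based position of
    the largest remaining peak in time order, ties resolving to the
    earliest.
    """
    peaks, _ = find_peaks(res.samples)
    peaks = peaks[peaks >= res.trigger_index]
    if len(peaks) == 0:
        raise UndefinedFeatureError("no post-trigger local maximum")
    order = int(np.argmax(res.samples[peaks])) + 1  # argmax -> earliest tie
    return order


def stft_max_time(sig: ChannelSignal, cfg: FeatureConfig = FeatureConfig()) -> float:
    """Time (ms after trigger) of the spectrogram's global maximum.

    Hamming-windowed STFT with ``stft_window_ms`` segments and
    ``stft_overlap_frac`` overlap; the returned time is the center of the
    time bin holding the largest magnitude.  Bins centred before the
    trigger are eligible.
    """
    cfg.validate(sig.sample_rate)
    nperseg = int(round(cfg.stft_window_ms * 1e-3 * sig.sample_rate))
    if len(sig) <= nperseg:
        raise SignalLengthError("signal shorter than one STFT window")
    hop = max(1, int(round(nperseg * (1 - cfg.stft_overlap_frac))))
    win = get_window(cfg.stft_window_shape, nperseg)
    stft = ShortTimeFFT(win, hop=hop, fs=sig.sample_rate)
    Z = stft.stft(sig.samples)
    t_bins = stft.t(len(sig))  # seconds from the first sample
    _, j = np.unravel_index(np.argmax(np.abs(Z)), Z.shape)
    t_trigger = t_bins[j] - sig.trigger_index / sig.sample_rate
    return float(t_trigger * 1e3)


def extract_features(kin: CgKinematics,
                     cfg: FeatureConfig = FeatureConfig(),
                     include_optional: bool = False,
                     event_id: str = "") -> FeatureVector:
    """Assemble the model feature vector from processed kinematics.

    Axis assignments: f1 on linear acceleration Z, f2 on angular
    acceleration X, f3 on angular acceleration Y, f4 on the resultant
    linear acceleration, f5/f6/f7 STFT times on linear Z / angular X /
    angular Y.
    """
    lin_z = kin.lin_acc_cg[2]
    aacc_x, aacc_y = kin.ang_acc[0], kin.ang_acc[1]

    def _wrap(fid, func, *args):
        try:
            return func(*args)
        except UndefinedFeatureError as err:
            raise UndefinedFeatureError(f"{fid}: {err}") from err

    fv = FeatureVector(
        f1=_wrap("f1", band_cdf_fraction, lin_z, cfg),
        f3=_wrap("f3", band_cdf_fraction, aacc_y, cfg),
        f4=_wrap("f4", global_peak_order, kin.resultant_lin),
        f7=_wrap("f7", stft_max_time, aacc_y, cfg),
        event_id=event_id,
    )
    if include_optional:
        fv.f2 = _wrap("f2", band_cdf_fraction, aacc_x, cfg)
        fv.f5 = _wrap("f5", stft_max_time, lin_z, cfg)
        fv.f6 = _wrap("f6", stft_max_time, aacc_x, cfg)
    return fv
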