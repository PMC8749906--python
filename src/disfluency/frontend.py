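"""Auditory front-end: 512-point FFT frames, A-weighting, 21 third-octave
band levels.

A 4-s, 22,050-Hz utterance is cut into consecutive non-overlapping
512-sample frames (~23.2 ms).  Each frame's power spectrum is A-weighted
and summed into base-ten one-third-octave bands with nominal centre
frequencies 100 Hz ... 10,000 Hz (21 bands), giving a 171 x 21 matrix of
band levels in dB — a coarse loudness-like representation of the signal as
the ear delivers it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .synth import Utterance

__all__ = [
    "FRAME_LEN",
    "N_FRAMES",
    "EXPECTED_FS",
    "BandTable",
    "FilterbankMatrix",
    "UnsupportedRateError",
    "third_octave_bands",
    "a_weighting_gain",
    "analyze",
    "ThirdOctaveFrontend",
]

FRAME_LEN = 512
N_FRAMES = 171
EXPECTED_FS = 22_050

#: linear-power floor added before taking logs so silence stays finite
POWER_FLOOR = 1e-12


class UnsupportedRateError(ValueError):
    """Raised for sampling rates other than the supported 22,050 Hz."""


@dataclass(frozen=True)
class BandTable:
    """Base-ten third-octave bands: contiguous, edge ratio 10^(1/10)."""

    centre_freqs: np.ndarray
    lower_edges: np.ndarray
    upper_edges: np.ndarray

    def __len__(self) -> int:
        return len(self.centre_freqs)


@dataclass
class FilterbankMatrix:
    """Per-frame third-octave band levels (dB) for one utterance."""

    levels: np.ndarray
    frame_duration: float
    band_centers: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.float64)
        self.band_centers = np.asarray(self.band_centers, dtype=np.float64)

    @property
    def shape(self):
        return self.levels.shape

    def frame_times(self) -> np.ndarray:
        return np.arange(self.levels.shape[0]) * self.frame_duration

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.levels,
                            columns=[f"{c:g}" for c in self.band_centers])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_duration: float = FRAME_LEN / EXPECTED_FS
                 ) -> "FilterbankMatrix":
        df = pd.read_csv(path)
        return cls(levels=df.to_numpy(dtype=np.float64),
                   frame_duration=frame_duration,
                   band_centers=np.asarray([float(c) for c in df.columns]),
                   sample_id=Path(path).stem)


def third_octave_bands(fmin: float = 100.0, fmax: float = 10_000.0
                       ) -> BandTable:
    """Base-ten third-octave bands with exact centres 10^(n/10) Hz.

    With the defaults this yields the 21 nominal centres
    100, 125, 160, ..., 8000, 10000 Hz; band edges are fc * 10^(∓1/20) so
    adjacent bands tile the axis exactly.
    """
    if not 0 < fmin < fmax:
        raise ValueError("need 0 < fmin < fmax")
    n_lo = int(np.ceil(10 * np.log10(fmin) - 1e-9))
    n_hi = int(np.floor(10 * np.log10(fmax) + 1e-9))
    if n_hi < n_lo:
        raise ValueError("no third-octave centre inside [fmin, fmax]")
    n = np.arange(n_lo, n_hi + 1)
    fc = 10.0 ** (n / 10.0)
    return BandTable(centre_freqs=fc,
                     lower_edges=fc * 10.0 ** (-1 / 20),
                     upper_edges=fc * 10.0 ** (1 / 20))


# IEC 61672 A-weighting pole frequencies (Hz)
_A_F1 = 20.598997
_A_F2 = 107.65265
_A_F3 = 737.86223
_A_F4 = 12194.217


def _ra(f: np.ndarray) -> np.ndarray:
    f2 = f * f
    return (_A_F4**2 * f2 * f2) / (
        (f2 + _A_F1**2)
        * np.sqrt((f2 + _A_F2**2) * (f2 + _A_F3**2))
        * (f2 + _A_F4**2)
    )


def a_weighting_gain(freq) -> np.ndarray | float:
    """A-weighting as a linear *power* gain, exactly 1 at 1,000 Hz.

    The amplitude response follows the IEC 61672 analytic form; it is
    renormalised at 1 kHz (the standard's +2.0 dB offset is equivalent up to
    rounding).  At 100 Hz the response is about -19.1 dB.
    """
    f = np.asarray(freq, dtype=np.float64)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    amp = _ra(f) / _ra(np.asarray(1000.0))
    out = amp * amp
    return float(out) if np.isscalar(freq) else out


def analyze(utterance: Utterance, a_weighting: bool = True,
            bands: BandTable | None = None,
            floor: float = POWER_FLOOR) -> FilterbankMatrix:
    """Transform a waveform into the 171 x 21 band-level matrix.

    Consecutive non-overlapping 512-sample frames are analysed with a plain
    (rectangular-window) FFT; per-bin powers are A-weighted and summed into
    the third-octave bands by proportional bin/band overlap; levels are
    10*log10(power + floor) dB.  A 4-s signal contains 172 complete frames;
    only the first 171 are retained so the output shape is exact.
    """
    if utterance.fs != EXPECTED_FS:
        raise UnsupportedRateError(
            f"expected fs={EXPECTED_FS} Hz, got {utterance.fs}")
    x = np.asarray(utterance.samples, dtype=np.float64)
    needed = N_FRAMES * FRAME_LEN
    if len(x) < needed:
        raise ValueError(
            f"signal too short: need >= {needed} samples, got {len(x)}")
    if bands is None:
        bands = third_octave_bands()

    frames = x[:needed].reshape(N_FRAMES, FRAME_LEN)
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2 / FRAME_LEN
    freqs = np.fft.rfftfreq(FRAME_LEN, d=1.0 / utterance.fs)

    # Each FFT bin covers a frequency interval of width fs/FRAME_LEN; its
    # power is shared among the bands proportionally to the overlap of that
    # interval with each band.  (The lowest bands are narrower than one bin
    # at this resolution, so a hard bin-to-band assignment would leave the
    # 100 Hz band empty.)  Overlap weighting conserves in-range power.
    df = utterance.fs / FRAME_LEN
    bin_lo, bin_hi = freqs - df / 2, freqs + df / 2
    overlap = (np.minimum(bin_hi[:, None], bands.upper_edges[None, :])
               - np.maximum(bin_lo[:, None], bands.lower_edges[None, :]))
    W = np.clip(overlap, 0.0, None) / df            # (n_bins, n_bands)
    power = spec
    if a_weighting:
        pos = freqs > 0
        gains = np.zeros_like(freqs)
        gains[pos] = a_weighting_gain(freqs[pos])
        power = power * gains[None, :]

    band_power = power @ W
    levels = 10.0 * np.log10(band_power + floor)
    return FilterbankMatrix(levels=levels,
                            frame_duration=FRAME_LEN / utterance.fs,
                            band_centers=bands.centre_freqs,
                            sample_id=utterance.id)


class ThirdOctaveFrontend(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer wrapping :func:`analyze`.

    ``transform`` maps a sequence of :class:`~disfluency.synth.Utterance`
    objects to a list of :class:`FilterbankMatrix`.
    """

    def __init__(self, a_weighting: bool = True, fmin: float = 100.0,
                 fmax: float = 10_000.0, floor: float = POWER_FLOOR):
        self.a_weighting = a_weighting
        self.fmin = fmin
        self.fmax = fmax
        self.floor = floor

    def fit(self, X=None, y=None):
        self.bands_ = third_octave_bands(self.fmin, self.fmax)
        return self

    def transform(self, X) -> list[FilterbankMatrix]:
        if not hasattr(self, "bands_"):
            self.fit()
        return [analyze(u, a_weighting=self.a_weighting, bands=self.bands_,
                        floor=self.floor) for u in X]
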