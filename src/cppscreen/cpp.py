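"""Cepstral peak prominence (CPP) extraction from sustained-vowel audio.

CPP quantifies how periodic (harmonic) a voice is: the windowed frame is
transformed to the cepstral domain, the cepstrum is smoothed along the
quefrency axis, and the prominence of the dominant peak inside the band of
plausible fundamental periods is measured as ``max - mean(rest of band)``.
The per-frame values are then smoothed along the frame (temporal) axis.
Hoarse, dysphonic voices have flatter cepstra and hence lower CPP.

Defaults encode the reference analysis at 16 kHz: 1024-sample frames with
87.5 % overlap (hop 128), Hamming analysis window, 7-tap unit-sum Hamming
smoothers in both directions, and a quefrency band of 22-400 samples
(fundamental frequencies of roughly 40-727 Hz at 16 kHz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import get_window
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ConfigError, TooShortError, ValidationError

logger = logging.getLogger(__name__)

REFERENCE_RATE = 16_000


@dataclass(frozen=True)
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples : ndarray of shape (n_samples,)
        Amplitudes, nominally in [-1, 1].
    rate : float
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValidationError(
                f"expected a single-channel signal, got shape {samples.shape}; "
                "downmix multi-channel audio before extraction"
            )
        if samples.size < 1:
            raise ValidationError("signal must contain at least one sample")
        if not self.rate > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.rate

    @classmethod
    def from_wav(cls, path) -> "AudioSignal":
        """Read a PCM or float WAV file; multi-channel input is rejected."""
        rate, data = wavfile.read(path)
        if data.ndim > 1:
            raise ValidationError(
                f"{path}: {data.shape[1]}-channel WAV not supported; "
                "downmix to mono first"
            )
        if np.issubdtype(data.dtype, np.integer):
            data = data / float(-np.iinfo(data.dtype).min)
        return cls(samples=np.asarray(data, dtype=float), rate=float(rate))

    def to_wav(self, path) -> None:
        wavfile.write(path, int(self.rate), self.samples.astype(np.float32))


@dataclass(frozen=True)
class FramingConfig:
    """Short-time analysis parameters: frame length, hop and window shape."""

    frame_len: int = 1024
    hop: int = 128
    window_kind: str = "hamming"

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.frame_len):
            raise ConfigError(
                f"need 0 < hop <= frame_len, got hop={self.hop}, "
                f"frame_len={self.frame_len}"
            )


@dataclass(frozen=True)
class CepstralConfig:
    """Cepstral band limits and smoothing-filter lengths.

    ``tmin``/``tmax`` are quefrency indices (samples) bounding the plausible
    fundamental periods; at 16 kHz the defaults 22-400 cover ~40-727 Hz.
    ``smooth_len_cepstral`` / ``smooth_len_temporal`` are the tap counts of
    the unit-sum Hamming-shaped FIR smoothers. ``log_floor`` guards the log
    of zero magnitudes (all-silence frames).
    """

    smooth_len_cepstral: int = 7
    tmin: int = 22
    tmax: int = 400
    smooth_len_temporal: int = 7
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if not (3 <= self.tmin < self.tmax):
            raise ConfigError(
                f"need 3 <= tmin < tmax, got tmin={self.tmin}, tmax={self.tmax}"
            )
        if self.smooth_len_cepstral < 1 or self.smooth_len_temporal < 1:
            raise ConfigError("smoothing filter lengths must be >= 1")
        if not self.log_floor > 0:
            raise ConfigError("log_floor must be positive")


@dataclass(frozen=True)
class CppSeries:
    """Per-frame CPP values (raw and temporally smoothed) for one recording."""

    raw: np.ndarray
    smoothed: np.ndarray
    hop_seconds: float

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        smoothed = np.asarray(self.smoothed, dtype=float)
        if raw.shape != smoothed.shape:
            raise ValidationError("raw and smoothed series must have equal length")
        object.__setattr__(self, "raw", raw)
        object.__setattr__(self, "smoothed", smoothed)

    def __len__(self) -> int:
        return self.raw.size

    def to_frame(self) -> pd.DataFrame:
        n = self.raw.size
        return pd.DataFrame(
            {
                "frame_index": np.arange(n),
                "time_s": np.arange(n) * self.hop_seconds,
                "cpp_raw": self.raw,
                "cpp_smoothed": self.smoothed,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def n_frames(n_samples: int, cfg: FramingConfig) -> int:
    """Number of full frames a signal of ``n_samples`` yields (no padding)."""
    if n_samples < cfg.frame_len:
        return 0
    return (n_samples - cfg.frame_len) // cfg.hop + 1


def frame_signal(signal: AudioSignal, cfg: FramingConfig = FramingConfig()) -> np.ndarray:
    """Slice a signal into overlapping frames.

    Frame ``i`` covers samples ``[i*hop, i*hop + frame_len)``; trailing
    samples that do not fill a frame are discarded.

    Returns
    -------
    ndarray of shape (n_frames, frame_len)
    """
    x = signal.samples
    if x.size < cfg.frame_len:
        raise TooShortError(
            f"signal of {x.size} samples is shorter than one frame; "
            f"at least {cfg.frame_len} samples are required"
        )
    view = np.lib.stride_tricks.sliding_window_view(x, cfg.frame_len)
    return np.ascontiguousarray(view[:: cfg.hop])


def _analysis_window(cfg: FramingConfig) -> np.ndarray:
    return get_window(cfg.window_kind, cfg.frame_len, fftbins=False)


def compute_cepstrum(
    frame: np.ndarray,
    cfg: FramingConfig = FramingConfig(),
    ccfg: CepstralConfig = CepstralConfig(),
) -> np.ndarray:
    """Real cepstrum of one windowed frame.

    ``real(IFFT(log(max(|FFT(x * w)|, log_floor))))`` with a Hamming analysis
    window ``w`` and the natural logarithm. Output length equals the frame
    length; a peak at quefrency ``q`` indicates periodicity with fundamental
    period ``q`` samples.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (cfg.frame_len,):
        raise ValidationError(
            f"frame must have length {cfg.frame_len}, got shape {frame.shape}"
        )
    if not np.all(np.isfinite(frame)):
        raise ValidationError("frame contains non-finite values")
    spectrum = np.fft.fft(frame * _analysis_window(cfg))
    log_mag = np.log(np.maximum(np.abs(spectrum), ccfg.log_floor))
    return np.fft.ifft(log_mag).real


def _unit_sum_hamming(ntaps: int) -> np.ndarray:
    a = get_window("hamming", ntaps, fftbins=False)
    return a / a.sum()


def _causal_fir(x: np.ndarray, ntaps: int) -> np.ndarray:
    """Causal unit-sum Hamming FIR; leading edge renormalized over the taps
    actually applied so that constant inputs are preserved everywhere."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    a = _unit_sum_hamming(ntaps)
    y = np.convolve(x, a)[: x.size]
    n_edge = min(ntaps - 1, x.size)
    if n_edge:
        y[:n_edge] /= np.cumsum(a)[:n_edge]
    return y


def smooth_cepstrum(c: np.ndarray, ccfg: CepstralConfig = CepstralConfig()) -> np.ndarray:
    """Smooth a cepstrum frame along the quefrency axis (removes spurious
    ripples while keeping the true peak)."""
    return _causal_fir(c, ccfg.smooth_len_cepstral)


def cpp_of_frame(cf: np.ndarray, ccfg: CepstralConfig = CepstralConfig()) -> float:
    """Peak prominence of a (smoothed) cepstrum frame.

    The frame is restricted to quefrencies ``[tmin, tmax]`` inclusive; the
    prominence is the band maximum minus the mean of the remaining band
    values, i.e. ``max - (sum - max) / (tmax - tmin)``.
    """
    cf = np.asarray(cf, dtype=float)
    if ccfg.tmax >= cf.size:
        raise ConfigError(
            f"quefrency band [{ccfg.tmin}, {ccfg.tmax}] out of range for a "
            f"cepstrum of length {cf.size}"
        )
    band = cf[ccfg.tmin : ccfg.tmax + 1]
    peak = band.max()
    return float(peak - (band.sum() - peak) / (ccfg.tmax - ccfg.tmin))


def band_argmax(cf: np.ndarray, ccfg: CepstralConfig = CepstralConfig()) -> int:
    """Quefrency (absolute index) of the band-limited cepstral maximum."""
    cf = np.asarray(cf, dtype=float)
    if ccfg.tmax >= cf.size:
        raise ConfigError("quefrency band out of range")
    return int(ccfg.tmin + np.argmax(cf[ccfg.tmin : ccfg.tmax + 1]))


def smooth_cpp_series(raw, ccfg: CepstralConfig = CepstralConfig()) -> np.ndarray:
    """Smooth the per-frame CPP vector along the frame (temporal) axis."""
    return _causal_fir(np.asarray(raw, dtype=float), ccfg.smooth_len_temporal)


def extract_cpp(
    signal: AudioSignal,
    cfg: FramingConfig = FramingConfig(),
    ccfg: CepstralConfig = CepstralConfig(),
) -> CppSeries:
    """Full CPP pipeline: frame -> cepstrum -> cepstral smoothing ->
    band-limited prominence -> temporal smoothing."""
    if signal.rate != REFERENCE_RATE:
        logger.warning(
            "sampling rate %s Hz != %s Hz: tmin/tmax defaults (%s, %s samples) "
            "are calibrated for the 16 kHz fundamental-frequency range",
            signal.rate,
            REFERENCE_RATE,
            ccfg.tmin,
            ccfg.tmax,
        )
    frames = frame_signal(signal, cfg)
    window = _analysis_window(cfg)
    spectra = np.fft.fft(frames * window, axis=1)
    log_mag = np.log(np.maximum(np.abs(spectra), ccfg.log_floor))
    cepstra = np.fft.ifft(log_mag, axis=1).real
    raw = np.array(
        [cpp_of_frame(smooth_cepstrum(c, ccfg), ccfg) for c in cepstra]
    )
    return CppSeries(
        raw=raw,
        smoothed=smooth_cpp_series(raw, ccfg),
        hop_seconds=cfg.hop / signal.rate,
    )


class CPPExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping :class:`AudioSignal` objects to
    :class:`CppSeries`.

    Composes with sklearn pipelines; ``fit`` only validates configuration.

    Parameters mirror :class:`FramingConfig` and :class:`CepstralConfig`.
    """

    def __init__(
        self,
        frame_len: int = 1024,
        hop: int = 128,
        window_kind: str = "hamming",
        smooth_len_cepstral: int = 7,
        tmin: int = 22,
        tmax: int = 400,
        smooth_len_temporal: int = 7,
        log_floor: float = 1e-10,
    ) -> None:
        self.frame_len = frame_len
        self.hop = hop
        self.window_kind = window_kind
        self.smooth_len_cepstral = smooth_len_cepstral
        self.tmin = tmin
        self.tmax = tmax
        self.smooth_len_temporal = smooth_len_temporal
        self.log_floor = log_floor

    def _configs(self) -> tuple[FramingConfig, CepstralConfig]:
        cfg = FramingConfig(self.frame_len, self.hop, self.window_kind)
        ccfg = CepstralConfig(
            self.smooth_len_cepstral,
            self.tmin,
            self.tmax,
            self.smooth_len_temporal,
            self.log_floor,
        )
        if ccfg.tmax >= cfg.frame_len:
            raise ConfigError("tmax must be smaller than frame_len")
        return cfg, ccfg

    def fit(self, X=None, y=None) -> "CPPExtractor":
        self._configs()
        return self

    def transform(self, X) -> list[CppSeries]:
        cfg, ccfg = self._configs()
        return [extract_cpp(sig, cfg, ccfg) for sig in X]
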