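"""Waveform → normalized log mel-filterbank features.

The acoustic front-end computes 80-dimensional log filterbank energies with
a 25 ms window and 10 ms hop, followed by per-utterance cepstral mean and
variance normalization (CMVN).  Mel filterbank construction, Hann
windowing, power-of-two FFT sizing and a configurable log floor follow
common end-to-end ASR practice; all are exposed in the config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile

__all__ = ["FeatureMatrix", "log_filterbank", "cmvn", "read_wav", "frame_count"]


@dataclass
class FeatureMatrix:
    """frames × n_bins real matrix of log filterbank energies."""

    values: np.ndarray
    frame_hop_s: float
    frame_len_s: float

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def frame_count(n_samples: int, win_samples: int, hop_samples: int) -> int:
    """Number of full analysis frames: floor((n − win)/hop) + 1, or 0."""
    if n_samples < win_samples:
        return 0
    return (n_samples - win_samples) // hop_samples + 1


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank_matrix(
    n_bins: int, n_fft: int, sample_rate: float, f_min: float = 0.0, f_max: float | None = None
) -> np.ndarray:
    """Triangular mel filters as an (n_fft//2 + 1, n_bins) matrix."""
    f_max = sample_rate / 2.0 if f_max is None else f_max
    mel_pts = np.linspace(_hz_to_mel(f_min), _hz_to_mel(f_max), n_bins + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    fb = np.zeros((bin_freqs.size, n_bins))
    for j in range(n_bins):
        left, center, right = hz_pts[j], hz_pts[j + 1], hz_pts[j + 2]
        up = (bin_freqs - left) / max(center - left, 1e-12)
        down = (right - bin_freqs) / max(right - center, 1e-12)
        fb[:, j] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def log_filterbank(
    waveform: np.ndarray,
    sample_rate: float,
    n_bins: int = 80,
    win_s: float = 0.025,
    hop_s: float = 0.010,
    log_floor: float = 1e-10,
) -> FeatureMatrix:
    """Log mel-filterbank energies of a mono waveform.

    Parameters
    ----------
    waveform : 1-D float array; integer PCM is rescaled to [-1, 1].
    sample_rate : sampling rate in Hz, > 0.
    n_bins : number of mel bands (default 80).
    win_s, hop_s : analysis window and hop in seconds (defaults 25/10 ms).
    log_floor : energies are clipped here before the log so silent frames
        yield ``log(log_floor)`` instead of -inf.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    x = np.asarray(waveform, dtype=np.float64).squeeze()
    if x.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    win = int(round(win_s * sample_rate))
    hop = int(round(hop_s * sample_rate))
    if win <= 0 or hop <= 0:
        raise ValueError("window and hop must span at least one sample")
    if x.size < win:
        raise ValueError(
            f"audio too short: {x.size} samples < one {win}-sample window"
        )
    frames = sliding_window_view(x, win)[::hop]
    n_fft = 1 << (win - 1).bit_length()
    spec = np.fft.rfft(frames * np.hanning(win), n=n_fft, axis=1)
    power = np.abs(spec) ** 2
    fb = mel_filterbank_matrix(n_bins, n_fft, sample_rate)
    feats = np.log(np.maximum(power @ fb, log_floor))
    if not np.all(np.isfinite(feats)):
        raise FloatingPointError("non-finite filterbank energies")
    return FeatureMatrix(feats, frame_hop_s=hop_s, frame_len_s=win_s)


def cmvn(feat: FeatureMatrix, var_floor: float = 1e-8) -> FeatureMatrix:
    """Per-utterance, per-bin zero-mean unit-variance normalization.

    Constant bins (variance below ``var_floor``) map to all zeros rather
    than blowing up.  Requires at least two frames, since a one-frame
    variance is meaningless.
    """
    v = feat.values
    if v.shape[0] < 2:
        raise ValueError("CMVN needs at least 2 frames")
    mean = v.mean(axis=0)
    std = v.std(axis=0)
    std = np.where(std * std < var_floor, 1.0, std)
    centered = (v - mean) / std
    # re-zero constant bins exactly
    centered[:, feat.values.std(axis=0) ** 2 < var_floor] = 0.0
    return FeatureMatrix(centered, feat.frame_hop_s, feat.frame_len_s)


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV file as float64 in [-1, 1]; stereo is down-mixed."""
    sr, data = wavfile.read(str(path))
    if data.ndim == 2:
        warnings.warn(f"{path}: stereo input down-mixed to mono")
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    return np.asarray(data, dtype=np.float64), int(sr)
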