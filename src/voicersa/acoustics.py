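"""Long-term average spectra (LTAS) and the acoustic nuisance RDM.

The LTAS of a clip is the short-time Fourier transform power spectrum
(squared magnitude per window) averaged across the time axis.  Acoustic
dissimilarity between two clips is 1 minus the cosine similarity of their
LTAS vectors — for nonnegative spectra this lies in [0, 1] and is invariant
to global loudness rescaling.

Default STFT parameters: n_fft 2048, hop 512, Hann window, 44100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import ShortTimeFFT, get_window

from .rdm import RDM

__all__ = ["LtasVector", "compute_ltas", "acoustic_rdm", "read_audio"]


@dataclass
class LtasVector:
    """Per-frequency-bin time-averaged power with its STFT parameters."""

    power: np.ndarray
    sample_rate: int
    n_fft: int
    hop: int
    window: str = "hann"

    def __post_init__(self):
        p = np.asarray(self.power, dtype=float)
        if p.ndim != 1 or (p < 0).any():
            raise ValueError("LTAS power must be a 1-D nonnegative vector")
        self.power = p

    @property
    def n_bins(self) -> int:
        return self.power.shape[0]

    def frequencies(self) -> np.ndarray:
        return np.fft.rfftfreq(self.n_fft, d=1.0 / self.sample_rate)


def compute_ltas(audio: np.ndarray, sample_rate: int = 44100, n_fft: int = 2048,
                 hop: int = 512, window: str = "hann") -> LtasVector:
    """Time-averaged STFT power spectrum of a waveform.

    Raises on silent (all-zero) input: the downstream cosine dissimilarity
    would be undefined for a zero-norm spectrum.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1 or audio.size == 0:
        raise ValueError("audio must be a non-empty 1-D waveform")
    if n_fft < hop or hop < 1:
        raise ValueError("need n_fft >= hop >= 1")
    if not np.any(audio):
        raise ValueError("silent clip: LTAS has zero norm, cosine undefined")
    win = get_window(window, n_fft)
    sft = ShortTimeFFT(win, hop=hop, fs=sample_rate, fft_mode="onesided")
    spec = sft.stft(audio)
    power = (np.abs(spec) ** 2).mean(axis=1)
    return LtasVector(power, sample_rate, n_fft, hop, window)


def acoustic_rdm(ltas_set, labels) -> RDM:
    """Acoustic RDM: 1 - cosine similarity between LTAS vectors."""
    vecs = [np.asarray(l.power if isinstance(l, LtasVector) else l, dtype=float)
            for l in ltas_set]
    n = len(vecs)
    if n != len(list(labels)):
        raise ValueError("label count does not match LTAS set")
    bins = {v.shape for v in vecs}
    if len(bins) != 1:
        raise ValueError("all LTAS vectors must have equal bin counts")
    norms = np.array([np.linalg.norm(v) for v in vecs])
    if (norms == 0).any():
        raise ValueError("zero-norm LTAS vector: cosine undefined")
    unit = np.stack(vecs) / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    return RDM(1.0 - cos, list(labels))


def read_audio(path):
    """Read a WAV file as (float waveform in [-1, 1], sample_rate)."""
    sr, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), int(sr)
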