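"""Frequency-domain gradient attribution of EEG-text cosine similarity.

Each window is re-parameterized by its per-channel real-FFT coefficients
(unitary normalization). The time-domain signal is reconstructed inside the
computation graph through an explicit inverse-rFFT basis matrix, forwarded
through the EEG encoder, and the gradient of the cosine similarity between
the EEG projection and a text prompt's projection is taken with respect to
the coefficients. Per-bin gradients are reported as magnitudes (or signed
real parts) averaged over windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .autodiff import Tensor

__all__ = ["SpectralAttribution", "frequency_gradients", "irfft_basis"]


@lru_cache(maxsize=8)
def irfft_basis(n_samples: int) -> np.ndarray:
    """Real (2F, T) matrix mapping stacked [real | imag] rFFT coefficients
    (norm="ortho") to the time-domain signal; F = T // 2 + 1."""
    n_freq = n_samples // 2 + 1
    eye = np.eye(n_freq)
    real_rows = np.fft.irfft(eye, n=n_samples, norm="ortho")
    imag_rows = np.fft.irfft(1j * eye, n=n_samples, norm="ortho")
    return np.vstack([real_rows, imag_rows]).astype(np.float64)


@dataclass
class SpectralAttribution:
    """Channel x frequency gradient map for one prompt."""

    grid: np.ndarray               # (F,) frequency bins in Hz
    per_channel: np.ndarray        # (C, F)
    pooled: np.ndarray             # (F,) channel-mean
    prompt: str
    n_windows: int
    signed: bool
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self):
        if not self.signed and (self.pooled < 0).any():
            raise ValueError("magnitude attribution must be non-negative")

    def peak_frequency(self, f_min: float = 0.0) -> float:
        """Frequency of the pooled maximum at or above ``f_min`` Hz.

        Convolutional encoders carry strong drift sensitivity in the lowest
        bins; pass ``f_min`` (e.g. 2 Hz) to search above that bulk.
        """
        keep = self.grid >= f_min
        return float(self.grid[keep][np.argmax(self.pooled[keep])])

    def channel_mean(self, names: list[str]) -> float:
        if self.channel_names is None:
            raise ValueError("channel names not attached")
        idx = [self.channel_names.index(n) for n in names]
        return float(self.per_channel[idx].mean())


def frequency_gradients(model, windows: np.ndarray, prompt: str,
                        signed: bool = False, rate: float = 100.0,
                        batch_size: int = 64,
                        channel_names: tuple[str, ...] | None = None,
                        ) -> SpectralAttribution:
    """Gradient of cosine(EEG projection, prompt projection) w.r.t. the
    per-channel rFFT coefficients of each window, averaged over windows.

    ``model`` needs ``encode_eeg(x, project_out=True)`` and
    ``encode_text(texts)``; an untrained model is allowed (near-noise map).
    """
    if not prompt or not prompt.strip():
        raise ValueError("prompt must be a non-empty string")
    windows = np.asarray(windows, dtype=np.float64)
    if windows.ndim != 3 or len(windows) == 0:
        raise ValueError("windows must be a non-empty (n, C, T) array")
    n, c, t = windows.shape
    n_freq = t // 2 + 1
    basis = irfft_basis(t)
    basis_t = Tensor(basis.astype(np.float32))

    was_training = getattr(model, "training", False)
    if hasattr(model, "eval"):
        model.eval()
    try:
        prompt_vec = model.encode_text([prompt]).data.reshape(-1)

        mag_sum = np.zeros((c, n_freq), dtype=np.float64)
        real_sum = np.zeros((c, n_freq), dtype=np.float64)
        for lo in range(0, n, batch_size):
            chunk = windows[lo:lo + batch_size]
            coeffs = np.fft.rfft(chunk, axis=-1, norm="ortho")
            params = Tensor(
                np.concatenate([coeffs.real, coeffs.imag], axis=-1
                               ).astype(np.float32),
                requires_grad=True)
            m = len(chunk)
            x = (params.reshape(m * c, 2 * n_freq) @ basis_t).reshape(m, c, t)
            proj = model.encode_eeg(x, project_out=True)
            cos = (proj * Tensor(prompt_vec[None, :])).sum(axis=-1)
            cos.sum().backward()
            grad = params.grad.astype(np.float64)     # (m, c, 2F)
            g_real, g_imag = grad[..., :n_freq], grad[..., n_freq:]
            # per-window magnitude (or signed real part), then average
            mag_sum += np.hypot(g_real, g_imag).sum(axis=0)
            real_sum += g_real.sum(axis=0)
    finally:
        if hasattr(model, "train"):
            model.train(was_training)

    per_channel = (real_sum if signed else mag_sum) / n
    return SpectralAttribution(
        grid=np.fft.rfftfreq(t, d=1.0 / rate),
        per_channel=per_channel,
        pooled=per_channel.mean(axis=0),
        prompt=prompt,
        n_windows=n,
        signed=signed,
        channel_names=channel_names,
    )
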