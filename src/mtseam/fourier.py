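"""Shared Fourier-space helpers: frequency grids and soft low-pass filters."""

from __future__ import annotations

import numpy as np


def freq_grids(shape: tuple[int, ...], spacing: float) -> list[np.ndarray]:
    """Per-axis FFT frequency grids in 1/Å (standard FFT layout)."""
    return [np.fft.fftfreq(n, d=spacing) for n in shape]


def radial_freq(shape: tuple[int, ...], spacing: float) -> np.ndarray:
    """Radial spatial frequency magnitude |q| in 1/Å on the FFT grid."""
    axes = freq_grids(shape, spacing)
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(sum(g**2 for g in grids))


def soft_lowpass_profile(q: np.ndarray, cutoff: float, edge_fraction: float = 0.1) -> np.ndarray:
    """Cosine-edge low-pass response: unity below ``(1-edge)·f_c``, a half
    cosine falling to zero AT ``f_c = 1/cutoff``, zero beyond.

    The taper ends exactly at the cutoff frequency, so the filtered
    signal carries no power beyond ``1/cutoff``.
    """
    if not np.isfinite(cutoff):
        return np.ones_like(q)
    fc = 1.0 / cutoff
    f0 = fc * (1.0 - edge_fraction)
    h = np.ones_like(q)
    edge = (q > f0) & (q < fc)
    h[edge] = 0.5 * (1.0 + np.cos(np.pi * (q[edge] - f0) / (fc - f0)))
    h[q >= fc] = 0.0
    return h


def lowpass(data: np.ndarray, spacing: float, cutoff: float, edge_fraction: float = 0.1) -> np.ndarray:
    """Soft cosine-edge low-pass filter of an N-D array.

    Parameters
    ----------
    spacing : voxel/pixel size in Å.
    cutoff : resolution in Å; all power beyond ``1/cutoff`` removed.
    """
    if not np.isfinite(cutoff):
        return data.copy()
    if cutoff < 2.0 * spacing:
        raise ValueError(
            f"cutoff {cutoff} Å is beyond the Nyquist limit {2.0 * spacing} Å"
        )
    q = radial_freq(data.shape, spacing)
    h = soft_lowpass_profile(q, cutoff, edge_fraction)
    return np.real(np.fft.ifftn(np.fft.fftn(data) * h))


def fourier_shift_2d(image: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Subpixel shift of a 2D image by (d0, d1) pixels via the Fourier
    shift theorem (circular boundary)."""
    f0 = np.fft.fftfreq(image.shape[0])[:, None]
    f1 = np.fft.fftfreq(image.shape[1])[None, :]
    phase = np.exp(-2j * np.pi * (f0 * shift[0] + f1 * shift[1]))
    return np.real(np.fft.ifft2(np.fft.fft2(image) * phase))
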