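"""CTF model and low-dose multi-frame movie simulation.

The forward model projects a 3D density along a view, modulates it with
the phase contrast transfer function of a defocused microscope, splits
the exposure into movie frames carrying cumulative beam-induced drift,
and adds frame-wise Gaussian noise (a Gaussian approximation of shot
noise at the stated dose).  Ground truth for every stochastic choice is
returned alongside the movie so downstream estimators can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .fourier import fourier_shift_2d, radial_freq
from .render import Volume


@dataclass
class ImagingParams:
    """Microscope and exposure parameters.

    Defaults follow a 300 kV instrument with a counting detector:
    1.99 Å effective pixel, ~15 e/Å^2 total dose over 15 frames,
    defocus in the 1-2.5 um range.
    """

    pixel_size: float = 1.99  # Å
    voltage: float = 300.0  # kV
    spherical_aberration: float = 2.7  # mm
    amplitude_contrast: float = 0.07
    defocus: float = 1.5  # µm, positive = underfocus
    total_dose: float = 15.0  # e-/Å^2
    n_frames: int = 15
    drift_per_frame: list = field(default_factory=list)  # (dx0, dx1) px per frame
    noise_sigma: float = 0.0
    seed: int = 0
    apply_ctf: bool = True

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.defocus <= 0:
            raise ValueError("defocus must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class Movie:
    frames: np.ndarray  # (n_frames, n0, n1)
    pixel_size: float
    dose_per_frame: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def average(self) -> np.ndarray:
        return self.frames.mean(axis=0)


@dataclass
class TruthRecord:
    """Ground truth of one simulated movie (JSON-serializable)."""

    view: tuple  # (rot, tilt, psi) degrees
    frame_shifts: list  # cumulative (d0, d1) px per frame
    defocus: float
    seam: int | None = None
    polarity: str | None = None
    seed: int = 0
    noise_sigma: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Å."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v**2)


def ctf_1d(q: np.ndarray, params: ImagingParams) -> np.ndarray:
    """Phase CTF at spatial frequency ``q`` (1/Å).

    ``CTF(q) = -sin(chi(q) + arcsin(A))`` with
    ``chi = pi*lambda*df*q^2 - (pi/2)*Cs*lambda^3*q^4`` and positive
    underfocus, so low-frequency contrast is negative (dense protein
    appears dark on a bright background).
    """
    lam = electron_wavelength(params.voltage)
    df = params.defocus * 1e4  # µm -> Å
    cs = params.spherical_aberration * 1e7  # mm -> Å
    chi = np.pi * lam * df * q**2 - 0.5 * np.pi * cs * lam**3 * q**4
    return -np.sin(chi + np.arcsin(params.amplitude_contrast))


def ctf_2d(shape: tuple[int, int], params: ImagingParams) -> np.ndarray:
    """2D CTF on the standard FFT frequency grid (astigmatism not modelled)."""
    return ctf_1d(radial_freq(shape, params.pixel_size), params)


def ctf_zeros(params: ImagingParams, q_max: float, n: int = 10) -> np.ndarray:
    """First ``n`` zero-crossing frequencies of the analytic CTF below q_max."""
    lam = electron_wavelength(params.voltage)
    df = params.defocus * 1e4
    cs = params.spherical_aberration * 1e7
    phi0 = np.arcsin(params.amplitude_contrast)
    zeros = []
    for m in range(1, n + 1):
        # solve pi*lam*df*q^2 - (pi/2)*cs*lam^3*q^4 = m*pi - phi0 (low-q branch)
        a = -0.5 * np.pi * cs * lam**3
        b = np.pi * lam * df
        c = -(m * np.pi - phi0)
        disc = b**2 - 4 * a * c
        if disc < 0:
            break
        q2 = (-b + np.sqrt(disc)) / (2 * a)
        if q2 <= 0:
            continue
        q = np.sqrt(q2)
        if q <= q_max:
            zeros.append(q)
    return np.array(zeros)


def project_volume(volume: Volume, rotation: np.ndarray, out_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Real-space projection of a volume along the view.

    The volume is resampled into the image frame (``vol_img(p) =
    vol(R^T p)`` about the grid centre, trilinear interpolation) and
    summed along image z; the result approximates the line integral
    scaled by the voxel size.
    """
    n = volume.shape
    if out_shape is None:
        out_shape = (n[0], n[1])
    depth = max(n)
    out3 = (out_shape[0], out_shape[1], depth)
    c_in = (np.array(n) - 1) / 2.0
    c_out = (np.array(out3) - 1) / 2.0
    mat = rotation.T
    offset = c_in - mat @ c_out
    rot_vol = ndimage.affine_transform(
        volume.data, mat, offset=offset, output_shape=out3, order=1, mode="constant", cval=0.0
    )
    return rot_vol.sum(axis=2) * volume.voxel_size


def simulate_movie(
    source: Volume | np.ndarray,
    imaging: ImagingParams,
    view: tuple[float, float, float] = (0.0, 90.0, 0.0),
    seam: int | None = None,
    polarity: str | None = None,
) -> tuple[Movie, TruthRecord]:
    """Simulate a low-dose movie of a projection.

    ``source`` is either a Volume (projected along ``view``) or an
    already-projected 2D image (``view`` recorded as-is).  Each frame is
    the CTF-modulated projection shifted by the cumulative drift up to
    that frame, scaled by 1/n_frames, plus Gaussian noise of
    ``noise_sigma`` grey levels.
    """
    imaging.validate()
    if isinstance(source, Volume):
        from .geometry import euler_matrix

        img = project_volume(source, euler_matrix(*view))
    else:
        img = np.asarray(source, dtype=np.float64)

    if imaging.apply_ctf:
        img = np.real(np.fft.ifft2(np.fft.fft2(img) * ctf_2d(img.shape, imaging)))

    drift = list(imaging.drift_per_frame) or [(0.0, 0.0)] * imaging.n_frames
    if len(drift) != imaging.n_frames:
        raise ValueError("drift_per_frame length must equal n_frames")
    cumulative = np.cumsum(np.asarray(drift, dtype=float), axis=0)

    rng = np.random.default_rng(imaging.seed)
    frames = np.empty((imaging.n_frames, *img.shape))
    for f in range(imaging.n_frames):
        shifted = fourier_shift_2d(img, tuple(cumulative[f])) if np.any(cumulative[f]) else img
        frames[f] = shifted / imaging.n_frames
        if imaging.noise_sigma > 0:
            frames[f] += rng.normal(0.0, imaging.noise_sigma, img.shape)

    movie = Movie(frames=frames, pixel_size=imaging.pixel_size, dose_per_frame=imaging.total_dose / imaging.n_frames)
    truth = TruthRecord(
        view=tuple(view),
        frame_shifts=[tuple(map(float, c)) for c in cumulative],
        defocus=imaging.defocus,
        seam=seam,
        polarity=polarity,
        seed=imaging.seed,
        noise_sigma=imaging.noise_sigma,
    )
    return movie, truth


def noise_sigma_for_snr(signal: np.ndarray, snr: float) -> float:
    """Noise sigma giving the requested signal-variance / noise-variance ratio."""
    return float(np.sqrt(signal.var() / snr))
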