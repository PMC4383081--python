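"""Rendering of decorated lattices into 3D density maps and 2D projections.

Subunits are rendered as small isotropic Gaussian mixtures (three
Gaussians per subunit) sized to the approximate dimensions of a tubulin
monomer (~4 nm) and a kinesin motor domain (~4.5 nm).  Alpha and beta
tubulin use the identical blob model, so an undecorated filament carries
only the 40 Å monomer periodicity; kinesin decoration (one motor per
80 Å dimer repeat) introduces the 80 Å periodicity whose layer line is
the decoration diagnostic.

Volumes are stored as arrays indexed ``[x, y, z]`` with the filament
axis along axis 2 (z).  Voxel ``(i, j, k)`` is centred at
``origin + voxel_size * (i, j, k)`` in Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import lowpass
from .lattice import DecoratedLattice

# Blob models: list of (offset vector in the subunit frame (Å), sigma
# (Å), weight).  The subunit frame has local x pointing radially outward
# and local z along the filament axis toward the plus end.  Alpha and
# beta tubulin use the identical model (so undecorated filaments carry
# only the 40 Å monomer periodicity).  The kinesin head is elongated
# radially with an extra plus-end-ward lobe: motor decoration both
# introduces the 80 Å periodicity and breaks the axial mirror symmetry
# that filament polarity determination depends on.
# Tubulin monomers are lobed, not mirror-symmetric about the lattice
# plane: the model gives each monomer a plus-end-ward lobe displaced
# slightly outward (a pear shape).  Alpha and beta remain IDENTICAL, so
# the undecorated filament still carries only 40 Å periodicity, while
# the monomer asymmetry (like the real molecule's) is what makes
# filament polarity determinable from projections.
_TUBULIN_BLOBS = [
    ((0.0, 0.0, -8.0), 8.0, 0.30),
    ((0.0, 0.0, 0.0), 9.0, 0.34),
    ((4.0, 0.0, 8.0), 9.5, 0.36),
]
_BLOBS = {
    "alpha_tubulin": _TUBULIN_BLOBS,
    "beta_tubulin": _TUBULIN_BLOBS,
    "kinesin": [
        ((-9.0, 0, 0), 10.0, 0.8 * 0.30),
        ((0.0, 0, 0), 10.0, 0.8 * 0.30),
        ((9.0, 0, 0), 10.0, 0.8 * 0.20),
        ((4.0, 0, 12.0), 8.0, 0.8 * 0.20),  # plus-end lobe
    ],
}


@dataclass
class Volume:
    """3D density grid.  ``data`` indexed [x, y, z]; ``voxel_size`` in Å;
    ``origin`` = position of voxel (0,0,0) in Å."""

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def center(self) -> np.ndarray:
        return self.origin + self.voxel_size * (np.array(self.shape) - 1) / 2.0

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size, self.origin.copy())

    @classmethod
    def zeros(cls, shape, voxel_size: float, origin=None) -> "Volume":
        shape = tuple(int(s) for s in shape)
        if origin is None:
            origin = -voxel_size * (np.array(shape) - 1) / 2.0
        return cls(np.zeros(shape, dtype=np.float64), float(voxel_size), np.asarray(origin, float))


def _blob_centers(lattice: DecoratedLattice) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand placements into individual Gaussian centres.

    Returns (centers (n,3), sigmas (n,), weights (n,))."""
    centers, sigmas, weights = [], [], []
    for p in lattice.placements:
        for off, sigma, w in _BLOBS[p.species]:
            centers.append(p.position + p.orientation @ np.asarray(off, float))
            sigmas.append(sigma)
            weights.append(w)
    if not centers:
        return np.zeros((0, 3)), np.zeros(0), np.zeros(0)
    return np.array(centers), np.array(sigmas), np.array(weights)


def render_density(
    lattice: DecoratedLattice,
    shape: tuple[int, int, int],
    voxel_size: float,
    resolution: float = np.inf,
    origin: np.ndarray | None = None,
    clip: bool = False,
) -> Volume:
    """Render a lattice into a 3D density map.

    Each Gaussian is normalized so its integral equals its weight, making
    the total integrated density proportional to the subunit count.  The
    map is then band-limited to ``resolution`` (soft cosine-edge filter).
    With ``clip=True`` subunits outside the grid are truncated silently
    (for rendering a window of a longer filament) instead of failing.

    Raises
    ------
    ValueError
        If any subunit centre falls outside the grid (unless ``clip``),
        or if ``resolution`` is below the Nyquist limit of the grid.
    """
    if np.isfinite(resolution) and resolution < 2.0 * voxel_size:
        raise ValueError(f"resolution {resolution} Å below Nyquist ({2 * voxel_size} Å)")
    centers, sigmas, weights = _blob_centers(lattice)
    if origin is None and len(centers) > 0:
        # centre the lattice in the grid so that projections of the volume
        # about the grid centre match render_projection
        origin = centers.mean(axis=0) - voxel_size * (np.array(shape) - 1) / 2.0
    vol = Volume.zeros(shape, voxel_size, origin)
    if len(centers) == 0:
        return vol
    idx = (centers - vol.origin) / voxel_size
    lo = np.array([0, 0, 0])
    hi = np.array(shape) - 1
    if not clip and (np.any(idx < lo - 0.5) or np.any(idx > hi + 0.5)):
        raise ValueError("grid too small to contain the lattice")
    _splat_gaussians_3d(vol.data, idx, sigmas / voxel_size, weights / voxel_size**3)
    if np.isfinite(resolution):
        vol.data = lowpass(vol.data, voxel_size, resolution)
    return vol


def _splat_gaussians_3d(data: np.ndarray, idx: np.ndarray, sigma_px: np.ndarray, amp: np.ndarray) -> None:
    """Accumulate unit-integral Gaussians (in voxel units) into ``data``."""
    shape = data.shape
    for (ci, cj, ck), s, a in zip(idx, sigma_px, amp):
        r = max(2, int(np.ceil(4.0 * s)))
        i0, i1 = max(0, int(ci) - r), min(shape[0], int(ci) + r + 1)
        j0, j1 = max(0, int(cj) - r), min(shape[1], int(cj) + r + 1)
        k0, k1 = max(0, int(ck) - r), min(shape[2], int(ck) + r + 1)
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        gi = np.exp(-((np.arange(i0, i1) - ci) ** 2) / (2 * s**2))
        gj = np.exp(-((np.arange(j0, j1) - cj) ** 2) / (2 * s**2))
        gk = np.exp(-((np.arange(k0, k1) - ck) ** 2) / (2 * s**2))
        norm = a / (np.sqrt(2 * np.pi) * s) ** 3
        data[i0:i1, j0:j1, k0:k1] += norm * gi[:, None, None] * gj[None, :, None] * gk[None, None, :]


def render_projection(
    lattice: DecoratedLattice,
    rotation: np.ndarray,
    shape: tuple[int, int],
    pixel_size: float,
    resolution: float = np.inf,
    center_offset: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Analytic 2D projection of a lattice along the viewing axis.

    ``rotation`` maps lattice coordinates to image coordinates; the
    projection integrates along image z, and image components (x, y) map
    to array axes (0, 1).  A 3D Gaussian projects exactly to a 2D
    Gaussian of the same sigma and weight, so this path is both fast and
    free of interpolation error; it is the forward model used by the
    synthetic imaging pipeline.
    """
    centers, sigmas, weights = _blob_centers(lattice)
    img = np.zeros(shape, dtype=np.float64)
    if len(centers) == 0:
        return img
    cam = (rotation @ centers.T).T[:, :2]
    lattice_center = centers.mean(axis=0)
    cam -= (rotation @ lattice_center)[:2]
    ci = cam[:, 0] / pixel_size + (shape[0] - 1) / 2.0 + center_offset[0]
    cj = cam[:, 1] / pixel_size + (shape[1] - 1) / 2.0 + center_offset[1]
    _splat_gaussians_2d(img, ci, cj, sigmas / pixel_size, weights / pixel_size**2)
    if np.isfinite(resolution):
        img = lowpass(img, pixel_size, resolution)
    return img


def _splat_gaussians_2d(img: np.ndarray, ci: np.ndarray, cj: np.ndarray, sigma_px: np.ndarray, amp: np.ndarray) -> None:
    shape = img.shape
    for x, y, s, a in zip(ci, cj, sigma_px, amp):
        r = max(2, int(np.ceil(4.0 * s)))
        i0, i1 = max(0, int(x) - r), min(shape[0], int(x) + r + 1)
        j0, j1 = max(0, int(y) - r), min(shape[1], int(y) + r + 1)
        if i0 >= i1 or j0 >= j1:
            continue
        gi = np.exp(-((np.arange(i0, i1) - x) ** 2) / (2 * s**2))
        gj = np.exp(-((np.arange(j0, j1) - y) ** 2) / (2 * s**2))
        img[i0:i1, j0:j1] += (a / (2 * np.pi * s**2)) * gi[:, None] * gj[None, :]


def auto_grid_shape(lattice: DecoratedLattice, voxel_size: float, pad: float = 30.0) -> tuple[int, int, int]:
    """Cubic-section grid shape that contains the lattice with ``pad`` Å margin."""
    pos = lattice.positions()
    span = pos.max(axis=0) - pos.min(axis=0) + 2 * pad
    return tuple(int(np.ceil(s / voxel_size)) | 1 for s in span)
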