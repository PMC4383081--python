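"""Shared fixtures: synthetic lattices, reference volumes, and the
two-domain hinge model used by the fitting and domain-motion tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mtseam.domains import AtomicModel
from mtseam.lattice import LatticeSpec, build_lattice
from mtseam.render import Volume, _splat_gaussians_3d
from mtseam.simulate import BOX_SIZE, VOXEL_SIZE, reference_volume


@pytest.fixture(scope="session")
def spec14() -> LatticeSpec:
    return LatticeSpec(n_pf=14)


@pytest.fixture(scope="session")
def ref_volume_14(spec14) -> Volume:
    """Box-filling 14-pf decorated reference volume (80^3 at 5 Å)."""
    return reference_volume(spec14)


@pytest.fixture(scope="session")
def lattice_14(spec14):
    return build_lattice(spec14, 7)


def helix_ca(n: int, origin: np.ndarray) -> np.ndarray:
    """Ideal alpha-helix CA trace: 2.3 Å radius, 1.5 Å rise, 100°/residue."""
    t = np.arange(n)
    return np.stack(
        [2.3 * np.cos(np.deg2rad(100 * t)), 2.3 * np.sin(np.deg2rad(100 * t)), 1.5 * t],
        axis=1,
    ) + origin


def make_two_domain_model() -> AtomicModel:
    """CA-only model of two helices joined by a linker (hinge at residue 41)."""
    a = helix_ca(30, np.array([0.0, 0.0, 0.0]))
    b = helix_ca(30, np.array([12.0, 0.0, 45.0]))
    linker = np.stack([np.linspace(a[-1][i], b[0][i], 12)[1:-1] for i in range(3)], axis=1)
    xyz = np.vstack([a, linker, b])
    n = len(xyz)
    return AtomicModel(
        np.array(["A"] * n), np.arange(1, n + 1), np.array(["ALA"] * n),
        np.array(["CA"] * n), np.array(["C"] * n), xyz, "two_domain",
    )


def rotate_domain(model: AtomicModel, res_from: int, angle_deg: float, axis: str = "x") -> AtomicModel:
    """Rigidly rotate residues >= res_from about a hinge at that residue."""
    out = model.copy()
    sel = out.resnum >= res_from
    hinge = out.xyz[np.argmax(sel)].copy()
    R = Rotation.from_euler(axis, angle_deg, degrees=True).as_matrix()
    out.xyz[sel] = (out.xyz[sel] - hinge) @ R.T + hinge
    return out


def ca_density(model: AtomicModel, extra: AtomicModel | None = None,
               voxel: float = 1.5, sigma: float = 2.5, pad: float = 12.0) -> Volume:
    """Gaussian-splat density of a CA model (grid covers both models)."""
    pts = [model.xyz] + ([extra.xyz] if extra is not None else [])
    allpts = np.vstack(pts)
    lo = allpts.min(0) - pad
    hi = allpts.max(0) + pad
    shape = tuple(int(np.ceil((h - l) / voxel)) for h, l in zip(hi, lo))
    grid = np.zeros(shape)
    _splat_gaussians_3d(grid, (model.xyz - lo) / voxel,
                        np.full(len(model), sigma / voxel), np.ones(len(model)))
    return Volume(grid, voxel, lo.copy())


@pytest.fixture(scope="session")
def two_domain_model() -> AtomicModel:
    return make_two_domain_model()
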