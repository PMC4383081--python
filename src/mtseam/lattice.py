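"""Parametric model of a kinesin-decorated microtubule lattice.

A microtubule is modelled as ``n_pf`` protofilaments (linear polymers of
alpha/beta-tubulin dimers) arranged on a cylinder.  Crossing laterally from
one protofilament to the next advances the lattice axially by
``start_number * monomer_rise / n_pf``, so that one full turn accumulates
``start_number * monomer_rise`` of rise (a 3-start monomer helix for the
canonical lattice).  Because that accumulated rise (120 Å with 40 Å
monomers) is not a multiple of the 80 Å dimer repeat, the alpha/beta
register necessarily breaks at one lateral interface: the seam.  Kinesin
motor domains decorate the lattice with one motor per tubulin dimer,
bound radially outward of the dimer, which introduces an 80 Å axial
periodicity on top of the 40 Å tubulin monomer spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

Species = Literal["alpha_tubulin", "beta_tubulin", "kinesin"]

#: Radial offset of the kinesin head centre from the protofilament axis
#: radius (the motor binds on the outside surface of the tubulin dimer).
KINESIN_RADIAL_OFFSET = 42.0


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry and decoration of one microtubule.

    Parameters use the canonical B-lattice defaults: 40 Å monomer rise
    (80 Å dimer repeat), 3-start monomer helix, 110 Å protofilament
    radius, zero supertwist.
    """

    n_pf: int = 14
    start_number: int = 3
    monomer_rise: float = 40.0
    radius: float = 110.0
    seam_position: int = 0
    supertwist: float = 0.0  # degrees of extra azimuth per dimer repeat
    decoration_occupancy: float = 1.0
    polarity: Literal["+", "-"] = "+"

    @property
    def dimer_repeat(self) -> float:
        return 2.0 * self.monomer_rise

    @property
    def twist_per_pf(self) -> float:
        """Azimuthal step between adjacent protofilaments, degrees."""
        return 360.0 / self.n_pf

    @property
    def rise_per_pf(self) -> float:
        """Axial step between adjacent protofilaments, Å."""
        return self.start_number * self.monomer_rise / self.n_pf

    def validate(self) -> None:
        if not float(self.n_pf).is_integer() or isinstance(self.n_pf, float):
            raise ValueError(f"n_pf must be an integer, got {self.n_pf!r}")
        if not 12 <= self.n_pf <= 15:
            raise ValueError(f"n_pf must be in [12, 15], got {self.n_pf}")
        if not 0.0 <= self.decoration_occupancy <= 1.0:
            raise ValueError(
                f"decoration_occupancy must be in [0, 1], got {self.decoration_occupancy}"
            )
        if not 0 <= self.seam_position < self.n_pf:
            raise ValueError(
                f"seam_position must be in [0, n_pf), got {self.seam_position}"
            )
        if self.monomer_rise <= 0 or self.radius <= 0:
            raise ValueError("monomer_rise and radius must be positive")
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")

    def with_seam(self, seam_position: int) -> "LatticeSpec":
        return replace(self, seam_position=seam_position)


@dataclass
class Placement:
    species: Species
    position: np.ndarray  # (3,) Å, filament axis along z
    orientation: np.ndarray  # (3, 3) rotation, body frame -> lattice frame
    pf_index: int
    repeat_index: int


@dataclass
class DecoratedLattice:
    """Realized subunit placements of a :class:`LatticeSpec`."""

    spec: LatticeSpec
    n_repeats: int
    placements: list[Placement] = field(default_factory=list)

    def positions(self, species: Species | None = None) -> np.ndarray:
        pts = [p.position for p in self.placements if species is None or p.species == species]
        return np.array(pts).reshape(-1, 3)

    def count(self, species: Species) -> int:
        return sum(1 for p in self.placements if p.species == species)

    def axial_extent(self) -> tuple[float, float]:
        z = self.positions()[:, 2]
        return float(z.min()), float(z.max())

    def union(self, other: "DecoratedLattice") -> "DecoratedLattice":
        return DecoratedLattice(
            spec=self.spec,
            n_repeats=self.n_repeats,
            placements=list(self.placements) + list(other.placements),
        )


def _rot_z(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_FLIP_X = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])


def build_lattice(
    spec: LatticeSpec,
    n_repeats: int,
    rng: np.random.Generator | None = None,
) -> DecoratedLattice:
    """Realize subunit placements for ``n_repeats`` dimer repeats.

    Dimer ``k`` on protofilament ``p`` sits at azimuth ``p * 360/n_pf``
    (plus supertwist accumulation) and axial offset
    ``((p - seam_position) mod n_pf) * rise_per_pf + k * dimer_repeat``,
    so the lateral register wraps (by one-and-a-half dimer repeats for
    the canonical 3-start lattice) between protofilaments
    ``seam_position - 1`` and ``seam_position``: the seam.

    Alpha tubulin sits at the dimer origin, beta tubulin one monomer rise
    above it, and a kinesin head radially outward of the beta monomer.
    Decoration below full occupancy is realized by a seeded Bernoulli
    draw per dimer (``rng`` required when 0 < occupancy < 1).
    """
    spec.validate()
    if n_repeats < 1:
        raise ValueError(f"n_repeats must be >= 1, got {n_repeats}")
    occ = spec.decoration_occupancy
    if 0.0 < occ < 1.0 and rng is None:
        rng = np.random.default_rng(0)

    lattice = DecoratedLattice(spec=spec, n_repeats=n_repeats)
    for p in range(spec.n_pf):
        azimuth = p * spec.twist_per_pf
        z0 = ((p - spec.seam_position) % spec.n_pf) * spec.rise_per_pf
        for k in range(n_repeats):
            phi = azimuth + k * spec.supertwist
            R = _rot_z(phi)
            radial = R @ np.array([spec.radius, 0.0, 0.0])
            z = z0 + k * spec.dimer_repeat
            alpha_pos = radial + np.array([0.0, 0.0, z])
            beta_pos = radial + np.array([0.0, 0.0, z + spec.monomer_rise])
            kin_dir = R @ np.array([1.0, 0.0, 0.0])
            kin_pos = beta_pos + KINESIN_RADIAL_OFFSET * kin_dir
            lattice.placements.append(Placement("alpha_tubulin", alpha_pos, R, p, k))
            lattice.placements.append(Placement("beta_tubulin", beta_pos, R, p, k))
            decorate = occ >= 1.0 or (occ > 0.0 and rng.random() < occ)
            if decorate:
                lattice.placements.append(Placement("kinesin", kin_pos, R, p, k))

    if spec.polarity == "-":
        _apply_polarity_flip(lattice)
    return lattice


def _apply_polarity_flip(lattice: DecoratedLattice) -> None:
    """Rotate the whole lattice 180° about the x axis (proper rotation),
    reversing which filament end points toward +z."""
    zmin, zmax = lattice.axial_extent()
    zc = 0.5 * (zmin + zmax)
    for p in lattice.placements:
        pos = p.position - np.array([0.0, 0.0, zc])
        p.position = _FLIP_X @ pos + np.array([0.0, 0.0, zc])
        p.orientation = _FLIP_X @ p.orientation
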