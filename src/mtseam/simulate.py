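"""Desk-scale synthetic filament datasets with known ground truth.

Stands in for the raw cryo-EM data: decorated-microtubule segment
stacks with per-filament seam position, polarity and viewing geometry
drawn at random, per-segment sub-repeat phase and in-plane jitter, and
additive Gaussian noise at a stated signal-to-noise ratio (signal
variance over noise variance).

Segments of one straight filament share a single viewing direction —
repeats differ only by an axial phase — so each filament is rendered
once into a padded view and its segments cut as whole-pixel crops at
random offsets, exactly as boxes stepped along a straight filament in a
micrograph would be.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import euler_matrix
from .lattice import LatticeSpec, build_lattice
from .micrograph import SegmentStack
from .imaging import noise_sigma_for_snr
from .render import Volume, render_density, render_projection
from .reconstruct import AlignmentRecord

#: desk-scale reconstruction box: 80 voxels at 5 Å = 400 Å, an exact
#: multiple of the 80 Å dimer repeat (required by the wrapped helical
#: operators) and large enough for a decorated 14-pf microtubule.
BOX_SIZE = 80
VOXEL_SIZE = 5.0


@dataclass
class FilamentTruth:
    seam: int
    polarity: str
    rot: float
    tilt: float
    psi: float
    n_pf: int


@dataclass
class SyntheticDataset:
    stack: SegmentStack
    records: list[AlignmentRecord]  # ground-truth alignment per segment
    filament_ids: np.ndarray
    truths: list[FilamentTruth]
    spec: LatticeSpec
    snr: float
    seed: int


def reference_volume(
    spec: LatticeSpec,
    box: int = BOX_SIZE,
    voxel: float = VOXEL_SIZE,
    n_repeats: int | None = None,
) -> Volume:
    """Box-filling density of the lattice (filament spanning the box)."""
    if n_repeats is None:
        n_repeats = int(np.ceil(box * voxel / spec.dimer_repeat)) + 2
    lat = build_lattice(spec, n_repeats)
    zc = lat.positions()[:, 2].mean()
    half = (box - 1) / 2.0 * voxel
    origin = np.array([-half, -half, zc - half])
    return render_density(lat, (box, box, box), voxel, clip=True, origin=origin)


def contained_phantom(
    spec: LatticeSpec, box: int = BOX_SIZE, voxel: float = VOXEL_SIZE, n_repeats: int = 3
) -> tuple[Volume, "object"]:
    """A short filament fully contained in the box (for projection /
    backprojection oracles where truncation must match exactly)."""
    lat = build_lattice(spec, n_repeats)
    return render_density(lat, (box, box, box), voxel), lat


def make_segment_dataset(
    n_filaments: int = 10,
    segments_per_filament: int = 12,
    snr: float = 0.3,
    seed: int = 0,
    spec: LatticeSpec | None = None,
    box: int = BOX_SIZE,
    voxel: float = VOXEL_SIZE,
    tilt_halfrange: float = 8.0,
    psi_halfrange: float = 4.0,
    shift_max: float = 3.0,
) -> SyntheticDataset:
    """Simulate a stack of filament segments with known truth.

    Per filament: seam index and polarity uniform, azimuth ``rot``
    uniform over 360°, out-of-plane tilt uniform within
    ``90 ± tilt_halfrange`` (inside the ±15° search window), in-plane
    angle uniform within ``± psi_halfrange``.  Per segment: a random
    axial repeat phase and a random in-plane shift up to ``shift_max``
    px, then Gaussian noise at the requested SNR (``snr = inf`` or 0 →
    noiseless).
    """
    if spec is None:
        spec = LatticeSpec()
    rng = np.random.default_rng(seed)
    n_rep = int(np.ceil(box * voxel / spec.dimer_repeat)) + 2

    boxes, records, fil_ids, truths = [], [], [], []
    for fid in range(n_filaments):
        seam = int(rng.integers(0, spec.n_pf))
        pol = "+" if rng.random() < 0.5 else "-"
        rot = float(rng.uniform(0.0, 360.0))
        tilt = float(90.0 + rng.uniform(-tilt_halfrange, tilt_halfrange))
        psi = float(rng.uniform(-psi_halfrange, psi_halfrange))
        truths.append(FilamentTruth(seam, pol, rot, tilt, psi, spec.n_pf))
        lat = build_lattice(replace(spec, seam_position=seam, polarity=pol), n_rep + 2)
        # pad the rendered view so that each segment is a genuine crop of
        # a longer filament image (offsets quantized to whole pixels):
        # circularly shifting a clipped projection would wrap filament
        # ends into the box and bias the seam scoring
        repeat_px = int(np.ceil(spec.dimer_repeat / voxel))
        pad0 = repeat_px + int(np.ceil(shift_max)) + 2
        pad1 = int(np.ceil(repeat_px * np.sin(np.deg2rad(psi_halfrange)) + shift_max)) + 2
        base = render_projection(
            lat, euler_matrix(rot, tilt, psi), (box + 2 * pad0, box + 2 * pad1), voxel
        )
        sigma = noise_sigma_for_snr(base, snr) if (snr and np.isfinite(snr)) else 0.0
        axis = np.array([np.cos(np.deg2rad(psi)), np.sin(np.deg2rad(psi))])
        for si in range(segments_per_filament):
            phase = rng.uniform(0.0, spec.dimer_repeat) / voxel
            lateral = rng.uniform(-shift_max, shift_max)
            d = phase * axis + lateral * np.array([-axis[1], axis[0]])
            o0, o1 = int(round(d[0])), int(round(d[1]))
            img = base[pad0 + o0: pad0 + o0 + box, pad1 + o1: pad1 + o1 + box].copy()
            if sigma > 0:
                img = img + rng.normal(0.0, sigma, img.shape)
            boxes.append(img)
            records.append(
                AlignmentRecord(
                    rot=rot, tilt=tilt, psi=psi, shift=(float(-o0), float(-o1)),
                    pf_class=spec.n_pf, seam_index=seam, polarity=pol,
                    filament_id=fid, repeat_index=si, score=1.0,
                )
            )
            fil_ids.append(fid)

    stack = SegmentStack(
        np.array(boxes), voxel, np.zeros((len(boxes), 2)), spec.dimer_repeat
    )
    return SyntheticDataset(
        stack=stack, records=records, filament_ids=np.array(fil_ids),
        truths=truths, spec=spec, snr=snr, seed=seed,
    )
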