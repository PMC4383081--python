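"""Pseudo-helical single-particle reconstruction of decorated microtubules.

A microtubule with a seam has no true helical symmetry, so processing
follows the pseudo-helical scheme: per-filament protofilament-number
classification, orientation search within a ±15° out-of-plane tilt
window, per-filament seam and polarity determination, remapping to
exactly one box per 8 nm repeat, direct-Fourier reconstruction of
half-maps, symmetrization of all asymmetric units onto one 'good'
protofilament followed by rebuilding through complementary wedge masks,
tight masking, and FSC resolution estimation with the 0.143 criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .fourier import fourier_shift_2d, lowpass
from .geometry import euler_matrix, rot_z
from .micrograph import SegmentStack
from .imaging import Movie, project_volume
from .render import Volume

TILT_MIN, TILT_MAX = 75.0, 105.0  # ±15° about edge-on


@dataclass
class AlignmentRecord:
    """Refined parameters of one boxed segment."""

    rot: float = 0.0
    tilt: float = 90.0
    psi: float = 0.0
    shift: tuple[float, float] = (0.0, 0.0)
    pf_class: int = 14
    seam_index: int = 0
    polarity: str = "+"
    score: float = 0.0
    filament_id: int = 0
    repeat_index: int = 0
    excluded: bool = False

    def euler(self) -> tuple[float, float, float]:
        return (self.rot, self.tilt, self.psi)


@dataclass
class FSCCurve:
    shell_freq: np.ndarray  # 1/Å, strictly increasing
    correlation: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_inv_A": self.shell_freq, "fsc": self.correlation})


# ---------------------------------------------------------------------------
# references and scoring


def make_reference(volume: Volume, cutoff: float) -> Volume:
    """Low-pass filtered alignment reference (soft cosine-edge cutoff)."""
    out = volume.copy()
    out.data = lowpass(volume.data, volume.voxel_size, cutoff)
    return out


class ProjectionLibrary:
    """Fast reference projections by Fourier central-slice extraction.

    The reference volume is Fourier-transformed once; each requested
    orientation samples a central slice (trilinear interpolation of the
    complex coefficients) and inverse-transforms it — the exact adjoint
    of the direct-Fourier reconstruction used here.  Projections are
    cached keyed by quantized Euler angles (default 0.25°, the finest
    search step), so searches over shared grids hit the cache.
    """

    def __init__(self, reference: Volume, out_shape: tuple[int, int], quantum: float = 0.25):
        self.reference = reference
        self.out_shape = out_shape
        self.quantum = quantum
        self._cache: dict[tuple[int, int, int], np.ndarray] = {}
        n = reference.shape[0]
        if reference.shape != (n, n, n):
            raise ValueError("reference volume must be cubic")
        if out_shape[0] != n or out_shape[1] != n:
            raise ValueError("projection shape must match the volume face")
        self.n = n
        c = (n - 1) / 2.0
        f = np.fft.fftfreq(n)
        p = np.exp(2j * np.pi * f * c)
        self._F3 = np.fft.fftn(reference.data) * (
            p[:, None, None] * p[None, :, None] * p[None, None, :]
        )
        q0, q1 = np.meshgrid(f, f, indexing="ij")
        self._qimg = np.stack([q0.ravel(), q1.ravel(), np.zeros(n * n)])
        self._uncenter = np.exp(-2j * np.pi * (q0 + q1) * c)

    def _project(self, rot: float, tilt: float, psi: float) -> np.ndarray:
        from scipy.ndimage import map_coordinates

        R = euler_matrix(rot, tilt, psi)
        q3 = ((R.T @ self._qimg) * self.n) % self.n
        re = map_coordinates(self._F3.real, q3, order=1, mode="grid-wrap")
        im = map_coordinates(self._F3.imag, q3, order=1, mode="grid-wrap")
        F2 = (re + 1j * im).reshape(self.n, self.n) * self._uncenter
        return np.real(np.fft.ifft2(F2)) * self.reference.voxel_size

    def get(self, rot: float, tilt: float, psi: float) -> np.ndarray:
        key = tuple(int(round(a / self.quantum)) for a in (rot % 360.0, tilt, psi))
        if key not in self._cache:
            if len(self._cache) > 8000:  # bound memory on long searches
                self._cache.pop(next(iter(self._cache)))
            angles = tuple(k * self.quantum for k in key)
            self._cache[key] = self._project(*angles).astype(np.float32)
        return self._cache[key]

    def get_fft(self, rot: float, tilt: float, psi: float) -> tuple[np.ndarray, float]:
        """Conjugate FFT and norm of the zero-mean template (cached),
        for one-inverse-FFT correlation scoring."""
        key = ("fft",) + tuple(int(round(a / self.quantum)) for a in (rot % 360.0, tilt, psi))
        if key not in self._cache:
            if len(self._cache) > 8000:
                self._cache.pop(next(iter(self._cache)))
            tmpl = self.get(rot, tilt, psi).astype(np.float64)
            b = tmpl - tmpl.mean()
            self._cache[key] = (np.conj(np.fft.fft2(b)).astype(np.complex64), float(np.linalg.norm(b)))
        return self._cache[key]


class SegmentScorer:
    """Precomputed zero-mean FFT of one segment, for repeated scoring."""

    def __init__(self, segment: np.ndarray):
        a = segment - segment.mean()
        self.fa = np.fft.fft2(a)
        self.na = float(np.linalg.norm(a))
        self.shape = segment.shape

    def score(self, library: "ProjectionLibrary", rot: float, tilt: float, psi: float,
              max_shift: float = 8.0) -> tuple[float, tuple[float, float]]:
        from .micrograph import _masked_peak

        conj_fb, nb = library.get_fft(rot, tilt, psi)
        if self.na == 0 or nb == 0:
            return 0.0, (0.0, 0.0)
        cc = np.real(np.fft.ifft2(self.fa * conj_fb)) / (self.na * nb)
        d0, d1, _ = _masked_peak(cc, max_shift)
        i, j = int(round(d0)) % cc.shape[0], int(round(d1)) % cc.shape[1]
        return float(cc[i, j]), (d0, d1)


def score_shift(segment: np.ndarray, template: np.ndarray, max_shift: float = 8.0) -> tuple[float, tuple[float, float]]:
    """Best normalized cross-correlation over shifts within ±max_shift px.

    Returns (correlation in [-1, 1], subpixel shift of the template that
    best matches the segment)."""
    from .micrograph import _masked_peak

    a = segment - segment.mean()
    b = template - template.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0, (0.0, 0.0)
    cc = np.real(np.fft.ifft2(np.fft.fft2(a) * np.conj(np.fft.fft2(b)))) / (na * nb)
    d0, d1, _ = _masked_peak(cc, max_shift)
    i, j = int(round(d0)) % cc.shape[0], int(round(d1)) % cc.shape[1]
    return float(cc[i, j]), (d0, d1)


# ---------------------------------------------------------------------------
# orientation search


def _angle_grid(center: float, half_range: float, step: float) -> np.ndarray:
    n = int(np.floor(half_range / step))
    return center + step * np.arange(-n, n + 1)


def global_search(
    segment: np.ndarray,
    library: ProjectionLibrary,
    psi0: float,
    rot_step: float = 4.0,
    tilt_step: float = 5.0,
    psi_halfrange: float = 4.0,
    max_shift: float = 8.0,
    score_floor: float = 0.0,
) -> AlignmentRecord:
    """Semi-exhaustive orientation search followed by local refinement.

    The in-plane angle is restricted to a window around the Radon
    estimate ``psi0``; the out-of-plane tilt spans the ±15° window about
    edge-on; the azimuth ``rot`` is searched exhaustively.  Coarse 4°
    sampling is followed by 1° and 0.25° local refinement, with shifts
    optimized by FFT cross-correlation and parabolic subpixel
    interpolation at every step.  A best score below ``score_floor``
    marks the segment for exclusion.
    """
    best = AlignmentRecord(score=-np.inf)
    scorer = SegmentScorer(segment)
    rots = np.arange(0.0, 360.0, rot_step)
    tilts = _angle_grid(90.0, 15.0, tilt_step)
    # coarse stage holds psi at the Radon estimate; the local stages
    # refine psi within its (subdegree) uncertainty
    psis = (psi0,) if psi_halfrange <= rot_step else _angle_grid(psi0, psi_halfrange, rot_step)
    for rot in rots:
        for tilt in tilts:
            for psi in psis:
                s, d = scorer.score(library, rot, tilt, psi, max_shift)
                if s > best.score:
                    best = AlignmentRecord(rot=rot, tilt=tilt, psi=psi, shift=d, score=s)
    best = local_search(segment, library, best, steps=(1.0, 0.25), max_shift=max_shift, _scorer=scorer)
    if best.score < score_floor:
        best.excluded = True
    return best


def local_search(
    segment: np.ndarray,
    library: ProjectionLibrary,
    start: AlignmentRecord,
    steps: tuple[float, ...] = (1.0, 0.25),
    n_steps: int = 2,
    max_shift: float = 8.0,
    n_sweeps: int = 2,
    _scorer: SegmentScorer | None = None,
) -> AlignmentRecord:
    """Refine Euler angles on successively finer local grids.

    Each stage runs coordinate-descent sweeps over (rot, tilt, psi) on
    grids snapped to absolute multiples of the step, so that segments
    refining near the same orientation share the projection cache.
    Shifts are re-optimized by FFT cross-correlation at every
    evaluation.
    """
    best = start
    scorer = _scorer or SegmentScorer(segment)

    def snapped(center, step):
        c = step * round(center / step)
        return c + step * np.arange(-n_steps, n_steps + 1)

    for step in steps:
        for _ in range(n_sweeps):
            before = best.score
            for rot in snapped(best.rot, step):
                s, d = scorer.score(library, rot, best.tilt, best.psi, max_shift)
                if s > best.score:
                    best = dc_replace(best, rot=rot, shift=d, score=s)
            for tilt in snapped(best.tilt, step):
                tilt = float(np.clip(tilt, TILT_MIN, TILT_MAX))
                s, d = scorer.score(library, best.rot, tilt, best.psi, max_shift)
                if s > best.score:
                    best = dc_replace(best, tilt=tilt, shift=d, score=s)
            for psi in snapped(best.psi, step):
                s, d = scorer.score(library, best.rot, best.tilt, psi, max_shift)
                if s > best.score:
                    best = dc_replace(best, psi=psi, shift=d, score=s)
            if best.score <= before + 1e-12:
                break
    return best


# ---------------------------------------------------------------------------
# protofilament-number classification


def classify_pf_number(
    stack: SegmentStack,
    references: dict[int, ProjectionLibrary],
    psi0: float = 0.0,
    filament_ids: np.ndarray | None = None,
    rot_step: float = 8.0,
) -> tuple[np.ndarray, int | dict[int, int]]:
    """Multi-reference protofilament-number classification (12-15 pf).

    Each segment takes the class whose reference achieves the best
    correlation over its orientation search; the filament-level class is
    the majority vote over its segments.  Ties break toward the lower
    protofilament number.

    Returns (per-segment classes, filament class) — the latter a dict
    per filament when ``filament_ids`` is given.
    """
    per_segment = np.empty(len(stack), dtype=int)
    for i, seg in enumerate(stack.boxes):
        best_class, best_score = None, -np.inf
        for n_pf in sorted(references):
            rec = global_search(seg, references[n_pf], psi0, rot_step=rot_step)
            if rec.score > best_score + 1e-12:  # tie -> lower pf wins
                best_class, best_score = n_pf, rec.score
        per_segment[i] = best_class

    def majority(classes: np.ndarray) -> int:
        vals, counts = np.unique(classes, return_counts=True)
        return int(vals[np.lexsort((vals, -counts))][0])  # tie -> lower pf

    if filament_ids is None:
        return per_segment, majority(per_segment)
    out = {}
    for fid in np.unique(filament_ids):
        out[int(fid)] = majority(per_segment[filament_ids == fid])
    return per_segment, out


# ---------------------------------------------------------------------------
# seam / polarity determination


def helical_transform(volume: Volume, angle_deg: float, rise_ang: float, wrap: bool = False) -> Volume:
    """Rotate about the filament (z) axis and shift axially.

    The rotation acts in the (x, y) = (axis0, axis1) plane about the
    grid centre; the rise shifts along axis 2 (trilinear interpolation).
    With ``wrap=True`` the axial shift wraps circularly — exact for a
    filament spanning the box when the box length is a multiple of the
    dimer repeat (the reconstruction-box convention); otherwise the ends
    fill with zeros."""
    R = rot_z(angle_deg)
    c = (np.array(volume.shape) - 1) / 2.0
    mat = R.T
    offset = c - mat @ c
    offset[2] -= rise_ang / volume.voxel_size * mat[2, 2]
    # rotation about z leaves axis 2 decoupled: mat[2] = (0, 0, 1)
    out = volume.copy()
    mode = "grid-wrap" if wrap else "constant"
    out.data = ndimage.affine_transform(volume.data, mat, offset=offset, order=1, mode=mode)
    return out


def flip_polarity(volume: Volume) -> Volume:
    """Rotate the volume 180° about the x (axis 0) axis — a proper
    rotation reversing the filament's plus/minus direction."""
    out = volume.copy()
    out.data = volume.data[:, ::-1, ::-1].copy()
    return out


def seam_candidate_volumes(reference: Volume, n_pf: int, rise_per_pf: float) -> dict[tuple[int, str], Volume]:
    """The 2N candidate references: N seam rotations × 2 polarities.

    Candidate ``k`` applies the 1-start helical operator k times
    (rotation by k·360/n_pf with rise k·start·monomer_rise/n_pf), which
    carries the seam to a new azimuth while leaving the rest of the
    lattice in register."""
    twist = 360.0 / n_pf
    out = {}
    for k in range(n_pf):
        v = helical_transform(reference, k * twist, k * rise_per_pf, wrap=True) if k else reference
        out[(k, "+")] = v
        out[(k, "-")] = flip_polarity(v)
    return out


def build_seam_libraries(
    candidates: dict[tuple[int, str], Volume], shape: tuple[int, int]
) -> dict[tuple[int, str], ProjectionLibrary]:
    """Projection libraries for the seam/polarity candidates, built once
    and reusable across all filaments of a dataset."""
    return {key: ProjectionLibrary(vol, shape) for key, vol in candidates.items()}


def seam_score_table(
    stack: SegmentStack,
    candidates: dict[tuple[int, str], Volume] | dict[tuple[int, str], ProjectionLibrary],
    records: list[AlignmentRecord],
    max_shift: float = 8.0,
) -> pd.DataFrame:
    """Score every segment against every seam/polarity candidate at its
    refined orientation (shift-optimized NCC)."""
    rows = []
    libs = {
        key: (v if isinstance(v, ProjectionLibrary) else ProjectionLibrary(v, stack.boxes.shape[1:]))
        for key, v in candidates.items()
    }
    for i, (seg, rec) in enumerate(zip(stack.boxes, records)):
        scorer = SegmentScorer(seg)
        for (k, pol), lib in libs.items():
            s, _ = scorer.score(lib, rec.rot, rec.tilt, rec.psi, max_shift)
            rows.append({"segment": i, "seam": k, "polarity": pol, "score": s})
    return pd.DataFrame(rows)


def find_seam_polarity(
    score_table: pd.DataFrame,
    margin_threshold: float = 0.004,
) -> tuple[int, str, bool]:
    """Filament-level seam/polarity decision by summing segment scores.

    Returns (seam_index, polarity, ambiguous).  The filament is flagged
    ambiguous when the top candidate's summed score exceeds the
    runner-up's by less than ``margin_threshold * sqrt(n_segments)``.
    The sqrt scaling matches how the top-two gap of signal-free score
    tables grows with the number of summed segments; the default
    coefficient sits at the ~95th percentile of that noise-only null
    (measured on randomized segment stacks), so a confident call means
    the margin is unlikely to be a noise ordering.  Seam candidates one
    protofilament apart are themselves ~0.99 correlated, which is why
    margins are small in absolute terms even for clean data.
    """
    sums = score_table.groupby(["seam", "polarity"])["score"].sum().sort_values(ascending=False)
    (seam, pol) = sums.index[0]
    top, runner = float(sums.iloc[0]), float(sums.iloc[1])
    n_segments = score_table["segment"].nunique()
    ambiguous = (top - runner) < margin_threshold * np.sqrt(n_segments)
    return int(seam), str(pol), ambiguous


def seam_hypothesis_record(record: AlignmentRecord, k: int, polarity: str, n_pf: int) -> AlignmentRecord:
    """The Euler angles a segment would take under an alternative
    seam/polarity hypothesis.

    Projecting the k-times helically transformed reference at angles R
    equals projecting the untransformed reference at azimuth
    ``rot + k*360/n_pf``; the polarity flip maps
    ``(rot, tilt, psi) -> (-rot, 180-tilt, psi+180)``.  Enumerating k in
    [0, n_pf) for both polarities spans all 2N candidates through a
    single projection library.
    """
    twist = 360.0 / n_pf
    rot, tilt, psi = record.rot, record.tilt, record.psi
    if polarity == "-":
        rot, tilt, psi = -rot, 180.0 - tilt, psi + 180.0
    return dc_replace(
        record, rot=(rot + k * twist) % 360.0, tilt=tilt,
        psi=((psi + 180.0) % 360.0) - 180.0,
    )


def invert_seam_hypothesis(k: int, polarity: str, n_pf: int) -> tuple[int, str]:
    """Inverse candidate transform: '+' rotations invert to (n-k, '+');
    flip hypotheses are involutions."""
    if polarity == "-":
        return k, "-"
    return (-k) % n_pf, "+"


def _euler_distance(a: AlignmentRecord, b: AlignmentRecord) -> float:
    """Geodesic angle (degrees) between two orientations."""
    Ra = euler_matrix(a.rot, a.tilt, a.psi)
    Rb = euler_matrix(b.rot, b.tilt, b.psi)
    cos = np.clip((np.trace(Ra.T @ Rb) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def consensus_orientation(
    records: list[AlignmentRecord],
    n_pf: int,
    max_distance: float = 8.0,
) -> AlignmentRecord:
    """Filament-consensus orientation from per-segment alignments.

    Segments of a straight filament share one view, but independent
    alignments can land in different seam/polarity candidate frames.
    Each record is mapped into the best-scoring segment's frame through
    the nearest candidate transform; records within ``max_distance``
    degrees of that frame are averaged (score-weighted, rotation via
    the mean rotation matrix), giving a consensus with smaller angular
    error than any single segment.
    """
    anchor = max(records, key=lambda r: r.score)
    acc = np.zeros((3, 3))
    w_sum = 0.0
    for r in records:
        best_c, best_d = None, np.inf
        for k in range(n_pf):
            for pol in ("+", "-"):
                d = _euler_distance(seam_hypothesis_record(anchor, k, pol, n_pf), r)
                if d < best_d:
                    best_c, best_d = (k, pol), d
        if best_d > max_distance:
            continue
        ki, pi = invert_seam_hypothesis(*best_c, n_pf)
        mapped = seam_hypothesis_record(r, ki, pi, n_pf)
        w = max(r.score, 0.0) + 1e-6
        acc += w * euler_matrix(mapped.rot, mapped.tilt, mapped.psi)
        w_sum += w
    if w_sum == 0:
        return anchor
    U, _, Vt = np.linalg.svd(acc / w_sum)
    R = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
    # decompose back to ZYZ
    tilt = float(np.degrees(np.arccos(np.clip(R[2, 2], -1, 1))))
    if abs(R[2, 2]) < 1 - 1e-9:
        rot = float(np.degrees(np.arctan2(R[2, 1], -R[2, 0])))
        psi = float(np.degrees(np.arctan2(R[1, 2], R[0, 2])))
    else:
        rot, psi = anchor.rot, anchor.psi
    return dc_replace(anchor, rot=rot % 360.0, tilt=tilt, psi=psi)


def records_to_reference_frame(
    records: list[AlignmentRecord], seam: int, polarity: str, n_pf: int
) -> list[AlignmentRecord]:
    """Re-express segment orientations in the common reference frame.

    A segment of a filament whose seam/polarity decision is (s, p)
    matches the seam-0, plus-polarity reference at modified Euler
    angles: the seam rotation adds ``s·360/n_pf`` to the azimuth, and a
    minus-polarity filament maps through the 180° flip about the image
    x axis, ``(rot, tilt, psi) -> (-rot, 180-tilt, psi+180)``.  Axial
    register is repeat-periodic and is recovered by the subsequent
    local shift refinement.
    """
    twist = 360.0 / n_pf
    out = []
    for r in records:
        rot, tilt, psi = r.rot, r.tilt, r.psi
        if polarity == "-":
            rot, tilt, psi = -rot, 180.0 - tilt, psi + 180.0
        rot = rot + seam * twist
        out.append(
            dc_replace(
                r, rot=rot % 360.0, tilt=tilt, psi=((psi + 180.0) % 360.0) - 180.0,
                seam_index=seam, polarity=polarity,
            )
        )
    return out


# ---------------------------------------------------------------------------
# repeat remapping


def remap_repeats(
    image: np.ndarray,
    stack: SegmentStack,
    records: list[AlignmentRecord],
    repeat: float,
    box_size: int | None = None,
) -> SegmentStack:
    """Re-extract exactly one box per dimer repeat along the filament.

    Refined shifts correct each segment centre; a low-order polynomial
    path is fitted through the corrected centres, then resampled by arc
    length at exactly ``repeat`` Å spacing over the filament span (one
    box per repeat, no duplicates).  Repeats whose boxes would extend
    off the image are dropped and counted in ``metadata``.
    """
    from .micrograph import extract_segments

    if box_size is None:
        box_size = stack.boxes.shape[1]
    px = stack.pixel_size
    centers = stack.source_positions + np.array([r.shift for r in records])
    # axial direction from the mean in-plane angle
    psi = np.deg2rad(np.mean([r.psi for r in records]))
    axis = np.array([np.cos(psi), np.sin(psi)])
    perp = np.array([-axis[1], axis[0]])
    s = centers @ axis  # axial coordinate, px
    t = centers @ perp  # lateral coordinate, px
    order = np.argsort(s)
    s, t = s[order], t[order]
    deg = min(3, len(s) - 1)
    poly = np.polynomial.Polynomial.fit(s, t, deg) if deg >= 1 else None

    span_px = (s.max() - s.min()) + stack.box_step / px
    n_rep = int(np.floor(span_px * px / repeat))
    s_new = s.min() + (repeat / px) * np.arange(n_rep)
    t_new = poly(s_new) if poly is not None else np.full_like(s_new, t[0])
    pts = np.outer(s_new, axis) + np.outer(t_new, perp)

    from .micrograph import extract_at_points

    new_stack = extract_at_points(image, pts, box_size, px, box_step=repeat)
    n_dropped = n_rep - len(new_stack)
    new_stack.metadata = pd.DataFrame({"n_repeats": [n_rep], "n_dropped": [n_dropped]})
    return new_stack


# ---------------------------------------------------------------------------
# reconstruction by direct Fourier insertion


def backproject(
    stack: SegmentStack,
    records: list[AlignmentRecord],
    half_split: bool = True,
) -> tuple[Volume, Volume] | Volume:
    """Direct-Fourier reconstruction from boxed segments.

    Each (shift-compensated) image's 2D Fourier transform is inserted as
    a central slice at its Euler orientation with trilinear gridding and
    overlap-weighted normalization.  Halves are split by even/odd repeat
    index; pass ``half_split=False`` for a single full map.
    """
    if half_split:
        even = [i for i, r in enumerate(records) if r.repeat_index % 2 == 0]
        odd = [i for i, r in enumerate(records) if r.repeat_index % 2 == 1]
        if not even or not odd:
            raise ValueError("one half-set is empty; cannot split by repeat parity")
        return (
            _fourier_insert(stack, records, even),
            _fourier_insert(stack, records, odd),
        )
    return _fourier_insert(stack, records, list(range(len(records))))


def _fourier_insert(
    stack: SegmentStack,
    records: list[AlignmentRecord],
    indices: list[int],
    oversample: int = 2,
) -> Volume:
    n = stack.boxes.shape[1]
    if stack.boxes.shape[2] != n:
        raise ValueError("boxes must be square")
    acc = np.zeros((n, n, n), dtype=np.complex128)
    wt = np.zeros((n, n, n), dtype=np.float64)

    # sample each slice on an `oversample`-times finer frequency grid
    # (zero-padded FFT = exact interpolation of the DFT), which reduces
    # the trilinear gridding error of the insertion
    m = oversample * n
    f = np.fft.fftfreq(m, d=1.0)  # cycles per pixel
    q0, q1 = np.meshgrid(f, f, indexing="ij")
    keep = (np.abs(q0) <= 0.5) & (np.abs(q1) <= 0.5)
    q0k, q1k = q0[keep], q1[keep]
    qimg = np.stack([q0k, q1k, np.zeros(len(q0k))])  # (3, n_samples)
    c = (n - 1) / 2.0
    # phase ramp moving the image centre to the FFT origin, so central
    # slices and the reconstructed volume share one origin convention
    recenter = np.exp(2j * np.pi * (q0k + q1k) * c)

    for i in indices:
        rec = records[i]
        if rec.excluded:
            continue
        img = fourier_shift_2d(stack.boxes[i], (-rec.shift[0], -rec.shift[1]))
        F2 = np.fft.fft2(img, s=(m, m))[keep] * recenter
        R = euler_matrix(*rec.euler())
        q3 = (R.T @ qimg) * n  # voxel-frequency coordinates
        _trilinear_scatter(acc, wt, q3, F2)

    good = wt > 1e-6
    F3 = np.zeros_like(acc)
    F3[good] = acc[good] / wt[good]
    # move the volume origin back to the grid centre
    p = np.exp(-2j * np.pi * np.fft.fftfreq(n) * c)
    F3 *= p[:, None, None] * p[None, :, None] * p[None, None, :]
    data = np.real(np.fft.ifftn(F3))
    # gridding correction: trilinear spreading in Fourier space multiplies
    # real space by a separable sinc^2 envelope — divide it back out
    t = (np.arange(n) - c) / n
    w = np.sinc(t) ** 2
    data /= w[:, None, None] * w[None, :, None] * w[None, None, :]
    vox = stack.pixel_size
    return Volume(data, vox, -vox * (np.array(data.shape) - 1) / 2.0)


def _trilinear_scatter(acc: np.ndarray, wt: np.ndarray, coords: np.ndarray, values: np.ndarray) -> None:
    """Scatter complex values into a 3D FFT-layout grid with trilinear
    weights; coordinates are signed voxel frequencies (wrapped mod N)."""
    n = acc.shape[0]
    base = np.floor(coords)
    frac = coords - base
    flat_acc = acc.ravel()
    flat_wt = wt.ravel()
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        w = np.prod(np.where(off[:, None] == 1, frac, 1.0 - frac), axis=0)
        idx = (base + off[:, None]).astype(int) % n
        flat = (idx[0] * n + idx[1]) * n + idx[2]
        np.add.at(flat_acc, flat, values * w)
        np.add.at(flat_wt, flat, w)


# ---------------------------------------------------------------------------
# pseudo-helical symmetrization


def wedge_masks(shape: tuple[int, int, int], n_pf: int, phi0: float = 0.0) -> np.ndarray:
    """Complementary soft wedge masks, one angular sector per
    protofilament (cosine edges, width 2·360/n_pf), summing to exactly
    1 at every voxel (a partition of unity)."""
    nx, ny, _ = shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = np.arange(nx)[:, None] - cx
    y = np.arange(ny)[None, :] - cy
    phi = np.rad2deg(np.arctan2(y, x))  # azimuth in the (axis0, axis1) plane
    delta = 360.0 / n_pf
    masks = np.empty((n_pf, nx, ny))
    for k in range(n_pf):
        d = (phi - phi0 - k * delta + 180.0) % 360.0 - 180.0
        m = np.zeros_like(phi)
        inside = np.abs(d) < delta
        m[inside] = 0.5 * (1.0 + np.cos(np.pi * d[inside] / delta))
        masks[k] = m
    # exact partition of unity (fixes boundary duplication at |d| = delta)
    masks /= masks.sum(axis=0, keepdims=True)
    return masks


def symmetrize_pseudo_helical(
    volume: Volume,
    n_pf: int,
    rise: float,
    twist: float | None = None,
    phi0: float = 0.0,
    wrap: bool = True,
) -> Volume:
    """Average all asymmetric units onto one 'good' protofilament, then
    rebuild the filament from transformed copies combined through
    complementary wedge masks.

    ``rise`` is the inter-protofilament rise (start·monomer_rise/n_pf,
    Å) and ``twist`` the inter-protofilament azimuth (default 360/n_pf).
    ``wrap=True`` (default) treats the box as axially periodic — exact
    for reconstruction boxes whose length is a multiple of the dimer
    repeat; use ``wrap=False`` for an object contained within the box.
    """
    if twist is None:
        twist = 360.0 / n_pf
    if abs(twist * n_pf - 360.0) > 1e-6:
        raise ValueError("twist must equal 360/n_pf for a closed lattice")
    if rise / volume.voxel_size > volume.shape[2] / 2:
        raise ValueError("rise is too large for the volume grid")

    # (i) average onto the good protofilament
    avg = volume.data.copy()
    for k in range(1, n_pf):
        avg += helical_transform(volume, -k * twist, -k * rise, wrap=wrap).data
    avg /= n_pf
    avg_vol = Volume(avg, volume.voxel_size, volume.origin.copy())

    # (ii) regenerate all protofilaments, (iii) combine via wedge masks
    masks = wedge_masks(volume.shape, n_pf, phi0=phi0)
    out = np.zeros_like(avg)
    for k in range(n_pf):
        copy = helical_transform(avg_vol, k * twist, k * rise, wrap=wrap) if k else avg_vol
        out += masks[k][:, :, None] * copy.data
    return Volume(out, volume.voxel_size, volume.origin.copy())


# ---------------------------------------------------------------------------
# masking and FSC


def make_tight_mask(
    volume: Volume,
    threshold: float = 0.2,
    smooth: float = 10.0,
    lowpass_res: float = 20.0,
) -> Volume:
    """Soft solvent mask from a thresholded low-resolution map.

    The map is low-passed, binarized at ``threshold`` × max, and
    smoothed with a Gaussian of ``smooth`` Å half-width (HWHM); values
    lie in [0, 1].
    """
    if smooth <= volume.voxel_size:
        raise ValueError("smooth must exceed the voxel size")
    if threshold <= 0.0:
        return Volume(np.ones(volume.shape), volume.voxel_size, volume.origin.copy())
    lp = lowpass(volume.data, volume.voxel_size, lowpass_res) if np.isfinite(lowpass_res) else volume.data
    binary = (lp >= threshold * lp.max()).astype(float)
    if binary.sum() == 0:
        raise ValueError("empty mask: threshold too high")
    sigma_vox = smooth / np.sqrt(2.0 * np.log(2.0)) / volume.voxel_size  # HWHM -> sigma
    soft = ndimage.gaussian_filter(binary, sigma_vox)
    return Volume(np.clip(soft, 0.0, 1.0), volume.voxel_size, volume.origin.copy())


def fsc(map_a: Volume, map_b: Volume, mask: Volume | None = None) -> FSCCurve:
    """Fourier shell correlation between two maps on the same grid."""
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a grid")
    a = map_a.data * mask.data if mask is not None else map_a.data
    b = map_b.data * mask.data if mask is not None else map_b.data
    fa, fb = np.fft.fftn(a), np.fft.fftn(b)
    n = a.shape[0]
    from .fourier import radial_freq

    q = radial_freq(a.shape, map_a.voxel_size)
    shell = np.round(q * n * map_a.voxel_size).astype(int)  # radius in Fourier px
    n_shells = n // 2
    num = np.zeros(n_shells)
    da = np.zeros(n_shells)
    db = np.zeros(n_shells)
    flat = shell.ravel()
    valid = flat < n_shells
    np.add.at(num, flat[valid], np.real(fa.ravel()[valid] * np.conj(fb.ravel()[valid])))
    np.add.at(da, flat[valid], np.abs(fa.ravel()[valid]) ** 2)
    np.add.at(db, flat[valid], np.abs(fb.ravel()[valid]) ** 2)
    corr = np.ones(n_shells)
    nz = (da > 0) & (db > 0)
    corr[nz] = num[nz] / np.sqrt(da[nz] * db[nz])
    freq = np.arange(n_shells) / (n * map_a.voxel_size)
    return FSCCurve(shell_freq=freq[1:], correlation=corr[1:])


def resolution_at(curve: FSCCurve, threshold: float = 0.143) -> tuple[float, bool]:
    """Resolution (Å) where the FSC first drops below the threshold,
    linearly interpolated in frequency between shells.

    Returns (resolution, crossed); when the curve never crosses, the
    Nyquist resolution is returned with ``crossed = False``."""
    c = curve.correlation
    f = curve.shell_freq
    below = np.where(c < threshold)[0]
    if len(below) == 0 or below[0] == 0:
        if len(below) == 0:
            return float(1.0 / f[-1]), False
        return float(1.0 / f[0]), True
    i = below[0]
    f_cross = f[i - 1] + (f[i] - f[i - 1]) * (c[i - 1] - threshold) / (c[i - 1] - c[i])
    return float(1.0 / f_cross), True


# ---------------------------------------------------------------------------
# refinement driver


@dataclass
class RefineResult:
    volume: Volume
    records: list[AlignmentRecord]
    fsc_curve: FSCCurve
    resolution: float
    mean_scores: list[float] = field(default_factory=list)
    report: dict = field(default_factory=dict)


class RefinementDiverged(RuntimeError):
    def __init__(self, report: dict):
        super().__init__(f"mean score diverged across rounds: {report}")
        self.report = report


def refine(
    stack: SegmentStack,
    records: list[AlignmentRecord],
    initial_reference: Volume,
    n_pf: int,
    rise_per_pf: float,
    ladder: tuple[float, ...] = (20.0, 15.0, 12.0, 10.0),
    mask_threshold: float = 0.2,
    local_steps: tuple[float, ...] = (2.0, 0.5),
    divergence_tol: float = 0.05,
) -> RefineResult:
    """Iterative local refinement and reconstruction.

    Per round: local orientation/shift search against the current
    reference low-passed at the ladder cutoff, half-map reconstruction
    (even/odd repeat split), pseudo-helical symmetrization, tight
    masking, and hand-off of the masked map as the next reference.  The
    final FSC comes from the masked symmetrized half-maps.  A drop of
    the mean correlation score by more than ``divergence_tol`` between
    rounds aborts with a report.
    """
    reference = initial_reference
    records = [dc_replace(r) for r in records]
    mean_scores: list[float] = []
    half_maps = None
    # divergence diagnostic: scores are evaluated against ONE fixed
    # reference (the starting reference at the first ladder cutoff) each
    # round — scores against the evolving, re-reconstructed references
    # are not comparable round-to-round
    eval_lib = ProjectionLibrary(make_reference(initial_reference, ladder[0]), stack.boxes.shape[1:])
    scorers = [SegmentScorer(seg) for seg in stack.boxes]
    for rnd, cutoff in enumerate(ladder):
        ref_lp = make_reference(reference, cutoff)
        library = ProjectionLibrary(ref_lp, stack.boxes.shape[1:])
        new_records = []
        for seg, rec, scorer in zip(stack.boxes, records, scorers):
            new_records.append(
                local_search(seg, library, dc_replace(rec, score=-np.inf), steps=local_steps, _scorer=scorer)
            )
        records = new_records
        eval_scores = [
            scorer.score(eval_lib, r.rot, r.tilt, r.psi)[0]
            for scorer, r in zip(scorers, records)
        ]
        mean_score = float(np.mean(eval_scores))
        if mean_scores and mean_score < mean_scores[-1] - divergence_tol:
            raise RefinementDiverged({"round": rnd, "mean_scores": mean_scores + [mean_score]})
        mean_scores.append(mean_score)

        half_a, half_b = backproject(stack, records, half_split=True)
        sym_a = symmetrize_pseudo_helical(half_a, n_pf, rise_per_pf)
        sym_b = symmetrize_pseudo_helical(half_b, n_pf, rise_per_pf)
        full = Volume((sym_a.data + sym_b.data) / 2.0, sym_a.voxel_size, sym_a.origin.copy())
        mask = make_tight_mask(full, threshold=mask_threshold)
        half_maps = (sym_a, sym_b, mask)
        reference = Volume(full.data * mask.data, full.voxel_size, full.origin.copy())

    curve = fsc(half_maps[0], half_maps[1], half_maps[2])
    res, crossed = resolution_at(curve)
    return RefineResult(
        volume=reference,
        records=records,
        fsc_curve=curve,
        resolution=res,
        mean_scores=mean_scores,
        report={"resolution_A": res, "fsc_crossed": crossed, "rounds": len(ladder)},
    )


# ---------------------------------------------------------------------------
# per-frame sub-average refinement


def subframe_refine(
    movies: list[Movie],
    records: list[AlignmentRecord],
    reference: Volume,
    group_size: int = 5,
    n_groups: int = 3,
    local_steps: tuple[float, ...] = (0.5,),
) -> tuple[list[list[AlignmentRecord]], list[bool]]:
    """Re-refine each segment from frame sub-averages.

    Each segment's movie is divided into ``n_groups`` sub-averages of
    ``group_size`` frames, and each sub-average is locally re-refined
    starting from the full-average parameters.  A movie with too few
    frames falls back to its full average (flagged).

    Returns (per-segment lists of refined records, fallback flags).
    """
    out: list[list[AlignmentRecord]] = []
    fallbacks: list[bool] = []
    shape = movies[0].frames.shape[1:]
    library = ProjectionLibrary(reference, shape)
    for movie, rec in zip(movies, records):
        if movie.n_frames < group_size * n_groups:
            avg = movie.average()
            out.append([local_search(avg, library, dc_replace(rec, score=-np.inf), steps=local_steps)])
            fallbacks.append(True)
            continue
        sub_records = []
        for g in range(n_groups):
            sub = movie.frames[g * group_size:(g + 1) * group_size].mean(axis=0)
            sub_records.append(local_search(sub, library, dc_replace(rec, score=-np.inf), steps=local_steps))
        out.append(sub_records)
        fallbacks.append(False)
    return out, fallbacks
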