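"""Rigid-body analysis of conformational changes between atomic models.

Quantifies the articulated subdomain motions of the kinesin motor
domain (the seesaw of the N-terminal subdomain, the smaller rotation of
the upper subdomain, and the microtubule-anchored switch II cluster /
lower subdomain) by least-squares superposition and axis-angle (screw)
decomposition, plus backbone RMSD, hydrogen-bond network checks and
steric-clash scanning between models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Standard van der Waals radii (Å) by element.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "MG": 1.73, "FE": 1.80,
    "ZN": 1.39, "NA": 2.27, "K": 2.75,
}


@dataclass
class AtomicModel:
    """Flat atom table: parallel arrays plus coordinates (n, 3) in Å."""

    chain: np.ndarray  # str
    resnum: np.ndarray  # int
    resname: np.ndarray  # str
    atom_name: np.ndarray  # str
    element: np.ndarray  # str
    xyz: np.ndarray  # (n, 3) float
    model_id: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom positions must be finite")

    def __len__(self) -> int:
        return len(self.resnum)

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            self.chain.copy(), self.resnum.copy(), self.resname.copy(),
            self.atom_name.copy(), self.element.copy(), self.xyz.copy(), self.model_id,
        )

    def keys(self) -> np.ndarray:
        """Unique (chain, resnum, atom_name) identification keys."""
        return np.array([f"{c}|{r}|{a}" for c, r, a in zip(self.chain, self.resnum, self.atom_name)])

    def mask(
        self,
        chain: str | None = None,
        res_range: tuple[int, int] | None = None,
        atom_names: tuple[str, ...] | None = None,
    ) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            m &= self.chain == chain
        if res_range is not None:
            m &= (self.resnum >= res_range[0]) & (self.resnum <= res_range[1])
        if atom_names is not None:
            m &= np.isin(self.atom_name, atom_names)
        return m

    def subset(self, mask: np.ndarray) -> "AtomicModel":
        return AtomicModel(
            self.chain[mask], self.resnum[mask], self.resname[mask],
            self.atom_name[mask], self.element[mask], self.xyz[mask], self.model_id,
        )

    def atom(self, chain: str, resnum: int, name: str) -> np.ndarray | None:
        m = (self.chain == chain) & (self.resnum == resnum) & (self.atom_name == name)
        idx = np.where(m)[0]
        return self.xyz[idx[0]] if len(idx) else None

    def transformed(self, t: "RigidTransform") -> "AtomicModel":
        out = self.copy()
        out.xyz = t.apply(self.xyz)
        return out


@dataclass
class SubdomainDefinition:
    """Named subdomain as a set of inclusive residue ranges."""

    name: str
    ranges: list[tuple[str, int, int]]  # (chain, start, end)

    def mask(self, model: AtomicModel) -> np.ndarray:
        m = np.zeros(len(model), dtype=bool)
        for chain, start, end in self.ranges:
            m |= model.mask(chain=chain, res_range=(start, end))
        return m


def validate_subdomain_set(defs: list[SubdomainDefinition]) -> None:
    """Residue ranges must not overlap across one definition set."""
    seen: set[tuple[str, int]] = set()
    for d in defs:
        for chain, start, end in d.ranges:
            for r in range(start, end + 1):
                if (chain, r) in seen:
                    raise ValueError(f"residue {chain}:{r} appears in more than one subdomain")
                seen.add((chain, r))


# Nominal subdomain boundaries for the kinesin-1 motor domain (K349
# numbering).  The central beta sheet divides between the strands
# anchoring the P-loop and the switch II loop: the P-loop half plus
# helices a1/a2/a6 forms the N-terminal subdomain, the switch half plus
# L7/L8 the upper subdomain, and the switch II helix with L11/L12 the
# lower subdomain.  These defaults are NOMINAL — calibrate against the
# rigid-body rotation targets before quantitative use on real models.
KINESIN_SUBDOMAINS = [
    SubdomainDefinition("N-terminal", [("K", 1, 127), ("K", 291, 349)]),
    SubdomainDefinition("upper", [("K", 128, 237)]),
    SubdomainDefinition("lower", [("K", 238, 290)]),
]


@dataclass
class RigidTransform:
    """Proper rigid-body transform ``x -> R x + t``."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9 or abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper orthogonal")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}


def pair_atoms(a: AtomicModel, b: AtomicModel) -> tuple[np.ndarray, np.ndarray]:
    """Indices of atoms shared by both models, matched by
    (chain, residue number, atom name); order follows model ``a``."""
    kb = {k: i for i, k in enumerate(b.keys())}
    ia, ib = [], []
    for i, k in enumerate(a.keys()):
        j = kb.get(k)
        if j is not None:
            ia.append(i)
            ib.append(j)
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def superpose(
    a: AtomicModel,
    b: AtomicModel,
    selection: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``b`` onto ``a`` (Kabsch).

    Atoms pair by (chain, residue, atom name); ``selection`` is a
    boolean mask over ``a``.  Returns the optimal proper transform T
    (so that T(b) ≈ a) and the RMSD over the paired selection.
    """
    ia, ib = pair_atoms(a, b)
    if selection is not None:
        keep = selection[ia]
        ia, ib = ia[keep], ib[keep]
    if len(ia) < 3:
        raise ValueError(f"need >= 3 paired atoms, found {len(ia)}")
    P, Q = a.xyz[ia], b.xyz[ib]
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    rmsd = float(np.sqrt(np.mean(np.sum((P - (Q @ R.T + t)) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


@dataclass
class AxisAngle:
    angle: float  # degrees in [0, 180]
    axis: np.ndarray  # unit 3-vector
    screw_point: np.ndarray  # point on the axis minimizing displacement
    degenerate: bool = False  # angle below resolution; axis undefined


def axis_angle(t: RigidTransform, min_angle: float = 0.1) -> AxisAngle:
    """Axis-angle (screw) decomposition of a rigid transform.

    The angle is ``arccos((trace(R) - 1)/2)`` in [0°, 180°]; the axis
    sign is chosen so the angle is non-negative.  The screw point is
    the point on the axis with minimal displacement, from the least-
    squares solution of ``(R - I) p = -t_perp``.  Rotations below
    ``min_angle`` degrees leave the axis undefined (flagged).
    """
    R = t.rotation
    cos_a = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_a)))
    if angle < min_angle:
        return AxisAngle(angle, np.array([0.0, 0.0, 1.0]), np.zeros(3), degenerate=True)
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if np.linalg.norm(w) > 1e-9:
        axis = w / np.linalg.norm(w)
    else:  # 180° rotation: axis from the eigenvector of R with eigenvalue +1
        vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
        axis = vecs[:, np.argmax(vals)]
    t_par = (t.translation @ axis) * axis
    t_perp = t.translation - t_par
    p, *_ = np.linalg.lstsq(R - np.eye(3), -t_perp, rcond=None)
    p = p - (p @ axis) * axis  # fix the free component along the axis
    return AxisAngle(angle, axis, p, degenerate=False)


def subdomain_rotations(
    state_a: AtomicModel,
    state_b: AtomicModel,
    definitions: list[SubdomainDefinition] | None = None,
    frame_selection: np.ndarray | None = None,
    min_atoms: int = 10,
) -> pd.DataFrame:
    """Per-subdomain rigid-body rotation between two conformational states.

    Both states are first superposed on the common frame selection
    (e.g., tubulin, or the microtubule-anchored lower subdomain); each
    subdomain's residual motion is then summarized by the axis-angle of
    its own backbone superposition.  Subdomains with fewer than
    ``min_atoms`` paired backbone atoms are excluded.
    """
    if definitions is None:
        definitions = KINESIN_SUBDOMAINS
    validate_subdomain_set(definitions)
    b = state_b
    if frame_selection is not None:
        t_frame, _ = superpose(state_a, state_b, frame_selection & np.isin(state_a.atom_name, BACKBONE_ATOMS))
        b = state_b.transformed(t_frame)
    rows = []
    bb = np.isin(state_a.atom_name, BACKBONE_ATOMS)
    for d in definitions:
        sel = d.mask(state_a) & bb
        ia, _ = pair_atoms(state_a, b)
        n_paired = int(sel[ia].sum())
        if n_paired < min_atoms:
            continue
        t, rmsd = superpose(state_a, b, sel)
        aa = axis_angle(t)
        rows.append(
            {
                "subdomain": d.name, "angle_deg": aa.angle,
                "axis_x": aa.axis[0], "axis_y": aa.axis[1], "axis_z": aa.axis[2],
                "rmsd_A": rmsd, "n_atoms": n_paired, "degenerate": aa.degenerate,
            }
        )
    return pd.DataFrame(rows)


def backbone_rmsd(
    a: AtomicModel,
    b: AtomicModel,
    chain: str | None = None,
    res_range: tuple[int, int] | None = None,
) -> float:
    """Backbone (N, CA, C, O) RMSD after superposition over the same selection."""
    sel = a.mask(chain=chain, res_range=res_range, atom_names=BACKBONE_ATOMS)
    if sel.sum() == 0:
        raise ValueError("empty backbone selection")
    _, rmsd = superpose(a, b, sel)
    return rmsd


# ---------------------------------------------------------------------------
# hydrogen bonds


@dataclass
class HBondSpec:
    """Heavy-atom donor/acceptor pair, with an optional donor antecedent
    for the angle proxy (hydrogens are absent in EM-derived models)."""

    donor: tuple[str, int, str]  # (chain, resnum, atom)
    acceptor: tuple[str, int, str]
    antecedent: tuple[str, int, str] | None = None
    label: str = ""


#: Hydrogen-bond network that locks the closed switch loops: the
#: switch I / switch II salt bridge plus contacts among the universally
#: conserved cluster (Y138, R203, E236, E250, N255).  Atom-level pairs
#: are a documented default (kinesin chain "K", K349 numbering) and can
#: be replaced by user-supplied lists.
CLOSED_SWITCH_NETWORK = [
    HBondSpec(("K", 203, "NH1"), ("K", 236, "OE1"), ("K", 203, "CZ"), "R203-E236 salt bridge"),
    HBondSpec(("K", 138, "OH"), ("K", 250, "OE1"), ("K", 138, "CZ"), "Y138-E250"),
    HBondSpec(("K", 255, "ND2"), ("K", 236, "O"), ("K", 255, "CG"), "N255-E236 backbone"),
]


def hbond_check(
    model: AtomicModel,
    pairs: list[HBondSpec],
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> pd.DataFrame:
    """Evaluate hydrogen-bond presence for donor/acceptor pairs.

    A bond is present when the heavy-atom donor-acceptor distance is at
    most ``d_max`` Å and (when an antecedent atom is available) the
    antecedent-donor-acceptor angle is at least ``angle_min`` degrees.
    Pairs with missing atoms are skipped and reported.
    """
    rows = []
    for p in pairs:
        d_pos = model.atom(*p.donor)
        a_pos = model.atom(*p.acceptor)
        if d_pos is None or a_pos is None:
            rows.append({"label": p.label or str(p.donor), "distance_A": np.nan,
                         "angle_deg": np.nan, "present": False, "skipped": True})
            continue
        dist = float(np.linalg.norm(d_pos - a_pos))
        angle = np.nan
        angle_ok = True
        if p.antecedent is not None:
            ant = model.atom(*p.antecedent)
            if ant is not None:
                v1 = ant - d_pos
                v2 = a_pos - d_pos
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                angle_ok = angle >= angle_min
        rows.append({"label": p.label or str(p.donor), "distance_A": dist,
                     "angle_deg": angle, "present": dist <= d_max and angle_ok, "skipped": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# steric clashes


def clash_scan(
    mobile: AtomicModel,
    fixed: AtomicModel,
    overlap_threshold: float = 0.4,
) -> pd.DataFrame:
    """All atom pairs whose van der Waals overlap meets the threshold.

    Overlap is ``r_vdw_i + r_vdw_j - d``; pairs are found with a
    spatial tree (results identical to the all-pairs scan).  The table
    lists every clashing pair and can be aggregated per residue via
    ``clash_table.groupby(...)``.
    """
    rm = np.array([VDW_RADII.get(e.upper(), 1.7) for e in mobile.element])
    rf = np.array([VDW_RADII.get(e.upper(), 1.7) for e in fixed.element])
    cutoff = rm.max() + rf.max() - overlap_threshold
    tree = cKDTree(fixed.xyz)
    rows = []
    for i, (pos, ri) in enumerate(zip(mobile.xyz, rm)):
        for j in tree.query_ball_point(pos, cutoff):
            d = float(np.linalg.norm(pos - fixed.xyz[j]))
            overlap = ri + rf[j] - d
            if overlap >= overlap_threshold:
                rows.append(
                    {
                        "mobile_chain": mobile.chain[i], "mobile_resnum": int(mobile.resnum[i]),
                        "mobile_atom": mobile.atom_name[i],
                        "fixed_chain": fixed.chain[j], "fixed_resnum": int(fixed.resnum[j]),
                        "fixed_atom": fixed.atom_name[j],
                        "distance_A": d, "overlap_A": float(overlap),
                    }
                )
    df = pd.DataFrame(rows, columns=[
        "mobile_chain", "mobile_resnum", "mobile_atom",
        "fixed_chain", "fixed_resnum", "fixed_atom", "distance_A", "overlap_A",
    ])
    return df.sort_values(
        ["mobile_chain", "mobile_resnum", "mobile_atom", "fixed_chain", "fixed_resnum", "fixed_atom"]
    ).reset_index(drop=True)
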