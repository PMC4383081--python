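"""File formats: MRC2014 maps, PDB models, CSV tables, YAML configs.

Volumes are written as MRC2014 mode-2 (float32) maps through gemmi,
with the voxel size carried in the cell header and the origin in the
origin fields.  The in-memory axis convention (array indexed [x, y, z],
filament axis along z) maps directly onto the MRC fast/medium/slow
axes.  Atomic models go through gemmi's PDB reader; for atoms with
alternate locations the highest-occupancy conformer is kept.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .domains import AtomicModel
from .kinetics import KineticDataset
from .render import Volume


# ---------------------------------------------------------------------------
# MRC volumes


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as an MRC2014 mode-2 map (voxel size in the header)."""
    ccp4 = gemmi.Ccp4Map()
    grid = gemmi.FloatGrid(np.ascontiguousarray(volume.data, dtype=np.float32))
    shape = volume.shape
    grid.set_unit_cell(
        gemmi.UnitCell(
            volume.voxel_size * shape[0],
            volume.voxel_size * shape[1],
            volume.voxel_size * shape[2],
            90.0, 90.0, 90.0,
        )
    )
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.set_header_float(50, float(volume.origin[0]))  # ORIGIN records
    ccp4.set_header_float(51, float(volume.origin[1]))
    ccp4.set_header_float(52, float(volume.origin[2]))
    ccp4.write_ccp4_map(str(path))


def read_volume(path: str | Path) -> Volume:
    """Read an MRC2014 map; mode-2 float expected.

    Raises a parse error for truncated or non-MRC input.
    """
    try:
        ccp4 = gemmi.Ccp4Map()
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as e:
        raise ValueError(f"cannot parse MRC file {path}: {e}") from e
    data = np.array(ccp4.grid, copy=True).astype(np.float64)
    cell = ccp4.grid.unit_cell
    vox = cell.a / data.shape[0]
    vy = cell.b / data.shape[1]
    vz = cell.c / data.shape[2]
    if abs(vy - vox) > 1e-3 or abs(vz - vox) > 1e-3:
        raise ValueError(f"anisotropic voxels not supported ({vox}, {vy}, {vz})")
    origin = np.array([ccp4.header_float(50), ccp4.header_float(51), ccp4.header_float(52)])
    return Volume(data, float(vox), origin)


# ---------------------------------------------------------------------------
# atomic models


def read_model(path: str | Path, model_id: str | None = None) -> AtomicModel:
    """Read a PDB (or mmCIF) file into an AtomicModel.

    Keeps the highest-occupancy alternate conformer per atom; tolerates
    missing side-chain atoms.  Raises on files without atoms.
    """
    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()  # keeps highest occupancy
    chains, resnums, resnames, names, elements, xyz = [], [], [], [], [], []
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                chains.append(chain.name)
                resnums.append(res.seqid.num)
                resnames.append(res.name)
                names.append(atom.name)
                elements.append(atom.element.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not xyz:
        raise ValueError(f"no ATOM records in {path}")
    return AtomicModel(
        np.array(chains), np.array(resnums, dtype=int), np.array(resnames),
        np.array(names), np.array(elements), np.array(xyz, dtype=float),
        model_id=model_id or Path(path).stem,
    )


def _gemmi_model(name: str, model: AtomicModel, xyz: np.ndarray) -> gemmi.Model:
    """Build a gemmi Model bottom-up (gemmi's add_* methods copy, so
    residues must be complete before insertion)."""
    md = gemmi.Model(name)
    chain_order: list[str] = []
    chain_residues: dict[str, list] = {}
    current_key = None
    for i in range(len(model)):
        cname = str(model.chain[i])
        rkey = (cname, int(model.resnum[i]), str(model.resname[i]))
        if rkey != current_key:
            res = gemmi.Residue()
            res.name = str(model.resname[i])
            res.seqid = gemmi.SeqId(int(model.resnum[i]), " ")
            if cname not in chain_residues:
                chain_residues[cname] = []
                chain_order.append(cname)
            chain_residues[cname].append(res)
            current_key = rkey
        atom = gemmi.Atom()
        atom.name = str(model.atom_name[i])
        atom.element = gemmi.Element(str(model.element[i]))
        atom.pos = gemmi.Position(*xyz[i])
        chain_residues[cname][-1].add_atom(atom)
    for cname in chain_order:
        chain = gemmi.Chain(cname)
        for res in chain_residues[cname]:
            chain.add_residue(res)
        md.add_chain(chain)
    return md


def write_model(model: AtomicModel, path: str | Path) -> None:
    """Write an AtomicModel as PDB (coordinates at PDB precision, 1e-3 Å)."""
    st = gemmi.Structure()
    st.name = model.model_id or "model"
    st.add_model(_gemmi_model("1", model, model.xyz))
    st.setup_entities()
    st.write_pdb(str(path))


def write_trajectory(traj, path: str | Path) -> None:
    """Write a fitting trajectory as a multi-model PDB."""
    st = gemmi.Structure()
    st.name = "trajectory"
    for fi in range(traj.n_frames):
        st.add_model(_gemmi_model(str(fi + 1), traj.model, traj.frames[fi]))
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# tables, records, config


def write_alignment_table(records, path: str | Path) -> None:
    rows = [
        {
            "filament_id": r.filament_id, "repeat_index": r.repeat_index,
            "rot": r.rot, "tilt": r.tilt, "psi": r.psi,
            "dx": r.shift[0], "dy": r.shift[1],
            "pf_class": r.pf_class, "seam": r.seam_index, "polarity": r.polarity,
            "score": r.score, "excluded": r.excluded,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_alignment_table(path: str | Path):
    from .reconstruct import AlignmentRecord

    df = pd.read_csv(path)
    return [
        AlignmentRecord(
            rot=row.rot, tilt=row.tilt, psi=row.psi, shift=(row.dx, row.dy),
            pf_class=int(row.pf_class), seam_index=int(row.seam), polarity=str(row.polarity),
            score=row.score, filament_id=int(row.filament_id),
            repeat_index=int(row.repeat_index), excluded=bool(row.excluded),
        )
        for row in df.itertuples()
    ]


def write_fsc(curve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)


def write_kinetics_csv(dataset: KineticDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def read_kinetics_csv(path: str | Path) -> KineticDataset:
    return KineticDataset.from_frame(pd.read_csv(path))


def write_truth_record(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
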