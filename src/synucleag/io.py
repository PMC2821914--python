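"""Readers and writers for the standard formats the pipeline consumes.

Small molecules go through RDKit (SDF/MOL2/PDB); partial charges are kept
as an ``PartialCharge`` atom property list in SDF so they round-trip
exactly, and Gasteiger (PEOE) charges are computed when a file carries
none. Trajectories are multi-model PDB parsed with Bio.PDB — ligand =
non-water HETATM records, protein = ATOM records (Cα required per
residue). Plate-reader ThT data and fibril measurement tables are CSV via
pandas.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from rdkit import Chem
from rdkit.Chem import AllChem

from .kinetics import ThTCurve
from .molecules import Molecule3D, vdw_radius
from .morphology import FibrilMeasurement
from .protein import ChargeSite, Frame, ProteinConformer, Residue, ResidueAtom, Trajectory

__all__ = [
    "read_molecules", "write_molecules_sdf", "molecule_from_rdkit",
    "molecule_to_rdkit", "read_trajectory", "write_trajectory",
    "read_plate_long", "read_plate_wide", "read_fibril_csv",
    "write_fibril_csv", "default_synuclein_annotations",
]

_WATER_RESNAMES = {"HOH", "WAT", "TIP", "SOL"}


def default_synuclein_annotations() -> dict[str, frozenset[int]]:
    """Canonical α-synuclein region annotations (1-based, inclusive)."""
    return {"nac": frozenset(range(61, 96)),
            "target": frozenset(range(125, 130)),
            "charged": frozenset({61, 83})}


# ---------------------------------------------------------------------------
# small molecules

def molecule_from_rdkit(mol: Chem.Mol, name: str | None = None) -> Molecule3D:
    """Convert an RDKit molecule (with a conformer) to :class:`Molecule3D`.

    Charges come from a ``PartialCharge`` atom property when present, else
    Gasteiger charges are computed on the spot.
    """
    if mol is None:
        raise ValueError("unparseable molecule")
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3-D conformer")
    conf = mol.GetConformer()
    elements, coords, charges = [], [], []
    have_props = all(a.HasProp("PartialCharge") for a in mol.GetAtoms())
    if not have_props:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:  # Gasteiger needs valence info; tolerate odd inputs
                Chem.SanitizeMol(mol)
            except Exception:
                pass
            AllChem.ComputeGasteigerCharges(mol)
    for atom in mol.GetAtoms():
        elements.append(atom.GetSymbol())
        p = conf.GetAtomPosition(atom.GetIdx())
        coords.append([p.x, p.y, p.z])
        if have_props:
            charges.append(atom.GetDoubleProp("PartialCharge"))
        else:
            q = atom.GetDoubleProp("_GasteigerCharge")
            charges.append(q if np.isfinite(q) else 0.0)
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    if name is None:
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else "mol"
    return Molecule3D(name=name or "mol", elements=elements,
                      coords=np.array(coords), charges=np.array(charges),
                      bonds=bonds)


def molecule_to_rdkit(mol: Molecule3D) -> Chem.Mol:
    """Build an RDKit molecule (no sanitisation) carrying coords + charges."""
    rw = Chem.RWMol()
    for e in mol.elements:
        rw.AddAtom(Chem.Atom(e))
    for i, j in mol.bonds:
        rw.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    m = rw.GetMol()
    conf = Chem.Conformer(mol.n_atoms)
    for i, xyz in enumerate(mol.coords):
        conf.SetAtomPosition(i, tuple(float(v) for v in xyz))
    m.AddConformer(conf)
    m.SetProp("_Name", mol.name)
    for atom, q in zip(m.GetAtoms(), mol.charges):
        atom.SetDoubleProp("PartialCharge", float(q))
        atom.SetNoImplicit(True)
    m.UpdatePropertyCache(strict=False)
    return m


def read_molecules(path: str | Path, fmt: str | None = None) -> list[Molecule3D]:
    """Read molecules from SDF, MOL2 or (single-molecule) PDB.

    Format is inferred from the suffix when not given. Coordinates are Å;
    missing charges are filled with Gasteiger values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    mols: list[Molecule3D] = []
    if fmt == "sdf":
        try:
            supplier = Chem.SDMolSupplier(str(path), removeHs=False,
                                          sanitize=False)
        except OSError as exc:
            raise ValueError(f"unreadable SDF file {path}: {exc}") from exc
        for i, m in enumerate(supplier):
            if m is None:
                raise ValueError(f"unparseable record {i} in {path}")
            mols.append(molecule_from_rdkit(m))
    elif fmt == "mol2":
        m = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
        if m is None:
            raise ValueError(f"unparseable MOL2 file {path}")
        mols.append(molecule_from_rdkit(m, name=path.stem))
    elif fmt == "pdb":
        m = Chem.MolFromPDBFile(str(path), removeHs=False, sanitize=False)
        if m is None:
            raise ValueError(f"unparseable PDB file {path}")
        mols.append(molecule_from_rdkit(m, name=path.stem))
    else:
        raise ValueError(f"unknown molecule format {fmt!r}")
    if not mols:
        raise ValueError(f"no molecules in {path}")
    return mols


def write_molecules_sdf(mols: list[Molecule3D], path: str | Path) -> None:
    """Write molecules to SDF with an exact ``PartialCharge`` property list."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mol in mols:
            m = molecule_to_rdkit(mol)
            Chem.CreateAtomDoublePropertyList(m, "PartialCharge")
            writer.write(m)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# trajectories (multi-model PDB)

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB (protein ATOM, ligand HETATM)."""
    protein, ligand = traj.protein, traj.ligand
    with open(path, "w") as fh:
        for mi, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {mi:4d}\n")
            serial = 1
            for ri, res in enumerate(protein.residues):
                shift = frame.protein_ca[ri] - res.ca
                serial = _write_atom(fh, serial, "CA", res.name, "A", res.index,
                                     frame.protein_ca[ri], "C", hetatm=False)
                for atom in res.atoms:
                    serial = _write_atom(fh, serial, atom.name, res.name, "A",
                                         res.index, atom.position + shift,
                                         atom.element, hetatm=False)
            for ai, xyz in enumerate(frame.ligand_coords):
                serial = _write_atom(fh, serial, f"L{ai + 1}", "LIG", "B", 1,
                                     xyz, ligand.elements[ai], hetatm=True)
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_atom(fh, serial, name, resname, chain, resseq, xyz, element, hetatm):
    record = "HETATM" if hetatm else "ATOM  "
    atom_name = name if len(name) == 4 else f" {name:<3s}"
    fh.write(f"{record}{serial:5d} {atom_name}{'':1s}{resname:<3s} {chain}"
             f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
             f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}\n")
    return serial + 1


def read_trajectory(path: str | Path,
                    ligand_charges: np.ndarray | None = None,
                    annotations: dict[str, frozenset[int]] | None = None,
                    ligand_name: str = "LIG",
                    charge_sites: dict[int, float] | None = None) -> Trajectory:
    """Parse a multi-model PDB into a :class:`Trajectory`.

    The ligand is the set of non-water HETATM records; waters are dropped.
    When ``annotations`` is omitted and the chain spans residue 129, the
    canonical α-synuclein regions are attached. ``charge_sites`` maps
    residue index → side-chain charge (e); by default residues named GLU or
    ASP in the charged annotation get −1 e at their side-chain centroid.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models in {path}")

    frames = []
    ref_protein: ProteinConformer | None = None
    lig_elements: list[str] | None = None
    for model in models:
        ca_list, res_meta, lig_coords, lig_elems = [], [], [], []
        for chain in model:
            for res in chain:
                hetflag = res.id[0].strip()
                resname = res.get_resname().strip()
                if hetflag:  # HETATM
                    if resname in _WATER_RESNAMES or resname == "W":
                        continue
                    for atom in res:
                        lig_coords.append(atom.coord.astype(float))
                        lig_elems.append(atom.element.strip().capitalize()
                                         or "C")
                    continue
                atoms = {a.get_name(): a for a in res}
                if "CA" not in atoms:
                    raise ValueError(f"residue {res.id[1]} lacks a CA atom")
                ca_list.append(atoms["CA"].coord.astype(float))
                extras = [ResidueAtom(a.element.strip().capitalize() or "C",
                                      name, a.coord.astype(float))
                          for name, a in atoms.items() if name != "CA"]
                res_meta.append((res.id[1], resname, extras))
        if ref_protein is None:
            lig_elements = lig_elems
            residues = []
            for idx, resname, extras in res_meta:
                residues.append(Residue(idx, resname,
                                        ca_list[len(residues)], extras))
            indices = {r.index for r in residues}
            if annotations is None and {61, 83, 125, 129} <= indices:
                annotations = default_synuclein_annotations()
            annotations = annotations or {}
            if charge_sites is None:
                charged = annotations.get("charged", frozenset())
                charge_sites = {i: -1.0 for i in charged}
            for r in residues:
                q = charge_sites.get(r.index)
                if q is not None:
                    side = [a.position for a in r.atoms
                            if a.element in ("O",)] or \
                           [a.position for a in r.atoms] or [r.ca]
                    r.charge_sites.append(ChargeSite(np.mean(side, axis=0), q))
            ref_protein = ProteinConformer(residues, dict(annotations),
                                           name=Path(path).stem)
        else:
            if len(ca_list) != ref_protein.n_residues or \
                    len(lig_elems) != len(lig_elements):
                raise ValueError("atom counts vary across models")
        if not lig_coords:
            raise ValueError("no ligand (non-water HETATM) atoms found")
        frames.append(Frame(np.array(ca_list), np.array(lig_coords)))

    n_lig = len(lig_elements)
    if ligand_charges is None:
        ligand_charges = np.zeros(n_lig)
    ligand = Molecule3D(name=ligand_name, elements=lig_elements,
                        coords=frames[0].ligand_coords,
                        charges=np.asarray(ligand_charges, dtype=float),
                        radii=np.array([vdw_radius(e) for e in lig_elements]))
    return Trajectory(ref_protein, ligand, frames)


# ---------------------------------------------------------------------------
# plate reader CSV

_LONG_COLS = {"time_min", "well", "sample", "replicate", "fluorescence"}


def read_plate_long(path: str | Path) -> list[ThTCurve]:
    """Long-format plate CSV: time_min, well, sample, replicate, fluorescence.

    An optional boolean ``is_background`` column marks no-protein control
    wells. One curve is returned per (sample, replicate, is_background).
    """
    df = pd.read_csv(path)
    missing = _LONG_COLS - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    if "is_background" not in df.columns:
        df["is_background"] = False
    curves = []
    for (sample, rep, bg), grp in df.groupby(
            ["sample", "replicate", "is_background"], sort=True):
        grp = grp.sort_values("time_min")
        curves.append(ThTCurve(grp["time_min"].to_numpy() / 60.0,
                               grp["fluorescence"].to_numpy(),
                               sample=str(sample), replicate=int(rep),
                               is_background=bool(bg)))
    if not curves:
        raise ValueError(f"no curves in {path}")
    return curves


def read_plate_wide(path: str | Path, map_path: str | Path) -> list[ThTCurve]:
    """Wide plate CSV (time_min + one column per well) plus a well map.

    The map CSV needs columns well, sample, replicate and optionally
    is_background.
    """
    df = pd.read_csv(path)
    wmap = pd.read_csv(map_path)
    if "time_min" not in df.columns:
        raise ValueError("wide plate CSV needs a time_min column")
    for col in ("well", "sample", "replicate"):
        if col not in wmap.columns:
            raise ValueError(f"well map missing column {col!r}")
    if "is_background" not in wmap.columns:
        wmap["is_background"] = False
    times = df["time_min"].to_numpy() / 60.0
    curves = []
    for _, row in wmap.iterrows():
        well = str(row["well"])
        if well not in df.columns:
            raise ValueError(f"well {well!r} not present in plate file")
        curves.append(ThTCurve(times, df[well].to_numpy(),
                               sample=str(row["sample"]),
                               replicate=int(row["replicate"]),
                               is_background=bool(row["is_background"])))
    return curves


# ---------------------------------------------------------------------------
# fibril measurement CSV

def read_fibril_csv(path: str | Path) -> list[FibrilMeasurement]:
    """Measurement CSV: sample, instrument, length_um, width_nm, flag."""
    df = pd.read_csv(path)
    for col in ("sample", "instrument", "length_um"):
        if col not in df.columns:
            raise ValueError(f"fibril CSV missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        width = row.get("width_nm")
        width = None if width is None or pd.isna(width) else float(width)
        flag = str(row.get("flag", "") or "")
        out.append(FibrilMeasurement(
            length_um=float(row["length_um"]), width_nm=width,
            sample=str(row["sample"]), instrument=str(row["instrument"]),
            spherical=flag.lower() == "spherical"))
    if not out:
        raise ValueError(f"no measurements in {path}")
    return out


def write_fibril_csv(measurements: list[FibrilMeasurement],
                     path: str | Path) -> None:
    rows = [{"sample": m.sample, "instrument": m.instrument,
             "length_um": m.length_um, "width_nm": m.width_nm,
             "flag": "spherical" if m.spherical else ""}
            for m in measurements]
    pd.DataFrame(rows).to_csv(path, index=False)
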