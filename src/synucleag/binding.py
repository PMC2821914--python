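"""Trajectory binding analysis: occupancy, contacts, point-charge energies.

A frame is *bound* when the minimum distance between any protein Cα and the
ligand centre of mass falls strictly below the cutoff (default 8 Å).
Occupancies are reported as percentages of frames, protein-wide and
restricted to annotated regions (target motif 125–129, NAC 61–95, ...).
Hydrogen bonds and hydrophobic contacts between ligand and protein are
detected with standard geometric criteria, and ligand–residue electrostatic
interactions are scored with a vacuum point-charge Coulomb model — a
deliberately crude, qualitative-only energy (no solvent screening) whose
per-residue means are normalised against the most negative neutral-ligand
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .esp import COULOMB_CONSTANT_KCAL
from .molecules import Molecule3D
from .protein import Frame, ProteinConformer, Trajectory

__all__ = [
    "BindingCriteria", "BindingProfile", "ContactEvent", "EnergyRow", "EnergyTable",
    "ligand_com", "min_calpha_com_distance", "is_bound", "binding_fractions",
    "region_occupancy", "detect_hbonds", "detect_hydrophobic",
    "persistent_contacts", "coulomb_energy", "energy_stats",
    "normalize_energy_table",
]


@dataclass
class BindingCriteria:
    """Bound-state definition: Cα–ligand-COM cutoff and persistence rule."""

    cutoff: float = 8.0
    persistence_threshold: float = 0.5  # strict > when flagging regions

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.persistence_threshold <= 1:
            raise ValueError("persistence threshold must lie in (0, 1]")


@dataclass
class BindingProfile:
    """Occupancy percentages plus per-frame bound labels."""

    pct_protein: float
    pct_target: float
    region_pct: dict[str, float]
    labels_protein: np.ndarray
    labels_target: np.ndarray

    def report_row(self, ligand: str) -> dict:
        """Integer-percentage row in the style of the binding summary table."""
        return {"ligand": ligand,
                "pct_protein": int(round(self.pct_protein)),
                "pct_target": int(round(self.pct_target))}


@dataclass
class ContactEvent:
    frame: int
    kind: str  # "hbond" | "hydrophobic"
    ligand_atom: int
    residue: int
    residue_atom: str
    distance: float
    angle_deg: float | None = None


@dataclass
class EnergyRow:
    ligand: str
    residue: int
    mean_kcal: float
    sd_kcal: float
    normalized: float | None = None
    charge_class: str = "neutral"  # or "charged"


@dataclass
class EnergyTable:
    rows: list[EnergyRow]
    reference_kcal: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "ligand": r.ligand, "residue": r.residue,
            "mean_kcal_mol": r.mean_kcal, "sd_kcal_mol": r.sd_kcal,
            "normalized": r.normalized, "charge_class": r.charge_class,
        } for r in self.rows])


def ligand_com(frame: Frame, ligand: Molecule3D) -> np.ndarray:
    """Mass-weighted centre of the ligand's heavy atoms at this frame."""
    mask = ligand.heavy_mask()
    if not mask.any():
        mask = np.ones(ligand.n_atoms, bool)
    m = ligand.masses[mask]
    return (frame.ligand_coords[mask] * m[:, None]).sum(axis=0) / m.sum()


def min_calpha_com_distance(frame: Frame, protein: ProteinConformer,
                            ligand: Molecule3D,
                            subset: frozenset[int] | set[int] | None = None) -> float:
    """Minimum over the residue subset's Cα of distance to the ligand COM."""
    indices = [r.index for r in protein.residues]
    if subset is not None:
        rows = [i for i, idx in enumerate(indices) if idx in subset]
        if not rows:
            raise ValueError("residue subset selects no residues")
        ca = frame.protein_ca[rows]
    else:
        ca = frame.protein_ca
    com = ligand_com(frame, ligand)
    return float(np.min(np.linalg.norm(ca - com, axis=1)))


def is_bound(frame: Frame, protein: ProteinConformer, ligand: Molecule3D,
             criteria: BindingCriteria | None = None,
             subset: frozenset[int] | None = None) -> bool:
    """True iff the minimum Cα–COM distance is strictly below the cutoff."""
    criteria = criteria or BindingCriteria()
    return min_calpha_com_distance(frame, protein, ligand, subset) < criteria.cutoff


def _min_distances_stacked(traj: Trajectory,
                           subset: frozenset[int] | None = None) -> np.ndarray:
    """Per-frame min Cα–ligand-COM distance, vectorised across frames."""
    ligand = traj.ligand
    mask = ligand.heavy_mask()
    if not mask.any():
        mask = np.ones(ligand.n_atoms, bool)
    m = ligand.masses[mask]
    lig = np.stack([f.ligand_coords[mask] for f in traj.frames])
    coms = (lig * m[None, :, None]).sum(axis=1) / m.sum()
    indices = [r.index for r in traj.protein.residues]
    if subset is not None:
        rows = [i for i, idx in enumerate(indices) if idx in subset]
        if not rows:
            raise ValueError("residue subset selects no residues")
    else:
        rows = slice(None)
    ca = np.stack([f.protein_ca[rows] for f in traj.frames])
    return np.linalg.norm(ca - coms[:, None, :], axis=2).min(axis=1)


def binding_fractions(traj: Trajectory,
                      criteria: BindingCriteria | None = None,
                      target_region: str = "target") -> BindingProfile:
    """Percentage of frames bound to the protein and to the target region.

    The target percentage applies the same COM-distance cutoff restricted
    to the target region's Cα. Percentages are kept as floats; rounding to
    integer percent happens only in ``BindingProfile.report_row``.
    """
    criteria = criteria or BindingCriteria()
    protein = traj.protein
    target = protein.annotations.get(target_region)
    lab_p = _min_distances_stacked(traj) < criteria.cutoff
    if target is not None:
        lab_t = _min_distances_stacked(traj, target) < criteria.cutoff
    else:
        lab_t = np.zeros(traj.n_frames, dtype=bool)
    region_pct = {}
    for name, members in protein.annotations.items():
        lab = _min_distances_stacked(traj, members) < criteria.cutoff
        region_pct[name] = 100.0 * lab.mean()
    return BindingProfile(
        pct_protein=100.0 * lab_p.mean(),
        pct_target=100.0 * lab_t.mean(),
        region_pct=region_pct,
        labels_protein=lab_p,
        labels_target=lab_t,
    )


def region_occupancy(traj: Trajectory, partition: dict[str, frozenset[int]],
                     criteria: BindingCriteria | None = None):
    """Per-region bound percentage plus the persistently occupied regions.

    Regions may overlap, in which case percentages can sum past 100. A
    region is listed as persistent when its occupancy strictly exceeds the
    persistence threshold.
    """
    criteria = criteria or BindingCriteria()
    if not partition:
        raise ValueError("empty region partition")
    pct = {}
    for name, members in partition.items():
        lab = _min_distances_stacked(traj, frozenset(members)) < criteria.cutoff
        pct[name] = 100.0 * lab.mean()
    persistent = sorted(n for n, p in pct.items()
                        if p > 100.0 * criteria.persistence_threshold)
    return pct, persistent


# ---------------------------------------------------------------------------
# contact detection

_ACCEPTOR_ELEMENTS = {"O", "N"}
_BACKBONE_NAMES = {"CA", "C", "N", "O"}


def _ligand_donors_acceptors(ligand: Molecule3D):
    """Donor/acceptor heavy-atom indices typed from element + bond pattern.

    N/O atoms are acceptors; an N/O bonded to an explicit hydrogen is also
    a donor. Without explicit hydrogens every N/O is treated as a potential
    donor (heavy-atom fallback).
    """
    has_h = "H" in ligand.elements
    neighbors: dict[int, list[int]] = {i: [] for i in range(ligand.n_atoms)}
    for i, j in ligand.bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    donors, acceptors = [], []
    for i, e in enumerate(ligand.elements):
        if e not in _ACCEPTOR_ELEMENTS:
            continue
        acceptors.append(i)
        if not has_h or not ligand.bonds:
            donors.append(i)
        elif any(ligand.elements[j] == "H" for j in neighbors[i]):
            donors.append(i)
    return donors, acceptors, neighbors, has_h and bool(ligand.bonds)


def detect_hbonds(frame: Frame, protein: ProteinConformer, ligand: Molecule3D,
                  frame_index: int = 0, max_da: float = 3.5,
                  min_angle_deg: float = 120.0) -> list[ContactEvent]:
    """Ligand–protein hydrogen bonds by distance (and angle when possible).

    Criterion: donor–acceptor distance ≤ ``max_da`` Å; when the donor has
    an explicit hydrogen, the D–H···A angle must also be ≥ ``min_angle_deg``.
    Protein N/O side-chain atoms act as both donors and acceptors (the
    coarse model carries no protein hydrogens).
    """
    donors, acceptors, neighbors, use_angles = _ligand_donors_acceptors(ligand)
    # per-residue protein polar atoms, positions at this frame
    events = []
    res_offsets = {r.index: frame.protein_ca[i] - r.ca
                   for i, r in enumerate(protein.residues)}
    for r in protein.residues:
        shift = res_offsets[r.index]
        for atom in r.atoms:
            if atom.element not in _ACCEPTOR_ELEMENTS:
                continue
            apos = atom.position + shift
            # ligand donor -> protein acceptor
            for d in donors:
                dpos = frame.ligand_coords[d]
                dist = float(np.linalg.norm(dpos - apos))
                if dist > max_da:
                    continue
                angle = None
                if use_angles:
                    hs = [j for j in neighbors[d] if ligand.elements[j] == "H"]
                    if hs:
                        angle = max(_angle(dpos, frame.ligand_coords[h], apos)
                                    for h in hs)
                        if angle < min_angle_deg:
                            continue
                events.append(ContactEvent(frame_index, "hbond", d, r.index,
                                           atom.name, dist, angle))
            # protein donor -> ligand acceptor (heavy-atom rule only)
            for a in acceptors:
                if a in donors:
                    continue  # already paired above in the fallback case
                dist = float(np.linalg.norm(frame.ligand_coords[a] - apos))
                if dist <= max_da:
                    events.append(ContactEvent(frame_index, "hbond", a, r.index,
                                               atom.name, dist, None))
    return events


def _angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1 = d - h
    v2 = a - h
    c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hydrophobic(frame: Frame, protein: ProteinConformer,
                       ligand: Molecule3D, frame_index: int = 0,
                       cutoff: float = 4.0) -> list[ContactEvent]:
    """Ligand-carbon / side-chain-carbon pairs within the cutoff (default 4 Å)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_c = [i for i, e in enumerate(ligand.elements) if e == "C"]
    events = []
    for ridx, r in enumerate(protein.residues):
        shift = frame.protein_ca[ridx] - r.ca
        for atom in r.atoms:
            if atom.element != "C" or atom.name in _BACKBONE_NAMES:
                continue
            apos = atom.position + shift
            for i in lig_c:
                dist = float(np.linalg.norm(frame.ligand_coords[i] - apos))
                if dist < cutoff:
                    events.append(ContactEvent(frame_index, "hydrophobic", i,
                                               r.index, atom.name, dist))
    return events


def persistent_contacts(traj: Trajectory, threshold: float = 0.5,
                        max_da: float = 3.5, min_angle_deg: float = 120.0,
                        hydrophobic_cutoff: float = 4.0) -> pd.DataFrame:
    """Per (residue, kind) fraction of frames with at least one event.

    Rows whose fraction strictly exceeds ``threshold`` are flagged
    persistent.
    """
    counts: dict[tuple[int, str], int] = {}
    for fi, frame in enumerate(traj.frames):
        seen = set()
        for ev in detect_hbonds(frame, traj.protein, traj.ligand, fi,
                                max_da, min_angle_deg):
            seen.add((ev.residue, "hbond"))
        for ev in detect_hydrophobic(frame, traj.protein, traj.ligand, fi,
                                     hydrophobic_cutoff):
            seen.add((ev.residue, "hydrophobic"))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    rows = [{"residue": res, "kind": kind,
             "fraction": n / traj.n_frames,
             "persistent": n / traj.n_frames > threshold}
            for (res, kind), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["residue", "kind", "fraction", "persistent"])


# ---------------------------------------------------------------------------
# point-charge energies

def coulomb_energy(ligand_coords: np.ndarray, ligand_charges: np.ndarray,
                   site_coords: np.ndarray, site_charges: np.ndarray) -> float:
    """Vacuum Coulomb energy (kcal/mol) between two point-charge sets.

    E = k_e Σ_ij q_i q_j / r_ij with k_e = 332.0636 kcal·Å/(mol·e²); no
    dielectric screening. Coincident charges raise (singular energy).
    """
    lc = np.atleast_2d(ligand_coords)
    sc = np.atleast_2d(site_coords)
    lq = np.atleast_1d(ligand_charges)
    sq = np.atleast_1d(site_charges)
    r = np.linalg.norm(lc[:, None, :] - sc[None, :, :], axis=2)
    if np.any(r == 0):
        raise ValueError("overlapping charges (zero distance)")
    return float(COULOMB_CONSTANT_KCAL * np.sum(lq[:, None] * sq[None, :] / r))


def _residue_sites_at(protein: ProteinConformer, frame: Frame, residue: int):
    for i, r in enumerate(protein.residues):
        if r.index == residue:
            shift = frame.protein_ca[i] - r.ca
            pos = np.array([s.position + shift for s in r.charge_sites])
            q = np.array([s.charge for s in r.charge_sites])
            return pos, q
    raise KeyError(f"no residue {residue}")


def energy_stats(traj: Trajectory, residues: tuple[int, ...] = (83, 61),
                 bound_only: bool = False,
                 criteria: BindingCriteria | None = None,
                 stride: int = 1) -> EnergyTable:
    """Per-residue mean ± sample sd of frame Coulomb energies.

    By default all frames contribute (bound and unbound); ``bound_only``
    restricts to bound frames, ``stride`` subsamples every n-th frame.
    Frames are weighted equally regardless of timestep. The sd uses the
    n−1 (sample) convention.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    ligand = traj.ligand
    lq = ligand.charges
    frames = list(enumerate(traj.frames))[::stride]
    if bound_only:
        criteria = criteria or BindingCriteria()
        frames = [(i, f) for i, f in frames
                  if is_bound(f, traj.protein, ligand, criteria)]
        if not frames:
            raise ValueError("no bound frames to average over")
    charge_class = "charged" if ligand.is_charged() else "neutral"
    rows = []
    for res in residues:
        energies = []
        for _i, f in frames:
            pos, q = _residue_sites_at(traj.protein, f, res)
            if len(q) == 0:
                energies.append(0.0)
                continue
            energies.append(coulomb_energy(f.ligand_coords, lq, pos, q))
        arr = np.asarray(energies)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        rows.append(EnergyRow(ligand.name, res, float(arr.mean()), sd,
                              charge_class=charge_class))
    return EnergyTable(rows)


def normalize_energy_table(table: EnergyTable) -> EnergyTable:
    """Normalise means against the most negative neutral-ligand mean.

    The reference row (most negative mean among neutral ligands) maps to
    −1.0 exactly; all rows — including charged-ligand rows, whose magnitude
    may then exceed 1 — are divided by |reference|. Raises when no
    neutral-ligand row has a negative mean (normalisation undefined).
    """
    neutral_means = [r.mean_kcal for r in table.rows
                     if r.charge_class == "neutral" and r.mean_kcal < 0]
    if not neutral_means:
        raise ValueError("no negative neutral-ligand mean; "
                         "normalization undefined")
    ref = min(neutral_means)
    rows = [EnergyRow(r.ligand, r.residue, r.mean_kcal, r.sd_kcal,
                      normalized=r.mean_kcal / abs(ref),
                      charge_class=r.charge_class)
            for r in table.rows]
    return EnergyTable(rows, reference_kcal=ref)
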