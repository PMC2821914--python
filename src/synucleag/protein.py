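"""Protein conformer and trajectory containers.

The protein model is deliberately coarse: an ordered list of residues, each
with a Cα position, optional extra heavy atoms (e.g. carboxylate oxygens on
acidic side chains) and optional point-charge sites. Named residue-index
annotations carry the biologically meaningful regions — for α-synuclein the
hydrophobic NAC core (61–95), the C-terminal dopamine-binding target motif
YEMPS (125–129) and the charged NAC residues E61/E83.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ResidueAtom", "ChargeSite", "Residue", "ProteinConformer",
           "Frame", "Trajectory"]


@dataclass
class ResidueAtom:
    """A heavy atom of a residue (element symbol, PDB-style name, Å coords)."""

    element: str
    name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class ChargeSite:
    """A point charge attached to a residue side chain (charge in e)."""

    position: np.ndarray
    charge: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class Residue:
    index: int          # 1-based residue number
    name: str           # three-letter code
    ca: np.ndarray      # Cα position, Å
    atoms: list[ResidueAtom] = field(default_factory=list)
    charge_sites: list[ChargeSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)

    def heavy_positions(self) -> np.ndarray:
        """Cα plus any extra heavy atoms, as an (m, 3) array."""
        pos = [self.ca] + [a.position for a in self.atoms if a.element != "H"]
        return np.array(pos)


@dataclass
class ProteinConformer:
    """Ordered residues plus named region annotations (1-based index sets)."""

    residues: list[Residue]
    annotations: dict[str, frozenset[int]] = field(default_factory=dict)
    name: str = "protein"

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        allset = set(idx)
        for region, members in self.annotations.items():
            if not set(members) <= allset:
                raise ValueError(f"annotation {region!r} references residues "
                                 "outside the chain")
            self.annotations[region] = frozenset(members)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue {index}")

    def ca_coords(self, subset: frozenset[int] | set[int] | None = None) -> np.ndarray:
        if subset is None:
            return np.array([r.ca for r in self.residues])
        rows = [r.ca for r in self.residues if r.index in subset]
        if not rows:
            raise ValueError("residue subset selects no residues")
        return np.array(rows)

    def with_coords(self, ca: np.ndarray) -> "ProteinConformer":
        """Copy with replaced Cα coordinates (side-chain sites rigidly follow)."""
        new_res = []
        for r, pos in zip(self.residues, ca):
            shift = np.asarray(pos) - r.ca
            new_res.append(Residue(
                r.index, r.name, np.asarray(pos, dtype=float),
                [ResidueAtom(a.element, a.name, a.position + shift) for a in r.atoms],
                [ChargeSite(c.position + shift, c.charge) for c in r.charge_sites],
            ))
        return ProteinConformer(new_res, dict(self.annotations), self.name)


@dataclass
class Frame:
    """One trajectory frame: protein Cα coords and ligand atom coords (Å)."""

    protein_ca: np.ndarray
    ligand_coords: np.ndarray

    def __post_init__(self) -> None:
        self.protein_ca = np.asarray(self.protein_ca, dtype=float)
        self.ligand_coords = np.atleast_2d(np.asarray(self.ligand_coords, dtype=float))


@dataclass
class Trajectory:
    """Time-ordered frames of one protein–ligand system.

    ``ligand`` supplies elements/charges/masses (coordinates per frame come
    from the frames); ``metadata`` may carry generator ground truth such as
    per-frame bound labels.
    """

    protein: ProteinConformer
    ligand: "object"           # Molecule3D; kept loose to avoid an import cycle
    frames: list[Frame]
    timestep_ps: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must have at least one frame")
        n_ca = self.frames[0].protein_ca.shape[0]
        n_lig = self.frames[0].ligand_coords.shape[0]
        for f in self.frames:
            if f.protein_ca.shape[0] != n_ca or f.ligand_coords.shape[0] != n_lig:
                raise ValueError("atom counts must be constant across frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def protein_at(self, i: int) -> ProteinConformer:
        return self.protein.with_coords(self.frames[i].protein_ca)
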