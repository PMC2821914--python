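"""Contact-count ranking of docked ligand–protein adducts.

Docked poses are ranked by the number of heavy-atom contacts between the
ligand and the C-terminal target motif (residues 125–129). The count is a
fast screen only — with an intrinsically disordered protein it carries no
structural-prediction weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molecules import Molecule3D
from .protein import ProteinConformer

__all__ = ["Pose", "ContactCount", "count_contacts", "rank_adducts"]


@dataclass
class Pose:
    """One docked ligand pose against a named protein conformer."""

    ligand: Molecule3D
    conformer_id: str = "conf1"
    source: str = ""

    @property
    def pose_id(self) -> str:
        return self.ligand.name


@dataclass
class ContactCount:
    pose_id: str
    conformer_id: str
    n_contacts: int
    region: frozenset[int]


def count_contacts(pose: Pose, protein: ProteinConformer,
                   region: frozenset[int] | set[int],
                   cutoff: float = 4.0) -> ContactCount:
    """Count (ligand heavy atom, region heavy atom/Cα) pairs within cutoff.

    Heavy atoms only on the ligand side; on the protein side each region
    residue contributes its Cα plus any extra heavy atoms.
    """
    if not region:
        raise ValueError("region must be non-empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    indices = {r.index for r in protein.residues}
    if not set(region) <= indices:
        raise ValueError("region references residues outside the protein")
    lig = pose.ligand.coords[pose.ligand.heavy_mask()]
    prot = np.vstack([protein.residue(i).heavy_positions() for i in sorted(region)])
    d = np.linalg.norm(lig[:, None, :] - prot[None, :, :], axis=2)
    return ContactCount(pose.pose_id, pose.conformer_id,
                        int(np.count_nonzero(d < cutoff)), frozenset(region))


def rank_adducts(counts: list[ContactCount]) -> list[ContactCount]:
    """Sort descending by contact count; ties by (conformer id, pose id)."""
    if not counts:
        raise ValueError("no contact counts to rank")
    return sorted(counts, key=lambda c: (-c.n_contacts, c.conformer_id, c.pose_id))
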