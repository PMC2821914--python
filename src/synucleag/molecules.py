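"""Small-molecule container used by the shape/electrostatics screening stage.

A :class:`Molecule3D` is a single 3-D conformer: element symbols, Cartesian
coordinates (Å), per-atom partial charges (e) and van der Waals radii (Å),
plus optional bonds and pharmacophore-style feature points. It deliberately
carries no chemistry engine of its own; RDKit is used at the I/O boundary to
parse standard formats and to assign Gasteiger (PEOE) charges when the input
file provides none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Bondi van der Waals radii (Å); fallback 1.7 Å for unlisted elements.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "B": 1.92, "Si": 2.10, "Se": 1.90, "Na": 2.27, "K": 2.75,
}

#: Standard atomic masses (amu) for centre-of-mass weighting.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
    "B": 10.81, "Si": 28.085, "Se": 78.971, "Na": 22.990, "K": 39.098,
}

FEATURE_CLASSES = ("donor", "acceptor", "aromatic", "cation", "anion", "hydrophobe")


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Å for an element symbol (1.7 Å default)."""
    return VDW_RADII.get(element.capitalize() if len(element) > 1 else element, 1.70)


def atomic_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.capitalize() if len(element) > 1 else element, 12.011)


@dataclass
class FeaturePoint:
    """Pharmacophore feature point used for the optional colour overlap."""

    kind: str  # one of FEATURE_CLASSES
    position: np.ndarray  # (3,) Å

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.kind!r}")
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class Molecule3D:
    """One conformer of a small molecule.

    Parameters
    ----------
    name
        Identifier; also the deterministic tie-break key in every ranking.
    elements
        Length-n list of element symbols.
    coords
        (n, 3) Cartesian coordinates in Å.
    charges
        (n,) partial charges in elementary charge units; zeros if unknown.
    radii
        (n,) van der Waals radii in Å; derived from ``elements`` if omitted.
    bonds
        Optional list of (i, j) atom-index pairs.
    features
        Optional pharmacophore feature points for colour scoring.
    metadata
        Free-form key→value store (the synthetic generators record ground
        truth such as the decoy perturbation rank here).
    """

    name: str
    elements: list[str]
    coords: np.ndarray
    charges: np.ndarray | None = None
    radii: np.ndarray | None = None
    bonds: list[tuple[int, int]] = field(default_factory=list)
    features: list[FeaturePoint] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n = len(self.elements)
        if n == 0:
            raise ValueError("molecule must contain at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.charges is None:
            self.charges = np.zeros(n)
        else:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (n,):
                raise ValueError("charges length mismatch")
        if abs(float(self.charges.sum())) >= 10.0:
            raise ValueError("implausible total charge (|q| >= 10 e)")
        if self.radii is None:
            self.radii = np.array([vdw_radius(e) for e in self.elements])
        else:
            self.radii = np.asarray(self.radii, dtype=float)
            if self.radii.shape != (n,):
                raise ValueError("radii length mismatch")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(e) for e in self.elements])

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def center_of_mass(self, heavy_only: bool = True) -> np.ndarray:
        """Mass-weighted centre, by default over heavy atoms only."""
        mask = self.heavy_mask() if heavy_only else np.ones(self.n_atoms, bool)
        if not mask.any():
            mask = np.ones(self.n_atoms, bool)
        m = self.masses[mask]
        return (self.coords[mask] * m[:, None]).sum(axis=0) / m.sum()

    def net_charge(self) -> float:
        return float(self.charges.sum())

    def is_charged(self, tol: float = 0.5) -> bool:
        """True when the rounded net charge is non-zero (|q| beyond tol)."""
        return abs(round(self.net_charge())) >= 1 and abs(self.net_charge()) > tol

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule3D":
        """Return a copy with coords rotated then translated."""
        new = Molecule3D(
            name=self.name,
            elements=list(self.elements),
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
            charges=self.charges.copy(),
            radii=self.radii.copy(),
            bonds=list(self.bonds),
            features=[FeaturePoint(f.kind, f.position @ np.asarray(rotation).T + translation)
                      for f in self.features],
            metadata=dict(self.metadata),
        )
        return new

    def copy(self) -> "Molecule3D":
        return self.transformed(np.eye(3), np.zeros(3))
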