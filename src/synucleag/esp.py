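"""Electrostatic-potential fields and the electrostatic Tanimoto metric.

The Coulomb potential of each molecule's point charges is evaluated on a
shared rectilinear grid covering both molecules (plus padding); nodes inside
either molecule's van der Waals envelope (radius + 0.5 Å) are masked out so
the comparison is made over solvent-accessible space only. Similarity is
the Tanimoto-style normalised inner product

    T_e = <E_A, E_B> / (<E_A, E_A> + <E_B, E_B> − <E_A, E_B>)

over unmasked nodes, which ranges over (−1/3, 1]: identical fields give 1,
a sign-flipped field gives exactly −1/3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molecules import Molecule3D
from .shape import RigidTransform

__all__ = ["ESPGridSpec", "ESPGrid", "esp_field", "electrostatic_tanimoto",
           "COULOMB_CONSTANT_KCAL"]

#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB_CONSTANT_KCAL = 332.0636


@dataclass
class ESPGridSpec:
    """Grid geometry: spacing/padding in Å, mask margin beyond vdW radius."""

    spacing: float = 0.5
    padding: float = 4.0
    mask_margin: float = 0.5

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.padding < 0 or self.mask_margin < 0:
            raise ValueError("padding and mask margin must be >= 0")


@dataclass
class ESPGrid:
    """Potential values (kcal/(mol·e)) on grid nodes, with an exclusion mask."""

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    values: np.ndarray  # flattened, NaN where masked
    mask: np.ndarray    # flattened bool, True = excluded

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())


def _grid_points(origin: np.ndarray, spacing: float, shape) -> np.ndarray:
    axes = [origin[d] + spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


def make_grid_spec_box(mols: list[Molecule3D], spec: ESPGridSpec):
    """Shared origin/shape covering every molecule's bounding box + padding."""
    lo = np.min([m.coords.min(axis=0) for m in mols], axis=0) - spec.padding
    hi = np.max([m.coords.max(axis=0) for m in mols], axis=0) + spec.padding
    shape = tuple(int(np.floor((hi[d] - lo[d]) / spec.spacing)) + 1 for d in range(3))
    return lo, shape


def _mask_for(points: np.ndarray, mols: list[Molecule3D], margin: float) -> np.ndarray:
    mask = np.zeros(len(points), dtype=bool)
    for m in mols:
        cut = (m.radii + margin) ** 2
        # chunk over atoms; molecules here are small so this is cheap
        for pos, c2 in zip(m.coords, cut):
            d2 = np.sum((points - pos) ** 2, axis=1)
            mask |= d2 < c2
    return mask


def esp_field(mol: Molecule3D, spec: ESPGridSpec | None = None,
              origin: np.ndarray | None = None,
              shape: tuple[int, int, int] | None = None,
              mask: np.ndarray | None = None,
              mask_mols: list[Molecule3D] | None = None) -> ESPGrid:
    """Coulomb potential Σ q_i/r_i (times k_e) of ``mol`` on a grid.

    With no explicit geometry the grid covers ``mol`` alone; pass
    ``origin``/``shape``/``mask`` (or ``mask_mols``) to evaluate two
    molecules on an identical shared grid.
    """
    spec = spec or ESPGridSpec()
    if origin is None or shape is None:
        origin, shape = make_grid_spec_box([mol], spec)
    origin = np.asarray(origin, dtype=float)
    points = _grid_points(origin, spec.spacing, shape)
    if mask is None:
        mask = _mask_for(points, mask_mols if mask_mols is not None else [mol],
                         spec.mask_margin)
    if mask.all():
        raise ValueError("all grid nodes are masked")

    values = np.full(len(points), np.nan)
    free = points[~mask]
    pot = np.zeros(len(free))
    for pos, q in zip(mol.coords, mol.charges):
        if q == 0:
            continue
        r = np.sqrt(np.sum((free - pos) ** 2, axis=1))
        pot += COULOMB_CONSTANT_KCAL * q / r
    values[~mask] = pot
    return ESPGrid(origin=origin, spacing=spec.spacing, shape=tuple(shape),
                   values=values, mask=mask)


def electrostatic_tanimoto(ref: Molecule3D, fit: Molecule3D,
                           overlay: RigidTransform | None = None,
                           spec: ESPGridSpec | None = None) -> float:
    """ESP Tanimoto of ``fit`` (after the shape overlay) against ``ref``.

    Both potentials are evaluated on one shared grid masked by the union of
    both molecules' envelopes. Raises if both fields are identically zero
    (the metric is undefined).
    """
    spec = spec or ESPGridSpec()
    moved = overlay.apply_molecule(fit) if overlay is not None else fit
    origin, shape = make_grid_spec_box([ref, moved], spec)
    points = _grid_points(np.asarray(origin), spec.spacing, shape)
    mask = _mask_for(points, [ref, moved], spec.mask_margin)
    ga = esp_field(ref, spec, origin, shape, mask)
    gb = esp_field(moved, spec, origin, shape, mask)
    ea = ga.values[~mask]
    eb = gb.values[~mask]
    aa = float(ea @ ea)
    bb = float(eb @ eb)
    ab = float(ea @ eb)
    if aa == 0.0 and bb == 0.0:
        raise ValueError("both ESP fields are identically zero; Tanimoto undefined")
    return ab / (aa + bb - ab)
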