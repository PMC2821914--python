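"""Gaussian shape overlap and shape Tanimoto similarity.

Each atom is an isotropic 3-D Gaussian ``p · exp(-α r²)`` whose exponent is
chosen so that the isolated-atom integral equals its hard-sphere van der
Waals volume (4/3)πR³ at amplitude p = 2.7 — the standard Gaussian-shape
convention. The molecular overlap between two molecules is the first-order
(pairwise) sum of Gaussian product integrals:

    V_AB = Σ_{i∈A, j∈B} p² (π/(α_i+α_j))^{3/2} exp(-α_i α_j d_ij² / (α_i+α_j))

and the shape Tanimoto is T = V_AB / (V_AA + V_BB − V_AB) at the optimised
rigid overlay. The overlay search is a gradient-free (Powell direction-set) local
refinement of quaternion + translation from several deterministic
quasi-random starts after centroid pre-alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .molecules import Molecule3D

__all__ = [
    "GaussianShapeParams",
    "RigidTransform",
    "SimilarityScore",
    "gaussian_alpha",
    "overlap_volume",
    "self_volume",
    "color_overlap",
    "optimize_overlay",
    "shape_tanimoto",
]


@dataclass
class GaussianShapeParams:
    """Parameters of the atom-centred Gaussian shape model.

    ``amplitude`` (p) is dimensionless; 2.7 is the literature default at
    which a single Gaussian reproduces the hard-sphere volume with the
    exponent rule used here. ``color_weight`` scales the optional
    feature-point (colour) overlap; ``color_radius`` is the effective
    radius of a feature Gaussian in Å.
    """

    amplitude: float = 2.7
    color_weight: float = 1.0
    color_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.color_weight < 0:
            raise ValueError("color weight must be >= 0")


@dataclass
class RigidTransform:
    """Rotation (unit quaternion, w-x-y-z) plus translation in Å."""

    quaternion: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.quaternion = np.asarray(self.quaternion, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        n = np.linalg.norm(self.quaternion)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("zero quaternion")
            self.quaternion = self.quaternion / n

    def rotation_matrix(self) -> np.ndarray:
        return _quat_to_matrix(self.quaternion)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation_matrix().T + self.translation

    def apply_molecule(self, mol: Molecule3D) -> Molecule3D:
        return mol.transformed(self.rotation_matrix(), self.translation)


@dataclass
class SimilarityScore:
    """Shape and electrostatic Tanimoto scores for one ref/fit pair."""

    shape_tanimoto: float
    esp_tanimoto: float | None = None
    color_tanimoto: float | None = None
    transform: RigidTransform | None = None

    @property
    def combo(self) -> float:
        """Unweighted shape + ESP sum, reporting only (not used to rank)."""
        return self.shape_tanimoto + (self.esp_tanimoto or 0.0)


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q / np.linalg.norm(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def gaussian_alpha(radii: np.ndarray, amplitude: float = 2.7) -> np.ndarray:
    """Exponent α per atom such that ∫ p·e^{-αr²} dV = (4/3)πR³.

    Solving p (π/α)^{3/2} = (4/3)πR³ gives α = π (3p / (4π R³))^{2/3}.
    """
    radii = np.asarray(radii, dtype=float)
    return np.pi * (3.0 * amplitude / (4.0 * np.pi * radii**3)) ** (2.0 / 3.0)


def _pair_overlap(coords_a, alpha_a, coords_b, alpha_b, amplitude) -> float:
    asum = alpha_a[:, None] + alpha_b[None, :]
    prod = alpha_a[:, None] * alpha_b[None, :]
    d2 = np.sum((coords_a[:, None, :] - coords_b[None, :, :]) ** 2, axis=2)
    return float(np.sum(amplitude**2 * (np.pi / asum) ** 1.5 * np.exp(-prod / asum * d2)))


def overlap_volume(a: Molecule3D, b: Molecule3D,
                   params: GaussianShapeParams | None = None) -> float:
    """First-order Gaussian shape overlap V_AB (Å³) at the given fixed poses."""
    params = params or GaussianShapeParams()
    aa = gaussian_alpha(a.radii, params.amplitude)
    ab = gaussian_alpha(b.radii, params.amplitude)
    return _pair_overlap(a.coords, aa, b.coords, ab, params.amplitude)


def self_volume(mol: Molecule3D, params: GaussianShapeParams | None = None) -> float:
    """V_AA — the molecule's Gaussian self-overlap (Å³)."""
    return overlap_volume(mol, mol, params)


def color_overlap(a: Molecule3D, b: Molecule3D,
                  params: GaussianShapeParams | None = None) -> float:
    """Feature-point ('colour') Gaussian overlap over matching classes.

    Feature points of the same pharmacophore class interact as Gaussians of
    radius ``color_radius``; the sum is scaled by ``color_weight``. Zero
    when either molecule has no features.
    """
    params = params or GaussianShapeParams()
    if not a.features or not b.features or params.color_weight == 0:
        return 0.0
    total = 0.0
    alpha = gaussian_alpha(np.array([params.color_radius]), params.amplitude)[0]
    for fa in a.features:
        for fb in b.features:
            if fa.kind != fb.kind:
                continue
            d2 = float(np.sum((fa.position - fb.position) ** 2))
            total += params.amplitude**2 * (np.pi / (2 * alpha)) ** 1.5 \
                * np.exp(-alpha / 2 * d2)
    return params.color_weight * total


class _OverlapObjective:
    """Precomputed pairwise kernels; evaluates −V_AB(q, t) cheaply."""

    def __init__(self, ref: Molecule3D, fit: Molecule3D, params: GaussianShapeParams):
        self.ref_coords = ref.coords
        self.fit_coords = fit.coords
        aa = gaussian_alpha(ref.radii, params.amplitude)
        ab = gaussian_alpha(fit.radii, params.amplitude)
        asum = aa[:, None] + ab[None, :]
        self.k = params.amplitude**2 * (np.pi / asum) ** 1.5
        self.g = aa[:, None] * ab[None, :] / asum

    def overlap(self, q: np.ndarray, t: np.ndarray) -> float:
        moved = self.fit_coords @ _quat_to_matrix(q).T + t
        d2 = np.sum((self.ref_coords[:, None, :] - moved[None, :, :]) ** 2, axis=2)
        return float(np.sum(self.k * np.exp(-self.g * d2)))

    def __call__(self, x: np.ndarray) -> float:
        q = x[:4]
        n = np.linalg.norm(q)
        if n < 1e-12:
            return 0.0
        return -self.overlap(q / n, x[4:])


def _quasi_random_quaternions(n: int, seed: int) -> np.ndarray:
    """Deterministic low-discrepancy-ish unit quaternions (seeded)."""
    rng = np.random.default_rng(seed)
    qs = [np.array([1.0, 0.0, 0.0, 0.0])]
    # axis-aligned half-turns cover the coarse orientation space
    for axis in np.eye(3):
        qs.append(np.concatenate([[np.cos(np.pi / 2)], np.sin(np.pi / 2) * axis]))
    while len(qs) < n:
        v = rng.normal(size=4)
        qs.append(v / np.linalg.norm(v))
    return np.array(qs[:n])


def optimize_overlay(ref: Molecule3D, fit: Molecule3D,
                     params: GaussianShapeParams | None = None,
                     n_starts: int = 10, seed: int = 0,
                     maxiter: int = 1000, xtol: float = 1e-4,
                     ftol: float = 1e-8) -> tuple[RigidTransform, float]:
    """Best rigid transform of ``fit`` onto ``ref`` maximising Gaussian overlap.

    Centroids are pre-aligned, then ``n_starts`` Powell (direction-set,
    gradient-free) refinements run from the identity rotation plus seeded
    quasi-random quaternions. The
    returned overlap is never worse than the identity (centroid-aligned)
    start.
    """
    params = params or GaussianShapeParams()
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if not (np.all(np.isfinite(ref.coords)) and np.all(np.isfinite(fit.coords))):
        raise ValueError("non-finite coordinates")

    obj = _OverlapObjective(ref, fit, params)
    t0 = ref.centroid() - fit.centroid()
    best_x = np.concatenate([[1.0, 0, 0, 0], t0])
    best_v = obj.overlap(best_x[:4], best_x[4:])

    for q in _quasi_random_quaternions(n_starts, seed):
        # rotate about the fit centroid, then translate onto the ref centroid
        rot = _quat_to_matrix(q)
        t = ref.centroid() - rot @ fit.centroid()
        x0 = np.concatenate([q, t])
        res = minimize(obj, x0, method="Powell",
                       options={"maxiter": maxiter, "xtol": xtol, "ftol": ftol})
        if -res.fun > best_v:
            best_v = -res.fun
            best_x = res.x
    q = best_x[:4] / np.linalg.norm(best_x[:4])
    return RigidTransform(q, best_x[4:]), best_v


def shape_tanimoto(ref: Molecule3D, fit: Molecule3D,
                   params: GaussianShapeParams | None = None,
                   n_starts: int = 10, seed: int = 0,
                   maxiter: int = 1000, xtol: float = 1e-4,
                   ftol: float = 1e-8) -> SimilarityScore:
    """Shape Tanimoto T = V_AB / (V_AA + V_BB − V_AB) at the optimal overlay.

    When both molecules carry feature points a colour Tanimoto (same formula
    over colour overlaps at the shape overlay) is reported separately.
    """
    params = params or GaussianShapeParams()
    vaa = self_volume(ref, params)
    vbb = self_volume(fit, params)
    if vaa <= 0 or vbb <= 0:
        raise RuntimeError("zero self-volume")
    transform, vab = optimize_overlay(ref, fit, params, n_starts, seed,
                                      maxiter, xtol, ftol)
    t = vab / (vaa + vbb - vab)
    score = SimilarityScore(shape_tanimoto=float(t), transform=transform)
    if ref.features and fit.features and params.color_weight > 0:
        moved = transform.apply_molecule(fit)
        cab = color_overlap(ref, moved, params)
        caa = color_overlap(ref, ref, params)
        cbb = color_overlap(moved, moved, params)
        if caa + cbb - cab > 0:
            score.color_tanimoto = float(cab / (caa + cbb - cab))
    return score
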