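"""Gaussian shape overlap and shape-Tanimoto behaviour."""

import numpy as np
import pytest

from synucleag.molecules import Molecule3D
from synucleag.shape import (GaussianShapeParams, RigidTransform, gaussian_alpha,
                             optimize_overlay, overlap_volume, self_volume,
                             shape_tanimoto)


def quadrature_overlap(a: Molecule3D, b: Molecule3D,
                       params: GaussianShapeParams, spacing: float = 0.05) -> float:
    """Independent oracle: numeric integral of the product of the two
    summed Gaussian densities on a regular grid."""
    alpha_a = gaussian_alpha(a.radii, params.amplitude)
    alpha_b = gaussian_alpha(b.radii, params.amplitude)
    allc = np.vstack([a.coords, b.coords])
    lo = allc.min(axis=0) - 4.5
    hi = allc.max(axis=0) + 4.5
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def density(coords, alphas):
        rho = np.zeros(len(pts))
        for pos, al in zip(coords, alphas):
            d2 = np.sum((pts - pos) ** 2, axis=1)
            rho += params.amplitude * np.exp(-al * d2)
        return rho

    return float(np.sum(density(a.coords, alpha_a) * density(b.coords, alpha_b))
                 * spacing**3)


def _mol(name, elements, coords, charges=None):
    return Molecule3D(name=name, elements=elements, coords=np.array(coords, float),
                      charges=charges)


@pytest.fixture()
def two_atom_pair():
    a = _mol("a", ["C"], [[0.0, 0.0, 0.0]])
    b = _mol("b", ["O"], [[1.5, 0.0, 0.0]])
    return a, b


def test_alpha_reproduces_hard_sphere_volume():
    # the isolated-atom Gaussian integral p (pi/alpha)^{3/2} must equal 4/3 pi R^3
    r = np.array([1.7])
    alpha = gaussian_alpha(r, 2.7)[0]
    integral = 2.7 * (np.pi / alpha) ** 1.5
    assert integral == pytest.approx(4.0 / 3.0 * np.pi * r[0] ** 3, rel=1e-12)


def test_overlap_self_equals_self_volume(templates):
    params = GaussianShapeParams()
    t = templates[0]
    assert overlap_volume(t, t, params) == pytest.approx(self_volume(t, params))


def test_overlap_symmetric_and_positive(templates):
    a, b = templates[0], templates[1]
    vab = overlap_volume(a, b)
    assert vab > 0
    assert vab == pytest.approx(overlap_volume(b, a), rel=1e-12)


def test_distant_atoms_have_negligible_overlap():
    a = _mol("a", ["C"], [[0.0, 0.0, 0.0]])
    b = _mol("b", ["C"], [[50.0, 0.0, 0.0]])
    assert overlap_volume(a, b) < 1e-9


def test_overlap_matches_quadrature_one_atom_pair(two_atom_pair):
    a, b = two_atom_pair
    params = GaussianShapeParams()
    analytic = overlap_volume(a, b, params)
    oracle = quadrature_overlap(a, b, params)
    assert analytic == pytest.approx(oracle, rel=0.01)


def test_overlap_matches_quadrature_multi_atom():
    a = _mol("a", ["C", "O", "N"],
             [[0.0, 0, 0], [1.4, 0, 0], [0.7, 1.2, 0]])
    b = _mol("b", ["C", "C"], [[0.5, 0.3, 0.2], [1.8, -0.4, 0.1]])
    params = GaussianShapeParams()
    assert overlap_volume(a, b, params) == pytest.approx(
        quadrature_overlap(a, b, params), rel=0.01)


def test_tanimoto_from_quadrature_volumes(two_atom_pair):
    a, b = two_atom_pair
    params = GaussianShapeParams()
    # fixed-pose Tanimoto computed twice: analytic volumes vs quadrature
    vaa, vbb, vab = (overlap_volume(a, a, params), overlap_volume(b, b, params),
                     overlap_volume(a, b, params))
    qaa, qbb, qab = (quadrature_overlap(a, a, params),
                     quadrature_overlap(b, b, params),
                     quadrature_overlap(a, b, params))
    assert vab / (vaa + vbb - vab) == pytest.approx(qab / (qaa + qbb - qab),
                                                    rel=0.01)


def test_self_tanimoto_is_one(templates):
    for t in templates[:3]:
        assert shape_tanimoto(t, t, seed=1).shape_tanimoto == pytest.approx(1.0, abs=1e-6)


def test_size_mismatch_bounds_tanimoto_below_one():
    a = _mol("a", ["C"], [[0.0, 0.0, 0.0]])
    b = _mol("b", ["C"] * 8, np.random.default_rng(0).normal(scale=2.0, size=(8, 3)))
    assert shape_tanimoto(a, b, seed=0).shape_tanimoto < 1.0


def test_overlay_recovers_translated_copy(templates):
    t = templates[0]
    moved = t.transformed(np.eye(3), np.array([10.0, 0.0, 0.0]))
    _, best = optimize_overlay(t, moved, seed=2)
    assert best == pytest.approx(self_volume(t), rel=0.01)


def test_overlay_recovers_rotated_copy(templates):
    t = templates[1]
    rot = RigidTransform(np.array([np.cos(np.pi / 4), 0, 0, np.sin(np.pi / 4)]))
    moved = rot.apply_molecule(t)
    _, best = optimize_overlay(t, moved, seed=3)
    assert best == pytest.approx(self_volume(t), rel=0.01)


def test_more_starts_never_worse(templates):
    ref, fit = templates[0], templates[2]
    _, v1 = optimize_overlay(ref, fit, n_starts=1, seed=5)
    _, v20 = optimize_overlay(ref, fit, n_starts=20, seed=5)
    assert v20 >= v1 - 1e-9


def test_tanimoto_symmetric_under_swap(templates):
    a, b = templates[0], templates[3]
    tab = shape_tanimoto(a, b, seed=7).shape_tanimoto
    tba = shape_tanimoto(b, a, seed=7).shape_tanimoto
    assert tab == pytest.approx(tba, abs=1e-3)


def test_tanimoto_invariant_under_rigid_motion(templates):
    a, b = templates[0], templates[1]
    t0 = shape_tanimoto(a, b, seed=9).shape_tanimoto
    rot = RigidTransform(np.array([0.5, 0.5, 0.5, 0.5]), np.array([3.0, -2.0, 1.0]))
    t1 = shape_tanimoto(a, rot.apply_molecule(b), seed=9).shape_tanimoto
    assert t1 == pytest.approx(t0, abs=1e-3)


def test_empty_molecule_rejected():
    with pytest.raises(ValueError):
        Molecule3D(name="empty", elements=[], coords=np.zeros((0, 3)))


def test_nonfinite_coordinates_rejected(templates):
    bad = templates[0].copy()
    bad.coords[0, 0] = np.nan
    with pytest.raises(ValueError):
        optimize_overlay(templates[0], bad)
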