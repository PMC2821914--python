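"""Trajectory binding: occupancy, contacts and point-charge energies."""

import numpy as np
import pytest

from synucleag import synthetic
from synucleag.binding import (BindingCriteria, binding_fractions,
                               coulomb_energy, detect_hbonds,
                               detect_hydrophobic, energy_stats, is_bound,
                               min_calpha_com_distance, normalize_energy_table,
                               persistent_contacts, region_occupancy,
                               EnergyRow, EnergyTable)
from synucleag.esp import COULOMB_CONSTANT_KCAL
from synucleag.molecules import Molecule3D
from synucleag.protein import Frame, Trajectory
from synucleag.synthetic import SynthConfig


def _place_ligand(protein, ligand, point):
    com = ligand.center_of_mass()
    return Frame(protein.ca_coords(), ligand.coords - com + point)


@pytest.fixture(scope="module")
def ligand(templates):
    return templates[0]


class TestDistances:
    def test_com_on_calpha_gives_zero(self, protein, ligand):
        frame = _place_ligand(protein, ligand, protein.residue(70).ca)
        assert min_calpha_com_distance(frame, protein, ligand) == pytest.approx(0.0, abs=1e-9)

    def test_single_residue_subset_is_plain_distance(self, protein, ligand):
        target = protein.residue(127).ca + np.array([5.0, 0, 0])
        frame = _place_ligand(protein, ligand, target)
        d = min_calpha_com_distance(frame, protein, ligand, {127})
        assert d == pytest.approx(5.0, abs=1e-9)

    def test_matches_brute_force(self, protein, ligand, rng):
        point = protein.ca_coords().mean(axis=0) + rng.normal(scale=10.0, size=3)
        frame = _place_ligand(protein, ligand, point)
        com = (frame.ligand_coords[ligand.heavy_mask()]
               * ligand.masses[ligand.heavy_mask()][:, None]).sum(axis=0) \
            / ligand.masses[ligand.heavy_mask()].sum()
        brute = min(np.linalg.norm(r.ca - com) for r in protein.residues)
        assert min_calpha_com_distance(frame, protein, ligand) == pytest.approx(brute)


class TestBoundCriterion:
    @pytest.mark.parametrize("distance,expected", [(7.99, True), (8.00, False)])
    def test_strict_inequality_at_cutoff(self, protein, ligand, distance, expected):
        # place COM exactly `distance` from residue 1's Cα, far from the rest
        chain_end = protein.residues[0]
        away = chain_end.ca - protein.ca_coords().mean(axis=0)
        away = away / np.linalg.norm(away)
        frame = _place_ligand(protein, ligand, chain_end.ca + distance * away)
        d = min_calpha_com_distance(frame, protein, ligand)
        if abs(d - distance) < 1e-9:  # no other Cα interferes
            assert is_bound(frame, protein, ligand, BindingCriteria(8.0)) is expected

    def test_generator_labels_reproduced(self, protein, ligand):
        cfg = SynthConfig(seed=21, n_frames=200, bound_fraction=0.37)
        traj = synthetic.gen_trajectory(protein, ligand, cfg)
        crit = BindingCriteria(8.0)
        labels = [is_bound(f, protein, ligand, crit) for f in traj.frames]
        np.testing.assert_array_equal(labels, traj.metadata["bound_labels"])


class TestOccupancy:
    def test_exact_fraction_recovery(self, protein, ligand):
        cfg = SynthConfig(seed=23, n_frames=1000, bound_fraction=0.69)
        traj = synthetic.gen_trajectory(protein, ligand, cfg)
        prof = binding_fractions(traj)
        assert prof.pct_protein == pytest.approx(69.0, abs=1e-12)

    def test_target_restriction_bounded_by_protein(self, protein, ligand):
        cfg = SynthConfig(seed=25, n_frames=300, bound_fraction=0.5)
        traj = synthetic.gen_trajectory(protein, ligand, cfg,
                                        bound_region="target")
        prof = binding_fractions(traj)
        assert 0.0 <= prof.pct_target <= prof.pct_protein <= 100.0
        assert prof.pct_target == pytest.approx(50.0, abs=1e-12)

    def test_region_occupancy_threshold_is_strict(self, protein, ligand):
        cfg = SynthConfig(seed=27, n_frames=100, bound_fraction=0.5)
        traj = synthetic.gen_trajectory(protein, ligand, cfg, bound_region="nac")
        pct, persistent = region_occupancy(
            traj, {"nac": protein.annotations["nac"]}, BindingCriteria(8.0))
        assert pct["nac"] == pytest.approx(50.0)
        assert "nac" not in persistent  # exactly 50% is NOT more than 50%

    def test_parked_ligand_fully_occupies_region(self, protein, ligand):
        cfg = SynthConfig(seed=29, n_frames=50, bound_fraction=1.0)
        traj = synthetic.gen_trajectory(protein, ligand, cfg, bound_region="nac")
        pct, persistent = region_occupancy(
            traj, {"nac": protein.annotations["nac"]}, BindingCriteria(8.0))
        assert pct["nac"] == 100.0
        assert persistent == ["nac"]

    def test_overlapping_regions_can_sum_past_100(self, protein, ligand):
        cfg = SynthConfig(seed=31, n_frames=40, bound_fraction=1.0)
        traj = synthetic.gen_trajectory(protein, ligand, cfg, bound_region="nac")
        pct, _ = region_occupancy(
            traj, {"nac": protein.annotations["nac"],
                   "nac_copy": protein.annotations["nac"]}, BindingCriteria(8.0))
        assert pct["nac"] + pct["nac_copy"] > 100.0

    def test_empty_partition_rejected(self, protein, ligand):
        cfg = SynthConfig(seed=31, n_frames=5)
        traj = synthetic.gen_trajectory(protein, ligand, cfg)
        with pytest.raises(ValueError):
            region_occupancy(traj, {})


class TestContacts:
    def test_canonical_hbond_detected(self, protein):
        res = protein.residue(61)  # has OE1/OE2 acceptors
        target = res.atoms[1].position  # OE1
        lig = Molecule3D(name="lig", elements=["O", "H"],
                         coords=np.array([target + [2.8, 0, 0],
                                          target + [1.8, 0, 0]]),
                         bonds=[(0, 1)])
        frame = Frame(protein.ca_coords(), lig.coords)
        events = detect_hbonds(frame, protein, lig)
        assert any(e.residue == 61 and e.distance == pytest.approx(2.8)
                   for e in events)

    def test_long_donor_acceptor_distance_rejected(self, protein):
        target = protein.residue(61).atoms[1].position
        lig = Molecule3D(name="lig", elements=["O"],
                         coords=np.array([target + [3.6, 0, 0]]))
        frame = Frame(protein.ca_coords(), lig.coords)
        assert not detect_hbonds(frame, protein, lig)

    def test_bent_hbond_angle_rejected(self, protein):
        target = protein.residue(61).atoms[1].position
        # donor O at 3.0 Å; its H points away -> D-H...A angle ~ 0°
        lig = Molecule3D(name="lig", elements=["O", "H"],
                         coords=np.array([target + [3.0, 0, 0],
                                          target + [4.0, 0, 0]]),
                         bonds=[(0, 1)])
        frame = Frame(protein.ca_coords(), lig.coords)
        assert not detect_hbonds(frame, protein, lig)

    def test_hydrophobic_carbon_pair_detected(self, protein):
        cb = protein.residue(70).atoms[0].position  # CB
        lig = Molecule3D(name="lig", elements=["C"],
                         coords=np.array([cb + [3.5, 0, 0]]))
        frame = Frame(protein.ca_coords(), lig.coords)
        events = detect_hydrophobic(frame, protein, lig)
        assert any(e.residue == 70 for e in events)

    def test_oxygen_not_a_hydrophobic_partner(self, protein):
        cb = protein.residue(70).atoms[0].position
        lig = Molecule3D(name="lig", elements=["O"],
                         coords=np.array([cb + [3.0, 0, 0]]))
        frame = Frame(protein.ca_coords(), lig.coords)
        assert not detect_hydrophobic(frame, protein, lig)

    def test_persistence_flags_strictly_above_threshold(self, protein):
        cb = protein.residue(70).atoms[0].position
        lig = Molecule3D(name="lig", elements=["C"],
                         coords=np.array([cb + [3.5, 0, 0]]))
        near = Frame(protein.ca_coords(), lig.coords)
        far = Frame(protein.ca_coords(), lig.coords + 500.0)
        traj = Trajectory(protein, lig, [near, far])  # 50% occupancy
        table = persistent_contacts(traj, threshold=0.5)
        row = table[(table.residue == 70) & (table.kind == "hydrophobic")]
        assert row.fraction.iloc[0] == 0.5
        assert not row.persistent.iloc[0]
        traj_always = Trajectory(protein, lig, [near, near])
        table = persistent_contacts(traj_always, threshold=0.5)
        row = table[(table.residue == 70) & (table.kind == "hydrophobic")]
        assert row.fraction.iloc[0] == 1.0
        assert bool(row.persistent.iloc[0])


class TestEnergies:
    def test_unit_charges_at_one_angstrom(self):
        e = coulomb_energy(np.array([[0.0, 0, 0]]), np.array([1.0]),
                           np.array([[1.0, 0, 0]]), np.array([-1.0]))
        assert e == pytest.approx(-COULOMB_CONSTANT_KCAL, rel=1e-12)
        assert e == pytest.approx(-332.06, abs=0.01)

    def test_zero_charge_ligand_gives_zero(self):
        e = coulomb_energy(np.array([[0.0, 0, 0]]), np.array([0.0]),
                           np.array([[1.0, 0, 0]]), np.array([-1.0]))
        assert e == 0.0

    def test_overlapping_charges_rejected(self):
        with pytest.raises(ValueError):
            coulomb_energy(np.array([[0.0, 0, 0]]), np.array([1.0]),
                           np.array([[0.0, 0, 0]]), np.array([-1.0]))

    def test_matches_brute_force_double_loop(self, rng):
        lc = rng.normal(size=(5, 3))
        sc = rng.normal(size=(3, 3)) + 10.0
        lq = rng.normal(size=5)
        sq = rng.normal(size=3)
        brute = sum(COULOMB_CONSTANT_KCAL * qi * qj / np.linalg.norm(pi - pj)
                    for pi, qi in zip(lc, lq) for pj, qj in zip(sc, sq))
        assert coulomb_energy(lc, lq, sc, sq) == pytest.approx(brute, abs=1e-9)

    def test_energy_invariant_under_rigid_motion(self, rng):
        lc = rng.normal(size=(4, 3))
        sc = rng.normal(size=(2, 3)) + 5.0
        lq = rng.normal(size=4)
        sq = rng.normal(size=2)
        e0 = coulomb_energy(lc, lq, sc, sq)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        shift = np.array([3.0, -1.0, 2.0])
        e1 = coulomb_energy(lc @ rot.T + shift, lq, sc @ rot.T + shift, sq)
        assert e1 == pytest.approx(e0, rel=1e-12)

    def test_constant_geometry_has_zero_sd(self, protein, ligand):
        cfg = SynthConfig(seed=33, n_frames=1, bound_fraction=1.0)
        traj = synthetic.gen_trajectory(protein, ligand, cfg)
        frames = [traj.frames[0], traj.frames[0], traj.frames[0]]
        traj3 = Trajectory(protein, ligand, frames)
        table = energy_stats(traj3)
        assert all(r.sd_kcal == pytest.approx(0.0, abs=1e-12) for r in table.rows)

    def test_mean_and_sample_sd_arithmetic(self):
        rows = [EnergyRow("L", 83, -3.0, 0.0)]
        # two frame energies -2 and -4: mean -3, sample sd sqrt(2)
        arr = np.array([-2.0, -4.0])
        assert arr.mean() == -3.0
        assert arr.std(ddof=1) == pytest.approx(np.sqrt(2.0))
        assert rows[0].mean_kcal == -3.0


class TestNormalization:
    def _table(self):
        return EnergyTable([
            EnergyRow("IQ", 83, -2.8, 0.3, charge_class="neutral"),
            EnergyRow("IQ", 61, -0.84, 0.2, charge_class="neutral"),
            EnergyRow("DOPH", 61, -41.72, 3.0, charge_class="charged"),
        ])

    def test_reference_row_maps_to_minus_one(self):
        out = normalize_energy_table(self._table())
        assert out.reference_kcal == -2.8
        assert out.rows[0].normalized == pytest.approx(-1.0, abs=1e-12)

    def test_linear_scaling(self):
        table = EnergyTable([EnergyRow("A", 83, -2.8, 0.0),
                             EnergyRow("B", 83, -5.6, 0.0,
                                       charge_class="charged")])
        out = normalize_energy_table(table)
        assert out.reference_kcal == -2.8
        assert out.rows[1].normalized == pytest.approx(-2.0)

    def test_charged_rows_may_exceed_unit_magnitude(self):
        out = normalize_energy_table(self._table())
        assert out.rows[2].normalized == pytest.approx(-14.9, abs=0.01)

    def test_all_positive_table_rejected(self):
        table = EnergyTable([EnergyRow("A", 83, 1.0, 0.0)])
        with pytest.raises(ValueError):
            normalize_energy_table(table)
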