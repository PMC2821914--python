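"""Synthetic-data generators: determinism, geometry, ground-truth labels."""

import numpy as np
import pytest

from synucleag import synthetic
from synucleag.morphology import classify_fibril
from synucleag.synthetic import SynthConfig, ThTParams


class TestLigandSet:
    def test_zero_decoys_returns_template_only(self, templates):
        cfg = SynthConfig(seed=0, n_decoys=0)
        out = synthetic.gen_ligand_set(templates[:1], cfg)
        assert len(out) == 1
        np.testing.assert_array_equal(out[0].coords, templates[0].coords)

    def test_library_size_arithmetic(self, templates):
        cfg = SynthConfig(seed=0, n_decoys=99)
        out = synthetic.gen_ligand_set(templates, cfg)
        assert len(out) == 6 * (1 + 99)

    def test_same_seed_is_byte_identical(self, templates):
        cfg = SynthConfig(seed=42, n_decoys=5)
        a = synthetic.gen_ligand_set(templates, cfg)
        b = synthetic.gen_ligand_set(templates, cfg)
        for ma, mb in zip(a, b):
            assert ma.coords.tobytes() == mb.coords.tobytes()
            assert ma.charges.tobytes() == mb.charges.tobytes()

    def test_ground_truth_rank_recorded(self, templates):
        cfg = SynthConfig(seed=1, n_decoys=3)
        out = synthetic.gen_ligand_set(templates[:1], cfg)
        assert [m.metadata["decoy_rank"] for m in out] == [0, 1, 2, 3]

    def test_empty_templates_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_ligand_set([], SynthConfig())


class TestProteinConformer:
    def test_target_region_annotation(self, protein):
        assert protein.annotations["target"] == frozenset(range(125, 130))
        assert protein.annotations["nac"] == frozenset(range(61, 96))

    def test_consecutive_ca_distance(self, protein):
        ca = protein.ca_coords()
        steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(steps - 3.8) <= 0.1 + 1e-12)

    def test_nonbonded_pairs_well_separated(self, protein):
        # exhaustive pair scan, excluding bonded neighbours
        ca = protein.ca_coords()
        n = len(ca)
        d = np.linalg.norm(ca[:, None] - ca[None, :], axis=2)
        iu = np.triu_indices(n, k=2)
        assert d[iu].min() > 3.0

    def test_charged_sites_at_e61_e83(self, protein):
        for idx in (61, 83):
            res = protein.residue(idx)
            assert res.name == "GLU"
            assert len(res.charge_sites) == 1
            assert res.charge_sites[0].charge == -1.0

    def test_same_seed_identical_chain(self):
        cfg = SynthConfig(seed=3)
        a = synthetic.gen_protein_conformer(140, cfg)
        b = synthetic.gen_protein_conformer(140, cfg)
        np.testing.assert_array_equal(a.ca_coords(), b.ca_coords())

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_protein_conformer(100, SynthConfig())


class TestTrajectory:
    def test_all_bound(self, protein, templates):
        cfg = SynthConfig(seed=5, n_frames=20, bound_fraction=1.0)
        traj = synthetic.gen_trajectory(protein, templates[0], cfg)
        assert traj.metadata["bound_labels"].all()

    def test_half_bound_rounding(self, protein, templates):
        cfg = SynthConfig(seed=5, n_frames=100, bound_fraction=0.5)
        traj = synthetic.gen_trajectory(protein, templates[0], cfg)
        assert traj.metadata["bound_labels"].sum() == 50

    def test_bad_cutoff_rejected(self, protein, templates):
        with pytest.raises(ValueError):
            synthetic.gen_trajectory(protein, templates[0], SynthConfig(),
                                     cutoff=0.0)

    def test_constant_atom_counts(self, protein, templates):
        cfg = SynthConfig(seed=5, n_frames=10, bound_fraction=0.3)
        traj = synthetic.gen_trajectory(protein, templates[0], cfg)
        assert traj.n_frames == 10


class TestThTCurves:
    def test_midpoint_identity_noiseless(self):
        p = ThTParams(f0=7.0, amplitude=50.0, t50_h=40.0, rate_per_h=0.2,
                      noise_sd=0.0)
        cfg = SynthConfig(seed=9, tht_params=p)
        curve = synthetic.gen_tht_curves(cfg, n_replicates=1)[0]
        i = np.argmin(np.abs(curve.times - 40.0))
        assert curve.fluorescence[i] == pytest.approx(7.0 + 25.0, abs=1e-9)

    def test_five_minute_grid_gives_1201_points(self):
        curve = synthetic.gen_tht_curves(SynthConfig(seed=9), n_replicates=1)[0]
        assert len(curve.times) == 1201

    def test_replicates_share_truth_distinct_noise(self):
        curves = synthetic.gen_tht_curves(SynthConfig(seed=9), n_replicates=3)
        assert len(curves) == 3
        assert curves[0].metadata["truth"] == curves[1].metadata["truth"]
        assert not np.array_equal(curves[0].fluorescence, curves[1].fluorescence)

    def test_bad_interval_rejected(self):
        with pytest.raises(ValueError):
            synthetic.gen_tht_curves(SynthConfig(), interval_min=0.0)


class TestFibrilPopulation:
    def test_pure_mature_mixture(self):
        cfg = SynthConfig(seed=2, class_mix=(0.0, 0.0, 1.0))
        pop = synthetic.gen_fibril_population(cfg, n=10)
        assert all(m.length_um > 0.75 for m in pop)

    def test_classifier_recovers_all_labels(self):
        cfg = SynthConfig(seed=2, class_mix=(0.3, 0.3, 0.4))
        pop = synthetic.gen_fibril_population(cfg, n=200)
        assert all(classify_fibril(m.length_um) == m.true_class for m in pop)

    def test_same_seed_identical_table(self):
        cfg = SynthConfig(seed=8)
        a = synthetic.gen_fibril_population(cfg, n=50)
        b = synthetic.gen_fibril_population(cfg, n=50)
        assert [(m.length_um, m.width_nm) for m in a] == \
               [(m.length_um, m.width_nm) for m in b]

    def test_degenerate_mixture_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(class_mix=(0.0, 0.0, 0.0))


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"bound_fraction": 1.5},
        {"n_frames": 0},
        {"perturb_sd": -0.1},
        {"class_mix": (0.5, 0.5, 0.5)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(**kwargs)
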