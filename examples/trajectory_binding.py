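"""Occupancy and point-charge energy analysis of a protein-ligand trajectory.

Generates a 140-residue Cα conformer annotated like α-synuclein (NAC
61-95, target motif 125-129, charges at E61/E83) and a 500-frame synthetic
trajectory in which 69% of frames place the ligand within the 8 Å
Cα-to-ligand-centre-of-mass bound criterion. The analysis then recovers
that occupancy, reports per-region percentages, and tabulates vacuum
Coulomb interaction energies with E61/E83, normalised so the most negative
neutral-ligand mean is -1.0.
"""

from synucleag import (BindingCriteria, SynthConfig, binding_fractions,
                       energy_stats, example_templates, gen_protein_conformer,
                       gen_trajectory, normalize_energy_table)

cfg = SynthConfig(seed=11, n_frames=500, bound_fraction=0.69)
protein = gen_protein_conformer(140, cfg)
ligand = example_templates()[0]
traj = gen_trajectory(protein, ligand, cfg, bound_region="nac")

profile = binding_fractions(traj, BindingCriteria(cutoff=8.0))
print(f"bound to protein: {profile.pct_protein:.1f}% of frames "
      f"(generator ground truth: {100 * cfg.bound_fraction:.1f}%)")
print(f"bound to target motif 125-129: {profile.pct_target:.1f}%")
for region, pct in sorted(profile.region_pct.items()):
    print(f"  region {region:8s} {pct:5.1f}%")

table = normalize_energy_table(energy_stats(traj, residues=(83, 61)))
print(f"\npoint-charge energies (reference {table.reference_kcal:.2f} kcal/mol):")
for row in table.rows:
    print(f"  {row.ligand} - E{row.residue}: {row.mean_kcal:+.2f} "
          f"+/- {row.sd_kcal:.2f} kcal/mol  (normalized {row.normalized:+.2f})")
print("\nNegative means are stabilising; the normalisation maps the most "
      "negative neutral-ligand mean to -1.0 for qualitative comparison.")
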