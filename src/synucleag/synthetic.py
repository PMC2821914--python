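"""Synthetic inputs with known ground truth for every pipeline stage.

Nothing in the original study is deposited as machine-readable data, so
this module generates statistically analogous inputs: a ligand library of
dopamine-like templates plus progressively perturbed decoys, a 140-residue
Cα-resolution α-synuclein-like conformer with annotated NAC (61–95) and
target (125–129) regions and −1 e side-chain charges at E61/E83,
protein–ligand trajectories with an exact known fraction of bound frames,
sigmoidal ThT curves with Gaussian noise, and fibril populations drawn from
a three-class length mixture that avoids the class boundaries.

Every generator is a pure function of its inputs and the config seed, and
records its ground truth in output metadata so downstream stages can be
scored without re-derivation. These are statistical emulations: decoy
geometry is not chemistry, the conformer is a self-avoiding walk rather
than an NMR ensemble, and trajectories place a rigid ligand rather than
integrating dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import ThTCurve, logistic
from .molecules import Molecule3D
from .morphology import FibrilMeasurement
from .protein import ChargeSite, Frame, ProteinConformer, Residue, ResidueAtom, Trajectory

__all__ = ["ThTParams", "SynthConfig", "example_templates", "gen_ligand_set",
           "gen_protein_conformer", "gen_trajectory", "gen_tht_curves",
           "gen_fibril_population"]


@dataclass
class ThTParams:
    """True parameters of generated ThT curves (a.u., hours)."""

    f0: float = 10.0
    amplitude: float = 100.0
    t50_h: float = 40.0
    rate_per_h: float = 0.2
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.rate_per_h <= 0 or self.amplitude <= 0:
            raise ValueError("rate and amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class SynthConfig:
    """Shared configuration for every generator.

    ``perturb_sd`` is the per-index decoy displacement step (Å): decoy i of
    a template is perturbed with sd = i·perturb_sd, so similarity to the
    template decreases monotonically with i in expectation.
    ``class_mix`` is (short, intermediate, mature) proportions.
    """

    seed: int = 0
    n_decoys: int = 9
    perturb_sd: float = 0.15
    n_frames: int = 1000
    bound_fraction: float = 0.69
    tht_params: ThTParams = field(default_factory=ThTParams)
    class_mix: tuple[float, float, float] = (0.2, 0.3, 0.5)

    def __post_init__(self) -> None:
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")
        if self.perturb_sd < 0:
            raise ValueError("perturb_sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must lie in [0, 1]")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if any(p < 0 for p in self.class_mix):
            raise ValueError("class_mix proportions must be >= 0")


# ---------------------------------------------------------------------------
# template molecules

def _ring(n: int = 6, bond: float = 1.40) -> np.ndarray:
    """Planar regular n-ring with the given bond length, in the xy plane."""
    r = bond / (2 * np.sin(np.pi / n))
    ang = 2 * np.pi * np.arange(n) / n
    return np.stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)], axis=1)


def example_templates() -> list[Molecule3D]:
    """Six dopamine-like template molecules built procedurally.

    Shapes emulate dopamine and its oxidation products (catechol ring plus
    an aminoethyl tail; quinone/indole-like variants): an aromatic carbon
    ring decorated with O/N substituents carrying small partial charges.
    One template carries a protonated (+1 net) amine, mirroring the one
    charged ligand of the study set; the others are net-neutral in the
    integer sense but carry a small positive excess on the amine tail, as
    catecholamines do at physiological pH, so their electrostatic
    interaction with anionic side chains is stabilising on average.
    """
    ring = _ring()
    templates = []

    def add(name, extra_elems, extra_coords, charges):
        elems = ["C"] * 6 + extra_elems
        coords = np.vstack([ring, extra_coords])
        templates.append(Molecule3D(name=name, elements=elems, coords=coords,
                                    charges=np.asarray(charges, dtype=float),
                                    metadata={"template": name, "decoy_rank": 0}))

    # catecholamine: two ring hydroxyls + ethylamine tail
    tail = np.array([[2.6, 0.0, 0.3], [3.6, 0.9, 0.6], [4.9, 0.4, 0.9]])
    oh = np.array([[-1.2, 2.0, 0.0], [-2.3, 0.2, 0.0]])
    add("T1_catecholamine", ["O", "O", "C", "C", "N"], np.vstack([oh, tail]),
        [0.05, 0.05, 0.1, 0.1, 0.1, 0.1, -0.35, -0.35, 0.0, 0.1, 0.3])
    # quinone-like: two carbonyl oxygens, shorter tail
    add("T2_quinone", ["O", "O", "C", "N"],
        np.vstack([oh, tail[:2]]),
        [0.15, 0.15, 0.05, 0.05, 0.05, 0.05, -0.45, -0.45, 0.05, 0.55])
    # indole-like: fused second ring approximated by three carbons + NH
    fused = np.array([[1.9, 1.4, 0.0], [3.1, 0.9, 0.0], [3.1, -0.5, 0.0],
                      [1.9, -1.1, 0.0]])
    add("T3_indole", ["C", "C", "C", "N"], fused,
        [0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.0, 0.0, 0.0, -0.12])
    # hydroxyindole: indole plus ring hydroxyl
    add("T4_hydroxyindole", ["C", "C", "C", "N", "O"],
        np.vstack([fused, [[-2.3, 0.2, 0.0]]]),
        [0.03, 0.03, 0.03, 0.03, 0.03, 0.03, 0.0, 0.0, 0.0, 0.1, -0.28])
    # protonated amine tail (net +1), dopamine-quinone-protonated analogue
    add("T5_ammonium", ["O", "C", "C", "N"],
        np.vstack([oh[:1], tail]),
        [0.1, 0.1, 0.1, 0.1, 0.1, 0.1, -0.4, 0.05, 0.15, 0.7])
    # plain aminophenol-like
    add("T6_aminophenol", ["O", "N"],
        np.array([[-2.3, 0.2, 0.0], [2.6, 0.0, 0.0]]),
        [0.05, 0.05, 0.05, 0.05, 0.05, 0.05, -0.25, 0.15])
    return templates


def gen_ligand_set(templates: list[Molecule3D], cfg: SynthConfig) -> list[Molecule3D]:
    """Templates plus perturbed decoys emulating a screening library.

    For each template, ``cfg.n_decoys`` decoys are produced; decoy i has
    coordinates displaced by zero-mean Gaussians of sd i·perturb_sd and
    charges jittered proportionally (relative sd 0.02·i). Ground truth —
    the source template and the perturbation rank i — is stored in each
    decoy's metadata, so rank order by perturbation magnitude is known.
    """
    if not templates:
        raise ValueError("template list must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    out: list[Molecule3D] = []
    for tmpl in templates:
        t = tmpl.copy()
        t.metadata.setdefault("template", tmpl.name)
        t.metadata["decoy_rank"] = 0
        out.append(t)
        for i in range(1, cfg.n_decoys + 1):
            sd = i * cfg.perturb_sd
            coords = tmpl.coords + rng.normal(0.0, sd, tmpl.coords.shape)
            charges = tmpl.charges * (1.0 + rng.normal(0.0, 0.02 * i, tmpl.n_atoms))
            out.append(Molecule3D(
                name=f"{tmpl.name}_d{i:03d}",
                elements=list(tmpl.elements),
                coords=coords,
                charges=charges,
                metadata={"template": tmpl.name, "decoy_rank": i,
                          "perturb_sd": sd}))
    return out


# ---------------------------------------------------------------------------
# protein conformer

_TARGET_NAMES = {125: "TYR", 126: "GLU", 127: "MET", 128: "PRO", 129: "SER"}


def gen_protein_conformer(n_residues: int = 140,
                          cfg: SynthConfig | None = None) -> ProteinConformer:
    """Self-avoiding Cα chain annotated like α-synuclein.

    Consecutive Cα are 3.8 ± 0.1 Å apart; non-bonded Cα pairs are kept
    beyond 3.5 Å by rejection (with restart), comfortably above a 3.0 Å
    clash threshold. Regions: NAC = 61–95, target = 125–129; residues 61
    and 83 are glutamates carrying a −1 e side-chain charge site flanked by
    two carboxylate-like oxygens; every residue gets a Cβ-like side-chain
    carbon so hydrophobic contacts are detectable.
    """
    cfg = cfg or SynthConfig()
    if n_residues < 129:
        raise ValueError("need at least 129 residues for the default "
                         "NAC/target annotations")
    rng = np.random.default_rng(cfg.seed + 7)
    min_sep = 3.5

    def build_chain() -> np.ndarray | None:
        pos = [np.zeros(3)]
        direction = _unit(rng.normal(size=3))
        for _ in range(n_residues - 1):
            placed = False
            for _attempt in range(60):
                step = 3.8 + rng.uniform(-0.1, 0.1)
                cand_dir = _unit(direction + 0.7 * rng.normal(size=3))
                cand = pos[-1] + step * cand_dir
                prev = np.array(pos[:-1]) if len(pos) > 1 else None
                if prev is None or np.min(np.linalg.norm(prev - cand, axis=1)) > min_sep:
                    pos.append(cand)
                    direction = cand_dir
                    placed = True
                    break
            if not placed:
                return None
        return np.array(pos)

    chain = None
    while chain is None:
        chain = build_chain()

    residues = []
    for i in range(1, n_residues + 1):
        ca = chain[i - 1]
        if i in (61, 83):
            name = "GLU"
        else:
            name = _TARGET_NAMES.get(i, "ALA")
        # deterministic side-chain direction: away from the local chain axis
        local = _unit(rng.normal(size=3))
        cb = ca + 1.5 * local
        atoms = [ResidueAtom("C", "CB", cb)]
        sites = []
        if i in (61, 83):
            site = ca + 3.0 * local
            atoms += [ResidueAtom("O", "OE1", site + np.array([0.6, 0, 0])),
                      ResidueAtom("O", "OE2", site - np.array([0.6, 0, 0]))]
            sites.append(ChargeSite(site, -1.0))
        residues.append(Residue(i, name, ca, atoms, sites))

    annotations = {
        "nac": frozenset(range(61, 96)),
        "target": frozenset(range(125, 130)),
        "charged": frozenset({61, 83}),
    }
    return ProteinConformer(residues, annotations, name="syn-synthetic")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# trajectory

def gen_trajectory(protein: ProteinConformer, ligand: Molecule3D,
                   cfg: SynthConfig, cutoff: float = 8.0,
                   bound_region: str | None = None) -> Trajectory:
    """Frames with an exact known number of bound frames.

    Exactly round(bound_fraction · n_frames) frames place the ligand centre
    of mass at a uniform random distance in [2 Å, cutoff − 0.5 Å] from a
    randomly chosen Cα (restricted to ``bound_region`` if given), so the
    8 Å bound criterion is met with margin; the remaining frames put the
    ligand at least 2·cutoff from every Cα. Per-frame ground-truth labels
    are stored in ``metadata['bound_labels']``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rng = np.random.default_rng(cfg.seed + 13)
    n_bound = int(round(cfg.bound_fraction * cfg.n_frames))
    labels = np.zeros(cfg.n_frames, dtype=bool)
    labels[rng.choice(cfg.n_frames, size=n_bound, replace=False)] = True

    ca_all = protein.ca_coords()
    if bound_region is not None:
        ca_pool = protein.ca_coords(protein.annotations[bound_region])
    else:
        ca_pool = ca_all
    com = ligand.center_of_mass()
    centered = ligand.coords - com
    centroid = ca_all.mean(axis=0)
    radius = float(np.max(np.linalg.norm(ca_all - centroid, axis=1)))

    frames = []
    for bound in labels:
        if bound:
            anchor = ca_pool[rng.integers(len(ca_pool))]
            d = rng.uniform(2.0, cutoff - 0.5)
            target = anchor + d * _unit(rng.normal(size=3))
        else:
            direction = _unit(rng.normal(size=3))
            target = centroid + (radius + 2.0 * cutoff + 2.0) * direction
            while np.min(np.linalg.norm(ca_all - target, axis=1)) < 2.0 * cutoff:
                target += 2.0 * cutoff * direction
        frames.append(Frame(ca_all, centered + target))

    return Trajectory(protein, ligand, frames, timestep_ps=1.0,
                      metadata={"bound_labels": labels,
                                "bound_region": bound_region,
                                "cutoff": cutoff})


# ---------------------------------------------------------------------------
# ThT curves and fibril populations

def gen_tht_curves(cfg: SynthConfig, n_replicates: int = 3,
                   sample: str = "syn", interval_min: float = 5.0,
                   duration_h: float = 100.0) -> list[ThTCurve]:
    """Replicate sigmoidal ThT curves sampled every 5 min over 0–100 h.

    All replicates share the true parameters in ``cfg.tht_params`` (stored
    in each curve's metadata) and differ only in Gaussian noise.
    """
    if interval_min <= 0:
        raise ValueError("sampling interval must be positive")
    p = cfg.tht_params
    rng = np.random.default_rng(cfg.seed + 29)
    times = np.arange(0.0, duration_h + 1e-9, interval_min / 60.0)
    truth = {"f0": p.f0, "amplitude": p.amplitude, "t50": p.t50_h,
             "rate": p.rate_per_h, "lag": p.t50_h - 2.0 / p.rate_per_h}
    curves = []
    for rep in range(1, n_replicates + 1):
        clean = logistic(times, p.f0, p.amplitude, p.t50_h, p.rate_per_h)
        noisy = clean + rng.normal(0.0, p.noise_sd, times.shape) \
            if p.noise_sd > 0 else clean
        curves.append(ThTCurve(times, noisy, sample=sample, replicate=rep,
                               metadata={"truth": dict(truth)}))
    return curves


#: length sampling ranges per class (µm); a ±0.01 µm margin keeps every
#: generated length strictly off the 0.5/0.75 µm class boundaries
_CLASS_RANGES = {
    "short": (0.05, 0.49),
    "intermediate": (0.51, 0.74),
    "mature": (0.76, 2.50),
}

#: TEM-like width distribution (nm): mean 9.2, sd 2.2
_WIDTH_MEAN_NM = 9.2
_WIDTH_SD_NM = 2.2


def gen_fibril_population(cfg: SynthConfig, n: int = 107,
                          sample: str = "syn",
                          instrument: str = "TEM") -> list[FibrilMeasurement]:
    """Fibril measurements from the three-class length mixture.

    Lengths are uniform within each class range (strictly inside the class
    boundaries); widths are Normal(9.2, 2.2) nm truncated at 1 nm. The true
    class label is stored on each measurement.
    """
    if all(p == 0 for p in cfg.class_mix):
        raise ValueError("degenerate class mixture")
    rng = np.random.default_rng(cfg.seed + 41)
    classes = rng.choice(len(_CLASS_RANGES), size=n, p=list(cfg.class_mix))
    names = list(_CLASS_RANGES)
    out = []
    for c in classes:
        lo, hi = _CLASS_RANGES[names[c]]
        length = rng.uniform(lo, hi)
        width = max(float(rng.normal(_WIDTH_MEAN_NM, _WIDTH_SD_NM)), 1.0)
        out.append(FibrilMeasurement(length_um=float(length), width_nm=width,
                                     sample=sample, instrument=instrument,
                                     true_class=names[c]))
    return out
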