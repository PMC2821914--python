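"""Two-stage template screening: shape Tanimoto top-k1, then ESP top-k2.

The screening protocol follows the dopamine-analogue virtual screen: for
each template the library is ranked by optimised shape Tanimoto and the
best k1 (default 100) retained; those candidates are then re-ranked by
electrostatic Tanimoto at the shape overlay and the best k2 (default 10)
kept. With 6 templates this yields 600 candidates and 60 final hits. Ties
are broken lexicographically by molecule name so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .esp import ESPGridSpec, electrostatic_tanimoto
from .molecules import Molecule3D
from .shape import GaussianShapeParams, SimilarityScore, shape_tanimoto

__all__ = ["ScreenHit", "screen_library", "esp_refine", "hits_to_frame"]


@dataclass
class ScreenHit:
    """One template/candidate score row."""

    template: str
    molecule: Molecule3D
    score: SimilarityScore
    rank: int = 0


def screen_library(templates: list[Molecule3D], library: list[Molecule3D],
                   k1: int = 100,
                   params: GaussianShapeParams | None = None,
                   n_starts: int = 4, seed: int = 0,
                   maxiter: int = 2, xtol: float = 1e-2,
                   ftol: float = 1e-4) -> dict[str, list[ScreenHit]]:
    """Per-template top-k1 shape-Tanimoto hits from the library.

    Returns a dict template-name → ranked hit list (descending shape
    Tanimoto; ties by molecule name). A molecule may be retained by more
    than one template. Total retention is len(templates)·k1.

    The overlay search here defaults to fewer starts (4: identity plus
    the three axis half-turns) and a coarser Powell budget (two outer
    iterations, loose tolerances) than single-pair
    :func:`~synucleag.shape.optimize_overlay`: at library scale the cheaper
    search ranks identically in practice because scores only need to order
    molecules, not squeeze out the last overlap decimal.
    """
    if not templates:
        raise ValueError("no templates given")
    if k1 > len(library):
        raise ValueError(f"k1={k1} exceeds library size {len(library)}")
    params = params or GaussianShapeParams()
    results: dict[str, list[ScreenHit]] = {}
    for t_idx, tmpl in enumerate(templates):
        scored = []
        for mol in library:
            score = shape_tanimoto(tmpl, mol, params, n_starts=n_starts,
                                   seed=seed + t_idx, maxiter=maxiter,
                                   xtol=xtol, ftol=ftol)
            scored.append(ScreenHit(tmpl.name, mol, score))
        scored.sort(key=lambda h: (-h.score.shape_tanimoto, h.molecule.name))
        top = scored[:k1]
        for i, h in enumerate(top):
            h.rank = i + 1
        results[tmpl.name] = top
    return results


def esp_refine(templates: list[Molecule3D], candidates: dict[str, list[ScreenHit]],
               k2: int = 10,
               spec: ESPGridSpec | None = None) -> dict[str, list[ScreenHit]]:
    """Re-rank each template's candidates by ESP Tanimoto; keep top k2.

    The shape-stage overlay transform is reused to pose each candidate
    before computing the field, mirroring a shape-then-electrostatics
    screening cascade.
    """
    spec = spec or ESPGridSpec()
    by_name = {t.name: t for t in templates}
    refined: dict[str, list[ScreenHit]] = {}
    for tname, hits in candidates.items():
        if k2 > len(hits):
            raise ValueError(f"k2={k2} exceeds candidate count {len(hits)} "
                             f"for template {tname}")
        tmpl = by_name[tname]
        rescored = []
        for h in hits:  # fresh hit objects: the shape-stage ranking stays intact
            score = SimilarityScore(h.score.shape_tanimoto,
                                    esp_tanimoto=electrostatic_tanimoto(
                                        tmpl, h.molecule, h.score.transform, spec),
                                    color_tanimoto=h.score.color_tanimoto,
                                    transform=h.score.transform)
            rescored.append(ScreenHit(h.template, h.molecule, score))
        rescored.sort(key=lambda h: (-h.score.esp_tanimoto, h.molecule.name))
        top = rescored[:k2]
        for i, h in enumerate(top):
            h.rank = i + 1
        refined[tname] = top
    return refined


def hits_to_frame(hits: dict[str, list[ScreenHit]]) -> pd.DataFrame:
    """Flatten hit lists to a tidy table (template, molecule, scores, rank)."""
    rows = []
    for tname, hlist in hits.items():
        for h in hlist:
            rows.append({
                "template": tname,
                "molecule": h.molecule.name,
                "shape_tanimoto": h.score.shape_tanimoto,
                "esp_tanimoto": h.score.esp_tanimoto,
                "combo": h.score.combo,
                "rank": h.rank,
            })
    return pd.DataFrame(rows, columns=["template", "molecule", "shape_tanimoto",
                                       "esp_tanimoto", "combo", "rank"])
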