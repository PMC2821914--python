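"""Fibril morphometry: three-class length classification and summaries.

AFM/TEM-measured fibrillar structures are classified by length into
short fibrils/fragments (protofibrils) below 0.5 µm, intermediate fibrils
between 0.5 and 0.75 µm, and mature fibrils above 0.75 µm. The outer
classes are strict (< 0.5, > 0.75), so the boundary lengths themselves fall
in the intermediate class. Spherical/oligomeric structures are not
length-classified and pass through with their flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FibrilMeasurement", "MorphologyThresholds", "MorphologySummary",
           "classify_fibril", "summarize", "CLASS_ORDER"]

CLASS_ORDER = ("short", "intermediate", "mature")


@dataclass
class FibrilMeasurement:
    """One measured structure: length in µm, optional width in nm."""

    length_um: float
    width_nm: float | None = None
    sample: str = "sample"
    instrument: str = "AFM"  # AFM or TEM
    spherical: bool = False  # oligomer-like round structure; not classified
    true_class: str | None = None  # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        if not self.spherical and self.length_um <= 0:
            raise ValueError("fibril length must be positive")
        if self.width_nm is not None and self.width_nm <= 0:
            raise ValueError("fibril width must be positive")
        if self.instrument not in ("AFM", "TEM"):
            raise ValueError("instrument must be AFM or TEM")


@dataclass
class MorphologyThresholds:
    """Length-class boundaries in µm (defaults 0.5 and 0.75)."""

    lower_um: float = 0.5
    upper_um: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.lower_um < self.upper_um:
            raise ValueError("need 0 < lower < upper")


@dataclass
class MorphologySummary:
    """Per-sample class counts/proportions plus width statistics."""

    counts: dict[str, int]
    proportions: dict[str, float]
    n: int
    width_mean_nm: float | None
    width_sd_nm: float | None
    width_n: int
    dominant_class: str
    n_spherical: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": list(CLASS_ORDER),
            "count": [self.counts[c] for c in CLASS_ORDER],
            "proportion": [self.proportions[c] for c in CLASS_ORDER],
        })


def classify_fibril(length_um: float,
                    thresholds: MorphologyThresholds | None = None) -> str:
    """Map a positive length to short / intermediate / mature.

    short: length < lower; intermediate: lower <= length <= upper;
    mature: length > upper. Boundary lengths are intermediate, forced by
    the strict inequalities on the outer classes.
    """
    thresholds = thresholds or MorphologyThresholds()
    if length_um <= 0:
        raise ValueError("fibril length must be positive")
    if length_um < thresholds.lower_um:
        return "short"
    if length_um <= thresholds.upper_um:
        return "intermediate"
    return "mature"


def summarize(measurements: list[FibrilMeasurement],
              thresholds: MorphologyThresholds | None = None) -> MorphologySummary:
    """Class counts/proportions and width mean ± sample sd.

    Widths are summarised over all non-spherical measurements that carry a
    width. Dominant class is the most populous; ties go to the longer
    class. Spherical structures are counted separately and excluded from
    length classes.
    """
    thresholds = thresholds or MorphologyThresholds()
    if not measurements:
        raise ValueError("no measurements")
    counts = {c: 0 for c in CLASS_ORDER}
    widths = []
    n_spherical = 0
    for m in measurements:
        if m.spherical:
            n_spherical += 1
            continue
        counts[classify_fibril(m.length_um, thresholds)] += 1
        if m.width_nm is not None:
            widths.append(m.width_nm)
    n = sum(counts.values())
    proportions = {c: (counts[c] / n if n else 0.0) for c in CLASS_ORDER}
    if widths:
        warr = np.asarray(widths, dtype=float)
        width_mean = float(warr.mean())
        width_sd = float(warr.std(ddof=1)) if len(warr) > 1 else 0.0
    else:
        width_mean = width_sd = None
    # ties broken toward the longer class: scan from mature down
    dominant = max(reversed(CLASS_ORDER), key=lambda c: counts[c])
    return MorphologySummary(counts, proportions, n, width_mean, width_sd,
                             len(widths), dominant, n_spherical)
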