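"""ThT fibrillization kinetics: background subtraction, sigmoid fit, lag time.

Thioflavin-T fluorescence traces of nucleated amyloid polymerisation show a
lag phase, an exponential growth phase and a plateau. Each replicate is
fitted with the logistic

    F(t) = F0 + A / (1 + exp(-k (t - t50)))

by least squares, and the lag time is the tangent-intercept convention
standard in amyloid kinetics: the intersection of the maximum-slope tangent
with the baseline, lag = t50 − 2/k. Group lags are compared with a one-way
fixed-effects F-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = ["ThTCurve", "KineticsFit", "logistic", "preprocess", "fit_sigmoid",
           "lag_time", "compare_lags", "LagComparison"]


@dataclass
class ThTCurve:
    """One fluorescence time series.

    times are hours (a uniform 5-minute grid is the expected layout but any
    strictly increasing grid is accepted); fluorescence is in arbitrary
    units. ``is_background`` marks ligand-only (no protein) control wells.
    """

    times: np.ndarray
    fluorescence: np.ndarray
    sample: str = "sample"
    replicate: int = 1
    is_background: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape:
            raise ValueError("times and fluorescence must match in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class KineticsFit:
    """Fitted logistic parameters for one replicate curve."""

    f0: float
    amplitude: float
    t50: float
    rate: float
    rmse: float
    converged: bool
    sample: str = "sample"
    replicate: int = 1

    @property
    def plateau(self) -> float:
        return self.f0 + self.amplitude

    @property
    def lag(self) -> float:
        return lag_time(self)


def logistic(t: np.ndarray, f0: float, amplitude: float, t50: float, k: float):
    return f0 + amplitude / (1.0 + np.exp(-k * (t - t50)))


def preprocess(curves: list[ThTCurve], align_tol_h: float = 2.5 / 60.0) -> list[ThTCurve]:
    """Subtract the per-sample background replicate mean pointwise.

    Background curves (``is_background=True``) are averaged per sample and
    subtracted from each matching signal replicate; samples without a
    background are passed through with a warning. Time grids must agree
    within ``align_tol_h`` (default 2.5 min).
    """
    backgrounds: dict[str, list[ThTCurve]] = {}
    for c in curves:
        if c.is_background:
            backgrounds.setdefault(c.sample, []).append(c)
    out = []
    for c in curves:
        if c.is_background:
            continue
        bgs = backgrounds.get(c.sample)
        if not bgs:
            warnings.warn(f"no background curves for sample {c.sample!r}; "
                          "skipping subtraction", stacklevel=2)
            out.append(c)
            continue
        for bg in bgs:
            if len(bg.times) != len(c.times) or \
                    np.max(np.abs(bg.times - c.times)) > align_tol_h:
                raise ValueError(f"background grid for {c.sample!r} cannot be "
                                 f"aligned within {align_tol_h * 60:.1f} min")
        bg_mean = np.mean([bg.fluorescence for bg in bgs], axis=0)
        out.append(ThTCurve(c.times, c.fluorescence - bg_mean,
                            c.sample, c.replicate, False, dict(c.metadata)))
    return out


def fit_sigmoid(curve: ThTCurve) -> KineticsFit:
    """Least-squares logistic fit of one preprocessed curve.

    Initial values come from data quantiles: baseline = 5th percentile,
    plateau = 95th, t50 = time of half-rise, rate from the maximum finite-
    difference slope. Non-convergence (or a degenerate flat curve) is
    reported via ``converged=False``, never an exception.
    """
    t = curve.times
    f = curve.fluorescence
    if len(t) < 10:
        raise ValueError("need at least 10 points to fit")
    f0_init = float(np.percentile(f, 5))
    plateau_init = float(np.percentile(f, 95))
    amp_init = plateau_init - f0_init
    span = float(f.max() - f.min())
    if span <= 0 or amp_init <= 0:
        return KineticsFit(float(f.mean()), 0.0, float(t.mean()), 0.0,
                           float(np.std(f)), False, curve.sample, curve.replicate)
    half = f0_init + amp_init / 2.0
    above = np.nonzero(f >= half)[0]
    t50_init = float(t[above[0]]) if len(above) else float(t.mean())
    slopes = np.diff(f) / np.diff(t)
    max_slope = float(np.max(slopes)) if len(slopes) else 0.0
    # logistic max slope = A k / 4
    k_init = max(4.0 * max_slope / amp_init, 1e-3) if max_slope > 0 else 0.1
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                logistic, t, f, p0=[f0_init, amp_init, t50_init, k_init],
                maxfev=20000)
        f0, amp, t50, k = (float(v) for v in popt)
        resid = f - logistic(t, *popt)
        rmse = float(np.sqrt(np.mean(resid**2)))
        converged = bool(amp > 0 and k > 0 and np.isfinite(rmse)
                         and rmse < 0.5 * span
                         and t.min() - (t.max() - t.min()) <= t50 <= t.max() + (t.max() - t.min()))
        return KineticsFit(f0, amp, t50, k, rmse, converged,
                           curve.sample, curve.replicate)
    except (RuntimeError, ValueError):
        return KineticsFit(f0_init, amp_init, t50_init, k_init,
                           float("nan"), False, curve.sample, curve.replicate)


def lag_time(fit: KineticsFit) -> float:
    """Tangent-intercept lag: t50 − 2/k (hours)."""
    if fit.rate <= 0:
        raise ValueError("lag time undefined for non-positive rate")
    return fit.t50 - 2.0 / fit.rate


@dataclass
class LagComparison:
    """One-way F-test comparison of per-sample lag times."""

    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    f_statistic: float
    p_value: float
    alpha: float
    excluded: list[str]

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def verdict(self) -> str:
        return ("significant difference between lag phases"
                if self.significant else "no significant difference")


def compare_lags(groups: dict[str, list[float]], alpha: float = 0.05) -> LagComparison:
    """Group means ± sd and a one-way fixed-effects F-test on lag times.

    Groups with fewer than 2 replicates are excluded with a warning. At
    least two usable groups are required.
    """
    usable: dict[str, list[float]] = {}
    excluded = []
    for name, lags in groups.items():
        if len(lags) < 2:
            warnings.warn(f"group {name!r} has <2 replicates; excluded",
                          stacklevel=2)
            excluded.append(name)
        else:
            usable[name] = list(lags)
    if len(usable) < 2:
        raise ValueError("need at least two groups with >=2 replicates")
    names = sorted(usable)
    arrays = [np.asarray(usable[n], dtype=float) for n in names]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = stats.f_oneway(*arrays)
    if not np.isfinite(p):  # zero within-group variance, identical groups
        means = [a.mean() for a in arrays]
        p = 0.0 if np.ptp(means) > 0 else 1.0
        f_stat = np.inf if p == 0.0 else 0.0
    return LagComparison(
        group_means={n: float(a.mean()) for n, a in zip(names, arrays)},
        group_sds={n: float(a.std(ddof=1)) for n, a in zip(names, arrays)},
        group_ns={n: len(a) for n, a in zip(names, arrays)},
        f_statistic=float(f_stat), p_value=float(p), alpha=alpha,
        excluded=excluded)
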