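"""Ensemble-level statistics for AUC and EM measurement tables.

Covers the study-level computations around the single-molecule work:
protein:DNA stoichiometry conversion, two-sample tests computed from
summary statistics only (the raw measurements are typically reported as
n/mean/sd), fractional structure-class scoring of EM particles, outlier
filtering of distance measurements, and full-width-at-half-maximum
summaries of sedimentation-coefficient distributions c(s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "ProportionCount",
    "DistributionCurve",
    "stoich_ratio",
    "ttest_from_summary",
    "two_prop_test",
    "classify_scores",
    "summarize_measurements",
    "fwhm",
]


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class ProportionCount:
    successes: float  # may be half-integer via fractional scoring
    trials: float

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.trials:
            raise ValueError("need 0 <= successes <= trials")
        if self.trials <= 0:
            raise ValueError("trials must be positive")


@dataclass(frozen=True)
class DistributionCurve:
    """A (grid, density) curve, e.g. a c(s) distribution over s-values."""

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "density", np.asarray(self.density, dtype=float))
        if len(self.grid) < 3 or len(self.grid) != len(self.density):
            raise ValueError("curve needs >= 3 (grid, density) pairs of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")


def stoich_ratio(
    dimer_conc: float,
    array_conc: float,
    repeats_per_array: int = 10,
    decimals: int = 1,
) -> float:
    """Protein dimers per DNA repeat unit, rounded half-up.

    ``dimer_conc / (array_conc * repeats_per_array)`` -- e.g. dimers per
    157 bp repeat for an N-mer nucleosome array.  Homogeneous in the two
    concentrations, so any common unit works.
    """
    if dimer_conc < 0 or array_conc <= 0 or repeats_per_array <= 0:
        raise ValueError("concentrations must be positive (dimer_conc >= 0)")
    ratio = dimer_conc / (array_conc * repeats_per_array)
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(ratio)).quantize(q, rounding=ROUND_HALF_UP))


def ttest_from_summary(a: SummaryStats, b: SummaryStats, equal_var: bool = True) -> dict:
    """Two-sided two-sample t-test from (n, mean, sd) summaries.

    Pooled-variance (Student) by default; Welch when ``equal_var`` is
    False.  With both sds zero: p = 1 for equal means, else t is +-inf
    and p = 0.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return {"t": 0.0, "df": float(a.n + b.n - 2), "p": 1.0}
        t = math.inf if a.mean > b.mean else -math.inf
        return {"t": t, "df": float(a.n + b.n - 2), "p": 0.0}
    if equal_var:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    t = (a.mean - b.mean) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}


def two_prop_test(a: ProportionCount, b: ProportionCount) -> dict:
    """Pooled two-sample proportion z-test, two-sided."""
    p_pool = (a.successes + b.successes) / (a.trials + b.trials)
    if p_pool in (0.0, 1.0):
        return {"z": 0.0, "p": 1.0}
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / a.trials + 1 / b.trials))
    z = (a.successes / a.trials - b.successes / b.trials) / se
    return {"z": float(z), "p": float(2.0 * sps.norm.sf(abs(z)))}


def classify_scores(particle_labels: list) -> dict:
    """Fractional structure-class percentages from per-particle labels.

    Each particle carries one or two distinct class labels (e.g. from
    {"globule", "ladder", "column"}); single-label particles score 1 for
    their class, dual-label particles 0.5 per class.  Percentages sum to
    100.
    """
    scores: dict = {}
    for labels in particle_labels:
        labels = set(labels) if not isinstance(labels, str) else {labels}
        if not 1 <= len(labels) <= 2:
            raise ValueError(f"each particle needs 1 or 2 distinct labels, got {labels}")
        w = 1.0 / len(labels)
        for lab in labels:
            scores[lab] = scores.get(lab, 0.0) + w
    total = sum(scores.values())
    return {lab: 100.0 * s / total for lab, s in scores.items()}


def summarize_measurements(values, outlier_cutoff: float | None = None) -> SummaryStats:
    """n, mean and sample sd after dropping values above the cutoff.

    The cutoff removes extreme outliers (e.g. inter-nucleosomal
    distances beyond 15 nm, which reflect locally open fibre rather than
    stacking).  Sample (n-1) standard deviation.
    """
    values = np.asarray(values, dtype=float)
    if outlier_cutoff is not None:
        values = values[values <= outlier_cutoff]
    if len(values) < 2:
        raise ValueError("fewer than 2 values survive the outlier filter")
    return SummaryStats(
        n=int(len(values)),
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)),
    )


def fwhm(curve: DistributionCurve, strict_single_peak: bool = False) -> dict:
    """Peak position/height and full width at half maximum of a curve.

    The peak is the discrete argmax; the width spans the two outermost
    half-maximum crossings bracketing the peak, located by linear
    interpolation (robust to shoulders on multi-modal curves).  With
    ``strict_single_peak`` the innermost crossings are used instead.
    """
    s, y = curve.grid, curve.density
    i_peak = int(np.argmax(y))
    peak, half = float(y[i_peak]), float(y[i_peak]) / 2.0

    # upward crossings left of the peak: y[i] < half <= y[i+1]
    up = np.flatnonzero((y[:i_peak] < half) & (y[1 : i_peak + 1] >= half))
    # downward crossings right of the peak: y[i] >= half > y[i+1]
    down = (
        np.flatnonzero((y[i_peak:-1] >= half) & (y[i_peak + 1 :] < half)) + i_peak
    )
    if len(up) == 0 or len(down) == 0:
        side = "left" if len(up) == 0 else "right"
        if len(up) == 0 and len(down) == 0:
            side = "either"
        raise ValueError(f"no half-maximum crossing on the {side} side of the peak")

    il = int(up[0] if not strict_single_peak else up[-1])
    ir = int(down[-1] if not strict_single_peak else down[0])

    def interp(i: int) -> float:
        # linear interpolation of the half-max crossing in [s[i], s[i+1]]
        return float(s[i] + (half - y[i]) * (s[i + 1] - s[i]) / (y[i + 1] - y[i]))

    return {
        "peak_position": float(s[i_peak]),
        "peak_height": peak,
        "fwhm": interp(ir) - interp(il),
    }
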