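"""Rupture-event detection and Bell-Evans dynamic force spectroscopy.

At high force each nucleosome's last wrapped DNA turn ruptures in a
single irreversible step.  Pooling rupture forces across an array and
across loading rates, the Bell-Evans most-probable-force relation

    F* = (kT/d) * ln[ N_rem * (dF/dt) * d / (k_off * kT) ]

is linear in x = ln(N_rem * dF/dt), where N_rem is the number of intact
nucleosomes just before the event.  A straight-line fit of rupture force
against x therefore yields the distance to the activation barrier
``d = kT/slope`` and the zero-force rupture rate
``k_off = (1/slope) * exp(-intercept/slope)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .traces import Trace

__all__ = [
    "RuptureEvent",
    "DFSResult",
    "detect_ruptures",
    "dfs_transform",
    "histogram_filter",
    "dfs_fit",
]


@dataclass(frozen=True)
class RuptureEvent:
    """One high-force unwrapping step."""

    f_rupt: float  # pN
    step: float  # nm
    order_index: int  # 1-based rupture number within its trace
    n_remaining: int  # intact nucleosomes just before the event
    loading_rate: float  # pN/s at the event
    trace_id: str = "trace0"
    time: float = float("nan")  # s (optional)

    def __post_init__(self) -> None:
        if not self.f_rupt > 0:
            raise ValueError("f_rupt must be positive")
        if not self.step > 0:
            raise ValueError("step must be positive")
        if self.n_remaining < 1:
            raise ValueError("n_remaining must be >= 1")


@dataclass(frozen=True)
class DFSResult:
    """Outcome of the dynamic-force-spectroscopy linear fit."""

    d: float  # nm
    k_off: float  # 1/s
    slope: float  # pN per ln-unit
    intercept: float  # pN
    n_used: int
    n_total_points: int
    fraction_discarded: float
    rms_residual: float = float("nan")  # pN


def detect_ruptures(
    trace: Trace,
    f_min: float = 7.0,
    min_step: float = 15.0,
    window: int = 5,
    n0: int | None = None,
) -> list[RuptureEvent]:
    """Locate extension discontinuities exceeding ``min_step`` nm.

    A candidate at index i is scored by the difference of medians of the
    flanking windows ``ext[i+1 .. i+window]`` and ``ext[i-window+1 .. i]``;
    local maxima of this score above ``min_step`` (at force >= f_min)
    are events.  The loading rate is the slope of a linear fit of force
    against time over +-``window`` points around the event.  Events are
    ordered by time; ``n_remaining = N0 - (order_index - 1)`` with N0
    taken as the event count when not supplied.
    """
    n = len(trace)
    if n < 2 * window + 2:
        return []
    ext = trace.extension
    score = np.full(n, -np.inf)
    for i in range(window, n - window - 1):
        score[i] = np.median(ext[i + 1 : i + 1 + window]) - np.median(
            ext[i - window + 1 : i + 1]
        )
    candidates = [
        i
        for i in range(window, n - window - 1)
        if score[i] > min_step
        and trace.force[i] >= f_min
        and score[i] == score[max(0, i - window) : i + window + 1].max()
    ]
    # collapse plateaus of equal score, then pin each event to the
    # steepest single-sample increment (the jump itself)
    located: list[tuple[int, float]] = []
    increments = np.diff(ext)
    for i in candidates:
        lo = max(0, i - window)
        j = lo + int(np.argmax(increments[lo : min(i + window + 1, n - 1)]))
        if not located or j - located[-1][0] > window:
            located.append((j, float(score[i])))

    if n0 is None:
        n0 = len(located)
    events = []
    for order, (i, step) in enumerate(located, start=1):
        # jump occurs between samples i and i+1
        lo, hi = max(0, i - window), min(n, i + window + 1)
        rate = float(np.polyfit(trace.time[lo:hi], trace.force[lo:hi], 1)[0])
        events.append(
            RuptureEvent(
                f_rupt=float(0.5 * (trace.force[i] + trace.force[min(i + 1, n - 1)])),
                step=step,
                order_index=order,
                n_remaining=max(1, n0 - (order - 1)),
                loading_rate=rate,
                trace_id=trace.bead_id,
                time=float(trace.time[i]),
            )
        )
    return events


def dfs_transform(
    events: list[RuptureEvent],
    n0: int,
    variant: str = "plus_one",
):
    """Map events to (x, F_rupt) points with x = ln(N_rem * dF/dt).

    ``variant`` selects the multiplicity term: ``"plus_one"`` uses
    N_rem = N0 - (order-1) (Bell-Evans count of intact attachments);
    ``"plus_inv"`` and ``"minus_inv"`` reproduce the two printed
    typographical variants N0 - order +- 1/order for sensitivity checks.
    Events with non-positive loading rate are excluded; the number
    excluded is returned alongside the points.

    Returns ``(x, f, n_excluded)`` as two float arrays and an int.
    """
    if events and n0 < max(e.order_index for e in events):
        raise ValueError("n0 must be >= the largest order_index")
    xs, fs, n_excl = [], [], 0
    for e in events:
        if e.loading_rate <= 0:
            n_excl += 1
            continue
        k = e.order_index
        if variant == "plus_one":
            mult = n0 - k + 1
        elif variant == "plus_inv":
            mult = n0 - k + 1.0 / k
        elif variant == "minus_inv":
            mult = n0 - k - 1.0 / k
        else:
            raise ValueError(f"unknown transform variant {variant!r}")
        if mult <= 0:
            n_excl += 1
            continue
        xs.append(math.log(mult * e.loading_rate))
        fs.append(e.f_rupt)
    return np.asarray(xs), np.asarray(fs), n_excl


def histogram_filter(
    x: np.ndarray,
    f: np.ndarray,
    bins: tuple[int, int] = (20, 20),
    rel_threshold: float = 0.5,
):
    """Keep points in dense 2D-histogram bins (robustness filter).

    The histogram spans the points' bounding box; points whose bin count
    strictly exceeds ``rel_threshold`` times the peak count are
    retained.  Returns ``(keep_mask, fraction_discarded)``.
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(f, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0 and np.ptp(f) == 0:
        raise ValueError("all points identical: degenerate histogram")
    hist, xe, fe = np.histogram2d(x, f, bins=bins)
    ix = np.clip(np.digitize(x, xe) - 1, 0, bins[0] - 1)
    jf = np.clip(np.digitize(f, fe) - 1, 0, bins[1] - 1)
    keep = hist[ix, jf] > rel_threshold * hist.max()
    return keep, float(1.0 - keep.mean())


def dfs_fit(
    x: np.ndarray,
    f: np.ndarray,
    f_range: tuple[float, float] = (7.0, 30.0),
    kT: float = 4.11,
    fraction_discarded: float = float("nan"),
    n_total_points: int | None = None,
) -> DFSResult:
    """Ordinary least squares of F_rupt on x within ``f_range``.

    ``d = kT / slope`` and ``k_off = (1/slope) * exp(-intercept/slope)``
    follow from the Bell-Evans most-probable-force relation with forces
    in pN, kT in pN nm and rates in 1/s.
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(f, dtype=float)
    in_range = (f > f_range[0]) & (f < f_range[1])
    if in_range.sum() < 5:
        raise ValueError(
            f"need >= 5 points with {f_range[0]} < F < {f_range[1]} pN, "
            f"got {int(in_range.sum())}"
        )
    slope, intercept = np.polyfit(x[in_range], f[in_range], 1)
    if slope <= 0:
        raise ValueError(
            "non-positive slope: unphysical activation-barrier distance"
        )
    resid = f[in_range] - (slope * x[in_range] + intercept)
    return DFSResult(
        d=float(kT / slope),
        k_off=float((1.0 / slope) * math.exp(-intercept / slope)),
        slope=float(slope),
        intercept=float(intercept),
        n_used=int(in_range.sum()),
        n_total_points=int(n_total_points if n_total_points is not None else len(x)),
        fraction_discarded=float(fraction_discarded),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )
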