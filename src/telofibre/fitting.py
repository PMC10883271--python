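"""Least-squares fitting of stretch traces to the fibre model.

Five adjustable parameters (n_total, n_unfold, k_fibre, dG1, dG2) plus a
bead-attachment extension offset are recovered from the equilibrium
stretch branch (default 0.3-10 pN, below the irreversible rupture
regime).  The worm-like-chain response depends only on force, so it is
precomputed once per segment and the model is re-evaluated cheaply
inside the optimiser.  Traces whose residuals stay large, or whose
parameters pin at a bound, are flagged unfittable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .fibre import FibreParams, _extension_given_response
from .traces import Trace
from .wlc import wlc_free_energy_per_bp, wlc_rel_ext

__all__ = ["FitResult", "select_stretch_segment", "fit_trace", "classify_fittable"]

_ADJUSTABLE = ("n_total", "n_unfold", "k_fibre", "dG1", "dG2")


@dataclass
class FitResult:
    """Fitted parameters and diagnostics for one trace."""

    params: FibreParams
    offset: float  # nm, bead-attachment nuisance offset
    rms_residual: float  # nm
    stderr: dict  # per adjustable parameter (and offset)
    n_points_used: int
    fit_ok: bool
    at_bounds: tuple = ()
    n_rupture_steps: int | None = None
    trace_id: str = "trace0"

    def as_record(self) -> dict:
        rec = {"trace_id": self.trace_id, "fit_ok": self.fit_ok,
               "rms_residual_nm": self.rms_residual,
               "n_points_used": self.n_points_used,
               "offset_nm": self.offset}
        rec.update({k: getattr(self.params, k) for k in _ADJUSTABLE})
        rec["n_fold"] = self.params.n_fold
        rec.update({f"se_{k}": v for k, v in self.stderr.items()})
        if self.n_rupture_steps is not None:
            rec["n_rupture_steps"] = self.n_rupture_steps
        return rec


def select_stretch_segment(trace: Trace, f_lo: float = 0.3, f_hi: float = 10.0) -> Trace:
    """First contiguous monotone-increasing force segment, clipped to [f_lo, f_hi].

    For a stretch-relief protocol this isolates the ascending branch up
    to the start of the rupture regime.
    """
    df = np.diff(trace.force)
    inc = df > -1e-12
    if not inc.any():
        raise ValueError("no monotonically increasing force segment found")
    # first maximal run of non-decreasing force
    start = int(np.argmax(inc))
    stop = start
    while stop < len(inc) and inc[stop]:
        stop += 1
    seg = trace.slice(start, stop + 1)
    mask = (seg.force >= f_lo) & (seg.force <= f_hi)
    if not mask.any():
        raise ValueError(f"no points in the force window [{f_lo}, {f_hi}] pN")
    lo, hi = np.flatnonzero(mask)[[0, -1]]
    return seg.slice(int(lo), int(hi) + 1)


def _bounds(fixed: FibreParams):
    n_max = fixed.dna_total / fixed.nrl
    lo = np.array([0.0, 0.0, 1e-3, 0.0, 0.0, -300.0])
    hi = np.array([n_max, n_max, 3.0, 40.0, 40.0, 300.0])
    return lo, hi


def _theta_to_params(theta: np.ndarray, fixed: FibreParams) -> tuple[FibreParams, float]:
    n_total, n_unfold, k_fibre, dg1, dg2, offset = theta
    n_unfold = min(n_unfold, n_total)
    return (
        replace(fixed, n_total=n_total, n_unfold=n_unfold,
                k_fibre=k_fibre, dG1=dg1, dG2=dg2),
        offset,
    )


def _initial_guess(seg: Trace, fixed: FibreParams) -> np.ndarray:
    """Heuristic start: nucleosome count from the contour deficit at the
    top of the window, where most nucleosomes retain ~wrap_u2 bp."""
    f_hi = np.quantile(seg.force, 0.95)
    top = seg.force >= f_hi
    zeta = wlc_rel_ext(float(np.median(seg.force[top])), fixed.wlc)
    bare = zeta * fixed.wlc.rise_per_bp * fixed.dna_total
    deficit_bp = max(bare - float(np.median(seg.extension[top])), 0.0) / (
        zeta * fixed.wlc.rise_per_bp
    )
    n_max = fixed.dna_total / fixed.nrl
    n0 = float(np.clip(deficit_bp / fixed.wrap_u2, 0.0, n_max))
    return np.array([n0, 0.1 * n0, 0.5, 20.0, 4.0, 0.0])


def fit_trace(
    trace: Trace,
    fixed: FibreParams | None = None,
    init: np.ndarray | None = None,
    f_window: tuple[float, float] = (0.3, 10.0),
    rms_threshold: float = 25.0,
    n_restarts: int = 4,
    n_rupture_steps: int | None = None,
) -> FitResult:
    """Fit the five adjustable fibre parameters to one stretch trace.

    Uniformly weighted least squares of extension against the model over
    the selected stretch segment; NRL and the other structural constants
    stay fixed.  Standard errors come from the Jacobian at the optimum.
    Deterministic for identical inputs and initialisation: restart
    jitter uses a fixed internal seed.
    """
    fixed = (fixed or FibreParams()).validate()
    seg = select_stretch_segment(trace, *f_window)
    if len(seg) < 30 or np.ptp(seg.force) < 5.0:
        raise ValueError(
            f"segment too small for a fit: {len(seg)} points spanning "
            f"{np.ptp(seg.force):.2f} pN (need >= 30 points over >= 5 pN)"
        )
    zeta = wlc_rel_ext(seg.force, fixed.wlc)
    g_over_kT = wlc_free_energy_per_bp(seg.force, fixed.wlc) / fixed.wlc.kT

    def residuals(theta):
        params, offset = _theta_to_params(theta, fixed)
        model = _extension_given_response(zeta, g_over_kT, seg.force, params)
        return model + offset - seg.extension

    lo, hi = _bounds(fixed)
    theta0 = np.clip(init if init is not None else _initial_guess(seg, fixed), lo, hi)
    rng = np.random.default_rng(12345)
    best = None
    for attempt in range(n_restarts + 1):
        start = theta0 if attempt == 0 else np.clip(
            theta0 + rng.normal(scale=0.15 * (hi - lo)), lo, hi
        )
        try:
            sol = least_squares(residuals, start, bounds=(lo, hi), method="trf",
                                x_scale=np.array([5.0, 5.0, 0.5, 5.0, 5.0, 20.0]))
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        rms = np.sqrt(2 * best.cost / len(seg))
        if rms <= rms_threshold:
            break
    if best is None:
        raise RuntimeError("optimiser failed on every start")

    params, offset = _theta_to_params(best.x, fixed)
    rms = float(np.sqrt(np.mean(best.fun**2)))
    stderr = _jacobian_stderr(best, len(seg))
    at_bounds = tuple(
        name
        for name, v, l, h in zip(_ADJUSTABLE + ("offset",), best.x, lo, hi)
        if name != "offset" and (v - l < 1e-6 * (h - l) or h - v < 1e-6 * (h - l))
    )
    result = FitResult(
        params=params,
        offset=float(offset),
        rms_residual=rms,
        stderr=stderr,
        n_points_used=len(seg),
        fit_ok=True,
        at_bounds=at_bounds,
        n_rupture_steps=n_rupture_steps,
        trace_id=trace.bead_id,
    )
    result.fit_ok = classify_fittable(result, rms_threshold)
    return result


def _jacobian_stderr(sol, n_points: int) -> dict:
    names = _ADJUSTABLE + ("offset",)
    dof = max(n_points - len(sol.x), 1)
    s2 = 2 * sol.cost / dof
    try:
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(sol.x), np.nan)
    return dict(zip(names, (float(v) for v in se)))


def classify_fittable(result: FitResult, rms_threshold: float = 25.0) -> bool:
    """A fit is trusted when residuals stay below one rupture-step scale
    and no parameter sits pinned at a bound."""
    return result.rms_residual <= rms_threshold and not result.at_bounds
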