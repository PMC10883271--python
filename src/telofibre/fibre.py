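"""Equilibrium statistical mechanics of nucleosome-array stretching.

A nucleosome array under force passes through discrete per-nucleosome
states: stacked in the folded fibre (S), unstacked with partially
unwrapped DNA (U1, 90 bp still wrapped), and unwrapped down to a single
DNA turn (U2, 77 bp wrapped).  A stacked nucleosome sequesters its full
repeat length (157 bp, linker buried in the columnar fibre).  Each state
is Boltzmann-weighted by its internal free energy (0, dG1, dG1+dG2, in
kT) minus the stretching work gained by the DNA it releases, and the
fibre extension is the released-DNA worm-like chain plus a Hookean term
for the residual folded stack.

Two nucleosome pools are distinguished: ``n_unfold`` nucleosomes never
participate in fibre folding (no S state); the remaining
``N_fold = n_total - n_unfold`` do.  Populations are ensemble averages,
so nucleosome counts are treated as continuous quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .wlc import WLCParams, wlc_free_energy_per_bp, wlc_rel_ext

__all__ = [
    "FibreParams",
    "StateOccupancy",
    "state_weights",
    "fibre_extension",
    "model_curve",
    "rupture_step_size",
]


@dataclass(frozen=True)
class FibreParams:
    """Fixed constants and adjustable parameters of the fibre model.

    Fixed: ``nrl`` (nucleosome repeat length, bp), ``dna_total``
    (template length, bp), ``wrap_u1``/``wrap_u2`` (bp wrapped in the
    U1/U2 states), ``z_node`` (rest extension per stacked nucleosome,
    nm) and the WLC constants.  A stacked nucleosome sequesters the full
    ``nrl``.

    Adjustable (recovered by trace fitting): ``n_total``, ``n_unfold``,
    ``k_fibre`` (whole-fibre folded-state stiffness, pN/nm), ``dG1`` and
    ``dG2`` (kT units).
    """

    nrl: float = 157.0
    dna_total: float = 3242.0
    wrap_u1: float = 90.0
    wrap_u2: float = 77.0
    z_node: float = 1.5
    wlc: WLCParams = field(default_factory=WLCParams)
    n_total: float = 20.0
    n_unfold: float = 2.0
    k_fibre: float = 0.4
    dG1: float = 20.0
    dG2: float = 4.0

    @property
    def wrap_stacked(self) -> float:
        """DNA sequestered per stacked nucleosome (= NRL)."""
        return self.nrl

    @property
    def n_fold(self) -> float:
        """Number of nucleosomes in the stacked folded fibre."""
        return self.n_total - self.n_unfold

    def validate(self) -> "FibreParams":
        if not 0.0 <= self.n_unfold <= self.n_total:
            raise ValueError(
                f"need 0 <= n_unfold <= n_total, got {self.n_unfold}, {self.n_total}"
            )
        if self.n_total * self.nrl > self.dna_total + 1e-9:
            raise ValueError("n_total * nrl exceeds the DNA template length")
        if not self.wrap_u2 <= self.wrap_u1 <= self.nrl:
            raise ValueError("need wrap_u2 <= wrap_u1 <= nrl")
        if not self.k_fibre > 0:
            raise ValueError("k_fibre must be positive")
        if not (math.isfinite(self.dG1) and math.isfinite(self.dG2)):
            raise ValueError("dG1 and dG2 must be finite")
        if self.z_node < 0:
            raise ValueError("z_node must be non-negative")
        return self

    def adjustable(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_unfold": self.n_unfold,
            "k_fibre": self.k_fibre,
            "dG1": self.dG1,
            "dG2": self.dG2,
        }

    def with_adjustable(self, **kwargs) -> "FibreParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StateOccupancy:
    """Per-nucleosome state probabilities at a given force."""

    p_stacked: np.ndarray
    p_u1: np.ndarray
    p_u2: np.ndarray


def _occupancies(g_over_kT: np.ndarray, params: FibreParams, pool: str):
    """Normalised Boltzmann weights of the S/U1/U2 states.

    ``g_over_kT`` is the per-basepair stretching free energy in kT.  The
    log-weight of state s is ``-G_s + b_s * g/kT`` with released contour
    b_S = 0, b_U1 = nrl - wrap_u1, b_U2 = nrl - wrap_u2.  For the
    unfolded pool the S state is excluded and U1 is the energy
    reference.
    """
    b_u1 = params.nrl - params.wrap_u1
    b_u2 = params.nrl - params.wrap_u2
    if pool == "folded":
        logw = [
            np.zeros_like(g_over_kT),
            -params.dG1 + b_u1 * g_over_kT,
            -params.dG1 - params.dG2 + b_u2 * g_over_kT,
        ]
    elif pool == "unfolded":
        logw = [
            np.full_like(g_over_kT, -np.inf),
            b_u1 * g_over_kT,
            -params.dG2 + b_u2 * g_over_kT,
        ]
    else:
        raise ValueError(f"pool must be 'folded' or 'unfolded', got {pool!r}")
    logw = np.stack(logw)
    logw -= logw.max(axis=0, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=0, keepdims=True)
    return w[0], w[1], w[2]


def state_weights(force, params: FibreParams, pool: str = "folded") -> StateOccupancy:
    """State occupancies of one nucleosome pool at ``force`` (pN)."""
    params.validate()
    force = np.asarray(force, dtype=float)
    g = wlc_free_energy_per_bp(force, params.wlc) / params.wlc.kT
    p_s, p_u1, p_u2 = _occupancies(np.atleast_1d(g), params, pool)
    if force.ndim == 0:
        return StateOccupancy(float(p_s[0]), float(p_u1[0]), float(p_u2[0]))
    return StateOccupancy(p_s, p_u1, p_u2)


def _extension_given_response(zeta, g_over_kT, force, params: FibreParams):
    """Fibre extension from precomputed WLC response arrays.

    Separating the WLC response (which depends only on force) from the
    adjustable parameters makes repeated evaluation during least-squares
    fitting cheap.
    """
    n_fold = params.n_fold
    ps_f, pu1_f, pu2_f = _occupancies(g_over_kT, params, "folded")
    _, pu1_u, pu2_u = _occupancies(g_over_kT, params, "unfolded")

    w_folded = ps_f * params.nrl + pu1_f * params.wrap_u1 + pu2_f * params.wrap_u2
    w_unfolded = pu1_u * params.wrap_u1 + pu2_u * params.wrap_u2
    free_bp = params.dna_total - n_fold * w_folded - params.n_unfold * w_unfolded

    ext = zeta * params.wlc.rise_per_bp * free_bp
    if n_fold > 0:
        # N_fold identical per-nucleosome springs in series: whole-fibre
        # stiffness k_fibre, population-scaled by the stacked fraction
        ext = ext + ps_f * (n_fold * params.z_node + force / params.k_fibre)
    return ext


def fibre_extension(force, params: FibreParams):
    """Expected fibre extension (nm) at ``force`` (pN).

    Sum of the released-DNA WLC term and the folded-stack Hookean term
    ``N_fold * p_stacked * (z_node + F / (k_fibre * N_fold))``; reduces
    to bare-DNA WLC for ``n_total = 0`` and is non-decreasing in force.
    """
    params.validate()
    force = np.asarray(force, dtype=float)
    f1 = np.atleast_1d(force)
    zeta = wlc_rel_ext(f1, params.wlc)
    g = wlc_free_energy_per_bp(f1, params.wlc) / params.wlc.kT
    ext = _extension_given_response(zeta, g, f1, params)
    return float(ext[0]) if force.ndim == 0 else ext


def model_curve(forces, params: FibreParams) -> np.ndarray:
    """Vectorised ``fibre_extension`` over an ascending force grid."""
    forces = np.asarray(forces, dtype=float)
    if forces.size == 0:
        return np.empty(0)
    if np.any(np.diff(forces) < 0):
        raise ValueError("forces must be sorted ascending")
    return fibre_extension(forces, params)


def rupture_step_size(force, params: FibreParams):
    """Extension gained (nm) when one nucleosome's last turn ruptures.

    The rupture releases ``wrap_u2`` basepairs which then stretch as
    bare DNA: ``zeta(F) * rise * wrap_u2``.
    """
    out = np.asarray(
        wlc_rel_ext(force, params.wlc) * params.wlc.rise_per_bp * params.wrap_u2
    )
    return out if out.ndim else float(out)
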