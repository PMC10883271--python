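"""Canned parameter-recovery experiments on synthetic ensembles.

These drive the whole pipeline end to end -- generate with known ground
truth, analyse blind, compare -- and are used both by the test suite and
by reproduction scripts.
"""

from __future__ import annotations

import numpy as np

from .fitting import fit_trace
from .rupture import dfs_fit, dfs_transform, histogram_filter
from .simulate import (
    NoiseModel,
    Protocol,
    RuptureKinetics,
    SimConfig,
    child_seeds,
    simulate_equilibrium_trace,
    simulate_ruptures,
)

__all__ = ["dfs_parameter_recovery", "equilibrium_parameter_recovery"]


def dfs_parameter_recovery(
    kinetics: RuptureKinetics,
    master_seed: int,
    n_replicates: int = 10,
    n_fibres: int = 50,
    n0: int = 20,
    ramp_rates: tuple = (2.0, 5.0, 10.0),
    f_range: tuple = (7.0, 30.0),
    bins: tuple = (20, 20),
) -> dict:
    """Recover (k_off, d) from simulated rupture ensembles.

    Each replicate simulates ``n_fibres`` rupture cascades of ``n0``
    nucleosomes on constant force ramps drawn from ``ramp_rates``, pools
    the events, applies the Bell-Evans transform, the 2D-histogram
    robustness filter and the force-windowed linear fit.  Returns the
    per-replicate estimates and their medians.
    """
    replicate_seeds = child_seeds(master_seed, n_replicates)
    d_hat, k_hat, fracs, n_events = [], [], [], 0
    for rep_seed in replicate_seeds:
        rng = np.random.default_rng(rep_seed)
        events = []
        for fibre_seed in child_seeds(rep_seed, n_fibres):
            rate = float(rng.choice(ramp_rates))
            cfg = SimConfig(
                kinetics=kinetics,
                protocol=Protocol(mode="force_ramp", ramp_rate=rate),
                seed=fibre_seed,
            )
            events.extend(simulate_ruptures(cfg, n0=n0))
        x, f, _ = dfs_transform(events, n0=n0)
        keep, frac = histogram_filter(x, f, bins=bins)
        res = dfs_fit(x[keep], f[keep], f_range=f_range,
                      fraction_discarded=frac, n_total_points=len(x))
        d_hat.append(res.d)
        k_hat.append(res.k_off)
        fracs.append(frac)
        n_events += len(events)
    return {
        "d": float(np.median(d_hat)),
        "k_off": float(np.median(k_hat)),
        "d_replicates": d_hat,
        "k_off_replicates": k_hat,
        "fraction_discarded": float(np.median(fracs)),
        "n_events": n_events,
    }


def equilibrium_parameter_recovery(
    master_seed: int,
    n_traces: int = 50,
    tracking_sd: float = 3.0,
    truth: SimConfig | None = None,
) -> dict:
    """Fit noisy synthetic equilibrium traces; report per-parameter medians."""
    base = truth or SimConfig()
    names = ("n_total", "n_unfold", "k_fibre", "dG1", "dG2")
    estimates: dict = {k: [] for k in names}
    n_ok = 0
    for seed in child_seeds(master_seed, n_traces):
        cfg = SimConfig(fibre=base.fibre, seed=seed,
                        noise=NoiseModel(tracking_sd=tracking_sd))
        res = fit_trace(simulate_equilibrium_trace(cfg))
        n_ok += res.fit_ok
        for k in names:
            estimates[k].append(getattr(res.params, k))
    out = {
        k: {
            "truth": getattr(base.fibre, k),
            "median": float(np.median(v)),
            "iqr": float(np.subtract(*np.percentile(v, [75, 25]))),
        }
        for k, v in estimates.items()
    }
    out["n_fittable"] = n_ok
    out["n_traces"] = n_traces
    return out
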