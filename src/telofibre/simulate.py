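"""Seeded synthetic magnetic-tweezers data with known ground truth.

The generator emulates multiplexed magnetic-tweezers stretch-relief
recordings of 20-nucleosome arrays on a 157 bp repeat: a triangular
8-0-8 mm magnet trajectory mapped exponentially to force (peak 56 pN),
the equilibrium fibre-model extension with bead-tracking and optional
thermal noise, and irreversible high-force rupture steps with
Bell-Evans kinetics.

Rupture sampling
----------------
The default sampler (``mode="bell_evans"``) draws each event's rupture
force from the Bell-Evans first-passage distribution at *effective*
loading rate ``n_rem * dF/dt`` -- the exact generative dual of the
pooled dynamic-force-spectroscopy transform ``x = ln(n_rem * dF/dt)``,
so that the downstream linear fit is asymptotically unbiased for
(k_off, d).  A literal sequential-cascade sampler (``mode="cascade"``,
total hazard ``n_rem * k_off * exp(F d / kT)``) is available for
sensitivity studies; its within-trace force ordering is *not*
linearised by the pooled transform (see docs/methods.md).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .fibre import FibreParams, fibre_extension, rupture_step_size
from .rupture import RuptureEvent
from .traces import Trace
from .wlc import wlc_rel_ext

__all__ = [
    "RuptureKinetics",
    "Protocol",
    "NoiseModel",
    "SimConfig",
    "SimOutput",
    "force_protocol",
    "simulate_equilibrium_trace",
    "simulate_ruptures",
    "simulate_trace",
    "generate_ensemble",
]


@dataclass(frozen=True)
class RuptureKinetics:
    """Bell-Evans kinetics of the last-turn rupture."""

    k_off: float = 8.9e-3  # 1/s, zero-force rupture rate
    d: float = 1.1  # nm, distance to the activation barrier


@dataclass(frozen=True)
class Protocol:
    """Force protocol of one pull.

    ``magnet_ramp``: triangular 8-0-8 mm magnet trajectory over
    ``duration`` seconds with exponential magnet-to-force mapping
    ``F(m) = f_max * exp(-m / decay_length)`` (peak ``f_max`` at
    mid-trajectory).  ``force_ramp``: a constant-rate ramp
    ``F = ramp_rate * t`` up to ``f_max``.
    """

    mode: str = "magnet_ramp"
    magnet_span: float = 8.0  # mm
    duration: float = 100.0  # s
    f_max: float = 56.0  # pN
    decay_length: float = 1.4  # mm
    ramp_rate: float = 5.0  # pN/s (force_ramp mode)


@dataclass(frozen=True)
class NoiseModel:
    tracking_sd: float = 2.0  # nm, camera/tracking noise
    thermal: bool = False  # equipartition noise from local stiffness
    plateau_shift: float = 0.0  # pN, anomalous shift (unfittable traces)


@dataclass(frozen=True)
class SimConfig:
    """Ground truth, protocol, noise model and seed of one simulation."""

    fibre: FibreParams = field(default_factory=FibreParams)
    kinetics: RuptureKinetics = field(default_factory=RuptureKinetics)
    protocol: Protocol = field(default_factory=Protocol)
    noise: NoiseModel = field(default_factory=NoiseModel)
    sample_rate: float = 60.0  # Hz
    seed: int = 0
    rupture_mode: str = "bell_evans"  # or "cascade"


@dataclass
class SimOutput:
    trace: Trace
    ground_truth_events: list[RuptureEvent]
    truth: SimConfig


def _magnet_position(t: np.ndarray, proto: Protocol) -> np.ndarray:
    half = proto.duration / 2.0
    return proto.magnet_span * np.abs(t - half) / half


def force_protocol(t, cfg: SimConfig):
    """Force (pN) at time ``t`` under the configured protocol."""
    proto = cfg.protocol
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > proto.duration + 1e-12):
        raise ValueError("t outside [0, duration]")
    if proto.mode == "magnet_ramp":
        out = proto.f_max * np.exp(-_magnet_position(t, proto) / proto.decay_length)
    elif proto.mode == "force_ramp":
        out = np.minimum(proto.ramp_rate * t, proto.f_max)
    else:
        raise ValueError(f"unknown protocol mode {proto.mode!r}")
    return out if out.ndim else float(out)


def _time_grid(cfg: SimConfig) -> np.ndarray:
    n = int(round(cfg.protocol.duration * cfg.sample_rate)) + 1
    return np.linspace(0.0, cfg.protocol.duration, n)


def _equilibrium_extension(force: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.noise.plateau_shift:
        force = np.maximum(force - cfg.noise.plateau_shift, 0.0)
    return fibre_extension(force, cfg.fibre)


def simulate_equilibrium_trace(cfg: SimConfig, rng: np.random.Generator | None = None) -> Trace:
    """Noisy equilibrium trace (no ruptures) under the protocol."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    t = _time_grid(cfg)
    force = np.asarray(force_protocol(t, cfg))
    ext = _equilibrium_extension(force, cfg)
    noise = np.zeros_like(ext)
    if cfg.noise.tracking_sd > 0:
        noise += rng.normal(0.0, cfg.noise.tracking_sd, size=ext.shape)
    if cfg.noise.thermal:
        # equipartition at the local system stiffness k_eff = dF/dz
        dz = np.gradient(ext)
        dF = np.gradient(force)
        with np.errstate(divide="ignore", invalid="ignore"):
            k_eff = np.abs(dF) / np.maximum(np.abs(dz), 1e-12)
        k_eff = np.clip(k_eff, 1e-3, None)
        noise += rng.normal(0.0, 1.0, size=ext.shape) * np.sqrt(cfg.fibre.wlc.kT / k_eff)
    magnet = (
        _magnet_position(t, cfg.protocol) if cfg.protocol.mode == "magnet_ramp" else None
    )
    return Trace(time=t, force=force, extension=ext + noise, magnet_pos=magnet,
                 bead_id=f"sim{cfg.seed}")


def _ascending_grid(cfg: SimConfig, n_grid: int = 4000):
    """Dense (t, F, dF/dt) grid over the rising branch of the protocol."""
    proto = cfg.protocol
    if proto.mode == "force_ramp":
        t_end = proto.f_max / proto.ramp_rate
    else:
        t_end = proto.duration / 2.0
    t = np.linspace(0.0, min(t_end, proto.duration), n_grid)
    f = np.asarray(force_protocol(t, cfg))
    dfdt = np.gradient(f, t)
    return t, f, dfdt


def simulate_ruptures(cfg: SimConfig, n0: int = 20) -> list[RuptureEvent]:
    """Sample the rupture cascade of one fibre under the force protocol.

    Returns events ordered by rupture number; events whose rupture force
    would exceed the protocol maximum are censored (not emitted).  With
    ``k_off = 0`` the list is empty.
    """
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    kin = cfg.kinetics
    if kin.k_off == 0:
        return []
    kT = cfg.fibre.wlc.kT
    rng = np.random.default_rng(cfg.seed)
    events: list[RuptureEvent] = []

    if cfg.rupture_mode == "bell_evans" and cfg.protocol.mode == "force_ramp":
        # closed-form inversion of the Bell-Evans survival at effective
        # loading rate n_rem * r
        r = cfg.protocol.ramp_rate
        for k in range(1, n0 + 1):
            n_rem = n0 - k + 1
            c = kin.k_off * kT / (kin.d * n_rem * r)
            f = (kT / kin.d) * np.log1p(rng.exponential() / c)
            if f > cfg.protocol.f_max:
                continue
            events.append(
                RuptureEvent(
                    f_rupt=float(f),
                    step=float(rupture_step_size(f, cfg.fibre)),
                    order_index=k,
                    n_remaining=n_rem,
                    loading_rate=r,
                    trace_id=f"sim{cfg.seed}",
                    time=float(f / r),
                )
            )
        return events

    t, f, dfdt = _ascending_grid(cfg)
    bell = kin.k_off * np.exp(f * kin.d / kT)

    def draw(cum_hazard: np.ndarray, t_start: float) -> float | None:
        """Invert a cumulative hazard; None when censored at ramp end."""
        base = np.interp(t_start, t, cum_hazard)
        target = base + rng.exponential()
        if target > cum_hazard[-1]:
            return None
        return float(np.interp(target, cum_hazard, t))

    if cfg.rupture_mode == "bell_evans":
        for k in range(1, n0 + 1):
            n_rem = n0 - k + 1
            cum = np.concatenate([[0.0], np.cumsum(
                0.5 * (bell[1:] + bell[:-1]) * np.diff(t))]) / n_rem
            tk = draw(cum, 0.0)
            if tk is None:
                continue
            fk = float(np.interp(tk, t, f))
            events.append(
                RuptureEvent(
                    f_rupt=fk,
                    step=float(rupture_step_size(fk, cfg.fibre)),
                    order_index=k,
                    n_remaining=n_rem,
                    loading_rate=float(np.interp(tk, t, dfdt)),
                    trace_id=f"sim{cfg.seed}",
                    time=tk,
                )
            )
    elif cfg.rupture_mode == "cascade":
        cum1 = np.concatenate([[0.0], np.cumsum(
            0.5 * (bell[1:] + bell[:-1]) * np.diff(t))])
        t_now = 0.0
        for k in range(1, n0 + 1):
            n_rem = n0 - k + 1
            tk = draw(cum1 * n_rem, t_now)
            if tk is None:
                break
            fk = float(np.interp(tk, t, f))
            events.append(
                RuptureEvent(
                    f_rupt=fk,
                    step=float(rupture_step_size(fk, cfg.fibre)),
                    order_index=k,
                    n_remaining=n_rem,
                    loading_rate=float(np.interp(tk, t, dfdt)),
                    trace_id=f"sim{cfg.seed}",
                    time=tk,
                )
            )
            t_now = tk
    else:
        raise ValueError(f"unknown rupture_mode {cfg.rupture_mode!r}")
    return events


def simulate_trace(cfg: SimConfig, n0: int | None = None) -> SimOutput:
    """Full stretch-relief trace: equilibrium model + spliced ruptures.

    Each rupture adds ``wrap_u2`` basepairs of bare DNA from its event
    time onward, so steps appear as instantaneous extension jumps on the
    rising branch and the released DNA stays released on the relief
    branch (hysteresis).
    """
    rng = np.random.default_rng(cfg.seed)
    if n0 is None:
        n0 = int(round(cfg.fibre.n_total))
    events = simulate_ruptures(replace(cfg, seed=cfg.seed), n0=n0) if n0 > 0 else []
    t = _time_grid(cfg)
    force = np.asarray(force_protocol(t, cfg))
    ext = _equilibrium_extension(force, cfg)
    if events:
        times = np.sort([e.time for e in events])
        n_ruptured = np.searchsorted(times, t, side="right")
        zeta = wlc_rel_ext(force, cfg.fibre.wlc)
        ext = ext + n_ruptured * cfg.fibre.wrap_u2 * cfg.fibre.wlc.rise_per_bp * zeta
    noise = rng.normal(0.0, cfg.noise.tracking_sd, size=ext.shape) \
        if cfg.noise.tracking_sd > 0 else 0.0
    magnet = (
        _magnet_position(t, cfg.protocol) if cfg.protocol.mode == "magnet_ramp" else None
    )
    trace = Trace(time=t, force=force, extension=ext + noise, magnet_pos=magnet,
                  bead_id=f"sim{cfg.seed}")
    return SimOutput(trace=trace, ground_truth_events=events, truth=cfg)


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-trace seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def generate_ensemble(cfg: SimConfig, n_traces: int, out_dir) -> dict:
    """Write ``n_traces`` full traces plus ground truth to ``out_dir``.

    Produces ``trace_###.tsv`` files, an ``events.csv`` table of all
    ground-truth rupture events, and ``manifest.json`` recording the
    configuration, per-trace seeds and content hashes.
    """
    import pandas as pd

    from .io import write_trace

    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(cfg.seed, n_traces)
    rows, files = [], []
    for i, seed in enumerate(seeds):
        out = simulate_trace(replace(cfg, seed=seed))
        fname = f"trace_{i:03d}.tsv"
        write_trace(out.trace, out_dir / fname, force=True)
        digest = hashlib.sha256((out_dir / fname).read_bytes()).hexdigest()[:16]
        files.append({"file": fname, "seed": seed, "sha256_16": digest})
        for e in out.ground_truth_events:
            rows.append(
                {
                    "trace_id": out.trace.bead_id,
                    "order_index": e.order_index,
                    "n_remaining": e.n_remaining,
                    "f_rupt_pN": e.f_rupt,
                    "step_nm": e.step,
                    "loading_rate_pN_s": e.loading_rate,
                    "time_s": e.time,
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "events.csv", index=False)
    manifest = {
        "package": "telofibre",
        "master_seed": cfg.seed,
        "n_traces": n_traces,
        "truth": _config_dict(cfg),
        "traces": files,
        "events_file": "events.csv",
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["fibre"]["wlc"] = asdict(cfg.fibre.wlc)
    return d
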