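# Methods

## Worm-like-chain elasticity

DNA elasticity uses the Marko–Siggia interpolation
F·Lp/kT = 1/(4(1−ζ)²) − 1/4 + ζ with an additive enthalpic term F/S
(extensible chain), solved for ζ by 64 vectorised bisection steps on
ζ ∈ [0, 1−10⁻⁹] (machine-precision roots, no pole). The seventh-order
Bouchiat polynomial refinement is available as `variant="bouchiat"`.
Defaults: Lp = 50 nm, rise = 0.34 nm/bp, S = 1000 pN, kT = 4.11 pN·nm
(25 °C) — standard literature values for dsDNA in physiological salt;
all four are configurable because fitted free energies shift by a few
percent between common WLC parameterisations.

The stretching free energy per released basepair,
g(F) = rise·∫₀^F ζ dF′, is evaluated in closed form by integration by
parts: ∫ζ dF = ζF − ∫F(ζ)dζ, and the antiderivative of the
(polynomial + pole) force law is elementary. This is exact (well below
the 10⁻⁶ pN·nm tolerance a quadrature would target) and cheap, which
matters because g(F) sits inside every Boltzmann weight evaluated by
the fit. A dense-trapezoid oracle in the test suite pins the agreement
at better than 10⁻⁴ relative.

## Fibre model

Each nucleosome occupies one of three states — stacked (S), unstacked
and partially unwrapped (U1, 90 bp wrapped), single-turn (U2, 77 bp
wrapped) — with internal free energies 0, ΔG₁, ΔG₁+ΔG₂ (kT) and
released-contour weights b_s = NRL − wrap_s. A stacked nucleosome
sequesters its full 157 bp repeat (linker buried in the columnar
fibre); the wrap constants are configurable. Two pools exist:
N_unfold nucleosomes never stack (no S state, U1 is their energy
reference), the other N_fold = N_total − N_unfold do. Nucleosome
counts are ensemble averages and therefore continuous.

Extension is the released-DNA WLC term plus a folded-stack term
N_fold·p_S·(z_node + F/(k_fibre·N_fold)): the folded fibre is modelled
as N_fold identical springs in series realising whole-fibre stiffness
k_fibre, scaled by the stacked fraction p_S. Choices made where the
design was open:

- z_node = 1.5 nm rest extension per stacked nucleosome, so an intact
  20-nucleosome fibre is ~30 nm long at zero force, consistent with
  the dimensions of columnar fibres in EM;
- the DNA template is 3242 bp (20 × 157 bp of array plus handle DNA),
  all of it treated as force-bearing WLC;
- the U1→U2 work term uses the full g(F) rather than a linear F·Δz
  approximation, for thermodynamic consistency across stages;
- octamer/hexamer subpopulations are not distinguished: both share the
  same last unwrapping step, which is the only rupture modelled.

## Trace fitting

The equilibrium fit uses the first contiguous monotone-increasing
force segment clipped to 0.3–10 pN — below the irreversible rupture
regime, so rupture events cannot bias the equilibrium free energies.
Six parameters are optimised (the five adjustable fibre parameters
plus a bead-attachment extension offset) by bounded trust-region least
squares with uniform weights; the WLC response ζ(F), g(F) is
precomputed once per segment, making each model evaluation a handful
of vector operations. Initialisation takes N_total from the contour
deficit at the top of the window (where nucleosomes retain ~77 bp);
up to four deterministic jittered restarts run before accepting a
local optimum. Standard errors come from the Jacobian covariance.
Bounds: counts in [0, dna_total/NRL], ΔG ∈ [0, 40] kT,
k_fibre ∈ (0, 3] pN/nm. A fit is flagged unfittable when its rms
residual exceeds 25 nm (one rupture-step scale) or any parameter pins
at a bound — the behaviour observed for compact, stage-less stretching
profiles, which the generator emulates via a plateau-shift anomaly.

## Rupture sampling and dynamic force spectroscopy

Rupture forces are analysed with the pooled Bell–Evans transform:
x = ln(N_rem·dF/dt) against F_rupt, ordinary least squares on points
with 7 pN < F < 30 pN after a 20×20 2D-histogram filter that keeps
points in bins strictly above 0.5× the peak count (discarding roughly
half to two-thirds of a realistic cloud). d = kT/slope and
k_off = (1/slope)·exp(−intercept/slope). N_rem = N₀ − (order−1);
the transform's multiplicity term is also available in two
typographical variants (±1/N) for sensitivity checks.

The default synthetic sampler draws each event's rupture force from
the Bell–Evans first-passage distribution at *effective* loading rate
N_rem·(dF/dt) — the exact generative dual of the pooled transform, so
the downstream fit is asymptotically unbiased. In time this
corresponds to a per-event hazard k_off·e^{Fd/kT}/N_rem; on constant
ramps it is inverted in closed form, on the magnet protocol by
trapezoid integration of the hazard on a dense grid. A literal
sequential-cascade sampler (total hazard N_rem·k_off·e^{Fd/kT},
time-ordered) is provided as `rupture_mode="cascade"`; note that its
within-trace force ordering *anti*-correlates with ln(N_rem·dF/dt)
(forces rise while N_rem falls), so the pooled transform does not
linearise cascade-ordered data — a structural property of the
transform, not an implementation detail. For the same reason,
recovery experiments pair each event with its generator-recorded
N_rem rather than re-deriving the pairing from detection order.

Known limitation (quantified by the test suite): with the
no-protein kinetics (d = 1.1 nm, k_off = 8.9×10⁻³ s⁻¹), ramps of
{2, 5, 10} pN/s and N₀ = 20, the upper columns of the force cloud
(x ≳ 4) have modal forces at or above the 30 pN fit ceiling; the
straddling columns are censored from above, flattening the slope, so
the recovered d overshoots by ~20–40% and k_off (exponentially
sensitive to the intercept) undershoots by a factor of ~3–8. The
10 nM-protein condition (kT/d ≈ 2 pN) sits inside the window and
recovers cleanly (d within a few %, k_off well within a factor of 2).

## Synthetic data generator

The generator emulates multiplexed magnetic-tweezers stretch–relief
recordings: a triangular 8–0–8 mm magnet trajectory over 100 s mapped
to force by F(m) = 56·exp(−m/1.4 mm) pN (span ~0.19–56 pN; real
magnet calibrations are setup-specific, so the mapping is
configuration, not a claim about any instrument), 60 Hz sampling,
Gaussian tracking noise (default 2 nm), optional equipartition thermal
noise from the local model stiffness, and instantaneous rupture steps
of ζ(F)·rise·77 bp spliced at their event times. Released DNA stays
released on the relief branch, producing hysteresis. A constant-rate
`force_ramp` mode bypasses the magnet map for controlled-loading
experiments. All randomness flows from a single seed through
`numpy.random.SeedSequence` spawning; ensembles are byte-reproducible.

What the generator does *not* emulate: instrument drift, bead
rotation/attachment artefacts, inter-nucleosome cooperativity, force
calibration error, refolding on the relief branch beyond simple
re-equilibration, and TRF2 binding itself (protein effects enter only
through the parameter values chosen for a condition). Passing
recovery tests therefore demonstrate correctness of the estimators
under the stated model, not robustness to every artefact of real
recordings.

## Ensemble statistics

Stoichiometry ratios round half-up to one decimal, matching how such
ratios are conventionally reported. Hypothesis tests are computed from
summary statistics only (pooled-variance Student t by default, Welch
optional; pooled two-proportion z), since published figure legends
report (n, mean, sd) rather than raw measurements — the test suite
pins both against independent reference implementations at 10⁻¹⁰.
Structure-class scoring assigns 0.5 per class to dual-feature
particles so percentages always total 100. Measurement summaries use
the sample (n−1) standard deviation and an optional upper cutoff
(15 nm for inter-nucleosomal distances, removing locally open
fibres). FWHM of a c(s) curve uses the discrete argmax and linear
interpolation of the outermost half-maximum crossings — robust to
shoulders on multi-modal curves; a strict single-peak mode (innermost
crossings) is available.

## Problem sizes

Defaults throughout were chosen as the smallest ensembles that give
stable estimates: 50 traces for equilibrium parameter recovery,
10 replicates × 50 fibres × 20 nucleosomes for rupture-kinetics
recovery, 5000 draws for distributional checks. Each completes in
seconds on one core; all are parameters of the corresponding
functions.
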