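# Methods

## Reaction model

Strand exchange is modelled as a chain of reversible mass-action steps
between a presynaptic filament A and donor duplex B:

    A + B ⇌ C1 ⇌ C2 ⇌ D + E        (three-step)
    A + B ⇌ C  ⇌ D + E             (two-step)

The filament is one kinetic species regardless of ssDNA length — the
standard assumption when fitting ensemble FRET courses — so there is no
per-site occupancy bookkeeping, no filament-length resolution, and no
ATP-state sub-modelling.  Capture (k₁, nM⁻¹s⁻¹) and the reverse of product
release (k₋₃, nM⁻¹s⁻¹) are bimolecular; the release reverse step is taken
as D + E → C2 for thermodynamic consistency, which gives K₃ = k₃/k₋₃ units
of nM and makes K_total = K₁K₂K₃ dimensionless.  Units are nM and seconds
throughout the kinetic core; the binding module works in μM with explicit
conversion at the boundary (`stoichiometric_concentration` returns μM).

Conservation (A + C1 + C2 + D = A₀ and B + C1 + C2 + D = B₀) and the
product symmetry E(t) = D(t) for clean starts are structural: they hold to
solver tolerance and are enforced as tests, not imposed numerically.

### Integration

`scipy.integrate.solve_ivp` with LSODA (stiff-capable), rtol 1e-8 and
atol 1e-10 nM by default.  Negative excursions smaller than ~100×atol are
numerical noise and are clamped to zero before reporting.  During
parameter estimation the tolerances may be relaxed (the simulation studies
use rtol 1e-6) since the residual scale is percentage points.

### Equilibrium oracle

`algebraic_equilibrium` solves the equilibrium reached from pure
substrates in closed form up to one scalar root: C1 = K₁AB, C2 = K₂C1,
D = E = √(K₃C2), with the filament-strand total fixing A by a bracketed
Brent search.  It is used as an independent long-time check of the
integrator, and reduces to the standard quadratic binding isotherm when
only the first step is active.

## Signal model

The fluorescence maps are affine and anchored at the physical extremes:
in pairing, F = F₀ means all substrate free and F = (1−E_max)F₀ fully
complexed; in displacement, F = F₀ is the fully quenched doubly labelled
donor and complete displacement raises emission by 1/(1−E_max).  The
heteroduplex product retains the rhodamine-labelled strand in pairing, so
substrate% tracks free A only.  These formulas are the package's own
calibration model (instruments report E_max per substrate; default
E_max = 0.6, configurable).  The 2AP map is the affine interpolation
between the filament emission (100% substrate) and the fully base-paired
level, default 60.1% of the filament signal.

The SDS-quench (abortive) decomposition uses the mass-balance reading

    C2+product% = 100 − substrate%_after   (DSP)   or   product%_after (DSD)
    C1% = (100 − substrate%_before) − (C2+product%)

C1% as the complexed fraction minus its C2/product part; in DSP mode this
equals the substrate gain across SDS addition.  SDS collapse is modelled
as instantaneous with a flat post-quench signal; the post-SDS readout
delay is a sampling offset parameter (default 150 s), not a constant,
because reported protocols use both 150 s and 300 s.  Small negative C1
(within 2 percentage points) is clamped to zero; larger inconsistencies
raise a warning rather than being silently repaired.

## Estimators

**Rate constants** (`StrandExchangeEstimator`): least squares between the
simulated observable and the percent data, parameters searched in log₁₀
space within [1e-7, 1e-1] (bimolecular) and [1e-6, 1] (unimolecular),
trust-region reflective steps, seeded multistart (bound-box centre plus
log-uniform draws; default 20 starts, studies use 3–5), best-of-starts
kept.  Standard errors come from the Jacobian-based covariance at the
optimum (delta method back to linear space); no bootstrap.  Fits are
deterministic given (data, seed, config).  The fitting target is the
pairing percent series; displacement data are used for validation
prediction.

**Model comparison**: AIC = m·ln(SSR/m) + 2p decides the selection; a
Wald–Wolfowitz runs test on residual signs (α = 0.01, via statsmodels) is
reported as the operational meaning of "systematic deviation" but does not
override AIC.  The three-step fit additionally receives warm starts built
by embedding the fitted two-step optimum (fast C1⇌C2 exchange with K₂ = 1
halves the effective capture constant and doubles the release rate), so
the richer scheme is never handicapped by multistart luck — without this
the comparison can fail in the three-step direction for purely
optimisation reasons.

**Hill binding**: anisotropy = baseline + amplitude·[R]ⁿ/(K_Dⁿ + [R]ⁿ),
total recombinase treated as free ligand (no depletion correction).  At
[R] = K_D the curve passes through baseline + amplitude/2 by construction.
K_D outside the sampled range triggers an extrapolation warning.

**Association**: V_N is the OLS slope over the nucleation window (10 s
for Dmc1, 5 s for Rad51; caller-set), T₁/₂ and shape from the time-sigmoid
fit, V_E the OLS slope over all samples in the closed interval
[T₁/₂ − 2 s, T₁/₂ + 2 s] — 9 points at 0.5 s sampling; the halfwidth is
configurable because the "±2 s (total 5 s)" protocol phrasing is
ambiguous.  On non-sigmoidal input (e.g. a pure linear ramp) V_N is still
returned and T₁/₂/V_E are NaN with a warning.

**Dissociation**: amplitude·exp(−k_off·t) + baseline with k_off ≥ 0,
seeded by a log-linear regression of the baseline-subtracted decay.
Constant or rising series return k_off ≈ 0 with a warning.

## Synthetic data

The generators define the study conditions and attach their ground truth.
Defaults: A₀ = B₀ = 36 nM (fragment concentrations of the standard
condition; doubling to 72 nM is a tested robustness case), observation
0–1000 s sampled at 1 Hz (real-time fluorometer), anisotropy assays
sampled every 0.5 s (association to 120 s, dissociation to 600 s), SDS
quenches at 150/300/600/900 s, and additive homoscedastic Gaussian noise
on the reported signal with sd defaulting to 1% of the percent scale
(instrument noise is not otherwise characterised; photobleaching, drift
and mixing dead time are deliberately not modelled, so passing tests say
nothing about those artefacts in real data).  Noise is injected in
fluorescence space and converted through the affine calibration, so the
percent-space noise is exactly Gaussian with the requested sd; all
randomness flows through one seeded generator and identical configs give
byte-identical output.

The default three-step generating constants are k₁ = 5e-4 nM⁻¹s⁻¹,
k₋₁ = 8e-2 s⁻¹, k₂ = 1.8e-2 s⁻¹, k₋₂ = 8e-3 s⁻¹, k₃ = 3.6e-3 s⁻¹,
k₋₃ = 3.3e-4 nM⁻¹s⁻¹ (K₁ = 6.25e-3 nM⁻¹, K₂ = 2.25, K₃ = 10.9 nM,
K_total = 0.153).  They were chosen once, by constrained design rather
than hand-tuning: candidates were screened to reproduce the qualitative
behaviour of the standard Dmc1 condition — roughly 40% of substrate
converted within 1000 s with the curve near plateau, a small and
near-constant C1 pool, about half of the intermediates reaching product —
while also (i) producing a pairing curve that a two-step mechanism
visibly misfits, as real data do, and (ii) keeping K_total identifiable
at 1% noise (Fisher-information screen), i.e. conditions under which the
fitting procedure is actually well-posed.  The two-step defaults share
the capture step with the release step rates taken from step 3.

## Problem sizes and numerical choices in the test suite

Simulation studies are sized for a single CPU: model selection uses 50
seeded replicates per generating scheme on a 5 s grid with 3 multistarts;
noisy parameter recovery uses 20 replicates on the 1 s grid with 5
multistarts, and K_total recovery is assessed on the replicate-averaged
estimate (replicate averaging is the standard reporting practice for
these constants; the single-replicate sampling error of K_total at 1%
noise is intrinsically ~15–25% because the late reverse flux is weakly
constrained by one pairing course).  Noiseless recovery of K₁–K₃ is
within 5%; equilibrium and closed-form oracles agree to 1e-6 relative;
conservation holds to 1e-6 nM and product symmetry to 1e-9 nM.

## Known limitations

- Percent observables from a single pairing course constrain K_total
  weakly near equilibrium-reversible conditions; confidence intervals from
  the local covariance underestimate this heavy-tailed uncertainty.
- The Hill fit ignores ligand depletion, as in the standard protocol; at
  K_D values near the probe concentration this biases K_D upward.
- No global multi-condition fitting with shared parameters, no Bayesian
  posterior sampling, no spatial/stochastic (Gillespie) simulation.
- The signal model omits photophysics (bleaching, inner-filter effects)
  and instrument gain drift.
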