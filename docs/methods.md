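# Methods

## Model

The pathway model is a deterministic mass-action/Michaelis–Menten hybrid
with sixteen states: seven inactive/active pairs (R, Ras, Raf, MEK, ERK,
NFB, PFB) and the two-tier DUSP induction (transcript `dusp`, protein
`DUSP`).  Each activation flux is net forward-minus-reverse with Michaelis
saturation on the substrate of each direction; three Hill-type gates shape
the regulation:

- `KNFB²/(KNFB² + NFB*²)` — active NFB suppresses Raf activation
  (negative feedback, both ligands);
- `R*²/(K3R² + R*²)` — receptor activity gates NFB activation, so negative
  feedback only engages at appreciable occupancy;
- `ERK*²/(Kdusp + ERK*²)` — ERK\* induces `dusp` transcription
  (slow negative feedback through the protein tier, half-lives 90 min).

Positive feedback (PFB\* activating Raf) is enabled only in NGF mode
(`kPFB = 0.75/60 s⁻¹` vs 0 for EGF); PFB\* activation additionally requires
active receptor.  Phosphatases and GAP are constant abundances folded into
the rate laws, which is why a 19-species reaction scheme closes at 16
dynamical states.  Ligand dose is expressed in units of the receptor
K_d; since the receptor on- and off-rate constants are equal, dose 1 K_d
gives half occupancy at equilibrium.

Two typesetting ambiguities in the source equations were resolved by
requiring internal consistency with the model's own reported equilibrium
levels (0.07/0.11/0.16 activated ERK at mean doses 0.012/0.02/0.04 K_d,
0.24 at 0.315 K_d): the Raf-activation flux saturates in Raf (not Raf\*),
and the MEK deactivation flux saturates in MEK as printed.  The rejected
variants miss those levels by 30–60%.  A switch (`v8_hill_squared`) exposes
the alternative `Kdusp² + ERK*²` induction denominator for sensitivity
analysis; it is off by default and clearly wrong against the same anchors.

**Conserved totals.**  All reported outputs are fraction-activation, so
every pair total defaults to 1.0 (configurable).  The resting state is fully
inactive with `dusp = DUSP = duspbasal`, their fixed point at zero ERK\*;
this makes the basal state an exact unstimulated equilibrium.

## Equilibria and dose–response

Conservation leaves 9 independent unknowns (seven active fractions plus
`dusp`, `DUSP`).  Steady states are found with a hybrid Powell solve
followed by damped-Newton polishing on a complex-step Jacobian; reported
residuals are below 1e-9 (typically 1e-14) in the infinity norm of the full
16-dimensional dynamics vector.  Dose–response curves are traced by
continuation from the basal state (default grid: 60 log-spaced doses,
1e-3–2.5 K_d); a light multi-start probe from a high-activation initial
guess flags any dose with a second distinct root (none is found for either
ligand mode at the default parameters — the curves are single-valued).
Stability is judged from the reduced 9×9 Jacobian spectrum.

## Linearization and transfer function

All Jacobians use complex-step differentiation (step 1e-30), exact to
machine precision for this rational vector field; agreement with central
finite differences is verified in the tests at 1e-5 relative.  The
direct-feedthrough term is identically zero because the output ERK\* is a
state.

The transfer function is extracted in zero-pole-gain form to avoid
ill-conditioned 16×16 determinant expansion: poles are the eigenvalues of A,
transmission zeros the finite generalized eigenvalues of the Rosenbrock
pencil [[A, B], [C, D]] against diag(I, 0), and the gain is fixed by one
resolvent evaluation.  Pole/zero pairs are cancelled when they coincide
within a relative tolerance of 1e-8, or when both lie within 1e-9 rad/s of
the origin (the seven structural integrator modes created by conservation).
Under EGF the PFB mode is unobservable and cancels exactly, leaving orders
(3, 8) — thirteen polynomial constants; under NGF the orders are (4, 9).
The relative degree is 5 in both cases, so the high-frequency magnitude
falls as ω⁻⁵ and the phase asymptote is −450° relative to DC.

The cancellation tolerance matters physically: at low dose (0.01 K_d) the
NFB-loop pole/zero pair approaches to ~1e-6 relative distance.  A looser
tolerance (1e-6) would collapse the orders to (2, 7); 1e-8 — the order of
√ε used by standard minimal-realization routines — preserves the weakly
coupled mode.  A diagnostic error is raised if any retained pair sits within
ten times the tolerance, the ambiguous zone between "cancel" and "keep";
reduction at such a dose should be re-run with an explicit tolerance.

## Bode analysis

Frequency responses are evaluated by direct resolvent solves (not from the
reduced polynomials, whose agreement to 1e-8 relative is itself a test).
The default grid is 100 points/decade over 1e-6–1e2 rad/s.  The two decades
above 1 rad/s exist so the unwrapped phase reaches its high-frequency
asymptote: at 1 rad/s it is still ~12° short, which would corrupt total
phase changes quoted to ±5°.

Phase convention: the unwrapped phase is shifted by a whole number of turns
so that its high-frequency end lies nearest −90° × (relative degree), with
the relative degree estimated from the terminal log–log magnitude slope.
Total phase change is reported as |φ(ω_max) − φ(ω_min)| and is independent
of that anchoring; the anchoring is what makes the low-frequency phase land
at 0° (EGF amplifier regime), 180° (suppressor regime, output counteracts
input) and 360° (NGF, one extra half-turn per extra feedback stage).
Headline peak-gain summaries use the window 1e-5–1e-2 rad/s.

## Periodic forcing

Rectangular trains (amplitude A, width τ, period T) use the closed-form
coefficients a₀/2 = Aτ/T, aₙ = (A/πn)·sin(2πnτ/T),
bₙ = (A/πn)·(1 − cos 2πnτ/T); triangular trains of amplitude A have mean
A/2 and odd cosine harmonics −4A/((2n−1)²π²).  Both are verified against
adaptive-quadrature Fourier integrals to 1e-10.  Defaults: 200 harmonics
(rectangular), 100 odd harmonics (triangular); metrics are read off the
last full period of a five-period reconstruction sampled at 1 s.  Doubling
the harmonic count moves the metrics by <0.5%.  Pulse-frequency convention:
"n pulses per hour" means period T = 3600/n s at fixed width τ = 180 s, so
the three standard protocols have mean doses 0.012, 0.02 and 0.04 K_d at
A = 0.08 K_d.

The baseline F′ is the constant equilibrium at the mean dose a₀/2.  The
reconstruction is strictly the steady periodic state; start-up transients
are not included (drive the nonlinear oracle when those are wanted).
Truncated Fourier reconstructions of discontinuous inputs show Gibbs
undershoot, so low-baseline outputs can dip slightly below zero; this is an
artifact of linearization plus truncation, not of the model.

## Nonlinear oracle

`simulate` integrates the full model with LSODA (rtol 1e-9, atol 1e-12,
analytic complex-step Jacobian); pairwise conservation drifts stay below
1e-8.  Step inputs start the integration at the basal state with the
post-step constant dose (an exact discontinuity).  The linearization
cross-check drives the model with u = mean + a·sin(ωt), waits sixteen
e-folds of the slowest non-structural mode (the switch-on transient decays
at system rates, not the forcing period), fits the fundamental harmonic by
least squares over three cycles, and verifies cycle-to-cycle amplitude
drift below 1e-6 relative (with an absolute floor of 100× the integrator
atol, below which the comparison is integration noise).  At amplitude 1e-3
of the mean dose the linear and nonlinear responses agree to ~1e-7
(passband) and ~1e-5 (roll-off) relative — far inside the 1% contract.

## Problem sizes and defaults

Bode sweeps use 801 frequency points; dose–response 60 doses; the
peak-modulation-vs-dose sweep 25 doses; pulse-train reconstructions 200
harmonics on a 1 s grid over 5 periods; step responses 7200 s horizons.
These sizes leave every reported metric converged (halving or doubling any
of them moves results by far less than the quoted tolerances).

## Known limitations

- The forced-response pipeline is linear; large-amplitude trains (2.1 K_d
  about a 0.315 K_d mean) stretch the small-perturbation assumption, and
  their reported peaks are systematically ~10% below the anchored reference
  values (still within the ±15% band those carry).  No harmonic-balance
  correction is attempted.
- The amplifier-to-suppressor transition (peak modulation crossing 1) falls
  near 0.13 K_d in this parameterization, below the 0.2–0.5 K_d range the
  source narrative quotes from its own coarser dose sweep; the rest of the
  dose dependence (monotone decline of peak modulation, 180° phase flip at
  the dose–response maximum near 0.22 K_d) agrees.
- Step-response one-hour retention at 1 K_d is 27% of peak for EGF and 77%
  for NGF — the transient-vs-sustained contrast is robust, but the exact
  printed 10–20% / 80–90% bands are not jointly reachable at any single
  step dose in this model.
- No stochastic variant, spatial compartments, delay terms or parameter
  fitting; NGF multistability is probed, not exhaustively mapped.
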