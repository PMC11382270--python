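# Methods

This note records the models, conventions, defaults and numerical
choices behind `phosflex`, and what the synthetic-data tests do and do
not demonstrate.

## Spin physics

**Spectral density.** The Lorentzian density is normalised as
J(ω) = (2/5)·τc/(1+(ωτc)²), with the 2/5 inside J and not in the
interaction prefactors. Both conventions circulate; all prefactors in
`spin_physics.relaxation_rates` are written for this one, so the pair is
internally consistent and R₁(CSA) peaks exactly at ω₀τc = 1.

**Interaction inventory.** The default ³¹P model is an axially symmetric
CSA of span Δσ = 150 ppm plus two effective P–H dipolar contacts at
2.6 Å. These are modelling defaults chosen to put R₁ in the
0.5–2 s⁻¹ range typical of small phosphometabolites at 11.7 T, not
measured tensor values; they are configuration, never hard-coded in the
algorithms. At 11.7 T the CSA term dominates R₁ (the two dipolar
contacts contribute ~5%), which is what makes the R₁(T) maximum sharp.

**Motion model.** A single isotropic rotational correlation time
(rigid rotor). No model-free order parameters, anisotropic diffusion
tensors or cross-correlated relaxation. Extreme-narrowing note: the
dipolar terms give R₁/R₂ → 1 as τc → 0 exactly, the CSA terms give
R₂/R₁ → 7/6, so the mixed default model sits between the two limits.

**Units.** Angular frequencies (rad/s) are internal only; public
interfaces use Hz, ppm, T, K, s, Å, mPa·s (viscosity tables) and Pa·s
(SI conversions). 1 ppm equals the carrier frequency in MHz expressed
in Hz.

## Exchange broadening

Two forms are provided:

* `fast_exchange_broadening`: Rex = p_G·p_E·Δω²/k_ex, valid for
  k_ex ≫ Δω. It raises on k_ex = 0, where the regime is undefined.
* `general_exchange_broadening`: Rex = p_G·p_E·Δω²·k_ex/(k_ex²+Δω²), an
  all-regime interpolation that reduces to the fast form for
  k_ex ≫ Δω and to p_E·k_ex (p_G ≈ 1) for slow exchange, peaking at
  coalescence k_ex = Δω.

The generator and the global relaxation fit use the general form: on the
slow/rising branch it is what makes R₂ *increase* with temperature (as
Arrhenius k_ex grows) while the exchange-free R₂ decreases — the
characteristic water-rich signature. The fast-limit form alone cannot
produce that behaviour. The fast form is validated against a
Bloch–McConnell oracle: the CEST dip width of the exchanging system
matches a single site carrying R₂+Rex within 10% for k_ex ≳ 3Δω.

## CEST simulation and the dispersion diagnostic

The two-site Bloch–McConnell system is propagated from thermal
equilibrium as dM/dt = A·M + b, M ∈ ℝ⁶, using the steady state
M_ss = −A⁻¹b and a batched eigendecomposition of A over the offset grid;
a scaling-and-squaring matrix exponential (`scipy.linalg.expm`) is the
fallback when the eigendecomposition is ill-conditioned. The two paths
agree to ~1e-12 on well-conditioned inputs.

**Dip extraction** fits a four-parameter inverted Lorentzian (baseline,
depth, centre, width) with bounded parameters. When a window is
requested (two-dip spectra) the window is never narrower than 2.5 crude
dip widths, so power-broadened dips are not truncated; the crude width is
the half-depth span of the spectrum. A spectrum whose deepest point is
within 3 noise standard deviations of the baseline raises a
"flat spectrum" error rather than returning a garbage width.

**Diagnostic.** For each irradiation power the dip FWHM (Hz) is divided
by √R₂ (the *measured*, exchange-bearing CPMG R₂, as in a real
experiment) and the ordinary-least-squares slope versus power is
compared with a no-exchange reference: a matched single-site simulation
at the same powers, R₁/R₂ and irradiation time. Exchange is flagged when
the measured slope exceeds the reference slope by more than 3 pooled
standard errors. Because reference and measurement share the same finite
irradiation time, the small transient bias that a 5 s saturation leaves
in the fitted width (order e^(−R₁·t_ex)) cancels in the comparison; the
R₂-invariance of the no-exchange slope is itself exact only at
saturation steady state, which is how the invariance property is tested.
The diagnostic is detection-only: no quantitative k_ex is extracted from
measured Z-spectra, and multi-pool fitting and B₀/B₁ inhomogeneity are
out of scope.

## Relaxometry fits

* Inversion recovery uses the three-parameter form
  M(t) = M∞(1−2α·e^(−t/T1)) (imperfect inversion α); more robust than
  the two-parameter form and unbiased when the 180° pulse is imperfect.
* CPMG decays are monoexponential; a decay whose last point retains more
  than 5% of the initial intensity triggers a truncation warning but is
  still fitted.
* When the noise level is known it is passed to the fitter and the
  covariance is absolute, which is what makes the 95% confidence
  intervals calibrated (93–97/100 coverage in the Monte-Carlo tests).
* `detect_r1_maximum` takes the discrete argmax and refines it with a
  parabola through the three neighbouring points. Monotone series are a
  valid outcome, annotated as maximum-below-range (warm side, the pure
  D₂O case) or above-range (cool side).

**Global R1/R2 fit.** τc(T) = 4πη(φ,T)r_H³/(3k_B T) maps a single
hydrodynamic radius through the mixture viscosity into both rate curves;
exchange (when enabled) adds the general Rex with Arrhenius
k_ex(T) = A·e^(−Ea/RT) to R₂ only. Fitted parameters: r_H ∈ [2, 20] Å,
log₁₀A ∈ [−2, 14], Ea ∈ [1, 150] kJ/mol; the dark-pool population
(default 0.5) and the site shift separation (default 2.3 ppm, the span
of the observed composition extremes; recovery runs on generated bundles
take the generative value from the manifest) are fixed to avoid the
p_E·Δω² degeneracy. The exchange term is zeroed with a warning when it
improves the residual cost by <1% or its fitted contribution is <1% of
the largest measured R₂; an exchange-free fit that under-predicts R₂ at
high temperature (data−model trend positive at >3 SE) is flagged as
possible unmodelled exchange. The viscosity model is supplied, never
co-fitted.

**Curie ratios.** ratio_i = (I_i·T_i)/(I_ref·T_ref), reference = lowest
temperature. The dark-state flag requires a negative linear trend at
>3 SE — a decision rule of this package (the trend test is not specified
by the underlying method). On noiseless synthetic input any
infinitesimal trend is "significant"; the flag is therefore meaningful
only at realistic noise, and is tested that way.

## Hydrodynamics

Capillary viscometry is ν = K·t and η = ρ·ν (1 g/cm³ × 1 mm²/s =
1 mPa·s); kinetic-energy and end-effect corrections are omitted
(negligible for long efflux times). Stokes–Einstein
(d_H = k_BT/(3πηD)) and stick-boundary SED (τc = 4πηr³/(3k_BT)) carry
an optional slip flag (factor 0.163). Stick is the default because it
reproduces a ~7.3 Å radius from τc = 0.8 ns at DMSO-like viscosity
(2.0 mPa·s, 298 K).

**Mixture viscosity model.** ln η(φ,T) = (1−φ)·ln η_w(T) + φ·ln η_d(T)
+ G·φ(1−φ), with Vogel–Fulcher–Tammann endpoint curves and a single
temperature-independent Grunberg–Nissan coefficient G = 3.0. The
packaged calibration table is an explicitly **synthetic stand-in** built
from literature-like endpoint values (η(D₂O, 298 K) = 1.095 mPa·s,
η(DMSO-d₆, 298 K) = 2.0 mPa·s) with an interior maximum (~3.2 mPa·s
near φ ≈ 0.6 at 298 K); the model refuses to evaluate outside
φ ∈ [0,1], T ∈ [270, 360] K and verifies on load that it reproduces its
own table within 2%. Replace the table via
`ViscosityModel.from_json` / the pipeline `viscosity_table` option when
measured values are available.

## DOSY

The rectangular-gradient Stejskal–Tanner form
ψ = exp(−Dg²γ²δ²(Δ−δ/3)) only; stimulated-echo coherence-pathway
corrections, shaped-gradient form factors, convection compensation and
multi-component inversion are out of scope. Gradients are accepted in
T/m or G/cm via an explicit flag; SI internally. Fitting is nonlinear
least squares, cross-checked against the log-linear regression oracle to
1e-8 on noiseless data.

## Synthetic scenarios

`ScenarioTruth` is the full generative ground truth; every observable is
a deterministic function of (truth, seed), with independent named
sub-streams per observable and condition.

* **Populations.** Three states (U/F/S) with reduced free energies
  (units of RT) linear in φ and T−298: ε_U = 0,
  ε_F = 8φ − 0.01(T−298), ε_S = 8 minus a per-composition stabilisation
  of 7.5 at φ ∈ {0.7, 0.8, 0.9}. Calibration: p_F(φ=0, 298 K) = 0.50
  (the room-temperature 50/50 folded/unfolded balance in water),
  p_U(φ=1) > 0.99 (all-unfolded in DMSO), and a folded fraction that
  grows on heating in water so the dark pool deepens with temperature,
  as the integral data show. The semifolded bump is a per-composition
  offset because a strictly linear-in-φ energy cannot produce an
  interior population maximum.
* **Sizes.** Rotational radii r_U = 7.24 Å, r_F = 5.9 Å,
  r_S = 1.15·r_U; translational diameters d_U = d_F = 10 Å,
  d_S = 11.5 Å. Rotational and translational effective sizes are kept
  separate — for a flexible dinucleotide they need not coincide. The
  ion-binding variant scales all radii by 1.15 and stabilises the folded
  state by 2 RT.
* **Kinetics.** Arrhenius k_ex with k_ex(298 K) ≈ 4 s⁻¹ and
  Ea = 19 kJ/mol: on the slow branch relative to the 4.6 ppm site
  separation, giving Rex of order 1–2 s⁻¹ at the top temperature
  (a ≥20% share of R₂ there) and a CEST-detectable dark pool.
* **Shifts.** δ_U = −8.7 ppm; δ_F = −13.3 ppm is back-calculated so the
  50/50 average reproduces the −11 ppm observed in water
  (2·(−11) − (−8.7)).
* **Noise.** Additive Gaussian: 1% (relative) on rates, decays, DOSY and
  integrals; 0.005 (absolute) on Z-spectra; 0.3% on efflux times.
* **Problem sizes.** Temperature grid 277–343 K in 6 K steps (12
  points); CEST powers 20, 30, 40, 50, 100, 150, 200 Hz with 5 s cw
  irradiation; offsets ±40 ppm, 1 ppm coarse with 0.1 ppm refinement
  within ±5 ppm of each site; 16 linear gradients reaching ≤3% residual
  intensity with δ ∈ [2.5, 6] ms, Δ ∈ [250, 550] ms; recovery studies
  use 100 seeded replicates.

**What the generator does not emulate.** Full 1D lineshapes (including
the strongly coupled ³¹P doublet-of-doublets), pD effects, B₀/B₁
inhomogeneity, temperature-dependent chemical shifts, baseline and phase
artefacts, and any correlated (non-Gaussian) noise. Passing
parameter-recovery tests therefore demonstrates the correctness and
calibration of the inference chain under the stated generative model,
not robustness to every instrumental imperfection of real spectra. The
dark pool is "dark" by construction — its integral is simply withheld —
with no explicit linewidth mechanism.

## Pipeline and I/O

CSV tables with JSON sidecars (17 significant digits; schema-checked
headers with named offending columns). The pipeline report is JSON +
markdown; its hash is SHA-256 of the canonical report with floats
rounded to 10 decimals and filesystem paths excluded, so reruns from the
same inputs, config and seed hash identically. Stage failures are
captured per composition and yield a partial report and nonzero exit.

## Known limitations

* The dispersion diagnostic's single-Lorentzian width is a pragmatic
  summary for well-separated or fully merged dips; strongly overlapped
  double dips of comparable depth at intermediate powers inflate the fit
  dispersion (this is visible as larger slope standard errors, which the
  3 SE rule absorbs).
* The global fit assumes the interaction inventory is known; Δσ and the
  dipolar contacts trade off against r_H³ if misspecified.
* The Grunberg–Nissan/VFT viscosity stand-in is smooth and unimodal by
  construction; real D₂O/DMSO-d₆ data may place the maximum elsewhere.
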