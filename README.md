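# phosflex

³¹P NMR inference of conformational exchange in binary solvents:
relaxometry, CEST linewidth dispersion, DOSY diffusion, and
Stokes–Einstein–Debye hydrodynamics, with a fully seeded synthetic-data
generator for parameter-recovery testing.

## The scientific problem

Small dinucleotide coenzymes such as NADH interconvert between a compact
**folded** and an extended **unfolded** conformation, with evidence for an
intermediate **semifolded** state; the balance shifts with solvent
composition (e.g. D₂O/DMSO-d₆ mixtures), temperature and bound metal
ions. The pyrophosphate ³¹P resonance is a clean reporter of this
equilibrium, but no single observable settles it. This package implements
the joint inference chain a spectroscopist runs:

* **Relaxation rates.** For an isotropic rigid rotor with correlation
  time τc, CSA and heteronuclear dipolar interactions give
  (J(ω) = (2/5)·τc/(1+(ωτc)²)):

  R₁ = c²·J(ω_P) + Σ (d²/4)[J(ω_P−ω_H) + 3J(ω_P) + 6J(ω_P+ω_H)],
  with c² = (ω_P·Δσ)²/3 and d = (μ₀/4π)·ħγ_Hγ_P/r³; R₂ analogously with
  J(0) terms. R₁(τc) peaks exactly at **ω₀τc = 1** (≈0.79 ns at
  201.86 MHz), so the temperature of the R₁ maximum pins the tumbling
  rate, and τc = 4πηr³/(3k_BT) (stick-boundary Stokes–Einstein–Debye)
  converts it into a hydrodynamic radius.

* **Exchange broadening.** A two-site exchange with populations p_G, p_E,
  shift separation Δω and rate k_ex adds
  Rex = p_G·p_E·Δω²·k_ex/(k_ex²+Δω²) to R₂ (→ p_G·p_E·Δω²/k_ex in the
  fast limit), which is why R₂ *rises* with temperature in water-rich
  mixtures while the exchange-free contribution falls.

* **CEST dispersion diagnostic.** Z-spectra are simulated by propagating
  the six-dimensional two-site Bloch–McConnell equations under cw
  irradiation. Without exchange the dip FWHM normalised by √R₂, plotted
  against irradiation power, has one slope regardless of R₂ (i.e. of
  temperature); exchange raises that slope monotonically with k_ex. The
  package flags exchange when the measured slope exceeds a matched
  simulated no-exchange reference by more than 3 standard errors.

* **Curie-corrected integrals.** Equilibrium magnetisation scales as 1/T,
  so I(T)·T relative to the coldest point is flat for one fully visible
  species and falls when population leaks into a "dark" (broadened or
  shifted-out) pool.

* **Diffusion.** Pulsed-field-gradient attenuation
  ψ = exp(−Dg²γ²δ²(Δ−δ/3)) is fitted for D, and
  d_H = k_BT/(3πηD) gives the hydrodynamic diameter, using measured
  mixture viscosities (ν = K·t, η = ρ·ν from capillary viscometry).

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from phosflex import ScenarioTruth, generate_scenario, run_pipeline, PipelineConfig

bundle = generate_scenario(ScenarioTruth(seed=1), "demo/bundle",
                           compositions=[0.0, 0.8, 1.0],
                           cest_temperatures=(310.0,))
report = run_pipeline(PipelineConfig(input_dir="demo/bundle", output_dir="demo/out"))
for c in report["conditions"]:
    cest = any(v["exchange"] for v in c["cest"].values())
    tmax = c["r1_maximum"]["T_max_K"]
    print(f"phi={c['phi_dmso']:.1f}  r_H={c['global_fit']['r_H_A']:.2f} A  "
          f"T(R1max)={f'{tmax:.0f} K' if tmax else 'below range'}  "
          f"exchange={cest}  dark_state={c['curie']['dark_state']}  "
          f"d_H={c['dosy']['d_H_A']:.2f} A")
print("recovered r_U:", round(report["truth_comparison"]["r_U_recovered_A"], 2),
      "A  (truth 7.24 A)")
```

prints

```
phi=0.0  r_H=6.57 A  T(R1max)=below range  exchange=True  dark_state=True  d_H=9.99 A
phi=0.8  r_H=7.64 A  T(R1max)=320 K  exchange=False  dark_state=False  d_H=10.48 A
phi=1.0  r_H=7.24 A  T(R1max)=299 K  exchange=False  dark_state=False  d_H=9.87 A
recovered r_U: 7.24 A  (truth 7.24 A)
```

Reading the rows: in pure D₂O (phi=0) the R₁ maximum lies below the
measured temperature range, the CEST dispersion slope flags chemical
exchange and the Curie-corrected integrals reveal a dark pool — the
folded/unfolded equilibrium is active. In pure DMSO-d₆ (phi=1) a single
unfolded species tumbles with an interior R₁ maximum near 299 K and no
exchange signature; the fitted hydrodynamic radius recovers the
generative truth (7.24 Å) to three figures. At phi=0.8 the semifolded
state enlarges the apparent diffusion size (d_H 10.5 Å vs the ~10 Å
plateau) and shifts the R₁ maximum to higher temperature through the
more viscous mixture.

The same steps are available as a CLI:
`phosflex simulate|fit-t1|fit-t2|cest-analyze|fit-dosy|viscosity|pipeline`
(exit codes 0/1/2 for ok / user error / internal error).

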