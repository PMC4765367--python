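# zonasim

Simulation and analysis of paracetamol (APAP) hepatotoxicity at the single-
hepatocyte and sinusoid scale: a mass-action kinetic model of APAP
metabolism with glutathione (GSH) depletion and drug–protein adduct
formation, embedded in a zonated liver sinusoid whose position-dependent
parameters follow an axial oxygen gradient, plus a Hill/AUC dose–response
layer for damage and survival metrics.

It is written for toxicologists and modellers who want a small, fully
testable mechanistic model of the classic APAP story — phase II
detoxification, P450 bioactivation to the reactive metabolite NAPQI, GSH
exhaustion, covalent protein binding, and the centrilobular localisation of
the resulting necrosis — without the overhead of a full PBPK platform.

## The model

A dosed hepatocyte is described by mass-action ODEs for APAP (*P*), the
depletable sulphation co-factor pool (*S*), NAPQI (*N*), glutathione (*G*)
and the cumulative drug–protein adduct (*T*):

```
dP/dt = −k_sul·S·P − k_gluc·P − k_450·P + k_rev·N
dS/dt = β_S − δ_S·S − k_sul·S·P
dN/dt = k_450·P − k_rev·N − k_GSH·G·N − k_PSH·N
dG/dt = β_G − δ_G·G − k_GSH·G·N
dT/dt = k_PSH·N
```

with initial state `P(0)=P0, S(0)=β_S/δ_S, N(0)=0, G(0)=β_G/δ_G, T(0)=0` —
exactly ten rate constants. P450 and the glucuronidation co-factors are
assumed abundant (effective first-order rates); the protein-SH pool is
inexhaustible, so adduction is a first-order NAPQI sink. Three cumulative
bookkeeping pools (`E_sul`, `E_gluc`, `C_GSH`) collect the excreted and
conjugated products so the drug mass balance
`P + N + T + E_sul + E_gluc + C_GSH = P0` is exact and testable.

The key nonlinearity is the NAPQI branch ratio `k_PSH/(k_PSH + k_GSH·G)`:
while GSH is plentiful almost all NAPQI is detoxified; once the dose
exhausts GSH the flux switches to protein adduction and *T* — the damage
readout — rises sharply. With the package's (synthetic) default parameters
this switch sits between 15 and 20 mM APAP, in the dose range where
perfused hepatocyte cultures show overt toxicity.

Around the cell model:

* **zonation** — a Krogh-cylinder sinusoid with a reduced plug-flow oxygen
  balance `Q dc/dz = −A_cell·V_max·c/(K_m+c)` generates a monotone axial
  oxygen profile; monotone maps send low oxygen to high `k_450` (CYP2E1/3A
  are centrilobular) and low `β_G`, the cell model runs per zone, and the
  terminal-adduct profile is classified as centrilobular / periportal /
  panlobular / none / mixed.
* **dose–response** — dose scans reduce each trajectory to a damage metric
  (terminal adduct, NAPQI AUC, or NAPQI peak), map damage to survival
  through a Hill transform, and fit the four-parameter logistic (bottom,
  top, EC50, Hill n) by bounded multi-start least squares.
* **fitting** — rate constants are recoverable from (synthetic, noisy)
  trajectories by trust-region least squares on log-parameters, with
  explicit non-identifiability reporting.

No measured parameter set exists for this pathway at this granularity; all
defaults are synthetic, physiologically plausible values (mM, hours)
documented in `docs/methods.md`.

## Worked example

```python
import numpy as np
import zonasim as zs

params = zs.RateConstants()          # synthetic defaults, mM / hours
init = zs.InitialCondition(P0=20.0)  # 20 mM APAP dose
traj = zs.simulate(init, params, t_end=24.0)

print(f"terminal adduct T      = {traj.terminal.T:.4f} mM")
print(f"minimum GSH            = {traj.species('G').min():.4f} mM")
print(f"mass balance residual  = {zs.conservation_residual(traj).max():.2e} mM")

z, ox, anoxic = zs.axial_oxygen_profile(zs.KroghGeometry(), zs.FlowConditions(), 24)
profile = zs.zonal_parameter_field(z, ox, anoxic=anoxic)
injury = zs.simulate_sinusoid(profile, params, t_end=24.0)
lo, hi = injury.terminal_T.min(), injury.terminal_T.max()
pattern = zs.classify_injury(injury, lo + 0.8 * (hi - lo))
print(f"terminal T portal/central = {injury.terminal_T[0]:.4f} / {injury.terminal_T[-1]:.4f} mM")
print(f"injury pattern         = {pattern}")

hill = zs.HillParams(bottom=0.0, top=1.0, ec50=1.0, hill_n=2.0)
scan = zs.dose_response_scan(np.geomspace(0.5, 50, 12), params, hill)
print(f"fitted EC50            = {scan.fit.params.ec50:.2f} mM")
```

prints

```
terminal adduct T      = 0.3873 mM
minimum GSH            = 0.0473 mM
mass balance residual  = 2.13e-14 mM
terminal T portal/central = 0.0067 / 0.6081 mM
injury pattern         = centrilobular
fitted EC50            = 24.29 mM
```

A 20 mM dose drives GSH from its 5 mM baseline to near exhaustion, leaving
0.39 mM of protein adduct; along the zonated sinusoid the adduct load rises
~90-fold from the portal to the central end, so injury above threshold is
confined to the centrilobular tertile — the hallmark APAP lesion pattern.
The fitted population EC50 of ~24 mM reflects where the GSH switch, pushed
through the survival transform, crosses half-kill.

The same pipelines are available from the shell:

```sh
zonasim simulate --config run.yaml --out out/
zonasim zonate --config run.yaml --out out/
zonasim dose-response --config run.yaml --out out/
```

with YAML configs validated strictly (unknown keys rejected; exit code 2 on
validation errors, 3 on solver failure). Outputs are CSV tables with JSON
sidecars carrying units and provenance (package version, config hash, seed).

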