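# Methods

## The cell model

The hepatocyte is treated as well mixed, so APAP handling reduces to
mass-action ODEs in five species: APAP `P`, the sulphation co-factor pool
`S`, NAPQI `N`, glutathione `G`, and the cumulative drug–protein adduct `T`.
Mechanistic assumptions:

* P450 and the glucuronidation co-factors are abundant and effectively
  constant, so bioactivation (`k_450`) and glucuronidation (`k_gluc`) are
  first-order in `P`. The sulphation co-factor is depletable and tracked,
  so sulphation is bimolecular (`k_sul·S·P`).
* NAPQI can revert to APAP (first-order `k_rev`), conjugate with GSH
  (bimolecular `k_GSH·G·N`), or bind protein thiols. Protein-SH is treated
  as inexhaustible, so adduction is a first-order NAPQI sink (`k_PSH·N`);
  all protein-SH species are lumped.
* `S` and `G` turn over constitutively (`β − δ·x`), giving the drug-free
  baselines `S0 = β_S/δ_S` and `G0 = β_G/δ_G`, which are also the initial
  conditions of a healthy dosed cell.
* All bimolecular steps are 1:1 stoichiometric — the simplest mass-action
  reading; sulphation removes one `S` per `P` consumed.
* `T` is a cumulative damage total, not an instantaneous concentration. An
  optional first-order decay `delta_T` (default 0, off) represents
  downstream adduct processing; turning it on deliberately opens the mass
  balance and adds an eleventh parameter, excluded from the ten-constant
  count while zero.

Three cumulative product pools (`E_sul`, `E_gluc`, `C_GSH`) are carried as
extra states purely for bookkeeping: they make the exact identity
`P + N + T + E_sul + E_gluc + C_GSH = P0` assertable at every output time,
which is the package's primary structural regression check (the continuous
system satisfies it exactly; the integrator must reproduce it to ~1e-14
relative).

The qualitative heart of the model is the NAPQI branch fraction
`k_PSH/(k_PSH + k_GSH·G)`: damage is negligible while `k_GSH·G ≫ k_PSH` and
grows sharply once the dose depletes `G` faster than `β_G` replaces it.

## Default parameters (synthetic)

No measured rate-constant set exists for this pathway at this granularity,
so the defaults are synthetic values chosen once for physiological
plausibility; they define the package's reference conditions and are not
fitted to any dataset. Units: mM and hours throughout; bimolecular rates in
mM⁻¹·h⁻¹.

| parameter | default | rationale |
|---|---|---|
| `k_sul` | 0.2 mM⁻¹h⁻¹ | with S0 = 0.5 mM, a minor clearance route (~10% share) that saturates as S depletes |
| `k_gluc` | 0.4 h⁻¹ | glucuronidation as the dominant phase II route |
| `k_450` | 0.3 h⁻¹ | effective bioactivation share (~35–40%) representative of the toxic-dose regime, where phase II saturation raises the P450 fraction above its therapeutic ~5–10% |
| `k_rev` | 0.02 h⁻¹ | slow NAPQI reversion; kinetically indistinguishable from a small back-reaction |
| `k_GSH` | 10 mM⁻¹h⁻¹ | fast conjugation: with G at baseline, detox outcompetes adduction ~500:1 |
| `k_PSH` | 0.1 h⁻¹ | slow covalent binding, relevant only once G is exhausted |
| `β_S`, `δ_S` | 0.05 mM/h, 0.1 h⁻¹ | S0 = 0.5 mM sulphate-donor pool with a few-hour turnover |
| `β_G`, `δ_G` | 0.5 mM/h, 0.1 h⁻¹ | G0 = 5 mM hepatic GSH, ~7 h turnover half-life |
| `P0`, `t_end` | 10 mM, 24 h | dose and exposure window in the range used for hepatocyte cultures |

Under these defaults the GSH switch — near-exhaustion of `G` and the onset
of substantial `T` — occurs between 15 and 20 mM, consistent with the doses
at which perfused hepatocyte systems show overt APAP toxicity. That
placement was a design choice of the default set, made before the test
values were frozen, not a fit.

## Numerical choices

* Integrator: `scipy.integrate.solve_ivp` with LSODA (stiff-capable;
  `k_GSH·G` can sit four decades above the turnover rates), `rtol = 1e-8`,
  `atol = 1e-10`, both configurable. Implicit methods (`Radau`, `BDF`)
  receive the analytic Jacobian.
* Non-negativity and monotone-pool assertions allow a −1e-9 margin (10×
  atol): LSODA's dense output can undershoot zero by slightly more than
  atol without indicating a model error.
* The conservation residual is reported per time point; its maximum is the
  summary statistic. Tolerance 1e-6·P0 in tests; observed ~1e-14·P0.
* Rate-constant fitting: trust-region reflective least squares on log10
  parameters (positivity by construction, scale equalisation), residuals
  normalised per species by the observed dynamic range. Non-identifiability
  is reported two ways: an a-priori excitation check (P0 = 0 or flat data)
  that refuses to optimise, and a Jacobian singular-value ratio (<1e-8) at
  the solution.
* Hill fitting: 4PL with EC50 parameterised as log-dose; bounds `bottom`,
  `top` within the padded response range, `hill_n ∈ (0, 20]`, EC50 within
  [min dose/10, max dose·10]; three deterministic starts across the log-dose
  range; ties broken by cost then by lower `hill_n`. Descending data (e.g.
  survival vs dose) are fitted with the reflected 4PL (`increasing=False`),
  which keeps `top ≥ bottom` and `hill_n > 0` and leaves the EC50 meaning
  unchanged. Constant responses are flagged non-identifiable, never given a
  fabricated EC50.

## Zonation

The sinusoid/hollow-fibre is a single Krogh unit (length `L = 20 mm`, lumen
radius 0.1 mm, membrane 0.02 mm, cell layer 0.1 mm). Oxygen transport is
deliberately reduced to a 1-D plug-flow axial balance with Michaelis–Menten
volumetric uptake by the annular cell layer:

    Q dc/dz = −A_cell·V_max·c/(K_m + c),  c(0) = c_in.

This keeps the single feature the cell model needs — a controlled, monotone
axial oxygen gradient — while leaving radial transport, membrane Starling
flow and lumen hydrodynamics out of scope. The balance is solved through its
exact implicit form `K_m·ln(c_in/c) + (c_in − c) = A_cell·V_max·z/Q`,
inverted per position by bracketing root-finding; the zero-order limit is
the clamped linear decline (clamping sets an anoxia flag rather than
raising), the first-order limit the exponential, and the identity
`c(z; 2Q) = c(z/2; Q)` holds exactly. Default flow `Q = 400 mm³/h` and
inlet oxygen 0.2 mM give an outlet of ~0.08 mM: a strong but non-anoxic
gradient.

Oxygen-to-parameter maps are linear and monotone by default, normalised to
the profile's own range: `k_450` from 0.15 h⁻¹ (portal) to 0.45 h⁻¹
(central; CYP2E1/3A are centrilobular), `β_G` from 0.5 down to 0.25 mM/h
(GSH depressed centrally), `P0` uniform (the drug is assumed well
perfused; an axial drug-depletion mode is a possible extension, not a
default claim). Custom maps may override any field; non-monotone ones are
accepted but flagged. Zones are independent cells — 24 closed-open
intervals by default, labelled by tertile (periportal / midzonal /
centrilobular).

Injury classification thresholds terminal `T` per zone: injury confined to
the distal tertile is `centrilobular`, to the proximal tertile
`periportal`, all tertiles `panlobular`, no zones `none`, and anything else
(e.g. midzonal-only) `mixed` — a label added because the four classic
patterns do not exhaust the combinatorics. When no explicit threshold is
given the CLI uses `T_min + 0.8·(T_max − T_min)`: with a monotone gradient
a tertile-confined pattern requires a threshold in the top part of the
range, and the 0.8 level places the crossing at z ≈ 0.8·L for a linear
profile, inside the distal tertile.

## Dose–response

Scans simulate each dose independently, reduce trajectories to one of three
damage/exposure metrics (terminal `T` by default; NAPQI AUC by composite
trapezoid; NAPQI peak over the output grid), and map damage to survival by
a decreasing unit Hill transform `1 − H(damage; ec50, n)` with fixed 0/1
asymptotes. The survival transform is a user configuration, not a claim:
the model does not quantitatively connect adduct load to cell death, so
`survival_ec50` (default 1 mM adduct) and `survival_hill_n` (default 2) are
explicit knobs. AUC and peak metrics can disagree (equal-AUC profiles with
different peaks), which is why all three are exposed rather than one being
canonical.

## Synthetic fixtures and what passing tests show

`zonasim.fixtures` samples rate constants log-uniformly (one decade either
side of the defaults), integrates clean trajectories, verifies the mass
balance pre-noise, and applies multiplicative Gaussian noise (1% for
trajectory fits, 2% for dose-response tables) from a single seeded
generator; identical seeds give byte-identical fixtures.

The generator emulates dense, low-noise, fully observed time courses: every
species including the bookkeeping pools is observed at 31–61 time points.
Real experiments observe far less (typically extracellular APAP and a few
endpoint measurements), with structured rather than i.i.d. noise. Passing
the recovery tests therefore demonstrates that the estimation machinery is
correct and well-conditioned under full observation; it does not show that
all ten constants are identifiable from realistic assay designs — with
partial observation, identifiability must be re-assessed per design (the
fitter's diagnostics are built for exactly that).

Problem sizes used by the test suite and acceptance script — 200 parameter
sets for the mass-balance sweep, 20 noise seeds for recovery, 24 zones,
101–201 output points — were chosen as the smallest sizes at which the
statistics are stable.

## Known limitations

* Linear phase II kinetics: glucuronidation never saturates, and sulphation
  saturates only through S-depletion; the toxic-regime P450 share is
  therefore baked into `k_450` rather than emerging from saturation.
* No enzyme dynamics (P450/UGT levels fixed), no Nrf2 adaptation, no
  mitochondrial or immune downstream pathology; `T` is a damage surrogate.
* Protein-SH inexhaustible: adduction never self-limits.
* Zonation is one-way: parameters depend on oxygen, but metabolism does not
  feed back on the oxygen profile, and zones do not exchange mass.
* The survival map is a configured transform, not a calibrated
  dose-lethality model.
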