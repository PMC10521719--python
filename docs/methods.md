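# Methods

## Device and transport model

Each unit cell is treated as two well-mixed compartments: the reaction
chamber (volume `V_cell`, default 500 pL) and the isolated
exchange-channel segment serving it (`V_res`, default 250 pL). Transport
through the connecting channel (length `l` = 50–450 µm, cross-section
25 µm × 15 µm) is quasi-steady 1-D diffusion, giving first-order
exchange with conjugate rates `k_cell = D·A/(l·V_cell)` and
`k_res = D·A/(l·V_res)`. The approximation is appropriate because the
channel volume is small against both compartments; no transport PDE,
Taylor dispersion, or concentration gradient inside the chamber is
modeled. Species diffusivities derive from molecular weight by cube-root
Stokes–Einstein scaling anchored at 90 µm²/s for the 27 kDa
fluorescent-protein class. Surface-anchored DNA templates never
exchange.

The five connecting-channel lengths on the default array are evenly
spaced, {50, 150, 250, 350, 450} µm, cycling along each row; only the
range and the count of five are fixed by the device, so even spacing is
the natural uncommitted choice and is configurable.

The flush is modeled as an instantaneous replacement of the reservoir
compartment at the flush timestamp: during the real ~60 s flow the
chamber is sealed behind the cell-inlet valve, so only the post-flush
composition is visible to it. The protocol begins with a flush at t = 0
(the exchange channel must be filled before the first incubation);
a 20 h run at the 15-minute cadence therefore logs 80 flushes. In the
limit of vanishing flush period the discrete protocol converges to a
continuous chemostat in which every mobile species is diluted at exactly
`k_cell`; this limit provides the analytic cross-check used in the
tests.

## Reaction model

Per cell, for each template `i` with effective concentration `G_i` (nM)
and promoter activity `f_i`:

    dM_i/dt  = k_tx G_i f_i ρ − δ_m M_i + exch
    dPd_i/dt = k_tl M_i ρ ψ − k_mat Pd_i + exch
    dP_i/dt  = k_mat Pd_i + exch
    dE/dt    = −ρ Σ_i (c_tx k_tx G_i f_i + c_tl k_tl M_i ψ) + exch
    dW/dt    = w_yield · k_tl ρ ψ Σ_i M_i + exch

with resource saturation `ρ = E/(K_E+E)`, translational-load inhibition
`ψ = 1/(1+(W/K_W)^2)`, independent-site repression
`f = Π_s 1/(1+(TF_free/K_d,s)^{n_s})`, and inducer sequestration at
instantaneous equilibrium `TF_free = TF_total/(1+(I/K_I)^h)`.
Transcription-factor activity uses total protein (dark + mature):
DNA binding does not wait for the fluorophore. mRNA decays in both
compartments; synthesis and consumption occur only in the chamber,
where the templates are anchored. The lumped resource `E` is small and
fast-diffusing (energy charge); the load `W` — spent machinery such as
stalled ribosomal complexes — is a large, slowly-exchanging species, so
it clears quickly from short-channel cells and lingers in long-channel
ones.

The load term is the model's account of the device's high-template
behavior: at template densities above the recommended dsDNA:ssDNA
operating ratio the reporter bursts early and then levels out to a
lower steady state, because reagent exchange cannot clear the
accumulating load. At the routine 1:10 density `W` stays far below
`K_W` and the model reduces to plain resource-limited expression. An
architecture in which only the consumable pool `E` limits expression
cannot produce that early peak at all: protein production is capped by
the time-constant resupply while the local stockpile turns over in
under an hour, so production — and hence the reporter — is monotone.
Setting `w_yield = 0` recovers that reduced model (the
`unlimited_resource` preset additionally zeroes the consumption
stoichiometries, making the constitutive closed form exact).

### Calibrated default parameters

No rate constants exist for this chemistry-on-chip combination, so the
defaults are an effective set, fixed once against two qualitative
anchors and then frozen: (a) constitutive expression at the lowest
default template density reaches detected steady state in 4–6 h across
all five geometries, ordered by `l`; (b) the early overshoot appears
(≥10% above final) at the 1:1 spotting density and is absent at 1:10.

| parameter | value | unit | meaning |
| --- | --- | --- | --- |
| `k_tx` | 8e-3 | 1/s | transcript initiation per template, resource-saturated |
| `k_tl` | 2e-2 | 1/s | protein per mRNA, resource-saturated |
| `δ_m` | 5e-4 | 1/s | mRNA decay (~33 min lifetime) |
| `k_mat` | 2e-4 | 1/s | fluorophore maturation (~83 min) |
| `K_E` | 25 | a.u. | resource half-saturation |
| `c_tx`, `c_tl` | 0.002, 0.01 | a.u./nM | resource stoichiometries |
| `E_supply` | 100 | a.u. | resource delivered by a 1:1 flush |
| `w_yield` | 1.0 | nM/nM | load deposited per protein synthesized |
| `K_W`, `h_W` | 2000 nM, 2 | | load inhibition knee and steepness |
| mRNA MW | 2000 kDa | | effective polysome size (slow exchange) |
| load MW | 250 kDa | | spent-complex size (l-dependent clearance) |

With these defaults the detected steady-state times at low density are
{4.0, 4.5, 5.0, 5.5, 6.0} h for l = {50…450} µm, and the 1:1-density
trace at l = 450 µm peaks ~16% above its final level. The overshoot
and the density-dependence of the settling time are characterized at
the longest connecting channel, where exchange is slowest and the
load effect strongest; at l = 50 µm the load clears within ~1 h and
high-density traces flatten without a visible peak.

### Effective template concentration

Spotted mixtures of biotinylated dsDNA template and ssDNA oligo compete
with equal per-molecule affinity for saturating surface sites, so the
template surface fraction is `ds/(ds+ss)`. Bound templates convert to a
solution-equivalent concentration via `count/(N_A·V_cell)` with default
site density 6000 µm⁻² over a 500 µm² patterned circle — an undiluted
spot is ≈10 nM effective template, and a plate map's `template_id`
names a circuit (a spotted DNA mix) whose member templates are scaled
jointly by the spot's surface fraction.

## PWM formulation

Duties are exact rationals; every schedule sums to exactly 1, the
energy solution holds exactly half of each cycle whenever the 1:1
lysate:energy constraint is active, and grid rounding breaks exact ties
toward the lower variable duty. The 5% minimum actuation duty on the 5%
grid yields the ten-level dilution series; three variable stocks may
share the lysate half-cycle for wider dynamic range. Plug mixing is an
effective fundamental-mode Fourier decay,
`residual = exp(−4π²·D·t_res/(u·T)²)`: the per-checkpoint residence
times are calibrated constants — not measured transport parameters —
chosen so that the serpentine end is fully mixed (residual ≤ 0.05)
exactly up to 800 ms cycle periods and the exchange-channel entry up to
1200 ms.

## Circuits

* **ZF panel.** Twelve promoter variants with one operator site each,
  screened against a PWM-dosed, purified ZF at four duty levels. The
  variant dissociation constants are synthetic placeholders spanning
  consensus (2 nM) to nonspecific (1 µM), plus two operator-deleted
  variants; the real affinities are not published with the device.
  Because the dosed stock is 5 µM against nM-scale K_d's, simulated
  fold-repression magnitudes are large; the analysis relies on their
  ordering (monotone in K_d and dose), not their absolute values.
* **TetR/aTc.** Constitutive TetR represses a Tet-operator GFP template
  (K_d 10 nM); aTc sequesters TetR cooperatively (K_I 50 nM, h = 2,
  two binding subunits per dimer), so a 2.5 µM delivered pulse restores
  ≥90% of the control production rate.
* **Toggle.** TetR and LacI each expressed from a promoter carrying two
  operator sites for the opposing repressor (the classic two-operator
  promoters), with a LacI-repressible GFP reporter. LacI binds its
  operator 2× more tightly (5 vs 10 nM), so a cold start settles
  LacI-high; an IPTG pulse (K_I 2 µM, h = 2) flips the circuit to the
  TetR-high state, which persists. Repressor templates default to the
  20 nM spotting concentration used on-device. An exactly symmetric
  toggle started symmetrically converges to the saddle; the state
  finder classifies endpoints by the leading Jacobian eigenvalue and
  returns such points flagged `stable=False` rather than picking a
  side.

## Analysis conventions

* Steady state: earliest sliding-window start (width 2 h, samples every
  30 min) from which the OLS relative slope |dF/dt|/F̄ stays below
  0.02/h in every later window; the reported level is the mean over the
  first passing window. The relative criterion makes detection
  invariant to uniform rescaling.
* Fold repression endpoint = last common timestamp of the two traces
  (configurable); FR = unrepressed / maximally-dosed signal.
* Response time: from the perturbation to the midpoint crossing between
  the pre-event level (last pre-event sample) and the post-event
  extremum; excursions under 5% of the pre-level are flagged
  not-responsive instead of raising.
* K_d fitting: least squares on `L0/(1+(TF/K_d)^n)` with fixed Hill
  coefficient; confidence intervals by seeded residual bootstrap.
* The noisy-trace generator applies multiplicative log-normal error
  (given CV) plus a Gaussian background, floored at zero, fully
  reproducible from its seed.

## Numerics

Incubation windows integrate with LSODA at rtol 1e-8 / atol 1e-10,
restarting at every flush boundary. Tiny negative excursions (down to
−1e-6 nM) are clipped to zero after each window; anything larger
raises. Fixed points must satisfy |RHS| < 1e-6 of the state scale and
are clustered at 5% relative distance. The discrete-flush → continuous
chemostat convergence is first order in the flush period (the
per-window equilibrated fraction `(V_res/V_tot)(1−e^{−(k_c+k_r)τ})/τ`
approaches `k_cell` linearly), so the oracle comparison uses a 20 s
period for the tightest check.

## What the simulations do and do not emulate

The synthetic pipelines reproduce the device's structure — PWM
formulation, mux routing, wash insertion, flush cadence, imaging
cadence, geometry spread, template dilution — and the qualitative
phenomenology the device exhibits (steady-state ordering by geometry,
density-dependent overshoot, derepression pulses, toggle switching).
They do not emulate image quantification, spot-to-spot or chip-to-chip
variability, evaporation or temperature drift (33 °C is carried as
metadata only), serpentine dead-volume carryover beyond the inserted
washes, or absolute fluorescence calibration; all levels are in
arbitrary units. Passing tests therefore validate the scheduling and
analysis machinery and the internal consistency of the reaction model,
not quantitative agreement with any particular chip run.

## Known limitations

* The kinetic constants are an effective, calibrated set; they are not
  transferable measurements.
* Repression uses independent-site products; cooperative multi-site
  binding is only available through the per-site Hill exponent.
* The reservoir compartment is passive (no translation of exchanged
  mRNA, no resource consumption outside the chamber).
* Valve dynamics are reduced to the minimum-duty constraint; BUTTON,
  NECK and SANDWICH valves are logged for completeness but do not
  affect transport.
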