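# cfchip

A desk-scale digital twin of an automated microfluidic cell-free
chemostat array, for synthetic biologists who develop screens and
dynamic gene circuits on such devices and want to prototype experiment
designs — valve schedules, reagent formulation programs, spotting
layouts, pulse timing — before committing chip time.

The device this package models is a two-layer PDMS chip whose flow layer
holds 280 unit-cell chemostats in 8 multiplexer-addressable rows. Each
chemostat runs a cell-free transcription–translation (tx–tl) reaction
from surface-immobilized DNA templates and is held at steady state by a
flush/incubate protocol: every 15 minutes fresh reagent mix replaces the
exchange channel, then reagents exchange with the sealed reaction
chamber by diffusion through a connecting channel of length *l*
(50–450 µm), which sets the per-cell dilution rate

    k_cell = D · A / (l · V_cell),

with *D* the species diffusivity, *A* the connecting-channel
cross-section and *V_cell* the chamber volume. Reagent compositions are
formulated on-chip by pulse-width modulation (PWM): each input flows for
*t = D·T* per cycle (duty *D*, period *T*), and the delivered
concentration is linear in the duty. Gene circuits follow a
resource-limited expression model with independent-site Hill repression
(`f = Π 1/(1+(TF/K_d)^n)`) and instantaneous inducer sequestration
(`TF_free = TF/(1+(I/K_I)^h)`); see `docs/methods.md` for the full ODE
system and the calibrated parameter set.

## What's inside

| module | contents |
| --- | --- |
| `cfchip.device` | array layout, geometry, diffusive exchange rates |
| `cfchip.spotting` | plate maps, dsDNA/ssDNA competitive surface binding |
| `cfchip.pwm` | duty schedules, dilution series, valve trains, plug-mixing check, mux routing |
| `cfchip.protocol` | valve state machine, flush/incubate execution, pulses, sampling |
| `cfchip.kinetics` | the tx–tl reaction model, closed-form chemostat oracle, toggle fixed points |
| `cfchip.experiments` | canned circuits (constitutive, ZF panel, TetR/aTc, toggle) and screen builders |
| `cfchip.analysis` | steady-state detection, fold repression, PWM linearity, response time, K_d fitting |
| `cfchip.config` / `cfchip.cli` | YAML experiment configs, seeding, manifests, `cfchip` command |

## Worked example

Simulate constitutive GFP expression across the five connecting-channel
geometries at the routine 1:10 dsDNA:ssDNA spotting density:

```
$ cfchip simulate circuit --hours 10
l=   50 um  steady=True  t_ss=4.0 h  level=69.49
l=  150 um  steady=True  t_ss=4.5 h  level=174.33
l=  250 um  steady=True  t_ss=5.0 h  level=293.13
l=  350 um  steady=True  t_ss=5.5 h  level=410.37
l=  450 um  steady=True  t_ss=6.0 h  level=521.82
```

Longer connecting channels dilute more slowly, so steady-state GFP
(arbitrary units) rises with *l* while the time to reach steady state
stretches from 4 h to 6 h — the slowest geometry still settles within
the 6 h operating envelope. The ten-level PWM dilution series on the 5%
duty grid (energy solution pinned at 50%, the other half split between
plain and dosed lysate):

```
$ cfchip pwm series | tail -1
# 10 schedules
```

and the toggle switch's long-time states at default parameters:

```
$ cfchip simulate toggle
stable: TetR=0.0 nM, LacI=342.6 nM, GFP=0.0 nM
stable: TetR=136.2 nM, LacI=0.0 nM, GFP=39.1 nM
```

— two stable states (LacI-high/GFP-off and TetR-high/GFP-on); a
transient IPTG pulse moves the circuit from the first to the second, and
it stays there after the pulse ends.

Full experiments are driven by YAML configs (`cfchip run --config ...`),
which emit a long-format time-series CSV
(`cell_id,row,col,length_um,time_h,species,value`), a JSON-lines valve
actuation log, and a manifest that makes reruns byte-reproducible.

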