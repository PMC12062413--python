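# fibroscar

Monodomain simulation of cardiac scar tissue bridged by random,
spatially non-local myocyte–fibroblast (M–F) gap-junction links.

In injured or fibrotic hearts, regions of myocardium can become
diffusively uncoupled from their surroundings (dense scar, ablation
lines), yet conduction across them is still observed — mediated by
fibroblasts and myofibroblasts that couple to myocytes through gap
junctions over surprisingly long distances. `fibroscar` implements a 2D
tissue model of this situation: a sheet of human ventricular myocytes
containing a zero-diffusion scar, with a layer of fibroblast units
attached inside the scar whose additional attachments may reach up to a
distance `Lmax` — including into the healthy tissue around the scar.
The annulus of normal tissue whose electrophysiology is altered purely
by these links is a *dynamic border zone*: nothing about its diffusion
or ionic properties is prescribed. The package provides the pacing
protocols and analyses (restitution, APD dispersion, reentry-regime
classification) used to study how this border zone turns rapid pacing
into conduction block and reentry.

It is intended for computational cardiac-electrophysiology researchers
who want a compact, fully scripted re-implementation of this model
rather than a general-purpose cardiac simulator.

## Model

Myocytes follow the ten Tusscher–Panfilov 2006 (TP06) human ventricular
model (epicardial, *Shallow*-restitution parameter set, maximum
restitution slope ≈ 0.7 so that reentry cannot arise from intrinsic
alternans). Fibroblasts follow the MacCannell "active" model with
myofibroblast capacitance Cf = 50 pF; a unit lumps Nf identical
fibroblasts in parallel. The tissue equations are

    ∂V/∂t  = −I_ion/Cm + Σ_links Nf·Gs·(Vf − V)/Cm + ∇·(D ∇V)
    dVf/dt = −I_f,ion + Σ_attachments Gs·(V − Vf)/Cf

with V in mV, t in ms, current densities in pA/pF, Gs (nS) the
per-fibroblast gap-junction conductance, D = 0.001 cm²/ms outside the
scar and D = 0 inside, no-flux boundaries at the domain edges and the
scar rim, forward-Euler integration with Δx = 0.25 mm and Δt = 0.01 ms
(Rush–Larsen exponential integration for the gating variables).

Link sets are random: each of `np` fibroblast units gets one uniform
proximal scar point plus Poisson(λ) candidate attachments, each drawn
uniformly over the lattice and accepted only within `Lmax` (2.5 mm) of
the proximal point. Runs are classified as NR (no reentry), BR
(retrograde activity confined to the border-zone annulus) or PR
(reentry invading the tissue) from the activation log.

## Worked example

Restitution of the single Shallow myocyte (the variant-defining slope):

```
$ fibroscar restitution --protocol dynamic
max restitution slope: 0.765
```

Paced steady state loses 1:1 capture just below a cycle length of
300 ms; the maximum slope of APD₉₀ against the diastolic interval on
the 1:1 branch is 0.765 — a shallow-restitution cell that does not
alternate at the study's pacing period of T = 300 ms.

Conduction across a fibroblast-bridged line scar (one plane wave paced
against a 0.25 mm zero-diffusion band whose only crossings are M–F
links, Nf = 8):

```python
from fibroscar.protocols import line_scar_conduction_test
for gs in (2.0, 4.0):
    r = line_scar_conduction_test(gs, nf=8)
    print(gs, r.conducted, round(r.delay_ms, 1))
# 2.0 False nan
# 4.0 True 43.3
```

Weak coupling (2 nS) blocks; strong coupling (4 nS) carries the wave
across with a 43 ms delay — purely fibroblast-mediated conduction. At
4 nS, Nf = 8 is the smallest unit size of {4, 6, 8} that conducts.

A random link realisation and its attachment-count distribution:

```
$ fibroscar linkgen --fixture small_circle --np 200 --lam 20 --seed 3 --out links.csv
{"1": 0.58, "2": 0.3, "3": 0.095, "4": 0.025}
```

58% of units hold a single (proximal) attachment; the tail of
multi-attachment units grows with λ and Lmax.

Full tissue experiments (rapid edge pacing of the 200×200 circular-scar
domain, 6 s at T = 300 ms) run through `fibroscar simulate` and
`fibroscar sweep`; each such run takes a few hours of CPU time and
writes a recording (snapshots, sampling-line traces, activation log)
plus an NR/BR/PR label.

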