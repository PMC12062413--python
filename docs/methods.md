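# Methods

## Model overview

`fibroscar` couples three components on a square lattice (Δx = 0.25 mm):

1. **Myocyte field** — the TP06 human ventricular ionic model
   (epicardial gating), one cell per grid point, diffusively coupled
   through a flux-conservative five-point stencil with face diffusivity
   D = 0.001 cm²/ms in normal tissue and 0 on any face touching a scar
   point. Zeroing scar faces implements both the scar-rim and
   domain-edge no-flux conditions and makes the discrete operator
   exactly conservative (telescoping fluxes).
2. **Scar** — a mask of grid points with zero diffusion. In
   *active* mode scar cells keep their full ionic dynamics (early-stage
   injury); in *inactive* mode their ionic current is zero and the
   membrane evolves only through gap junctions (late-stage injury).
3. **Fibroblast units** — MacCannell active fibroblasts, Nf identical
   cells in parallel per unit (Cf = 50 pF per fibroblast, the
   myofibroblast value). Each unit is anchored at one *proximal* scar
   point and may hold further *distal* attachments within Lmax.

### Gap-junction coupling and Nf lumping

Each of the Nf fibroblasts in a unit forms its own junction of
conductance Gs with every attached grid point. The lumped unit
therefore injects `Nf·Gs·(Vf − V)` pA into the myocyte, while its own
membrane equation, after dividing the total junction current by the
unit capacitance Nf·Cf, reduces to the per-fibroblast form
`dVf/dt = −I_f,ion + Σ Gs·(V − Vf)/Cf`. This is the only reading we
found to be simultaneously charge-consistent (it conserves
`Cm·V + Nf·Cf·Vf` for an isolated pair), to reduce to the published
unit equation, and to reproduce the model's characteristic behaviour —
conduction across the bridged line scar requires both strong coupling
(4 nS, not 2 nS) and large units (Nf = 8, not 4 or 6). An alternative
normalization in which the myocyte receives only `Gs(Vf − V)`
regardless of Nf never conducts at any tested Gs and leaves Nf almost
without effect, so it was rejected.

### Link-set generation

For each of `np` units: a proximal point uniform over the scar; a
candidate count k ~ Poisson(λ); k candidate points uniform over the
full lattice, each accepted iff within Lmax (Euclidean, mm) of the
proximal point; rejected candidates are discarded (not redrawn) and
duplicate hits on an already-attached point are skipped. The accepted
distal count is then approximately Poisson(λ·p_acc) with p_acc the
lattice fraction within Lmax (≈ 0.8% for the 200×200 study geometry),
which is why most units are singly attached even at λ = 50, and why
Lmax = 0 forces degree 1 exactly. Drawing candidates from the whole
lattice (not the scar alone) is what lets rim-proximal units attach
into the surrounding tissue — the border-zone bridge. A `scar`-only
candidate pool is available behind a switch for comparison. Realisation
ids 1–5 map to fixed seeds (7101–7105) so "case n" runs are exactly
reproducible.

## Numerical scheme

Forward Euler at Δt = 0.01 ms for the membrane potential,
concentrations and fibroblast units, with the stability margin
`4·D·Δt/Δx² ≈ 0.064` checked at configuration time. Gating variables
use Rush–Larsen exponential integration by default: the TP06 Na⁺
activation gate has τ_m ≈ 10⁻³ ms near rest, below Δt, so a pure
forward-Euler gate update is amplifying at this step size and cannot
hold the quiescent state; Rush–Larsen is unconditionally stable for
gates and is the scheme the TP06 reference implementations use. A
clamped forward-Euler gate mode remains available (`gate_mode="euler"`)
for experimentation. Halving Δt changes the single-cell APD by well
under 1 ms.

For tissue runs all purely voltage-dependent factors (gate steady
states, per-step gate update factors, and the exponential coefficients
of I_CaL, I_NaCa, I_NaK, I_pK, I_K1) are tabulated on a 0.02 mV grid
and linearly interpolated; the table path agrees with the direct
evaluation to ~10⁻⁴ relative (conduction velocity matches to 4
significant figures). Both sides of every gap junction are evaluated at
the same time level. A voltage-magnitude guard (|V| > 1000 mV) aborts
a run with the failing time and grid point.

### Initial conditions and settle period

The myocyte field starts from the published TP06 resting state followed
by 2 s of quiescent single-cell equilibration. Fibroblast units start
*at the myocyte resting potential* and the fully coupled tissue then
relaxes for 200 ms before t = 0 (stimuli, recordings and the
activation log all start at t = 0). Starting units at their uncoupled
resting potential instead (−24.5 mV for the depolarized variant)
injects a large coupling-onset transient that can fire border-zone
myocytes spuriously; the settle period plus myocyte-rest initialisation
removes this artefact while converging to the same coupled equilibrium.

### Fibroblast resting-potential variants

The two study variants are produced by shifting the Kv gating voltage
dependence; the shift is found by root search on the algebraic
steady-state current balance, restricted to the depolarizing branch
(shift ∈ [−5, 60] mV) where the resting potential is monotone in the
shift. The calibrated constants (+34.7168 mV → −24.5 mV;
−0.0985 mV → −49.0 mV, the native model rest being −48.93 mV) are
frozen in the bundled parameter files so tissue runs never re-run the
calibration. The fibroblast I_K1 uses the alpha/beta inward-rectifier
form, which reproduces the documented native resting potential of the
source model (≈ −49 mV).

## Restitution measurement

The *Shallow* myocyte variant is defined by a maximum restitution slope
of ≈ 0.7. The package measures this with the **dynamic (steady-pacing)
protocol**: the cell is paced to an approximately periodic state at
descending cycle lengths (30 beats each, state carried over), APD₉₀ of
the final beats is plotted against the preceding diastolic interval,
and the protocol stops at alternans onset (beat-to-beat APD difference
> 5 ms) or loss of 1:1 capture, where a single steady APD no longer
exists. The maximum finite-difference slope over the retained branch is
0.765 for the Shallow set and 1.03 for the default epicardial set —
matching the 0.7 / 1.1 labels of the source model's variants, which is
the evidence that those labels are dynamic-protocol quantities. The
classical premature-S2 protocol is also implemented
(`s1s2_restitution`); its maximum slope is substantially steeper for
every TP06 variant (the short-DI branch is dominated by ICaL and
SR-release recovery) and is not the variant-defining number. Tissue
analyses use the same beat-to-beat quantity: local restitution curves
are (CL_n, APD_{n+1}) point sets per sampling-line cell.

APD is APD₉₀ with per-beat amplitude: activation at the upward −40 mV
crossing (50 ms lockout), resting level the minimum over the 20 ms
before the upstroke, repolarization threshold rest + 10% of the beat's
amplitude. Beats that never reach 90% repolarization before the next
activation are flagged, and S2 responses that do not overshoot 0 mV
count as failure to capture.

## Stimulus

Edge pacing drives a 3-grid-point strip (0.75 mm) along one domain edge
with −52 pA/pF for 1 ms (≈ 2× diastolic threshold); point pacing uses a
5×5 block. The stimulus current is included in the K⁺ bookkeeping, as
in the source model's reference code.

## Regime classification

The study's NR/BR/PR outcomes are judged from movies in the original
setting; here they are codified on the activation log. A reference
wavefront arrival per beat and column is taken from scar-free rows near
the domain edges. An activation is *retrograde evidence* when it lags
the reference by more than half a pacing period and lies in a connected
component (8-connectivity, ≥ 3 points) whose activation-time gradient
opposes the pacing direction. The label is PR if any such component
reaches beyond the border-zone annulus (distance > Lmax + 2Δx from the
scar rim) or outlives pacing by more than two periods; BR if components
exist but stay confined and die out; NR otherwise. All thresholds
(late fraction 0.5, annulus margin 2Δx, die-out horizon 2T, minimum
component size 3) are exposed in `ClassifierSettings`. This is an
explicit formalization, not the original authors' visual procedure, and
borderline runs can legitimately be labelled differently by different
threshold choices.

## Fixtures, problem sizes and what the tests show

Named fixtures: `tiny_strip` (12×60, no scar), `small_circle` (100×100,
R = 0.5 cm), `line_scar` (60×200, single-column scar band),
`paper_circle` (200×200, R = 2 cm — the full study geometry). The
line-scar band is one grid point (0.25 mm) wide — an ablation-line-like
scar — bridged deterministically by one unit per scar point attached to
both flanking columns.

The test suite and the acceptance script run reduced problem sizes
chosen to exercise the full code path at desk scale: conduction
thresholds on 16×100 (tests) and 200×60 (acceptance script) strips over
300–600 ms, solver properties on strips and a 48×48 circular scar, and
single-cell protocols at full duration. The 180-run parameter sweep
(λ × np × realisation × Gs on the 200×200 domain, 6 s each) is fully
implemented and resumable but takes multi-hour CPU time per
configuration; its enumeration, bookkeeping and classification logic
are what the suite verifies. Passing tests therefore demonstrate the
correctness of the solver, generator and analyses, and the reproduction
of the desk-scale electrophysiology — not the statistics of the full
sweep.

The synthetic geometries idealise real scar: perfectly circular or
straight, with a binary diffusion field, homogeneous myocytes and
stationary links; none of the structural texture, conductivity
gradients or ionic remodelling of real border zones is represented, by
design — the model isolates the effect of non-local M–F coupling alone.

## Known limitations

- Single uniform Gs (G_loc = G_long); no distance-dependent weakening.
- Links are static; no fibroblast–fibroblast or ephaptic coupling; no
  mechanics.
- 2D monodomain only; no bidomain, anisotropy or 3D.
- The regime classifier is a formalization of a visual judgement and
  its thresholds, while exposed and documented, are conventions.
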