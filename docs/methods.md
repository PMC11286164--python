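# Methods

## Model

The simulator treats a capture thread as *N* parallel elements clamped at
both ends and loaded in displacement control. Because the external strain
`x` is imposed, equal load sharing is implicit: every surviving element sees
the same `x`, and "load redistribution" after a failure is simply the
shrinking force sum. No inertial or rate effects are modelled
(quasi-static), and no local load-sharing variant is provided.

Each element carries force

    F_el = σ(x_e) · d_rel²,    0 < x_e ≤ x_c
    F_el = 0                   otherwise,

with `σ` an odd polynomial through the origin with non-negative
coefficients (so σ(0) = 0 and σ is monotone), `d_rel` the relative fibre
diameter (area scaling as diameter squared — the standard mechanical
contract), and `x_e` the effective elongation

    x_e = x − Σ own slack − Cs · (upstream slack).

Negative `x_e` is legal and carries zero force: released loop length is
still straightening. Exceeding the applicable critical strain breaks the
element irreversibly.

**Looped elements** hold an inventory of loops, each with an opening
threshold and a hidden length. Loops open in ascending threshold order —
after every opening the effective elongation restarts from below zero, so
the smallest remaining threshold is necessarily reached first; ties are
broken by loop index. On opening, the accumulated slack grows by
*(threshold + hidden length)*: the new effective elongation is minus the
hidden length, i.e. the force across the structure resets to zero. This
"reset" rule is the default because it is what produces the observed
~4000% extensibility with the default parameters: each of a fibre's 200
loops contributes on average 0.150 + 0.038 = 0.188 of slack, so a looped
fibre survives to external strain ≈ 200·0.188 + 0.5 ≈ 38, and the maximum
over eight independent looped fibres lands near 40. A `slack_mode:
hidden_only` switch (slack grows by the hidden length alone) is available
for parametric study. While any loop remains unopened the element cannot
fail; afterwards it fails at a configurable post-loop critical strain
(default 0.5, mirroring the axial fibres — the failure criterion of
fully-unravelled looped fibres is not empirically constrained).

**Hierarchical coupling.** Each axial fibre receives upstream slack from
the *most elongating* member of its coupling set — the looped element with
the largest accumulated slack, by default the two undulating fibres —
scaled by the transmission coefficient Cs (default 0.999). This keeps the
axial fibre's effective elongation oscillating well below its 0.5 critical
strain until the undulating fibres run out of loops, after which it loads
terminally. An alternative reading (each axial bound to one specific fibre)
is expressible by giving each axial group a single-source coupling.

## Default parameters

| group | count | d_rel | law (GPa) | x_c | loops | threshold | hidden length | Cs |
|---|---|---|---|---|---|---|---|---|
| radial | 1 | 1.0 | linear E = 7 | 0.2 | — | — | — | — |
| axial | 2 | 0.2 | 0.1·ε + 5·ε³ | 0.5 | — | — | — | 0.999 → uf |
| uf | 2 | 0.175 | linear E = 7 | post-loop 0.5 | 200 | U(0.150 ± 0.145) | U(0.038 ± 0.002) | — |
| pc | 6 | 0.035 | linear E = 7 | post-loop 0.5 | 200 | U(0.150 ± 0.145) | U(0.038 ± 0.002) | — |

All `±` values denote the halfwidth of a uniform distribution — the only
distribution family the underlying model names. "200 loops" is per fibre
(1600 in total): loops are a per-fibre geometric feature. Stress is in GPa
and strain dimensionless; element force is σ·d_rel², so total force is in
arbitrary relative units — no absolute cross-sections are available, and
all headline quantities are strains and counts.

Two documented tensions in the source parameters are preserved, not
resolved: the undulating-fibre relative diameter (0.175) is *smaller* than
the axial one (0.2) even though the axial fibre is described as five times
thinner; and an alternative description ties loop thresholds to 0–300% of
the loop size (max ≈ 0.114) rather than the tabulated 0.150 ± 0.145
(max 0.295). The tabulated values govern the defaults; both variants are
reachable through the config file.

## Numerical scheme

The external strain ramps from 0 in fixed increments `dx` (default 0.005).
At each grid point, events are resolved to a fixed point: recompute every
effective elongation (coupled elements read the current slack of their
sources), open every loop whose threshold is reached, mark every failure,
and repeat until nothing changes, with an iteration cap of (total loops +
element count + 2) guaranteeing termination. Events land on grid points
rather than being bisected; the step-size-robustness test (halving `dx`
moves the default final strain by < 1%) bounds the discretization error.
Threshold and failure comparisons use a 1e-9 absolute tolerance so that
grid points landing exactly on a threshold trigger deterministically. An
element still carries force *at* its critical strain and fails on the first
grid point beyond it, so recorded per-element maxima can exceed the
critical strain by up to one `dx`.

The simulation stops at the first grid point where every element has failed
(recorded, with zero force) or at `x_max` (default 50). The *final strain*
is the last grid point with strictly positive total force.

Randomness enters only through bundle construction. Loop thresholds, hidden
lengths and sampled critical strains are drawn from independent substreams
keyed by (seed, group index, fibre index, quantity), so narrowing one
distribution never shifts the draws of another, and identical (config,
seed) pairs give identical bundles. Simulation itself is deterministic.

## Curve analysis conventions

* The *radial peak* is identified as the global force maximum (in both the
  modelled and empirical axial-test curves the radial failure dominates all
  later forces). This assumption fails for radial-free vertical-test
  curves, for which `summarize(..., radial=False)` reports only the overall
  peak and break strain.
* *Strain at break* is the largest strain with force above a noise floor of
  1% of the global maximum (configurable). This is a declared convention —
  break detection on noisy empirical tails is not otherwise defined. On
  simulated curves it can trail the true last-failure strain slightly when
  the last survivor is a thin paracribellar fibre whose terminal force sits
  below the floor.
* *Drop detection* turns each maximal strictly-decreasing run whose
  relative drop exceeds `min_rel_drop` into one event. On a single looped
  fibre this recovers the event log one-to-one; on the full bundle, small
  paracribellar teeth (relative force ~0.002) can be masked by the
  simultaneous elastic loading of the other ten elements, so detected drops
  are a large subset of logged events, not a census.
* Vertical-test geometry: a hook pulling the midpoint of a thread of
  half-length *h* by travel *t* gives strain `(2·√(h² + t²) − 2h)/(2h)`;
  balance readings convert as |grams| × 9.81 → mN (g = 9.81 m/s² exactly).

## What passing tests do and do not show

The default configuration *is* the study condition: simulations demonstrate
that the stated loop inventories and couplings reproduce the ~4000%
extensibility, the dominant early radial peak, and the ≤50% per-element
bound. They do not validate the model against real silk forces: empirical
peak forces are in mN and require material cross-sections the model does
not have, empirical sawtooth amplitudes vary more than the model's
(slip-stick effects during fracture are not modelled), and the cribellar
nanofibre mat is not represented by an element of its own. Adhesion and
peeling mechanics, viscoelasticity, humidity effects and strain-rate
dependence are out of scope.

## Problem sizes

The default acceptance computation averages the final strain over ten
seeded runs of the full 11-element, 1600-loop bundle at dx = 0.005
(~8000 grid steps each, under a second per run). The Monte-Carlo check of
the classic fibre-bundle closed form uses 10⁴ linear fibres on a 0.01
strain grid. Test fixtures use scaled-down inventories (3–30 loops) where
the closed-form opening schedule can be traced by hand.
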