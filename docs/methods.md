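# Model and methods

`spindlesim` is an agent-based, three-dimensional stochastic model of how
spindle microtubules find, attach to, and error-correct their connections
with chromosomes during prometaphase/metaphase, and of how depletion of
CKAP5 (ch-TOG/XMAP215) — modelled purely as a weakening of the
kinetochore–microtubule coupling spring — changes the outcome.

## Geometry and agents

A spherical cell of radius `r_cell = 10 um` contains two static centrosomes
(spindle poles) at `(±d_cent, 0, 0)` with `d_cent = 6 um`, and `n_ch = 80`
chromosome pairs. Each pair is a rigid body for translation, described by a
centre, a unit sister axis and a sister separation; the two sister
kinetochores (KTs) sit at `centre ± (sep/2)·axis`. The arm centre, where
the polar ejection and steric forces act, coincides with the pair centre.
Each pole nucleates `n_mt_per_pole = 600` astral microtubules (MTs): rays
with a fixed anchor, a unit direction, a length and a growth state. Tips
are clipped at the cell boundary.

## Forces

* **Polar ejection.** Chromosome arms are pushed away from each pole with
  magnitude `A_pe·exp(-x/L)` (`x` = distance from that pole); both poles
  contribute. The exponential prefactor encodes the assumed exponential
  decay of astral MT density with distance, so no per-MT hit counting is
  done. `L = 5 um` is the average-MT-length scale shared with the boundary
  force.
* **kMT–KT attachment spring.** An attached MT's tip is re-aimed at its KT
  every step, so tip, KT and pole are collinear; the signed extension is
  `e = d − l − l0` (`d` = pole–KT distance, `l` = MT length, `l0 = 0.1 um`
  rest length). Tension (`e > 0`) pulls the KT poleward with force `K·e`,
  unbounded. Compression (`e < 0`, tip at or past the KT plate) pushes the
  KT away from the pole with force capped at `f_push` — a polymerizing
  plus-end pressing on the kinetochore cannot exert more than a stall-scale
  force. The cap matters: with the control stiffness
  (`K_kmt_kt = 20 pN/um`) the cap (`f_push = 5 pN`) is reached at a 0.35 um
  overshoot, whereas the CKAP5-depleted spring (`K_kmt_kt = 2 pN/um`)
  rarely builds more than ~1 pN of push before a catastrophe intervenes.
  This asymmetry is the model's main engine of control-specific error
  correction by transport: strongly coupled (control) chromosomes parked at
  a pole are pushed back toward the spindle midzone, weakly coupled
  (depleted) ones are not.
* **Sister cohesion.** A Hookean spring of stiffness `K_cohesion = 40
  pN/um` and rest length `l_cohesion = 1 um` links the sisters along their
  axis.
* **Steric repulsion.** Pairwise inverse-square repulsion
  `A_ch_ch/d²` (`A_ch_ch = 7 pN·um²`) between arm centres, distance-floored
  at 0.1 um. Besides preventing overlap it disperses unattached
  chromosomes through the cell, which keeps the search-and-capture targets
  from competing for the same MTs.
* **Boundary.** Inward force `A_boundary·exp(-x/L)` (`x` = distance to the
  wall, `A_boundary = 20 pN`).

## Motion

Overdamped first-order dynamics: the pair centre moves by
`F_body·dt/gamma_ch` with a single drag coefficient `gamma_ch = 20
pN·s/um`; the sister separation evolves under the axial component of the
per-KT forces with the same drag, bounded to [0.2, 2.5] um; the sister
axis re-aligns instantaneously with the resultant of opposing kMT pulls
whenever both sisters are attached (torque-free quasi-static rotation).
Stability requires `K_kmt_kt·dt/gamma_ch < 1`; the defaults give 0.5.

## Microtubule dynamics

Free MTs grow at `v_g = 0.2 um/s`, shrink at `v_s = 0.35 um/s`, and switch
with rescue frequency `f_r = 0.05 /s` and catastrophe frequency
`f_c = 0.075 /s`, sampled per step as `1 − exp(−rate·dt)`. A fully shrunk
free MT is re-nucleated in a fresh uniformly random direction. Attached
MTs instead use load-corrected switching: a shrinking kMT rescues with the
per-step probability `1 − exp(−F/f_s)` set by its current tensile load
(`f_s = 5 pN` stall force), and a growing kMT catastrophes at the
length-dependent rate `R_cat·l` (`R_cat = 0.06 /(um·s)`). The
length-dependent catastrophe both keeps kMT tips near their kinetochores
and generates the periodic tension excursions that drive force-dependent
error correction. An optional `R_cat_free` adds the same length dependence
to free MTs (default 0: off).

## Search and capture

Any free MT whose anchor–tip segment passes within `r_kt = 0.6 um` of an
eligible KT attaches with probability `p_capture = 1` (at most one new
attachment per MT per step; the nearest eligible KT wins). A KT is
eligible while its pair is not amphitelic and its occupancy is below
`n_max = 3` MTs. On capture the MT is converted to end-on: re-aimed at the
KT with length `d − l0`, so the spring starts at rest.

## Attachment classes and error correction

Pairs are classified from the per-KT, per-pole occupancy table:
merotelic (either sister holds MTs of both poles — checked first),
syntelic (both sisters attached, one pole), amphitelic (both sisters,
opposite poles exclusively), monotelic, unattached.

* **Amphitelic pairs are absorbing**: inter-KT tension stabilises them, so
  no kMT detaches and no new MT attaches. Their kMT dynamics (and hence
  plate oscillation) continue.
* **Force-dependent detachment.** Every other attached MT detaches
  stochastically. On a single-pole KT the rate is
  `R_detach·exp(F/F0)` with `F` the magnitude of that MT's (bounded)
  spring force, `R_detach = 1.2e-2 /s` and `F0 = 2.5 pN`. The exponent is
  written `F/F0` because a dimensionful force cannot be exponentiated;
  `F0` is of the order of the stall force and was calibrated jointly with
  `R_detach` against the control census.
* **Merotelic (dual-pole) kinetochores** use
  `R_detach·(n_i/n_j)·exp(F/F0)·exp(beta_sign·beta)`, where `n_i` counts
  the MTs on that KT from the considered MT's own pole, `n_j` those from
  the opposite pole, and `beta` is the angle between the KT→tip vector and
  the KT→sister direction.

### The angle convention

With `beta` measured toward the sister, an erroneous kMT (one pointing at
the same pole its sister is attached to) has small `beta`, the correctly
oriented one `beta ≈ pi`. Which sign of the exponent corrects errors is
genuinely ambiguous in the underlying biology literature, because the
angle can be referenced to either end of the inter-KT axis. We exposed the
sign as `beta_sign` and let the attachment census arbitrate. The
calibrated default is `beta_sign = +1`: kMTs aligned with the sister
direction (the established, syntelic-side fiber) are protected and the
opposite-pole newcomer on a dual-pole KT is preferentially shed, so
merotely created when a searching MT strikes an already-attached KT is
rejected quickly and the standing merotelic population stays at the
observed trace level. Algebraically this is identical to `exp(−beta)`
with `beta` measured from the outward sister axis, with `R_detach`
rescaled by `e^pi`. The opposite sign (erroneous MT shed first) is
available via `beta_sign = -1` but leaves a standing merotelic population
an order of magnitude too large under otherwise matched conditions.

## The CKAP5-depleted condition

The `mutant` preset changes exactly one number: `K_kmt_kt` drops from 20
to 2 pN/um. Everything that differs downstream is emergent: weaker springs
transmit smaller loads, so force-dependent detachment and the capped
polymerization push both lose their corrective power; syntelic pairs park
at and behind the poles instead of being expelled; about a third of
chromosomes remain syntelic after 20 simulated minutes with a small
merotelic residue, and bi-oriented KTs freeze with more MTs attached
because fewer are shed before bi-orientation.

## Time stepping and reproducibility

One step applies, in a fixed order: force assembly → overdamped motion →
MT length/switching dynamics → search-and-capture → error correction →
reclassification; `dt = 0.5 s`, `t_end = 1200 s` (~20 min, long enough for
control cells to bi-orient). All stochastic kernels draw from a single
seeded stream; each ensemble replicate reseeds from a
`SeedSequence`-derived 31-bit integer of `(base_seed, index)`, so results
are independent of execution order and bit-reproducible. Detachment,
switching and capture events use exponential waiting-time per-step
probabilities, so no `rate·dt ≤ 1` constraint is needed; the per-step form
of the load-dependent rescue makes the rescue cap weakly dt-dependent,
which is why the census dt-stability check is part of the test suite.

## Calibration

The published model parameter table is not reproduced in the text
available to us, so every constant above is either a standard order of
magnitude for mitotic mechanics (speeds, stall force, geometry) or was
calibrated, once, against the published in-silico census (control:
essentially all amphitelic with at most trace errors; depleted: ~33%
syntelic, ~0.56% merotelic) and the qualitative statements about
chromosome positioning. After calibration the control census saturates at
100% amphitelic — slightly cleaner than the published ~0.07% syntelic and
~0.4% monotelic/unattached residues, which we could not reproduce without
degrading a primary target. Ensemble sizes: published statistics average
2000 cells; the test suite and acceptance script use 200 cells per
condition (and 40–50 per sweep point), which resolves all the targeted
contrasts at their sampling error.

## What the model does not contain

No explicit motor proteins, no fibrous-corona remodelling, no MT–MT
interactions or tubulin pool, no kinetochore geometry beyond a capture
sphere, no spindle assembly checkpoint or anaphase: the run simply stops
at `t_end`. Chromosome arms are a point of force application; rotational
dynamics reduce to the quasi-static axis realignment. Passing tests
therefore validate the model's internal logic and its agreement with the
published in-silico statistics, not the mechanics of real spindles.

## Known limitations

* The per-step interpretation of the load-dependent rescue makes the
  effective rescue force cap scale like `sqrt(dt)`; census statistics are
  nevertheless stable under dt halving at the tested resolution.
* The axial spread of bi-oriented chromosomes is narrower in the depleted
  condition than in the control, opposite to the published ordering; see
  the discussion of steric crowding in the test suite — the control's
  larger bi-oriented population forms a thicker plate at any steric
  amplitude we probed without breaking capture.
* With the default calibration the control census has no residual errors
  at all; the published trace levels presumably reflect parameter choices
  we could not recover.
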