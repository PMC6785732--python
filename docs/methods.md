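# Methods

This note records the models, conventions and numerical choices behind
`permeon`, and what the synthetic-pore validation does and does not show.

## Coordinate and unit conventions

Internal units are Angstrom, picosecond and kcal/mol; converters for
nm/kJ inputs live in `permeon.units`. The permeation axis is +z by
convention (intracellular → extracellular); a pore model with
`axis_direction="-z"` flips every landmark comparison rather than
transforming coordinates. Temperature is fixed at 310 K
(kT = 0.616 kcal/mol) to match the thermostat of the simulations the
analyses target. The elementary charge uses the SI-exact value.

Trajectories store one dense `(frames, particles, 3)` array over a fixed
labeled particle set. PDB reading/writing is delegated to biotite; the
plain-text columnar format (`frame time_ps id x y z box_x box_y box_z`)
round-trips float64 losslessly and is the interchange format of the
pipeline. Ion z-traces are unwrapped with a minimum-image rule on
successive frames (jump threshold `box_z/2`) before any event counting,
because the counting logic presumes continuous traces.

## Event detection: committed crossings

Gate flicker makes naive single-plane counting ill-defined, so an event
requires a *committed* traversal: from below `lower − margin` to above
`upper + margin` (default margin 2 Å) without retreating behind the
entry-side committed plane. The margin default is a design choice of this
package; it makes detection robust to frame-stride halving in the
scripted scenarios, which the tests assert. For recycled (periodic)
trajectories, where an unwrapped trace climbs k box lengths after k
transits, crossings are counted against every periodic image of the
interval that the trace spans — equivalent to counting transits of the
physical pore.

Rates are per-run counts over simulated time; group statistics use the
sample (n−1) SD, which reproduces the bundled reference table's printed
group spreads exactly. Conductance is `g = N·e/(t·V)`; it is flagged
undefined at zero voltage rather than reported as infinite.

## PMF by Boltzmann inversion

`G(z) = −kT ln n(z)` on 0.5-Å slices between the intracellular entrance
and the SF end, with ions counted inside a radial cutoff (default 8 Å,
configurable — the defining radius is not standardized in the
literature). Zero-count bins are masked, never pseudo-counted; the
profile is referenced to its minimum (a convention choice — the zero
line is otherwise arbitrary); across-run aggregation reports per-bin mean
and sample SD over runs where a bin is sampled in at least two runs, with
a block-SD alternative deliberately omitted in favor of the across-run
spread. Because the occupancy is sampled under an applied field, the
profile is *effective-biased*: it contains the bias by construction and
no reweighting is attempted.

## Geometry

Minimum distances scan all inter-selection atom pairs (shipped
selections are heavy-atom only); the gate aperture uses the narrower of
the (A,C) and (B,D) opposing-pair distances per frame, with the G-loop
selection spanning residues 316–320. Dihedrals follow the IUPAC sign
convention and were cross-checked against mdtraj. The TMD↔CTD rotation
is the torsion between the planes (TMD-COM, CTD-COM, TMD-subunit-COM)
and (TMD-COM, CTD-COM, CTD-subunit-COM) relative to a reference
structure; the sign is fixed so that counterclockwise rotation viewed
from the extracellular side prints negative, matching the convention of
the bundled rotation table (all entries negative). Centers of mass use
unit masses by default — the topology carries no masses, and on bead
clouds the difference is a configuration choice, not an assumption; a
mass table can be supplied. Collinear degenerate geometries yield NaN
for that frame rather than an arbitrary angle. Histogram bins are
left-closed, right-open, anchored at zero; threshold fractions are
computed on the raw series, so they are exact.

## Solvation and hydration

Distance boundaries are closed (a water at exactly the cutoff counts).
The pore axis for radial tests is the instantaneous x–y centroid of the
SF selection when one resolves (tracking channel drift; trajectories are
superposed on the SF backbone first in the pipeline), else the box
center. The G-loop passage extractor centers a 4 Å × 4 Å cylinder on the
COM of all G318+M319 atoms of all four subunits — atom subsets are not
standardized, so all atoms are used.

## Hydrogen bonds

Donor–acceptor distance ≤ 3.5 Å and hydrogen–donor–acceptor angle ≤ 30°,
the convention of the widely used trajectory tools. Hydrogens are
associated to donors by a 1.25 Å proximity rule in the first frame. In
systems without hydrogens the detector switches to an implicit mode
(distance-only, records flagged); salt bridges are reported through this
mode with N/O heavy atoms.

## Selectivity-filter mechanism

Site windows derive from six boundary z-values (from the carbonyl-plane
beads of the pseudo-protein, or from configuration); windows are
left-closed, so a particle exactly on a boundary belongs to the lower
site. A site prints K if it holds at least one ion (ions take priority
over waters), W for water, 0 for empty. The T153-entrance region is
treated as part of the cavity compartment, not a sixth site. An event is
*direct knock-on* iff no frame in its window shows a W between two K
symbols and no water co-permeates; *water-mediated* iff every ion–ion
gap holds a W; otherwise *mixed*. Water co-permeation uses the same
committed-crossing rule applied to water traces, with a ±1 ns pairing
window around the event — ion exits happen within a few ns, so a 1-ns
tolerance pairs a water with the event it actually accompanied.

## The synthetic pore

The generator emulates the statistical structure of channel-MD data, not
its physics. Defaults mirror the target study's conditions: 20-ps frame
stride (the write-out interval of the source trajectories), 310 K,
580 mV over a 145-Å box, K⁺ diffusion 0.2 Å²/ps (bulk-like), 50,000
frames (1 µs); analyses and tests pass smaller `n_frames` — desk-scale
problem sizes chosen by this package and stated with each result.

- **Ions**: overdamped Euler–Maruyama on U(z) plus the field force, 10
  substeps per frame (fixed step = stride/substeps; the simplest
  integrator with a known stationary distribution). Radial confinement
  is a reflecting cylinder whose radius narrows at gate windows and in
  the filter (1.5 Å: single file).
- **Gates**: two-state telegraph processes (rates in 1/ns). A closed
  gate narrows the confinement radius *and* raises a 6 kcal/mol Gaussian
  barrier at the gate plane — radial confinement alone cannot block an
  on-axis ion, so the steric term is what makes flicker modulate flux.
  Default kinetics give the G-loop an open fraction of 0.55 and the HBC
  0.91, reproducing the qualitative picture of a flickering cytoplasmic
  gate under a mostly open bundle crossing.
- **Filter rule**: after each frame, ions in the filter are reassigned
  bottom-up to distinct sites; an ion pushed past S0 exits — the direct
  knock-on displacement. This conserves ion count and never co-locates
  two ions in one site (property-tested).
- **Waters**: non-interacting tracers diffusing on the effective
  potential −kT ln ρ(z) of the configured relative density profile (so
  the profile is the stationary distribution), integrated at substep
  resolution; the filter is water-free when single occupancy is enabled.
  Solvation re-seeding moves waters onto/off a 2.6–3.4 Å shell so ions
  outside the filter hold the configured hydration number (default 6,
  a bulk-like K⁺ first shell). The default water count (480) gives the
  toy cavity a bulk-like density, ~80 waters in the cavity slice.
- **Scheduled-flux mode**: permeation events arrive as a Poisson process
  at a configured rate; each event is a constant-speed transit of
  exactly one box length (so recycling is a clean periodic wrap), with
  small positional noise. Planted events give exact ground truth for
  rate-recovery tests.
- **Scripted scenarios** are frame-exact and noise-free so detector and
  classifier tests are deterministic; each phase is held for several
  frames so results are invariant to stride halving.

What passing the synthetic validation shows: the analysis operators
recover planted rates, potentials, geometries and mechanisms from data
with the right label structure, noise and periodicity. What it does not
show: anything about force-field physics, real gate energetics, water
orientation, or electrostatics — the generator has none of these, by
design.

## Validation problem sizes and tolerances

- PMF recovery: 4 ions, 2×10⁵ frames (tests; 5×10⁴ in the acceptance
  script), D = 0.5 Å²/ps for fast mixing, planted barriers of 2.0 and
  1.5 kcal/mol; RMSE threshold 0.15 kcal/mol, with expected statistical
  error ≈ 0.04–0.08 kcal/mol from effective-sample counting.
- Equilibrium sampling: KS distance < 0.05 against exp(−U/kT) at 5×10⁴
  frames, the bound implied by the ~36-frame mixing time of the
  reflected diffusion.
- Drift: mean velocity within 10% of mobility × force at 4×10³ frames.
- Water profile: reduced χ² < 3 with a Poisson + 2% systematic error
  model (the 2% floor covers Euler discretization at the substep size).
- Rate recovery: pooled detected counts within 3σ Poisson of λt for
  λ = 5, 15, 30 events/µs over 5 seeds of 1 µs each.
- Rotation recovery: constructed rotations within 0.01°.

## Known limitations

- The pseudo-protein scaffold is rigid apart from gate beads and thermal
  jitter; RMSD analyses on it are exercised, not stressed.
- Water–water and ion–water interactions are absent; hydration numbers
  are enforced, not emergent.
- The scheduled-flux mode plants at most one transiting ion per slot and
  keeps resident filter ions out of the way, so multi-ion correlation
  statistics in that mode are trivial by construction; use the
  free-diffusion mode with single occupancy for correlated-file studies.
- Event detection assumes the pore axis is a fixed z-interval after SF
  superposition; severely tilted channels would need a frame-local axis,
  which is not implemented.
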