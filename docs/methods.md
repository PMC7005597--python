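# Methods

## The docking model

glowdock samples rigid-body placements of a ligand protein around a fixed
receptor protein. A placement (*pose*) is a translation plus a unit
quaternion; rotation acts about the ligand's coordinate centroid so that
the two parameter blocks stay approximately decoupled during optimization.
Candidate poses are grouped into *swarms*: sampling loci anchored a fixed
distance outside the receptor surface, each holding an independent
population of *glowworm* agents.

Interface information enters at three points:

- **S1 — swarm filtering.** For every receptor-side restraint residue
  (active or passive), only the `swarms_per_restraint` (default 10) swarm
  centers nearest that residue's representative atom (CB; CA for glycine)
  are kept; the union over restraints is the sampling set. With no
  receptor restraints all swarms survive.
- **S2 — ligand pre-orientation.** When ligand-side restraints exist, each
  initial pose is re-oriented so the unit vector from the ligand centroid to
  a randomly drawn ligand restraint atom aligns with the unit vector from
  the swarm center to a randomly drawn receptor anchor. The remaining spin
  about that axis is fixed by a *second* randomly drawn restraint pair
  (closed-form in-plane alignment) whenever both sides offer at least two
  restraints; with a single pair the spin is uniform random. Orientation
  from restraint pairs is what seeds agents near the implied binding
  orientation — with one pair and a random spin only ~10% of agents start
  in the native orientation sector. Both steps use passive restraints;
  passivity only exempts a residue from S3.
- **S3 — scoring bias.** At every evaluation the fitness is scaled by the
  fraction `s` of satisfied *active* restraints: `f·s` for `f ≥ 0` and
  `f·(2−s)` for `f < 0`. Full satisfaction is the identity; any `s < 1`
  strictly worsens a nonzero fitness, continuously in `s`. The functional
  form is a deliberate reconstruction — the simplest rule with those three
  properties — and is isolated in `scoring.bias_score` so alternatives can
  be swapped in.

### Restraint-satisfaction cutoffs

A residue restraint is *satisfied* when any atom of its residue lies within
a cutoff of any partner atom. Two cutoffs exist deliberately:

- the **interface-definition cutoff** (3.9 Å, the LIGPLOT contact
  convention) defines the true interface and the scenario constructors;
- the **runtime satisfaction cutoff** (default 10 Å) is what S3 uses during
  optimization.

The runtime cutoff must be wider than the interface definition: swarm
centers start roughly `ligand bounding radius + 5 Å` off the surface, so
under a 3.9 Å runtime cutoff every starting pose of a swarm would have
`s = 0` and (because the bias is multiplicative) identically zero biased
fitness — no luciferin gradient, no movement. A 10 Å horizon gives
near-contact poses a restraint gradient while still penalizing
wrong-patch poses; it is configurable (`satisfaction_cutoff`).

## Scoring

The potential is a distance-binned, atom-typed pair potential (the shape of
DFIRE-class statistical potentials): atom types are (residue name, atom
name) tokens, distance bins have upper edges `e_1 < … < e_K`, and a
receptor–ligand atom pair at distance `d < e_K` contributes the tabulated
energy of its (type, type, bin). Energies are *loaded*, never derived: the
text format (`scoring.load_scoring_table`) accepts any converted published
parameter set; the test fixtures carry a small synthetic table. Energies are
summed over inter-molecular pairs only; fitness = −energy. Hydrogens and
atoms without a table type are skipped and counted.

Two implementations coexist and must agree: small systems use one dense
C-level distance matrix against a precomputed per-atom-pair energy lookup;
large systems use a receptor k-d tree with per-atom ball queries. The test
suite pins both against an explicit Python double loop at 1e-9.

## Glowworm swarm optimization

Each agent holds a pose, a luciferin level and a vision radius. Per step:

1. fitness of every (moved) agent is evaluated through S3;
2. luciferin decays and accumulates fitness: `l ← (1−ρ)l + γJ`;
3. each agent picks a brighter visible neighbor with probability
   proportional to the luciferin difference and steps toward it — a fixed
   translation step along the connecting line and a fixed slerp fraction of
   the orientation gap;
4. vision radii adapt toward a target neighbor count:
   `r ← clamp(r + β(n_t − |N|), 0, r_s)`.

Defaults: ρ = 0.4, γ = 0.6, l₀ = 5, n_t = 5, β = 0.08, translation step
0.5 Å, rotation step 0.1, 100 steps, 200 glowworms per swarm. Two details
matter and were learned the hard way:

- **No luciferin floor.** Clamping luciferin at zero erases the brightness
  ordering on landscapes where every pose scores below zero (e.g. a pure
  quadratic well used as an analytic test), freezing the swarm; luciferin
  here is an unconstrained decaying trace of fitness, as in the original
  algorithm.
- **The translation step overshoots.** The step is not capped at the gap to
  the target: an agent closer than one step passes through and beyond it.
  This overshoot jitter is the algorithm's only local-search mechanism — a
  capped step can never improve on the best *initial* sample, which on a
  docking landscape (agents start ~13 Å off the surface) means no descent
  into a binding site at all. Convergence onto a fixed attractor is
  therefore into a band one translation step wide, not monotone onto the
  point.

Neighborhoods use a hybrid SE(3) metric: Euclidean translation distance
plus `w·(quaternion geodesic angle)` with w = 10 Å/rad; the default vision
range is `r_s = r₀ = 4·jitter` (8 Å for the 2 Å jitter default). Under this
metric agents with strongly differing orientations are mutually invisible,
which partitions a swarm into orientation sectors that optimize
independently — deliberate niching: widening the range to cover the full
orientation spread makes the whole swarm collapse onto one early consensus
and measurably *hurts* native-pose recovery on the toy benchmark.

Swarms are independent; a single run seed fans out to per-swarm generators
by `sub = (seed + 0x9E3779B1·(stream+1)) mod 2³¹`, so results are
reproducible and independent of swarm execution order.

## Evaluation

CAPRI-style quality against a native complex: fnat over 5 Å any-atom native
residue contacts; l-RMSD over ligand backbone after least-squares
superposition of the receptor backbone; i-RMSD over the backbone of native
interface residues (10 Å definition) after superposition on those atoms.
Classes: high (fnat ≥ 0.5 and l-RMSD ≤ 1 or i-RMSD ≤ 1), medium
(fnat ≥ 0.3 and l-RMSD ≤ 5 or i-RMSD ≤ 2), acceptable (fnat ≥ 0.1 and
l-RMSD ≤ 10 or i-RMSD ≤ 4), else incorrect. Models are ranked globally by
descending biased fitness (per-swarm truncation is available but off by
default); the Top-N success rate over a case set is the percentage of cases
with at least one non-incorrect model among the N best. `post_filter`
implements the a-posteriori baseline: discarding ranked models whose
restraint satisfaction falls below a threshold, without having used the
information during sampling.

## Synthetic complexes (what they test, and what they do not)

`fixtures.generate_toy_complex` builds both partners from reduced 5-atom
residues (N, CA, C, O, CB) on a jittered 5 Å lattice. The receptor is a
two-layer slab whose top layer carries an L-tetromino-shaped hole with a
raised pedestal beneath it: a chiral, deliberately shallow binding cavity.
The ligand is an L-tetromino block matching the hole; it bottoms out on the
pedestal at ring level, so most native contacts are lateral wall pairs that
a pose hovering an Angstrom or two above the native placement still keeps
(making near-native sampling detectable by fnat). The block is lowered
straight in until just above a 2.5 Å clash margin and then refined by a
greedy rigid-body descent of a surrogate contact energy, so the bound pose
is a genuine local optimum of the energy shape the toy table encodes. Chirality is the point: an L-tetromino has no
in-plane rotational symmetry and a distinct mirror image, so no flipped or
spun insertion fits — without it, symmetric nestings are iso-energetic with
the native pose and "recovering the native" is ill-defined.

The synthetic scoring table puts a firm but climbable repulsive wall below
3 Å (steep enough to forbid interpenetration, shallow enough that the
optimizer's 0.5 Å overshoot jitter near the native pose is not punished
into a needle-thin basin), an attractive well over native contact distances
(3–4.5 Å) and a weak tail to 15 Å that gives distant swarms a gradient
toward the receptor. Wells are *contrastive*: atom-type pairs that occur in
native contacts keep the deep well while all other type pairs get a quarter
of it, so decoy packings that pair different atom types score visibly
worse. Per-pair energies also get a ±10% seeded perturbation so the table
is not uniform.
Construction is verified by sampling: the bound pose must outscore every
random rigid perturbation with ≥ 2 Å displacement (the generator raises
otherwise).

These fixtures exercise every pipeline contract — interface detection,
scenario construction, filtering, pre-orientation, biased optimization,
CAPRI classification — under a controlled energy model with a known global
optimum. They do **not** emulate real protein docking: no side-chain
packing, no unbound-to-bound conformational change, no rugged physical
energy surface, no false minima of a real potential. A passing toy
benchmark says the machinery drives poses to the optimum its scoring
function defines when the information points there; it says nothing about
the accuracy of any particular potential on real complexes.

## Restraint scenarios

From the true interface (TI) of a bound complex the eight standard
degradations are constructed per side: TI (unchanged); TI_50 (a random half
of the TI padded back to size with false positives); TI_25 (a quarter,
padded 3:1); TI_REC / TI_REC_50 / TI_REC_25 (receptor side only); TI_SINGLE
(the single closest real-contact residue pair); TI_ONE (that pair's
receptor residue alone). False positives are non-interfacial residues
ranked by an exposure proxy (few heavy-atom neighbors within 10 Å of the
representative atom) and grown greedily into a patch contiguous with the
retained true residues, so true + false residues form one plausible but
partly wrong interface. Replicates (2 for halves, 4 for quarters) retain
disjoint blocks of one seeded shuffle drawn before any other randomness, so
equal generator seeds guarantee disjointness.

## Toy benchmark problem sizes

The self-contained benchmark used by the tests and the acceptance script
runs 10 seeded toy complexes; per case one TI run, two TI_50 replicates and
four TI_25 replicates, each with 200 generated swarm centers (dense enough
that a center sits over the binding cavity), 30 glowworms per filtered
swarm and 100 optimization steps. These sizes are the
package's study conditions for the toy system: large enough that TI
recovery is reproducible across seeds, small enough to run on one CPU in
minutes. Production defaults (400 swarms, 200 glowworms) remain the
documented CLI defaults.

## Known limitations

- Rigid-body only: no backbone or side-chain flexibility enters the
  optimization variables.
- The bias functional form and the patch-growth rule are reconstructions
  (documented above) — equivalent in spirit, not guaranteed identical in
  detail, to any published implementation.
- The exposure proxy is a neighbor count, not a solvent-accessible surface
  area; it ranks residues correctly on compact globules but has no absolute
  physical scale.
- Success statistics quoted anywhere in this repository are toy-scale
  statistics on the synthetic benchmark above, not protein-benchmark
  results.
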