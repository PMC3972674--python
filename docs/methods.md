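# Methods

## The modeling framework

`spatialrules` couples a rule-based reaction description to a coarse-grained
particle simulation. A model has three ingredients, each a plain-text table
or a short rule file:

1. **Elementary molecules** — named types with binding sites and optional
   modification states, written in a BNGL subset:
   `A(a,a,b~none~mod)` declares a monomer with two interchangeable binding
   sites `a` and a site `b` carrying a `none`/`mod` label.
2. **Reaction rules** — site-graph patterns with BNGL bond labels:
   `A(a) + A(a) -> A(a!1).A(a!1) kon` defines an implicit, unbounded family
   of polymerization reactions. Omitted sites are wildcards; a mentioned
   site without `!` must be unbound; `!+` means bound to anything, `!?`
   leaves the bond state unconstrained. Rules are unidirectional (a
   reversible reaction is two rules), conserve molecules, and are classified
   as bind / unbind / modify / modify-propagate from the difference between
   their two sides. `+`-separated pattern complexes must map to distinct
   particles but may belong to the same assembled complex, so ring closure
   is a matter of geometry, not of the rule language.
3. **Geometry** — each molecule is a sphere. When no measured radius is
   available it follows from the molecular mass `m` under a constant-density
   assumption calibrated to histone H3: `r(m) = 15.00 Å · (m / 15 kDa)^(1/3)`.
   Binding sites sit on the surface in spherical coordinates (polar angle
   from the zenith, azimuth, reach; the reach defaults to the radius, i.e.
   reactions happen on contact). A site without declared angles is
   isotropic — the whole surface is reactive and no angular veto applies.
   Multi-sphere **structural templates** (flexible bead chains, or rigid
   bodies such as nucleosomes and microtubules) represent complexes with
   known shape; rigid templates are integrated as rigid bodies and conserve
   their internal distances exactly, and templates may be anchored at a
   fixed position while remaining free to rotate.

### Pattern matching semantics

`match_pattern` enumerates every injective embedding of a pattern into the
world's site graph. Interchangeable (identically named) sites make several
assignments describe the same rewrite; embeddings related by such
permutations are deduplicated by default (a flag restores the raw count), so
a symmetric dimerization does not double its propensity. The matcher is
validated against an independent brute-force enumerator on all small worlds
in the test suite.

### Dynamics

Particles follow overdamped Langevin (Brownian) dynamics in a reflective
box. Reduced units: energies in kT, lengths in Å, friction γ = 1, so the
free diffusion coefficient is D = kT/γ. Per step each free particle moves
by `F·dt/γ` plus Gaussian noise of per-axis variance `2·kT·dt/γ`. Forces:

* **Excluded volume** — Lennard-Jones truncated at its minimum (purely
  repulsive), σ = sum of the two radii, ε = 1 kT, with a per-pair force cap
  (4 kT/Å) so transient overlaps relax instead of exploding. Directly
  bonded pairs are excluded, making a bond's rest state force-free.
* **Bonds** — harmonic springs, rest length = sum of the two site reaches
  (template-internal bonds: the distance at which the template placed the
  members, so templates start unstressed).
* **Angles** — optional harmonic terms whose equilibria derive from the
  declared site angles; off by default and unused by the bundled model.
* **Centering drag** — a harmonic pull applied outside a sphere around the
  reactor centre. It keeps the dilute reactor contents near the structure
  being assembled without forcing a uniform distribution.

Rigid bodies aggregate member forces into a net force and torque; the
rotation update uses Rodrigues' formula on exact member offsets, so rigid
internal distances drift only at floating-point level (measured < 1e-12 of
the diameter over 1e5 steps). A per-axis displacement cap of 10 Å per step
bounds the motion of pathological force spikes (a standard Brownian-dynamics
limiter); an integration step that would exceed half the box still aborts
with a diagnostic.

Stability note: the overdamped update is stable only while the total
stiffness acting on a particle satisfies Σk·dt/γ < 2. Hub particles can
carry eight or more bonds, which bounds the usable bond stiffness at a given
step size; the presets below respect this margin.

### Reactions in space

Reactive free sites are tested for encounters every `react_interval` steps
(10 by default) with a KD-tree. A bimolecular bind rule fires when the two
particle centres come within the sum of the two site reaches plus 10% slack,
the rule is enabled (switches), any declared site angles point within a 45°
half-cone, and a per-encounter probability (the rule's rate, default 1)
accepts. Candidate pairs are processed in RNG-shuffled order and a site
binds at most once per sweep. Unimolecular rules (unbind, modify,
modification propagation) fire per matched embedding with probability
`1 − exp(−k·Δt)` where Δt covers the steps since the last sweep. Rules whose
patterns carry extra context (modification states, bound neighbours) are
verified against a full pattern-match before firing.

An optional **seeded-growth** mode restricts binding to pairs in which at
least one partner's complex touches a designated anchor; the bundled
kinetochore model uses it so that, initially, only the nucleosomes can bind
anything and assembly grows outward from chromatin.

Trajectories are bit-reproducible for a fixed seed: all randomness
(placement, noise, encounter ordering, acceptance) flows from one seeded

generator, and noise is pre-generated outside the compiled kernel so the
numba-accelerated and pure-Python integration paths produce identical
output.

## Structure analysis

Given two structures `p`, `q` with matched particles:

* positional RMSD removes translation by fixing an anchor particle at the
  origin and rotation by aligning the two rays from the anchor to two
  reference particles (an exact two-ray alignment, deliberately not a
  least-squares superposition);
* paired RMSD is the RMSD of all pairwise inter-particle distances with
  prefactor 2/(n²+n) (the inner sum includes the vanishing diagonal
  terms), invariant under rigid motion of either structure;
* local RMSD clips every distance at a cutoff C before comparing, so only
  sub-cutoff structure contributes; it converges to paired RMSD as C grows.

Distance matrices over replicate runs are clustered with a hand-implemented
UPGMA (size-weighted average linkage; merge height = average inter-cluster
distance, not halved; ties break on the smallest label pair). The tree
exports to Newick; `scipy.cluster.hierarchy` serves as an independent
cross-check in the tests, never as the implementation.

Bond statistics: per-rule realized fractions over replicates (final bonds
summed over runs divided by runs × per-run capacity, the capacity being the
smaller partner's copy number × site multiplicity), per-rule bond-count
histograms, and nucleosome-bridge analysis. Two bridge quantities are
reported: `bridge_count` (for each pair of anchor groups, is there a bond
path between them that avoids every other anchor group?) and
`rosette_bridge_count`, the spanning count `n_groups − n_components` of the
anchor-contracted bond graph — the number of bridges actually holding the
rosette together, with additional links between already-joined nucleosomes
counted as cross-links rather than bridges.

## The bundled kinetochore model

The packaged tables define 49 proteins (masses and radii) and 67
deduplicated pairwise interactions spanning the CCAN inner kinetochore, the
KMN outer kinetochore and the spindle assembly checkpoint (SAC). Almost
every protein exposes one specific site per listed partner, so all its
partners can bind simultaneously. Two hub proteins are the exception:
Zwint shares one docking site between Knl1 and Mis12 (it engages one
*instead of* the other) and Mps1 shares one docking site between its
kinetochore receptors Mis12 and Hec1; each keeps a separate site for its
remaining partner (Zw10, BubR1). This exclusivity is what makes the
corresponding interactions sub-stoichiometric in the assembled structure.

Complexes with known elongated shape — the Mis12, Ndc80, Mad1:Mad2, RZZ and
APC complexes, and CenpC/T/Q — are flexible bead chains whose adjacent
members are pre-bonded (through the listed interaction sites where one
exists, otherwise through structural link sites). The Ska complex is a
w-shaped six-bead dimer and the microtubule a rigid 25 nm-diameter cylinder
of tubulin beads; both appear only in the attached variants. Nucleosomes
are rigid eight-bead particles (two copies each of the centromeric histone
plus core histones) packed within ~10 Å of their centre; the second CenpA
bead is inert so the effective CenpA copy number is one. Histone masses,
Ska subunit masses, the tubulin bead and all template coordinates are
synthetic fixture choices (documented in the data files), not published
values.

The simulated scene is the mitotic rosette: the CenpA nucleosome fixed at
the origin, six H3 nucleosomes fixed on a regular hexagon 14 nm away (free
to rotate in place), and everything else — six copies of each protein and
mobile template, except one CenpA and two CenpN — placed uniformly in
x ∈ (−400, 400), y ∈ (−400, 800), z ∈ (−400, 400) Å. A centering drag
(sphere radius 250 Å, strength 0.02 kT/Å²) keeps the reactor contents
available for assembly. Binding is assembly-only (probability 1 per
encounter, no unbinding) because the source data provide interaction lists,
not kinetic rates; the four variants differ in microtubule count (0–3), the
SAC switch (on only when unattached; attachment also enables unbinding of
SAC-gated bonds), and a three-fold copy-number increase when two or more
microtubules are present.

Kinetochore preset numerics: dt = 1.0 (per-axis noise σ = 1.4 Å, about a
tenth of the smallest bead radius), bond stiffness 0.2 kT/Å² (stable for
hub particles with many bonds, see the stability note), encounter tests
every 20 steps. The reference protocol is 6×10⁶ steps with snapshots every
5×10³; the desk-scale campaigns in the tests and the acceptance script use
5×10⁵ steps and 6–16 replicates, at which point the bond count has
plateaued and the rosette is fully connected in nearly every run.

## What the desk-scale campaigns do and do not show

At the reduced scale the model reproduces: the full geometry table from
masses alone; the 7.5 nm CenpB+CenpW bridge-impossibility argument (the
short CCAN bridge never appears in simulation); near-complete rosette
assembly (mean ≈ 5.3 of 6 spanning bridges joining the seven nucleosomes,
with many cross-links); and sub-stoichiometric Zwint–Mis12 binding driven
by docking competition with Knl1. The competition outcomes are, however,
only qualitatively right: we measure Zwint–Mis12 near 50% (reported ~30%)
and Hec1–Mps1 near 50% (reported ~10%, with ~65% of runs lacking the bond
entirely — we see almost none). Both discrepancies have the same origin:
the suppression of these contacts in the source model rests on the detailed
shapes and binding angles of its structural templates, which are not
published. With published-data-only geometry — isotropic surface sites on
mass-derived spheres — a hub's competing receptors split roughly by
encounter cross-section and anchoring order (Mis12 complexes anchor early
through CenpC, Knl1 late through the SAC proteins; Hec1 is as exposed as
Mis12 and larger), so neither contact drops to the published level. We
chose not to invent angular site data to force the published numbers; the
discrepancies are reported as measured.

The synthetic generator (random placement + Brownian assembly) emulates
crowding, diffusion-limited encounter and geometric reach constraints; it
does not emulate binding kinetics (no rates), conformational change,
or chromatin mechanics, so passing tests demonstrate geometric and
combinatorial consistency, not kinetic realism.

## Numerical and degenerate-input choices

* Angle unit: degrees in all files, radians internally.
* UPGMA ties break deterministically on the smallest label pair; an
  all-zero matrix yields a tree with all merge heights 0.
* `local_rmsd` with C = 0 is 0 by definition; `paired_rmsd` rejects empty
  structures; positional RMSD rejects collinear or coincident anchors.
* Placement retries 200 times per copy before failing (reactor too small).
* Overlapping template members warn but build (rigid nucleosomes are
  intentionally denser than free spheres).
* Seeds: every run derives all randomness from one integer seed; campaign
  seeds are spread with fixed odd multipliers and kept below 2³¹.

## Known limitations

* Free particles carry no rotational state; declared site angles are
  evaluated in the declared body frame, which is exact for rigid bodies and
  approximate for free spheres. The bundled model therefore uses isotropic
  sites throughout.
* The reflective boundary acts on free particles and rigid-group centroids;
  a rigid body grazing a wall may transiently poke members past it.
* No hydrodynamic interactions, no NPT/pressure control, no in-simulation
  change of a molecule's geometry.
* Bimolecular encounter testing every N steps slightly undercounts contacts
  briefer than N steps; N trades accuracy against speed.
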