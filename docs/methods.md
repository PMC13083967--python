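# Methods

This note documents the models inside `molkmc`, the parameters that matter,
the numerical choices, and what the synthetic systems do and do not
represent.

## Topology model

A chemical state is a molecular graph: atoms (element, type label, charge,
mass), bonds with harmonic parameters and an integer-ish *bond order*
(default 1), plus derived bonded terms. Angles are all length-2 simple bond
paths, proper dihedrals all length-3 simple bond paths, and 1-4 pairs all
atom pairs at shortest bond-graph distance exactly 3; after any bond edit
these are regenerated wholesale from the new graph, preserving parameters of
terms that survived and parameterizing new ones generically (bond r₀ = sum
of covalent radii, k = 50 kcal mol⁻¹ Å⁻²; angle θ₀ by central element,
k = 15 kcal mol⁻¹ rad⁻²; torsions carried but energetically inert in the toy
force field). Improper dihedrals pass through parsing untouched and are
never auto-generated — they encode chemistry a generic assigner cannot
guess.

Radicals are bookkept by **valence deficit**: an atom is a radical iff the
sum of its bond orders is below the nominal valence of its element
(H 1, C 4, N 3, O 2, S 2, P 3; table configurable), and the deficit is the
unpaired-electron count. Bond orders exist precisely so this rule works for
closed-shell chemistry: a carbonyl carbon with three graph neighbours but a
C=O of order 2 is correctly closed-shell. The convention survives arbitrary
recipe edits without any explicit spin attribute. Over-coordinated atoms
(possible after the dimerization recipe, which adds two bonds without
demoting the C5=C6 double bonds to single — a known simplification) clamp at
zero and are not radicals.

On disk, topologies use a section-based text dialect (`[ atoms ]`,
`[ bonds ]`, `[ pairs ]`, `[ angles ]`, `[ dihedrals ]`) with 1-based
indices and `;` comments; numeric fields round-trip at six significant
digits. Coordinates use XYZ or multi-MODEL PDB (three decimals), read and
written through MDAnalysis.

## Reactions as recipes

A reaction is an ordered list of elementary steps:

* `Break(i, j)` / `Bind(i, j)` edit the bond set (validated stepwise, so
  Break-then-Bind of the same pair is legal);
* `Place(atom, xyz)` overwrites one atom's coordinates in the working
  snapshot;
* `Relax` invokes the registered relaxation hook.

Bonded terms are regenerated once after the last bond edit; each `Relax`
then acts on the fully parameterized product topology. The default hook is
200 steps of steepest descent with a 0.02 Å per-step displacement cap on the
toy force field — enough to heal the locally distorted geometry a reaction
leaves behind. A gradual reactant→product parameter interpolation
(slow-growth relaxation) is deliberately not implemented; the hook contract
(product coordinates in, relaxed product coordinates out) is the extension
point for anything more elaborate.

Constructors cover the four built-in chemistries. Hydrogen atom transfer is
Break(H–donor), Bind(H–acceptor), Place, Relax; the hydrogen is placed
1.1 Å from the acceptor on the *donor side* of the donor→acceptor axis
(the physically sensible side; a zero-length axis falls back to x̂).
Hydrolysis uses an explicit water as the atom donor — Break(C–N),
Break(O_w–H_w), Bind(O_w–C), Bind(H_w–N) — so atom count is conserved and
the product is closed-shell; protonation states beyond that are ignored.
Homolysis is a single Break (two radicals by the valence rule).
Dimerization binds C5–C5′ and C6–C6′, forming the cyclobutane ring.

## Ensemble generation

The sampler integrates overdamped (position) Langevin dynamics,
x ← x + μF dt + √(2k_BT μ dt)·ξ, on the toy potential

* bonds: k(r − r₀)², k = 50 kcal mol⁻¹ Å⁻²;
* angles: k(θ − θ₀)², k = 15 kcal mol⁻¹ rad⁻²;
* repulsion: 2·(r − 2.5 Å)² for r < 2.5 Å between atoms at bond-graph
  distance ≥ 4 or in different molecules.

Its **only contract is the stationary Boltzmann distribution** at the
requested temperature; dynamics realism is explicitly not claimed. Two
choices follow from that contract:

* *Uniform mobility.* The stationary distribution of overdamped Langevin
  dynamics is independent of the per-atom mobilities, so all atoms share
  μ = 1/(3 u × friction) — hydrogen-mass repartitioning taken to its
  logical end. This equalises the stiffest modes and admits a 4 fs Euler
  step (λ·dt ≈ 0.05 for the stiffest bond mode, a ~3% variance bias, well
  inside the 10% thermostat tolerance).
* *Soft everything.* Euler stability caps μ·dt ∝ 1/k, so conformational
  exploration per step is inversely proportional to the stiffest force
  constant. The soft bonds/angles above are what make an octyl chain
  actually traverse its coil ensemble within affordable windows; a
  freely-rotating-chain calculation shows ~40% of conformers put C1 and C5
  within contact range, and the sampler must reach them. The repulsion
  constant is kept low (2 kcal mol⁻¹ Å⁻²) because a stiffer floor measurably
  compresses bonds in coiled chains and biases the bond-energy thermostat
  check.

The hot loop has a numba-jitted kernel; the pure-numpy implementation is
retained as the reference and the two agree to float round-off (asserted in
tests). Noise is drawn from one seeded `numpy` Generator in both paths, so
a given (seed, path) is bitwise reproducible. Non-finite forces raise with
the offending step index. PBC, electrostatics and solvent are out of scope.

Defaults (temperature 300 K, friction 5 ps⁻¹, dt 0.004 ps) hold for all
operations unless a run configuration overrides them.

## Rate models

* **Eyring**: k = (k_BT/h)·exp(−ΔG‡/k_BT) with k_B = 0.0019872
  kcal mol⁻¹ K⁻¹ and h = 9.5306·10⁻¹⁴ kcal mol⁻¹ s (so k_BT/h ≈ 6.26·10¹²
  s⁻¹ at 300 K). Ensemble combination averages *rates*, not barriers; by
  Jensen's inequality the ensemble rate is never below the rate of the mean
  barrier, and in practice the most reactive frames dominate — this is how
  conformational entropy enters the kinetics.
* **Surrogate HAT barriers**: a table keyed by shift class — 1-2: 36,
  1-3: 33, 1-4: 25, 1-5: 21, 1-6: 23, 1-7: 25, long-range: 26,
  intermolecular: 24, default: 28 kcal/mol — plus a 2 kcal mol⁻¹ Å⁻¹ penalty
  on the H–acceptor distance beyond the covalent 1.1 Å. The ordering encodes
  transition-state ring strain (six-membered ring of the 1-5 shift most
  favourable; three- and four-membered rings most strained); the magnitudes
  sit in the high-20s/low-30s range typical of condensed-phase HAT barriers.
  Any object with the same call signature (topology, H, acceptor, frame →
  barrier) plugs into the orchestrator, which is the intended seam for a
  learned predictor. Tunnelling is ignored, so absolute times are
  systematically long even where selection probabilities are sensible.
* **Bell homolysis**: k(F) = k₀·exp(FΔx/k_BT), k_BT in pN·Å via 1 kcal/mol
  = 69.48 pN·Å (41.4 pN·Å at 300 K). Defaults k₀ = 10⁻¹⁵ s⁻¹, Δx = 0.4 Å.
* **Heuristic hydrolysis**: k = k_ref · exp(α(F−F_ref)/(1+F/F_sat)) ·
  10^(pH−pH_ref) · SASA/SASA_ref with defaults k_ref = 10⁻⁷ s⁻¹ at
  F_ref = 1000 pN, α = 0.006 pN⁻¹, F_sat = 2000 pN, pH_ref = 7,
  SASA_ref = 50 Å². The force response saturates (exponent → α·F_sat), one
  pH unit is one decade (base catalysis), and solvent accessibility enters
  linearly. With the Bell defaults this reproduces the qualitative
  competition: both channels negligible at zero force (~10⁻¹⁰ s⁻¹ scale
  hydrolysis, 10⁻¹⁵ s⁻¹ homolysis), hydrolysis ahead by ~4 orders of
  magnitude at 1 nN, and an analytically guaranteed crossover force
  (≈3 nN at the defaults) beyond which the unbounded homolysis channel
  wins — the regime where hydrolysis tapers off and homolysis still scales.
  These constants are plausible-scale placeholders, not fits to any
  force-clamp dataset; all are run-configuration fields.
* **Dimerization**: rate = A·exp(−d/d₀)·cos θ for |θ| ≤ θ_max, else 0,
  with d the distance between the two C5=C6 bond midpoints and θ the
  torsion across them; defaults A = 10¹² s⁻¹, d₀ = 0.5 Å, θ_max = 60°,
  threshold 10⁸ s⁻¹. Frames above the threshold are dimerisable and the
  quantum yield ϕ is their fraction; ϕ is exact on constructed ensembles
  and matches the analytic window probability of the generating
  distributions on sampled ones. The parameters are meant to be tuned
  against measured quantum yields; only the cis-syn-like geometry is
  modelled (no trans isomers or 6-4 photoproducts).

## kMC engine

Rejection-free selection uses the cumulative probability function with the
boundary rule F(p_{i−1}) < u₁ ≤ F(p_i) taken literally (binary search,
`bisect_left`); zero-rate events can never satisfy it. u₁ and u₂ are drawn
on (0, 1] (never 0, so −ln u₂ is finite) and the generator is consumed
exactly twice per step. Total rates use compensated summation; the last
cumulative entry is pinned to 1.0 so a draw of exactly 1 cannot fall off
the list. The first-reaction method is an interface slot left
unimplemented. Event lists are built fresh from the current state's
ensemble each cycle (adaptive event-list generation): only visited states
are ever enumerated.

## Orchestration, determinism, checkpoints

Per-cycle sampler seeds are pure functions of (run seed, cycle index,
stream id) through `SeedSequence` spawn keys; the kMC generator is the only
stateful RNG and its exact state is serialised into every checkpoint (JSON:
topology text, coordinates, simulated time, PCG64 state, config echo).
Restoring therefore continues bitwise identically to an uninterrupted run,
and a fixed seed reproduces the full record list bitwise. An empty event
list triggers fresh re-sampling up to a configurable retry count (default
2) before halting gracefully. Equilibration after each reaction defaults to
2000 sampler steps in the canonical alkyl study (8 ps) — a pragmatic
compromise, not an auto-detected decorrelation time; it is a configuration
field.

## Synthetic systems and study conditions

The built-in fixtures are graphs with idealised geometry: all-trans
alkanes/alkyl radicals (3–8 carbons), a glycylglycine-like dipeptide with
one explicit water, and a stacked thymine pair with order-2 C5=C6 bonds.
They are chemically faithful at the connectivity/valence level; their
coordinates are only a starting point for sampling. The dimer-geometry
generator draws (distance, torsion) features from a zero-truncated normal
and a wrapped normal — a stand-in for features measured on real stacked-base
trajectories that reproduces unimodal spread but none of the multi-modal
structure (syn/anti states) of real DNA.

The canonical alkyl HAT study (`molkmc.studies`) runs the 1-octyl radical
at 500 K, 100 000 burn-in steps, per-cycle windows of 40 000 steps with 101
recorded frames, 2000-step equilibration, 30 kMC steps, twenty independent
seeds, HAT search cutoff 3.0 Å. These sizes were chosen so contact
geometries reshuffle between cycles while a full batch stays at desk scale;
passing them shows the pipeline ranks shift classes correctly under the
shipped barrier table, not that any real alkane kinetics are reproduced.
The thermostat check runs saturated octane at 300 K for 10⁵ steps and
discards the first fifth as burn-in.

## Known limitations

* Bond orders are edited only where recipes say so; the dimerization
  recipe leaves the former double bonds at order 2 (over-coordination is
  clamped in radical detection).
* The toy force field has no electrostatics, LJ attraction, or torsional
  barriers; conformational distributions are those of a soft excluded-
  volume chain, not of any specific force field.
* Rate-model constants are scale-plausible defaults, not fitted values;
  absolute simulated times inherit their uncertainty (and the absence of
  tunnelling) even where selection probabilities are robust.
* SASA is a user-supplied number, not computed from structure.
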