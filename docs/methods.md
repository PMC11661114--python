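# Methods

`prd` simulates stochastic reaction–diffusion dynamics of spherical
particles and rigid multi-site molecules in a reflecting box, in 3D, in 2D
on a membrane at z = 0, and transitioning between the two, with a
spatially decomposed parallel engine layered on the same kernels.  This
note records the model, the numerical choices, and what the validation
suite does and does not establish.

## Pair reaction model

Bimolecular association is resolved per reactive site pair.  A pair at
separation r0 with summed diffusion constant D = D1 + D2 reacts within one
timestep Δt with the probability obtained by integrating the Green's
function of the Smoluchowski equation with a radiation boundary at the
contact radius σ, parameterized by the intrinsic rate ka:

    p(Δt | r0) = (σ/r0) · ka/(ka + kD) · [ erfc(x) − e^{2xy+y²} erfc(x+y) ]
    x = (r0−σ)/√(4DΔt),   y = α√Δt,   α = (√D/σ)(1 + ka/kD),   kD = 4πσD

evaluated with the scaled complementary error function so large arguments
cannot overflow.  The macroscopic (diffusion-convolved) rate observed in
well-mixed kinetics is kon = (1/ka + 1/kD)⁻¹; conversions in both
directions, their 2D analogues, the finite-density 2D trap radius
b_ρ = 2√(S/(π n) + σ²) and the steady-state 2D rate live in
`prd.rate_theory`.  Internally all rates are nm/µs quantities
(1 µM⁻¹s⁻¹ = 1.66054 nm³/µs); file I/O converts at the boundary.

In 2D no closed form exists; the survival problem is integrated by
Crank–Nicolson on the radial backward equation with a Robin boundary at σ
and tabulated per (rule, D, Δt) for linear interpolation in r0.  The table
converges to ~4 digits at the default resolution and agrees with a
fine-step Brownian-dynamics oracle within its statistical error.

Diffusion constants entering pair kernels are those of the *complexes*
(friction-additive, below), refreshed as assemblies grow; membrane-bound
pairs of rules carrying a projection length h use the 2D kernel with
ka2D = ka3D/h and in-plane separations.

### Reflecting walls: method of images

The free-space kernel underestimates reaction near a reflecting face
(partner density "beyond the wall" is physically reflected back).  For
every box face within the cutoff the engine adds the kernel evaluated at
the image separation (reflecting one partner across the face), which
restores the uniform-bath flux integral exactly for single faces; corner
(double-reflection) terms are neglected and leave the measured flux ~1%
low in a 100×100 nm² channel — the thinnest benchmark geometry.  For a
partner residing on the membrane the z-image coincides with the partner
itself, doubling the near-membrane kernel; this is the half-space Green's
function limit, and makes the realized per-trap rate of a membrane-bound
partner equal to the macroscopic kon of the rule, consistent with how the
3D↔2D benchmark rates are defined.

### Cutoffs and timestep

A pair farther apart than Rcut = σ + 3√(2dDΔt) + l1 + l2 (site arms l)
cannot react within Δt; the system cutoff (max over rules) sets the
sub-volume size and the parallel ghost width.  The density-limited maximal
timestep equates the 3σ diffusional reach with the nearest-neighbor
spacing, Δt_max = [(3/(4πρ)+σ^d)^{1/d} − σ]²/(18d(D1+D2)); `prd validate`
reports both.  Pairs beyond Rcut are not evaluated; the neglected tail of
the flux integral is ≲10⁻⁹ of the total at the benchmark parameters.

## Rigid bodies

Molecules are rigid arrangements of interface sites around a center of
mass, oriented by unit quaternions.  Bound molecules form complexes that
translate and rotate as one unit; per-axis translational and rotational
diffusion constants compose by friction additivity (1/D sums over
members), which reproduces the dimer diffusing at half the monomer rate. A
membrane-bound member pins the z axis (and restricts rotation to the
membrane normal).  Brownian updates draw per-axis Gaussian displacements
(variance 2DΔt) and small-angle rotations (variance 2DrotΔt per axis,
composed exactly), keyed to the complex's stable lead id.  Reflection at
the box faces mirrors the complex center of mass; members of a complex
hugging a face may transiently protrude.

Association places the two sites at separation σ along the bond axis.  By
default the axis is the stationary partner's center-to-site direction, the
mobile partner (the faster-diffusing complex; never a membrane-bound one)
is rotated so its own site arm is anti-parallel to the axis, and the body
normals are aligned by a final rotation about the axis.  Monomers whose
two site arms subtend the ring's interior angle (60° for a trimer, 120°
for a hexamer, 120° triskelion legs for the lattice) then produce closed
rings and flat lattices with the final site pair landing at exactly σ, so
no per-rule angle table is needed; explicit five-angle specifications are
stored on rules for models that need them.  If the placed geometry puts
any other reactive site pair (within the merged complex or against a
third party, at frozen positions) inside its σ, the event is rejected and
the state reverts — volume is excluded between reactive partners only.

Dissociation removes a bond at the intrinsic rate kb = koff·ka/kon; if the
complex fragments, the pieces are displaced to σ + 10⁻³ nm along the
former bond axis and subsequent re-encounters are handled by the ordinary
pair kernel, which is what turns the intrinsic rate back into the
macroscopic koff.  A ring bond dissociates without any displacement (the
complex stays connected); the open ring can re-close as a loop-closure
event: free intra-complex site pairs geometrically within 20% of σ close
at kclose = ka·c0·exp(−ΔG_coop/kBT) with c0 = 0.6022 nm⁻³ (1 M).  At the
benchmark parameters kclose·Δt exceeds 1, so the per-candidate probability
is clamped at 1 and rings close within a step of becoming eligible; every
other channel is orders of magnitude slower, so the clamp has no kinetic
consequence.  Because geometry is rigid, closure candidates are cached per
complex and recomputed only on topology changes.

Implicit membranes replace explicit lipids by a depletable surface
density ρ_free.  A binder site at height z binds within Δt with the 1D
half-space radiation-boundary probability at surface reactivity
κ = ρ_free · k_trap, where k_trap = (1/ka + 1/(4πσD))⁻¹ is the pair's
macroscopic rate — the same per-trap rate an explicit membrane particle
realizes — so the implicit and explicit routes give matching kinetics
(verified within 3 SEM).  Binding decrements the free pool (restored on
unbinding) and adds the lipid's friction to the complex.

## Order of operations and conflict resolution

Each step: (a) zeroth-order creations per sub-volume; (b) first-order
events (dissociation, loop closure, decay, implicit unbinding), sampled
per member with probability k·Δt (warned above 0.1, refused above 1);
(c) pair probabilities over cutoff-limited candidates from the cell list
(cells ≥ Rcut plus the site-arm allowance; each unordered pair enumerated
once via 13 forward neighbors); (d) acceptance draws and execution;
(e) Brownian propagation of all complexes that did not react, with
overlap screening; (f) bookkeeping.  A molecule and a site undergo at most
one reaction per step: events are ordered canonically by (gid_lo, gid_hi)
and an accepted event is voided if any canonically earlier accepted event
shares a molecule (one-hop rule; chains of voided events are not
re-awarded, which loses a fraction ~(Σp per molecule)² ≈ 10⁻⁶ of events).

Overlap screening is Metropolis-like: a proposed move that would bring a
reactive site pair inside its σ *and* closer than it started is rejected
and the complex simply does not move that step.  Re-drawing alternative
moves instead would sample only the outward part of the proposal
distribution near contact and measurably deplete the contact shell (a ~5%
loss of association flux at the oligomer benchmark density); stay-put
rejection preserves the equilibrium measure.  Moves are screened against
frozen step-start neighbor positions so all decisions are concurrent;
mutually moving pairs can therefore transiently overlap, and such pairs
are evaluated at contact (r0 := σ) until diffusion separates them.

## Randomness and parallel execution

Every stochastic decision draws from a counter-based hash of (seed, step,
channel, global ids) — splitmix64-style mixing, Box–Muller for normals —
never from a sequential stream, and every floating-point reduction over
complex members runs in global-id order.  Decisions are therefore
independent of enumeration order and of the spatial decomposition.

The parallel engine splits the box along x into per-rank intervals
aligned to sub-volume columns.  A rank holds its owned molecules plus
ghosts: the neighbor's two boundary columns, complexes duplicated in
their entirety when any member enters that window, and two further shells
of reaction partners around duplicated complexes — the visibility needed
to decide every event that can touch an owned molecule (one-hop conflict
resolution requires seeing the candidates of a candidate).  With keyed
draws each rank computes identical updates for shared molecules, so the
staggered protocol — first-order events, pair probabilities, left-half
reactions/diffusion, leftward serialize/send/merge, right half, rightward
exchange, migration cleanup — is pure data motion, and loopback runs at
p = 1, 2, 4 are asserted *bitwise identical* for every benchmark system:
a strictly stronger property than the statistical serial-vs-parallel
agreement the method requires.  Serialized batches are flat octet buffers
keyed by global ids (schema-versioned; round-trip bit-exact); migration
follows the center of mass, and copies that leave the window are dropped.
A consistency audit (unique ownership, bitwise-identical ghost copies,
fully resident complexes, resolvable bonds) runs in the tests.  The
transport is an abstract contract; the deterministic in-process loopback
backend is used throughout, and a message-passing backend (mpi4py) can be
slotted in where that library is available.

The largest complex must not exceed half a rank's interval (checked at
decomposition); multi-level schemes for larger assemblies are out of
scope.  Decomposition is x-only; y/z decomposition is future work.

## Reference solutions and statistics

* Reversible bimolecular kinetics: closed-form two-root solution;
  equilibrium from the quadratic root.
* Ring-oligomer assembly: mass-action ODEs auto-generated with
  per-distinguishable-site-pair statistical factors (chain join flux
  2·kon·c_i·c_j for i≠j, kon·c_i² for i=j; every bond breaks
  independently; chains beyond the ring size are sterically excluded).
  Optionally diffusion-aware: the intrinsic pair rate is reconvolved per
  species pair with Einstein–Stokes complex diffusion D/k, which the
  simulation exhibits and a single-kon ODE misses at the few-percent
  level.  Ring opening uses the intrinsic kb (an intra-complex event with
  no diffusional re-encounter); the ring/chain equilibrium ratio is
  kclose/(n·kb).
* Ring equilibrium ladder: c_n = K^{n−1}c1^n with
  c_ring = (kclose/(n·kb))·K^{n−1}c1^n, solved for c1 by bisection with
  monomer conservation to 10⁻¹⁰; agrees with the ODE steady state to
  machine-level tolerance.
* Membrane adsorption: a 1D-in-z method-of-lines diffusion–adsorption
  solver with a saturating reactive bottom boundary serves as the
  continuum reference for 3D→2D kinetics.
* MSD/Deff: origin-constrained weighted slope of MSD(lag), with errors
  from independent particle groups (overlapping-window and cross-lag
  correlations make the naive SE optimistic).
* Scaling metrics: S(p) = T1/Tp, Estrong = T1/(p·Tp), Eweak = T1w/Tpw
  from measured wall-clock timings; the package computes the metrics but
  makes no claims about absolute wall-clock behavior, which is
  hardware-bound.

Statistical comparisons in the validation suite use three standard
errors.  With three trajectories a per-time-point SEM has two degrees of
freedom, so SEMs are pooled over the time course; species with expected
occupancy below ~1 complex carry a Poisson floor (an empirical SEM from
windows shorter than the occupancy correlation time underestimates); and
kinetic matches additionally test the trajectory-resolved time-averaged
offset, which is the quantity a systematic rate error would move.

## Benchmark systems and desk-scale conditions

`prd.validation_observables.build_benchmark` generates the benchmark
model files programmatically: reversible A+B in 3D (10⁴ copies each,
D = 10 µm²/s, kon = 100 µM⁻¹s⁻¹, koff = 10 s⁻¹, σ = 2 nm, box
[20000, 2000, 2000] nm, Δt = 0.1 µs); C+D purely in 2D (ka2D = 0.53
nm²/µs, kb2D = 15.9 s⁻¹, σ = 2 nm, D = (2,2,0) µm²/s); E+F from 3D to an
explicit 2D particle and G+H to an implicit density field (kon = 55
µM⁻¹s⁻¹, koff = 5.5 s⁻¹); trimer and hexamer ring assemblers (two-site
monomers, 60°/120° interior angles, σ = 0.73/1 nm, Drot = 0.1 rad²/µs,
with both published box/rate pairings); and triskelion lattice assembly
on an implicit membrane (three 120° legs, an adaptor protein bridging to
lipids, four reaction lines including an adaptor-bound cooperativity
variant with ΔG_coop = 2.3 kBT).  Site-arm lengths (1 nm for ring
monomers, 10 nm triskelion legs) and the E+F/G+H contact parameters
(σ = 1 nm, h = 2 nm) are fixture choices where no published value exists.
The macroscopic oligomer rates invert to round intrinsic rates
(ka = 20 or 100 nm³/µs, kb = 1000 or 10 s⁻¹) at the stated σ, which both
cross-checks the table and fixes the loop-closure rates.

The `scale` knob shrinks box and copy numbers together, preserving
concentrations, rates, Δt and geometry conventions, so desk-scale runs
probe the same kinetics with larger statistical errors.  Deviations the
suite runs with: the 3D A+B desk validation uses Δt = 2 µs (well under
its density limit of ~3.3 µs at that concentration, and the per-pair
kernel is exact in Δt) so the near-equilibrium tail is reachable; the
trimer kinetics validation runs the quarter-scale variant, where the
3-SEM band (~1%) sits above the ~0.3–0.5% fast-assembly residual of the
unreweighted free-propagator scheme (below); the
hexamer equilibrium validation starts *from* the theoretical species
distribution and verifies the dynamics preserve it over many bond
lifetimes, because the absolute ring-turnover time at the published rates
(~0.4 s: a ring must shed a member before the near-instant re-closure) is
beyond any desk-scale run; and the implicit/explicit membrane equivalence
uses Δt = 0.25 µs where the per-step adsorption discretization is small.

## What passing tests do and do not show

The synthetic benchmarks start well-mixed with ideal (point or rigid)
geometries and literature-style rate magnitudes; they exercise the
kernels, bookkeeping and parallel protocol, not the biology of any real
system (crowding, flexible linkers, hydrodynamics, heterogeneous
membranes are all absent, and the lattice model's parameters are
illustrative).  Known numerical limitations: the free-propagator update
is applied without trajectory reweighting, so surviving-pair statistics
are approximate — at the benchmark rate regimes the measured flux error
is at the percent level, inside the validation tolerances, but strongly
diffusion-limited reactions (kon approaching 4πσD) would show larger
biases; corner image terms are neglected; concurrent (frozen-neighbor)
moves allow transient overlaps that are resolved by contact-rate
evaluation and subsequent diffusion; and the implicit-lipid propensity is
a constructed uniform-field model validated only by equivalence with the
explicit-particle route.
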