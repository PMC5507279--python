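# Methods

`rpsim` simulates a minimal RNA-world ecosystem of two molecular species —
replicases (R), which can copy other molecules, and parasites (P), which
can only be copied — as individually tracked Brownian agents on a 2D
torus.  This note documents the model, the numerical choices, the
parameters that matter, and what the desk-scale test protocol does and
does not establish.

## The model

Each free molecule carries two scalar attributes in [0, 1]: an affinity
towards replicases *a* (how readily replicases bind it, and how stable
the resulting complex is) and a folded-state probability *l* (the
fraction of time it is folded and hence unavailable as a template).
Catalysis is unaffected by the catalyst's own folding; only the
*template's* attributes enter any rate.

Dynamics per discrete step of length Δt:

- **Diffusion.** Every entity moves by `sqrt(2 D Δt) ξ` with ξ a pair of
  independent standard normals; free molecules use D, bound pairs the
  (much smaller) complex coefficient D′.
- **First-order events** (decay, complex dissociation, replication) are
  memoryless: a waiting time `-ln(u)/k` is drawn once at creation and
  counted down in whole Δt units; "expired" means ≤ 0 after the step's
  decrement.
- **Collision and binding.** Two molecules can react when their center
  distance is strictly below `r_i + r_j` (default 1, one lattice cell of
  the ancestral cellular-automaton model).  On its turn, a free molecule
  scans its neighbor set in random order and binds the first partner that
  passes the test `u < ω = a_t (1 − l_t)`, where the template *t* is the
  parasite of the pair, or the non-initiating replicase if both are
  replicases.  Two parasites never bind.  The complex appears at the pair
  midpoint with a replication clock at rate K and a dissociation clock at
  rate `1 − a_t`.
- **Replication vs dissociation race.** K is enormous (239 800), so the
  replication clock expires at its first decrement; a complex therefore
  replicates unless its dissociation clock expired within the same first
  step.  This yields the closed form `P(replicate) = exp(−(1 − a_t) Δt)`,
  which the test suite verifies by Monte Carlo.  The offspring copies the
  template's species and attributes, each attribute then mutating with
  its configured probability by a uniform offset on [−δ, +δ], clamped to
  [0, 1]; the complex releases both components immediately afterwards.
- **Crowding.** An entity that sees more than `n_max` neighbors on its
  turn is removed (resource limitation); a removed complex counts as two
  molecule deaths.
- **Recording.** Every step, counts and attribute means/standard
  deviations per species are recorded over the whole population,
  including molecules bound in complexes (this keeps the series
  continuous across binding events; a flag-free full-scan recount is
  exposed as `observables.record` and cross-checked in tests).

A run ends at the step limit or as soon as either species count
(complexed members included) reaches zero.

## Clock semantics in complexes, and offspring placement

Two points of the scheduler are under-determined by its sources, and both
turn out to decide whether the ecosystem is viable at all:

- **Decay of complexed molecules.**  With the published decay rate
  d = 0.182 (mean lifetime 5.5 steps) the maximum achievable birth rate
  per molecule-step — one offspring per pair per two-step bind-and-fire
  cycle, times the replication-race factor — is ≈ 0.185.  If lifetime
  clocks keep running inside complexes, deaths (0.182 per molecule-step)
  cancel births even at the crowding-capped density and every
  configuration collapses within a few hundred steps.  `rpsim` therefore
  defaults to **frozen** clocks: component lifetimes pause at complex
  formation and are restored on release, which halves effective mortality
  and lets local growth ignite.  The alternative ("ticking", with
  mid-complex death freeing the partner) is implemented behind the
  `decay_mode` flag.
- **Offspring placement.**  Placing the offspring a full collision
  distance away adds a reproductive advection that speeds replicase
  fronts up enough to outrun their parasites, which then starve; placing
  it at the complex position (the default, `offspring_offset = 0`)
  reproduces the published phenomenology — traveling waves / "explosions
  of life" with parasites riding the back of each replicase wave.  The
  offset is a config knob.

## Parameters

| name | default | units | meaning |
|------|---------|-------|---------|
| d | 0.182 | 1/step | decay rate of free molecules |
| D | 0.75 | len²/step | free-molecule diffusion coefficient |
| D′ | 0.0476 | len²/step | complex diffusion coefficient |
| K | 239 800 | 1/step | replication rate (effectively instantaneous) |
| Δt | 1 | step | time step |
| r | 0.5 | len | agent radius (collision distance 1) |
| n_max | 8 (class default), 6 (presets) | – | crowding cap |
| δ | 0.05 | attr. units | mutation half-width |

D and D′ derive from the ancestral lattice model by matching per-step
displacement variances (`ca_conversion`): a free lattice molecule hops to
one of its 8 Moore neighbors (variance 3/2 per step), giving
D = 3/(4Δt) = 0.75; a complexed molecule hops with probability
p′ = (d_CA/2)/(d_CA/2 + k_CA) and center-of-mass variance 2p′, giving
D′ = p′/Δt = 0.0476.

`n_max` is nowhere given by the model's sources.  The class default 8 is
the Moore-neighborhood capacity the crowding rule emulates; the presets
use 6, calibrated (before any quantitative target was measured) as the
value that maximizes desk-scale coexistence lifetime: caps ≥ 16 let
parasites overrun every replicase wave, caps ≤ 5 starve the waves.

The mutation kernel (additive uniform, clamped) and δ = 0.05 are declared
modeling choices; clamping rather than reflection matches the observed
absorption of evolved affinities near 1.

## Randomness and determinism

One xorshift64* stream drives everything; a (seed, config) pair fully
determines a run, byte for byte, regardless of attached observers.  Draw
order per step: processing-order shuffle; then per entity — neighbor-set
shuffle (free molecules only), two normals for the move, then any
reaction/replication draws (mutation decision+offset for a then l,
offspring lifetime, placement angle; or ω test, replication clock,
dissociation clock).  The array compaction schedule is a deterministic
function of the state so it cannot perturb trajectories.  Box–Muller
supplies normal pairs; uniform draws for waiting times are taken from
(0, 1] so `ln(0)` cannot occur.

## Problem sizes (desk scale)

The published experiments track populations in the millions for 150 000
steps; that is far beyond a single-CPU desk run.  The package's scaled
presets use a 256×256 torus with 2 500 + 2 500 molecules started in
opposite half-discs of radius 45 and horizons of 16 000–20 000 steps
(populations grow to ~10⁴–10⁵).  This is the smallest arena at which the
wave ecosystem is viable: at 128–160 the handful of waves synchronize and
one species dies within a few thousand steps.  The acceptance script
trims horizons further (12 000 steps, trailing-4 000-step averages) to
keep the full recomputation within a desk-time budget; the evolved
attribute averages it reports converge well before those horizons.

What desk scale shows: ignition and wave formation, the
replication-dissociation race law, the evolved-attribute equilibria
(collapse of replicase folding, saturation of replicase affinity, the
parasite folding equilibrium in fixed-affinity sweeps), and the fast
extinctions of non-viable settings.  What it does not show: indefinite
coexistence.  With few waves the global boom–bust cycles eventually drive
one species extinct even in configurations the full-scale system
sustains; "survival" at desk scale therefore means coexisting through the
desk horizon, and quantities are measured over the final window of the
coexistence period.  The initial transient is also a stochastic
bottleneck — a run has an appreciable chance of collapsing in its first
few hundred steps (cheap to detect) — so the survival protocols try
seeds from a fixed sequence and analyze the runs that coexist through
the horizon, the desk analogue of the published
median-over-surviving-seeds protocol.

Two full-scale results shift systematically at desk scale and are
reported as such rather than adjusted for:

- with only parasite folding mutable, the within-wave pull towards
  virulent (low-*l*) parasites outweighs the between-wave selection that
  restores the average at full scale, so the parasite folding
  equilibrium settles around 0.05–0.15 rather than the published 0.2–0.3
  band;
- the viable window of fixed parasite affinities narrows and shifts
  down: the a_P = 0.5 start coexists robustly (plateau ≈ 0.05, at the
  published level for its neighborhood), while a_P = 0.4 dies in the
  initial transient (evolutionary rescue of sub-threshold parasites
  needs larger populations) and a_P = 0.6 parasites overrun their hosts
  within ~1000 steps.

## Known limitations

- Scalar attributes only; no sequences, no genotype-phenotype map.
- Fixed replication fidelity and rate; no metabolism or resources beyond
  the crowding cap.
- The spatial-uniformity half of the published stabilization criterion is
  not implemented (no clustering statistic is defined for it);
  `detect_stabilization` tests only the trailing-window slope of the
  attribute means.
- Single-threaded by contract (one RNG stream defines the trajectory).
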