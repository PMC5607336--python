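# Methods

`dnadamage` simulates the chain of events between a charged-particle
traversal of a cell nucleus and the tally of DNA double-strand breaks
(DSBs), normalised the way pulsed-field gel electrophoresis (PFGE)
experiments report them. This note describes the model stage by stage: its
assumptions, the parameters that matter, the numerical choices, and what
the synthetic stages do and do not claim about real data.

## Genome geometry

The genome is hierarchical. A nucleotide pair is six spheres — two
phosphates (radius 0.27 nm), two 2-deoxyriboses (0.29 nm) and two
complementary bases (0.30 nm) — wrapped in a hydration-shell volume
(radius 1.25 nm around the pair centre) standing for the tightly bound
inner water layer, which can transfer ionisation damage to the backbone.
Overlapping spheres are cut against each other; the cuts are realised as
the power diagram of the arrangement (a point belongs to the containing
sphere of smallest power distance `|x−c|² − r²`), which is exactly the
radical-plane half-space construction and makes the volumes disjoint by
construction. The hydration shell is split into two half-shells by the
plane separating the strands so that shell energy is attributable to a
specific strand; this matters because a strand break is strand-specific.

Pairs stack along a fibre path with a 36°-per-pair helical twist carried
by parallel-transported frames. The DNA wraps ~1.65 turns around each
histone sphere (radius 2.4 nm, wrap radius 3.3 nm, pitch 2.4 nm — a
canonical nucleosome-like superhelix; the exact internal winding is not
critical because only the genomic indexing and the constituent positions
feed the damage scoring). Nucleosomes sit on a solenoid (6 per turn,
helix diameter 10.46 nm) around the fibre axis of a 50 nm cubic voxel.
Five voxel kinds tile space: `straight` (fibre axis crossing between
opposite faces, 23 nucleosomes, 4860 pairs) and four quarter-turn kinds
(11 nucleosomes, 2459–2470 pairs) whose axis is a quarter circle of
radius 25 nm joining orthogonal faces (arc length 39.3 nm, matching the
configured 39 nm fibre length). Because the per-kind pair totals are not
divisible by the nucleosome count, pairs are apportioned to the path
segments proportionally to arc length with largest-remainder rounding, so
the totals are met exactly.

Domains are 500 nm spheres (configurable) filled with voxels on a 50 nm
grid clipped to the sphere; a self-avoiding walk chooses the voxel kinds
so the fibre is continuous (exit face of each voxel abuts the entry face
of the next; dead ends backtrack within a bounded budget). Chromosome
territories are placed directly as compact groups of non-overlapping
domain spheres inside the ellipsoidal nucleus (default half axes 9.85,
7.1, 2.5 μm); this replaces a condensation/relaxation simulation of
territory shapes, which is out of scope — territory morphology does not
enter the damage scoring, only the genomic index does. Base identity is
drawn uniformly per pair at fill time; the four bases share one sphere
radius, so sequence only affects the chemistry bookkeeping (which base an
OH radical hit), not the geometry.

At desk scale the defaults are two chromosomes of two domains each inside
a 1.2 × 0.9 × 0.6 μm nucleus; per-bp semantics are identical to the full
configuration, and all conservation invariants (pair counts per voxel,
domain, chromosome and genome) hold exactly at any scale.

## Synthetic tracks

The physical stage is a parametric stand-in for track-structure physics.
Primaries start uniformly on a rectangle above the nucleus (default
16 × 12 μm, shadowing 92% of the nucleus volume) and travel along −z.
Deposits are placed along the vertical chord through the ellipsoid as a
Poisson process whose linear density is LET divided by the mean deposit
energy, so the expected deposited energy per unit path equals the
configured LET (1 keV/μm ≡ 1 eV/nm); per-track energy bookkeeping is
exact by construction. The per-deposit energy spectrum is an explicit
model input: shifted exponential with minimum 5 eV, mean 45 eV, capped at
500 eV — the scale of small ionisation/excitation clusters. Lateral
spread is Gaussian (σ = 5 nm) as a stand-in for secondary-electron
transport. Deposits carry an interaction label (ionisation, excitation,
attachment, elastic) with configurable fractions.

Each deposit is attributed to a volume by the geometry index. Two
datasets result: deposits inside DNA volumes (constituents plus hydration
shells) feed the direct-damage criterion; deposits inside a chromatin
voxel but outside DNA become water-radiolysis seeds (ionised water,
excited water, or a solvated electron for attachment) and feed the
chemistry stage. Seeds outside every voxel are dropped — chemistry is
simulated only where DNA can be reached. Because the deposit spectrum and
clustering statistics of real track structure are not modelled, absolute
damage yields are conditional on the synthetic spectrum; the chain's
contracts are therefore exact bookkeeping, calibrated LET, and the
documented record schemas (which double as an import contract for
externally produced records).

## Direct strand breaks

Backbone energy — deposits in phosphate, deoxyribose and the
strand-assigned hydration half-shell — is accumulated per (event,
chromosome, bp, strand); base deposits never contribute. The accumulation
window is per strand (the shell half decides the strand), switchable to
per pair. A site breaks when the accumulated energy reaches the
threshold, read inclusively (≥ 17.5 eV by default; 12.5 and 30 eV
variants), or, in linear mode, with probability 0 below 5 eV rising
linearly to 1 above 37.5 eV. All interaction labels contribute by
default (switchable). A site breaks at most once per event. Threshold
scoring is deterministic; the threshold family is monotone (a higher
threshold selects a subset of sites), though DSB counts downstream are
not claimed monotone because removing one break can split or reclassify a
cluster.

## Radical chemistry

The physicochemical stage converts each radiolysis seed into chemical
species through branching dissociation channels, placing products
uniformly in a 1 nm sphere around the seed. The channel table and the
diffusion coefficients are standard literature values shipped as editable
defaults (marked "external default" in the configuration): ionised water
→ OH• + H₃O⁺; excited water → OH• + H• (50%), H₂ + 2 OH• (15%), or
relaxation (35%); a solvated-electron seed maps to one e_aq unchanged.

The chemical stage is a Brownian-dynamics diffusion–reaction walk per
(voxel, track) pair: species react only with others from the same track
(independent-track approximation) and within the same voxel. DNA
constituents are static species (diffusion coefficient zero) carrying
their strand number; the histone is an absorber that removes whatever
touches it and persists. Rate constants are realised as encounter radii
via the Smoluchowski inversion R = k/(4π D′ N_A) with D′ the mutual
diffusion coefficient (the mobile species' coefficient for mobile–static
pairs). A pair reacts when the end-of-step distance is within R, or with
the Brownian-bridge first-passage probability
exp(−(d₀−R)(d₁−R)/(D′ dt)) otherwise; candidate pairs are gathered within
R plus three step widths of the end-of-step positions (pairs that start
near and end far contribute negligibly through the bridge). Products
appear at the reactant midpoint; simultaneous candidates are resolved by
increasing end distance with deterministic tie-breaks, so runs are
bit-reproducible under a fixed seed.

The step schedule is a geometric ladder (0.1 ps until 10 ps, 0.5 ps until
100 ps, 2 ps until 500 ps, 5 ps to the end), chosen so the RMS step stays
at or below the encounter-radius scale early, when the species
distribution is most clustered. The stage stops at 2.5 ns; together with
the voxel confinement (reflecting walls by default, absorbing optional)
and the histone absorber this stands in for radical scavenging, which is
not modelled explicitly. Only OH• reacts with DNA (2-deoxyribose
2.5×10⁹, adenine 6.1, guanine 9.2, thymine 6.4, cytosine 6.1 ×10⁹ /(M s));
e_aq and H• attack is slower and out of scope. The phosphate is
unreactive toward OH• by default — the deoxyribose is the strand-break
attack site — with a flag to make it reactive for sensitivity studies.
Each OH• + deoxyribose reaction converts into an indirect strand break
with probability 2/5 (two of the five sugar sites are reachable from
outside the helix); base reactions are logged but never break the strand
(base damage is out of scope).

A well-mixed box fixture recovers the configured rate constants from
tracer survival; against a uniform non-depleting target field the exact
reference is exp(−k(t)·c·t) with the transient Smoluchowski coefficient
k(t) = k(1 + 2R/√(πDt)). Inside real voxel geometry the chemistry is
diffusion-limited at the mesoscale — radicals born tens of nanometres
from the fibre cannot reach it within 2.5 ns — so indirect yields are
well below a well-mixed estimate; this is a property of the model, not a
numerical artefact.

## Clustering, fragments, yields

Deduplicated strand breaks are clustered per chromosome copy and per
event by transitive closure of "separated by fewer than 10 bp",
regardless of strand (linkage is strand-agnostic; classification is not):
a cluster with breaks on both strands is a DSB, a multi-break
single-strand cluster a complex SSB, a singleton a simple SSB; complexity
is the member count. Removing the only opposite-strand break of a DSB
cluster reclassifies it as an SSB, which is why the direct-criterion
choice propagates strongly into DSB counts.

For PFGE comparison each DSB cuts its chromosome once at the cluster
midpoint (configurable: min/max/first member). A copy with k cuts yields
k+1 fragments whose lengths sum exactly to the chromosome length.
Fragments strictly shorter than the 10000 bp detection threshold are
removed (a fragment of exactly 10000 bp survives); the detectable
("distant") DSB count is the number of cuts adjacent to at least one
surviving fragment (strict mode requiring both flanks is available). The
per-event distant-DSB count N is normalised to

    N_DSB/Gy/Gbp = N · E_1Gy / (l̄ · LET · n) · F

with defaults E_1Gy = 4570 keV (the ellipsoid volume at water density;
the helper recomputes 4571 keV, 4570 at 3 significant figures),
l̄ = 3.5 μm (printed constant; the geometric helper reports 3.66 μm for
the source-restricted mean chord and 3.33 μm for the full projection —
the printed value is kept as the default), n = 6.4 Gbp and F = 0.95 (the
source shadows 92% of the nucleus volume; F is configured, not derived
from that number). Batch control adds batches of 1000 primaries
(configurable) until the standard error of the batch means falls below 2%
of the mean, with a minimum of two batches.

## Determinism and problem sizes

Every stage draws from a child stream spawned deterministically from the
run seed, and every stage reads its inputs from the files the previous
stage wrote, so single-stage reruns reproduce downstream outputs
bit-exactly; geometry files round-trip bit-exactly (floats are written
with shortest round-trip repr). The test suite runs the chain at desk
scale (a sub-micron nucleus, a few domains, tens of primaries) and the
kinetics fixtures use 1–2×10³ tracer radicals; these sizes were chosen so
the full suite exercises every stage in about a minute while keeping
Monte Carlo tolerances at three standard errors.

## Known limitations

Absolute DSB/Gy/Gbp-versus-LET curves require a real track-structure
physics stage (interaction cross sections, secondary-electron cascades);
the synthetic generator makes no claim to reproduce them, and the
package's quantitative guarantees are the property and parameter-recovery
checks above. Base damage and its conversion to strand breaks, e_aq/H•
attack on DNA, explicit scavengers, chromatin dynamics and cell-cycle
variation are not modelled. Territory shapes are simplified to compact
domain groups. The nucleosome winding and the B-DNA constituent layout
are geometrically plausible rather than crystallographic.
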