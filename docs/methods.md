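# Methods

This note records the models implemented in `mprasim`, the conventions and
default parameters the package fixes where the underlying physics leaves a
choice open, and what the synthetic data do and do not emulate.

## Coordinates and sequences

Promoters are single-stranded ACGT strings with 0-based internal indexing.
Display coordinates are TSS-relative (`display = index − tss_index`); the
default 160-bp promoter with `tss_index = 115` spans −115..+44, wide enough
for upstream activator sites and motif insertions at −80.  Binding sites
are half-open intervals in display coordinates.  All energy matrices are
given on the coding strand; reverse-complement binding is out of scope.

The default wild type (`consensus_promoter`) is a seeded uniform-random
sequence with the σ70 consensus elements written in: TTGACA at −35 and
TATAAT at −12.  This gives the wild type a canonical core promoter so that
"one letter away from consensus" statements about inserted motifs are
meaningful.

## Energy matrices

A factor's sequence specificity is an additive l×4 matrix of energies in
kBT, canonically wild-type-normalized: the entry at each position's
wild-type base is zero, so the matrix scores the *change* in binding energy
of a variant relative to wild type.  Normalization is validated as "every
row contains a zero" rather than "exactly one zero", because neutral
mutations legitimately contribute extra zeros.  Un-normalized matrices are
re-anchored against a supplied wild-type window by subtracting each row's
wild-type entry.

Absolute energies are carried separately: each `BindingSite` holds a
`wt_energy`, the wild-type specific-over-non-specific binding energy, and a
variant's total energy is `wt_energy + Σ_i ε_{i,b_i}`.  Defaults are −5 kBT
(RNAP) and −15 kBT (repressor), the standard lac-system values, and
−13 kBT for activators — a package convention chosen to give strong but
non-saturating activation at 100 activator copies; it is not an externally
measured number.

Synthetic matrices place `mutant_energy` (default 1 kBT) at every mutant
base.  The σ70-like matrix (`sigma70_site`) instead concentrates
specificity the way measured RNAP matrices do: 2 kBT per mismatch in the
−10 hexamer, 0.1 kBT in the −35 hexamer, 0.02 kBT elsewhere.  The weak −35
dependence reflects promoters that fire from an extended −10; it is what
lets a short TATA-like motif inserted elsewhere on the promoter create an
appreciable spurious RNAP site.

## Mutant libraries

Mutagenesis is independent per-base Bernoulli(θ): each position of each
variant mutates with probability θ (default 0.1) and the target base is
drawn from the spectrum row of the source base.  This matches the
"mutation rate" framing of scanning MPRAs rather than a fixed per-variant
mutation count.  Spectra are row-stochastic 4×4 tables with zero diagonal;
an all-zero row declares a base immutable and such positions are silently
skipped.  The wild type is not included in the library unless requested.
The default library size is 5,000 variants — large enough to suppress
hitch-hiking noise while remaining experimentally realistic.

## The states-and-weights engine

The generic engine enumerates all occupancy states of the declared binding
sites.  A state's log-weight is Σ over bound sites of
`ln(copies/N_NS) − β·Δε(site, variant)`, plus interaction terms −β·ω for
co-bound interacting pairs; weights are normalized with logsumexp so no
intermediate exponential can overflow.  `N_NS = 4×10⁶` (the genome as
non-specific reservoir), β = 1 per kBT.

Steric exclusion and logic: a state is excluded when RNAP is bound together
with a *repressing* repressor configuration.  With one repressor, bound
means repressing.  With two repressors: AND requires both bound (and adds a
repressor–repressor cooperativity ω_rr = −5 kBT, which is what makes two
individually weak repressors work jointly); OR lets either bound repressor
repress (no cooperativity); XOR represses only when exactly one is bound.
Activators never exclude RNAP; each bound activator interacts with bound
RNAP through ω_ap = −4 kBT, a typical class-I recruitment energy (package
convention).

The transcriptionally active states are, by default, all RNAP-bound states
with a uniform rate; the rule is a configurable callable over the
bound/unbound assignment, which the kinetics comparison uses (below).

Worked-example magnitudes under the defaults: RNAP weight
(P/N_NS)e^{5} ≈ 0.04, repressor weight (R/N_NS)e^{15} ≈ 8, so the wild type
is strongly repressed (p_bound ≈ 0.004 vs ≈ 0.036 constitutive), and the
weak-polymerase simplification (dropping the RNAP weight from the
denominator) is accurate to < 4%.

## κ and the optimal mutation rate

The repressor/RNAP weight ratio
κ = (R/P)·e^{−β(Δε_rd − Δε_pd + m_r·ΔΔε_rd − m_p·ΔΔε_pd)} diagnoses which
binding site dominates a mutated library; the θ-form substitutes
m = θ·l.  Setting κ = 1 gives the closed-form balanced mutation rate

    θ* = [ln(R/P)/β − (Δε_rd − Δε_pd)] / (l_r·ΔΔε_rd − l_p·ΔΔε_pd),

clipped to [0,1] with a flag.  With the default parameters (R = 10,
P = 1000, Δε_rd = −15, Δε_pd = −5 kBT, and the measured per-mutation shifts
ΔΔε_rd = 2.24, ΔΔε_pd = 0.36 kBT over l = 20 bp, i.e. a 37.6-kBT
length-weighted combination) the closed form evaluates to θ* ≈ 0.143.  The
solver is cross-checked against bisection on κ(θ) − 1 to 1e-10.

## MWC induction

An inducible repressor follows the two-state Monod–Wyman–Changeux model
with two inducer sites: p_active(c) = (1+c/K_A)² / [(1+c/K_A)² +
e^{−βΔε_AI}(1+c/K_I)²], defaults K_A = 139 µM, K_I = 0.53 µM,
Δε_AI = 4.5 kBT (lac/IPTG constants).  The pool splits into
R_A = p_active·R (binding at Δε_rdA = −15 kBT plus the matrix shift) and
R_I = (1−p_active)·R; the inactive conformation's wild-type energy defaults
to 0 kBT (no specific binding), so full induction approaches the
constitutive limit.  The four-state partition function (empty, RNAP, active
repressor, inactive repressor) gives p_bound.

## Binding-site copy number (chemical potential)

Multiple binding-site copies are handled grand-canonically: one fugacity λ
is tuned so the mean bound number over the n specific sites plus a
zero-energy non-specific reservoir of N_NS sites equals the factor's copy
number; the partition function then factorizes per site.  The reporter's
repressor weight becomes λ·e^{−βε_r} in place of (R/N_NS)e^{−βε_r}.  Root
finding is monotone bracketed bisection in ln λ to a 1e-12 relative
tolerance, and particle number is conserved to the solver tolerance.

Two caveats are worth recording.  First, the grand-canonical (mean-
constrained) ensemble matches exact fixed-N enumeration only for degenerate
site energies or in the large-reservoir limit; at tiny reservoir sizes the
ensembles genuinely differ, and the tests assert exact agreement only where
it mathematically holds.  Second, with a single binding-site copy the
mean constraint lets the reporter site itself deplete the repressor pool
(occupancy ≈ 0.9 of R = 10 at the defaults), so the single-copy model
agrees with the standard dilute-limit p_bound only to within that
self-depletion fraction (~9%), not exactly.

## Non-specific RNAP binding

In non-specific mode every window start i ∈ [0, L − l_p] is a mutually
exclusive RNAP-bound state with weight (P/N_NS)e^{−βΔε_pd,i}, where the
window energy anchors at the canonical site's `wt_energy` plus the matrix
mapped onto the window sequence.  A repressor-bound state coexists with
RNAP at windows that do not overlap the operator; geometrically overlapping
windows are excluded, and the canonical window is always repressible —
canonically bound RNAP's physical footprint extends downstream across the
TSS, which is what lets a downstream operator repress at all.  By default
every RNAP-bound state transcribes (this is what produces non-canonical
binding-site signals); a restricted start-site set is selectable.

## Expression, noise, resampling

Counts are m* = α·p_bound with α = 100, placing counts on a realistic
RNA-Seq scale; α cancels from all footprint statistics (asserted by test).
Extrinsic noise draws per-variant copy numbers from a log-normal
parameterized by arithmetic mean m and CV v (σ² = ln(1+v²),
location = ln m − σ²/2, so the mean is exact); defaults are 5000 RNAPs and
100 repressors, one draw per variant (each variant's measurement is treated
as one cell/aggregate).  Sequencing noise is opt-in multinomial (exact
total = depth) or Poisson (expected total = depth) resampling of expected
counts; no fragment-level PCR model is attempted.  The default output is
deterministic expected counts.

## Footprint statistics

Mutual information uses plug-in empirical frequencies with 0·log 0 := 0 and
no bias correction.  Base identity is coarse-grained to wild-type/mutant by
default (the 4-letter mode is available), and expression is split into two
bins at the mean count — counts exactly equal to the mean go to the *high*
bin, a tie rule fixed here as a convention.  More than two bins switches to
equal-count rank binning.  Under the default 2×2 coarse-graining
0 ≤ I ≤ 1 bit for any input.  A position never mutated in the library has
I := 0 and is flagged rather than raising.  Expression shifts follow the
absolute (count-unit) definition per position and the relative (fold)
definition per base in the 4×L shift matrix, with wild-type entries exactly
zero.  SNR is the mean on-site over mean off-site information; a zero
off-site mean (the noiseless analytic limit of a constitutive promoter) is
reported as infinite with a flag.

The 2-bp, two-letter minimal promoter is implemented as a first-class
fixture (letters X/Y encoded as A/C): the full 4-sequence library gives
exactly 0 bits at the non-binding site and 1 bit at the specific site,
while the reduced {XX, YY} library gives 1 bit at both — the hitch-hiking
artifact in its sharpest form.

## Kinetic (non-equilibrium) models

Promoter states form a directed graph with positive edge rates; the steady
state follows the Matrix Tree Theorem (probability ∝ sum over spanning
trees rooted into the state of the product of edge rates), enumerated
exactly for ≤ 6 states with a Laplacian null-space solve beyond — and the
null-space route doubles as an independent oracle in the tests.  Binding
edges carry k_on·[X] with a shared diffusion-limited, sequence-independent
k_on; off-rates inherit sequence specificity through K_d = c0·e^{βΔε}
(c0 = 1 M), k_off = k_on·K_d, with interaction energies entering the
unbinding edges out of jointly bound states so that the undriven graph
satisfies detailed balance exactly.  A drive multiplies one edge's rate by
e^{βU}, making that cycle's forward/backward rate product e^{βU} ≠ 1.

For the four-state simple-activation square graph the default active set is
{A, AP} — the activator-bound states, as the steady-state expression is
conventionally written.  Note the tension with the thermodynamic engine's
RNAP-bound rule: under {A, AP} a driven activator cannot present as a
repressor, because mutations weakening activation always lower p_active.
Both conventions are selectable; the demonstrations of (i) equivalence with
the thermodynamic engine at U = 0 (per-variant agreement to 1e-6 relative,
using the matching active set on each side) and (ii) the activator-to-
repressor sign flip under a positive AP→A drive with ~10× activator
concentration use the RNAP-bound set {P, AP}.

## Orchestration and reproducibility

A `RunConfig` (YAML) fixes exactly one model mode per run; validation
collects every violation into one report.  All randomness flows from a
master seed through deterministic counter-derived child seeds
(`SeedSequence(entropy, spawn_key)`), so identical config + seed produces
byte-identical output bundles (library FASTA, counts/footprint/shift-matrix
TSV, JSON manifest recording every resolved parameter).  Sweeps emit tidy
long-format tables of per-site mean information and SNR over a value grid
with replicate seeds.

Problem sizes: the shipped experiments use libraries of 2,000–5,000
variants with 3–8 replicate datasets per grid point, sizes at which the
qualitative parameter dependences (signal loss at weak/strong repressor
energies, titration collapse, inducer response, SNR growth with library
size, the TATA-like-motif signal, the driven sign flip) are stable across
seeds; the full default pipeline runs in well under a minute on one CPU.

## What the synthetic data do not emulate

Energies are strictly additive (no epistasis); there are no indels, no
reverse-strand sites, no sigma-factor competition, no supercoiling, and at
most two regulated factors per promoter.  Intrinsic (bursting) noise is not
modeled — extrinsic copy-number noise only — and PCR bias is reduced to
count resampling.  Expression is single-gene: no regulatory-network
coupling.  Passing tests therefore show that the *inference statistics*
behave as expected under the stated physics; they do not validate the
thermodynamic model against any particular real promoter.
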