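# Methods

This note records the model, the numerical choices and the design
decisions behind `frustfold`, in the spirit of a simulation paper's
methods section. Everything quantitative stated here is computed by the
test suite or the acceptance script; nothing is asserted that the code
does not itself verify.

## Model definition

**Representation.** One bead per residue at the Cα position. The native
structure defines all reference quantities (subscript 0): bond lengths
`r_i,0`, bond angles `θ_i,0`, dihedrals `φ_i,0`, and the native contact
list with Cα–Cα reference distances `r_ij,0`.

**Native contacts.** A pair `(i, j)` with `j − i ≥ 4` is a native
contact when the minimum distance over all heavy-atom (non-hydrogen,
backbone included) pairs of the two residues is below 5.5 Å in the
native structure. The 12-10 well and the contact-hold criterion both use
the Cα–Cα distance: the model is Cα-only, and the hold rule
(`r ≤ 1.2 r₀`) is explicitly a Cα criterion, so using the Cα distance
for `r_ij,0` keeps well minimum and hold window consistent. Structures
with missing heavy atoms are a hard error by default; a Cα-only fallback
must be enabled explicitly, because silently changing cutoff semantics
corrupts contact maps.

**Couplings.** Native couplings are `ε_ij = s·|e_ij|`, where `e_ij` is
the embedded 20×20 knowledge-based contact-energy table and the single
global scale `s` is fixed by requiring `mean(ε_ij) = 0.18 ε₀` over the
contact list. Absolute values are taken because the raw statistical
energies are negative (attractive) while the 12-10 form already carries
the sign — ε_ij must be a positive well depth. The normalization makes
the model invariant to any positive rescaling of the table (property
tested), so only the *ratios* of table entries matter.

**Nonnative pairs.** Every `j − i ≥ 4` pair that is not a native contact
repels as `ε̄ (C/r)¹²` with `C = 4 Å` and `ε̄ = 0.18 ε₀`. The coupling
written for nonnative pairs is taken as the constant ε̄ rather than a
per-pair flavored value: flavoring is defined by contact statistics of
*native* contacts and has no canonical extension to non-contacting
pairs, and ε̄ matches the normalization scale of the native couplings.

**Frustration.** In the frustrated model, hydrophobic–hydrophobic
nonnative pairs exchange their repulsion for the 12-10 well
`σ ε̄ [5(C_f/r)¹² − 6(C_f/r)¹⁰]` with `C_f = 5.5 Å`, `σ = 0.5`. The well
*replaces* the bare repulsion (the 12-10 form contains its own
short-range wall); an additive variant is available as a switch. With
`σ = 0` the frustrated model reproduces the minimal model bit for bit
(tested). The hydrophobic set is {A, V, L, I, M, F, W, Y, C}; glycine is
classed hydrophilic (an Ala→Gly substitution removes hydrophobicity).
The set is configurable.

**Dihedral term.** The default is the standard structure-based form
`K_φ[(1 − cos(φ − φ₀)) + ½(1 − cos 3(φ − φ₀))]`, which vanishes at the
native state — a requirement of the Gō construction, where the native
frame must be the minimum of every bonded term. An alternative
native-independent form `K_φ/2 (1 − cos(2φ − π/2))²` is provided as
`dihedral_form="as_printed"` for fidelity experiments; it is nonzero at
the native frame and is not the default. Dihedrals follow the IUPAC
signed convention, range (−π, π], computed with the atan2 two-normal
formula.

**Constants** (reduced units): `K_b = 200 ε₀/Å²`, `K_θ = 40 ε₀/rad²`,
`K_φ = 0.3 ε₀`, `C = 4 Å`, `C_f = 5.5 Å`, `σ = 0.5`, `ε̄ = 0.18 ε₀`,
`ε₀ = 1.89 kcal/mol`, bead mass 119 a.m.u., `l₀ = 3.8 Å`.

## Units and integration

Internally: lengths in Å, energies in ε₀, k_B = 1, bead mass 1, time in
`t* = √(m Å²/ε₀)`. The characteristic time is `τ = l₀ t*/Å` (1.47 ps in
laboratory units); the default step `Δt = 0.007 τ` and friction
`β = 0.2/τ` convert internally to 0.0266 t* and 0.0526/t*. Unit
conversions to ps and kcal/mol happen only at I/O.

The integrator is the BAOAB splitting of underdamped Langevin dynamics,
chosen for its configurational accuracy at moderate friction. The force
is evaluated once per step. Gaussian noise is drawn from a numpy
`Generator` carried on the integrator state, outside the compiled
kernel, in chunks: this makes a run bitwise reproducible for a given
seed and makes two half-segments with carried state identical to one
full segment (both tested). With friction → 0 and T = 0 the O-step
disappears and the scheme reduces to velocity Verlet; total-energy
conservation in that limit (drift < 10⁻³ ε₀ over 10⁵ steps at
Δt = 0.001 τ) validates the force/integrator consistency.

**Thermostat validation.** Equipartition checks use an isolated bond and
an isolated angle. They deliberately run at a shorter step and different
friction than the folding defaults: the bond frequency is
ω = √(K_b/μ) = 20/t*, so at the folding step ω·Δt ≈ 0.53 and the
low-friction BAOAB configurational bias, of order (ωΔt)²/4 ≈ 7%, would
mask the fluctuation–dissipation check; at Δt = 0.001 τ the bias is
≈ 0.1%. The bond check uses strong friction (80/τ) so the stiff mode
decorrelates quickly; the angle check uses moderate friction (10/τ)
because the soft bending mode (ω ≈ 2.4/t*) would otherwise decorrelate
too slowly to accumulate independent samples, and averages several
replicas. These numbers come from the a-priori error budget, with both
bias and statistical error well below the 3% assertion.

## VTF sampling

One epoch = `N_T` Langevin steps at fixed temperature (2×10⁷ at
production scale; the fixtures use 5×10⁴–10⁵). After each epoch the Q
values of the up-to-now trajectory (cumulative by default; per-epoch
optional) are histogrammed. Default binning is one bin per possible
contact count (`n_contacts + 1` bins), which removes binning bias for
small systems; the density is smoothed with a 3-bin moving average,
local maxima (boundary bins included) are peak candidates, the two
highest are the unfolded/folded peaks and the valley is the minimum
between them. The update rule: unfolded peak higher → `T − ΔT`; folded
peak higher → `T + ΔT`; exact tie → random sign from the run's seeded
generator. A unimodal distribution steers toward bimodality: mode in the
folded half (Q > 0.5) → heat, in the unfolded half → cool. ΔT defaults
to 0.002 (about 0.5% of a typical collapse temperature).

The initial temperature, when not supplied, comes from a bracketing
pre-scan: short segments on a geometric temperature grid, picking the
mean-Q = 0.5 crossing by log-linear interpolation.

The averaged collapse temperature `T̄_θ` is the mean of the post-burn-in
epoch temperatures (first 25% discarded by default) and is the
temperature factor in the apparent free energy `F(Q) = −T̄_θ ln P(Q)`.
Empty histogram bins give undefined (NaN) free energies, never zeros.

**Calibration at fixture scale.** For the 12-residue hairpin the
equal-peak-height temperature that VTF converges to (≈ 0.205–0.208
ε₀/k_B, confirmed by independent long fixed-temperature runs) sits about
0.02 above the specific-heat-maximum temperature (≈ 0.186–0.190 from
fixed-T scans, Cv = var(U)/T²). This is a property of a marginally
two-state 8-contact system — P(Q) has no deep valley, and the
equal-height and maximum-Cv conditions need not coincide for broad
transitions. The corresponding convergence assertion in the test suite
is kept at its strict tolerance and documents this gap rather than
loosening it; for cooperative systems of realistic size the two
temperatures approach each other.

## TSE analysis

TSE: frames with `Q₁ < Q < Q₂`, where `Q₁ = (Q_valley + Q_unfolded)/2`
and `Q₂ = (Q_valley + Q_folded)/2` from the bimodal histogram. φ-values
divide the TSE-averaged held-contact count of a residue by its
native-state count; residues with zero native contacts have *undefined*
φ (NaN) — excluded from secondary-structure-element averages, never
counted as zero, since the defining ratio has a zero denominator.
Element averages are unweighted means over defined residues. The
ensemble contact map `c_ij` is the per-native-pair hold fraction over
TSE frames (non-native entries zero); its row sums reproduce the φ
numerators exactly (tested). Difference maps are frustrated minus
minimal, with each model's TSE extracted from its own histogram, and can
be rendered in the split-triangle layout (one model per triangle).

## Synthetic fixtures

The fixture generators exist so that every stage is testable without any
external structure; they are idealized geometries and carry no
biological claims.

- **Hairpin** (default 12 residues): two pleated antiparallel strands,
  3.5 Å rise, 4.6 Å strand separation, a two-residue turn, and a small
  seeded jitter that breaks collinearity without moving any pair across
  the contact cutoff. Default sequence alternates Ala/Val on the strands
  (hydrophobic, so the frustrated model has nonnative wells to act on)
  with an Asn-Gly turn. Eight native contacts result.
- **Mock β-sandwich** (110 residues): eight strands in two flat pleated
  sheets 10 Å apart, with Cβ pseudo-atoms alternating into and out of
  the core, so both intra-sheet (Cα–Cα ≈ 4.8 Å) and inter-sheet
  (Cβ–Cβ ≈ 5 Å) contacts arise under the 5.5 Å rule; strand order puts
  hairpin partners adjacent and the first strand against the C-terminal
  strand of the last hairpin. Linkers are circular arcs bowing away from
  the body with ≈ 3.8 Å spacing. Named elements B1, L1, B2, L2, BH1,
  L3, BH2, L4, BH3 cover residues 1–110; the sequence fixes wild-type
  identities at the mutation sites exercised in tests (R23, N36, D43,
  T53, V60, D71, A80, Y94).
- **Toy chain**: a compact self-avoiding random walk (centroid-biased)
  guaranteed at least one native contact; used for force/finite-
  difference and oracle tests.
- **Labeled trajectories**: mixtures of jittered native frames (Q high)
  and expanded frames (Q = 0) in a prescribed ratio with known labels,
  for exact brute-force oracles of Q, φ and contact maps.

What these fixtures do *not* emulate: real side-chain packing, loop
entropy, solvent, sequence-dependent geometry, or the cooperativity of a
real Ig-like domain. Tests passing on fixtures validate the machinery —
contact bookkeeping, energetics, sampling, statistics — not biological
conclusions about any particular protein.

## Degenerate inputs and tie-breaks

Collinear bead triplets (undefined angle/dihedral) and coincident beads
abort energy evaluation with a hard error; the integrator surfaces the
step index and keeps the last state for inspection. The contact-hold
test is inclusive (`r ≤ 1.2 r₀`), so a uniform 1.2× expansion still
holds every contact. Histogram peak ties break by seeded RNG. Mutation
directives validate the wild-type letter and reject mismatches.

## Known limitations

- Vacuum, implicit-geometry model: φ-values are relative indicators, not
  quantitative predictions of experimental φ.
- The nonnative-pair coupling is constant (ε̄); per-pair flavored
  nonnative couplings are not implemented.
- Fixture-scale transitions are weakly cooperative; barrier heights on
  the hairpin are fractions of ε₀ and barrier *locations* on a 9-level Q
  grid are the robust observable, as used in the model-comparison test.
- Trajectory storage is in-memory with optional `.npz` export; there is
  no out-of-core trajectory format.
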