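# Methods

This note documents the model implemented by `qphi`, the numerical and
design choices that were genuinely open, and the limits of what the test
suite demonstrates.

## Model and assumptions

The package analyzes a closed register of n qubits (n ≤ 3 in practice; the
algorithms are general but exponential) in a pure or mixed state ρ, updated
by a single unitary U.  The register is the universe: background
conditioning of external units is out of scope, as are non-unitary (Kraus)
dynamics — the cause-side computation requires the channel inverse to equal
the adjoint, so `apply()` rejects non-unitary maps explicitly rather than
silently producing an undefined quantity.  Qudits with d > 2 are not
supported.

Tensor order is the declaration order of unit labels; basis strings read
left to right in register order (`"10"` on AB is index 0b10).  The CNOT
control is the first unit of the named pair, enforced by a test pinning
10 → 11.

## Repertoires

Effect repertoires causally marginalize the mechanism's complement
(maximally mixed noise), apply U, reduce onto the purview, and factorize
across the maximal separability partition P* of the reduced state.  Each
P*-block's factor is recomputed as an independent conditional onto that
block; for unitary channels this coincides with the partial trace of the
joint conditional, but independent noising per block is the defining
semantics and the implementation follows it.  A pure joint conditional is
returned unchanged (its P* factors recompose to it exactly).

Cause repertoires split the *mechanism* state into its P*-blocks, propagate
each block backwards through U† with everything else noised, and combine
the per-block operators by matrix product, trace-normalized.  The operands
commute (are simultaneously diagonalizable) in every regime this package
targets; should they not, the product is symmetrized to (X + X†)/2 with a
`RuntimeWarning`, a documented convention rather than a derived rule.  A
zero-trace product marks the repertoire undefined; downstream it scores as
+∞ under partitions (visible, never clipped).

## Separability structure (P*)

Deciding multipartite mixed-state separability exactly is open in general.
The cascade used here, per candidate partition from finest to coarsest:

1. negative partial transpose across any induced cut rejects the candidate
   definitively;
2. pure states: a block splits off iff its reduced state is pure;
3. explicit product factorization (ρ = ⊗ᵢ ρ^{V(i)}) or diagonality in a
   product basis certifies separability with a shared term-by-term
   decomposition; candidate bases combine each block's reduced-state
   eigenbasis (unique when non-degenerate) with the three Pauli eigenbases
   for degenerate single-qubit blocks;
4. otherwise, PPT positive across all induced cuts accepts the candidate —
   exactly for two-qubit states (2×2 cuts), heuristically above that, with
   the method tag `ppt-heuristic` surfaced in reports.

The definition of mixed-state separability used here requires a *single*
partition shared by all terms of the mixture; regimes 2–3 certify that by
construction, regime 4 assumes it.  Bound entanglement (PPT but entangled)
would be misclassified in regime 4; no state analyzed by the shipped
scenarios reaches that regime.

## Measure and degeneracy

QID(ρ‖σ) = maxᵢ pᵢ[log₂pᵢ − Σⱼ P_ij log₂qⱼ].  The bracketing (pᵢ
multiplies the whole term) is the only reading that reduces to the
classical intrinsic difference maxₐ pₐlog₂(pₐ/qₐ) when the states commute
and makes the optimizer against a maximally mixed σ the maximal-eigenvalue
eigenvector; both properties are tested.

Eigenvalues within 1e-8 are grouped as degenerate; the basis inside a group
is whatever the eigensolver returns, and every downstream quantity is
tested to be invariant to that choice.  A degenerate optimum is reported as
the spanned eigenspace; the scalar value uses the shared eigenvalue once.
For φ at a degenerate intrinsic eigenspace, the score is the maximum over
the group's basis vectors — against maximally mixed comparisons these
coincide; against general σ the maximum is taken and the convention noted
here.  Zero eigenvalues are dropped before logarithms (0·log 0 = 0); weight
of the intrinsic state on the comparison's null space yields +∞, reported
as such.

A caution on orderings: QID is *not* bounded by the quantum relative
entropy in general.  The max of the pointwise terms exceeds their sum
whenever some terms are negative — already classically,
ID([0.9, 0.1]‖[0.5, 0.5]) ≈ 0.763 > KLD ≈ 0.531.  What does hold, and is
tested: equality on pure ρ, coincidence with the classical measure for
commuting operands, invariance under joint unitaries, and QID ≥ 0.

## Partitions, normalization, MIP

Disintegrating partitions of (M, Z) are enumerated as set partitions of the
disjoint union M ⊎ Z into ≥ 2 blocks, with the constraint that a block
containing all of M carries no purview unit.  This is a bijection with the
pair-partition definition (empty sides appear as blocks containing only
mechanism or only purview elements) and is validated against a brute-force
label-assignment enumerator.

The normalization of the MIP search counts the mechanism-unit × purview-unit
pairs severed by the partition: |M|·|Z| − Σᵢ|M(i)|·|Z(i)|.  This
reconstruction of "pairwise interactions affected" is isolated in one
function (`normalization_factor`) so an alternative convention can be
swapped without touching the search.

Tie-breaking at the MIP: ties in *normalized* φ are resolved toward the
smaller *unnormalized* φ, then toward canonical enumeration order, and all
co-minimal partitions are recorded.  The secondary key is load-bearing: for
the COPY-XOR mechanism 10→11 the total cut (φ=2, norm 4) and the aligned
pairwise cut (φ=1, norm 2) tie at normalized 0.5, and the analysis must
report the smaller unnormalized value (φ = 1 ibit).  Negative raw scores
(possible when a partition raises the weight of the selected eigenstate)
clamp to 0.  When the intrinsic information is zero the repertoire equals
the maximally mixed state and the total cut scores exactly 0, so the search
short-circuits — an exact identity, not an approximation.

Purview maximization resolves ties toward larger purviews, then first in
canonical order, recording same-size co-optima.

## Self-mode (identity channel)

With U = I the forward and backward analyses are conceptually equivalent
constraints of the state on itself (they can differ *formally*, since only
the effect side factorizes the purview).  The package reports the
effect-side value once per mechanism, tagged `constraint`.

## Classical engine

The classical oracle implements the probability-vector pipeline: per-unit
effect repertoires under uniform interventional noise, product composition,
Bayes-rule cause repertoires from per-mechanism-unit likelihoods, the
intrinsic difference (with a KLD variant for contrast), and the same
partition combinatorics as the quantum modules — shared deliberately, so
the exhaustive convergence test (all 24 two-bit reversible gates × 4 basis
states, both directions, every mechanism, exact equality of φ, purview and
intrinsic state) exercises the genuinely quantum components rather than two
copies of the same bookkeeping.  TPM state indexing is big-endian (leftmost
unit = most significant bit), matching the quantum Kronecker convention.

## Randomized instances and what tests show

Property tests draw Haar unitaries (QR of complex Gaussians with phase
correction), random permutation gates, Dirichlet-spectrum mixed states and
Haar-random pure states, at 2–3 qubits, from fixed seeds.  They demonstrate
measure-level invariances and pipeline invariants on such instances; they
do not probe bound entanglement, near-degenerate spectra at the tolerance
boundary, or registers beyond 3 qubits, where the P* heuristic regime and
the partition search cost would both bite.

## Numerical choices

Global tolerance 1e-9 for Hermiticity/trace/positivity (with small
multipliers where eigensolver noise accumulates), degeneracy tolerance
1e-8, report rounding half-even to 6 decimals.  All values arising in the
shipped scenarios are dyadic rationals or simple surds, so tolerances only
absorb floating-point noise.  Exhaustive purview × partition searches are
cached per analysis run, keyed by mechanism units, rounded state bytes and
purview; a full three-qubit unfolding completes in well under a second.
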