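# Methods

## The factorial model on the subset lattice

The object of study is a complete genotype–phenotype map over L biallelic
sites: every subset g of the L candidate mutations has a phenotype λ(g)
(λ_max in nm) or a nonfunctional flag. The model

λ(g) = λ_anc + Σ_{∅≠T⊆g} θ_T

is saturated: with all 2^L genotypes present there are exactly as many
parameters as observations, so the θ are not regression estimates but an
exact re-coordinatisation of the data (a Möbius/ Walsh-type transform in the
one-sided, "ancestor-referenced" basis). Two consequences worth keeping in
mind:

- every θ is interpretable only relative to the chosen ancestral genotype
  (the background-averaged/Fourier convention would give different numbers);
- a single wrong λ propagates into every θ above it in the lattice.

### Solving order and exactness

Genotypes and effect subsets are sorted by subset size, then bitmask value.
In that ordering the incidence matrix C (C[g,T] = 1 ⇔ T ⊆ g) is unit
lower-triangular, so the solve is a forward substitution: θ_g = λ(g) − λ_anc
− Σ_{∅≠T⊊g} θ_T, processed in increasing order of |g|. For integer-valued λ
the arithmetic involves only sums of floats that are exactly representable,
so decomposition and reconstruction round-trip to machine precision; no
linear-algebra tolerance enters. The independent oracle `mobius_decompose`
computes θ_S = Σ_{T⊆S} (−1)^{|S|−|T|} λ(T) by the in-place per-bit difference
transform; tests require exact agreement with the recursion on thousands of
random landscapes.

### Imputation of nonfunctional genotypes

A genotype that does not form a pigment has no λ_max. The analysis adopts
the rule that such a mutation cannot shift the phenotype: processing subsets
in increasing size, a nonfunctional genotype g gets θ_g := 0 and an imputed
λ(g) := λ_anc + Σ_{∅≠T⊊g} θ_T. Because processing is size-ordered, nested
nonfunctional genotypes cascade deterministically — each uses the
already-imputed values below it. Imputed records are flagged (`source =
imputed`) and are treated as *nonfunctional* by every trajectory operation:
imputed λ values never appear in a path profile, and termination depends
only on the functional flag. The `decompose_stable_only` variant runs the
same recursion on functional genotypes alone (skipped terms contribute 0);
it provably returns the identical value for every estimable θ, which the
tests check on random lethality patterns — this is the internal-consistency
argument for the imputation rule.

On lethality-heavy landscapes the imputation necessarily concentrates
signal in high-order terms above the imputed zeros (visible in the
`analysis/02` output as large alternating five-, six- and seven-way terms);
this is a property of the method, not a bug, and is why the per-path
reconstruction — not individual high-order θ — is the robust summary.

### Uncertainty

With observation covariance V (default I: unit variance, zero covariance,
the convention for λ_max reads off absorbance spectra), the estimator is
X = C⁻¹Y, so SE on the diagonal of C⁻¹V(C⁻¹)ᵀ. C⁻¹ has entries ±1 (Möbius
coefficients), giving the closed form SE(θ_S) = 2^{|S|/2} under V = I: √2
for singles, 2 for pairs, ≈ 11.3 for the seven-way term — higher-order
estimates are intrinsically noisy. Significance is a two-sided z-test
against the standard normal, starred at 0.05 and 0.01, with no
multiple-testing correction by default (the conventional per-term report);
Benjamini–Hochberg is available behind a flag. A zero SE with nonzero θ
(V = 0 edge case) reports p = 0 with a warning.

## Trajectories

A trajectory is one of the L! orders of accumulation; its intermediates are
the nested prefix genotypes. Termination is at the first nonfunctional
intermediate; accessibility additionally requires the *endpoint* functional
(the stricter reading — unobservable when the full mutant is functional, as
in the motivating study). Counts use the subset DP
f(S) = Σ_{i∉S, S∪{i} functional} f(S∪{i}), f(full) = 1, which gives the
accessible total as f(∅) and the per-first-mutation decomposition as its
first-step terms, in O(2^L·L) exact integer arithmetic. Brute-force
enumeration (vectorised permutation-prefix scan) is retained purely as an
oracle and for per-path listings; it refuses L > 10.

Classification thresholds are literal: the gradualness criterion is strict
(|Δλ| < 25 nm at every step), and the variance split is a strict, signed
Δλ > 30 nm on any single step. The per-path step-variance denominator is
n−1 (sample variance) by default; population variance (n) is available via
`ddof=0` / `--pop-variance` since the convention in prior reports of such
distributions is not fixed — reproductions should report both.

## Ordering on the phylogeny

Substitution order on the focal lineage is inferred by small parsimony on
the fixed rooted input tree (no re-rooting; node ages are annotation only).
The bottom-up pass uses Hartigan state counts — identical to Fitch
intersection/union on bifurcating trees and exact on polytomies. For the
top-down resolution the implementation departs from the textbook three-rule
uppass: it computes, by unit-cost Sankoff down/up tables, the exact minimum
number of changes conditional on each (node, state) assignment, and reports
as the node's resolved set every state attainable in *some*
most-parsimonious reconstruction. This is the same answer where the
textbook rules apply, is verified against exhaustive labeling on small
trees, and extends directly to the placement question: a focal-path branch
(u, v) is a candidate location for a site's substitution iff some
most-parsimonious reconstruction gives u a non-derived state and v the
derived state (checked via the conditional-cost tables). Ambiguous ties
yield multi-branch candidate sets and the full set of resulting partial
orders — never a silent accelerated/delayed-transformation choice. Sites
placed on the same branch form one group; groups in root→tip order form the
partial order, with Π(group size)! linear extensions.

## Synthetic data

`generate_landscape` draws landscapes with the structure the analysis
assumes. Defaults are the emulated study conditions, fixed up front:

| parameter | default | rationale |
|---|---|---|
| L | 7 | seven focal replacements |
| λ_anc | 357 nm | ultraviolet ancestral pigment |
| main effects | N(0, 2²) nm | single effects are −3…+2 nm in the motivating data |
| interaction sparsity | 0.28 per term | with magnitude N(0, 10²), ≈17% of the 120 interactions exceed 5 nm, the reported scale (21/120) |
| interaction magnitude | N(0, 10²) nm | large interactions reach tens of nm |
| nonfunctional fraction | 60/127 | reported lethality rate |
| noise SD | 1 nm | the V = I error convention |

Noise is i.i.d. Gaussian per measured genotype, ancestor included unless
`fix_anchor` (so λ_anc is itself an observation, as in a real assay). The
draw order is a documented contract (θ in lattice order with inclusion and
magnitude drawn unconditionally, then noise per genotype, then lethality
uniforms), so outputs are stable under one named seed. λ is emitted rounded
to 0.1 nm by file writers only; in-memory values keep full precision, which
is what makes the noise-free generator→decomposer closure exact.

What the generator does **not** emulate: correlated measurement error,
genotype-dependent assay variance, lethality that clusters structurally
(beyond explicit pattern rules), and any selection/fixation dynamics.
Passing tests therefore demonstrate correctness of the *computations* under
the stated error model, not robustness of the science to violations of it.

### Fixed fixtures

`human_m_fixture` is the real three-locus instance: it is fully determined
by its seven published effect terms, so its λ table (555/550/543,
545/536/534, 531 nm around 560) is data, not simulation.

`s1_like_fixture` is **synthetic**: a hand-set seven-site effect table whose
mains equal the published single effects and whose six interaction terms
carry the 54-nm ultraviolet→blue shift, plus a lethality rule (the T52F
analogue is nonfunctional in any background with ≤ 4 total mutations —
trajectories starting with it terminate immediately, late arrivals are
tolerated) and a 15-taxon mammal tree/character matrix whose parsimony
placement yields the four-branch grouping (T93P, A114G) → (F86L) →
(F49L, S118T) → (F46T, T52F) with 8 linear extensions. It exercises every
pipeline stage end to end with the right shape and scale; its aggregate
counts (e.g. 2,160/5,040 accessible) are properties of the synthetic rule,
not measurements. The measured 128-genotype table itself is distributed
only as the study's supplementary PDF and is not included here; the
acceptance test that reproduces its aggregate counts looks for a
transcription at `data/anc_boreotheria_s1_table.tsv` and fails until one is
supplied.

## Problem sizes and numerical choices

Property tests run 1,000 random landscapes (L ≤ 8) for the Möbius oracle,
500 random lethality patterns (L 3–8) for DP-versus-enumeration, 2,000
noise replicates at L = 3 for SD calibration (sampling error of an SD at
n = 2,000 is ≈1.6%, comfortably inside the 5% band), and exhaustive
parsimony oracles on ≤ 8-tip trees; the whole suite completes in seconds.
Ties in permutation streaming are avoided by fixing lexicographic order of
site labels (trajectories) and sorted within-group permutations (linear
extensions). Degenerate inputs are errors, not warnings: nonfunctional
ancestor, incomplete lattice in `decompose`, overlapping partial-order
groups, thresholds ≤ 0, unscored tips.

## Known limitations

- The decomposition is exactly determined, so it cannot flag an inconsistent
  λ (there are no degrees of freedom left for lack-of-fit); replicate
  measurements would have to be reconciled upstream.
- Trajectory counting weights all accessible orderings equally — no
  selection coefficients or fixation probabilities.
- Parsimony ordering assumes the input topology; uncertainty in the tree is
  outside scope, as is maximum-likelihood ancestral reconstruction.
- Brute-force path listings are O(L!·L); beyond L = 10 only DP counts are
  offered.
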