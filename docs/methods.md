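# Methods

## The measures

Let C be an N×N confusion matrix with rows indexing the true class and
columns the predicted class, entries C_{i,j} ≥ 0 and total S = ΣΣ C_{i,j} > 0.
Entries are *reals*, not just integer counts: every measure in the package
is invariant under multiplication of the whole matrix by a positive
constant, so parametric families with real-valued parameters are
first-class inputs.

**CEN.** For class j write D_j = Σ_k (C_{j,k} + C_{k,j}) (row sum plus
column sum; the diagonal cell is counted twice). The misclassification
probabilities "subject to class j" are P^j_{i,j} = C_{i,j}/D_j (i ≠ j),
and the per-class confusion entropy is

CEN_j = −Σ_{k≠j} [ P^j_{j,k} log_{2(N−1)} P^j_{j,k} + P^j_{k,j} log_{2(N−1)} P^j_{k,j} ],

i.e. the entropy contributed by row j and column j, both normalized by
D_j. The overall CEN = Σ_j P_j CEN_j with P_j = D_j / 2S (a convex
combination: Σ P_j = 1). The log base 2(N−1) — base 2 when N = 2 — makes
the per-class entropy at most 1 for the 2(N−1) cells involved.

**MCEN.** The double-counting of C_{j,j} in D_j is what breaks CEN in the
binary case. MCEN uses D̃_j = D_j − C_{j,j} in the probabilities
(P̃^j_{i,j} = C_{i,j}/D̃_j, now a genuine relative frequency) and weights

P̃_j = D̃_j / (2S − α Σ_k C_{k,k}),   α = 1/2 if N = 2, else 1.

For N > 2 the weights sum to 1; for N = 2 they sum to ≤ 1, with equality
exactly when the diagonal is zero. MCEN is guaranteed to lie in [0, 1]
for every N.

**Companions.** ACC* = 1 − trace(C)/S. MCC is the Matthews correlation:
for N = 2 the classical (TP·TN − FP·FN)/√((TP+FN)(FP+TN)(TP+FP)(TN+FN));
for N > 2 the generalized correlation between true and predicted labels
computed directly from the matrix (Gorodkin's R_K), which reduces to the
binary formula at N = 2. MCC* = (1 − MCC)/2 puts it on [0, 1],
lower-is-better, like the others. IN(C)/OUT(C) are plain base-2 Shannon
entropies of the diagonal/off-diagonal cells and `entropy_overall` of all
N² cells. (For the U_A family a published expression for the overall
entropy drops the contribution of the cell equal to 1; we compute the
entropy of all cells and do not reproduce that expression.)

## Conventions and degenerate inputs

- 0·log 0 = 0 throughout.
- A 0/0 probability (a class absent from both its row and its column)
  is defined as 0, and the corresponding per-class entropy term as 0.
  This is the continuous limit and keeps perfect classification at
  exactly 0.
- IN/OUT of an all-zero diagonal (resp. off-diagonal) is 0, not an error;
  the standalone `shannon_entropy` of an all-zero set *is* an error.
- MCC with a vanishing covariance denominator (e.g. all predictions in
  one class) is 0, hence MCC* = 1/2 ("no information").
- Validation rejects non-square input, negative entries, all-zero
  matrices and N < 2 with specific exception types.

## Numerical choices

- Per-class entropies use `scipy.special.xlogy` (exact 0·log 0) divided
  by log 2(N−1).
- MCC is computed from the sum-normalized matrix with every covariance
  term written as sums and differences of non-negative products
  (cov_xy = Σ_k [C_kk·R_k − o_k·q_k] with R_k the mass outside row and
  column k; s² − Σp_k² as the pairwise sum Σ_{k≠l} p_k p_l). The textbook
  `s² − Σp²` form loses ~1e-12 of scale invariance under extreme class
  imbalance through catastrophic cancellation; this form keeps all
  measures scale invariant to ≤1e-12, which the property suite asserts.
- Extremum location uses bounded Brent minimization (parameter tolerance
  1e-10); unit crossings scan a 512-point grid for sign changes and
  polish with Brent to 1e-12. Brackets come from the analytically known
  behaviour of each family.
- Printed-table regression compares at each cell's printed number of
  decimals with round-half-even.

## The matrix families

The families are the package's synthetic data: parametric confusion
matrices designed to isolate one behaviour each, not samples from any
classifier. U_A = (1,A;A,0) (symmetric, unbalanced: CEN > 1 for every
A > 1), V_A = (1,A;1,0) (asymmetric: CEN > 1 only on (1, ≈1.41)),
X_{A,r} = (A,rA;rA,1) and Y_{A,r} = (rA,rA;A,1) (doubly indexed, same
overall entropy, different measure behaviour), Z_A (all-ones with entry
(N,1) = A), M_A = (1,50;A,1) and W_A = (50,1;1,A) (constant diagonal /
off-diagonal, for correlating the measures with OUT resp. IN entropy over
A = 1..100), the symmetric balanced case (diagonal T, off-diagonal F,
γ = T/F), and the minority-improvement grids (50,100;101−α,α) and
(100,100;101−β,β), α, β = 1..101. Each family has closed-form expressions
for all four measures (`closed_forms`), re-derived from the general
binary forms where the published rendering is ambiguous, and the central
test of the repository asserts closed form ≡ general implementation to
≤1e-9 on ≥200-point grids. Because the families are exhaustive for the
behaviours under study, passing tests characterize the *measures*
completely; they say nothing about any particular classifier or dataset.

Default sweep grids: integer A = 1..100 for M/W (the correlation
analyses), indices 1..101 for α/β, 400 log-spaced points on (1e-3, 1e3)
for the continuous families.

## Properties verified, and two corrections to received claims

The suite verifies: scale invariance (≤1e-12); MCEN, ACC*, MCC* ∈ [0,1]
and CEN ∈ [0,1] for N > 2 on randomized matrices (10⁴ draws, N = 2..6,
for the MCEN bound); CEN = MCEN = 1 under complete symmetric
misclassification; the duality MCEN(2γ) = CEN(γ) in the symmetric
balanced case for N > 2; the ordering MCC* < ACC* < CEN < MCEN for
N > 2, γ > 0; the binary CEN maximum 1.061475 at γ = e/2 − 1; the Z-family
unit crossings {1, ≈1.85}; and the CEN peaks at α = 18 / β = 14 on the
minority-improvement grids while MCEN, ACC* and MCC* decrease
monotonically there.

Two received claims required correction:

1. **"CEN = MCEN = 0 iff the off-diagonal is zero"** fails for degenerate
   matrices: [[0,1],[0,0]] scores CEN = MCEN = 0 because its single
   misclassified cell has probability 1 and hence zero entropy. The
   "only if" direction holds whenever the diagonal is strictly positive
   (then every misclassification probability lies strictly inside (0,1)),
   and is tested in that form, with the degenerate case documented by its
   own test.
2. **"MCEN is monotonically increasing in A along X_{A,r}"** fails for
   r ≤ 1: the MCEN profile overshoots its A → ∞ limit
   4r/(8r+3)·log₂(2(2r+1)/r) and then decreases toward it (at r = 0.5 the
   overshoot is ≈2.5e-3, far above numerical noise, and the closed form
   and the general implementation agree). Monotonicity is asserted where
   it holds (r = 2); the overshoot at r ∈ {0.5, 1} has explicit tests.

Four printed reference cells are likewise inconsistent with their own
closed forms (two MCC* cells of the binary toy-example table that
contradict the classical MCC formula, and two last-digit
rounded-intermediate artifacts); the regression suite compares against
the formula-consistent values, which are recorded next to the printed
ones in `tests/expected_tables.py`.

## Ranking comparison

Orderings are best-to-worst under the fixed lower-is-better polarity of
the four scaled measures, with stable tie-breaking by input order. The
reference ranking ("criterion of entropy") orders classifiers by OUT
entropy ascending, breaking ties by IN entropy. Agreement indicators:
Hamming distance (positions holding different items) and the degree of
consistency c — the fraction of item pairs ordered concordantly by two
score lists, with pairs tied in either list excluded. The published
definition of c is not restated in full anywhere we could verify, so the
concordant-pair-fraction reading (which keeps c ∈ [0,1], invariant under
strictly monotone transforms, and interpretable as an ordering-agreement
probability) is an interpretation; it is NaN when every pair is tied.

## Known limitations

- Probabilistic accuracy (PACC), entropy-modulated accuracy (EMA) and the
  NIT factor are out of scope; so are ROC/AUC/F-scores and any actual
  classifier training.
- CEN ≤ 1 for N > 2 is asserted on randomized matrices, not proven here.
- The CLI's sweep grid parser treats `lo:hi:n` as log-spaced when
  hi/lo ≥ 100 and lo > 0, otherwise linear; pass explicit comma-separated
  values for full control.
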