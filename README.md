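# mcen — confusion-entropy performance measures for classifier evaluation

`mcen` scores N×N confusion matrices (rows = true class, columns =
predicted class, N ≥ 2, non-negative real entries) with entropy-based
performance measures:

- **CEN**, the Confusion Entropy of Wang et al.: a weighted sum of
  per-class Shannon entropies of misclassification probabilities, with
  logarithms in base 2(N−1),

  CEN_j = −Σ_{k≠j} [ P^j_{j,k} log_{2(N−1)} P^j_{j,k} + P^j_{k,j} log_{2(N−1)} P^j_{k,j} ],
  CEN = Σ_j P_j · CEN_j,

  where P^j_{i,j} = C_{i,j} / Σ_k (C_{j,k} + C_{k,j}) and
  P_j = Σ_k (C_{j,k} + C_{k,j}) / 2S;
- **MCEN**, the Modified Confusion Entropy: the same construction with the
  double-counted diagonal term removed from every denominator
  (P̃^j_{i,j} = C_{i,j} / (Σ_k (C_{j,k} + C_{k,j}) − C_{j,j})) and weights
  P̃_j = (Σ_k (C_{j,k} + C_{k,j}) − C_{j,j}) / (2S − α Σ_k C_{k,k}),
  α = 1/2 for N = 2 and 1 otherwise;
- **ACC\*** = 1 − Accuracy and **MCC\*** = (1 − MCC)/2, rescalings of
  accuracy and the Matthews correlation coefficient so that every measure
  is lower-is-better on [0, 1] (multiclass MCC uses the generalized
  correlation computed directly from the matrix);
- **IN / OUT entropies**: base-2 Shannon entropy of the diagonal /
  off-diagonal cells.

Why MCEN? In the binary case CEN is broken as a performance measure: it
exceeds 1 on intermediate matrices (e.g. CEN of [[2,4],[4,2]] is 1.0566,
with a maximum of ≈1.06148 at diagonal/off-diagonal ratio γ = e/2 − 1) and
it moves non-monotonically while misclassification grows or shrinks
monotonically. MCEN removes both pathologies: it is guaranteed to lie in
[0, 1] for every N and it decreases monotonically as classification of a
minority class improves. The package ships the parametric matrix families
(U_A, V_A, X_{A,r}, Y_{A,r}, Z_A, M_A, W_A, the symmetric balanced case)
that expose these behaviours, their analytic closed forms as an
independent oracle, sweep/correlation machinery, and ranking-agreement
indicators (Hamming distance, degree of consistency c, the OUT-then-IN
"criterion of entropy") for comparing classifiers.

Intended users: anyone evaluating or comparing classifiers — particularly
under class imbalance, where accuracy is misleading — and anyone studying
the metrics themselves.

## Worked example

Score a binary confusion matrix with 5 correct and 1 misclassified case
per class:

```
$ printf '5,1\n1,5\n' > matrix.csv
$ mcen score matrix.csv
cen = 0.5975
mcen = 0.5910
acc_star = 0.1667
mcc = 0.6667
mcc_star = 0.1667
entropy_in = 1.0000
entropy_out = 1.0000
entropy_overall = 1.6500
```

One case in six is misclassified (ACC\* = 0.1667); the confusion entropies
quantify how that misclassification is *distributed*: CEN = 0.5975 and
MCEN = 0.5910, roughly halfway to complete confusion (both measures reach
1 when every case is misclassified uniformly, 0 only for perfect
classification). The same numbers from Python:

```python
>>> import mcen
>>> report = mcen.score([[5, 1], [1, 5]])
>>> round(report.cen, 4), round(report.mcen, 4)
(0.5975, 0.591)
```

The binary pathology of CEN, and MCEN's fix, in two lines:

```python
>>> round(mcen.cen([[2, 4], [4, 2]]), 4)   # out of range
1.0566
>>> round(mcen.mcen([[2, 4], [4, 2]]), 4)  # bounded
0.9614
```

Other CLI entry points: `mcen sweep --family u` (measure sweeps over a
family), `mcen corr --family m` (Pearson correlation matrix of a sweep),
`mcen compare DIR` (rank the per-classifier matrices in a directory, with
Hamming/consistency agreement against the entropy criterion),
`mcen tables --which 8` (regenerate a worked-example table), and
`mcen fixtures OUT` (write the example matrices as CSV files).

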