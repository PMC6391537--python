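# Methods

## Model and assumptions

A protein sequence is treated as a realisation of a stationary first-order
Markov chain on the 20 amino-acid states, ordered
`A I L M F P W V D E N C Q G S T Y R H K` (this ordering is fixed
package-wide; matrix row/column *i* always refers to state *i*). The 1-step
transition matrix is the maximum-likelihood estimate from overlapping
adjacent-pair counts. Powering the matrix (Chapman–Kolmogorov) mixes the
chain; when two consecutive powers agree to `rmsd < tol` the rows have
collapsed onto (a numerical approximation of) the stationary distribution,
and a single row is kept as the sequence's feature vector. The method
therefore assumes the estimated chain is ergodic enough to mix: a strictly
periodic chain (e.g. from an exactly repeating artificial sequence) has no
such fixed point and is reported as a non-convergence error rather than
silently truncated.

Similarity of two feature vectors is an information-fusion problem: each
amino-acid state contributes evidence `rho_i = 1 - |v_i - t_i|` whose weight
is its density `mu_i = max(v_i, t_i)`, and the Sugeno integral of the
evidence against the λ-fuzzy measure built from those densities gives a
similarity in [0, 1]. Because both feature vectors lie on the simplex,
`sum(mu) >= 1` always, so λ lies in (−1, 0], with λ = 0 exactly when the
vectors coincide.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `tol` | 1e-6 | rmsd between consecutive matrix powers that defines the optimal step h (dimensionless, per matrix entry). The default reads "agreement to six decimal places" literally. |
| `max_steps` | 1000 | power budget before a non-convergence error; protects against periodic/reducible chains. |
| `row_policy` | `first_row` | which row of the converged matrix becomes the feature vector. `row_average` is available; at convergence the rows agree to ~`tol`-level spread, so the choice is immaterial up to that spread. A warning fires if rows disagree by more than 1e-3. |
| sanitize policy | `drop` | non-canonical residues (B, Z, X, U, O, J, gaps) are removed with a logged count; `error` aborts instead. |
| `workers` | 2 | thread count for the pairwise stage. Results are written to preallocated matrix positions, so output is bit-identical for any worker count. |

## Numerical choices

- **λ root.** `1 + λ = Π(1 + λ μ_i)` always has the trivial root λ = 0; the
  measure-defining root is found on the deflated function
  `g(λ) = f(λ)/λ` (with `g(0) = Σμ − 1` by continuity), which brackets
  cleanly on (−1, 0) or (0, ∞) depending on the sign of `Σμ − 1`.
  `f` is evaluated as `expm1(Σ log1p(λ μ_i)) − λ` to keep full relative
  precision near λ = 0; Brent's method is followed by a short Newton polish
  so the residual of the original equation stays below 1e-12 (1e-10 is the
  enforced ceiling). `|Σμ − 1| < 1e-9` is taken as the exactly-additive
  case λ = 0.
- **Degenerate densities.** If some `μ_i = 1` with `Σμ > 1` (disjoint
  δ-like feature vectors), the non-zero root merges with the inadmissible
  λ = −1; λ = 0 is returned and the measure cannot normalise to
  `μ(G) = 1`. The chain builder warns instead of failing in exactly this
  case; the Sugeno integral is still well defined and yields the intuitive
  distance D = 1 for disjoint supports. In every non-degenerate case a
  final chain value off 1 by more than 1e-4 is a hard error.
- **Sorting ties.** The evidence is sorted descending with a stable sort,
  ties broken by ascending amino-acid index. The integral is provably
  tie-invariant (verified exhaustively over permutations for small sets);
  the rule just makes output byte-reproducible.
- **Matrix powers** are computed by repeated multiplication with the 1-step
  matrix, not eigendecomposition, because h is defined as the *least* step
  meeting the tolerance. Row sums are renormalised once at the end to shed
  ~1e-14 of accumulated drift.
- **Zero-count rows** (states absent from a sequence) are filled with the
  uniform row 1/20. This keeps the matrix stochastic, avoids absorbing
  artifacts and makes convergence well defined for short sequences. No
  other pseudocount smoothing is applied.
- **Trees.** UPGMA and NJ break minimum ties by the smallest (row, col)
  cluster-index pair; NJ clamps negative branch lengths to 0 with a
  warning. The λ-measure chain recursion is O(m) per pair; the power-set
  construction of the measure survives only as a test oracle.
- **PHYLIP dialect.** Square matrices, 10-character padded names, 6-decimal
  fixed point; labels that collide after truncation are rejected rather
  than silently merged. The reader accepts wrapped rows and averages away
  asymmetries up to 1e-6.

## Design decisions that were genuinely open

- *Which row becomes the feature vector* is not determined by the model
  (all rows agree at convergence): row 0 is the deterministic default,
  `row_average` the alternative, and a divergence between them beyond 1e-3
  is surfaced as a warning rather than hidden.
- *Ambiguous residues*: both a tolerant (`drop`, default) and a strict
  (`error`) policy are exposed, since real-world FASTA routinely contains
  X/B/Z codes but a user comparing curated sequences may prefer to know.
- *Correlation between distance matrices* is Pearson over strict
  upper-triangle entries paired by label (Spearman behind a flag). Other
  conventions (cophenetic correlation, whole-matrix correlation) exist; the
  choice is documented rather than claimed canonical.
- *ROC convention*: positives are intra-group pairs scored by similarity
  `1 − D`; AUC is the Mann–Whitney rank statistic with midrank ties
  (equal to the trapezoidal area under the step curve).
- *Fitch–Margoliash* least-squares trees are not implemented; the PHYLIP
  writer keeps that workflow available through external tools.

## Synthetic data: what it does and does not show

`make_family_models` draws each family's transition rows from
`Dirichlet(20 · b · (1/d − 1) + 0.1)` around a shared base composition `b`
(itself `Dirichlet(5·1)`), where `d ∈ (0, 1]` is the divergence knob: as
`d → 0` the concentration diverges and all families collapse onto `b`; at
`d = 1` rows are nearly unconstrained. The additive floor 0.1 keeps the
Dirichlet parameters valid at `d = 1`. Sequences start in the family
chain's stationary distribution, so the pipeline's feature vector has the
stationary distribution as its exact ground truth — this is what the
recovery tests exploit (length 1e5 recovers it to 0.02 per entry; the
benchmark length of 2000 with divergence 0.8 separates 4 families of 5
sequences essentially perfectly, AUC > 0.95 in every seeded replicate).

The generator matches the method's own model assumption (first-order
Markov, no indels, no site heterogeneity, no substitution-matrix
structure). Passing these tests therefore shows the pipeline correctly
recovers structure *when the Markov assumption holds*; it says nothing
about robustness to real protein evolution, and is not intended to.

## Problem sizes

The verification script and test suite use: 1000 random instances for the
integral/λ contracts, 100 random chains for convergence and semigroup
checks, exhaustive subset × insertion-order enumeration up to m = 5, and
20 seeded benchmark replicates of 4 families × 5 sequences × length 2000
for family recovery. These sizes give stable worst-case statistics while
keeping a full run in seconds.

## Known limitations

- First-order chains only; no higher-order memory, and no smoothing beyond
  the uniform-row fill, so feature vectors from very short sequences are
  dominated by that fill.
- The fuzzy distance satisfies identity and symmetry but the triangle
  inequality is not claimed (nor required by downstream UPGMA/NJ).
- Exactly periodic sequences (artificial repeats) are rejected by design.
- ROC treats pairs as independent observations, as is conventional; no
  significance is attached to AUC values.
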