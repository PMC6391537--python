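# fimseq

Alignment-free comparison of protein sequences via Markov-chain features and
Sugeno fuzzy-integral similarity, with distance-based tree building
(UPGMA / neighbor joining) and the evaluation statistics used to validate
such methods (Robinson–Foulds distance, distance-matrix correlation,
ROC/AUC).

Multiple sequence alignment becomes unreliable when sequences are highly
diverged or rearranged. `fimseq` compares protein sequences without aligning
them: each sequence is summarised by the statistics of its own amino-acid
transitions, and similarity between two sequences is computed by fusing the
agreement of those statistics with a fuzzy integral. It is aimed at anyone
doing exploratory phylogenetics or clustering of protein families where an
alignment is unavailable or untrustworthy.

## The method

**Stage 1 — Markov features.** A protein sequence over the 20-letter
alphabet `M = {A, I, L, M, F, P, W, V, D, E, N, C, Q, G, S, T, Y, R, H, K}`
is modelled as a realisation of a 20-state Markov chain. With
`N(a_i, a_j)` the count of adjacent residue pairs, the 1-step transition
matrix is

    p_ij = N(a_i, a_j) / sum_j N(a_i, a_j)

(rows with no observations are filled with the uniform row). The k-step
matrix is the k-th power `P^k` (Chapman–Kolmogorov). `P` is powered up to
the least step `h` at which

    rmsd(P^h, P^{h+1}) < 1e-6,   rmsd = sqrt(mean (P_ij - Q_ij)^2),

at which point all rows approximate the chain's stationary distribution and
one row of `P^h` becomes the sequence's feature vector `x` (a point on the
20-simplex).

**Stage 2 — fuzzy-integral similarity.** For feature vectors `v`, `t`:

- evidence `rho_i = 1 - |v_i - t_i|`,
- densities `mu_i = max(v_i, t_i)`,
- `lambda` is the root > −1 of `1 + L = prod_i (1 + L mu_i)` (so the
  λ-fuzzy measure built from the densities satisfies `mu(G) = 1`),
- with the evidence sorted descending and `A_k` the nested prefix sets,
  the measure chain follows `mu(A ∪ {x}) = mu(A) + mu_x + λ mu(A) mu_x`,
- similarity is the Sugeno integral
  `I = max_k min(rho_(k), mu(A_k))`, and the distance is `D = 1 − I ∈ [0, 1]`.

**Stage 3 — matrix and trees.** Pairwise distances are assembled into a
symmetric matrix, written in PHYLIP square format (so PHYLIP `neighbor`
remains usable), and trees are built with UPGMA or Saitou–Nei neighbor
joining.

A synthetic generator produces family-structured benchmarks from known
Markov chains so every stage can be validated against ground truth without
external data.

## Worked example

Generate a 3-family benchmark (3 sequences each, length 1000), compute the
distance matrix, build a tree, and evaluate:

```sh
fim synth --families 3 --per-family 3 --length 1000 --divergence 0.8 --seed 42 -o bench
fim distmat bench/benchmark.fasta -o dist.phy
fim tree dist.phy --method upgma -o tree.nwk
fim roc dist.phy --labels bench/labels.tsv
fim compare --matrices dist.phy dist.phy
```

which prints:

```
wrote 9 sequences to bench/benchmark.fasta
wrote 9x9 matrix to dist.phy
wrote upgma tree for 9 taxa to tree.nwk
AUC	1.000000
CC	1.000000
```

The first lines of `dist.phy` (PHYLIP square format):

```
    9
fam0_rep0 0.000000 0.017731 0.023904 0.055063 0.064072 0.055513 0.047025 0.048037 0.048031
fam0_rep1 0.017731 0.000000 0.033371 0.061979 0.070988 0.056908 0.042057 0.044905 0.043063
```

Within-family distances (≈ 0.02–0.03) are clearly below between-family
distances (≈ 0.04–0.07), the UPGMA tree in `tree.nwk` groups each family as
a clade, and `AUC 1.000000` says intra-family pairs are perfectly separated
from inter-family pairs by the fuzzy-integral distance. `CC 1.000000` is
the Pearson correlation of a distance matrix with itself — the same command
compares matrices from different tools.

The same pipeline is available as a library, including sklearn-style
estimators:

```python
from fimseq import MarkovFeatureTransformer, FuzzyIntegralDistance, read_fasta

seqs = read_fasta("bench/benchmark.fasta")
X = MarkovFeatureTransformer().fit_transform(seqs)   # (n, 20) features
est = FuzzyIntegralDistance().fit(seqs)
est.distance_matrix_                                  # skbio DistanceMatrix
```

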