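"""Stage 1: Markov-chain feature extraction from a protein sequence.

Each sequence is modelled as a realisation of a 20-state discrete-time Markov
chain over the amino-acid alphabet. The 1st-step transition matrix is the
row-normalised matrix of adjacent-pair counts; k-step matrices follow by
Chapman-Kolmogorov (matrix powers). The matrix is powered up until two
consecutive steps agree to an rmsd tolerance, at which point all rows are
(approximately) the chain's stationary distribution and a single row serves
as the sequence's 20-dimensional feature vector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .alphabet import AA_INDEX, N_STATES
from .seqio import ProteinSequence

logger = logging.getLogger(__name__)

RowPolicy = Literal["first_row", "row_average"]

#: Maximum allowed inter-row spread of a "converged" matrix before
#: feature_vector warns that the rows are not effectively identical.
ROW_AGREEMENT_WARN = 1e-3


class ConvergenceError(RuntimeError):
    """The k-step matrices did not converge within the step budget."""


@dataclass(frozen=True)
class TransitionMatrix:
    """A row-stochastic 20x20 matrix together with its step index k."""

    p: np.ndarray
    step: int

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (N_STATES, N_STATES):
            raise ValueError(f"expected {N_STATES}x{N_STATES}, got {p.shape}")
        if self.step < 1:
            raise ValueError("step must be a positive integer")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("entries must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1 within 1e-9")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class FeatureVector:
    """A 20-dim probability vector extracted at the optimal step h."""

    x: np.ndarray
    h: int

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if x.shape != (N_STATES,):
            raise ValueError(f"expected length-{N_STATES} vector, got {x.shape}")
        if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
            raise ValueError("entries must lie in [0, 1]")
        if abs(x.sum() - 1.0) > 1e-9:
            raise ValueError("entries must sum to 1 within 1e-9")
        object.__setattr__(self, "x", x)


def count_pairs(seq: ProteinSequence | str) -> np.ndarray:
    """Count adjacent (overlapping) amino-acid pairs.

    Returns a 20x20 integer matrix C with C[i, j] = number of positions t
    where residue t is state i and residue t+1 is state j. The total equals
    len(seq) - 1.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if len(residues) < 2:
        raise ValueError("sequence must have at least 2 residues")
    idx = np.fromiter((AA_INDEX[c] for c in residues), dtype=np.intp,
                      count=len(residues))
    counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    np.add.at(counts, (idx[:-1], idx[1:]), 1)
    return counts


def first_step_matrix(counts: np.ndarray) -> TransitionMatrix:
    """Row-normalise pair counts into the 1st-step transition matrix.

    Rows whose count sum is zero (amino acids absent from the sequence, or
    only occurring terminally) are filled with the uniform row 1/20 so the
    matrix stays stochastic and powering is well defined.
    """
    counts = np.asarray(counts)
    if counts.shape != (N_STATES, N_STATES) or np.any(counts < 0):
        raise ValueError("counts must be a non-negative 20x20 matrix")
    row_sums = counts.sum(axis=1, dtype=float)
    p = np.full((N_STATES, N_STATES), 1.0 / N_STATES)
    nz = row_sums > 0
    p[nz] = counts[nz] / row_sums[nz, None]
    return TransitionMatrix(p, step=1)


def step_matrix(P: TransitionMatrix, k: int) -> TransitionMatrix:
    """Return the k-step transition matrix P^k (Chapman-Kolmogorov)."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    return TransitionMatrix(np.linalg.matrix_power(P.p, k), step=k)


def rmsd(P: TransitionMatrix | np.ndarray, Q: TransitionMatrix | np.ndarray) -> float:
    """Root-mean-square distance between two 20x20 matrices.

    sqrt( (1/400) * sum_{i,j} (P_ij - Q_ij)^2 )
    """
    a = P.p if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    b = Q.p if isinstance(Q, TransitionMatrix) else np.asarray(Q, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must share a shape")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def optimal_step(
    P1: TransitionMatrix,
    tol: float = 1e-6,
    max_steps: int = 1000,
) -> tuple[TransitionMatrix, int]:
    """Find the least step h with rmsd(P^h, P^{h+1}) < tol.

    Iterates by repeated multiplication with P1 (so h really is the *least*
    such step, not a bracketing approximation).

    Returns
    -------
    (Ph, h) : the converged matrix and its step index.

    Raises
    ------
    ConvergenceError
        If no step up to ``max_steps`` meets the tolerance, e.g. for a
        periodic chain; the message reports the final rmsd.
    """
    if P1.step != 1:
        raise ValueError("optimal_step expects a 1st-step matrix")
    Pk = P1.p
    last_r = np.inf
    for k in range(1, max_steps + 1):
        Pk1 = Pk @ P1.p
        last_r = rmsd(Pk, Pk1)
        if last_r < tol:
            return TransitionMatrix(_renormalize(Pk), step=k), k
        Pk = Pk1
    raise ConvergenceError(
        f"no convergence within {max_steps} steps "
        f"(final rmsd {last_r:.3e} >= tol {tol:g}); "
        "the chain may be periodic or reducible"
    )


def _renormalize(p: np.ndarray) -> np.ndarray:
    # repeated multiplication accumulates ~1e-14 row-sum drift; rescale
    return p / p.sum(axis=1, keepdims=True)


def feature_vector(
    Ph: TransitionMatrix,
    h: int | None = None,
    row_policy: RowPolicy = "first_row",
) -> FeatureVector:
    """Reduce a converged matrix to the per-sequence feature vector.

    Under ``first_row`` (default) the row of amino acid A (index 0) is taken;
    under ``row_average`` the column-wise mean of all 20 rows. When the rows
    disagree by more than 1e-3 in any entry, a warning is emitted: the
    "all rows approximately identical" premise does not hold and the two
    policies would differ materially.
    """
    p = Ph.p
    spread = float(np.max(p.max(axis=0) - p.min(axis=0)))
    if spread > ROW_AGREEMENT_WARN:
        warnings.warn(
            f"converged matrix rows disagree by up to {spread:.2e} "
            f"(> {ROW_AGREEMENT_WARN:g}); feature vector depends on row_policy",
            RuntimeWarning,
            stacklevel=2,
        )
    if row_policy == "first_row":
        x = p[0].copy()
    elif row_policy == "row_average":
        x = p.mean(axis=0)
    else:
        raise ValueError(f"unknown row_policy {row_policy!r}")
    x = x / x.sum()
    return FeatureVector(x, h=h if h is not None else Ph.step)


def extract_features(
    seq: ProteinSequence | str,
    tol: float = 1e-6,
    max_steps: int = 1000,
    row_policy: RowPolicy = "first_row",
) -> FeatureVector:
    """Full Stage-1 pipeline for one sequence: counts -> P1 -> P^h -> feature."""
    P1 = first_step_matrix(count_pairs(seq))
    Ph, h = optimal_step(P1, tol=tol, max_steps=max_steps)
    return feature_vector(Ph, h, row_policy=row_policy)


def stationary_distribution(P: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Stationary left eigenvector of a stochastic matrix (eigen oracle)."""
    p = P.p if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    w, v = np.linalg.eig(p.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


class MarkovFeatureTransformer:
    """Sklearn-style transformer: protein sequences -> 20-dim feature vectors.

    Parameters
    ----------
    tol : float, default 1e-6
        rmsd tolerance defining the optimal step h.
    max_steps : int, default 1000
        Step budget before a ConvergenceError is raised.
    row_policy : {"first_row", "row_average"}, default "first_row"
        Which row of the converged matrix becomes the feature vector.

    Attributes
    ----------
    n_features_in_ : int
        Always 1 (a sequence is one "column"); set by fit.
    step_counts_ : ndarray of int
        Optimal step h per input sequence; set by transform.

    The transformer is stateless (fit learns nothing); it exists so the
    extraction stage composes with sklearn pipelines and model selection.
    """

    def __init__(self, tol: float = 1e-6, max_steps: int = 1000,
                 row_policy: RowPolicy = "first_row"):
        self.tol = tol
        self.max_steps = max_steps
        self.row_policy = row_policy

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"tol": self.tol, "max_steps": self.max_steps,
                "row_policy": self.row_policy}

    def set_params(self, **params) -> "MarkovFeatureTransformer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- estimator API -----------------------------------------------------
    def fit(self, X: Sequence[ProteinSequence | str], y=None):
        self._validate(X)
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[ProteinSequence | str]) -> np.ndarray:
        """Return an (n_sequences, 20) array of feature vectors."""
        self._validate(X)
        feats = []
        hs = []
        for s in X:
            fv = extract_features(s, tol=self.tol, max_steps=self.max_steps,
                                  row_policy=self.row_policy)
            feats.append(fv.x)
            hs.append(fv.h)
        self.step_counts_ = np.asarray(hs, dtype=int)
        return np.vstack(feats)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    @staticmethod
    def _validate(X) -> None:
        if len(X) == 0:
            raise ValueError("X must contain at least one sequence")
        for s in X:
            r = s.residues if isinstance(s, ProteinSequence) else str(s)
            if len(r) < 2:
                raise ValueError("every sequence needs at least 2 residues")
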