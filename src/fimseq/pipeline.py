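"""Stage 3: assemble pairwise fuzzy-integral distances into a matrix.

The distance matrix container is ``skbio.DistanceMatrix`` (symmetric, hollow,
id-labelled). Matrices are serialised in PHYLIP square format (taxon-count
header, 10-character padded names, 6-decimal fixed point) so PHYLIP's
``neighbor`` remains directly usable downstream.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix

from .fuzzy import fuzzy_distance
from .markov import MarkovFeatureTransformer, RowPolicy
from .seqio import ProteinSequence, SanitizePolicy, read_fasta

logger = logging.getLogger(__name__)


class PhylipFormatError(ValueError):
    """Malformed PHYLIP square distance file."""


def pairwise_distances(
    features: np.ndarray,
    ids: Sequence[str],
    workers: int = 2,
) -> DistanceMatrix:
    """Fuzzy-integral distance matrix over feature vectors.

    Parameters
    ----------
    features : (n, 20) array
        One feature vector per row.
    ids : sequence of n unique labels.
    workers : int, default 2
        Thread count for the pairwise stage. Results are written into
        preallocated positions, so the matrix is bit-identical for any
        worker count; parallelism is a speed contract only.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    ids = list(ids)
    if len(ids) != n:
        raise ValueError("ids and features disagree in length")
    if len(set(ids)) != n:
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ids: {dups}")
    if n < 2:
        raise ValueError("need at least 2 feature vectors")
    if workers < 1:
        raise ValueError("workers must be >= 1")

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    d = np.zeros((n, n), dtype=float)

    def _block(block):
        for i, j in block:
            d[i, j] = fuzzy_distance(features[i], features[j])

    if workers == 1 or len(pairs) < 2:
        _block(pairs)
    else:
        blocks = [pairs[b::workers] for b in range(workers)]
        with ThreadPoolExecutor(max_workers=workers) as pool:
            list(pool.map(_block, blocks))
    d = d + d.T
    return DistanceMatrix(d, ids=ids)


def write_phylip(dm: DistanceMatrix, path: str | Path,
                 lower_triangular: bool = False) -> None:
    """Write a distance matrix in PHYLIP square (or lower-triangular) format.

    Names are left-justified and padded/truncated to exactly 10 characters;
    distances carry 6 decimal places. Labels that collide after truncation
    are rejected.
    """
    labels = list(dm.ids)
    short = [lab[:10] for lab in labels]
    if len(set(short)) != len(short):
        dups = sorted({s for s in short if short.count(s) > 1})
        raise ValueError(
            f"labels collide after 10-character truncation: {dups}"
        )
    n = len(labels)
    with open(path, "w") as fh:
        fh.write(f"{n:>5}\n")
        for i, name in enumerate(short):
            row = dm.data[i, :i] if lower_triangular else dm.data[i]
            cells = " ".join(f"{x:.6f}" for x in row)
            fh.write(f"{name:<10}{cells}".rstrip() + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a PHYLIP square-format distance file.

    Wrapped rows (values continued on following lines) are supported.
    Asymmetries up to 1e-6 are averaged away; larger ones are an error.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()
             if ln.strip()]
    if not lines:
        raise PhylipFormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise PhylipFormatError(f"{path}: bad taxon-count line {lines[0]!r}")
    def _floats(tokens: list[str]) -> list[float] | None:
        try:
            return [float(tok) for tok in tokens]
        except ValueError:
            return None

    labels: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        if rows and len(rows[-1]) < n:
            # wrapped rows continue on all-numeric lines
            cont = _floats(ln.split())
            if cont is not None:
                rows[-1].extend(cont)
                continue
        name = ln[:10].strip()
        rest = ln[10:].split()
        if not name:
            raise PhylipFormatError(f"{path}: row with empty taxon name")
        labels.append(name)
        vals = _floats(rest)
        if vals is None:
            raise PhylipFormatError(
                f"{path}: non-numeric field in row {name!r}"
            )
        rows.append(vals)
    if len(labels) != n:
        raise PhylipFormatError(
            f"{path}: header declares {n} taxa but {len(labels)} rows found"
        )
    for lab, row in zip(labels, rows):
        if len(row) != n:
            raise PhylipFormatError(
                f"{path}: row {lab!r} has {len(row)} values, expected {n}"
            )
    d = np.asarray(rows, dtype=float)
    asym = float(np.max(np.abs(d - d.T))) if n else 0.0
    if asym > 1e-6:
        raise PhylipFormatError(
            f"{path}: matrix asymmetric by {asym:.3e} (> 1e-6)"
        )
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=labels)


@dataclass
class PipelineResult:
    """Everything the distance pipeline produces for one FASTA input."""

    distance_matrix: DistanceMatrix
    features: np.ndarray            # (n, 20)
    step_counts: np.ndarray         # optimal h per sequence
    ids: list[str] = field(default_factory=list)

    def feature_table(self) -> list[str]:
        """Tab-separated lines: id then 20 feature values."""
        return [
            "\t".join([sid] + [f"{x:.10g}" for x in row])
            for sid, row in zip(self.ids, self.features)
        ]


class FuzzyIntegralDistance:
    """Sklearn-style estimator for the full sequences-to-distances pipeline.

    ``fit(X)`` extracts Markov features from the sequences in X and computes
    the pairwise Sugeno fuzzy-integral distance matrix; fitted attributes
    carry the results. ``transform(X)`` returns distances from new sequences
    to the fitted ones, so the estimator composes with sklearn tools that
    expect a precomputed-distance transformer.

    Parameters mirror the CLI: tol, max_steps, row_policy, workers.
    """

    def __init__(self, tol: float = 1e-6, max_steps: int = 1000,
                 row_policy: RowPolicy = "first_row", workers: int = 2):
        self.tol = tol
        self.max_steps = max_steps
        self.row_policy = row_policy
        self.workers = workers

    def get_params(self, deep: bool = True) -> dict:
        return {"tol": self.tol, "max_steps": self.max_steps,
                "row_policy": self.row_policy, "workers": self.workers}

    def set_params(self, **params) -> "FuzzyIntegralDistance":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _extractor(self) -> MarkovFeatureTransformer:
        return MarkovFeatureTransformer(
            tol=self.tol, max_steps=self.max_steps, row_policy=self.row_policy
        )

    def fit(self, X: Sequence[ProteinSequence | str], y=None):
        ids = [s.id if isinstance(s, ProteinSequence) else f"seq{i}"
               for i, s in enumerate(X)]
        ext = self._extractor()
        self.features_ = ext.fit_transform(X)
        self.step_counts_ = ext.step_counts_
        self.ids_ = ids
        self.distance_matrix_ = pairwise_distances(
            self.features_, ids, workers=self.workers
        )
        return self

    def transform(self, X: Sequence[ProteinSequence | str]) -> np.ndarray:
        """(len(X), n_fitted) matrix of distances to the fitted sequences."""
        if not hasattr(self, "features_"):
            raise RuntimeError("estimator is not fitted")
        feats = self._extractor().fit_transform(X)
        out = np.empty((feats.shape[0], self.features_.shape[0]))
        for i, f in enumerate(feats):
            for j, g in enumerate(self.features_):
                out[i, j] = fuzzy_distance(f, g)
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X)
        return np.asarray(self.distance_matrix_.data)


def run_pipeline(
    fasta: str | Path,
    tol: float = 1e-6,
    max_steps: int = 1000,
    row_policy: RowPolicy = "first_row",
    sanitize_policy: SanitizePolicy = "drop",
    workers: int = 2,
) -> PipelineResult:
    """Full pipeline: FASTA -> per-sequence features (own optimal h each) ->
    pairwise fuzzy distances -> labelled distance matrix."""
    seqs = read_fasta(fasta, policy=sanitize_policy)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    est = FuzzyIntegralDistance(tol=tol, max_steps=max_steps,
                                row_policy=row_policy, workers=workers)
    try:
        est.fit(seqs)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed on {fasta}: {exc}") from exc
    for sid, h in zip(est.ids_, est.step_counts_):
        logger.info("sequence %s: optimal step h = %d", sid, h)
    return PipelineResult(
        distance_matrix=est.distance_matrix_,
        features=est.features_,
        step_counts=est.step_counts_,
        ids=est.ids_,
    )
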