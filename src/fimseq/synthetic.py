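"""Family-structured synthetic protein sequences from known Markov chains.

Each "family" is a random 20-state Markov chain whose rows are Dirichlet
draws around a shared base composition; a divergence knob in (0, 1] sets the
Dirichlet concentration (low divergence -> families nearly identical, high
divergence -> rows close to independent draws). Sequences are sampled from
the family chain starting at its stationary distribution, so the pipeline's
feature vectors have a known ground truth to recover. Sequence ids encode
family and replicate (famX_repY), letting group labels be rebuilt from ids.

This is a statistical test harness, not a model of protein evolution: there
are no indels, no site heterogeneity, no substitution-matrix structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS, N_STATES
from .markov import stationary_distribution
from .seqio import ProteinSequence, write_fasta


@dataclass(frozen=True)
class FamilyModel:
    """A named generating Markov chain: transition rows + initial law."""

    name: str
    transition: np.ndarray       # (20, 20) row-stochastic
    initial: np.ndarray          # (20,) sums to 1

    def __post_init__(self):
        t = np.asarray(self.transition, dtype=float)
        p0 = np.asarray(self.initial, dtype=float)
        if t.shape != (N_STATES, N_STATES):
            raise ValueError("transition must be 20x20")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1 within 1e-12")
        if abs(p0.sum() - 1.0) > 1e-9 or np.any(p0 < 0):
            raise ValueError("initial must be a probability vector")
        object.__setattr__(self, "transition", t)
        object.__setattr__(self, "initial", p0)


def make_family_models(
    n_families: int, divergence: float, seed: int
) -> list[FamilyModel]:
    """Draw family chains around a shared base composition.

    Rows of family f are Dirichlet(alpha) with alpha = 20*b*(1/d - 1) + 0.1,
    where b is the shared base composition and d the divergence: as d -> 0
    the concentration diverges and every family's rows collapse onto b; at
    d = 1 rows are nearly unconstrained draws. Fully reproducible from seed.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not 0 < divergence <= 1:
        raise ValueError("divergence must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(N_STATES, 5.0))
    alpha = N_STATES * base * (1.0 / divergence - 1.0) + 0.1
    models = []
    for f in range(n_families):
        rows = rng.dirichlet(alpha, size=N_STATES)
        rows = rows / rows.sum(axis=1, keepdims=True)
        models.append(
            FamilyModel(
                name=f"fam{f}",
                transition=rows,
                initial=stationary_distribution(rows),
            )
        )
    return models


def sample_sequence(
    model: FamilyModel, length: int, seed: int, name: str = "seq"
) -> ProteinSequence:
    """Sample one sequence: first residue from the initial law, then the
    chain. Reproducible from seed."""
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(model.transition, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(length)
    states = np.empty(length, dtype=np.intp)
    states[0] = np.searchsorted(np.cumsum(model.initial), u[0])
    s = states[0]
    for t in range(1, length):
        s = int(np.searchsorted(cum[s], u[t]))
        states[t] = s
    residues = "".join(AMINO_ACIDS[i] for i in states)
    return ProteinSequence(id=name, residues=residues)


def make_benchmark(
    n_families: int,
    per_family: int,
    length: int,
    divergence: float,
    seed: int,
    outdir: str | Path,
) -> dict:
    """Write a family-structured benchmark: FASTA + labels TSV + manifest.

    Returns a dict with the models, sequences, labels and file paths. The
    manifest records every parameter, so regeneration is byte-identical.
    """
    if min(n_families, per_family, length) < 1:
        raise ValueError("all counts must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = make_family_models(n_families, divergence, seed)
    seqs: list[ProteinSequence] = []
    labels: dict[str, str] = {}
    # per-sequence seeds derived deterministically, kept below 2^31
    child = np.random.default_rng(seed).integers(
        0, 2**31 - 1, size=n_families * per_family
    )
    k = 0
    for model in models:
        for rep in range(per_family):
            sid = f"{model.name}_rep{rep}"
            seqs.append(
                sample_sequence(model, length, int(child[k]), name=sid)
            )
            labels[sid] = model.name
            k += 1
    fasta = outdir / "benchmark.fasta"
    labels_path = outdir / "labels.tsv"
    manifest_path = outdir / "manifest.json"
    write_fasta(seqs, fasta)
    labels_path.write_text(
        "".join(f"{sid}\t{grp}\n" for sid, grp in labels.items())
    )
    manifest_path.write_text(json.dumps({
        "n_families": n_families,
        "per_family": per_family,
        "length": length,
        "divergence": divergence,
        "seed": seed,
    }, indent=2) + "\n")
    return {
        "models": models,
        "sequences": seqs,
        "labels": labels,
        "fasta": fasta,
        "labels_path": labels_path,
        "manifest": manifest_path,
    }
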