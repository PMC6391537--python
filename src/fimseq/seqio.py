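"""Reading, validating and sanitizing protein sequences from FASTA.

Sequences are restricted to the canonical 20-letter alphabet; anything else
(ambiguity codes B/Z/X/J, selenocysteine U, pyrrolysine O, gaps, whitespace)
is either dropped with a count or rejected, depending on policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO as _BioSeqIO

from .alphabet import AA_INDEX

logger = logging.getLogger(__name__)

SanitizePolicy = Literal["drop", "error"]


class FastaError(ValueError):
    """Malformed FASTA input (empty file, bad header, duplicate ids)."""


class SanitizeError(ValueError):
    """Sequence contains residues outside the canonical alphabet."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence over the canonical 20-letter alphabet.

    Attributes
    ----------
    id : str
        Record identifier (FASTA header up to first whitespace).
    residues : str
        Sanitized residue string; only canonical symbols.
    source_length : int
        Residue count before sanitization.
    """

    id: str
    residues: str
    source_length: int = -1

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 2:
            raise ValueError(
                f"sequence {self.id!r}: needs at least 2 residues, got "
                f"{len(self.residues)}"
            )
        bad = set(self.residues) - set(AA_INDEX)
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: non-canonical residues {sorted(bad)}"
            )
        if self.source_length < 0:
            object.__setattr__(self, "source_length", len(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


def sanitize(raw: str, policy: SanitizePolicy = "drop") -> tuple[str, int]:
    """Uppercase ``raw`` and enforce the canonical alphabet.

    Parameters
    ----------
    raw : str
        Residue text, any case, possibly containing gaps/ambiguity codes.
    policy : {"drop", "error"}
        ``drop`` removes non-canonical characters and reports how many were
        removed; ``error`` raises on the first offending character.

    Returns
    -------
    (residues, removed) : tuple of str and int
        Sanitized uppercase string and the number of characters removed.
    """
    upper = raw.upper()
    if policy == "error":
        for pos, ch in enumerate(upper):
            if ch not in AA_INDEX:
                raise SanitizeError(
                    f"non-canonical character {ch!r} at position {pos}"
                )
        cleaned = upper
    elif policy == "drop":
        cleaned = "".join(ch for ch in upper if ch in AA_INDEX)
    else:  # pragma: no cover - guarded by Literal typing
        raise ValueError(f"unknown sanitize policy {policy!r}")
    removed = len(upper) - len(cleaned)
    if len(cleaned) < 2:
        raise SanitizeError(
            f"fewer than 2 canonical residues remain after sanitization "
            f"(kept {len(cleaned)} of {len(upper)})"
        )
    return cleaned, removed


def read_fasta(
    path: str | Path, policy: SanitizePolicy = "drop"
) -> list[ProteinSequence]:
    """Read a multi-record protein FASTA file.

    Record ids are the header token up to the first whitespace; record order
    is preserved. Residues are sanitized under ``policy``.

    Raises
    ------
    FastaError
        On an empty file, a file with no records, or duplicate ids.
    SanitizeError
        Propagated from :func:`sanitize` under ``policy="error"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise FastaError(f"{path}: empty file")
    records = list(_BioSeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"{path}: no FASTA records found (line 1)")
    seen: dict[str, int] = {}
    out: list[ProteinSequence] = []
    for rec in records:
        if not rec.id:
            raise FastaError(f"{path}: record with empty header")
        seen[rec.id] = seen.get(rec.id, 0) + 1
        raw = str(rec.seq)
        try:
            residues, removed = sanitize(raw, policy)
        except SanitizeError as exc:
            raise SanitizeError(f"record {rec.id!r}: {exc}") from exc
        if removed:
            logger.info(
                "record %s: removed %d non-canonical character(s)",
                rec.id, removed,
            )
        out.append(ProteinSequence(rec.id, residues, source_length=len(raw)))
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise FastaError(f"{path}: duplicate sequence ids: {dups}")
    return out


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path,
                width: int = 70) -> None:
    """Write sequences as wrapped FASTA (round-trips with read_fasta)."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")
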