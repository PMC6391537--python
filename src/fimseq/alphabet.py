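"""Canonical amino-acid state space shared by every module.

The 20 one-letter codes are kept in a fixed, deliberately non-alphabetical
order; row/column ``i`` of every transition matrix and position ``i`` of every
feature vector refer to ``AMINO_ACIDS[i]``.
"""

from __future__ import annotations

#: Ordered 20-letter amino-acid alphabet. Index i <-> Markov state a_{i+1}.
AMINO_ACIDS: tuple[str, ...] = (
    "A", "I", "L", "M", "F", "P", "W", "V", "D", "E",
    "N", "C", "Q", "G", "S", "T", "Y", "R", "H", "K",
)

N_STATES: int = len(AMINO_ACIDS)

#: symbol -> state index 0..19
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

assert N_STATES == 20 and len(AA_INDEX) == 20


def index_of(symbol: str) -> int:
    """Return the state index of a one-letter amino-acid code.

    Raises
    ------
    KeyError
        If ``symbol`` is not one of the 20 canonical residues.
    """
    return AA_INDEX[symbol]
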