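"""Validated sequence records and residue groups."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidArgumentError, InvalidSequenceError
from .scales import AA_INDEX, ALPHABET

_ALPHABET_SET = frozenset(ALPHABET)


@dataclass(frozen=True)
class SequenceRecord:
    """An identifier plus a validated amino-acid string.

    The sequence is the signal peptide fused N-terminally to the mature
    protein.  Input is uppercased; any letter outside the 20-letter alphabet
    is rejected (B, J, O, U, X, Z included — no silent mapping), and the
    sequence must be at least two residues long so that dipeptide features
    are defined.
    """

    id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 2:
            raise InvalidSequenceError(
                f"record {self.id!r}: sequence length {len(seq)} < 2"
            )
        for pos, ch in enumerate(seq):
            if ch not in _ALPHABET_SET:
                raise InvalidSequenceError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def encoded(self) -> np.ndarray:
        """Sequence as an int array over 0..19 (alphabetical residue order)."""
        return np.fromiter(
            (AA_INDEX[c] for c in self.sequence), dtype=np.int64, count=len(self.sequence)
        )


@dataclass(frozen=True)
class ResidueGroup:
    """A named, non-empty set of residue letters."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        members = frozenset(str(m).upper() for m in self.members)
        object.__setattr__(self, "members", members)
        if not members:
            raise InvalidArgumentError(f"group {self.name!r}: empty member set")
        bad = members - _ALPHABET_SET
        if bad:
            raise InvalidArgumentError(
                f"group {self.name!r}: members outside the amino-acid alphabet: {sorted(bad)}"
            )

    def mask(self) -> np.ndarray:
        """Boolean membership vector over the 20-letter alphabet."""
        out = np.zeros(20, dtype=bool)
        for m in self.members:
            out[AA_INDEX[m]] = True
        return out
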