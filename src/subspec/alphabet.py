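"""Amino-acid alphabet shared by all modules.

The frequency algebra of the position-weighting and SDP algorithms is defined
over the 20 canonical amino acids plus the gap symbol.  Nonstandard residue
codes (B, Z, X, U, O, J and '.') are mapped to gap, with a logged count, so
that every column frequency vector lives on the same 21-symbol simplex.
"""

from __future__ import annotations

import logging

logger = logging.getLogger(__name__)

#: Canonical residues in alphabetical one-letter order.  This order doubles as
#: the tie-break order when selecting "most frequent" symbols, and matches the
#: Easel/HMMER amino alphabet used for profile export.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

GAP = "-"

#: Residues first, gap last: with a first-argmax rule the gap loses any tie
#: against a residue and residues tie-break alphabetically.
SYMBOLS: tuple[str, ...] = AMINO_ACIDS + (GAP,)

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
SYMBOL_INDEX = {s: i for i, s in enumerate(SYMBOLS)}

_NONSTANDARD = set("BZXUOJ.")


def sanitize_sequence(seq: str, *, seq_id: str = "?") -> str:
    """Uppercase ``seq`` and map nonstandard residue codes to gap."""
    seq = seq.upper()
    bad = [c for c in seq if c in _NONSTANDARD]
    if bad:
        logger.warning(
            "sequence %s: %d nonstandard residue(s) (%s) mapped to gap",
            seq_id, len(bad), ",".join(sorted(set(bad))),
        )
        for c in set(bad):
            seq = seq.replace(c, GAP)
    unknown = set(seq) - set(SYMBOLS)
    if unknown:
        raise ValueError(
            f"sequence {seq_id} contains unknown symbols: {sorted(unknown)}"
        )
    return seq
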