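"""IUPAC consensus-motif scanning of promoter sequences on both strands.

Supports locating putative transcription-factor binding sites — e.g. the
canonical RBPJ core consensus ``TGGGAA``, the DNA-binding effector of NOTCH
signaling — in a promoter sequence.  The motif is always a parameter, never
hard-coded as biological truth.

Coordinates are 1-based and inclusive on the forward (supplied) strand;
minus-strand hits are matches of the motif's reverse complement against the
forward sequence, reported at their forward-strand start.  ``N`` in the
sequence never matches any motif position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from xsub.errors import XsubError

__all__ = ["MotifHit", "RBPJ_CORE_MOTIF", "scan_iupac"]

RBPJ_CORE_MOTIF = "TGGGAA"

_SEQUENCE_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class MotifHit:
    """One motif match: 1-based forward-strand start, strand, matched bases."""

    start: int
    strand: str
    match: str
    motif: str

    def tss_relative(self, tss_position: int) -> int:
        """Start relative to a 1-based transcription-start-site position."""
        return self.start - tss_position


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for pos, code in enumerate(motif, start=1):
        bases = ambiguous_dna_values.get(code.upper())
        if bases is None:
            raise XsubError(f"invalid IUPAC code {code!r} at motif position {pos}")
        # restrict to unambiguous bases so sequence 'N' never matches
        parts.append(f"[{bases}]" if len(bases) > 1 else bases)
    # lookahead makes overlapping matches visible
    return re.compile(f"(?=({''.join(parts)}))")


def scan_iupac(sequence: str, motif: str, strands: str = "both") -> list[MotifHit]:
    """Report every occurrence of an IUPAC motif in a DNA sequence.

    Parameters
    ----------
    sequence
        DNA over {A, C, G, T, N}, case-insensitive.
    motif
        IUPAC consensus (e.g. ``"TGGGAA"``, ``"YGTGRGAA"``).
    strands
        ``"both"`` (default) or ``"forward"``.

    Returns hits sorted by start position (then strand), overlapping hits
    included.
    """
    if strands not in ("both", "forward"):
        raise XsubError(f"strands must be 'both' or 'forward', got {strands!r}")
    if not motif:
        raise XsubError("empty motif")
    seq = sequence.upper()
    for pos, base in enumerate(seq, start=1):
        if base not in _SEQUENCE_ALPHABET:
            raise XsubError(f"invalid sequence character {base!r} at position {pos}")

    hits: list[MotifHit] = []
    for match in _iupac_regex(motif).finditer(seq):
        hits.append(
            MotifHit(start=match.start() + 1, strand="+", match=match.group(1), motif=motif)
        )
    if strands == "both":
        rc_motif = str(Seq(motif).reverse_complement())
        for match in _iupac_regex(rc_motif).finditer(seq):
            hits.append(
                MotifHit(start=match.start() + 1, strand="-", match=match.group(1), motif=motif)
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits
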