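"""Open reading frames on circular RNAs.

A back-spliced circRNA has no 5' end: an IRES-driven ribosome that initiates
at an internal AUG keeps reading codons across the back-splice junction, and
when the coding span exceeds the circle length it traverses the junction more
than once before hitting a stop ("rolling-circle" translation).  This module
finds every AUG-initiated ORF on a circle under that reading rule, annotates
IRES-proximal starts, derives tryptic peptides unique to the circular protein
relative to its linear counterpart, and extracts junction-spanning probe
sequences.

Circular coordinates are 1-based with position 1 defined as the first
nucleotide downstream of the back-splice junction, so the junction lies
between positions L and 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq
from pyteomics import parser as _pyt_parser

from circscreen.errors import AnalysisError, ContractError

STOP_CODONS = ("UAA", "UAG", "UGA")
START_CODON = "AUG"
_RNA_RE = re.compile(r"^[ACGU]+$")
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


@dataclass
class CircularTranscript:
    """A circular RNA sequence with junction-anchored coordinates.

    ``ires`` is a 1-based inclusive ``(start, end)`` interval on the circle,
    e.g. ``(201, 374)`` for the canonical 1733-nt fixture circle.
    """

    id: str
    sequence: str
    circular: bool = True
    ires: Optional[tuple[int, int]] = None
    source_exons: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("T", "U")
        if len(self.sequence) < 3:
            raise ContractError(f"{self.id}: circular sequence must be >= 3 nt")
        if not _RNA_RE.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGU"))
            raise ContractError(f"{self.id}: non-RNA characters {bad}")
        if self.ires is not None:
            s, e = self.ires
            if not (1 <= s <= e <= len(self.sequence)):
                raise ContractError(
                    f"{self.id}: IRES interval {self.ires} outside 1..{len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrfCall:
    """One predicted ORF on a circle.

    ``traversals`` counts back-splice junction crossings before the stop codon
    completes: ``floor((start - 1 + length_nt - 1) / L)``.  A junction-spanning
    call has ``traversals >= 1``; a rolling-circle call whose coding span
    exceeds the circle length necessarily spans the junction.
    """

    start: int
    frame_offset: int
    length_aa: int
    length_nt: int
    traversals: int
    stop_codon: str
    peptide: str
    ires_proximal: bool = False

    @property
    def unterminated(self) -> bool:
        return self.stop_codon == "none"

    @property
    def junction_spanning(self) -> bool:
        return self.traversals >= 1


def _codon_at(seq: str, start0: int, codon_index: int) -> str:
    """Codon ``codon_index`` (0-based) of the reading that begins at 0-based
    circular position ``start0``, wrapping across the junction as needed."""
    L = len(seq)
    off = start0 + 3 * codon_index
    return "".join(seq[(off + j) % L] for j in range(3))


def find_circular_orfs(
    circ: CircularTranscript,
    max_traversals: int = 4,
    min_length_aa: int = 20,
) -> list[OrfCall]:
    """Scan every AUG on the circle and read until a stop or the traversal cap.

    For each AUG whose A lies at circular positions 1..L, codons are read on
    the conceptually repeated sequence, crossing the junction as needed, until
    the first in-frame stop codon or until the reading would cross the
    junction more than ``max_traversals`` times (the call is then flagged
    unterminated with ``stop_codon="none"``).  Calls shorter than
    ``min_length_aa`` amino acids are dropped.  The result is sorted by
    ``length_aa`` descending, then ``start`` ascending; the "primary ORF" of a
    circle is its first junction-spanning call (see :func:`primary_orf`).
    """
    if not circ.circular:
        raise ContractError(
            f"{circ.id}: not flagged circular; use a linear ORF scanner instead"
        )
    seq = circ.sequence
    L = len(seq)
    calls: list[OrfCall] = []
    for start0 in range(L):
        if _codon_at(seq, start0, 0) != START_CODON:
            continue
        length_aa = None
        stop = "none"
        i = 1
        while True:
            # crossing count once this codon is consumed
            crossings = (start0 + 3 * (i + 1) - 1) // L
            if crossings > max_traversals:
                length_aa = i  # codons consumed so far, AUG included
                break
            codon = _codon_at(seq, start0, i)
            if codon in STOP_CODONS:
                length_aa = i
                stop = codon
                break
            i += 1
        length_nt = 3 * (length_aa + (0 if stop == "none" else 1))
        if stop == "none":
            traversals = max_traversals
        else:
            traversals = (start0 + length_nt - 1) // L
        if length_aa < min_length_aa:
            continue
        pep = str(
            Seq("".join(_codon_at(seq, start0, j) for j in range(length_aa))).translate()
        )
        calls.append(
            OrfCall(
                start=start0 + 1,
                frame_offset=start0 % 3,
                length_aa=length_aa,
                length_nt=length_nt,
                traversals=traversals,
                stop_codon=stop,
                peptide=pep,
            )
        )
    calls.sort(key=lambda c: (-c.length_aa, c.start))
    return calls


def primary_orf(calls: list[OrfCall]) -> Optional[OrfCall]:
    """First junction-spanning call in the sorted call list, or None."""
    for c in calls:
        if c.junction_spanning:
            return c
    return None


def annotate_ires(
    calls: list[OrfCall],
    circ: CircularTranscript,
    proximity_window: int = 60,
) -> list[OrfCall]:
    """Flag calls whose start lies within the IRES or ``proximity_window`` nt
    downstream of it (circular interval, boundaries inclusive).

    Cap-independent initiation on a circle requires an IRES; a biologically
    plausible coding call therefore starts in or just downstream of it.
    """
    if circ.ires is None:
        import warnings

        warnings.warn(f"{circ.id}: no IRES interval; calls returned unchanged")
        return calls
    s, e = circ.ires
    L = len(circ)
    hi = e + proximity_window
    for c in calls:
        pos = c.start
        if s <= pos <= hi:
            c.ires_proximal = True
        elif hi > L and pos <= hi - L:  # window wraps past the junction
            c.ires_proximal = True
        else:
            c.ires_proximal = False
    return calls


def junction_peptides(
    circ_protein: str,
    linear_protein: str,
    protease: str = "trypsin",
    missed_cleavages: int = 0,
    min_length: int = 6,
) -> set[str]:
    """Peptides of an in-silico digest unique to the circular protein.

    Trypsin cleaves C-terminal to K or R except when the next residue is P.
    Peptides shorter than ``min_length`` residues (default 6, the usual
    MS-detectability convention) are excluded.  These are the peptides that
    can validate a circRNA-encoded isoform by mass spectrometry, since they
    are absent from the linear host-gene product.
    """
    for name, p in (("circ_protein", circ_protein), ("linear_protein", linear_protein)):
        if not p:
            raise AnalysisError(f"{name} is empty")
        if not _AA_RE.match(p.upper()):
            bad = sorted(set(p.upper()) - set("ACDEFGHIKLMNPQRSTVWY"))
            raise AnalysisError(f"{name}: non-amino-acid characters {bad}")

    def digest(protein: str) -> set[str]:
        peps = _pyt_parser.cleave(
            protein.upper(), protease, missed_cleavages=missed_cleavages
        )
        return {p for p in peps if len(p) >= min_length}

    return digest(circ_protein) - digest(linear_protein)


def junction_probe_sequence(circ: CircularTranscript, flank: int = 25) -> str:
    """Sequence of length ``2*flank`` spanning the back-splice junction.

    Concatenates the last ``flank`` nt of the circle with its first ``flank``
    nt: the region a junction-specific in-situ probe or divergent-primer
    amplicon must cover, since it does not exist on the linear transcript.
    """
    L = len(circ)
    if flank < 0 or flank > L // 2:
        raise ContractError(f"flank {flank} exceeds half the circle length {L}")
    if flank == 0:
        return ""
    return circ.sequence[L - flank :] + circ.sequence[:flank]
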