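"""Six-frame ORF detection used as an assembly-quality cross-check.

An ORF is an ATG-initiated, stop-terminated codon run (standard genetic
code: stops TAA/TAG/TGA).  Only *maximal* ORFs are reported: for each
stop codon in each frame, the first ATG downstream of the previous stop
(the longest ATG..stop run ending at that stop).  ORFs truncated by the
sequence end are excluded by default since they inflate calls on
assembly fragments; ``include_truncated=True`` reports them too.

Codons containing ``N`` are treated as neither start nor stop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import UnigeneRecord

STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfHit:
    """One ORF; ``start`` is the 0-based leftmost position of the ORF on
    the forward strand, ``length_nt`` includes the stop codon."""

    unigene_id: str
    frame: int  # +1, +2, +3, -1, -2, -3
    start: int
    length_nt: int

    def __post_init__(self):
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {self.frame}")
        if self.length_nt % 3:
            raise ValueError("ORF length must be a multiple of 3")


def _scan_strand(seq: str, min_orf_nt: int, include_truncated: bool):
    """Yield (frame_offset, start, length) for maximal ORFs on one strand."""
    n = len(seq)
    for offset in range(3):
        open_start = None  # first ATG since last stop in this frame
        for pos in range(offset, n - 2, 3):
            codon = seq[pos:pos + 3]
            if "N" in codon:
                continue
            if codon in STOP_CODONS:
                if open_start is not None:
                    length = pos + 3 - open_start
                    if length >= min_orf_nt:
                        yield offset, open_start, length
                    open_start = None
            elif codon == START_CODON and open_start is None:
                open_start = pos
        if include_truncated and open_start is not None:
            # run to the last complete codon of this frame
            end = offset + 3 * ((n - offset) // 3)
            length = end - open_start
            if length >= min_orf_nt:
                yield offset, open_start, length


def find_orfs(
    record: UnigeneRecord,
    min_orf_nt: int = 300,
    include_truncated: bool = False,
) -> list[OrfHit]:
    """All maximal ATG..stop ORFs of length >= *min_orf_nt* in six frames.

    Reverse-strand ORFs are reported in forward coordinates (``start``
    is the leftmost base of the ORF on the forward strand).
    """
    if min_orf_nt < 3 or min_orf_nt % 3:
        raise ValueError("min_orf_nt must be a positive multiple of 3")
    seq = record.seq
    n = len(seq)
    hits: list[OrfHit] = []
    for offset, start, length in _scan_strand(seq, min_orf_nt, include_truncated):
        hits.append(OrfHit(record.id, offset + 1, start, length))
    rc = reverse_complement(seq)
    for offset, start, length in _scan_strand(rc, min_orf_nt, include_truncated):
        # position on forward strand of the leftmost ORF base
        fwd_start = n - (start + length)
        hits.append(OrfHit(record.id, -(offset + 1), fwd_start, length))
    hits.sort(key=lambda h: (h.start, h.frame, h.length_nt))
    return hits


def screen_unigenes(
    records: Sequence[UnigeneRecord],
    min_orf_nt: int = 300,
    include_truncated: bool = False,
) -> tuple[set[str], float]:
    """Ids with at least one qualifying ORF and the fraction they make up."""
    if not records:
        raise ValueError("screen_unigenes requires a non-empty record list")
    coding = {
        r.id for r in records if find_orfs(r, min_orf_nt, include_truncated)
    }
    return coding, len(coding) / len(records)
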