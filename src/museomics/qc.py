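"""Read QC: adapter trimming and length filtering.

The historical-library QC is deliberately minimal: trim 3' adapter
contamination requiring as little as a single base of overlap, then discard
anything shorter than 30 bp. Degraded museum libraries are dominated by short
inserts, so adapter read-through is the norm rather than the exception.
"""

from __future__ import annotations

from .io import Read

#: Illumina single-end / TruSeq read-1 adapter, the documented default.
DEFAULT_ADAPTER = "AGATCGGAAGAGC"


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _trim_once(bases: str, adapter: str, min_overlap: int, max_error_rate: float) -> int:
    """Return the cut position for one application of the trimming rule,
    or len(bases) if nothing matches.

    A full internal adapter occurrence removes the occurrence and everything
    3' of it; otherwise the longest read suffix matching an adapter prefix
    (length >= min_overlap) is removed.
    """
    la, lb = len(adapter), len(bases)
    # full internal occurrence (leftmost)
    if lb >= la:
        if max_error_rate == 0.0:
            idx = bases.find(adapter)
            if idx != -1:
                return idx
        else:
            budget_full = int(max_error_rate * la)
            for i in range(lb - la + 1):
                if _mismatches(bases[i : i + la], adapter) <= budget_full:
                    return i
    # longest suffix of read == prefix of adapter
    for l in range(min(la, lb), min_overlap - 1, -1):
        if _mismatches(bases[lb - l :], adapter[:l]) <= int(max_error_rate * l):
            return lb - l
    return lb


def trim_adapter(
    read: Read,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 1,
    max_error_rate: float = 0.0,
) -> Read:
    """Trim 3' adapter sequence from a read (single application).

    A full internal adapter occurrence removes the occurrence and everything
    3' of it; otherwise the longest read suffix equal to an adapter prefix
    (length >= min_overlap) is removed. With the default ``max_error_rate=0``
    matching is exact. Single-base overlaps are honoured, so a read whose
    last base happens to match the adapter start loses that base — the
    accepted cost of trimming adapters from very short inserts.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    cut = _trim_once(read.bases, adapter.upper(), min_overlap, max_error_rate)
    quals = read.quals[:cut] if read.quals is not None else None
    return Read(read.id, read.bases[:cut], quals)


def length_filter(reads: list[Read], min_len: int = 30) -> list[Read]:
    """Keep reads of length >= min_len (order preserved)."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in reads if len(r) >= min_len]


def qc_reads(
    reads: list[Read],
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 1,
    min_len: int = 30,
    max_error_rate: float = 0.0,
) -> tuple[list[Read], dict]:
    """Trim then length-filter a read set; returns (reads, summary dict)."""
    trimmed = [trim_adapter(r, adapter, min_overlap, max_error_rate) for r in reads]
    kept = length_filter(trimmed, min_len)
    summary = {
        "n_in": len(reads),
        "n_out": len(kept),
        "n_discarded_short": len(reads) - len(kept),
    }
    return kept, summary
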