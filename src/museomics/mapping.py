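"""Seed-and-extend ungapped read mapping with a mismatch budget.

A k-mer hash index stands in for an FM-index at the scale of a mitochondrial
genome. Reads are placed ungapped on either strand at the offset minimising
the Hamming distance to the reference; a stringency parameter expressed as a
mismatch *fraction* of read length bounds the accepted distance
(budget = floor(frac * L)), echoing how short-read aligners expose ``-n``.

Mapping quality is a declared deterministic function of placement ambiguity:
60 for a unique best placement within budget, 0 for a tied best, and an
intermediate value scaled by the best/second-best mismatch gap otherwise.
Filtering at MAPQ >= 30 therefore keeps only confidently unique placements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import NucleotideSequence, Read

_CODE = np.full(256, 5, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("N")] = 4
_CODE[ord("-")] = 5

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def encode(bases: str) -> np.ndarray:
    """Encode bases as int8: A,C,G,T -> 0..3; N -> 4; gap/other -> 5.

    Codes 4 and 5 never compare equal to anything, so N in a read mismatches
    every reference base and vice versa.
    """
    raw = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def revcomp(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadAlignment:
    """Ungapped placement of a read on a reference."""

    read_id: str
    ref_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive; end - start == read length
    strand: str  # "+" or "-"
    n_mismatch: int
    mapq: int


@dataclass
class StringencySweepResult:
    stringency: float
    n_mapped: int
    n_total: int

    @property
    def fraction_mapped(self) -> float:
        return self.n_mapped / self.n_total if self.n_total else 0.0


class KmerIndex:
    """Exact k-mer positional index over a reference (forward strand only;
    reads are additionally searched in reverse complement)."""

    def __init__(self, ref: NucleotideSequence, k: int = 13, circular: bool = False):
        if k < 4:
            raise ValueError("k must be >= 4")
        if len(ref) < k:
            raise ValueError(f"reference shorter than k ({len(ref)} < {k})")
        self.ref = ref
        self.k = k
        self.circular = circular
        self.length = len(ref.bases)
        # circular references are handled by a wrap-around extension; hits are
        # re-projected modulo the true length at lookup time
        seq = ref.bases + (ref.bases[: self.length - 1] if circular else "")
        self.codes = encode(seq)
        self._index: dict[int, list[int]] = {}
        kmers, valid = _rolling_kmers(self.codes, k)
        for pos in np.nonzero(valid)[0]:
            self._index.setdefault(int(kmers[pos]), []).append(int(pos))

    def positions(self, kmer_code: int) -> list[int]:
        return self._index.get(kmer_code, [])


def _rolling_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer integer codes of a coded sequence plus a validity mask
    (windows containing N/gap are invalid)."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows < 4).all(axis=1)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    kmers = windows.astype(np.int64) @ weights
    return kmers, valid


def build_index(ref: NucleotideSequence, k: int = 13, circular: bool = False) -> KmerIndex:
    return KmerIndex(ref, k=k, circular=circular)


def _candidate_starts(seq_codes: np.ndarray, index: KmerIndex) -> set[int]:
    k = index.k
    L = len(seq_codes)
    kmers, valid = _rolling_kmers(seq_codes, k)
    # non-circular: the read must fit inside the reference; circular: any
    # start in [0, length) is a distinct placement on the extended sequence
    max_start = index.length - 1 if index.circular else index.length - L
    starts: set[int] = set()
    for i in np.nonzero(valid)[0]:
        for pos in index.positions(int(kmers[i])):
            s = pos - int(i)
            if 0 <= s <= max_start:
                starts.add(s)
    return starts


def map_read(read: Read, index: KmerIndex, max_mismatch_frac: float = 0.04) -> ReadAlignment | None:
    """Best ungapped placement of a read within the mismatch budget, or None.

    Budget = floor(max_mismatch_frac * read length). Among candidate
    placements seeded by exact k-mer hits on either strand, the one with the
    fewest mismatches wins; ties are broken towards the smallest (start,
    strand) and reported with MAPQ 0.
    """
    L = len(read)
    if L < index.k:
        return None
    if L > index.length:
        return None
    budget = int(max_mismatch_frac * L)
    placements: list[tuple[int, int, str]] = []  # (mismatches, start, strand)
    for strand, codes in (("+", encode(read.bases)), ("-", encode(revcomp(read.bases)))):
        for start in _candidate_starts(codes, index):
            mm = int(np.count_nonzero(index.codes[start : start + L] != codes))
            if mm <= budget:
                placements.append((mm, start, strand))
    if not placements:
        return None
    placements.sort()  # "+" < "-" breaks strand ties towards forward
    mm, start, strand = placements[0]
    if len(placements) == 1:
        mapq = 60
    elif placements[1][0] == mm:
        mapq = 0
    else:
        gap = placements[1][0] - mm
        mapq = min(60, int(60 * gap / (budget + 1)))
    if index.circular:
        start %= index.length
    return ReadAlignment(read.id, index.ref.id, start, start + L, strand, mm, mapq)


def map_reads(
    reads: list[Read], index: KmerIndex, max_mismatch_frac: float = 0.04
) -> list[ReadAlignment]:
    out = []
    for read in reads:
        aln = map_read(read, index, max_mismatch_frac)
        if aln is not None:
            out.append(aln)
    return out


def filter_mapq(alignments: list[ReadAlignment], min_mapq: int = 30) -> list[ReadAlignment]:
    """Keep alignments with MAPQ >= min_mapq (the ``-Q 30`` semantics)."""
    return [a for a in alignments if a.mapq >= min_mapq]


def remove_duplicates(alignments: list[ReadAlignment]) -> list[ReadAlignment]:
    """Collapse presumed PCR duplicates.

    Alignments sharing (start, end, strand) are reduced to a single
    representative: highest MAPQ, ties by lexicographically smallest read id.
    Output is sorted by start. Idempotent.
    """
    best: dict[tuple[int, int, str], ReadAlignment] = {}
    for a in alignments:
        key = (a.start, a.end, a.strand)
        cur = best.get(key)
        if cur is None or (-a.mapq, a.read_id) < (-cur.mapq, cur.read_id):
            best[key] = a
    return sorted(best.values(), key=lambda a: (a.start, a.end, a.strand))


def endogenous_sweep(
    reads: list[Read],
    ref: NucleotideSequence,
    stringencies: tuple[float, ...] = (0.04, 0.01, 0.001),
    min_mapq: int = 30,
    k: int = 13,
) -> list[StringencySweepResult]:
    """Estimate endogenous content: map -> MAPQ filter -> dedup -> count,
    at each mismatch stringency. Tighter stringencies can only lose reads."""
    index = build_index(ref, k=k)
    results = []
    for frac in stringencies:
        alns = map_reads(reads, index, max_mismatch_frac=frac)
        alns = filter_mapq(alns, min_mapq)
        alns = remove_duplicates(alns)
        results.append(StringencySweepResult(frac, len(alns), len(reads)))
    return results


def write_samlite(alignments: list[ReadAlignment], path) -> None:
    """Emit the TSV alignment dump ("SAM-lite")."""
    with open(path, "w") as fh:
        fh.write("read_id\tref_id\tstart\tend\tstrand\tn_mismatch\tmapq\n")
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.ref_id}\t{a.start}\t{a.end}\t{a.strand}\t{a.n_mismatch}\t{a.mapq}\n"
            )
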