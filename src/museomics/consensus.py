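"""Majority-rule consensus calling and iterative reference refinement.

The reconstruction strategy for a degraded library is: map reads to a
diverged starting reference with a permissive mismatch budget, call a 50%
majority-rule consensus (falling back to the reference where nothing mapped),
and use that consensus as the reference for the next round. The mapped
read-ID set stabilises within a few rounds; a stricter consensus (90%
majority, depth >= 3, no reference fill) is then called on the final
alignment, and an optional last pass re-maps everything with the strict
budget and calls an 85% majority / depth >= 10 consensus. Regions of depth
>= 3 delimit the trustworthy portion of the result.

Conventions (documented, tested): majority comparisons use >= threshold;
ties among most-frequent bases yield N; "regions lacking mapped reads" means
depth == 0 exactly — columns with 0 < depth < min_depth are called N, never
filled from the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import NucleotideSequence, Read, Region
from .mapping import (
    ReadAlignment,
    build_index,
    encode,
    filter_mapq,
    map_reads,
    revcomp,
)

_BASES = np.array(list("ACGT"))


@dataclass
class Pileup:
    """Per-column A/C/G/T counts over a reference. N bases in reads do not
    contribute to counts or depth."""

    ref_id: str
    counts: np.ndarray  # (L, 4) int

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __len__(self) -> int:
        return self.counts.shape[0]


@dataclass
class ConsensusConfig:
    majority_threshold: float
    min_depth: int
    fill_with_reference: bool

    def __post_init__(self) -> None:
        if not (0 < self.majority_threshold <= 1):
            raise ValueError("majority_threshold must be in (0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


#: Iteration-phase call: permissive, keeps reference where nothing mapped.
ITER_CONFIG = ConsensusConfig(0.5, 1, True)
#: Final call after convergence: 90% majority, depth >= 3, no fill.
FINAL_CONFIG = ConsensusConfig(0.9, 3, False)
#: Stringent re-mapped call: 85% majority, depth >= 10, no fill.
STRINGENT_CONFIG = ConsensusConfig(0.85, 10, False)


@dataclass
class IterationLog:
    iteration: int
    n_mapped: int
    n_changed_sites: int
    converged: bool


def build_pileup(
    alignments: list[ReadAlignment], reads: dict[str, Read] | list[Read], ref: NucleotideSequence
) -> Pileup:
    """Stack aligned read bases into per-column counts."""
    if not isinstance(reads, dict):
        reads = {r.id: r for r in reads}
    L = len(ref)
    counts = np.zeros((L, 4), dtype=np.int64)
    for aln in alignments:
        if aln.start < 0 or aln.end > L:
            raise ValueError(f"alignment {aln.read_id} out of reference bounds")
        read = reads[aln.read_id]
        bases = read.bases if aln.strand == "+" else revcomp(read.bases)
        codes = encode(bases)
        ok = codes < 4
        pos = np.arange(aln.start, aln.end)[ok]
        np.add.at(counts, (pos, codes[ok].astype(np.int64)), 1)
    return Pileup(ref.id, counts)


def call_consensus(pileup: Pileup, ref: NucleotideSequence, cfg: ConsensusConfig) -> NucleotideSequence:
    """Majority-rule consensus call over a pileup.

    Per column: below min_depth the call is N, except that a depth-0 column
    is filled from the reference when cfg.fill_with_reference; otherwise the
    modal base is called iff count/depth >= majority_threshold (ties -> N).
    """
    if len(pileup) != len(ref):
        raise ValueError("pileup/reference length mismatch")
    counts = pileup.counts
    depth = pileup.depth
    top = counts.max(axis=1)
    argtop = counts.argmax(axis=1)
    tied = (counts == top[:, None]).sum(axis=1) > 1
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    out = _BASES[argtop].copy()
    out[tied | (frac < cfg.majority_threshold)] = "N"
    shallow = depth < cfg.min_depth
    out[shallow] = "N"
    if cfg.fill_with_reference:
        zero = depth == 0
        ref_arr = np.array(list(ref.bases))
        out[zero] = ref_arr[zero]
    return NucleotideSequence(ref.id + "_consensus", "".join(out))


def iterative_refine(
    reads: list[Read],
    initial_ref: NucleotideSequence,
    max_iterations: int = 10,
    iter_cfg: ConsensusConfig = ITER_CONFIG,
    final_cfg: ConsensusConfig = FINAL_CONFIG,
    map_frac: float = 0.10,
    k: int = 13,
) -> tuple[NucleotideSequence, list[IterationLog]]:
    """Iteratively refine a mapping reference from the reads themselves.

    Each round maps all reads at the permissive budget, drops unmapped ones,
    calls the iteration-phase consensus and uses it as the next reference.
    Iteration stops early once the mapped read-ID set is identical to the
    previous round's (or after max_iterations). The returned consensus is the
    final_cfg call on the last round's alignment.
    """
    if not initial_ref.bases:
        raise ValueError("initial reference is empty")
    reads_by_id = {r.id: r for r in reads}
    ref = initial_ref
    prev_ids: set[str] | None = None
    logs: list[IterationLog] = []
    alignments: list[ReadAlignment] = []
    for it in range(1, max_iterations + 1):
        index = build_index(ref, k=k)
        alignments = map_reads(reads, index, max_mismatch_frac=map_frac)
        if it == 1 and not alignments:
            raise ValueError("no seed alignment: zero reads mapped in iteration 1")
        mapped_ids = {a.read_id for a in alignments}
        pileup = build_pileup(alignments, reads_by_id, ref)
        new_ref = call_consensus(pileup, ref, iter_cfg)
        new_ref = NucleotideSequence(initial_ref.id + "_iter", new_ref.bases)
        n_changed = sum(a != b for a, b in zip(ref.bases, new_ref.bases))
        converged = prev_ids is not None and mapped_ids == prev_ids
        logs.append(IterationLog(it, len(mapped_ids), n_changed, converged))
        ref = new_ref
        if converged:
            break
        prev_ids = mapped_ids
    final_pileup = build_pileup(alignments, reads_by_id, ref)
    final = call_consensus(final_pileup, ref, final_cfg)
    final = NucleotideSequence(initial_ref.id + "_refined", final.bases)
    return final, logs


def final_stringent_call(
    reads: list[Read],
    converged_consensus: NucleotideSequence,
    cfg: ConsensusConfig = STRINGENT_CONFIG,
    map_frac: float = 0.04,
    min_mapq: int = 0,
    k: int = 13,
) -> tuple[NucleotideSequence, Pileup]:
    """Re-map all reads at the strict budget and call the stringent consensus.

    Sites below cfg.min_depth (default 10) are N. Returns the consensus and
    the pileup so depth-based region extraction can reuse the alignment.
    """
    # mapping target must not contain gaps; N is fine (never matches a seed)
    index = build_index(converged_consensus, k=k)
    alignments = map_reads(reads, index, max_mismatch_frac=map_frac)
    if min_mapq > 0:
        alignments = filter_mapq(alignments, min_mapq)
    pileup = build_pileup(alignments, reads, converged_consensus)
    consensus = call_consensus(pileup, converged_consensus, cfg)
    consensus = NucleotideSequence(converged_consensus.id + "_stringent", consensus.bases)
    return consensus, pileup


def extract_regions(
    depths: Pileup | np.ndarray,
    min_depth: int = 3,
    min_length: int = 1,
    ref_id: str = "ref",
) -> list[Region]:
    """Maximal runs of consecutive columns with depth >= min_depth (and run
    length >= min_length), as 0-based half-open Regions with mean depth."""
    if isinstance(depths, Pileup):
        ref_id = depths.ref_id
        depths = depths.depth
    depths = np.asarray(depths)
    if (depths < 0).any():
        raise ValueError("depths must be non-negative")
    ok = depths >= min_depth
    regions: list[Region] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start >= min_length:
            regions.append(Region(ref_id, int(start), int(end), float(depths[start:end].mean())))
    return regions
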