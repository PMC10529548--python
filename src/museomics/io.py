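"""Readers and writers for the plain-text formats the pipeline touches.

All in-memory coordinates are 0-based half-open; only rendered, human-readable
reports use 1-based inclusive positions. FASTA/FASTQ parsing is delegated to
Biopython, Newick to dendropy; this module adds the validation and coordinate
conventions the rest of the package relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

REFERENCE_ALPHABET = frozenset("ACGTN-")
READ_ALPHABET = frozenset("ACGTN")


@dataclass
class NucleotideSequence:
    """A named nucleotide sequence over {A,C,G,T,N,-}.

    Lowercase input is normalised to uppercase on construction; any character
    outside the alphabet raises with the offending 0-based position.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        for pos, ch in enumerate(self.bases):
            if ch not in REFERENCE_ALPHABET:
                raise ValueError(
                    f"illegal character {ch!r} at position {pos} in sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Read:
    """A sequencing read: bases over {A,C,G,T,N} plus optional Phred qualities."""

    id: str
    bases: str
    quals: list[int] | None = None

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.quals)} qualities"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Region:
    """A contiguous reference interval, 0-based half-open, with mean read depth."""

    ref_id: str
    start: int
    end: int
    mean_depth: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end})")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (multi-)FASTA file. IDs are the first whitespace token."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or non-FASTA file: {path}")
    return [NucleotideSequence(rec.id, str(rec.seq)) for rec in records]


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.bases), width):
                fh.write(seq.bases[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)


def read_fastq(path: str | Path) -> list[Read]:
    """Read a FASTQ file into Reads; an empty file yields an empty list."""
    out: list[Read] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            out.append(Read(rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"])))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc
    return out


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            quals = read.quals if read.quals is not None else [40] * len(read.bases)
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# BED (3-column, 0-based half-open)


def write_bed(regions: Sequence[Region], path: str | Path) -> None:
    """Serialise regions as 3-column BED in input order."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.ref_id}\t{r.start}\t{r.end}\n")


def format_region_report(regions: Sequence[Region]) -> str:
    """Human-readable region report: 1-based inclusive coordinates."""
    lines = ["ref\tstart_1based\tend_1based\tlength\tmean_depth"]
    for r in regions:
        lines.append(f"{r.ref_id}\t{r.start + 1}\t{r.end}\t{len(r)}\t{r.mean_depth:.2f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Newick


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree; duplicate tip labels are an error."""
    return parse_newick_string(Path(path).read_text())


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialise preserving branch lengths to 12 significant digits."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
        unquoted_underscores=True,
    )
    Path(path).write_text(s)


def parse_newick_string(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises format-specific subclasses
        if "occurrences of the same tax" in str(exc):
            raise ValueError(f"duplicate tip labels: {exc}") from exc
        raise ValueError(f"malformed newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels")
    return tree


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
        unquoted_underscores=True,
    ).strip()


# ---------------------------------------------------------------------------
# Morphology CSV

#: Values in the sex column treated as missing.
MISSING_SEX_CODES = {"", "?", "NA", "na", "n/a", "unknown"}

FACTOR_COLUMNS = ("specimen_id", "population", "sex")


def read_morph_csv(path: str | Path) -> pd.DataFrame:
    """Read a specimen-by-character morphology table.

    Expected columns: specimen_id, population, sex, then numeric character
    columns. Empty cells are missing data (kept as NaN, never zero); unknown
    sex codes (e.g. ``?``) become missing. A non-numeric value in a character
    column raises, naming the offending cell.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in FACTOR_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"morphology table missing required column {col!r}")
    char_cols = [c for c in df.columns if c not in FACTOR_COLUMNS]
    out = df[list(FACTOR_COLUMNS)].copy()
    out["sex"] = out["sex"].where(~out["sex"].isin(MISSING_SEX_CODES), other=pd.NA)
    out["population"] = out["population"].astype("category")
    for col in char_cols:
        vals = []
        for i, raw in enumerate(df[col]):
            raw = raw.strip()
            if raw == "" or raw.upper() == "NA":
                vals.append(float("nan"))
                continue
            try:
                vals.append(float(raw))
            except ValueError:
                raise ValueError(
                    f"non-numeric value {raw!r} in column {col!r}, row {i + 2} of {path}"
                ) from None
        out[col] = vals
    return out


def write_morph_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
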