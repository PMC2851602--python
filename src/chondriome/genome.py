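"""Circular-sequence data model and rotation/strand-invariant utilities.

Plant mitochondrial genomes are conventionally represented as a single
"master circle" even though the physical DNA is likely multipartite.  All
downstream stages (contig assembly, synteny, annotation) therefore work on
a :class:`CircularGenome`, and comparisons between alternative
reconstructions are done on a canonical form that is invariant under
rotation and reverse complementation.

Internal coordinates are 0-based half-open throughout; anything written to
reports or GFF3 is converted to 1-based inclusive at the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularGenome",
    "Interval",
    "GeneModel",
    "revcomp",
    "read_genomes",
    "write_fasta",
    "write_metadata",
    "rotate",
    "canonical_form",
    "subseq",
    "percent_identity",
]

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a genome, optionally wrapping the origin.

    ``start`` is 0-based inclusive, ``end`` exclusive.  When ``wraps`` is
    set the interval runs from ``start`` to the sequence end and continues
    from the origin to ``end`` (so ``end <= start`` is legal only then).
    """

    start: int
    end: int
    strand: Literal["+", "-"] = "+"
    wraps: bool = False

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps:
            if genome_length is None:
                raise ValueError("wrapping interval needs the genome length")
            return (self.end - self.start) % genome_length
        return self.end - self.start

    def to_one_based(self) -> tuple[int, int]:
        """External (reported) coordinates: 1-based inclusive."""
        return self.start + 1, self.end


@dataclass
class CircularGenome:
    """A single (usually circular) genome sequence.

    Attributes
    ----------
    id:
        Record identifier, e.g. an accession number.
    seq:
        Uppercase DNA over ``{A, C, G, T, N}``.
    topology:
        ``"circular"`` or ``"linear"``.  Circular genomes admit rotation
        without loss of information.
    source:
        Free-text provenance (file of origin, simulation seed, ...).
    """

    id: str
    seq: str
    topology: Literal["circular", "linear"] = "circular"
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - _ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"genome {self.id!r}: illegal character {self.seq[pos]!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


@dataclass
class GeneModel:
    """One catalog gene: name, class and coding (or structural) sequence."""

    name: str
    kind: Literal["protein", "tRNA", "rRNA", "pseudo"]
    cds_seq: str
    notes: str = ""

    def __post_init__(self) -> None:
        self.cds_seq = self.cds_seq.upper()
        if self.kind == "protein":
            trimmed = self.cds_seq
            if trimmed[-3:] in ("TAA", "TAG", "TGA"):
                trimmed = trimmed[:-3]
            if len(trimmed) % 3 != 0:
                raise ValueError(f"gene {self.name!r}: CDS length not a multiple of 3")


# ---------------------------------------------------------------------------
# I/O


def read_genomes(
    path: str | Path,
    format: Literal["fasta", "genbank"] = "fasta",
    topology_default: Literal["circular", "linear"] = "circular",
) -> list[CircularGenome]:
    """Read genome records from a FASTA or GenBank flat file.

    Topology is taken from GenBank metadata when present, otherwise
    ``topology_default`` applies (public records are not consistent about
    marking circular topology, so the default is configurable).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise ValueError(f"{path}: no records")
    out: list[CircularGenome] = []
    for rec in records:
        topology = topology_default
        annot = getattr(rec, "annotations", {}) or {}
        if annot.get("topology") in ("circular", "linear"):
            topology = annot["topology"]
        out.append(
            CircularGenome(
                id=rec.id, seq=str(rec.seq), topology=topology, source=str(path)
            )
        )
    return out


def write_fasta(genomes: Iterable[CircularGenome], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.seq), id=g.id, description=g.topology) for g in genomes
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def write_metadata(genomes: Iterable[CircularGenome], path: str | Path) -> None:
    """JSON sidecar with id, topology, length and source per record."""
    meta = [
        {"id": g.id, "topology": g.topology, "length": len(g), "source": g.source}
        for g in genomes
    ]
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Rotation / canonical form


def rotate(g: CircularGenome, k: int) -> CircularGenome:
    """Rotate a circular genome so that former position ``k`` becomes 0."""
    if not g.is_circular:
        raise ValueError("cannot rotate a linear genome")
    k %= len(g)
    return CircularGenome(g.id, g.seq[k:] + g.seq[:k], g.topology, g.source)


def _least_rotation(s: str) -> str:
    """Booth's algorithm: lexicographically minimal rotation in O(n)."""
    ss = s + s
    n = len(s)
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + n]


def canonical_form(g: CircularGenome) -> str:
    """Rotation- and strand-invariant representative of a circular sequence.

    Defined as the lexicographically minimal string over all rotations of
    the sequence and of its reverse complement; two master-circle
    hypotheses describe the same molecule iff their canonical forms agree.
    """
    if not g.is_circular:
        raise ValueError("canonical_form is defined for circular genomes only")
    return min(_least_rotation(g.seq), _least_rotation(revcomp(g.seq)))


# ---------------------------------------------------------------------------
# Slicing


def subseq(g: CircularGenome, iv: Interval) -> str:
    """Extract the sequence of an interval, wrap- and strand-aware."""
    n = len(g)
    if not (0 <= iv.start < n):
        raise ValueError(f"interval start {iv.start} out of range for length {n}")
    if iv.wraps:
        if not g.is_circular:
            raise ValueError("wrapping interval on a linear genome")
        if not (0 <= iv.end <= n):
            raise ValueError(f"interval end {iv.end} out of range for length {n}")
        s = g.seq[iv.start :] + g.seq[: iv.end]
    else:
        if not (iv.start <= iv.end <= n):
            raise ValueError(f"interval end {iv.end} out of range for length {n}")
        s = g.seq[iv.start : iv.end]
    return revcomp(s) if iv.strand == "-" else s


# ---------------------------------------------------------------------------
# Identity arithmetic


def percent_identity(total_bases: int, mismatches: int) -> float:
    """Percent identity from base and mismatch counts, half-up to 2 decimals.

    E.g. 2 mismatches over 20,513 bases gives 99.99.
    """
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    if mismatches < 0 or mismatches > total_bases:
        raise ValueError("mismatches must lie in [0, total_bases]")
    frac = Decimal(100) * (Decimal(1) - Decimal(mismatches) / Decimal(total_bases))
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
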