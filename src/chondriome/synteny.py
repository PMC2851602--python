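"""Pairwise comparison of circular genomes.

The comparison strategy mirrors how whole-organelle dot plots are usually
read by eye: find maximal exact matches (anchors) between the two circles,
chain colinear anchors into syntenic blocks, and interpret the block
structure.  From the blocks we derive

* large duplications (self-comparison, repeat pairs above a size cutoff),
* recombination junctions (consecutive blocks on the circular query whose
  images on the subject are not adjacent and colinear),
* large insertions/deletions (gap present in only one genome), and
* SNP/small-indel tallies inside syntenic blocks (gap regions between
  consecutive anchors are globally aligned with affine gap costs).

Because one crossover on a circle produces two new block junctions,
junction counts are even for simple repeat-mediated exchanges; published
event counts derived from dot plots are treated as lower bounds.

The subject genome should be masked for large duplications before
junction counting (``mask_large_duplications``) so that each duplicated
region is represented once; otherwise every duplication pair shows up as
a spurious rearrangement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align

from .genome import CircularGenome, revcomp

__all__ = [
    "Anchor",
    "SyntenyBlock",
    "StructuralCall",
    "find_anchors",
    "chain_blocks",
    "mask_large_duplications",
    "detect_duplications",
    "detect_recombination",
    "detect_large_indels",
    "count_syntenic_variants",
    "export_dotplot",
]


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match between query and subject.

    Coordinates are 0-based half-open on the *forward* strand of each
    genome; for a minus-strand anchor the query interval matches the
    reverse complement of the subject interval.  Intervals may run past
    the sequence end (``end > genome length``) to describe matches that
    wrap the origin of a circular genome.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # "+" or "-"

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


@dataclass
class SyntenyBlock:
    """A colinear, consistently stranded chain of anchors."""

    anchors: list[Anchor]
    strand: str
    n_snp: int = 0
    n_indel: int = 0
    aligned_bases: int = 0
    mismatch_bases: int = 0

    @property
    def q_start(self) -> int:
        return self.anchors[0].q_start

    @property
    def q_end(self) -> int:
        return self.anchors[-1].q_end

    @property
    def q_length(self) -> int:
        return self.q_end - self.q_start

    @property
    def s_start(self) -> int:
        return min(a.s_start for a in self.anchors)

    @property
    def s_end(self) -> int:
        return max(a.s_end for a in self.anchors)

    @property
    def identity(self) -> float:
        if self.aligned_bases == 0:
            return 1.0
        return 1.0 - self.mismatch_bases / self.aligned_bases


@dataclass(frozen=True)
class StructuralCall:
    """One structural difference between (or within) genomes."""

    kind: str  # duplication | recombination_junction | insertion | deletion
    q_interval: tuple[int, int]
    s_interval: tuple[int, int]
    size: int
    note: str = ""


# ---------------------------------------------------------------------------
# Maximal exact matches


def _linear_mems(q: str, s: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal exact matches of length >= min_len between two strings.

    Returns (q_start, s_start, length) triples.  Uses a k-mer index with
    k = min_len: every maximal match of length >= k is a maximal run of
    consecutive k-mer hits on one diagonal, so merging runs is exact.
    """
    k = min_len
    if len(q) < k or len(s) < k:
        return []
    index: dict[str, list[int]] = {}
    for j in range(len(s) - k + 1):
        index.setdefault(s[j : j + k], []).append(j)
    # diagonal -> sorted q positions of k-mer hits
    diagonals: dict[int, list[int]] = {}
    for i in range(len(q) - k + 1):
        hits = index.get(q[i : i + k])
        if hits:
            for j in hits:
                diagonals.setdefault(j - i, []).append(i)
    out: list[tuple[int, int, int]] = []
    for d, positions in diagonals.items():
        run_start = positions[0]
        prev = positions[0]
        for i in positions[1:]:
            if i == prev + 1:
                prev = i
                continue
            out.append((run_start, run_start + d, prev - run_start + k))
            run_start = prev = i
        out.append((run_start, run_start + d, prev - run_start + k))
    return out


def find_anchors(
    q: CircularGenome, s: CircularGenome, min_len: int = 50
) -> list[Anchor]:
    """All maximal exact matches >= ``min_len`` on both strands.

    Circular genomes are searched via the doubled-sequence technique;
    duplicate images of the same circular match are suppressed and no
    match is reported longer than either genome.
    """
    qs = q.seq + q.seq if q.is_circular else q.seq
    ss = s.seq + s.seq if s.is_circular else s.seq
    nq, ns = len(q), len(s)
    cap = min(nq, ns)
    seen: set[tuple[int, int, int, str]] = set()
    anchors: list[Anchor] = []

    def add(qi: int, si: int, length: int, strand: str) -> None:
        length = min(length, cap)
        qi_n = qi % nq if q.is_circular else qi
        # normalise so each circular match is reported once, keyed by its
        # query start in [0, nq)
        shift = qi - qi_n
        si_adj = si + (shift if strand == "+" else -shift)
        si_n = si_adj % ns if s.is_circular else si_adj
        key = (qi_n, si_n, length, strand)
        if key in seen:
            return
        seen.add(key)
        if strand == "+":
            anchors.append(Anchor(qi_n, qi_n + length, si_n, si_n + length, "+"))
        else:
            # minus strand: q[qi:qi+L] == revcomp(s[s_left:s_left+L]) where the
            # match was found against revcomp(ss)
            anchors.append(Anchor(qi_n, qi_n + length, si_n, si_n + length, "-"))

    for qi, si, length in _linear_mems(qs, ss, min_len):
        if q.is_circular and qi >= nq:
            continue
        if s.is_circular and si >= ns:
            # keep only if its normalised image was not produced; normalise here
            pass
        add(qi, si, length, "+")
    ss_rc = revcomp(ss)
    for qi, si_rc, length in _linear_mems(qs, ss_rc, min_len):
        if q.is_circular and qi >= nq:
            continue
        # map back to forward-strand subject coordinates
        si = len(ss) - (si_rc + length)
        length_c = min(length, cap)
        # truncating the query match at its right end truncates the subject
        # interval at its left end on the minus strand
        si += length - length_c
        qi_n = qi % nq if q.is_circular else qi
        si_n = si % ns if s.is_circular else si
        key = (qi_n, si_n, length_c, "-")
        if key in seen:
            continue
        seen.add(key)
        anchors.append(Anchor(qi_n, qi_n + length_c, si_n, si_n + length_c, "-"))
    if q.is_circular or s.is_circular:
        anchors = _drop_circularly_contained(anchors, nq, ns)
    anchors.sort(key=lambda a: (a.q_start, a.s_start, a.strand))
    return anchors


def _drop_circularly_contained(
    anchors: list[Anchor], nq: int, ns: int
) -> list[Anchor]:
    """Remove anchors that are circular sub-matches of a longer anchor.

    The doubled-sequence search reports truncated images of a match that
    crosses the sequence boundary (the truncation point is an artifact of
    where the circle was opened); such images are exactly the anchors
    contained in a longer anchor on the same circular diagonal.
    """
    by_strand: dict[str, list[Anchor]] = {"+": [], "-": []}
    for a in anchors:
        by_strand[a.strand].append(a)
    kept: list[Anchor] = []
    for strand, group in by_strand.items():
        group.sort(key=lambda a: -a.length)
        for i, a in enumerate(group):
            contained = False
            for b in group:
                if b.length <= a.length:
                    break
                t = (a.q_start - b.q_start) % nq
                if t + a.length > b.length:
                    continue
                if strand == "+":
                    if (b.s_start + t - a.s_start) % ns == 0:
                        contained = True
                        break
                else:
                    expect = b.s_start + b.length - t - a.length
                    if (a.s_start - expect) % ns == 0:
                        contained = True
                        break
            if not contained:
                kept.append(a)
    return kept


# ---------------------------------------------------------------------------
# Chaining


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -2
_aligner.open_gap_score = -4
_aligner.extend_gap_score = -0.5

_MAX_ALIGN_GAP = 50_000  # gap regions above this are reported unaligned


def _gap_stats(qgap: str, sgap: str) -> tuple[int, int, int, int]:
    """(n_snp, n_indel_events, aligned_bases, mismatches) for one gap pair."""
    if not qgap and not sgap:
        return 0, 0, 0, 0
    if not qgap or not sgap:
        return 0, 1, max(len(qgap), len(sgap)), max(len(qgap), len(sgap))
    if len(qgap) > _MAX_ALIGN_GAP or len(sgap) > _MAX_ALIGN_GAP:
        return 0, 1, max(len(qgap), len(sgap)), max(len(qgap), len(sgap))
    aln = _aligner.align(qgap, sgap)[0]
    qa, sa = str(aln[0]), str(aln[1])
    n_snp = 0
    n_indel = 0
    mism = 0
    in_gap = False
    for a, b in zip(qa, sa):
        if a == "-" or b == "-":
            mism += 1
            if not in_gap:
                n_indel += 1
                in_gap = True
        else:
            in_gap = False
            if a != b or a == "N":
                n_snp += 1
                mism += 1 if a != b else 0
    return n_snp, n_indel, len(qa), mism


def _circ_gap(raw: int, n: int, circular: bool) -> int:
    """Map a raw coordinate difference onto the circle, centred on zero."""
    if not circular:
        return raw
    return (raw + n // 2) % n - n // 2


def _circ_slice(seq: str, start: int, length: int) -> str:
    """Circular substring of ``length`` bases starting at ``start`` mod n."""
    if length <= 0:
        return ""
    n = len(seq)
    start %= n
    if start + length <= n:
        return seq[start : start + length]
    return (seq + seq)[start : start + length]


def _chain_step(last: Anchor, a: Anchor, nq: int, ns: int, qc: bool, sc: bool,
                max_gap: int) -> tuple[int, int] | None:
    """Gaps (qgap, sgap) if ``a`` colinearly extends ``last``, else None."""
    if last.strand != a.strand:
        return None
    qgap = _circ_gap(a.q_start - last.q_end, nq, qc)
    if qgap < -min(a.length, last.length) // 2 or qgap > max_gap:
        return None
    if a.strand == "+":
        sgap = _circ_gap(a.s_start - last.s_end, ns, sc)
    else:
        sgap = _circ_gap(last.s_start - a.s_end, ns, sc)
    if sgap < -min(a.length, last.length) // 2 or sgap > max_gap:
        return None
    if abs(qgap - sgap) > max_gap:
        return None
    return qgap, sgap


def _unroll_chain(
    chain: list[Anchor], nq: int, ns: int, qc: bool, sc: bool
) -> list[Anchor]:
    """Rewrite chained anchor coordinates to be monotonic.

    A chain merged across the origin mixes raw coordinates from both
    sides of the wrap; unrolling makes every gap a plain difference (the
    resulting coordinates may exceed the genome length and are taken mod
    n when reported).
    """
    out = [chain[0]]
    for a in chain[1:]:
        prev = out[-1]
        qgap = _circ_gap(a.q_start - prev.q_end, nq, qc)
        q0 = prev.q_end + qgap
        if a.strand == "+":
            sgap = _circ_gap(a.s_start - prev.s_end, ns, sc)
            s0 = prev.s_end + sgap
        else:
            sgap = _circ_gap(prev.s_start - a.s_end, ns, sc)
            s0 = prev.s_start - sgap - a.length
        out.append(Anchor(q0, q0 + a.length, s0, s0 + a.length, a.strand))
    return out


def chain_blocks(
    anchors: Sequence[Anchor],
    q: CircularGenome,
    s: CircularGenome,
    max_gap: int = 5000,
) -> list[SyntenyBlock]:
    """Greedy colinear chaining of anchors into syntenic blocks.

    Consecutive anchors join a block iff they are on the same strand, the
    gaps on both genomes are <= ``max_gap`` (computed on the circle when a
    genome is circular), and the gap sizes are mutually consistent within
    ``max_gap``.  After the greedy pass, chains whose ends meet across the
    origin are merged, so the block decomposition is rotation-invariant.
    Gap regions between chained anchors are globally aligned to fill the
    block's SNP/indel statistics.
    """
    if not anchors:
        return []
    nq, ns = len(q), len(s)
    qc, sc = q.is_circular, s.is_circular
    ordered = sorted(anchors, key=lambda a: (a.q_start, -(a.q_end - a.q_start)))
    chains: list[list[Anchor]] = []
    for a in ordered:
        best = None
        best_gap = None
        for chain in chains:
            step = _chain_step(chain[-1], a, nq, ns, qc, sc, max_gap)
            if step is None:
                continue
            score = abs(step[0]) + abs(step[1])
            if best is None or score < best_gap:
                best, best_gap = chain, score
        if best is None:
            chains.append([a])
        else:
            best.append(a)
    # merge chains across the origin (the greedy pass runs in linear
    # q-order, so a chain ending near the origin cannot pick up anchors
    # that were processed first)
    merged = True
    while merged and len(chains) > 1:
        merged = False
        for i, ca in enumerate(chains):
            for j, cb in enumerate(chains):
                if i == j:
                    continue
                if _chain_step(ca[-1], cb[0], nq, ns, qc, sc, max_gap) is not None:
                    ca.extend(cb)
                    del chains[j]
                    merged = True
                    break
            if merged:
                break
    blocks: list[SyntenyBlock] = []
    for chain in chains:
        chain = _unroll_chain(chain, nq, ns, qc, sc)
        block = SyntenyBlock(anchors=chain, strand=chain[0].strand)
        aligned = sum(a.length for a in chain)
        mism = 0
        n_snp = n_indel = 0
        for prev, nxt in zip(chain, chain[1:]):
            qg = _circ_gap(nxt.q_start - prev.q_end, nq, qc)
            qgap = _circ_slice(q.seq, prev.q_end, qg)
            if chain[0].strand == "+":
                sg = _circ_gap(nxt.s_start - prev.s_end, ns, sc)
                sgap = _circ_slice(s.seq, prev.s_end, sg)
            else:
                sg = _circ_gap(prev.s_start - nxt.s_end, ns, sc)
                sgap = revcomp(_circ_slice(s.seq, nxt.s_end, sg))
            ds, di, ab, mm = _gap_stats(qgap, sgap)
            n_snp += ds
            n_indel += di
            aligned += ab
            mism += mm
        if len(chains) == 1 and qc and sc:
            # a single chain around the whole circle still has a seam
            # between its last and first anchor; if the seam is colinear
            # its gap belongs to the block statistics
            step = _chain_step(chain[-1], chain[0], nq, ns, qc, sc, max_gap)
            if step is not None:
                qg, sg = step
                qgap = _circ_slice(q.seq, chain[-1].q_end, qg)
                if chain[0].strand == "+":
                    sgap = _circ_slice(s.seq, chain[-1].s_end, sg)
                else:
                    sgap = revcomp(
                        _circ_slice(s.seq, chain[0].s_end, sg)
                    )
                ds, di, ab, mm = _gap_stats(qgap, sgap)
                n_snp += ds
                n_indel += di
                aligned += ab
                mism += mm
        block.n_snp = n_snp
        block.n_indel = n_indel
        block.aligned_bases = aligned
        block.mismatch_bases = mism
        blocks.append(block)
    blocks.sort(key=lambda b: b.q_start % nq if qc else b.q_start)
    return blocks


# ---------------------------------------------------------------------------
# Duplications (self-comparison)


def _self_repeat_pairs(
    g: CircularGenome, dup_min: int, min_len: int = 50
) -> list[tuple[tuple[int, int], tuple[int, int], str]]:
    """Distinct repeat pairs >= dup_min within one genome.

    Self-anchors away from the identity diagonal come in symmetric images
    ((a,b) and (b,a)); each physical pair is reported once, the copy with
    the smaller start first.
    """
    anchors = find_anchors(g, g, min_len=min_len)
    n = len(g)
    pairs: set[tuple[tuple[int, int], tuple[int, int], str]] = set()
    for a in anchors:
        if a.length < dup_min or a.length >= n:
            continue
        if a.strand == "+" and a.q_start == a.s_start:
            continue  # identity diagonal
        left = (a.q_start % n, (a.q_start % n) + a.length)
        right = (a.s_start % n, (a.s_start % n) + a.length)
        if left > right:
            left, right = right, left
        if a.strand == "-" and left == right:
            continue  # a self-palindrome, not two copies
        pairs.add((left, right, a.strand))
    return sorted(pairs)


def detect_duplications(
    g: CircularGenome, dup_min: int = 10_000, min_identity: float = 0.99
) -> list[StructuralCall]:
    """Large duplicated-region pairs within one genome (pairs, not copies)."""
    calls = []
    for left, right, strand in _self_repeat_pairs(g, dup_min):
        calls.append(
            StructuralCall(
                kind="duplication",
                q_interval=left,
                s_interval=right,
                size=left[1] - left[0],
                note=f"strand={strand}",
            )
        )
    return calls


def mask_large_duplications(
    g: CircularGenome, dup_min: int = 10_000, min_identity: float = 0.99
) -> tuple[CircularGenome, list[tuple[int, int]]]:
    """Remove one copy of every large duplication pair.

    The later copy in the current rotation is deleted, iterating until no
    repeat >= ``dup_min`` remains; returns the shortened genome and the
    intervals that were removed (coordinates on the genome as it was at
    each removal step).  Used to build the duplication-free subject that
    rearrangement plots are referenced against.
    """
    masked: list[tuple[int, int]] = []
    current = g
    while True:
        pairs = _self_repeat_pairs(current, dup_min)
        if not pairs:
            break
        # remove the later copy of the pair with the largest second copy
        left, right, _ = max(pairs, key=lambda p: p[1][1] - p[1][0])
        s0, s1 = right
        s1 = min(s1, len(current))
        masked.append((s0, s1))
        current = CircularGenome(
            current.id, current.seq[:s0] + current.seq[s1:], current.topology, current.source
        )
    return current, masked


# ---------------------------------------------------------------------------
# Rearrangement junctions


def _overlap_circ(
    a: tuple[int, int], b: tuple[int, int], n: int | None
) -> int:
    """Overlap of two intervals, considering circular images when n given."""
    shifts = (0,) if n is None else (-n, 0, n)
    best = 0
    for sh in shifts:
        lo = max(a[0] + sh, b[0])
        hi = min(a[1] + sh, b[1])
        best = max(best, hi - lo)
    return best


def _tile_query(
    blocks: list[SyntenyBlock], min_block: int, nq: int | None = None
) -> list[SyntenyBlock]:
    """Select a non-redundant covering subset of blocks on the query.

    Repeats produce short blocks whose query span is already covered by a
    longer block (multi-mapping); keep the longest block for any heavily
    overlapped region and drop blocks below ``min_block``.
    """
    kept: list[SyntenyBlock] = []
    for b in sorted(blocks, key=lambda b: -b.q_length):
        if b.q_length < min_block:
            continue
        overlap = sum(
            _overlap_circ((b.q_start, b.q_end), (k.q_start, k.q_end), nq)
            for k in kept
        )
        if overlap > 0.5 * b.q_length:
            continue
        kept.append(b)
    kept.sort(key=lambda b: b.q_start)
    return kept


def detect_recombination(
    blocks: Sequence[SyntenyBlock],
    q: CircularGenome,
    s: CircularGenome,
    max_gap: int = 5000,
    min_block: int = 1000,
) -> tuple[int, list[StructuralCall]]:
    """Count rearrangement junctions around the circular query.

    Blocks are ordered around the query; a junction is a boundary between
    consecutive blocks whose subject images are not adjacent and colinear
    (same strand, subject gap within ``max_gap``, order consistent with
    the strand).  Adjacency wraps: the last block is compared with the
    first.  A single crossover produces two junctions.
    """
    if not blocks:
        raise ValueError("no syntenic blocks given")
    tiled = _tile_query(list(blocks), min_block, nq=len(q) if q.is_circular else None)
    if len(tiled) <= 1:
        return 0, []
    ns = len(s)
    calls: list[StructuralCall] = []
    m = len(tiled)
    for i in range(m):
        a = tiled[i]
        b = tiled[(i + 1) % m]
        colinear = False
        if a.strand == b.strand:
            if a.strand == "+":
                sgap = b.s_start - a.s_end
            else:
                sgap = a.s_start - b.s_end
            if s.is_circular:
                sgap %= ns
                if sgap > ns // 2:
                    sgap -= ns
            if -max_gap <= sgap <= max_gap:
                colinear = True
        if not colinear:
            calls.append(
                StructuralCall(
                    kind="recombination_junction",
                    q_interval=(a.q_end, b.q_start),
                    s_interval=(a.s_end, b.s_start),
                    size=0,
                    note=f"between blocks {i} and {(i + 1) % m}",
                )
            )
    return len(calls), calls


# ---------------------------------------------------------------------------
# Large InDels


def detect_large_indels(
    blocks: Sequence[SyntenyBlock],
    indel_min: int = 1000,
    max_gap: int = 5000,
    q: CircularGenome | None = None,
    s: CircularGenome | None = None,
) -> list[StructuralCall]:
    """Gaps present in exactly one genome, larger than ``indel_min``.

    Scans both the anchor gaps inside each block and the boundaries
    between consecutive colinear blocks (an insertion longer than the
    chaining gap limit splits its block in two).  A gap whose skipped
    sequence is largely covered by *another* block is not an indel but
    the return jump of a duplication, and is skipped.
    """
    calls: list[StructuralCall] = []
    nq0 = len(q) if q is not None and q.is_circular else None
    ns0 = len(s) if s is not None and s.is_circular else None
    q_spans = [(b.q_start, b.q_end) for b in blocks]
    s_spans = [(b.s_start, b.s_end) for b in blocks]

    def covered_elsewhere(
        iv: tuple[int, int], spans, skip: set[int], n: int | None
    ) -> bool:
        size = iv[1] - iv[0]
        if size <= 0:
            return False
        cov = sum(
            _overlap_circ(iv, sp, n)
            for i, sp in enumerate(spans)
            if i not in skip
        )
        return cov > 0.5 * size

    def classify(qgap: int, sgap: int, q_at: int, s_at: int, skip: set[int]) -> None:
        qgap, sgap = max(qgap, 0), max(sgap, 0)
        diff = qgap - sgap
        if diff > indel_min:
            if not covered_elsewhere((q_at, q_at + qgap), q_spans, skip, nq0):
                calls.append(
                    StructuralCall(
                        "insertion", (q_at, q_at + qgap), (s_at, s_at), diff
                    )
                )
        elif -diff > indel_min:
            if not covered_elsewhere((s_at, s_at + sgap), s_spans, skip, ns0):
                calls.append(
                    StructuralCall(
                        "deletion", (q_at, q_at), (s_at, s_at + sgap), -diff
                    )
                )

    for bi, block in enumerate(blocks):
        for prev, nxt in zip(block.anchors, block.anchors[1:]):
            qgap = nxt.q_start - prev.q_end
            if block.strand == "+":
                sgap = nxt.s_start - prev.s_end
                s_at = prev.s_end
            else:
                sgap = prev.s_start - nxt.s_end
                s_at = nxt.s_end
            classify(qgap, sgap, prev.q_end, s_at, {bi})
    # boundaries between consecutive blocks, wrap-aware when the genomes
    # are circular (an indel may sit at the seam between the last and
    # first block of the circle)
    nq = len(q) if q is not None and q.is_circular else None
    ns = len(s) if s is not None and s.is_circular else None
    order = sorted(range(len(blocks)), key=lambda i: blocks[i].q_start)
    pairs = list(zip(order, order[1:]))
    if nq is not None:
        # the circular seam: between the last and first block, or the
        # self-seam of a single block covering the whole circle
        pairs.append((order[-1], order[0]))
    for ia, ib in pairs:
        a, b = blocks[ia], blocks[ib]
        if a.strand != b.strand:
            continue
        qgap = _circ_gap(b.q_start - a.q_end, nq, True) if nq else b.q_start - a.q_end
        if a.strand == "+":
            sgap_raw = b.s_start - a.s_end
            s_at = a.s_end
        else:
            sgap_raw = a.s_start - b.s_end
            s_at = b.s_end
        sgap = _circ_gap(sgap_raw, ns, True) if ns else sgap_raw
        if sgap < -max_gap or qgap < -max_gap:
            continue  # not a simple colinear boundary
        classify(qgap, sgap, a.q_end, s_at, {ia, ib})
    return calls


# ---------------------------------------------------------------------------
# Variant tally and dot plot


def count_syntenic_variants(
    blocks: Sequence[SyntenyBlock],
) -> tuple[int, list[dict]]:
    """Total SNPs + indel events in syntenic regions, plus a per-block table.

    Each contiguous gap run counts as one indel event regardless of its
    length.
    """
    table = []
    total = 0
    for i, b in enumerate(blocks):
        total += b.n_snp + b.n_indel
        table.append(
            {
                "block": i,
                "q_start": b.q_start,
                "q_end": b.q_end,
                "s_start": b.s_start,
                "s_end": b.s_end,
                "strand": b.strand,
                "identity": round(b.identity, 6),
                "n_snp": b.n_snp,
                "n_indel": b.n_indel,
            }
        )
    return total, table


def export_dotplot(
    blocks: Sequence[SyntenyBlock],
    path: str | Path,
    dup_min: int = 10_000,
    duplicated_q: Iterable[tuple[int, int]] = (),
) -> None:
    """Write blocks as a dot-plot TSV (1-based inclusive coordinates)."""
    dup_ivs = list(duplicated_q)
    lines = ["q_start\tq_end\ts_start\ts_end\tstrand\tidentity\tis_duplication"]
    for b in blocks:
        is_dup = any(
            max(b.q_start, lo) < min(b.q_end, hi) for lo, hi in dup_ivs
        ) and b.q_length > dup_min
        lines.append(
            f"{b.q_start + 1}\t{b.q_end}\t{b.s_start + 1}\t{b.s_end}\t"
            f"{b.strand}\t{b.identity:.4f}\t{int(is_dup)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def compare_genomes(
    q: CircularGenome,
    s: CircularGenome,
    min_len: int = 50,
    max_gap: int = 5000,
    dup_min: int = 10_000,
    indel_min: int = 1000,
) -> dict:
    """Full pairwise comparison against the duplication-masked subject.

    Convenience wrapper reproducing the standard workflow: mask subject
    duplications, anchor, chain, then count junctions, large indels and
    syntenic variants.
    """
    s_masked, masked_ivs = mask_large_duplications(s, dup_min=dup_min)
    anchors = find_anchors(q, s_masked, min_len=min_len)
    blocks = chain_blocks(anchors, q, s_masked, max_gap=max_gap)
    # repeats shorter than dup_min map each copy to every other copy; the
    # redundant multi-mapping blocks are removed by tiling the query once
    # before any counting
    tiled = _tile_query(list(blocks), min_block=1000,
                        nq=len(q) if q.is_circular else None)
    n_junc, junctions = detect_recombination(tiled, q, s_masked, max_gap=max_gap)
    indels = detect_large_indels(
        tiled, indel_min=indel_min, max_gap=max_gap, q=q, s=s_masked
    )
    n_var, table = count_syntenic_variants(tiled)
    return {
        "blocks": blocks,
        "tiled_blocks": tiled,
        "masked_subject": s_masked,
        "masked_intervals": masked_ivs,
        "n_junctions": n_junc,
        "junctions": junctions,
        "large_indels": indels,
        "n_syntenic_variants": n_var,
        "variant_table": table,
        "q_duplications": detect_duplications(q, dup_min=dup_min),
        "s_duplications": detect_duplications(s, dup_min=dup_min),
    }
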