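"""Contig filtering, linkage graphs and parsimonious master circles.

Manual assembly of an organelle genome from assembler contigs proceeds in
three steps that this module mechanizes:

1. **Filtering** — discard contigs by four criteria, in order of
   precedence: membership of an explicit exclusion list (e.g. plasmid-like
   molecules), full-length 100% identity to a nuclear reference
   (contaminants), "dead-end" contigs with an unlinked end (applied
   iteratively, since removing one dead end can expose another), and
   bridging contigs whose read depth falls below a threshold (default:
   depth < 15 discards, so a contig at exactly 15 survives).

2. **Graph building** — retained contigs become nodes whose 5'/3' ends are
   joined by validated link edges; a per-contig multiplicity bound is
   inferred from the ratio of its depth to the median depth (a collapsed
   two-copy repeat shows ~2x depth).

3. **Master-circle enumeration** — the parsimonious reconstruction: find
   the smallest multiplicity assignment within bounds that admits a closed
   walk traversing every contig exactly its multiplicity, then enumerate
   all such walks, deduplicated up to rotation and reversal.  All returned
   circles share the same minimal total length.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import networkx as nx

from .genome import CircularGenome, revcomp

__all__ = [
    "Contig",
    "LinkEdge",
    "ContigGraph",
    "MasterCircle",
    "FilterReport",
    "filter_contigs",
    "build_graph",
    "enumerate_master_circles",
    "select_canonical",
    "contig_stats",
    "linearize",
    "walk_canonical",
]

END5, END3 = "5'", "3'"


@dataclass
class Contig:
    id: str
    seq: str
    depth: float
    label: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class LinkEdge:
    """Undirected link between two contig ends (PCR-validated analogue)."""

    contig1: str
    end1: str
    contig2: str
    end2: str
    support: int = 1
    validated: bool = False

    def __post_init__(self) -> None:
        if (self.contig1, self.end1) == (self.contig2, self.end2):
            raise ValueError("link joins a physical end to itself")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    def ends(self) -> frozenset[tuple[str, str]]:
        return frozenset({(self.contig1, self.end1), (self.contig2, self.end2)})


@dataclass
class ContigGraph:
    contigs: dict[str, Contig]
    edges: list[LinkEdge]
    multiplicity: dict[str, tuple[int, int]]  # id -> (min, max)


@dataclass(frozen=True)
class MasterCircle:
    """A closed signed walk over the contig set; sign -1 = reverse strand."""

    walk: tuple[tuple[str, int], ...]
    total_length: int


@dataclass
class FilterReport:
    retained: list[Contig]
    discarded: list[tuple[Contig, str]]  # (contig, reason)

    def reasons(self) -> dict[str, str]:
        return {c.id: r for c, r in self.discarded}


# ---------------------------------------------------------------------------
# Filtering


def _matches_full_length(seq: str, refs: Sequence[str]) -> bool:
    rc = revcomp(seq)
    return any(seq in ref or rc in ref for ref in refs)


def filter_contigs(
    contigs: Sequence[Contig],
    edges: Sequence[LinkEdge],
    nuclear_refs: Sequence[str] = (),
    exclusion_seqs: Sequence[str] = (),
    depth_min: float = 15.0,
) -> FilterReport:
    """Apply the four assembly filtering criteria.

    Precedence: exclusion list, nuclear match (full-length 100% identity
    to any reference, either strand), dead ends (iterated to a fixpoint),
    then low-depth bridging contigs (depth < ``depth_min``).
    """
    discarded: list[tuple[Contig, str]] = []
    alive: dict[str, Contig] = {}
    for c in contigs:
        if exclusion_seqs and _matches_full_length(c.seq, exclusion_seqs):
            discarded.append((c, "exclusion_list"))
        elif nuclear_refs and _matches_full_length(c.seq, nuclear_refs):
            discarded.append((c, "nuclear_match"))
        else:
            alive[c.id] = c
    # dead-end fixpoint: an end with no link to a surviving contig kills it
    changed = True
    while changed:
        changed = False
        for cid in list(alive):
            linked_ends = set()
            for e in edges:
                for (ca, ea), (cb, _) in (
                    ((e.contig1, e.end1), (e.contig2, e.end2)),
                    ((e.contig2, e.end2), (e.contig1, e.end1)),
                ):
                    if ca == cid and cb in alive:
                        linked_ends.add(ea)
            if linked_ends != {END5, END3}:
                discarded.append((alive.pop(cid), "dead_end"))
                changed = True
    for cid in list(alive):
        if alive[cid].depth < depth_min:
            discarded.append((alive.pop(cid), "low_depth"))
    return FilterReport(retained=list(alive.values()), discarded=discarded)


# ---------------------------------------------------------------------------
# Graph building


def build_graph(
    report: FilterReport,
    edges: Sequence[LinkEdge],
    max_multiplicity: int = 3,
    multiplicity_override: dict[str, tuple[int, int]] | None = None,
) -> ContigGraph:
    """Linkage graph over retained contigs with inferred multiplicity bounds.

    The bound for a contig is its depth divided by the median depth,
    rounded to the nearest integer and clipped to [1, max_multiplicity];
    per-contig overrides win.
    """
    kept = {c.id: c for c in report.retained}
    kept_edges = [
        e for e in edges if e.contig1 in kept and e.contig2 in kept
    ]
    med = statistics.median(c.depth for c in kept.values()) if kept else 1.0
    mult: dict[str, tuple[int, int]] = {}
    for cid, c in kept.items():
        m = int(round(c.depth / med)) if med > 0 else 1
        m = max(1, min(max_multiplicity, m))
        mult[cid] = (1, m)
    if multiplicity_override:
        mult.update(multiplicity_override)
    return ContigGraph(contigs=kept, edges=kept_edges, multiplicity=mult)


# ---------------------------------------------------------------------------
# Walk canonicalization


def _reverse_walk(walk: Sequence[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
    return tuple((c, -s) for c, s in reversed(walk))


def walk_canonical(
    walk: Sequence[tuple[str, int]], dedup_reversal: bool = True
) -> tuple[tuple[str, int], ...]:
    """Canonical representative of a circular signed walk.

    Minimal tuple over all rotations, and over the reversed walk (signs
    flipped) unless ``dedup_reversal`` is off.
    """
    walk = tuple(walk)
    n = len(walk)
    variants = [walk[i:] + walk[:i] for i in range(n)]
    if dedup_reversal:
        rev = _reverse_walk(walk)
        variants += [rev[i:] + rev[:i] for i in range(n)]
    return min(variants)


# ---------------------------------------------------------------------------
# Master-circle enumeration


def _entry_end(sign: int) -> str:
    return END5 if sign > 0 else END3


def _exit_end(sign: int) -> str:
    return END3 if sign > 0 else END5


def _adjacency(edges: Iterable[LinkEdge]) -> dict[tuple[str, str], set[tuple[str, str]]]:
    adj: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for e in edges:
        a, b = (e.contig1, e.end1), (e.contig2, e.end2)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def _walks_for_assignment(
    graph: ContigGraph,
    counts: dict[str, int],
    cap: int | None,
    dedup_reversal: bool,
    count_only: bool = False,
) -> tuple[set[tuple[tuple[str, int], ...]], bool]:
    """Enumerate closed walks using each contig exactly ``counts[c]`` times.

    The walk is anchored at the lexicographically smallest contig in
    forward orientation; every equivalence class under rotation (and
    reversal, when deduplicating) contains such a representative.  Returns
    (canonical walks, truncated flag).
    """
    adj = _adjacency(graph.edges)
    start = min(counts)
    found: set[tuple[tuple[str, int], ...]] = set()
    truncated = False
    remaining = dict(counts)
    total = sum(counts.values())
    path: list[tuple[str, int]] = []

    def step(cid: str, sign: int) -> bool:
        remaining[cid] -= 1
        path.append((cid, sign))
        return True

    def unstep(cid: str) -> None:
        remaining[cid] += 1
        path.pop()

    start_entry = (start, _entry_end(1))

    def dfs(current_exit: tuple[str, str]) -> None:
        nonlocal truncated
        if truncated:
            return
        if len(path) == total:
            if start_entry in adj.get(current_exit, ()):
                found.add(walk_canonical(path, dedup_reversal))
                if cap is not None and len(found) >= cap:
                    truncated = True
            return
        for nxt_cid, nxt_end in sorted(adj.get(current_exit, ())):
            if remaining.get(nxt_cid, 0) <= 0:
                continue
            sign = 1 if nxt_end == END5 else -1
            step(nxt_cid, sign)
            dfs((nxt_cid, _exit_end(sign)))
            unstep(nxt_cid)

    step(start, 1)
    dfs((start, _exit_end(1)))
    unstep(start)
    return found, truncated


def enumerate_master_circles(
    graph: ContigGraph,
    cap: int = 10_000,
    dedup_reversal: bool = True,
) -> tuple[list[MasterCircle], int, bool]:
    """All parsimonious master circles of a contig graph.

    Searches multiplicity assignments within the graph's bounds in order
    of increasing total genome length and returns every distinct closed
    walk for the smallest feasible length.  Returns (circles, exact count,
    truncated flag); enumeration stops at ``cap`` circles, in which case
    the flag is set and the count reflects only what was enumerated.
    """
    if not graph.contigs:
        raise ValueError("empty contig graph")
    und = nx.Graph()
    und.add_nodes_from(graph.contigs)
    for e in graph.edges:
        und.add_edge(e.contig1, e.contig2)
    if not nx.is_connected(und):
        comps = [sorted(c) for c in nx.connected_components(und)]
        raise ValueError(f"disconnected contig graph; components: {comps}")
    ids = sorted(graph.contigs)
    lengths = {cid: len(graph.contigs[cid]) for cid in ids}
    ranges = [range(graph.multiplicity[cid][0], graph.multiplicity[cid][1] + 1) for cid in ids]
    assignments = sorted(
        product(*ranges),
        key=lambda ms: sum(m * lengths[c] for c, m in zip(ids, ms)),
    )
    best_walks: set[tuple[tuple[str, int], ...]] = set()
    best_length: int | None = None
    truncated = False
    for ms in assignments:
        total_length = sum(m * lengths[c] for c, m in zip(ids, ms))
        if best_length is not None and total_length > best_length:
            break
        counts = dict(zip(ids, ms))
        walks, trunc = _walks_for_assignment(
            graph, counts, cap - len(best_walks) if cap else None, dedup_reversal
        )
        if walks:
            best_length = total_length
            best_walks |= walks
            truncated |= trunc
            if truncated:
                break
    if best_length is None:
        raise ValueError("no feasible closed walk within multiplicity bounds")
    circles = [
        MasterCircle(walk=w, total_length=best_length) for w in sorted(best_walks)
    ]
    return circles, len(circles), truncated


def select_canonical(circles: Sequence[MasterCircle]) -> MasterCircle:
    """Deterministic representative: minimal canonical signed-id sequence."""
    if not circles:
        raise ValueError("no master circles to select from")
    return min(circles, key=lambda c: walk_canonical(c.walk))


def linearize(
    circle: MasterCircle, contigs: dict[str, Contig], genome_id: str = "master-circle"
) -> CircularGenome:
    """Concatenate contig sequences in walk order/orientation (butt joints)."""
    parts = []
    for cid, sign in circle.walk:
        seq = contigs[cid].seq
        parts.append(seq if sign > 0 else revcomp(seq))
    return CircularGenome(id=genome_id, seq="".join(parts), topology="circular")


# ---------------------------------------------------------------------------
# Stats


def contig_stats(contigs: Sequence[Contig]) -> tuple[int, float, float]:
    """(n, mean length in bp, mean depth) of a contig set."""
    if not contigs:
        raise ValueError("empty contig set")
    n = len(contigs)
    mean_len = round(sum(len(c) for c in contigs) / n)
    mean_depth = sum(c.depth for c in contigs) / n
    return n, float(mean_len), mean_depth
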