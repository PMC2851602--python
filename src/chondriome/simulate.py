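"""Seeded generator of synthetic mitochondrial genomes and contig sets.

The generator emulates the data a pyrosequencing-plus-manual-assembly
project produces for a plant mitochondrion, at the scale of the rice
chondriome: a ~490 kb circular reference with dispersed repeat pairs and
planted genes, rearranged derivatives (repeat-mediated exchanges, large
duplications, insertions, deletions, point variants), contig sets carrying
per-contig depth and end-to-end linkage evidence, low-depth "dead-end"
decoys, nuclear-contaminant decoys, and binary marker panels across many
accessions.

Every run is driven by a single NumPy PRNG stream seeded once, so all
outputs are bit-reproducible per seed.  A :class:`TruthRecord` accompanies
each derived object and is sufficient to recompute it from its parent
deterministically (``replay``), which makes the generator usable as an
oracle for the analysis stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import CircularGenome, GeneModel, revcomp

__all__ = [
    "SimConfig",
    "RepeatPair",
    "RearrangementEvent",
    "TruthRecord",
    "SimContig",
    "simulate_reference",
    "apply_events",
    "replay",
    "random_events",
    "shred",
    "simulate_marker_panel",
    "write_contig_set",
]

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class SimConfig:
    """Knobs of the generator; defaults match the rice-chondriome scale.

    ``genome_length`` defaults to the Nipponbare master-circle length and
    ``contig_mean_depth`` to the observed pyrosequencing depth (~42x).
    ``substitution_rate`` defaults to 0 because the platform error rate
    measured against independent clone sequencing was ~1 in 10^4; set it
    above 0 for robustness experiments.
    """

    seed: int = 0
    genome_length: int = 490_669
    gc: float = 0.44
    n_repeat_pairs: int = 3
    repeat_length: int = 12_000
    repeat_orientation: str = "inverted"  # inverted | direct | mixed
    repeat_copy_gap: tuple[int, int] | None = None  # force copies this far apart
    n_genes: int = 30
    contig_mean_depth: float = 42.0
    depth_noise_sd: float = 4.0
    n_contigs: int = 20
    min_contig: int = 2_000
    n_dead_end: int = 3
    n_nuclear_contaminants: int = 2
    n_low_depth_bridges: int = 2
    substitution_rate: float = 0.0
    depth_min: float = 15.0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.repeat_length <= 0:
            raise ValueError("lengths must be positive")
        if not (0.0 <= self.gc <= 1.0 and 0.0 <= self.substitution_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class RepeatPair:
    pair_id: str
    first: tuple[int, int]
    second: tuple[int, int]
    orientation: str  # direct | inverted


@dataclass
class RearrangementEvent:
    """One edit applied to a genome; coordinates refer to the genome state
    at application time.  ``payload_seq``/``alt`` make the event replayable."""

    kind: str  # recombination | duplication | insertion | deletion | snp | small_indel
    positions: list[tuple[int, int]]
    repeat_used: str | None = None
    payload_length: int = 0
    payload_seq: str = ""
    alt: str = ""


@dataclass
class TruthRecord:
    parent_id: str
    derived_id: str
    events: list[RearrangementEvent] = field(default_factory=list)
    labels: dict[str, str] = field(default_factory=dict)
    walk: list[tuple[str, int]] = field(default_factory=list)  # signed contig order

    def to_json(self) -> str:
        d = {
            "parent_id": self.parent_id,
            "derived_id": self.derived_id,
            "events": [asdict(e) for e in self.events],
            "labels": self.labels,
            "walk": [[c, s] for c, s in self.walk],
        }
        return json.dumps(d, indent=2)


@dataclass
class SimContig:
    id: str
    seq: str
    depth: float
    label: str  # genuine | dead_end | nuclear | low_depth


# ---------------------------------------------------------------------------
# Reference synthesis


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)
    return codes.tobytes().decode()


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_CODONS) for _ in range(n_codons - 2))
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


def _place(
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    length: int,
    genome_length: int,
    margin: int = 200,
) -> int:
    """Pick a non-wrapping start that keeps ``margin`` bp from existing
    features."""
    for _ in range(2000):
        start = int(rng.integers(margin, genome_length - length - margin))
        iv = (start - margin, start + length + margin)
        if all(iv[1] <= a or iv[0] >= b for a, b in occupied):
            return start
    raise ValueError("requested features exceed genome capacity")


def simulate_reference(
    cfg: SimConfig,
) -> tuple[CircularGenome, list[GeneModel], list[RepeatPair]]:
    """Synthesize a circular reference genome with planted genes and repeats.

    Returns the genome, its gene catalog (mostly protein genes with a few
    tRNA-like entries) and the map of exact dispersed repeat pairs.
    """
    rng = np.random.default_rng(cfg.seed)
    seq = list(_random_seq(rng, cfg.genome_length, cfg.gc))
    occupied: list[tuple[int, int]] = []
    catalog: list[GeneModel] = []
    n_trna = min(3, cfg.n_genes // 10)
    for i in range(cfg.n_genes):
        if i < cfg.n_genes - n_trna:
            cds = _random_cds(rng, int(rng.integers(100, 500)))
            kind = "protein"
        else:
            cds = _random_seq(rng, 72, cfg.gc)
            kind = "tRNA"
        start = _place(rng, occupied, len(cds), cfg.genome_length)
        occupied.append((start, start + len(cds)))
        strand = "+" if rng.random() < 0.5 else "-"
        planted = cds if strand == "+" else revcomp(cds)
        seq[start : start + len(cds)] = list(planted)
        catalog.append(
            GeneModel(
                name=f"gene{i + 1:02d}",
                kind=kind,
                cds_seq=cds,
                notes=f"planted at {start} strand {strand}",
            )
        )
    repeats: list[RepeatPair] = []
    for r in range(cfg.n_repeat_pairs):
        unit = _random_seq(rng, cfg.repeat_length, cfg.gc)
        if cfg.repeat_copy_gap is not None:
            # place both copies as one slot so the requested gap always fits
            gap = int(rng.integers(*cfg.repeat_copy_gap))
            slot = _place(rng, occupied, 2 * cfg.repeat_length + gap, cfg.genome_length)
            a, b = slot, slot + cfg.repeat_length + gap
        else:
            a = _place(rng, occupied, cfg.repeat_length, cfg.genome_length)
            occupied.append((a, a + cfg.repeat_length))
            b = _place(rng, occupied, cfg.repeat_length, cfg.genome_length)
            if a > b:
                a, b = b, a
        occupied.append((a, a + cfg.repeat_length))
        occupied.append((b, b + cfg.repeat_length))
        if cfg.repeat_orientation == "mixed":
            orientation = "direct" if rng.random() < 0.5 else "inverted"
        else:
            orientation = cfg.repeat_orientation
        seq[a : a + cfg.repeat_length] = list(unit)
        second = unit if orientation == "direct" else revcomp(unit)
        seq[b : b + cfg.repeat_length] = list(second)
        repeats.append(
            RepeatPair(
                pair_id=f"rep{r + 1}",
                first=(a, a + cfg.repeat_length),
                second=(b, b + cfg.repeat_length),
                orientation=orientation,
            )
        )
    g = CircularGenome(
        id=f"sim-ref-seed{cfg.seed}",
        seq="".join(seq),
        topology="circular",
        source=f"simulate_reference(seed={cfg.seed})",
    )
    return g, catalog, repeats


# ---------------------------------------------------------------------------
# Rearrangement events


def _apply_one(seq: str, ev: RearrangementEvent) -> str:
    if ev.kind == "recombination":
        (a0, a1), (b0, b1) = ev.positions
        if not (0 <= a0 < a1 <= b0 < b1 <= len(seq)):
            raise ValueError("recombination intervals invalid or out of order")
        return seq[:a1] + revcomp(seq[a1:b0]) + seq[b0:]
    if ev.kind == "duplication":
        (s0, s1), (at, _) = ev.positions
        payload = seq[s0:s1]
        return seq[:at] + payload + seq[at:]
    if ev.kind in ("insertion", "small_indel") and ev.payload_seq:
        at = ev.positions[0][0]
        return seq[:at] + ev.payload_seq + seq[at:]
    if ev.kind in ("deletion", "small_indel"):
        d0, d1 = ev.positions[0]
        return seq[:d0] + seq[d1:]
    if ev.kind == "snp":
        p = ev.positions[0][0]
        if seq[p] == ev.alt:
            raise ValueError(f"snp at {p}: alt equals reference base")
        return seq[:p] + ev.alt + seq[p + 1 :]
    raise ValueError(f"unknown event kind {ev.kind!r}")


def apply_events(
    g: CircularGenome,
    events: Sequence[RearrangementEvent],
    derived_id: str | None = None,
) -> tuple[CircularGenome, TruthRecord]:
    """Apply events in order; each event sees the genome left by the last."""
    seq = g.seq
    for ev in events:
        for s0, s1 in ev.positions:
            if not (0 <= s0 <= s1 <= len(seq)):
                raise ValueError(
                    f"event {ev.kind} positions {ev.positions} invalid for "
                    f"length {len(seq)}"
                )
        seq = _apply_one(seq, ev)
    derived = CircularGenome(
        id=derived_id or f"{g.id}-derived",
        seq=seq,
        topology=g.topology,
        source=f"apply_events(parent={g.id})",
    )
    truth = TruthRecord(parent_id=g.id, derived_id=derived.id, events=list(events))
    return derived, truth


def derived_position(events: Sequence[RearrangementEvent], pos: int) -> int:
    """Map a parent-genome coordinate to the derived genome.

    Valid for event sets built by :func:`random_events` (disjoint slots,
    applied top-down), where every event's coordinates are also parent
    coordinates: the derived position is the parent position plus the
    length changes of all events applied strictly below it.
    """
    shift = 0
    for ev in events:
        if ev.kind == "recombination" or ev.kind == "snp":
            continue
        if ev.kind == "duplication":
            at, delta = ev.positions[1][0], ev.payload_length
        elif ev.payload_seq:  # insertion / small insertion
            at, delta = ev.positions[0][0], len(ev.payload_seq)
        else:  # deletion / small deletion
            at, delta = ev.positions[0][0], ev.positions[0][0] - ev.positions[0][1]
        if at < pos:
            shift += delta
    return pos + shift


def replay(parent: CircularGenome, truth: TruthRecord) -> CircularGenome:
    """Recompute the derived genome from its parent and truth record."""
    derived, _ = apply_events(parent, truth.events, derived_id=truth.derived_id)
    return derived


def random_events(
    rng: np.random.Generator,
    g: CircularGenome,
    repeats: Sequence[RepeatPair] = (),
    n_recomb: int = 0,
    n_dup: int = 0,
    dup_length: int = 12_000,
    dup_spacing: int = 25_000,
    n_ins: int = 0,
    ins_length: int = 6_881,
    n_del: int = 0,
    del_length: int = 2_000,
    n_snp: int = 0,
    n_small_indel: int = 0,
    small_indel_len: int = 3,
    gc: float = 0.44,
    margin: int = 2_000,
) -> list[RearrangementEvent]:
    """Draw a non-overlapping event set on ``g``.

    Recombinations use the inverted repeat pairs of ``repeats`` (one event
    per pair).  Each event's full footprint (including a duplication's
    source and destination, which sit ``dup_spacing`` apart in one slot)
    occupies a disjoint genome slot, and events are returned sorted by
    descending slot position: applying them in order then never shifts
    the coordinates of a not-yet-applied event, so recorded positions are
    valid on both parent and derived genomes (up to length changes
    strictly above them).
    """
    n = len(g)
    events: list[RearrangementEvent] = []
    occupied: list[tuple[int, int]] = []
    inverted = [r for r in repeats if r.orientation == "inverted"]
    if n_recomb > len(inverted):
        raise ValueError("not enough inverted repeat pairs for requested exchanges")
    for pair in inverted[:n_recomb]:
        span = (pair.first[0], pair.second[1])
        occupied.append((span[0] - margin, span[1] + margin))
        events.append(
            RearrangementEvent(
                kind="recombination",
                positions=[pair.first, pair.second],
                repeat_used=pair.pair_id,
            )
        )

    def free_spot(length: int) -> int:
        for _ in range(2000):
            start = int(rng.integers(margin, n - length - margin))
            iv = (start - margin, start + length + margin)
            if all(iv[1] <= a or iv[0] >= b for a, b in occupied):
                occupied.append(iv)
                return start
        raise ValueError("no room left for events")

    for _ in range(n_dup):
        slot = free_spot(2 * dup_length + dup_spacing)
        src = slot
        at = slot + dup_length + dup_spacing
        events.append(
            RearrangementEvent(
                kind="duplication",
                positions=[(src, src + dup_length), (at, at)],
                payload_length=dup_length,
            )
        )
    for _ in range(n_ins):
        at = free_spot(1)
        events.append(
            RearrangementEvent(
                kind="insertion",
                positions=[(at, at)],
                payload_length=ins_length,
                payload_seq=_random_seq(rng, ins_length, gc),
            )
        )
    for _ in range(n_del):
        d0 = free_spot(del_length)
        events.append(
            RearrangementEvent(
                kind="deletion",
                positions=[(d0, d0 + del_length)],
                payload_length=del_length,
            )
        )
    for _ in range(n_snp):
        p = free_spot(1)
        ref = g.seq[p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        events.append(
            RearrangementEvent(kind="snp", positions=[(p, p + 1)], alt=alt)
        )
    for _ in range(n_small_indel):
        p = free_spot(small_indel_len)
        if rng.random() < 0.5:
            events.append(
                RearrangementEvent(
                    kind="small_indel",
                    positions=[(p, p)],
                    payload_length=small_indel_len,
                    payload_seq=_random_seq(rng, small_indel_len, gc),
                )
            )
        else:
            events.append(
                RearrangementEvent(
                    kind="small_indel",
                    positions=[(p, p + small_indel_len)],
                    payload_length=small_indel_len,
                )
            )
    events.sort(key=lambda e: -e.positions[0][0])
    return events


# ---------------------------------------------------------------------------
# Shredding into contigs


def shred(
    g: CircularGenome,
    cfg: SimConfig,
    repeats: Sequence[RepeatPair] = (),
    decoy: str | None = None,
) -> tuple[list[SimContig], list[tuple[str, str, str, str, int]], TruthRecord]:
    """Partition a genome into contigs with depth, links and decoys.

    The genome is cut at repeat boundaries (each repeat pair is emitted as
    a single contig with doubled depth, as an assembler would collapse it)
    plus random cuts, yielding roughly ``cfg.n_contigs`` genuine contigs.
    Decoy contigs are added: dead-ends (depth < 15, one free end), nuclear
    contaminants (verbatim substrings of ``decoy``), and low-depth bridges
    (depth < 15, linked on both ends).  Link evidence lists which contig
    ends abut in the true genome; the truth record carries per-contig
    labels and the signed contig order of the circle.
    """
    rng = np.random.default_rng(cfg.seed + 7_919)
    n = len(g)
    if n < 2 * cfg.min_contig:
        raise ValueError("genome shorter than minimum contig size")
    # --- segment boundaries
    cuts: set[int] = set()
    repeat_ivs: list[tuple[int, int, str, str]] = []  # start, end, pair, which
    for pair in repeats:
        for which, iv in (("first", pair.first), ("second", pair.second)):
            cuts.update(iv)
            repeat_ivs.append((iv[0], iv[1], pair.pair_id, which))
    n_extra = max(cfg.n_contigs - 2 * len(repeats) - len(repeats), 2)
    attempts = 0
    while len(cuts) < n_extra + 4 * len(repeats) and attempts < 10_000:
        attempts += 1
        c = int(rng.integers(0, n))
        if all(min(abs(c - x), n - abs(c - x)) >= cfg.min_contig for x in cuts):
            if not any(s < c < e for s, e, _, _ in repeat_ivs):
                cuts.add(c)
    boundaries = sorted(cuts) or [0]
    segments: list[tuple[int, int]] = []
    for i, b in enumerate(boundaries):
        e = boundaries[(i + 1) % len(boundaries)]
        segments.append((b, e))  # last one wraps
    # --- contigs: merge repeat-pair copies into one contig
    seg_contig: dict[tuple[int, int], tuple[str, int]] = {}  # seg -> (id, sign)
    contigs: list[SimContig] = []
    links: list[tuple[str, str, str, str, int]] = []
    labels: dict[str, str] = {}
    by_pair: dict[str, str] = {}
    idx = 0

    def seg_seq(s0: int, s1: int) -> str:
        return g.seq[s0:s1] if s1 > s0 else g.seq[s0:] + g.seq[:s1]

    def depth_draw(lo: float) -> float:
        for _ in range(100):
            d = float(rng.normal(cfg.contig_mean_depth, cfg.depth_noise_sd))
            if d > lo:
                return round(d, 2)
        return lo + 1.0

    for s0, s1 in segments:
        rep = next(
            (r for r in repeat_ivs if r[0] == s0 and r[1] == s1), None
        )
        if rep is not None and rep[3] == "second":
            pair = next(p for p in repeats if p.pair_id == rep[2])
            cid = by_pair[rep[2]]
            sign = 1 if pair.orientation == "direct" else -1
            seg_contig[(s0, s1)] = (cid, sign)
            continue
        idx += 1
        cid = f"ctg{idx:03d}"
        seq = seg_seq(s0, s1)
        sign = 1
        if rep is None and rng.random() < 0.3:
            seq = revcomp(seq)  # emit in flipped orientation
            sign = -1
        if rep is not None:
            by_pair[rep[2]] = cid
            depth = depth_draw(cfg.depth_min) * 2
        else:
            depth = depth_draw(cfg.depth_min)
        if cfg.substitution_rate > 0:
            arr = list(seq)
            for i in range(len(arr)):
                if rng.random() < cfg.substitution_rate:
                    arr[i] = str(rng.choice([b for b in "ACGT" if b != arr[i]]))
            seq = "".join(arr)
        contigs.append(SimContig(id=cid, seq=seq, depth=depth, label="genuine"))
        labels[cid] = "genuine"
        seg_contig[(s0, s1)] = (cid, sign)

    def exit_end(sign: int) -> str:
        return "3'" if sign > 0 else "5'"

    def entry_end(sign: int) -> str:
        return "5'" if sign > 0 else "3'"

    walk: list[tuple[str, int]] = []
    for i, seg in enumerate(segments):
        nxt = segments[(i + 1) % len(segments)]
        c1, s1_ = seg_contig[seg]
        c2, s2_ = seg_contig[nxt]
        walk.append((c1, s1_))
        links.append((c1, exit_end(s1_), c2, entry_end(s2_), int(rng.integers(3, 30))))

    genuine_ids = [c.id for c in contigs]

    def random_end() -> tuple[str, str]:
        cid = str(rng.choice(genuine_ids))
        return cid, str(rng.choice(["5'", "3'"]))

    for d in range(cfg.n_dead_end):
        idx += 1
        cid = f"ctg{idx:03d}"
        length = int(rng.integers(cfg.min_contig // 2, cfg.min_contig * 2))
        contigs.append(
            SimContig(
                id=cid,
                seq=_random_seq(rng, length, cfg.gc),
                depth=round(float(rng.uniform(2, cfg.depth_min - 1)), 2),
                label="dead_end",
            )
        )
        labels[cid] = "dead_end"
        h, he = random_end()
        links.append((cid, "5'", h, he, int(rng.integers(1, 5))))

    if cfg.n_nuclear_contaminants > 0 and decoy is None:
        decoy = _random_seq(rng, 50_000, cfg.gc)
    for d in range(cfg.n_nuclear_contaminants):
        idx += 1
        cid = f"ctg{idx:03d}"
        length = int(rng.integers(cfg.min_contig // 2, cfg.min_contig * 2))
        start = int(rng.integers(0, len(decoy) - length))
        contigs.append(
            SimContig(
                id=cid,
                seq=decoy[start : start + length],
                depth=round(float(rng.uniform(2, cfg.depth_min - 1)), 2),
                label="nuclear",
            )
        )
        labels[cid] = "nuclear"
        h, he = random_end()
        links.append((cid, "5'", h, he, int(rng.integers(1, 5))))

    for d in range(cfg.n_low_depth_bridges):
        idx += 1
        cid = f"ctg{idx:03d}"
        length = int(rng.integers(cfg.min_contig // 2, cfg.min_contig * 2))
        contigs.append(
            SimContig(
                id=cid,
                seq=_random_seq(rng, length, cfg.gc),
                depth=round(float(rng.uniform(2, cfg.depth_min - 1)), 2),
                label="low_depth",
            )
        )
        labels[cid] = "low_depth"
        h1, he1 = random_end()
        h2, he2 = random_end()
        links.append((cid, "5'", h1, he1, int(rng.integers(1, 5))))
        links.append((cid, "3'", h2, he2, int(rng.integers(1, 5))))

    truth = TruthRecord(
        parent_id=g.id,
        derived_id=f"{g.id}-contigs",
        labels=labels,
        walk=walk,
    )
    return contigs, links, truth


# ---------------------------------------------------------------------------
# Marker panels


def simulate_marker_panel(
    markers: Sequence[str],
    n_accessions: int,
    seed: int,
    frequencies: dict[str, float] | None = None,
    reference_profiles: dict[str, dict[str, bool]] | None = None,
) -> pd.DataFrame:
    """Binary presence/absence matrix over a marker panel.

    Each marker is drawn Bernoulli per accession with its configured
    frequency (default 0.2).  ``reference_profiles`` rows (e.g. the CMS
    lines themselves) are appended verbatim after the random accessions.
    """
    if not markers:
        raise ValueError("at least one marker required")
    if n_accessions <= 0:
        raise ValueError("zero accessions")
    rng = np.random.default_rng(seed)
    freqs = {m: (frequencies or {}).get(m, 0.2) for m in markers}
    rows = {}
    for i in range(n_accessions):
        acc = f"acc{i + 1:03d}"
        rows[acc] = [bool(rng.random() < freqs[m]) for m in markers]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(markers))
    if reference_profiles:
        ref = pd.DataFrame.from_dict(
            {k: [bool(v[m]) for m in markers] for k, v in reference_profiles.items()},
            orient="index",
            columns=list(markers),
        )
        df = pd.concat([df, ref])
    return df


# ---------------------------------------------------------------------------
# Writers


def write_contig_set(
    contigs: Sequence[SimContig],
    links: Sequence[tuple[str, str, str, str, int]],
    truth: TruthRecord,
    outdir: str | Path,
) -> None:
    """contigs FASTA + depth TSV + links TSV + truth JSON in one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "contigs.fasta", "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.seq), 70):
                fh.write(c.seq[i : i + 70] + "\n")
    with open(outdir / "depth.tsv", "w") as fh:
        fh.write("contig_id\tdepth\n")
        for c in contigs:
            fh.write(f"{c.id}\t{c.depth}\n")
    with open(outdir / "links.tsv", "w") as fh:
        fh.write("contig_id_1\tend_1\tcontig_id_2\tend_2\tsupport_count\n")
        for c1, e1, c2, e2, sup in links:
            fh.write(f"{c1}\t{e1}\t{c2}\t{e2}\t{sup}\n")
    (outdir / "truth.json").write_text(truth.to_json())
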