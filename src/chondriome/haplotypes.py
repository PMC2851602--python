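"""In-silico PCR marker assays and binary-profile haplogrouping.

A marker is either a primer pair assayed against a genome sequence
(``in_silico_pcr``) or a precomputed presence/absence column.  Accessions
with identical presence/absence vectors over a marker panel form one
haplogroup; groups are lettered A, B, C, ... in order of first appearance,
while designated reference profiles (e.g. the CMS lines themselves) keep
their own names and are excluded from lettering.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd

from .genome import CircularGenome, Interval, revcomp

__all__ = [
    "Marker",
    "MarkerProfile",
    "Haplogroup",
    "in_silico_pcr",
    "profile_genome",
    "group_profiles",
    "marker_concordance",
    "uniqueness_report",
    "load_reference_panel",
    "read_profile_matrix",
    "write_profile_matrix",
]


@dataclass(frozen=True)
class Marker:
    name: str
    forward: str
    reverse: str
    max_product: int = 3000

    def __post_init__(self) -> None:
        if len(self.forward) < 15 or len(self.reverse) < 15:
            raise ValueError(f"marker {self.name}: primers must be >= 15 nt")


@dataclass
class MarkerProfile:
    accession: str
    presence: tuple[bool, ...]


@dataclass
class Haplogroup:
    label: str
    pattern: tuple[bool, ...]
    members: list[str]


# ---------------------------------------------------------------------------
# In-silico PCR


def _find_all(hay: str, needle: str) -> list[int]:
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def in_silico_pcr(
    g: CircularGenome, m: Marker, max_mismatch: int = 0
) -> list[Interval]:
    """Predicted amplicons of a primer pair on a (circular) genome.

    An amplicon requires the forward primer and the reverse complement of
    the reverse primer to occur convergently within ``max_product`` bp,
    wrap-aware.  Matching is exact (``max_mismatch`` is reserved for a
    tolerant mode and currently must be 0).
    """
    if max_mismatch != 0:
        raise NotImplementedError("only exact primer matching is supported")
    n = len(g)
    target = g.seq + g.seq if g.is_circular else g.seq
    products: set[tuple[int, int]] = set()
    for top, fwd, rev in (
        (target, m.forward, m.reverse),
        (target, revcomp(m.reverse), revcomp(m.forward)),
    ):
        rc = revcomp(rev)  # where the reverse primer binds the bottom strand
        f_sites = [i for i in _find_all(top, fwd) if i < n or not g.is_circular]
        r_sites = _find_all(top, rc)
        for i in f_sites:
            for j in r_sites:
                if j < i:
                    continue
                end = j + len(rc)
                size = end - i
                if 0 < size <= m.max_product:
                    products.add((i % n if g.is_circular else i, size))
    out = []
    for start, size in sorted(products):
        end = start + size
        wraps = g.is_circular and end > n
        out.append(Interval(start, end % n if wraps else end, "+", wraps))
    # deduplicate identical circular images
    uniq = {(iv.start, iv.end, iv.wraps): iv for iv in out}
    return list(uniq.values())


def profile_genome(
    g: CircularGenome, markers: Sequence[Marker]
) -> MarkerProfile:
    """Presence/absence vector of a genome over a primer-pair panel."""
    return MarkerProfile(
        accession=g.id,
        presence=tuple(bool(in_silico_pcr(g, m)) for m in markers),
    )


# ---------------------------------------------------------------------------
# Haplogrouping


def group_profiles(
    profiles: Sequence[MarkerProfile],
    reference_names: Sequence[str] = (),
) -> list[Haplogroup]:
    """Exact-pattern grouping of presence/absence profiles.

    Non-reference groups are labelled A, B, ... by first appearance in
    input order.  Profiles whose accession is in ``reference_names`` keep
    that name as their group label and never receive a letter, even when
    an ordinary accession shares their pattern.
    """
    sizes = {len(p.presence) for p in profiles}
    if len(sizes) > 1:
        raise ValueError(f"mixed panel sizes: {sorted(sizes)}")
    refs = set(reference_names)
    groups: dict[tuple[bool, ...], Haplogroup] = {}
    order: list[tuple[bool, ...]] = []
    # reference profiles claim their patterns first
    for p in profiles:
        if p.accession in refs and p.presence not in groups:
            groups[p.presence] = Haplogroup(p.accession, p.presence, [])
            order.append(p.presence)
    letter = 0
    for p in profiles:
        if p.presence not in groups:
            label = _letter_label(letter)
            letter += 1
            groups[p.presence] = Haplogroup(label, p.presence, [])
            order.append(p.presence)
        groups[p.presence].members.append(p.accession)
    return [groups[pat] for pat in order]


def _letter_label(i: int) -> str:
    label = ""
    while True:
        label = chr(ord("A") + i % 26) + label
        i = i // 26 - 1
        if i < 0:
            return label


def marker_concordance(
    profiles: Sequence[MarkerProfile],
    panel: Sequence[str],
    a: str,
    b: str,
) -> tuple[float, list[str]]:
    """Agreement between two markers: fraction of accessions where the
    presence calls coincide, plus the discordant accession ids."""
    try:
        ia, ib = panel.index(a), panel.index(b)
    except ValueError as exc:
        raise KeyError(f"unknown marker: {exc}") from exc
    exceptions = [
        p.accession for p in profiles if p.presence[ia] != p.presence[ib]
    ]
    frac = 1.0 - len(exceptions) / len(profiles) if profiles else 1.0
    return frac, exceptions


def uniqueness_report(
    profiles: Sequence[MarkerProfile],
    panel: Sequence[str],
    reference_names: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-marker summary: positive count/fraction among ordinary
    accessions and whether the marker is exclusive to reference profiles."""
    refs = set(reference_names)
    ordinary = [p for p in profiles if p.accession not in refs]
    rows = []
    for i, name in enumerate(panel):
        pos = [p.accession for p in ordinary if p.presence[i]]
        ref_pos = [p.accession for p in profiles if p.accession in refs and p.presence[i]]
        rows.append(
            {
                "marker": name,
                "n_positive": len(pos),
                "fraction_positive": len(pos) / len(ordinary) if ordinary else 0.0,
                "positive_references": ",".join(ref_pos),
                "exclusive_to_reference": bool(ref_pos) and not pos,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Profile matrix I/O and the bundled reference panel


def read_profile_matrix(path) -> tuple[list[str], list[MarkerProfile]]:
    """Read an accessions x markers +/- (or 1/0) TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    panel = list(df.columns)
    profiles = [
        MarkerProfile(
            accession=str(acc),
            presence=tuple(v in ("+", "1", "True", "true") for v in row),
        )
        for acc, row in df.iterrows()
    ]
    return panel, profiles


def write_profile_matrix(
    panel: Sequence[str], profiles: Sequence[MarkerProfile], path
) -> None:
    df = pd.DataFrame(
        [["+" if v else "-" for v in p.presence] for p in profiles],
        index=[p.accession for p in profiles],
        columns=list(panel),
    )
    df.to_csv(path, sep="\t", index_label="accession")


def load_reference_panel() -> tuple[list[str], list[MarkerProfile]]:
    """The published nine-marker presence/absence patterns of the rice
    mitochondrial haplogroup survey (12 cultivar/wild haplogroups plus the
    two CMS reference lines)."""
    ref = resources.files("chondriome.data").joinpath("rice_haplogroup_patterns.tsv")
    with resources.as_file(ref) as path:
        return read_profile_matrix(path)
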