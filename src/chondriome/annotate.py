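"""Gene search, coding variants, ORF prediction, chimeras, SNP panels.

The annotation layer answers five questions about a (re)assembled
mitochondrial genome:

* which catalog genes are present, partial, absent or pseudo
  (``locate_catalog_genes``);
* what coding changes a present gene carries, classified synonymous /
  non-synonymous per codon under the standard genetic code
  (``call_coding_variants``) — two point mutations inside one codon are
  reported as a single amino-acid change such as ``R144G``;
* what ORFs of at least 70 codons the genome encodes in six frames,
  wrap-aware (``find_orfs``);
* which of those ORFs are novel chimeras stitched from fragments of known
  genes plus sequence of unknown origin — the classic anatomy of
  CMS-associated candidate genes (``detect_chimeras``);
* how the genome genotypes at a panel of known SNP/indel sites defined by
  flanking sequences (``genotype_snp_panel``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
from Bio import Align
from Bio.Seq import Seq

from .genome import CircularGenome, GeneModel, Interval, revcomp
from .synteny import _linear_mems

__all__ = [
    "GeneHit",
    "CodingVariant",
    "OrfCall",
    "ChimeraCall",
    "SnpPanelSite",
    "locate_catalog_genes",
    "call_coding_variants",
    "find_orfs",
    "detect_chimeras",
    "genotype_snp_panel",
]


@dataclass
class GeneHit:
    gene: str
    status: str  # present | partial | absent | pseudo
    location: Interval | None
    identity: float
    covered_fraction: float
    note: str = ""


@dataclass
class CodingVariant:
    gene: str
    cds_position: int  # 0-based position of the first changed base
    ref: str
    alt: str
    effect: str  # synonymous | nonsynonymous | indel
    aa_label: str = ""
    n_snp: int = 0

    def __post_init__(self) -> None:
        if (self.effect == "nonsynonymous") != bool(self.aa_label):
            raise ValueError("aa_label present iff effect is nonsynonymous")


@dataclass
class OrfCall:
    location: Interval
    strand: str
    length_aa: int
    protein: str
    nt_seq: str = ""


@dataclass
class ChimeraCall:
    orf: OrfCall
    segments: list[tuple[tuple[int, int], str, float]]  # (orf interval, gene|unknown, identity)
    novel: bool = True


@dataclass
class SnpPanelSite:
    site_id: str
    left_flank: str
    right_flank: str
    alleles: dict[str, str]  # named genome -> allele (may be "" for deletions)


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 2
_aligner.mismatch_score = -3
_aligner.open_gap_score = -6
_aligner.extend_gap_score = -1

_local = Align.PairwiseAligner()
_local.mode = "local"
_local.match_score = 2
_local.mismatch_score = -3
_local.open_gap_score = -6
_local.extend_gap_score = -1


# ---------------------------------------------------------------------------
# Catalog gene search


def _cluster_anchors(
    mems: list[tuple[int, int, int]], gene_len: int
) -> list[list[tuple[int, int, int]]]:
    """Group gene-vs-genome exact matches into loci by diagonal proximity."""
    clusters: list[list[tuple[int, int, int]]] = []
    for qi, si, length in sorted(mems, key=lambda t: t[1]):
        d = si - qi
        placed = False
        for cl in clusters:
            lqi, lsi, ll = cl[-1]
            if abs((lsi - lqi) - d) <= gene_len and 0 <= si - (lsi + ll) <= 2 * gene_len:
                cl.append((qi, si, length))
                placed = True
                break
        if not placed:
            clusters.append([(qi, si, length)])
    return clusters


def _align_identity(cds: str, window: str) -> tuple[float, float, tuple[int, int]]:
    """(identity, covered_fraction, covered cds span) of cds vs a window."""
    if not window:
        return 0.0, 0.0, (0, 0)
    aln = _local.align(cds, window)[0]
    qa, sa = str(aln[0]), str(aln[1])
    q0 = aln.aligned[0][0][0] if len(aln.aligned[0]) else 0
    q1 = aln.aligned[0][-1][1] if len(aln.aligned[0]) else 0
    matched = sum(1 for a, b in zip(qa, sa) if a == b and a != "-")
    aligned = sum(1 for a, b in zip(qa, sa) if a != "-" and b != "-")
    identity = matched / aligned if aligned else 0.0
    covered = (q1 - q0) / len(cds)
    return identity, covered, (q0, q1)


def _frame_intact(hit_seq: str) -> bool:
    if len(hit_seq) < 6 or len(hit_seq) % 3 != 0:
        return False
    if not hit_seq.startswith("ATG"):
        return False
    prot = str(Seq(hit_seq).translate())
    return "*" not in prot[:-1] and prot.endswith("*")


def locate_catalog_genes(
    g: CircularGenome,
    catalog: Sequence[GeneModel],
    present_cov: float = 0.98,
    min_identity: float = 0.95,
    seed_len: int = 20,
) -> list[GeneHit]:
    """Locate every catalog gene in a genome and classify its status.

    Anchored search: exact seed matches between the CDS and the doubled
    genome (both strands) are clustered into candidate loci; each locus is
    re-aligned to compute identity and coverage.  ``present`` requires
    coverage >= ``present_cov``, identity >= ``min_identity`` and, for
    protein genes, an intact reading frame.  Multi-copy genes yield one
    hit per locus.  Partial hits are annotated with the missing terminus.
    """
    n = len(g)
    doubled = g.seq + g.seq if g.is_circular else g.seq
    hits: list[GeneHit] = []
    for gene in catalog:
        cds = gene.cds_seq
        loci: list[GeneHit] = []
        for strand in "+-":
            target = doubled if strand == "+" else revcomp(doubled)
            mems = [
                m
                for m in _linear_mems(cds, target, min(seed_len, len(cds)))
                if m[1] % n < n  # all, but normalise below
            ]
            # suppress doubled-sequence duplicates: keep loci starting in 1st copy
            mems = [m for m in mems if m[1] < len(target) - n or not g.is_circular]
            for cl in _cluster_anchors(mems, len(cds)):
                s_lo = min(si for _, si, _ in cl)
                s_hi = max(si + L for _, si, L in cl)
                margin = len(cds) // 4 + 30
                w0, w1 = max(0, s_lo - margin), min(len(target), s_hi + margin)
                window = target[w0:w1]
                identity, covered, (q0, q1) = _align_identity(cds, window)
                if covered * len(cds) < seed_len:
                    continue
                if strand == "+":
                    loc0 = (w0) % n if g.is_circular else w0
                else:
                    loc0 = (len(target) - w1) % n if g.is_circular else 0
                end = loc0 + (w1 - w0)
                wraps = g.is_circular and end > n
                iv = Interval(loc0, end % n if wraps else end, strand, wraps)
                if gene.kind == "pseudo":
                    status = "pseudo"
                elif covered >= present_cov and identity >= min_identity:
                    status = "present"
                    if gene.kind == "protein":
                        hit_seq = _hit_cds(cds, window)
                        if hit_seq is not None and not _frame_intact(hit_seq):
                            status = "partial"
                else:
                    status = "partial"
                note = ""
                if status == "partial":
                    if q0 >= 30:
                        note = "N-terminal deletion"
                    elif len(cds) - q1 >= 30:
                        note = "C-terminal deletion"
                loci.append(
                    GeneHit(
                        gene=gene.name,
                        status=status,
                        location=iv,
                        identity=round(identity, 4),
                        covered_fraction=round(covered, 4),
                        note=note,
                    )
                )
        # deduplicate loci that are images of each other (same span)
        uniq: dict[tuple, GeneHit] = {}
        for h in loci:
            key = (h.location.start, h.location.end, h.location.strand)
            if key not in uniq or h.covered_fraction > uniq[key].covered_fraction:
                uniq[key] = h
        loci = sorted(uniq.values(), key=lambda h: -h.covered_fraction)
        if not loci:
            hits.append(GeneHit(gene.name, "absent", None, 0.0, 0.0))
        else:
            hits.extend(loci)
    return hits


def _hit_cds(cds: str, window: str) -> str | None:
    """Extract the genome-side sequence aligned to the full CDS, if any."""
    aln = _local.align(cds, window)[0]
    blocks_q, blocks_s = aln.aligned
    if not len(blocks_q):
        return None
    s0 = blocks_s[0][0] - blocks_q[0][0]
    s1 = blocks_s[-1][1] + (len(cds) - blocks_q[-1][1])
    if s0 < 0 or s1 > len(window):
        return None
    return window[s0:s1]


# ---------------------------------------------------------------------------
# Coding variants


def call_coding_variants(ref_gene: GeneModel, hit_seq: str) -> list[CodingVariant]:
    """Classify coding differences between a reference CDS and its hit.

    The two sequences are globally aligned; mismatches are grouped per
    codon and each affected codon is translated on both sides.  Codons
    altered by several point mutations yield a single variant (with
    ``n_snp`` recording the underlying SNP count).  In-frame gap runs are
    reported as ``indel`` variants; a frame-breaking gap run flags the
    whole gene and suppresses per-codon calls.
    """
    if ref_gene.kind != "protein":
        raise ValueError("coding variants are defined for protein genes")
    ref = ref_gene.cds_seq
    hit_seq = hit_seq.upper()
    if ref == hit_seq:
        return []
    aln = _aligner.align(ref, hit_seq)[0]
    qa, sa = str(aln[0]), str(aln[1])
    # gap runs
    indels: list[tuple[int, str, str]] = []  # (ref pos, ref seg, alt seg)
    mismatches: list[tuple[int, str, str]] = []  # (ref pos, ref base, alt base)
    rpos = 0
    i = 0
    while i < len(qa):
        if qa[i] == "-" or sa[i] == "-":
            j = i
            while j < len(qa) and (qa[j] == "-" or sa[j] == "-"):
                j += 1
            rseg = qa[i:j].replace("-", "")
            aseg = sa[i:j].replace("-", "")
            indels.append((rpos, rseg, aseg))
            rpos += len(rseg)
            i = j
        else:
            if qa[i] != sa[i]:
                mismatches.append((rpos, qa[i], sa[i]))
            rpos += 1
            i += 1
    frame_broken = any((len(r) - len(a)) % 3 != 0 for _, r, a in indels)
    variants: list[CodingVariant] = []
    for pos, rseg, aseg in indels:
        variants.append(
            CodingVariant(
                gene=ref_gene.name,
                cds_position=pos,
                ref=rseg or "-",
                alt=aseg or "-",
                effect="indel",
                n_snp=0,
            )
        )
    if frame_broken:
        raise FrameshiftError(ref_gene.name, variants)
    by_codon: dict[int, list[tuple[int, str, str]]] = {}
    for pos, rb, ab in mismatches:
        by_codon.setdefault(pos // 3, []).append((pos, rb, ab))
    for codon_idx, muts in sorted(by_codon.items()):
        ref_codon = list(ref[codon_idx * 3 : codon_idx * 3 + 3])
        alt_codon = list(ref_codon)
        for pos, rb, ab in muts:
            alt_codon[pos % 3] = ab
        ref_aa = str(Seq("".join(ref_codon)).translate())
        alt_aa = str(Seq("".join(alt_codon)).translate())
        first = muts[0][0]
        if ref_aa == alt_aa:
            variants.append(
                CodingVariant(
                    gene=ref_gene.name,
                    cds_position=first,
                    ref="".join(rb for _, rb, _ in muts),
                    alt="".join(ab for _, _, ab in muts),
                    effect="synonymous",
                    n_snp=len(muts),
                )
            )
        else:
            variants.append(
                CodingVariant(
                    gene=ref_gene.name,
                    cds_position=first,
                    ref="".join(rb for _, rb, _ in muts),
                    alt="".join(ab for _, _, ab in muts),
                    effect="nonsynonymous",
                    aa_label=f"{ref_aa}{codon_idx + 1}{alt_aa}",
                    n_snp=len(muts),
                )
            )
    variants.sort(key=lambda v: v.cds_position)
    return variants


class FrameshiftError(ValueError):
    """Raised when an alignment contains a frame-breaking indel."""

    def __init__(self, gene: str, indels: list[CodingVariant]):
        super().__init__(f"frame-breaking indel in {gene}")
        self.gene = gene
        self.indels = indels


# ---------------------------------------------------------------------------
# ORF prediction


def find_orfs(g: CircularGenome, min_aa: int = 70) -> list[OrfCall]:
    """Six-frame ORF scan; ORFs below ``min_aa`` codons are ignored.

    An ORF runs from the first ATG after the previous in-frame stop to
    the next in-frame stop (one ORF per stop-to-stop span); its length in
    amino acids excludes the stop.  On circular genomes an ORF may wrap
    the origin once; a frame with no stop at all yields no calls.
    """
    n = len(g)
    calls: list[OrfCall] = []
    for strand in "+-":
        fwd = g.seq if strand == "+" else revcomp(g.seq)
        scan = fwd + fwd if g.is_circular else fwd
        for frame in range(3):
            stops = [
                i
                for i in range(frame, len(scan) - 2, 3)
                if scan[i : i + 3] in ("TAA", "TAG", "TGA")
            ]
            if not stops:
                continue
            spans: list[tuple[int, int]] = []
            if g.is_circular:
                first_real = [s for s in stops if s >= 3]  # span boundaries
                for a, b in zip(stops, stops[1:]):
                    if a >= n:
                        break
                    spans.append((a + 3, b))
                # span wrapping the origin: from last stop < n to first stop image >= n
                # is already covered because scan is doubled
            else:
                for a, b in zip([-3] + stops, stops + [None]):
                    if b is None:
                        break
                    spans.append((a + 3, b))
            for span_start, span_end in spans:
                if span_end - span_start < 3 * (min_aa + 1) - 3:
                    pass  # still need ATG search; cheap to check below
                sub = scan[span_start:span_end]
                atg = -1
                for k in range(0, len(sub) - 2, 3):
                    if sub[k : k + 3] == "ATG":
                        atg = k
                        break
                if atg < 0:
                    continue
                start = span_start + atg
                length_nt = span_end - start
                length_aa = length_nt // 3
                if length_aa < min_aa or (g.is_circular and length_nt >= n):
                    continue
                nt = scan[start : span_end + 3]
                prot = str(Seq(nt).translate())[:-1]
                if strand == "+":
                    s0 = start % n if g.is_circular else start
                    e0 = s0 + length_nt + 3
                else:
                    s0_rc = start % n if g.is_circular else start
                    # map back to forward coordinates
                    e_fwd = n - s0_rc if g.is_circular else len(fwd) - s0_rc
                    s0 = (e_fwd - (length_nt + 3)) % n if g.is_circular else e_fwd - (length_nt + 3)
                    e0 = s0 + length_nt + 3
                wraps = g.is_circular and e0 > n
                iv = Interval(s0, e0 % n if wraps else e0, strand, wraps)
                calls.append(
                    OrfCall(
                        location=iv,
                        strand=strand,
                        length_aa=length_aa,
                        protein=prot,
                        nt_seq=nt,
                    )
                )
    # deduplicate wrap images
    uniq: dict[tuple, OrfCall] = {}
    for c in calls:
        key = (c.location.start, c.location.end, c.strand)
        uniq.setdefault(key, c)
    return sorted(
        uniq.values(), key=lambda c: (c.location.start, c.location.end, c.strand)
    )


# ---------------------------------------------------------------------------
# Chimeras


def _present_in(genome: CircularGenome, seq: str, max_divergence: float = 0.01) -> bool:
    """Is ``seq`` present (near-)full-length in ``genome`` on either strand?"""
    target = genome.seq + genome.seq if genome.is_circular else genome.seq
    limit = int(max_divergence * len(seq))
    for t in (target, revcomp(target)):
        r = edlib.align(seq, t, mode="HW", task="distance", k=limit)
        if r["editDistance"] != -1:
            return True
    return False


def detect_chimeras(
    g: CircularGenome,
    reference_g: CircularGenome,
    catalog: Sequence[GeneModel],
    min_aa: int = 70,
    min_frag: int = 100,
    min_identity: float = 0.85,
) -> list[ChimeraCall]:
    """Novel chimeric ORFs: known-gene fragments fused to unknown sequence.

    Among ORFs of ``g`` absent from the reference genome (no full-length
    match at >= 99% identity), each ORF is decomposed into segments
    matching catalog genes at >= ``min_identity`` over >= ``min_frag`` bp
    plus unknown remainder.  A call is emitted when the ORF combines a
    known-gene fragment with unknown sequence, or fragments of two
    different genes.
    """
    calls: list[ChimeraCall] = []
    for orf in find_orfs(g, min_aa=min_aa):
        if _present_in(reference_g, orf.nt_seq):
            continue
        segments: list[tuple[tuple[int, int], str, float]] = []
        covered = [False] * len(orf.nt_seq)
        for gene in catalog:
            best: tuple[tuple[int, int], float] | None = None
            for cand in (gene.cds_seq, revcomp(gene.cds_seq)):
                aln = _local.align(cand, orf.nt_seq)[0]
                bq, bs = aln.aligned
                if not len(bq):
                    continue
                o0, o1 = int(bs[0][0]), int(bs[-1][1])
                if o1 - o0 < min_frag:
                    continue
                qa, sa = str(aln[0]), str(aln[1])
                matched = sum(1 for a, b in zip(qa, sa) if a == b and a != "-")
                aligned = sum(1 for a, b in zip(qa, sa) if a != "-" and b != "-")
                ident = matched / aligned if aligned else 0.0
                if ident < min_identity:
                    continue
                if best is None or (o1 - o0) > (best[0][1] - best[0][0]):
                    best = ((o0, o1), ident)
            if best is not None:
                (o0, o1), ident = best
                segments.append(((o0, o1), gene.name, round(ident, 4)))
                for i in range(o0, o1):
                    covered[i] = True
        # unknown remainder
        run_start = None
        for i, c in enumerate(covered + [True]):
            if not c and run_start is None:
                run_start = i
            elif c and run_start is not None:
                if i - run_start >= min_frag:
                    segments.append(((run_start, i), "unknown", 0.0))
                run_start = None
        gene_segs = [s for s in segments if s[1] != "unknown"]
        unknown_segs = [s for s in segments if s[1] == "unknown"]
        distinct_genes = {s[1] for s in gene_segs}
        if (gene_segs and unknown_segs) or len(distinct_genes) >= 2:
            segments.sort(key=lambda s: s[0])
            calls.append(ChimeraCall(orf=orf, segments=segments, novel=True))
    return calls


# ---------------------------------------------------------------------------
# SNP panel genotyping


_GENOME_CODE = {"93-11": "9", "Nipponbare": "n", "PA64S": "p"}
_JAPONICA = ("Nipponbare", "PA64S")


def _code_for(carriers: set[str], japonica: Sequence[str] = _JAPONICA) -> str:
    if not carriers:
        return "cms"
    if all(j in carriers for j in japonica):
        return "j"
    short = sorted(_GENOME_CODE.get(c, c) for c in carriers)
    return "/".join(short)


def genotype_snp_panel(
    g: CircularGenome, panel: Sequence[SnpPanelSite]
) -> tuple[dict[str, str], int]:
    """Genotype a genome at flank-defined variant sites.

    For each site the pattern left-flank + allele + right-flank is
    searched (both strands, wrap-aware) for every known allele; the code
    reflects which named reference genomes carry the observed allele
    (``j`` = both japonica genomes, ``9``/``n``/``p`` single genomes,
    ``cms`` = an allele none of them carries, ``-`` = flanks absent or
    ambiguous, i.e. no syntenic region present).  Also returns the number
    of detectable (non ``-``) sites.
    """
    target = g.seq + g.seq if g.is_circular else g.seq
    strands = (target, revcomp(target))
    codes: dict[str, str] = {}
    for site in panel:
        if not site.left_flank or not site.right_flank:
            raise ValueError(f"site {site.site_id}: malformed flanks")
        observed: set[str] = set()
        located = False
        for t in strands:
            # locate flank pair allowing any allele up to the longest known
            max_len = max((len(a) for a in site.alleles.values()), default=1) + 5
            start = 0
            while True:
                i = t.find(site.left_flank, start)
                if i == -1:
                    break
                start = i + 1
                if g.is_circular and i >= len(g):
                    continue
                j = t.find(
                    site.right_flank,
                    i + len(site.left_flank),
                    i + len(site.left_flank) + max_len + len(site.right_flank),
                )
                if j == -1:
                    continue
                located = True
                observed.add(t[i + len(site.left_flank) : j])
        if not located:
            codes[site.site_id] = "-"
            continue
        if len(observed) != 1:
            codes[site.site_id] = "-"
            continue
        allele = observed.pop()
        carriers = {gname for gname, a in site.alleles.items() if a == allele}
        codes[site.site_id] = _code_for(carriers)
    detectable = sum(1 for v in codes.values() if v != "-")
    return codes, detectable
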