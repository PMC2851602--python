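"""Gene status, coding variants, ORFs, chimeras, SNP-panel genotyping."""

import numpy as np
import pytest
from Bio.Seq import Seq

from chondriome.genome import CircularGenome, GeneModel, revcomp, rotate
from chondriome import annotate as ann
from chondriome import simulate as sim
from chondriome.simulate import _CODONS, _random_cds, _random_seq

from conftest import STOP_SPACER


def _gene_with_codon(seed, n_codons, idx, codon):
    """Protein gene whose 1-based codon ``idx`` is ``codon``."""
    rng = np.random.default_rng(seed)
    body = [_CODONS[int(i)] for i in rng.integers(0, len(_CODONS), n_codons - 2)]
    body[idx - 2] = codon  # codon 1 is the ATG
    return GeneModel("g", "protein", "ATG" + "".join(body) + "TAA")


class TestLocateCatalogGenes:
    def test_catalog_against_its_own_genome_all_present(self, small_reference):
        g, catalog, _ = small_reference
        hits = ann.locate_catalog_genes(g, catalog)
        assert all(h.status == "present" for h in hits)
        assert all(h.identity == 1.0 for h in hits)

    def test_n_terminal_deletion_reported_partial(self, small_reference):
        g, catalog, _ = small_reference
        gene = catalog[0]
        pos = g.seq.find(gene.cds_seq)
        if pos == -1:
            pos = g.seq.find(revcomp(gene.cds_seq))
        mutated = CircularGenome("del", g.seq[:pos] + g.seq[pos + 120 :])
        hits = [h for h in ann.locate_catalog_genes(mutated, catalog)
                if h.gene == gene.name]
        assert hits[0].status == "partial"
        assert "deletion" in hits[0].note

    def test_absent_gene_has_no_location(self, small_reference):
        g, catalog, _ = small_reference
        gene = catalog[0]
        pos = g.seq.find(gene.cds_seq)
        if pos == -1:
            pos = g.seq.find(revcomp(gene.cds_seq))
        gone = CircularGenome("gone", g.seq[:pos] + g.seq[pos + len(gene.cds_seq) :])
        hits = [h for h in ann.locate_catalog_genes(gone, catalog)
                if h.gene == gene.name]
        assert hits == [ann.GeneHit(gene.name, "absent", None, 0.0, 0.0)]

    def test_rotation_invariant_statuses(self, small_reference):
        g, catalog, _ = small_reference
        base = [(h.gene, h.status) for h in ann.locate_catalog_genes(g, catalog)]
        rot = [(h.gene, h.status)
               for h in ann.locate_catalog_genes(rotate(g, 12_345), catalog)]
        assert base == rot


class TestCodingVariants:
    def test_identical_cds_no_variants(self):
        gene = _gene_with_codon(1, 60, 10, "AAA")
        assert ann.call_coding_variants(gene, gene.cds_seq) == []

    def test_r144g_two_point_mutations_single_call(self):
        gene = _gene_with_codon(5, 200, 144, "AGG")  # Arg
        alt = list(gene.cds_seq)
        alt[143 * 3] = "G"
        alt[143 * 3 + 2] = "T"  # AGG -> GGT, Gly
        variants = ann.call_coding_variants(gene, "".join(alt))
        assert len(variants) == 1
        v = variants[0]
        assert v.effect == "nonsynonymous"
        assert v.aa_label == "R144G"
        assert v.n_snp == 2

    def test_adjacent_codon_changes_reported_separately(self):
        # two neighbouring codons altered -> two labelled calls (K183N, F184Y)
        gene = _gene_with_codon(6, 200, 183, "AAA")  # Lys
        cds = list(gene.cds_seq)
        cds[183 * 3 : 183 * 3 + 3] = "TTT"  # codon 184 -> Phe
        gene = GeneModel("rps2", "protein", "".join(cds))
        alt = list(gene.cds_seq)
        alt[182 * 3 + 2] = "C"  # AAA -> AAC, Asn
        alt[183 * 3 + 1] = "A"  # TTT -> TAT, Tyr
        variants = ann.call_coding_variants(gene, "".join(alt))
        labels = [v.aa_label for v in variants]
        assert labels == ["K183N", "F184Y"]

    def test_effects_agree_with_translation_oracle_exhaustively(self):
        gene = _gene_with_codon(7, 50, 25, "TGG")
        ref = gene.cds_seq
        ref_prot = str(Seq(ref).translate())
        for pos in range(3, len(ref)):  # skip the start codon itself
            for base in "ACGT":
                if base == ref[pos]:
                    continue
                mutated = ref[:pos] + base + ref[pos + 1 :]
                variants = ann.call_coding_variants(gene, mutated)
                assert len(variants) == 1
                expect = (
                    "synonymous"
                    if str(Seq(mutated).translate()) == ref_prot
                    else "nonsynonymous"
                )
                assert variants[0].effect == expect, (pos, base)

    def test_in_frame_indel_reported_frameshift_raises(self):
        gene = _gene_with_codon(8, 60, 20, "AAA")
        cds = gene.cds_seq
        inframe = ann.call_coding_variants(gene, cds[:30] + cds[33:])
        assert [v.effect for v in inframe] == ["indel"]
        with pytest.raises(ann.FrameshiftError):
            ann.call_coding_variants(gene, cds[:30] + cds[32:])


class TestFindOrfs:
    def test_stop_only_genome_has_no_orfs(self):
        g = CircularGenome("stops", "TAA" * 50)
        assert ann.find_orfs(g) == []

    def test_threshold_drops_69aa_orf(self):
        seq = (
            STOP_SPACER
            + _random_cds(np.random.default_rng(1), 81)  # 80 aa
            + STOP_SPACER
            + _random_cds(np.random.default_rng(2), 76)  # 75 aa
            + STOP_SPACER
            + _random_cds(np.random.default_rng(3), 70)  # 69 aa
            + STOP_SPACER
        )
        g = CircularGenome("planted", seq, topology="linear")
        lengths = sorted(c.length_aa for c in ann.find_orfs(g, min_aa=70))
        assert lengths == [75, 80]

    def test_wraps_origin_once(self):
        core = _random_cds(np.random.default_rng(4), 100)
        g = CircularGenome("wrap", core[150:] + STOP_SPACER + core[:150])
        plus = [c for c in ann.find_orfs(g, min_aa=70) if c.strand == "+"]
        assert any(c.location.wraps and c.length_aa == 99 for c in plus)

    def test_strand_symmetric(self):
        g = CircularGenome("sym", _random_seq(np.random.default_rng(5), 9_000, 0.44))
        fwd = sorted((c.length_aa, c.strand) for c in ann.find_orfs(g, min_aa=25))
        rc = sorted(
            (c.length_aa, {"+": "-", "-": "+"}[c.strand])
            for c in ann.find_orfs(CircularGenome("rc", revcomp(g.seq)), min_aa=25)
        )
        assert fwd == rc

    def test_agrees_with_bruteforce_scanner(self):
        for seed in range(4):
            g = CircularGenome(
                f"r{seed}", _random_seq(np.random.default_rng(seed), 5_000, 0.44)
            )
            got = sorted(
                (c.location.start, c.location.end, c.strand, c.length_aa)
                for c in ann.find_orfs(g, min_aa=30)
            )
            assert got == sorted(brute_force_orfs(g, 30))


def brute_force_orfs(g: CircularGenome, min_aa: int):
    """Independent six-frame scan: walk every position on both strands."""
    n = len(g)
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for strand in "+-":
        seq = g.seq if strand == "+" else revcomp(g.seq)

        def codon(p):
            return "".join(seq[(p + k) % n] for k in range(3))

        for p in range(n):
            if codon(p) != "ATG":
                continue
            # walk backwards by codons: valid start iff a stop comes before
            # any ATG (i.e. first ATG after the previous in-frame stop)
            ok = False
            q = (p - 3) % n
            for _ in range(n // 3 + 1):
                c = codon(q)
                if c in stops:
                    ok = True
                    break
                if c == "ATG":
                    break
                q = (q - 3) % n
            if not ok:
                continue
            # walk forward to the next stop
            length = None
            q = (p + 3) % n
            for steps in range(1, n // 3 + 1):
                if codon(q) in stops:
                    length = steps
                    break
                q = (q + 3) % n
            if length is None or length < min_aa or (length + 1) * 3 >= n:
                continue
            end_fwd = p + (length + 1) * 3
            if strand == "+":
                s0 = p
            else:
                s0 = (n - end_fwd) % n
            e0 = s0 + (length + 1) * 3
            wraps = e0 > n
            out.append((s0, e0 % n if wraps else e0, strand, length))
    return out


@pytest.fixture(scope="module")
def chimera_setup():
    cfg = sim.SimConfig(seed=42, genome_length=30_000, n_repeat_pairs=0, n_genes=5)
    ref, catalog, _ = sim.simulate_reference(cfg)
    return ref, catalog


class TestChimeras:
    @staticmethod
    def _chimeric_cds(frag: str, novel: str) -> str:
        merged = frag + novel
        codons = [merged[i : i + 3] for i in range(0, len(merged) // 3 * 3, 3)]
        codons = [c if c not in ("TAA", "TAG", "TGA") else "AAA" for c in codons]
        return "ATG" + "".join(codons) + "TAA"

    def test_known_gene_orf_is_not_a_chimera(self, chimera_setup):
        ref, catalog = chimera_setup
        assert ann.detect_chimeras(ref, ref, catalog) == []

    def test_planted_gene_fragment_plus_unknown(self, chimera_setup):
        ref, catalog = chimera_setup
        frag = catalog[0].cds_seq[:294]
        novel = _random_seq(np.random.default_rng(99), 630, 0.44)
        cds = self._chimeric_cds(frag, novel)
        host = CircularGenome(
            "host", ref.seq[:10_000] + STOP_SPACER + cds + STOP_SPACER + ref.seq[10_000:]
        )
        calls = ann.detect_chimeras(host, ref, catalog)
        assert len(calls) == 1
        names = [s[1] for s in calls[0].segments]
        assert catalog[0].name in names and "unknown" in names

    def test_all_planted_chimeras_found_no_false_calls(self):
        for seed in range(6):
            cfg = sim.SimConfig(seed=200 + seed, genome_length=25_000,
                                n_repeat_pairs=0, n_genes=6)
            ref, catalog, _ = sim.simulate_reference(cfg)
            rng = np.random.default_rng(300 + seed)
            inserts = []
            for i in range(5):
                gene = catalog[i % len(catalog)]
                frag = gene.cds_seq[: 150 + 30 * i]
                novel = _random_seq(rng, 400 + 40 * i, 0.44)
                inserts.append(self._chimeric_cds(frag, novel))
            # insertion points outside planted genes, applied in descending
            # order so earlier insertions do not shift later coordinates
            occupied = []
            for gene in catalog:
                at = int(gene.notes.split()[2])
                occupied.append((at - 200, at + len(gene.cds_seq) + 200))
            spots = []
            while len(spots) < 5:
                p = int(rng.integers(1_000, len(ref) - 1_000))
                if all(p <= a or p >= b for a, b in occupied):
                    occupied.append((p - 200, p + 200))
                    spots.append(p)
            host_seq = ref.seq
            for ins, at in zip(inserts, sorted(spots, reverse=True)):
                host_seq = host_seq[:at] + STOP_SPACER + ins + STOP_SPACER + host_seq[at:]
            host = CircularGenome("host", host_seq)
            # final coordinates of the inserted blocks
            regions = []
            shift = 0
            for ins, at in zip(inserts[::-1], sorted(spots)):
                block = len(STOP_SPACER) * 2 + len(ins)
                regions.append((at + shift, at + shift + block))
                shift += block
            calls = ann.detect_chimeras(host, ref, catalog)
            hit_regions = set()
            for c in calls:
                loc = c.orf.location
                inside = [
                    i for i, (a, b) in enumerate(regions)
                    if a <= loc.start and loc.end <= b
                ]
                # every call must sit inside a planted insert (no false calls
                # elsewhere; antisense ORFs nested in an insert may add calls)
                assert inside, f"seed {seed}: call outside planted loci at {loc}"
                hit_regions.update(inside)
            assert hit_regions == set(range(5)), f"seed {seed}: planted locus missed"


class TestSnpPanel:
    def _panel_from(self, g, positions, alt_of):
        sites = []
        for i, p in enumerate(positions):
            ref = g.seq[p]
            alt = alt_of(ref)
            sites.append(
                ann.SnpPanelSite(
                    f"s{i}",
                    g.seq[p - 30 : p],
                    g.seq[p + 1 : p + 31],
                    {"Nipponbare": ref, "PA64S": ref, "93-11": alt},
                )
            )
        return sites

    def test_reference_genome_codes_japonica_everywhere(self, small_reference):
        g, _, _ = small_reference
        panel = self._panel_from(g, [5_000, 9_000, 13_000],
                                 lambda r: "A" if r != "A" else "G")
        codes, det = ann.genotype_snp_panel(g, panel)
        assert det == 3
        assert set(codes.values()) == {"j"}

    def test_site_inside_deletion_reports_dash(self, small_reference):
        g, _, _ = small_reference
        panel = self._panel_from(g, [5_000], lambda r: "A" if r != "A" else "G")
        deleted = CircularGenome("d", g.seq[:4_000] + g.seq[7_000:])
        codes, det = ann.genotype_snp_panel(deleted, panel)
        assert codes == {"s0": "-"} and det == 0

    def test_planted_alleles_recovered(self, small_reference):
        g, _, _ = small_reference
        positions = [5_000, 9_000, 13_000]
        panel = self._panel_from(g, positions, lambda r: "A" if r != "A" else "G")
        seq = list(g.seq)
        seq[5_000] = panel[0].alleles["93-11"]  # 93-11 allele at site 0
        novel = "T" if g.seq[9_000] != "T" else "C"
        if novel == panel[1].alleles["93-11"]:
            novel = "C" if novel != "C" else "G"
        seq[9_000] = novel  # an allele no reference carries
        mutant = CircularGenome("m", "".join(seq))
        codes, det = ann.genotype_snp_panel(mutant, panel)
        assert codes["s0"] == "9"
        assert codes["s1"] == "cms"
        assert codes["s2"] == "j"
        assert det == 3
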